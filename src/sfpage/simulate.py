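"""Synthetic input generation with known ground truth.

Every external input the pipeline consumes can be emulated here:
candidate gene lists and age tables, ortholog-validation id sets,
genes x tissues expression matrices with planted tissue-specific genes,
STRING-style scored edge tables with planted interaction modules, and
per-gene polymorphism/divergence counts with a known true adaptive
fraction alpha.  Generators are pure functions of (parameters, seed)
and return both the emitted tables and a truth record sufficient to
score recovery without re-inspecting generator internals.

The ``paper_like_bundle`` preset reproduces the marginal structure of
the study system this package models: a catalog of 357 genes (228
shared between the two source lists, one unaged pseudogene), age-class
counts (220, 36, 36, 28, 36) for A..E, 31 adult tissues, interaction
modules of sizes (64, 13, 6, 5, 5, 5) over 98 networked genes among 163
with any interaction data, and two population samples for the
McDonald-Kreitman layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json

import numpy as np
import pandas as pd

from .catalog import AGE_CLASSES
from .mkt import SiteCounts
from .network import CHANNELS
from .stats import seeded_rng

__all__ = [
    "CatalogBundle",
    "ExpressionBundle",
    "NetworkBundle",
    "MKTBundle",
    "gen_catalog",
    "gen_expression",
    "gen_network",
    "gen_mkt_counts",
    "paper_like_bundle",
    "write_bundle",
    "PAPER_LIKE_CLASS_COUNTS",
    "PAPER_LIKE_BLOCK_SIZES",
    "DEFAULT_CLASS_PROPS",
    "DEFAULT_BACKGROUND_PROPS",
]

#: Age-class counts of the aged catalog in the paper-like preset (A..E).
PAPER_LIKE_CLASS_COUNTS: tuple[int, ...] = (220, 36, 36, 28, 36)

#: Subnetwork block sizes in the paper-like preset.
PAPER_LIKE_BLOCK_SIZES: tuple[int, ...] = (64, 13, 6, 5, 5, 5)

#: Catalog age-class proportions (A..E) used when counts are not given.
DEFAULT_CLASS_PROPS: tuple[float, ...] = (0.62, 0.10, 0.10, 0.08, 0.10)

#: Genome-wide background proportions used by the preset: ancient genes
#: dominate the genome far more than they dominate the gene set, so the
#: set looks young against this background.
DEFAULT_BACKGROUND_PROPS: tuple[float, ...] = (0.866, 0.040, 0.034, 0.025, 0.035)

#: Tissue panel: two male-reproductive-gland columns plus generic parts.
MRG_TISSUES: tuple[str, ...] = ("male_accessory_gland", "male_ejaculatory_duct")


def _gene_ids(n: int, prefix: str = "SFP") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# catalog


@dataclass(frozen=True)
class CatalogBundle:
    list_a: list[str]
    list_b: list[str]
    age_table: dict[str, str]
    exceptions: frozenset[str]
    ortholog_ids: list[str]
    ancient_candidate_ids: list[str]
    truth: dict


def gen_catalog(
    n: int = 357,
    class_props: Sequence[float] = DEFAULT_CLASS_PROPS,
    overlap: float = 228 / 357,
    seed: int = 0,
    class_counts: Sequence[int] | None = None,
    n_exceptions: int = 0,
    n_checked: int | None = None,
    n_discrepant: int = 0,
    n_ancient_candidates: int = 0,
    n_ancient_class_a: int = 0,
) -> CatalogBundle:
    """Generate two candidate lists, an age table, and validation id sets.

    ``overlap`` fixes |A intersect B| = round(overlap * n); the
    non-shared remainder is split equally between the lists.  Age
    classes follow a multinomial over ``class_props`` unless exact
    ``class_counts`` (A..E) are supplied.  ``n_exceptions`` genes are
    omitted from the age table (declared exceptions, e.g. pseudogenes).
    Optionally plants an ortholog-validation set of ``n_checked`` genes
    of which exactly ``n_discrepant`` sit in young classes (D/E), and an
    "ancient candidate" set with a fixed class-A share.
    """
    if n < 2:
        raise ValueError("need at least two genes")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    props = np.asarray(class_props, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    rng = seeded_rng(seed, "gen_catalog")
    ids = _gene_ids(n)

    # source-list membership
    n_shared = int(round(overlap * n))
    order = list(rng.permutation(ids))
    shared = order[:n_shared]
    rest = order[n_shared:]
    a_only = rest[: (len(rest) + 1) // 2]
    b_only = rest[(len(rest) + 1) // 2 :]
    list_a = sorted(shared + a_only)
    list_b = sorted(shared + b_only)

    # age classes (exceptions stay out of the table)
    exception_ids = sorted(rng.choice(ids, size=n_exceptions, replace=False)) if n_exceptions else []
    aged_ids = [g for g in ids if g not in set(exception_ids)]
    if class_counts is not None:
        counts = list(class_counts)
        if sum(counts) != len(aged_ids):
            raise ValueError(
                f"class_counts sum to {sum(counts)}, but {len(aged_ids)} genes need ages"
            )
    else:
        counts = list(rng.multinomial(len(aged_ids), props))
    shuffled = list(rng.permutation(aged_ids))
    age_table: dict[str, str] = {}
    pos = 0
    for cls, k in zip(AGE_CLASSES, counts):
        for g in shuffled[pos : pos + k]:
            age_table[g] = cls
        pos += k

    by_class: dict[str, list[str]] = {c: [] for c in AGE_CLASSES}
    for g, c in age_table.items():
        by_class[c].append(g)
    for c in AGE_CLASSES:
        by_class[c].sort()

    # planted ortholog-validation set: old-class members plus known discrepancies
    ortholog_ids: list[str] = []
    if n_checked:
        old_pool = by_class["A"] + by_class["B"] + by_class["C"]
        young_pool = by_class["D"] + by_class["E"]
        n_old = n_checked - n_discrepant
        if n_old > len(old_pool) or n_discrepant > len(young_pool):
            raise ValueError("not enough genes to plant the requested validation set")
        ortholog_ids = sorted(rng.choice(old_pool, size=n_old, replace=False)) + sorted(
            rng.choice(young_pool, size=n_discrepant, replace=False)
        )

    # planted "very ancient candidate" set with a fixed class-A share
    ancient_ids: list[str] = []
    if n_ancient_candidates:
        non_a = [g for c in AGE_CLASSES[1:] for g in by_class[c]]
        n_non_a = n_ancient_candidates - n_ancient_class_a
        if n_ancient_class_a > len(by_class["A"]) or n_non_a > len(non_a):
            raise ValueError("not enough genes to plant the requested candidate set")
        ancient_ids = sorted(rng.choice(by_class["A"], size=n_ancient_class_a, replace=False)) + sorted(
            rng.choice(non_a, size=n_non_a, replace=False)
        )

    truth = {
        "seed": seed,
        "n": n,
        "n_shared": n_shared,
        "class_counts": {c: int(k) for c, k in zip(AGE_CLASSES, counts)},
        "exception_ids": exception_ids,
        "n_checked": len(ortholog_ids),
        "n_discrepant": n_discrepant if ortholog_ids else 0,
        "n_ancient_candidates": len(ancient_ids),
        "n_ancient_class_a": n_ancient_class_a if ancient_ids else 0,
    }
    return CatalogBundle(
        list_a=list_a,
        list_b=list_b,
        age_table=age_table,
        exceptions=frozenset(exception_ids),
        ortholog_ids=ortholog_ids,
        ancient_candidate_ids=ancient_ids,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class ExpressionBundle:
    matrix: pd.DataFrame  # genes x tissues
    truth: dict


def gen_expression(
    gene_ids: Sequence[str] | int,
    n_tissues: int = 31,
    p_specific: float | Mapping[str, float] = 0.5,
    p_target: float = 0.8,
    fg_level: float = 500.0,
    bg_level: float = 0.5,
    noise_cv: float = 0.2,
    target_tissues: Sequence[str] = MRG_TISSUES,
    seed: int = 0,
) -> ExpressionBundle:
    """Expression matrix with a planted fraction of tissue-specific genes.

    A planted-specific gene expresses at ``fg_level`` in one peak tissue
    (drawn from ``target_tissues`` with probability ``p_target``, else
    uniformly elsewhere) and ``bg_level`` everywhere else; nonspecific
    genes sit at ``bg_level`` throughout.  Multiplicative lognormal
    noise with coefficient of variation ``noise_cv`` is applied to all
    positive entries.  ``p_specific`` may be a scalar or a per-gene
    mapping (e.g. to make planted specificity depend on age class).
    """
    if isinstance(gene_ids, int):
        gene_ids = _gene_ids(gene_ids)
    gene_ids = list(gene_ids)
    if fg_level <= bg_level or bg_level < 0:
        raise ValueError("need fg_level > bg_level >= 0")
    tissues = list(target_tissues) + [
        f"tissue_{i + 1:02d}" for i in range(n_tissues - len(target_tissues))
    ]
    if len(tissues) != n_tissues:
        raise ValueError("n_tissues smaller than the target tissue panel")
    rng = seeded_rng(seed, "gen_expression")
    sigma = np.sqrt(np.log1p(noise_cv**2))
    values = np.full((len(gene_ids), n_tissues), bg_level, dtype=float)
    planted: dict[str, dict] = {}
    target_idx = list(range(len(target_tissues)))
    other_idx = list(range(len(target_tissues), n_tissues))
    for i, g in enumerate(gene_ids):
        p = p_specific[g] if isinstance(p_specific, Mapping) else p_specific
        is_specific = bool(rng.random() < p)
        peak = None
        if is_specific:
            if target_idx and rng.random() < p_target:
                peak = int(rng.choice(target_idx))
            else:
                peak = int(rng.choice(other_idx if other_idx else target_idx))
            values[i, peak] = fg_level
        planted[g] = {
            "specific": is_specific,
            "peak_tissue": tissues[peak] if peak is not None else None,
            "target_specific": is_specific and peak in target_idx,
        }
    if noise_cv > 0:
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=values.shape)
        values = values * noise
    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=tissues)
    truth = {
        "seed": seed,
        "tissues": tissues,
        "target_tissues": list(target_tissues),
        "fg_level": fg_level,
        "bg_level": bg_level,
        "noise_cv": noise_cv,
        "genes": planted,
    }
    return ExpressionBundle(matrix=matrix, truth=truth)


# ---------------------------------------------------------------------------
# interaction network


@dataclass(frozen=True)
class NetworkBundle:
    edges: pd.DataFrame
    sfp_ids: list[str]
    blocks: list[list[str]]
    truth: dict


def _edge_rows(
    pairs: Iterable[tuple[str, str]],
    rng: np.random.Generator,
    kind: str,
) -> list[dict]:
    """Channel-score rows for edges of a given confidence kind.

    ``high``: experiments alone clears the 0.7 threshold; ``weak``: a
    single mid-range channel that stays below it; ``textmining``: strong
    text-mining evidence only, so the edge survives only if text mining
    is *not* excluded.
    """
    rows = []
    for a, b in pairs:
        scores = dict.fromkeys(CHANNELS, 0.0)
        if kind == "high":
            scores["experiments"] = float(rng.uniform(0.75, 0.97))
            scores["database"] = float(rng.uniform(0.0, 0.9))
            scores["coexpression"] = float(rng.uniform(0.0, 0.4))
        elif kind == "weak":
            scores[str(rng.choice(["experiments", "coexpression", "database"]))] = float(
                rng.uniform(0.15, 0.55)
            )
        elif kind == "textmining":
            scores["textmining"] = float(rng.uniform(0.85, 0.99))
        else:  # pragma: no cover
            raise ValueError(kind)
        rows.append({"protein1": a, "protein2": b, **scores})
    return rows


def gen_network(
    block_sizes: Sequence[int] = PAPER_LIKE_BLOCK_SIZES,
    p_in: float = 0.25,
    p_out: float = 0.0,
    n_nonsfp: int = 100,
    p_cross: float = 0.0,
    sfp_ids: Sequence[str] | None = None,
    blocks: Sequence[Sequence[str]] | None = None,
    small_component_sizes: Sequence[int] = (),
    n_peripheral: int = 0,
    n_weak: int = 0,
    n_textmining_decoys: int = 0,
    seed: int = 0,
) -> NetworkBundle:
    """Planted-partition Sfp interaction graph with STRING-style scores.

    Blocks (the planted subnetworks) receive high-confidence within-block
    edges with probability ``p_in`` on top of a random spanning tree, so
    each block is connected whenever ``p_in > 0``.  Between-block edges
    appear with probability ``p_out`` and Sfp-to-non-Sfp edges with
    probability ``p_cross``.  ``small_component_sizes`` plants extra
    connected Sfp components below the reporting size; ``n_peripheral``
    Sfps interact only with non-Sfp partners; ``n_weak`` sub-threshold
    and ``n_textmining_decoys`` text-mining-only edges exercise score
    filtering.  If ``sfp_ids``/``blocks`` are not supplied they are
    generated.
    """
    if not 0.0 <= p_out <= p_in <= 1.0:
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    rng = seeded_rng(seed, "gen_network")
    if blocks is not None:
        blocks = [list(b) for b in blocks]
        block_sizes = [len(b) for b in blocks]
    n_block_genes = int(sum(block_sizes))
    n_small = int(sum(small_component_sizes))
    n_needed = n_block_genes + n_small + n_peripheral
    if sfp_ids is None:
        sfp_ids = _gene_ids(n_needed)
    sfp_ids = list(sfp_ids)
    if len(sfp_ids) < n_needed:
        raise ValueError(f"need at least {n_needed} sfp ids, got {len(sfp_ids)}")
    if blocks is None:
        blocks = []
        pos = 0
        for size in block_sizes:
            blocks.append(sfp_ids[pos : pos + size])
            pos += size
    else:
        unknown = {g for b in blocks for g in b} - set(sfp_ids)
        if unknown:
            raise ValueError(f"block members missing from sfp_ids: {sorted(unknown)[:5]}")
    # remaining sfp ids after block members
    block_members = {g for b in blocks for g in b}
    rest = [g for g in sfp_ids if g not in block_members]
    small_components: list[list[str]] = []
    pos = 0
    for size in small_component_sizes:
        small_components.append(rest[pos : pos + size])
        pos += size
    peripheral = rest[pos : pos + n_peripheral]
    nonsfp_ids = _gene_ids(n_nonsfp, prefix="NSP")

    def spanning_tree(members: Sequence[str]) -> list[tuple[str, str]]:
        order = list(rng.permutation(list(members)))
        return [
            (order[i], order[int(rng.integers(0, i))]) for i in range(1, len(order))
        ]

    high_pairs: list[tuple[str, str]] = []
    for members in list(blocks) + small_components:
        if len(members) < 2:
            continue
        high_pairs.extend(spanning_tree(members))
        members = list(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < p_in:
                    high_pairs.append((members[i], members[j]))
    if p_out > 0:
        for bi in range(len(blocks)):
            for bj in range(bi + 1, len(blocks)):
                for a in blocks[bi]:
                    for b in blocks[bj]:
                        if rng.random() < p_out:
                            high_pairs.append((a, b))
    # cross edges to non-Sfp space
    if p_cross > 0 and nonsfp_ids:
        for g in block_members | set(g for c in small_components for g in c):
            for h in nonsfp_ids:
                if rng.random() < p_cross:
                    high_pairs.append((g, h))
    for g in peripheral:
        k = int(rng.integers(1, 4))
        for h in rng.choice(nonsfp_ids, size=min(k, len(nonsfp_ids)), replace=False):
            high_pairs.append((g, str(h)))

    # canonical dedupe
    seen: set[tuple[str, str]] = set()
    uniq: list[tuple[str, str]] = []
    for a, b in high_pairs:
        key = (a, b) if a < b else (b, a)
        if key not in seen and a != b:
            seen.add(key)
            uniq.append(key)
    rows = _edge_rows(uniq, rng, "high")

    def random_pairs(k: int) -> list[tuple[str, str]]:
        out = []
        all_ids = sfp_ids + nonsfp_ids
        while len(out) < k:
            a, b = rng.choice(all_ids, size=2, replace=False)
            key = (str(a), str(b)) if a < b else (str(b), str(a))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    rows += _edge_rows(random_pairs(n_weak), rng, "weak")
    rows += _edge_rows(random_pairs(n_textmining_decoys), rng, "textmining")
    edges = pd.DataFrame(rows, columns=["protein1", "protein2", *CHANNELS])
    edges = edges.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)
    truth = {
        "seed": seed,
        "blocks": [sorted(b) for b in blocks],
        "small_components": [sorted(c) for c in small_components],
        "peripheral": sorted(peripheral),
        "n_high_edges": len(uniq),
        "n_weak": n_weak,
        "n_textmining_decoys": n_textmining_decoys,
        "nonsfp_ids": nonsfp_ids,
    }
    return NetworkBundle(edges=edges, sfp_ids=sfp_ids, blocks=[list(b) for b in blocks], truth=truth)


# ---------------------------------------------------------------------------
# MKT counts


@dataclass(frozen=True)
class MKTBundle:
    counts: list[SiteCounts]
    truth: dict


def gen_mkt_counts(
    n_genes: int = 100,
    Ln: float = 800.0,
    Ls: float = 250.0,
    theta_s: float = 20.0,
    d_s: float = 40.0,
    omega0: float = 0.15,
    true_alpha: float = 0.0,
    frac_deleterious: float = 0.0,
    del_freq_max: float = 0.05,
    sample_size: int = 160,
    population_label: str = "SIM",
    gene_ids: Sequence[str] | None = None,
    seed: int = 0,
) -> MKTBundle:
    """Polymorphism/divergence counts with known true alpha.

    Per gene: Ps ~ Poisson(theta_s), Ds ~ Poisson(d_s); neutral
    nonsynonymous divergence and polymorphism scale with ``omega0`` (the
    nonadaptive rate ratio); adaptive substitutions are added so the
    expected adaptive fraction of Dn equals ``true_alpha``.  The neutral
    nonsynonymous SFS follows the standard neutral 1/i expectation; an
    optional deleterious fraction of nonsynonymous polymorphism is
    confined to bins at frequency <= ``del_freq_max``, creating the
    low-frequency excess the 5% threshold correction is designed to
    remove.
    """
    if not 0.0 <= true_alpha < 1.0:
        raise ValueError("true_alpha must lie in [0, 1)")
    if not 0.0 <= frac_deleterious < 1.0:
        raise ValueError("frac_deleterious must lie in [0, 1)")
    if sample_size < 2:
        raise ValueError("sample_size must be >= 2")
    rng = seeded_rng(seed, "gen_mkt_counts")
    if gene_ids is None:
        gene_ids = _gene_ids(n_genes, prefix="GEN")
    gene_ids = list(gene_ids)
    n_genes = len(gene_ids)

    counts_arr = np.arange(1, sample_size)
    neutral_probs = (1.0 / counts_arr) / np.sum(1.0 / counts_arr)
    low_mask = counts_arr / sample_size <= del_freq_max
    if frac_deleterious > 0 and not low_mask.any():
        raise ValueError("del_freq_max leaves no SFS bin for deleterious variants")
    del_probs = np.where(low_mask, 1.0 / counts_arr, 0.0)
    if frac_deleterious > 0:
        del_probs = del_probs / del_probs.sum()

    mu_dn_neutral = omega0 * (Ln / Ls) * d_s
    mu_dn_adaptive = mu_dn_neutral * true_alpha / (1.0 - true_alpha)
    mu_pn_neutral = omega0 * (Ln / Ls) * theta_s
    mu_pn_del = mu_pn_neutral * frac_deleterious / (1.0 - frac_deleterious)

    out: list[SiteCounts] = []
    for g in gene_ids:
        ps = int(rng.poisson(theta_s))
        ds = int(rng.poisson(d_s))
        dn = int(rng.poisson(mu_dn_neutral)) + int(rng.poisson(mu_dn_adaptive))
        pn_neutral = int(rng.poisson(mu_pn_neutral))
        sfs = rng.multinomial(pn_neutral, neutral_probs)
        if frac_deleterious > 0:
            pn_del = int(rng.poisson(mu_pn_del))
            sfs = sfs + rng.multinomial(pn_del, del_probs)
        out.append(
            SiteCounts(
                gene_id=g,
                Pn=int(sfs.sum()),
                Ps=ps,
                Dn=dn,
                Ds=ds,
                Ln=Ln,
                Ls=Ls,
                sfs_n=tuple(int(x) for x in sfs),
                sample_size=sample_size,
                population_label=population_label,
            )
        )
    truth = {
        "seed": seed,
        "true_alpha": true_alpha,
        "omega0": omega0,
        "frac_deleterious": frac_deleterious,
        "del_freq_max": del_freq_max,
        "sample_size": sample_size,
        "population_label": population_label,
        "gene_ids": gene_ids,
    }
    return MKTBundle(counts=out, truth=truth)


# ---------------------------------------------------------------------------
# paper-like preset


def paper_like_bundle(seed: int = 0, n_resample_note: int | None = None) -> dict:
    """Full synthetic input bundle mirroring the study's marginal structure.

    Returns a dict with keys ``catalog`` (CatalogBundle), ``expression``
    (ExpressionBundle), ``network`` (NetworkBundle), ``mkt`` (dict of
    population label -> MKTBundle), ``repro_flags`` (gene -> bool),
    ``background_props`` (genome-wide age-class proportions) and
    ``truth`` (merged generator truth).
    """
    cat = gen_catalog(
        n=357,
        class_counts=PAPER_LIKE_CLASS_COUNTS,
        overlap=228 / 357,
        n_exceptions=1,
        n_checked=178,
        n_discrepant=5,
        n_ancient_candidates=98,
        n_ancient_class_a=78,
        seed=seed,
    )
    by_class: dict[str, list[str]] = {c: [] for c in AGE_CLASSES}
    for g, c in sorted(cat.age_table.items()):
        by_class[c].append(g)

    # --- planted subnetwork blocks with age structure -------------------
    rng = seeded_rng(seed, "paper_like_blocks")
    remaining = {c: list(v) for c, v in by_class.items()}

    def take(cls: str, k: int) -> list[str]:
        picked = sorted(rng.choice(remaining[cls], size=k, replace=False))
        remaining[cls] = [g for g in remaining[cls] if g not in set(picked)]
        return picked

    def take_mixed(k: int, exclude: Sequence[str] = ()) -> list[str]:
        pool = [g for c in AGE_CLASSES if c not in exclude for g in remaining[c]]
        picked = sorted(rng.choice(pool, size=k, replace=False))
        picked_set = set(picked)
        for c in AGE_CLASSES:
            remaining[c] = [g for g in remaining[c] if g not in picked_set]
        return picked

    core = take("E", 20) + take_mixed(44, exclude=("E",))          # core: young-leaning
    second = take("A", 13)                                          # all ancient
    third = take("D", 4) + take_mixed(2, exclude=("D",))            # class-D leaning
    others = [take_mixed(5), take_mixed(5), take_mixed(5)]
    blocks = [core, second, third, *others]

    net = gen_network(
        blocks=blocks,
        sfp_ids=sorted(cat.age_table) + sorted(cat.exceptions),
        p_in=0.25,
        p_out=0.0,
        n_nonsfp=120,
        p_cross=0.01,
        small_component_sizes=(2, 2, 2, 2, 2, 2, 2, 3),  # 17 genes below min size
        n_peripheral=48,
        n_weak=60,
        n_textmining_decoys=40,
        seed=seed,
    )

    # --- reproductive GO flags: core-enriched, second/fourth depleted ---
    flag_rng = seeded_rng(seed, "paper_like_repro")
    repro_flags: dict[str, bool] = {}
    block_of = {g: i for i, b in enumerate(blocks) for g in b}
    for g in sorted(cat.age_table) + sorted(cat.exceptions):
        i = block_of.get(g)
        if i == 0:
            p = 0.90
        elif i in (1, 3):
            p = 0.08
        elif i is not None:
            p = 0.45
        else:
            p = 0.40
        repro_flags[g] = bool(flag_rng.random() < p)

    # --- expression: ancient genes broader, young genes gland-specific --
    p_specific = {
        g: {"A": 0.30, "B": 0.65, "C": 0.70, "D": 0.80, "E": 0.85}[c]
        for g, c in cat.age_table.items()
    }
    for g in cat.exceptions:
        p_specific[g] = 0.5
    expr = gen_expression(
        gene_ids=sorted(p_specific),
        n_tissues=31,
        p_specific=p_specific,
        p_target=0.85,
        fg_level=500.0,
        bg_level=0.5,
        noise_cv=0.2,
        seed=seed,
    )

    # --- MKT counts: older classes slower, lower adaptive fraction ------
    omega0_by_class = {"A": 0.06, "B": 0.10, "C": 0.12, "D": 0.16, "E": 0.20}
    alpha_by_class = {"A": 0.10, "B": 0.20, "C": 0.25, "D": 0.35, "E": 0.40}
    mkt_bundles: dict[str, MKTBundle] = {}
    for pop, n_lines in (("RAL", 160), ("ZI", 154)):
        all_counts: list[SiteCounts] = []
        truth_by_class = {}
        for c in AGE_CLASSES:
            sub = gen_mkt_counts(
                gene_ids=by_class[c],
                omega0=omega0_by_class[c],
                true_alpha=alpha_by_class[c],
                frac_deleterious=0.25,
                sample_size=n_lines,
                population_label=pop,
                seed=seed * 7 + AGE_CLASSES.index(c) + (0 if pop == "RAL" else 1000),
            )
            all_counts.extend(sub.counts)
            truth_by_class[c] = sub.truth
        mkt_bundles[pop] = MKTBundle(
            counts=sorted(all_counts, key=lambda s: s.gene_id),
            truth={"by_class": truth_by_class, "population_label": pop},
        )

    return {
        "catalog": cat,
        "expression": expr,
        "network": net,
        "mkt": mkt_bundles,
        "repro_flags": repro_flags,
        "background_props": dict(zip(AGE_CLASSES, DEFAULT_BACKGROUND_PROPS)),
        "truth": {
            "seed": seed,
            "catalog": cat.truth,
            "network": net.truth,
            "expression": {k: v for k, v in expr.truth.items() if k != "genes"},
            "blocks": [sorted(b) for b in blocks],
        },
    }


def write_bundle(bundle: dict, outdir: str | Path) -> dict[str, Path]:
    """Write a generated bundle to TSV/JSON files; returns written paths."""
    from .mkt import write_site_counts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cat: CatalogBundle = bundle["catalog"]
    paths: dict[str, Path] = {}

    def tsv(name: str, df: pd.DataFrame) -> None:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p

    tsv("list_a", pd.DataFrame({"gene_id": cat.list_a}))
    tsv("list_b", pd.DataFrame({"gene_id": cat.list_b}))
    tsv("ages", pd.DataFrame(sorted(cat.age_table.items()), columns=["gene_id", "age_class"]))
    tsv("exceptions", pd.DataFrame({"gene_id": sorted(cat.exceptions)}))
    tsv("ortholog_ids", pd.DataFrame({"gene_id": cat.ortholog_ids}))
    tsv("ancient_candidates", pd.DataFrame({"gene_id": cat.ancient_candidate_ids}))
    expr: ExpressionBundle = bundle["expression"]
    p = outdir / "expression.tsv"
    expr.matrix.to_csv(p, sep="\t")
    paths["expression"] = p
    net: NetworkBundle = bundle["network"]
    tsv("edges", net.edges)
    tsv(
        "repro_flags",
        pd.DataFrame(
            sorted(bundle["repro_flags"].items()), columns=["gene_id", "reproductive"]
        ),
    )
    tsv(
        "background_props",
        pd.DataFrame(
            list(bundle["background_props"].items()), columns=["age_class", "proportion"]
        ),
    )
    for pop, mb in bundle["mkt"].items():
        p = outdir / f"mkt_{pop}.json"
        write_site_counts(mb.counts, p)
        paths[f"mkt_{pop}"] = p
    p = outdir / "truth.json"
    p.write_text(json.dumps(bundle["truth"], indent=1, default=str))
    paths["truth"] = p
    return paths
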