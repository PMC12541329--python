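"""High-confidence protein-interaction graph over an Sfp gene universe.

Edges arrive with per-channel confidence scores in the STRING style
(neighborhood, fusion, cooccurrence, coexpression, experiments,
database, textmining).  Channels are combined after removing the prior
from each, excluding text mining by default:

    s_i'     = max(0, (s_i - prior) / (1 - prior))
    s_nop    = 1 - prod_i (1 - s_i')
    combined = s_nop + prior * (1 - s_nop)   (0 if no channel beats the prior)

Only edges with combined score >= 0.7 ("high confidence") are kept.
The module then partitions each Sfp's degree into within-Sfp versus
outside partners, extracts connected components of the Sfp-induced
subgraph with >= 4 members (the largest is the "core" subnetwork), and
tests each subnetwork for age-class enrichment by Monte Carlo
resampling without replacement, and for association with reproductive
function with a fixed-margin Monte Carlo chi-square test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .stats import (
    TestResult,
    adjusted_residuals,
    bh_adjust,
    chi_square_independence,
    empirical_pvalue,
    seeded_rng,
)

logger = logging.getLogger(__name__)

#: STRING-style evidence channels, in canonical column order.
CHANNELS: tuple[str, ...] = (
    "neighborhood",
    "fusion",
    "cooccurrence",
    "coexpression",
    "experiments",
    "database",
    "textmining",
)

DEFAULT_PRIOR = 0.041
DEFAULT_THRESHOLD = 0.700
DEFAULT_EXCLUDED: tuple[str, ...] = ("textmining",)

__all__ = [
    "CHANNELS",
    "DEFAULT_PRIOR",
    "DEFAULT_THRESHOLD",
    "DEFAULT_EXCLUDED",
    "PPINetwork",
    "Subnetwork",
    "combine_scores",
    "read_edge_table",
    "build_network",
    "degree_partition",
    "extract_subnetworks",
    "mc_age_enrichment",
    "reproductive_association",
    "export_network",
]


# ---------------------------------------------------------------------------
# score combination


def combine_scores(
    channel_scores: Mapping[str, float],
    excluded: Iterable[str] = DEFAULT_EXCLUDED,
    prior: float = DEFAULT_PRIOR,
) -> float:
    """Combine per-channel confidences into one score, prior removed/re-added.

    Channels in ``excluded`` are ignored entirely.  Returns 0.0 when no
    retained channel exceeds the prior (the prior floor is reported as 0
    rather than as the prior itself).
    """
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must lie in (0, 1)")
    excluded = set(excluded)
    unknown = excluded - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels in exclusion set: {sorted(unknown)}")
    keep = 1.0
    any_evidence = False
    for channel, score in channel_scores.items():
        if channel not in CHANNELS:
            raise ValueError(f"unknown channel {channel!r}")
        if channel in excluded:
            continue
        s = float(score)
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"channel {channel} score {s} outside [0, 1]")
        s_nop = (s - prior) / (1.0 - prior)
        if s_nop > 0:
            any_evidence = True
            keep *= 1.0 - s_nop
    if not any_evidence:
        return 0.0
    s_nop_total = 1.0 - keep
    return float(s_nop_total + prior * (1.0 - s_nop_total))


# ---------------------------------------------------------------------------
# graph containers


@dataclass(frozen=True)
class Subnetwork:
    """A size-filtered connected component of the Sfp-induced subgraph."""

    id: str
    members: frozenset[str]
    is_core: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PPINetwork:
    """Score-filtered interaction graph over a flagged Sfp universe."""

    graph: nx.Graph
    sfp_ids: frozenset[str]
    threshold: float

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def sfp_subgraph(self) -> nx.Graph:
        """Subgraph induced on Sfp nodes (edges among Sfps only)."""
        return self.graph.subgraph([n for n in self.graph if n in self.sfp_ids]).copy()

    def sfps_with_interactions(self) -> frozenset[str]:
        return frozenset(n for n in self.graph if n in self.sfp_ids and self.graph.degree(n) > 0)


# ---------------------------------------------------------------------------
# edge table IO


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Read an edge TSV with columns protein1, protein2 and channel scores.

    Channel columns may be reals in [0, 1] or STRING-export integers in
    0..999 (auto-detected per file and rescaled to [0, 1]).  Missing
    channel columns are treated as all-zero.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("protein1", "protein2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    present = [c for c in CHANNELS if c in df.columns]
    if not present:
        raise ValueError(f"{path}: no channel score columns found (expected some of {CHANNELS})")
    scores = df[present].astype(float)
    if (scores.values < 0).any():
        raise ValueError(f"{path}: negative channel scores")
    if (scores.values > 1.0).any():
        if (scores.values > 999).any():
            raise ValueError(f"{path}: channel scores exceed the 0..999 integer scale")
        scores = scores / 1000.0  # STRING integer export dialect
    for c in CHANNELS:
        df[c] = scores[c] if c in present else 0.0
    return df[["protein1", "protein2", *CHANNELS]]


# ---------------------------------------------------------------------------
# network construction and partitioning


def build_network(
    edges: pd.DataFrame,
    sfp_ids: Iterable[str],
    threshold: float = DEFAULT_THRESHOLD,
    excluded: Iterable[str] = DEFAULT_EXCLUDED,
    prior: float = DEFAULT_PRIOR,
) -> PPINetwork:
    """Build the high-confidence graph from a scored edge table.

    Self-loops are dropped with a warning; duplicate pairs (either
    orientation) are merged keeping the highest combined score.  Every
    Sfp id is retained as a node even if isolated, so degree-0 Sfps are
    visible downstream.
    """
    sfp_ids = frozenset(str(g) for g in sfp_ids)
    excluded = tuple(excluded)
    graph = nx.Graph()
    graph.add_nodes_from(sfp_ids)
    n_self = 0
    for row in edges.itertuples(index=False):
        a, b = str(row.protein1), str(row.protein2)
        if a == b:
            n_self += 1
            continue
        score = combine_scores(
            {c: getattr(row, c) for c in CHANNELS}, excluded=excluded, prior=prior
        )
        if score < threshold:
            continue
        if graph.has_edge(a, b):
            if score > graph.edges[a, b]["score"]:
                graph.edges[a, b]["score"] = score
        else:
            graph.add_edge(a, b, score=score)
    if n_self:
        logger.warning("dropped %d self-loop edges", n_self)
    for node in graph.nodes:
        graph.nodes[node]["is_sfp"] = node in sfp_ids
    return PPINetwork(graph=graph, sfp_ids=sfp_ids, threshold=threshold)


def degree_partition(network: PPINetwork) -> pd.DataFrame:
    """Per-Sfp degree split into within-Sfp and outside partners.

    Returns a DataFrame indexed by gene id with columns ``k_total``,
    ``k_within`` and ``k_outside``; the identity
    k_total = k_within + k_outside holds by construction.
    """
    rows = {}
    g = network.graph
    for gene in sorted(network.sfp_ids):
        if gene in g:
            partners = list(g.neighbors(gene))
            k_within = sum(1 for p in partners if p in network.sfp_ids)
            k_total = len(partners)
        else:  # pragma: no cover - sfp nodes are always added
            k_within = k_total = 0
        rows[gene] = (k_total, k_within, k_total - k_within)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["k_total", "k_within", "k_outside"]
    )
    df.index.name = "gene_id"
    return df


def extract_subnetworks(network: PPINetwork, min_size: int = 4) -> list[Subnetwork]:
    """Connected components of the Sfp-induced subgraph with >= min_size members.

    Components are sorted by size descending, ties by smallest
    lexicographic member id; the largest is flagged as the core.
    Interactions routed through non-Sfp intermediates do not merge
    components.
    """
    sub = network.sfp_subgraph()
    comps = [frozenset(c) for c in nx.connected_components(sub) if len(c) >= min_size]
    if not comps:
        logger.warning("no Sfp subnetwork reaches min_size=%d", min_size)
        return []
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [
        Subnetwork(id=f"S{i + 1}", members=c, is_core=(i == 0))
        for i, c in enumerate(comps)
    ]


# ---------------------------------------------------------------------------
# Monte Carlo enrichment


def _resample_counts(
    member_matrix: np.ndarray,  # (n_classes, N) bool
    size: int,
    n_resamples: int,
    rng: np.random.Generator,
    chunk: int = 20000,
) -> np.ndarray:
    """Class counts in random size-`size` subsets of the universe.

    Subsets are uniform without replacement: each resample ranks N iid
    uniforms and takes the lowest `size` positions.  Returns an
    (n_resamples, n_classes) integer array.
    """
    n_classes, n_universe = member_matrix.shape
    out = np.empty((n_resamples, n_classes), dtype=np.int64)
    done = 0
    while done < n_resamples:
        b = min(chunk, n_resamples - done)
        ranks = rng.random((b, n_universe)).argpartition(size - 1, axis=1)[:, :size]
        for k in range(n_classes):
            out[done : done + b, k] = member_matrix[k][ranks].sum(axis=1)
        done += b
    return out


def mc_age_enrichment(
    subnetworks: Sequence[Subnetwork],
    age_labels: Mapping[str, str],
    universe: Iterable[str] | None = None,
    n_resamples: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte Carlo age-class enrichment of each subnetwork.

    For every (subnetwork, age class) cell, ``n_resamples`` random
    gene sets of the subnetwork's size are drawn from the universe
    without replacement; the enrichment p-value is
    (1 + #{resamples with count >= observed}) / (n_resamples + 1), the
    depletion p-value analogously with <=.  BH adjustment is applied per
    direction across all subnetwork x class cells.  The expected count
    is size x class frequency in the universe.

    The universe defaults to the union of subnetwork members (the
    networked gene set); pass e.g. all Sfps with interaction data to
    widen it.  Each subnetwork draws from an independent child stream
    keyed by its id, so results do not depend on processing order.
    """
    if universe is None:
        universe_ids = sorted(set().union(*(s.members for s in subnetworks)))
    else:
        universe_ids = sorted(set(universe))
    missing = [g for g in universe_ids if g not in age_labels]
    if missing:
        raise ValueError(f"universe genes without age class: {missing[:5]}")
    for s in subnetworks:
        if not s.members <= set(universe_ids):
            raise ValueError(f"subnetwork {s.id} has members outside the universe")
        if s.size > len(universe_ids):
            raise ValueError(f"subnetwork {s.id} larger than the universe")
    classes = sorted(set(age_labels[g] for g in universe_ids))
    labels = np.array([age_labels[g] for g in universe_ids])
    member_matrix = np.vstack([labels == c for c in classes])
    class_freq = member_matrix.mean(axis=1)

    rows = []
    for s in sorted(subnetworks, key=lambda s: s.id):
        observed = np.array(
            [sum(1 for g in s.members if age_labels[g] == c) for c in classes]
        )
        rng = seeded_rng(seed, "mc_age_enrichment", s.id)
        counts = _resample_counts(member_matrix, s.size, n_resamples, rng)
        for k, c in enumerate(classes):
            p_enr = (1 + int((counts[:, k] >= observed[k]).sum())) / (n_resamples + 1)
            p_dep = (1 + int((counts[:, k] <= observed[k]).sum())) / (n_resamples + 1)
            expected = s.size * class_freq[k]
            rows.append(
                {
                    "subnetwork": s.id,
                    "is_core": s.is_core,
                    "size": s.size,
                    "age_class": c,
                    "observed": int(observed[k]),
                    "expected": float(expected),
                    "direction": "over" if observed[k] > expected else (
                        "under" if observed[k] < expected else "none"
                    ),
                    "p_enrichment": p_enr,
                    "p_depletion": p_dep,
                    "n_resamples": n_resamples,
                }
            )
    df = pd.DataFrame(rows)
    df["p_enrichment_adj"] = bh_adjust(df["p_enrichment"])
    df["p_depletion_adj"] = bh_adjust(df["p_depletion"])
    df["p_raw"] = np.where(df["direction"] == "under", df["p_depletion"], df["p_enrichment"])
    df["p_adj"] = np.where(
        df["direction"] == "under", df["p_depletion_adj"], df["p_enrichment_adj"]
    )
    return df


def reproductive_association(
    subnetworks: Sequence[Subnetwork],
    repro_flags: Mapping[str, bool],
    n_sim: int = 2000,
    seed: int = 0,
) -> tuple[TestResult, pd.DataFrame]:
    """Association between subnetwork membership and reproductive function.

    Builds the subnetworks x {reproductive, non-reproductive} contingency
    table, tests independence with a Pearson chi-square whose p-value is
    estimated from ``n_sim`` fixed-margin Monte Carlo tables, and runs
    per-cell post hoc adjusted-residual tests (BH across cells of the
    reproductive column).
    """
    ids = [s.id for s in sorted(subnetworks, key=lambda s: s.id)]
    by_id = {s.id: s for s in subnetworks}
    table = []
    for sid in ids:
        members = by_id[sid].members
        missing = [g for g in members if g not in repro_flags]
        if missing:
            raise ValueError(f"subnetwork {sid} members without reproductive flag: {missing[:5]}")
        n_repro = sum(1 for g in members if repro_flags[g])
        table.append([n_repro, len(members) - n_repro])
    t = np.asarray(table, dtype=float)
    if np.any(t.sum(axis=0) == 0):
        # all genes share one flag value: no association is testable
        if np.all(t[:, 1] == 0) or np.all(t[:, 0] == 0):
            omnibus = TestResult(0.0, 1.0, "chi-square independence (degenerate)", df=len(ids) - 1)
            posthoc = pd.DataFrame(
                {
                    "subnetwork": ids,
                    "n_reproductive": t[:, 0].astype(int),
                    "n_non_reproductive": t[:, 1].astype(int),
                    "z": 0.0,
                    "p_raw": 1.0,
                    "p_adj": 1.0,
                }
            )
            return omnibus, posthoc
    rng = seeded_rng(seed, "reproductive_association")
    omnibus = chi_square_independence(t, monte_carlo_n=n_sim, seed=rng)
    from scipy import stats as sps

    z = adjusted_residuals(t)[:, 0]  # reproductive column
    p_raw = 2.0 * sps.norm.sf(np.abs(z))
    p_adj = bh_adjust(p_raw)
    posthoc = pd.DataFrame(
        {
            "subnetwork": ids,
            "n_reproductive": t[:, 0].astype(int),
            "n_non_reproductive": t[:, 1].astype(int),
            "z": z,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    return omnibus, posthoc


# ---------------------------------------------------------------------------
# export


def export_network(
    network: PPINetwork,
    subnetworks: Sequence[Subnetwork],
    path: str | Path,
    fmt: str = "graphml",
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
) -> Path:
    """Write the graph with node annotations as GraphML or an edge-list TSV.

    ``node_attrs`` maps attribute name -> {gene id -> value} (e.g. age
    class, reproductive flag).  Subnetwork membership and core status are
    always attached.
    """
    path = Path(path)
    g = network.graph.copy()
    membership: dict[str, str] = {}
    core: dict[str, bool] = {}
    for s in subnetworks:
        for gene in s.members:
            membership[gene] = s.id
            core[gene] = s.is_core
    for node in g.nodes:
        g.nodes[node]["subnetwork"] = membership.get(node, "")
        g.nodes[node]["is_core"] = bool(core.get(node, False))
        for attr, mapping in (node_attrs or {}).items():
            if node in mapping:
                value = mapping[node]
                g.nodes[node][attr] = value if not isinstance(value, (bool, np.bool_)) else bool(value)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        rows = [
            {"protein1": a, "protein2": b, "score": d["score"]}
            for a, b, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["protein1", "protein2", "score"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path
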