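"""McDonald-Kreitman statistics with a low-frequency SFS correction.

For each gene we hold polymorphism counts (Pn, Ps), divergence counts
(Dn, Ds), site counts (Ln, Ls), and the nonsynonymous site frequency
spectrum.  From these:

    omega    = (Dn / Ln) / (Ds / Ls)          (per-site; raw-count optional)
    Pn_corr  = nonsynonymous segregating sites above the frequency cutoff
    alpha    = 1 - (Ds * Pn_corr) / (Dn * Ps)
    omega_a  = alpha * omega
    omega_na = (1 - alpha) * omega

The 5% frequency cutoff on the nonsynonymous class removes segregating
slightly-deleterious variants that depress alpha; sites at a derived
allele frequency strictly above the cutoff are retained (the boundary
frequency is excluded).  alpha may be negative under residual
segregating deleterious variation and is reported unclipped.

Genes with zero synonymous divergence or polymorphism cannot yield the
corresponding ratio and are flagged unusable with a reason rather than
silently dropped; a pooled (summed-counts) estimator over a gene group
is provided for stability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteCounts",
    "MKTResult",
    "threshold_sfs",
    "omega",
    "alpha",
    "decompose_omega",
    "mkt_gene",
    "mkt_table",
    "pooled_alpha",
    "compare_rates",
    "read_site_counts",
    "write_site_counts",
]


@dataclass(frozen=True)
class SiteCounts:
    """Per-gene polymorphism/divergence counts plus the nonsynonymous SFS.

    ``sfs_n[i]`` is the number of segregating nonsynonymous sites whose
    derived allele is carried by ``i + 1`` of the ``sample_size``
    sampled chromosomes; its sum must equal ``Pn``.
    """

    gene_id: str
    Pn: int
    Ps: int
    Dn: int
    Ds: int
    Ln: float
    Ls: float
    sfs_n: tuple[int, ...]
    sample_size: int
    population_label: str = ""

    def __post_init__(self) -> None:
        for name in ("Pn", "Ps", "Dn", "Ds"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.gene_id}: {name} must be non-negative")
        if self.Ln <= 0 or self.Ls <= 0:
            raise ValueError(f"{self.gene_id}: site counts Ln, Ls must be positive")
        if self.sample_size < 2:
            raise ValueError(f"{self.gene_id}: sample_size must be >= 2")
        if len(self.sfs_n) != self.sample_size - 1:
            raise ValueError(
                f"{self.gene_id}: SFS must have sample_size-1 = "
                f"{self.sample_size - 1} bins, got {len(self.sfs_n)}"
            )
        if sum(self.sfs_n) != self.Pn:
            raise ValueError(
                f"{self.gene_id}: SFS sums to {sum(self.sfs_n)} but Pn = {self.Pn}"
            )


@dataclass(frozen=True)
class MKTResult:
    gene_id: str
    omega: float | None
    alpha: float | None
    omega_a: float | None
    omega_na: float | None
    Pn_corrected: int | None
    usable: bool
    reason: str = ""
    population_label: str = ""


def threshold_sfs(
    sfs_n: Sequence[int],
    sample_size: int,
    cutoff: float = 0.05,
    folded: bool = False,
) -> int:
    """Corrected Pn: segregating sites at frequency strictly above ``cutoff``.

    Frequencies are derived-allele counts over ``sample_size`` (unfolded,
    default) or minor-allele frequencies (``folded=True``).  Sites at
    exactly the cutoff frequency are excluded.
    """
    sfs = np.asarray(sfs_n, dtype=np.int64)
    if sfs.size != sample_size - 1:
        raise ValueError("SFS must have sample_size - 1 bins")
    if np.any(sfs < 0):
        raise ValueError("SFS bins must be non-negative")
    if not 0.0 <= cutoff < 1.0:
        raise ValueError("cutoff must lie in [0, 1)")
    counts = np.arange(1, sample_size)
    freq = counts / sample_size
    if folded:
        freq = np.minimum(freq, 1.0 - freq)
    return int(sfs[freq > cutoff].sum())


def omega(
    Dn: int, Ds: int, Ln: float, Ls: float, per_site: bool = True
) -> float:
    """dN/dS ratio: (Dn/Ln)/(Ds/Ls), or raw Dn/Ds with ``per_site=False``."""
    if Ds <= 0:
        raise ZeroDivisionError("omega undefined for Ds = 0")
    if per_site:
        if Ln <= 0 or Ls <= 0:
            raise ValueError("Ln and Ls must be positive")
        return (Dn / Ln) / (Ds / Ls)
    return Dn / Ds


def alpha(Pn_corr: int, Ps: int, Dn: int, Ds: int) -> float:
    """Proportion of substitutions fixed by positive selection (unclipped).

    alpha = 1 - (Ds * Pn_corr) / (Dn * Ps); negative values indicate an
    excess of (slightly deleterious) nonsynonymous polymorphism and are
    reported as-is.
    """
    if Ps <= 0:
        raise ZeroDivisionError("alpha undefined for Ps = 0")
    if Dn <= 0:
        raise ZeroDivisionError("alpha undefined for Dn = 0")
    return 1.0 - (Ds * Pn_corr) / (Dn * Ps)


def decompose_omega(omega_value: float, alpha_value: float) -> tuple[float, float]:
    """Split omega into adaptive and nonadaptive components.

    omega_a = alpha * omega, omega_na = (1 - alpha) * omega; the identity
    omega_a + omega_na = omega holds exactly.  Negative alpha yields a
    negative omega_a, flagged upstream but not suppressed.
    """
    omega_a = alpha_value * omega_value
    return omega_a, omega_value - omega_a


def mkt_gene(
    counts: SiteCounts,
    cutoff: float = 0.05,
    folded: bool = False,
    per_site: bool = True,
) -> MKTResult:
    """Full per-gene MKT: omega, corrected alpha, omega_a/omega_na.

    Genes failing a precondition (Ds = 0, Ps = 0, or Dn = 0) come back
    with ``usable=False`` and an explanatory reason.
    """
    reasons = []
    if counts.Ds == 0:
        reasons.append("zero synonymous divergence")
    if counts.Ps == 0:
        reasons.append("zero synonymous polymorphism")
    if counts.Dn == 0:
        reasons.append("zero nonsynonymous divergence")
    if reasons:
        return MKTResult(
            counts.gene_id, None, None, None, None, None,
            usable=False, reason="; ".join(reasons),
            population_label=counts.population_label,
        )
    pn_corr = threshold_sfs(counts.sfs_n, counts.sample_size, cutoff=cutoff, folded=folded)
    w = omega(counts.Dn, counts.Ds, counts.Ln, counts.Ls, per_site=per_site)
    a = alpha(pn_corr, counts.Ps, counts.Dn, counts.Ds)
    wa, wna = decompose_omega(w, a)
    return MKTResult(
        counts.gene_id, w, a, wa, wna, pn_corr,
        usable=True,
        reason="negative alpha" if a < 0 else "",
        population_label=counts.population_label,
    )


def mkt_table(
    counts: Iterable[SiteCounts],
    cutoff: float = 0.05,
    folded: bool = False,
    per_site: bool = True,
) -> pd.DataFrame:
    """Per-gene MKT results as a DataFrame indexed by gene id."""
    rows = []
    for c in counts:
        r = mkt_gene(c, cutoff=cutoff, folded=folded, per_site=per_site)
        rows.append(
            {
                "gene_id": r.gene_id,
                "population": r.population_label,
                "omega": r.omega,
                "alpha": r.alpha,
                "omega_a": r.omega_a,
                "omega_na": r.omega_na,
                "Pn_corrected": r.Pn_corrected,
                "usable": r.usable,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def pooled_alpha(
    counts: Iterable[SiteCounts],
    cutoff: float = 0.05,
    folded: bool = False,
) -> float:
    """Group-level alpha from summed counts (stable when per-gene counts are small)."""
    tot_pn = tot_ps = tot_dn = tot_ds = 0
    for c in counts:
        tot_pn += threshold_sfs(c.sfs_n, c.sample_size, cutoff=cutoff, folded=folded)
        tot_ps += c.Ps
        tot_dn += c.Dn
        tot_ds += c.Ds
    if tot_ps == 0 or tot_dn == 0:
        raise ZeroDivisionError("pooled alpha undefined: zero Ps or Dn total")
    return 1.0 - (tot_ds * tot_pn) / (tot_dn * tot_ps)


def compare_rates(
    results: pd.DataFrame,
    groups: Mapping[str, str],
    metric: str = "omega",
):
    """Compare a rate metric across gene groups (age classes, network strata).

    ``groups`` maps gene id -> group label; unusable genes and genes
    without a group are excluded (their count is recorded on the
    returned comparison's omnibus ``extra``).  Returns a
    :class:`sfpage.stats.GroupComparison`.
    """
    from .stats import compare_groups

    if metric not in ("omega", "alpha", "omega_a", "omega_na"):
        raise ValueError(f"unknown metric {metric!r}")
    usable = results[results["usable"]]
    data: dict[str, list[float]] = {}
    n_excluded = int((~results["usable"]).sum())
    for gene_id, value in usable[metric].items():
        label = groups.get(gene_id)
        if label is None:
            n_excluded += 1
            continue
        data.setdefault(str(label), []).append(float(value))
    comparison = compare_groups(data, min_n=2)
    comparison.omnibus.extra["n_excluded"] = n_excluded
    return comparison


# ---------------------------------------------------------------------------
# IO


def write_site_counts(counts: Sequence[SiteCounts], path: str | Path) -> None:
    """Serialize counts + SFS as JSON (one object per gene)."""
    payload = [
        {
            "gene_id": c.gene_id,
            "Pn": c.Pn,
            "Ps": c.Ps,
            "Dn": c.Dn,
            "Ds": c.Ds,
            "Ln": c.Ln,
            "Ls": c.Ls,
            "sample_size": c.sample_size,
            "population_label": c.population_label,
            "sfs_n": list(c.sfs_n),
        }
        for c in counts
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_site_counts(path: str | Path) -> list[SiteCounts]:
    """Read counts from JSON produced by :func:`write_site_counts`."""
    payload = json.loads(Path(path).read_text())
    return [
        SiteCounts(
            gene_id=obj["gene_id"],
            Pn=int(obj["Pn"]),
            Ps=int(obj["Ps"]),
            Dn=int(obj["Dn"]),
            Ds=int(obj["Ds"]),
            Ln=float(obj["Ln"]),
            Ls=float(obj["Ls"]),
            sfs_n=tuple(int(x) for x in obj["sfs_n"]),
            sample_size=int(obj["sample_size"]),
            population_label=obj.get("population_label", ""),
        )
        for obj in payload
    ]
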