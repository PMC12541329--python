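"""Shared statistical machinery.

Nonparametric group comparisons, chi-square tests (analytic and Monte
Carlo), Benjamini-Hochberg adjustment, empirical p-values from resampling
null distributions, and a deterministic seeding scheme.

All Monte Carlo routines take an explicit integer seed (or a
:class:`numpy.random.Generator`) and are bit-reproducible for a fixed
seed.  Stochastic stages elsewhere in the package derive child generators
with :func:`seeded_rng` keyed by (seed, operation, item), so results do
not depend on the order in which items are processed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "GroupComparison",
    "PairwiseResult",
    "seeded_rng",
    "bh_adjust",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "chi_square_independence",
    "adjusted_residuals",
    "empirical_pvalue",
    "compare_groups",
]


# ---------------------------------------------------------------------------
# results containers


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``statistic`` is the test statistic on its conventional scale (H for
    Kruskal-Wallis, U for rank-sum, Pearson chi-square for contingency
    tests).  ``n_sim`` is set when the p-value is a Monte Carlo estimate.
    """

    statistic: float
    p: float
    method: str
    df: int | None = None
    n_sim: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value outside [0, 1]: {self.p}")


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adj: float


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus test plus BH-adjusted pairwise post hoc comparisons."""

    omnibus: TestResult
    groups: dict[str, tuple[int, float]]  # label -> (n, median)
    pairwise: list[PairwiseResult]

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        return [r.pair for r in self.pairwise if r.p_adj < alpha]


# ---------------------------------------------------------------------------
# seeding


def seeded_rng(seed: int, *keys: object) -> np.random.Generator:
    """Derive a child generator from ``seed`` and a tuple of string/int keys.

    String keys are hashed with CRC32 so the stream depends only on the
    key values, never on Python's per-process hash randomization.
    """
    entropy: list[int] = [int(seed) & 0x7FFFFFFF]
    for key in keys:
        if isinstance(key, (int, np.integer)):
            entropy.append(int(key) & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(key).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# rank tests


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square reference (k-1 df)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # degenerate: every observation identical
        return TestResult(0.0, 1.0, "kruskal-wallis", df=df)
    stat, p = sps.kruskal(*arrays)
    return TestResult(float(stat), float(p), "kruskal-wallis", df=df)


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    alternative: str = "two-sided",
) -> TestResult:
    """Wilcoxon rank-sum / Mann-Whitney test.

    ``mode='exact'`` enumerates the null (tie-free samples only);
    ``'normal_approx'`` uses the tie-corrected normal approximation without
    continuity correction; ``'auto'`` picks exact for small tie-free
    samples.  The signed z-score is reported in ``extra['z']`` (negative
    when x tends to be smaller than y), with z**2 alongside for comparison
    against software that prints two-group rank tests on a chi-square scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (not has_ties and x.size * y.size <= 400) else "normal_approx"
    method = {"exact": "exact", "normal_approx": "asymptotic"}[mode]
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    u = float(res.statistic)
    n1, n2 = x.size, y.size
    mu = n1 * n2 / 2.0
    # tie-corrected variance of U
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (u - mu) / np.sqrt(var) if var > 0 else 0.0
    return TestResult(
        u,
        float(res.pvalue),
        f"wilcoxon-rank-sum ({mode})",
        extra={"z": float(z), "z_squared": float(z * z)},
    )


# ---------------------------------------------------------------------------
# contingency tables


def _pearson_chi2(table: np.ndarray) -> tuple[float, np.ndarray]:
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / table.sum()
    return float(((table - expected) ** 2 / expected).sum()), expected


def chi_square_independence(
    table: Sequence[Sequence[float]],
    monte_carlo_n: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    With ``monte_carlo_n`` set, the p-value is estimated by simulating
    that many tables with both margins fixed (Patefield sampling) and
    applying the (r+1)/(n+1) empirical estimator; otherwise the analytic
    chi-square reference distribution is used.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be 2-D with at least 2 rows and 2 columns")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin; drop empty rows/columns first")
    stat, expected = _pearson_chi2(t)
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    if monte_carlo_n is None:
        p = float(sps.chi2.sf(stat, df))
        return TestResult(stat, p, "chi-square independence", df=df)
    rng = _as_rng(seed)
    sampler = sps.random_table(t.sum(axis=1).astype(int), t.sum(axis=0).astype(int))
    sims = sampler.rvs(monte_carlo_n, random_state=rng)
    rows = sims.sum(axis=2, keepdims=True)
    cols = sims.sum(axis=1, keepdims=True)
    exp = rows * cols / t.sum()
    stats_sim = ((sims - exp) ** 2 / exp).sum(axis=(1, 2))
    p = empirical_pvalue(stat, stats_sim, direction="ge")
    return TestResult(stat, p, "chi-square independence (Monte Carlo)", df=df, n_sim=monte_carlo_n)


def adjusted_residuals(table: Sequence[Sequence[float]]) -> np.ndarray:
    """Adjusted standardized residuals (O-E)/sqrt(E(1-p_i.)(1-p.j))."""
    t = np.asarray(table, dtype=float)
    _, expected = _pearson_chi2(t)
    n = t.sum()
    row_frac = t.sum(axis=1, keepdims=True) / n
    col_frac = t.sum(axis=0, keepdims=True) / n
    denom = np.sqrt(expected * (1 - row_frac) * (1 - col_frac))
    return (t - expected) / denom


# ---------------------------------------------------------------------------
# resampling


def empirical_pvalue(
    observed: float, null_draws: Sequence[float], direction: str = "ge"
) -> float:
    """Pseudo-count empirical p-value (r+1)/(n+1); never returns 0."""
    draws = np.asarray(null_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("need at least one null draw")
    if direction == "ge":
        r = int(np.sum(draws >= observed))
    elif direction == "le":
        r = int(np.sum(draws <= observed))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return (r + 1) / (draws.size + 1)


# ---------------------------------------------------------------------------
# composite group comparison


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    min_n: int = 1,
) -> GroupComparison:
    """Omnibus rank test across named groups plus pairwise post hoc tests.

    Empty / undersized groups are dropped.  The omnibus test is
    Kruskal-Wallis (a two-group call reduces to the rank-sum test but is
    still reported on the H scale); pairwise comparisons use the rank-sum
    test with BH adjustment across all C(k, 2) pairs.
    """
    usable = {
        str(k): np.asarray(v, dtype=float)
        for k, v in groups.items()
        if len(v) >= min_n and len(v) > 0
    }
    if len(usable) < 2:
        raise ValueError("need at least two usable groups")
    labels = sorted(usable)
    omnibus = kruskal_wallis([usable[lab] for lab in labels])
    summary = {lab: (int(usable[lab].size), float(np.median(usable[lab]))) for lab in labels}
    pairs = list(combinations(labels, 2))
    raw: list[tuple[tuple[str, str], float, float]] = []
    for a, b in pairs:
        res = wilcoxon_rank_sum(usable[a], usable[b], mode="normal_approx")
        raw.append(((a, b), res.statistic, res.p))
    adj = bh_adjust([p for *_, p in raw])
    pairwise = [
        PairwiseResult(pair, stat, p, float(pa))
        for (pair, stat, p), pa in zip(raw, adj)
    ]
    return GroupComparison(omnibus=omnibus, groups=summary, pairwise=pairwise)
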