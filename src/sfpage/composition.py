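"""Age-class composition tests.

Given the observed age-class counts of a gene set (all five
phylostratigraphic classes A..E) and the genome-wide background
proportions of those classes, test whether the set's composition
deviates from the background with a chi-square goodness-of-fit test,
then locate the deviating classes with per-class adjusted standardized
residual tests under BH correction.

The per-class residual is

    z_c = (O_c - E_c) / sqrt(E_c * (1 - p_c)),

with E_c = p_c * N the expected count under the background proportion
p_c; the (1 - p_c) factor accounts for the multinomial constraint, so
z_c is asymptotically standard normal under the null.  Two-sided normal
p-values are BH-adjusted across the k classes of one composition test
(the smallest defensible family; configurable by adjusting externally).

An independence-style variant is also provided for the case where raw
background *counts* (rather than proportions) are available: the gene
set is contrasted against the rest of the genome in a 2 x k table.
The goodness-of-fit form is the default throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .catalog import AGE_CLASSES
from .stats import TestResult, adjusted_residuals, bh_adjust, chi_square_independence

__all__ = [
    "ClassCounts",
    "ResidualResult",
    "GofResult",
    "expected_counts",
    "gof_test",
    "posthoc_residuals",
    "composition_test",
    "composition_independence_test",
]

_PROP_TOL = 1e-9


def _as_vector(values: Mapping[str, float] | Sequence[float], classes: Sequence[str]) -> np.ndarray:
    if isinstance(values, Mapping):
        missing = [c for c in classes if c not in values]
        if missing:
            raise ValueError(f"missing classes: {missing}")
        return np.asarray([float(values[c]) for c in classes])
    arr = np.asarray(values, dtype=float)
    if arr.size != len(classes):
        raise ValueError(f"expected {len(classes)} values, got {arr.size}")
    return arr


@dataclass(frozen=True)
class ClassCounts:
    """Observed (integer) or expected (real) counts per age class."""

    counts: tuple[float, ...]
    classes: tuple[str, ...] = AGE_CLASSES

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.classes):
            raise ValueError("counts/classes length mismatch")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(sum(self.counts))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.classes, self.counts))


@dataclass(frozen=True)
class ResidualResult:
    age_class: str
    observed: float
    expected: float
    z: float
    p_raw: float
    p_adj: float

    @property
    def direction(self) -> str:
        return "over" if self.z > 0 else ("under" if self.z < 0 else "none")


@dataclass(frozen=True)
class GofResult:
    """Omnibus composition test plus per-class residual post hocs."""

    omnibus: TestResult
    residuals: tuple[ResidualResult, ...]

    def to_dict(self) -> dict:
        return {
            "chi2": self.omnibus.statistic,
            "df": self.omnibus.df,
            "p": self.omnibus.p,
            "method": self.omnibus.method,
            "residuals": [
                {
                    "age_class": r.age_class,
                    "observed": r.observed,
                    "expected": r.expected,
                    "z": r.z,
                    "p_raw": r.p_raw,
                    "p_adj": r.p_adj,
                    "direction": r.direction,
                }
                for r in self.residuals
            ],
        }


def expected_counts(
    background_props: Mapping[str, float] | Sequence[float],
    total: float,
    classes: Sequence[str] = AGE_CLASSES,
) -> ClassCounts:
    """Expected real-valued counts E_c = p_c * total; conserves the total."""
    props = _as_vector(background_props, classes)
    if abs(props.sum() - 1.0) > _PROP_TOL:
        raise ValueError(f"background proportions sum to {props.sum()}, not 1")
    if total < 0:
        raise ValueError("total must be non-negative")
    return ClassCounts(tuple(props * total), tuple(classes))


def gof_test(
    observed: Mapping[str, float] | Sequence[float],
    expected: Mapping[str, float] | Sequence[float],
    classes: Sequence[str] = AGE_CLASSES,
) -> TestResult:
    """Chi-square goodness-of-fit: chi2 = sum (O-E)^2/E, df = k - 1."""
    obs = _as_vector(observed, classes)
    exp = _as_vector(expected, classes)
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be positive; pool sparse classes first")
    if abs(obs.sum() - exp.sum()) > 1e-6 * max(obs.sum(), 1.0):
        raise ValueError("observed and expected totals differ; recompute expected counts")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return TestResult(chi2, float(sps.chi2.sf(chi2, df)), "chi-square goodness-of-fit", df=df)


def posthoc_residuals(
    observed: Mapping[str, float] | Sequence[float],
    background_props: Mapping[str, float] | Sequence[float],
    classes: Sequence[str] = AGE_CLASSES,
) -> tuple[ResidualResult, ...]:
    """Per-class adjusted standardized residual tests with BH correction."""
    obs = _as_vector(observed, classes)
    props = _as_vector(background_props, classes)
    if abs(props.sum() - 1.0) > _PROP_TOL:
        raise ValueError(f"background proportions sum to {props.sum()}, not 1")
    exp = props * obs.sum()
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be positive")
    z = (obs - exp) / np.sqrt(exp * (1.0 - props))
    p_raw = 2.0 * sps.norm.sf(np.abs(z))
    p_adj = bh_adjust(p_raw)
    return tuple(
        ResidualResult(c, float(o), float(e), float(zz), float(pr), float(pa))
        for c, o, e, zz, pr, pa in zip(classes, obs, exp, z, p_raw, p_adj)
    )


def composition_test(
    observed: Mapping[str, float] | Sequence[float],
    background_props: Mapping[str, float] | Sequence[float],
    classes: Sequence[str] = AGE_CLASSES,
) -> GofResult:
    """Omnibus goodness-of-fit against background proportions + post hocs."""
    obs = _as_vector(observed, classes)
    exp = expected_counts(background_props, obs.sum(), classes)
    omnibus = gof_test(obs, exp.counts, classes)
    residuals = posthoc_residuals(obs, background_props, classes)
    return GofResult(omnibus, residuals)


def composition_independence_test(
    observed: Mapping[str, float] | Sequence[float],
    background_counts: Mapping[str, float] | Sequence[float],
    classes: Sequence[str] = AGE_CLASSES,
) -> GofResult:
    """2 x k independence variant against raw background counts.

    The gene set is one row; the background minus the set is the other.
    Post hoc cells use adjusted residuals of the 2 x k table (the gene-set
    row), BH-adjusted across classes.
    """
    obs = _as_vector(observed, classes)
    bg = _as_vector(background_counts, classes)
    rest = bg - obs
    if np.any(rest < 0):
        raise ValueError("background counts must dominate the observed subset")
    table = np.vstack([obs, rest])
    omnibus = chi_square_independence(table)
    z = adjusted_residuals(table)[0]
    p_raw = 2.0 * sps.norm.sf(np.abs(z))
    p_adj = bh_adjust(p_raw)
    exp = table.sum(axis=1, keepdims=True) * table.sum(axis=0) / table.sum()
    residuals = tuple(
        ResidualResult(c, float(o), float(e), float(zz), float(pr), float(pa))
        for c, o, e, zz, pr, pa in zip(classes, obs, exp[0], z, p_raw, p_adj)
    )
    return GofResult(omnibus, residuals)
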