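"""Tau tissue-specificity from a genes x tissues expression matrix.

The tau index of a gene expressed at levels x_1..x_N across N tissues is

    tau = sum_i (1 - x_i / max_j x_j) / (N - 1),

which is 0 for perfectly uniform expression and 1 for single-tissue
expression.  A gene is called tissue-specific at tau >= 0.9 (default),
and specific to a target tissue set (e.g. the male reproductive glands)
when additionally its maximal expression falls in that set.

Expression values are transformed with log2(x + 1) by default before
computing tau, the usual treatment for FPKM-scale RNA-seq abundances so
that the top tissue does not saturate the index; pass
``transform='identity'`` to use raw values.  Note tau is scale-invariant
under the identity transform but not under the log transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TauResult",
    "tau",
    "read_expression_matrix",
    "specificity_calls",
    "compare_tau_by_age",
]

TRANSFORMS = ("log2", "identity")


def _apply_transform(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return x
    if transform == "log2":
        return np.log2(x + 1.0)
    raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")


@dataclass(frozen=True)
class TauResult:
    gene_id: str
    tau: float | None  # None when all-zero (undefined)
    argmax_tissue: str | None
    argmax_tied: bool
    is_specific: bool
    is_target_specific: bool


def tau(expression_row: Sequence[float], transform: str = "log2") -> float | None:
    """Tau tissue-specificity of one expression vector; None if all-zero."""
    x = np.asarray(expression_row, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs at least two tissues")
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise ValueError("expression values must be finite and non-negative")
    x = _apply_transform(x, transform)
    m = x.max()
    if m == 0:
        return None
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def read_expression_matrix(path: str | Path, id_column: str = "gene_id") -> pd.DataFrame:
    """Read a genes-in-rows, tissues-in-columns TSV into a float DataFrame."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if id_column not in df.columns:
        raise ValueError(f"{path}: missing id column {id_column!r}")
    df = df.set_index(id_column)
    mat = df.astype(float)
    if mat.shape[1] < 2:
        raise ValueError("expression matrix needs at least two tissue columns")
    if mat.columns.duplicated().any():
        raise ValueError("tissue labels must be unique")
    if (mat.values < 0).any():
        raise ValueError("expression values must be non-negative")
    return mat


def specificity_calls(
    matrix: pd.DataFrame,
    threshold: float = 0.9,
    target_tissues: Iterable[str] = (),
    transform: str = "log2",
) -> pd.DataFrame:
    """Per-gene tau, argmax tissue, and specificity flags.

    Returns a DataFrame indexed by gene id with columns ``tau``,
    ``argmax_tissue``, ``argmax_tied``, ``is_specific`` and
    ``is_target_specific``.  All-zero genes get NaN tau and False flags
    (undefined; excluded from calls).  Argmax ties resolve to the first
    tissue in column order, with the tie recorded.
    """
    targets = list(target_tissues)
    unknown = [t for t in targets if t not in matrix.columns]
    if unknown:
        raise ValueError(f"unknown target tissues: {unknown}")
    vals = _apply_transform(matrix.values.astype(float), transform)
    if (vals < 0).any():
        raise ValueError("expression values must be non-negative")
    n = vals.shape[1]
    maxima = vals.max(axis=1)
    defined = maxima > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        taus = np.where(defined, (1.0 - vals / maxima[:, None]).sum(axis=1) / (n - 1), np.nan)
    argmax_idx = vals.argmax(axis=1)
    tied = (vals == maxima[:, None]).sum(axis=1) > 1
    tissues = matrix.columns.to_numpy()
    argmax_tissue = tissues[argmax_idx]
    is_specific = defined & (taus >= threshold)
    in_target = np.isin(argmax_tissue, targets) if targets else np.zeros(len(matrix), bool)
    out = pd.DataFrame(
        {
            "tau": taus,
            "argmax_tissue": np.where(defined, argmax_tissue, None),
            "argmax_tied": tied & defined,
            "is_specific": is_specific,
            "is_target_specific": is_specific & in_target,
        },
        index=matrix.index,
    )
    out.index.name = "gene_id"
    return out


def compare_tau_by_age(
    tau_table: pd.DataFrame,
    catalog,
    grouping: str = "five_class",
):
    """Compare tau distributions across gene-age groups.

    ``grouping='five_class'`` contrasts age classes A..E;
    ``'pre_vs_during'`` pools B..E into a "during-radiation" group and
    contrasts it with the pre-radiation class A.  Returns a
    :class:`sfpage.stats.GroupComparison` (Kruskal-Wallis omnibus with
    pairwise rank-sum post hocs under BH).  Genes without an assigned
    age or with undefined tau are excluded.
    """
    from .stats import compare_groups

    groups: dict[str, list[float]] = {}
    for rec in catalog:
        if rec.age_class == "unassigned" or rec.gene_id not in tau_table.index:
            continue
        value = tau_table.loc[rec.gene_id, "tau"]
        if pd.isna(value):
            continue
        if grouping == "five_class":
            label = rec.age_class
        elif grouping == "pre_vs_during":
            label = "pre" if rec.age_class == "A" else "during"
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        groups.setdefault(label, []).append(float(value))
    return compare_groups(groups)
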