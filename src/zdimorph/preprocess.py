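"""Across-array normalization and probe→EST summarization.

Stands in for the "RMA normalized" step of the original processing chain:
quantile normalization forces all arrays to share one empirical intensity
distribution, and Tukey median polish robustly fits the additive probe-level
model ``log2 y[p, s] = mu + probe_p + sample_s`` per EST, reporting
``mu + sample_s`` as the EST's log2 expression.  Full RMA background
correction (normal+exponential deconvolution) is intentionally omitted:
the downstream analysis is a between-sex contrast within each array set,
which a global background shift leaves essentially unchanged.  An optional
global percentile shift is provided for users who want one.

Median polish sweeps start with the sample (column) medians.  This makes
summarization exactly equivariant under per-sample constant shifts — adding
c to every log2 intensity of one array adds exactly c to that array's EST
expression values — because the first column sweep absorbs the shift and
every subsequent sweep sees identical residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ArrayDesign, MatrixError, SampleSheet

__all__ = [
    "quantile_normalize",
    "background_shift",
    "median_polish",
    "median_polish_summarize",
    "QCReport",
    "sample_qc",
]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the same empirical distribution.

    Rank r in each column is replaced by the mean across columns of the
    rank-r order statistics.  Ties within a column receive the mean of the
    target values they would have occupied, so the result is deterministic
    regardless of sort stability.  The grand sum of the matrix is preserved.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize with a single column is the identity")
        return matrix.copy()
    x = matrix.to_numpy(dtype=float)
    nrow, ncol = x.shape
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(ncol):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = target.copy()
        # average target values over blocks of tied input values
        sorted_col = col[order]
        block_start = 0
        for i in range(1, nrow + 1):
            if i == nrow or sorted_col[i] != sorted_col[block_start]:
                if i - block_start > 1:
                    assigned[block_start:i] = assigned[block_start:i].mean()
                block_start = i
        out[order, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def background_shift(matrix: pd.DataFrame, percentile: float = 1.0) -> pd.DataFrame:
    """Optional global background adjustment: subtract a low global
    percentile of the pooled intensities from every entry, flooring at a
    small positive value to preserve positivity."""
    bg = np.percentile(matrix.to_numpy(), percentile)
    floor = matrix.to_numpy().min() * 1e-3
    return (matrix - bg).clip(lower=max(floor, 1e-6))


def median_polish(
    y: np.ndarray, tol: float = 0.01, max_iter: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Median polish of a stack of two-way tables.

    Parameters
    ----------
    y : ndarray, shape (n_tables, n_rows, n_cols)
        Tables to polish (rows = probes, cols = samples).
    tol : float
        Convergence: stop once the largest absolute sweep adjustment falls
        below this (after the first full iteration).
    max_iter : int
        Maximum number of full (column + row) sweep iterations.

    Returns
    -------
    overall : (n_tables,) grand effects (median of row effects)
    row : (n_tables, n_rows) probe effects (relative to overall)
    col : (n_tables, n_cols) sample effects
    resid : (n_tables, n_rows, n_cols) residuals

    The fitted value is ``overall + row + col + resid = y`` exactly.
    Column sweeps come first (see module docstring).
    """
    r = np.asarray(y, dtype=float).copy()
    if r.ndim == 2:
        r = r[None, :, :]
    n_t, n_r, n_c = r.shape
    row = np.zeros((n_t, n_r))
    col = np.zeros((n_t, n_c))
    for it in range(max_iter):
        cd = np.median(r, axis=1)  # over rows -> per-column medians
        col += cd
        r -= cd[:, None, :]
        rd = np.median(r, axis=2)  # over columns -> per-row medians
        row += rd
        r -= rd[:, :, None]
        delta = max(np.abs(cd).max(initial=0.0), np.abs(rd).max(initial=0.0))
        if it > 0 and delta < tol:
            break
    overall = np.median(row, axis=1)
    row = row - overall[:, None]
    return overall, row, col, r


def median_polish_summarize(
    matrix: pd.DataFrame,
    design: ArrayDesign,
    tol: float = 0.01,
    max_iter: int = 10,
) -> pd.DataFrame:
    """Summarize normalized probe intensities to EST-level log2 expression.

    Per EST the additive model ``log2 y = mu + probe + sample`` is fitted by
    median polish; the EST's expression in sample s is ``mu + sample_s``.
    ESTs are processed in vectorised groups of equal probe count.
    """
    probe_index = {p: i for i, p in enumerate(matrix.index)}
    missing = [p for p in design.probe_to_est() if p not in probe_index]
    if missing:
        raise MatrixError(f"{len(missing)} design probe(s) missing from matrix, e.g. {missing[:3]}")
    log2x = np.log2(matrix.to_numpy(dtype=float))
    n_samples = matrix.shape[1]

    counts = design.probe_counts()
    est_ids = design.est_ids
    expr = np.empty((len(est_ids), n_samples))
    est_pos = {e: i for i, e in enumerate(est_ids)}
    for k in sorted(counts.unique()):
        members = counts.index[counts == k]
        rows = np.array(
            [[probe_index[p] for p in design.table.at[e, "probe_ids"]] for e in members]
        )
        stack = log2x[rows]  # (n_member, k, n_samples)
        overall, _row, col, _resid = median_polish(stack, tol=tol, max_iter=max_iter)
        vals = overall[:, None] + col
        for e, v in zip(members, vals):
            expr[est_pos[e]] = v
    return pd.DataFrame(expr, index=est_ids.rename("est_id"), columns=matrix.columns)


@dataclass
class QCReport:
    """Within-species replicate-correlation QC."""

    correlations: dict[str, pd.DataFrame] = field(default_factory=dict)
    mean_correlation: dict[str, float] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)
    threshold: float = 0.9


def sample_qc(expr: pd.DataFrame, sheet: SampleSheet, threshold: float = 0.9) -> QCReport:
    """Flag samples whose mean correlation to same-species replicates is low.

    Report-only: exclusion of flagged samples is a pipeline option, mirroring
    how deviating replicate profiles are handled by inspection in practice.
    A non-positive threshold disables flagging (correlations are still
    reported).
    """
    report = QCReport(threshold=threshold)
    for species in sheet.table["species"].unique():
        ids = [s for s in sheet.for_species(species).index if s in expr.columns]
        if len(ids) < 2:
            continue
        corr = expr[ids].corr(method="pearson")
        report.correlations[species] = corr
        off_diag = corr.where(~np.eye(len(ids), dtype=bool))
        means = off_diag.mean(axis=1, skipna=True)
        for s, m in means.items():
            report.mean_correlation[s] = float(m)
            if threshold > 0 and m < threshold:
                report.flagged.append(s)
    return report
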