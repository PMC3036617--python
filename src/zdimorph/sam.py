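"""Two-class unpaired Significance Analysis of Microarrays (SAM).

SAM scores each EST with a moderated relative difference

    d_i = (mean_treatment_i - mean_control_i) / (s_i + s0)

where s_i is the pooled standard error of the difference and s0 is a small
"fudge factor" chosen so that the variance of d is roughly independent of
expression level.  Significance is judged against permutations of the
sample labels: observed order statistics d_(i) are compared with their
permutation expectations d̄_(i); for a chosen displacement delta, ESTs
whose d falls beyond the identity line by more than delta are called
significant, and the false discovery rate is estimated as the (median)
number of permuted scores falling outside the cutoffs divided by the number
of calls.  Delta is selected to bring the estimated FDR as close as
possible to a target (3% by default, as in two-class brain-expression
scans where fold changes are small and no fold-change criterion is
imposed).

The interface follows the model/results idiom: build a :class:`SAMTwoClass`
from an expression matrix plus group labels, call :meth:`~SAMTwoClass.fit`,
inspect the returned :class:`SAMResults` (or ``summary()``).  Lower-level
pieces (``compute_d``, ``estimate_s0``, ``permutation_null``,
``select_delta``) are module functions usable on their own.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SamConfig",
    "SAMTwoClass",
    "SAMResults",
    "compute_d",
    "estimate_s0",
    "permutation_null",
    "select_delta",
    "fold_change",
]


@dataclass
class SamConfig:
    """Settings for one SAM run."""

    n_permutations: int = 500
    target_fdr: float = 0.03
    s0_method: str = "tusher_percentile_scan"  # or "fixed_percentile", "zero"
    s0_fixed_percentile: float = 50.0
    delta_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.05, 5.0 + 1e-9, 0.01), 10)
    )
    pi0: float | str = 1.0  # 1.0 (conservative) or "estimate"
    max_fdr: float = 0.5  # operating points above this estimated FDR are unusable
    seed: int | None = None

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.target_fdr < 1.0:
            raise ValueError("target_fdr must be in (0, 1)")
        if self.s0_method not in {"tusher_percentile_scan", "fixed_percentile", "zero"}:
            raise ValueError(f"unknown s0_method {self.s0_method!r}")


def compute_d(
    x: np.ndarray, treatment_mask: np.ndarray, s0: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Relative difference d_i and pooled standard error s_i per row.

    d_i = (x̄_treatment - x̄_control) / (s_i + s0) with

    s_i = sqrt{(1/n1 + 1/n2) * [SS_control + SS_treatment] / (n1 + n2 - 2)}.

    At s0 = 0 this is the ordinary pooled-variance two-sample t statistic.
    """
    x = np.asarray(x, dtype=float)
    t_mask = np.asarray(treatment_mask, dtype=bool)
    n2 = int(t_mask.sum())
    n1 = int((~t_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    xt = x[:, t_mask]
    xc = x[:, ~t_mask]
    mt = xt.mean(axis=1)
    mc = xc.mean(axis=1)
    ss = ((xc - mc[:, None]) ** 2).sum(axis=1) + ((xt - mt[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    num = mt - mc
    denom = s + s0
    zero = denom <= 0
    if (zero & (num != 0)).any():
        raise ValueError(
            "zero pooled error with a nonzero difference at s0=0 gives an "
            "infinite d; increase s0 or use the percentile scan"
        )
    d = np.zeros_like(num)
    np.divide(num, denom, out=d, where=~zero)  # 0/0 (constant EST) -> d = 0
    return d, s


def _scan_criterion(num: np.ndarray, s: np.ndarray, s0: float, n_windows: int = 100) -> float:
    """Coefficient of variation of windowed MADs of d(s0).

    Windows are s-quantile bins; the MAD of d within each bin measures the
    spread of d at that expression-variability level.  A good s0 makes that
    spread flat in s, i.e. minimizes the CV across windows.
    """
    denom = s + s0
    d = np.zeros_like(num)
    np.divide(num, denom, out=d, where=denom > 0)
    order = np.argsort(s, kind="mergesort")
    d_sorted = d[order]
    n = len(d)
    n_windows = max(2, min(n_windows, n // 2))
    edges = np.linspace(0, n, n_windows + 1).astype(int)
    mads = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            w = d_sorted[a:b]
            mads.append(np.median(np.abs(w - np.median(w))) * 1.4826)
    mads = np.asarray(mads)
    mean = mads.mean()
    if mean == 0:
        return np.inf
    return float(mads.std(ddof=1) / mean)


def estimate_s0(
    d: np.ndarray, s: np.ndarray, method: str = "tusher_percentile_scan",
    fixed_percentile: float = 50.0,
) -> float:
    """Choose the fudge factor s0 from d (computed at s0=0) and s.

    ``tusher_percentile_scan`` evaluates candidate s0 values at the
    percentiles {0, 5, ..., 95} of s and returns the candidate minimizing
    the coefficient of variation of windowed MADs of the resulting d;
    ties (including the all-s-equal degenerate case) resolve to the
    smallest candidate.  Deterministic.
    """
    if method == "zero":
        return 0.0
    s = np.asarray(s, dtype=float)
    if method == "fixed_percentile":
        return float(np.percentile(s, fixed_percentile))
    num = np.asarray(d, dtype=float) * s  # recover the numerator
    candidates = np.unique(np.percentile(s, np.arange(0, 100, 5)))
    if candidates.max() == candidates.min():
        return float(candidates.min())
    best_s0 = float(candidates[0])
    best_cv = np.inf
    for cand in sorted(candidates):
        cv = _scan_criterion(num, s, float(cand))
        if cv < best_cv - 1e-12:
            best_cv = cv
            best_s0 = float(cand)
    return best_s0


def _assignments(n: int, n_treatment: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct treatment-label assignments as a (B', n) boolean matrix.

    Full enumeration when C(n, n_treatment) <= B, otherwise B distinct
    assignments sampled uniformly without replacement.
    """
    total = math.comb(n, n_treatment)
    if total <= 1:
        raise ValueError("no nontrivial label permutation exists")
    if total <= B:
        combos = list(combinations(range(n), n_treatment))
    elif total <= 200_000:
        all_combos = list(combinations(range(n), n_treatment))
        idx = rng.choice(total, size=B, replace=False)
        combos = [all_combos[i] for i in sorted(idx)]
    else:
        seen: set[tuple[int, ...]] = set()
        while len(seen) < B:
            pick = tuple(sorted(rng.choice(n, size=n_treatment, replace=False).tolist()))
            seen.add(pick)
        combos = sorted(seen)
    out = np.zeros((len(combos), n), dtype=bool)
    for i, c in enumerate(combos):
        out[i, list(c)] = True
    return out


def permutation_null(
    x: np.ndarray,
    n_treatment: int,
    s0: float,
    n_permutations: int = 500,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected order statistics d̄_(i) and per-permutation sorted d.

    Labels are permuted jointly across all rows (preserving inter-gene
    correlation).  Returns (dbar, perm_sorted) where perm_sorted has shape
    (B, n_genes) with each row sorted ascending and dbar is its column
    mean.
    """
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    n = x.shape[1]
    masks = _assignments(n, n_treatment, n_permutations, rng)
    B = masks.shape[0]
    n1 = n - n_treatment
    n2 = n_treatment
    # vectorised across permutations: group sums via matmul
    tot = x.sum(axis=1, keepdims=True)  # (g, 1)
    sum_t = x @ masks.T.astype(float)  # (g, B)
    sum_c = tot - sum_t
    mt = sum_t / n2
    mc = sum_c / n1
    sq = (x**2).sum(axis=1, keepdims=True)
    sq_t = (x**2) @ masks.T.astype(float)
    sq_c = sq - sq_t
    ss = (sq_c - n1 * mc**2) + (sq_t - n2 * mt**2)
    ss = np.maximum(ss, 0.0)  # guard tiny negative round-off
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    denom = s + s0
    d = np.zeros_like(denom)
    np.divide(mt - mc, denom, out=d, where=denom > 0)
    perm_sorted = np.sort(d, axis=0).T  # (B, g)
    dbar = perm_sorted.mean(axis=0)
    return dbar, perm_sorted


def select_delta(
    d: np.ndarray,
    dbar: np.ndarray,
    perm_sorted: np.ndarray,
    delta_grid: np.ndarray,
    target_fdr: float,
    pi0: float = 1.0,
    max_fdr: float = 0.5,
) -> tuple[float, float, float, float]:
    """Pick the delta whose estimated FDR is closest to the target.

    For each delta: cutup is the smallest observed order statistic lying
    above the identity line by more than delta, cutlow the largest lying
    below by more than delta; ESTs outside (cutlow, cutup) are called.
    FDR(delta) = pi0 * median_b #{permuted d_b outside cutoffs} / #called.
    Ties in |FDR - target| break toward the smallest delta, so when the
    median-based estimate plateaus at zero the call set is the largest one
    achieving that estimate rather than a single extreme EST.  Operating
    points whose estimated FDR exceeds ``max_fdr`` are not usable: on data
    with no real group difference every delta estimates an FDR near 1, and
    the honest answer is an empty significant set, not a full one.

    Returns (delta, fdr_estimate, cutlow, cutup).  If no delta yields a
    usable call set, returns the largest delta with (fdr 0.0, +/-inf
    cutoffs) and warns.
    """
    d_sorted = np.sort(np.asarray(d, dtype=float))
    diff = d_sorted - dbar
    best = None  # (gap, delta, fdr, cutlow, cutup, n_called)
    for delta in delta_grid:
        up_idx = np.nonzero(diff > delta)[0]
        lo_idx = np.nonzero(diff < -delta)[0]
        cutup = d_sorted[up_idx[0]] if up_idx.size else np.inf
        cutlow = d_sorted[lo_idx[-1]] if lo_idx.size else -np.inf
        n_called = int(((d >= cutup) | (d <= cutlow)).sum())
        if n_called == 0:
            continue
        false_counts = ((perm_sorted >= cutup) | (perm_sorted <= cutlow)).sum(axis=1)
        fdr = pi0 * float(np.median(false_counts)) / n_called
        if fdr > max_fdr:
            continue
        gap = abs(fdr - target_fdr)
        if best is None or gap < best[0] - 1e-15:
            best = (gap, float(delta), fdr, float(cutlow), float(cutup), n_called)
    if best is None:
        warnings.warn("no delta in the grid yields a usable significant set")
        return float(delta_grid[-1]), 0.0, -np.inf, np.inf
    return best[1], best[2], best[3], best[4]


def fold_change(
    unlogged: pd.DataFrame, male_ids: Sequence[str], female_ids: Sequence[str]
) -> pd.Series:
    """Unlogged fold change: mean male expression over mean female expression."""
    fc = unlogged[list(male_ids)].mean(axis=1) / unlogged[list(female_ids)].mean(axis=1)
    return fc.rename("fold_change")


def estimate_pi0(d: np.ndarray, perm_sorted: np.ndarray) -> float:
    """Fraction of observed d inside the permutation interquartile band,
    scaled so that a pure-null d vector gives ~1; capped at 1."""
    q25, q75 = np.percentile(perm_sorted.ravel(), [25, 75])
    inside = ((d >= q25) & (d <= q75)).sum()
    return float(min(1.0, inside / (0.5 * len(d))))


class SAMTwoClass:
    """Two-class unpaired SAM model.

    Parameters
    ----------
    expr : pandas.DataFrame
        EST-by-sample log2 expression.
    groups : Sequence[str]
        Group label per column of ``expr`` (two distinct labels).
    control, treatment : str
        Which label is which.  The statistic is treatment minus control;
        significance calls and directions are invariant to the designation.
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        groups: Sequence[str],
        control: str = "male",
        treatment: str = "female",
    ):
        if len(groups) != expr.shape[1]:
            raise ValueError("one group label per sample column required")
        groups = pd.Series(list(groups), index=expr.columns)
        labels = set(groups)
        if labels != {control, treatment}:
            raise ValueError(
                f"group labels {sorted(labels)} do not match control={control!r}, "
                f"treatment={treatment!r}"
            )
        for lab in (control, treatment):
            if (groups == lab).sum() < 2:
                raise ValueError(f"group {lab!r} needs >= 2 samples")
        self.expr = expr
        self.groups = groups
        self.control = control
        self.treatment = treatment

    @classmethod
    def from_frames(
        cls,
        expr: pd.DataFrame,
        sheet,
        group_by: str = "sex",
        control: str = "male",
        treatment: str = "female",
        species: str | None = None,
    ) -> "SAMTwoClass":
        """Build from an expression matrix and a sample sheet."""
        tab = sheet.table
        if species is not None:
            tab = tab[tab["species"] == species]
        ids = [s for s in expr.columns if s in tab.index]
        return cls(expr[ids], tab.loc[ids, group_by], control=control, treatment=treatment)

    def fit(self, config: SamConfig | None = None, **overrides) -> "SAMResults":
        """Run the full SAM procedure and return a :class:`SAMResults`."""
        if config is None:
            config = SamConfig(**overrides)
        elif overrides:
            import dataclasses

            config = dataclasses.replace(config, **overrides)
        config.validate()
        rng = np.random.default_rng(config.seed)
        x = self.expr.to_numpy(dtype=float)
        t_mask = (self.groups == self.treatment).to_numpy()

        d0, s = compute_d(x, t_mask, s0=0.0)
        s0 = estimate_s0(
            d0, s, method=config.s0_method, fixed_percentile=config.s0_fixed_percentile
        )
        d, s = compute_d(x, t_mask, s0=s0)
        dbar, perm_sorted = permutation_null(
            x, int(t_mask.sum()), s0, n_permutations=config.n_permutations, rng=rng
        )
        pi0 = estimate_pi0(d, perm_sorted) if config.pi0 == "estimate" else float(config.pi0)
        delta, fdr, cutlow, cutup = select_delta(
            d, dbar, perm_sorted, np.asarray(config.delta_grid), config.target_fdr, pi0,
            max_fdr=config.max_fdr,
        )
        called = (d >= cutup) | (d <= cutlow)

        sex = self.groups  # may be any two labels; directions use means
        male_like = self.control  # conventionally "male"
        mc = x[:, ~t_mask].mean(axis=1)
        mt = x[:, t_mask].mean(axis=1)
        # direction: which group mean is larger (control-designation invariant)
        higher_in_control = mc > mt

        return SAMResults(
            model=self,
            config=config,
            d=pd.Series(d, index=self.expr.index, name="d"),
            s=pd.Series(s, index=self.expr.index, name="s"),
            s0=s0,
            dbar=dbar,
            perm_sorted=perm_sorted,
            pi0=pi0,
            delta=delta,
            fdr=fdr,
            cutlow=cutlow,
            cutup=cutup,
            significant=self.expr.index[called],
            higher_in_control=pd.Series(higher_in_control, index=self.expr.index),
        )


@dataclass
class SAMResults:
    """Results of a SAM fit: scores, operating point, calls, fold changes."""

    model: SAMTwoClass
    config: SamConfig
    d: pd.Series
    s: pd.Series
    s0: float
    dbar: np.ndarray
    perm_sorted: np.ndarray
    pi0: float
    delta: float
    fdr: float
    cutlow: float
    cutup: float
    significant: pd.Index
    higher_in_control: pd.Series

    @property
    def n_called(self) -> int:
        return len(self.significant)

    def direction(self, male_label: str = "male", female_label: str = "female") -> pd.Series:
        """Per-EST direction among significant ESTs: which sex is higher."""
        m = self.model
        if male_label == m.control:
            is_male = self.higher_in_control
        elif male_label == m.treatment:
            is_male = ~self.higher_in_control
        else:
            raise ValueError(f"{male_label!r} is neither group of this fit")
        lab = np.where(is_male[self.significant], male_label, female_label)
        return pd.Series(lab, index=self.significant, name="direction")

    def fold_changes(self, male_label: str = "male", female_label: str = "female") -> pd.Series:
        """Unlogged FC (mean male / mean female) for significant ESTs."""
        m = self.model
        unlogged = np.exp2(m.expr.loc[self.significant])
        male_ids = m.groups.index[m.groups == male_label]
        female_ids = m.groups.index[m.groups == female_label]
        return fold_change(unlogged, male_ids, female_ids)

    def to_frame(self) -> pd.DataFrame:
        """Per-EST result table (all ESTs; calls and FC filled where defined)."""
        out = pd.DataFrame({"d": self.d, "s": self.s})
        out["significant"] = out.index.isin(self.significant)
        try:
            direc = self.direction()
            fc = self.fold_changes()
            out["direction"] = direc.reindex(out.index)
            out["fold_change"] = fc.reindex(out.index)
        except ValueError:
            out["direction"] = pd.NA
            out["fold_change"] = np.nan
        return out

    def summary(self) -> str:
        direc = None
        try:
            direc = self.direction()
        except ValueError:
            pass
        lines = [
            "Two-class unpaired SAM",
            "=" * 46,
            f"ESTs tested            {len(self.d):>10d}",
            f"samples                {self.model.expr.shape[1]:>10d}"
            f"  ({self.model.control} vs {self.model.treatment})",
            f"permutations           {self.perm_sorted.shape[0]:>10d}",
            f"s0 (fudge factor)      {self.s0:>10.4f}",
            f"pi0                    {self.pi0:>10.3f}",
            f"delta                  {self.delta:>10.3f}",
            f"estimated FDR          {self.fdr:>10.4f}",
            f"cutlow / cutup         {self.cutlow:>10.3f} / {self.cutup:.3f}",
            f"significant ESTs       {self.n_called:>10d}",
        ]
        if direc is not None and self.n_called:
            n_m = int((direc == "male").sum())
            n_f = self.n_called - n_m
            lines.append(f"  male-biased          {n_m:>10d}")
            lines.append(f"  female-biased        {n_f:>10d}")
        return "\n".join(lines)

    def save_tsv(self, path, precision: int = 6) -> None:
        self.to_frame().rename_axis("est_id").to_csv(
            path, sep="\t", float_format=f"%.{precision}f"
        )
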