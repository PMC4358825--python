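"""Longitudinal analysis of apparent cell counts.

A cohort of subjects is imaged at an ordered set of timepoints and each scan is
reduced to an apparent cell count N̂.  The within-subject decay over time is
tested with a one-way repeated-measures ANOVA whose degrees of freedom are
scaled by the Greenhouse–Geisser sphericity estimate ε̂ — producing the familiar
fractional df — followed by Tukey HSD pairwise comparisons of timepoints based
on the studentized-range distribution.  Percent-of-baseline and per-timepoint
detectability tallies summarize the biology-facing quantities.

Zero counts are valid observations (an undetectable implant is still a
measurement); subjects with *missing* timepoints are excluded from the ANOVA
(complete-case analysis) with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LongitudinalTable",
    "AnovaResult",
    "TukeyResult",
    "rm_anova",
    "tukey_posthoc",
    "percent_remaining",
    "detectability_tally",
]


@dataclass(frozen=True)
class LongitudinalTable:
    """Subjects × timepoints matrix of cell counts.

    ``counts`` is a DataFrame indexed by subject with one ordered column per
    timepoint; NaN marks a missing scan.  ``complete`` flags subjects with a
    value at every timepoint — only those enter the ANOVA.
    """

    counts: pd.DataFrame
    complete: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        counts = self.counts.astype(float)
        if counts.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if (counts.to_numpy() < 0).any():
            raise ValueError("cell counts must be nonnegative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "complete", counts.notna().all(axis=1))

    @property
    def timepoints(self) -> list:
        return list(self.counts.columns)

    @property
    def subjects(self) -> list:
        return list(self.counts.index)

    def complete_cases(self) -> pd.DataFrame:
        dropped = [s for s, ok in self.complete.items() if not ok]
        if dropped:
            warnings.warn(
                f"excluding {len(dropped)} subject(s) with missing timepoints: {dropped}",
                stacklevel=3,
            )
        return self.counts.loc[self.complete]

    @classmethod
    def from_long(cls, df: pd.DataFrame, subject: str = "subject",
                  timepoint: str = "timepoint", value: str = "cell_count",
                  timepoint_order: list | None = None) -> "LongitudinalTable":
        """Build from a long-format table (one row per subject × timepoint)."""
        wide = df.pivot(index=subject, columns=timepoint, values=value)
        if timepoint_order is not None:
            wide = wide[timepoint_order]
        return cls(wide)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "LongitudinalTable":
        return cls.from_long(pd.read_csv(path), **kwargs)


@dataclass(frozen=True)
class AnovaResult:
    """Repeated-measures ANOVA with sphericity-corrected fractional df.

    ``df1 = ε̂(k−1)`` and ``df2 = ε̂(k−1)(n−1)``, so df2/df1 = n−1 exactly,
    which is how the number of complete cases can be read off a printed
    F(df1, df2).
    """

    F: float
    df1: float
    df2: float
    epsilon: float
    p: float
    n_subjects: int
    n_timepoints: int

    def __str__(self) -> str:  # e.g. "F(1.703, 6.812) = 39.85, p = 0.0002, n = 5"
        return (f"F({self.df1:.3f}, {self.df2:.3f}) = {self.F:.2f}, "
                f"p = {self.p:.4g}, n = {self.n_subjects}")


@dataclass(frozen=True)
class TukeyResult:
    """All pairwise timepoint comparisons (studentized-range adjusted)."""

    table: pd.DataFrame  # columns: level_a, level_b, mean_diff, q, p_adj
    ms_error: float
    df_error: float
    n_subjects: int


def _anova_components(wide: pd.DataFrame) -> tuple[np.ndarray, float, float, int, int]:
    """Complete-case matrix and within-subject sums of squares."""
    x = wide.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 complete subjects")
    grand = x.mean()
    col_means = x.mean(axis=0)
    row_means = x.mean(axis=1)
    ss_time = n * float(((col_means - grand) ** 2).sum())
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_error = float((resid**2).sum())
    return x, ss_time, ss_error, n, k


def greenhouse_geisser_epsilon(x: np.ndarray) -> float:
    """Greenhouse–Geisser ε̂ from the double-centered timepoint covariance.

    With S the k×k sample covariance of the timepoint columns and S̃ its
    double-centered form, ε̂ = tr(S̃)² / ((k−1)·tr(S̃²)) — equivalently the
    eigenvalue form (Σλᵢ)²/((k−1)Σλᵢ²).  Clipped to its theoretical range
    [1/(k−1), 1]; a degenerate (all-zero) covariance reports ε̂ = 1.
    """
    n, k = x.shape
    s = np.cov(x, rowvar=False, ddof=1)
    dc = s - s.mean(axis=0)[None, :] - s.mean(axis=1)[:, None] + s.mean()
    tr = float(np.trace(dc))
    tr2 = float(np.trace(dc @ dc))
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / ((k - 1) * tr2)
    return float(min(1.0, max(1.0 / (k - 1), eps)))


def rm_anova(table: LongitudinalTable) -> AnovaResult:
    """One-way repeated-measures ANOVA on complete cases, GG-corrected.

    F = MS_time / MS_error from the within-subject decomposition; the p-value
    is taken from the F distribution at (ε̂(k−1), ε̂(k−1)(n−1)) degrees of
    freedom.  A constant table (no time effect anywhere) yields F = 0, p = 1.
    """
    wide = table.complete_cases()
    x, ss_time, ss_error, n, k = _anova_components(wide)
    eps = greenhouse_geisser_epsilon(x)
    df1 = eps * (k - 1)
    df2 = eps * (k - 1) * (n - 1)
    if ss_time == 0.0:
        return AnovaResult(F=0.0, df1=df1, df2=df2, epsilon=eps, p=1.0,
                           n_subjects=n, n_timepoints=k)
    ms_time = ss_time / (k - 1)
    ms_error = ss_error / ((k - 1) * (n - 1))
    if ms_error == 0.0:
        return AnovaResult(F=np.inf, df1=df1, df2=df2, epsilon=eps, p=0.0,
                           n_subjects=n, n_timepoints=k)
    f = ms_time / ms_error
    p = float(stats.f.sf(f, df1, df2))
    return AnovaResult(F=float(f), df1=float(df1), df2=float(df2),
                       epsilon=eps, p=p, n_subjects=n, n_timepoints=k)


def tukey_posthoc(table: LongitudinalTable, gg_correct_df: bool = False) -> TukeyResult:
    """Tukey HSD over all timepoint pairs with the within-subject error term.

    q = |mean difference| / sqrt(MS_error / n); adjusted p from the
    studentized-range distribution with k means and the (by default
    uncorrected) error df (k−1)(n−1).  Set ``gg_correct_df`` to scale the
    error df by ε̂.
    """
    wide = table.complete_cases()
    x, _, ss_error, n, k = _anova_components(wide)
    ms_error = ss_error / ((k - 1) * (n - 1))
    df_error = float((k - 1) * (n - 1))
    if gg_correct_df:
        df_error *= greenhouse_geisser_epsilon(x)
    col_means = x.mean(axis=0)
    levels = list(wide.columns)
    rows = []
    se = np.sqrt(ms_error / n) if ms_error > 0 else 0.0
    for i, j in combinations(range(k), 2):
        diff = float(col_means[j] - col_means[i])
        if se > 0:
            q = abs(diff) / se
            p = float(np.clip(stats.studentized_range.sf(q, k, df_error), 0.0, 1.0))
        else:  # zero error variance: any difference is infinitely significant
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        rows.append({"level_a": levels[i], "level_b": levels[j],
                     "mean_diff": diff, "q": q, "p_adj": p})
    return TukeyResult(table=pd.DataFrame(rows), ms_error=float(ms_error),
                       df_error=df_error, n_subjects=n)


def percent_remaining(table: LongitudinalTable, baseline_timepoint) -> pd.DataFrame:
    """Per-subject counts as percent of the baseline timepoint.

    The baseline column is 100 by construction.  Subjects with a zero (or
    missing) baseline cannot be normalized; they are dropped with a warning.
    """
    if baseline_timepoint not in table.counts.columns:
        raise ValueError(f"baseline timepoint {baseline_timepoint!r} not in table")
    baseline = table.counts[baseline_timepoint]
    bad = baseline.isna() | (baseline <= 0)
    if bad.any():
        warnings.warn(
            f"excluding subject(s) with zero/missing baseline: {list(baseline.index[bad])}",
            stacklevel=2,
        )
    kept = table.counts.loc[~bad]
    return kept.div(kept[baseline_timepoint], axis=0) * 100.0


def detectability_tally(flags: pd.DataFrame) -> pd.DataFrame:
    """Count detectable subjects per timepoint from a subjects × timepoints flag table.

    Returns one row per timepoint with columns ``n_detectable``, ``n_total``,
    ``fraction`` and a display string like ``"2/7"``.
    """
    flags = flags.astype(bool)
    n_det = flags.sum(axis=0).astype(int)
    n_tot = flags.shape[0]
    out = pd.DataFrame({
        "timepoint": list(flags.columns),
        "n_detectable": n_det.to_numpy(),
        "n_total": n_tot,
    })
    out["fraction"] = out["n_detectable"] / out["n_total"]
    out["display"] = [f"{a}/{n_tot}" for a in out["n_detectable"]]
    return out
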