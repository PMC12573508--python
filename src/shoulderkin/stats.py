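"""Cohort statistics: paired t-tests, agreement ICCs, and the summary table.

Supine and upright joint angles are repeated measures on the same patients,
so pose differences are tested with two-sided paired t-tests (significance
p <= .05, marginal significance p <= .10; no multiple-testing correction
across the six degrees of freedom).

Landmarking reliability is quantified with the single-measure,
absolute-agreement intraclass correlation coefficient from the two-way
ANOVA decomposition (McGraw & Wong ICC(A,1)).  The same point estimate
serves the two-way random model (interobserver: multiple observers, one
time point) and the two-way mixed model (intraobserver: one observer,
multiple time points); only the interpretation of the rater factor changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .angles import GH_DOFS, ST_DOFS, PosePair

__all__ = [
    "TTestResult",
    "ICCResult",
    "InsufficientCohortError",
    "paired_t_test",
    "icc_single_absolute",
    "icc_interpretation",
    "summarize_cohort",
]

SIGNIFICANCE_P = 0.05
MARGINAL_P = 0.10


class InsufficientCohortError(ValueError):
    """Fewer than two valid patients remain after exclusions."""


@dataclass(frozen=True)
class TTestResult:
    """Two-sided paired t-test on differences d = b - a."""

    mean_diff: float
    sd_diff: float
    t_stat: float
    df: int
    p_value: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return not self.degenerate and self.p_value <= SIGNIFICANCE_P

    @property
    def marginal(self) -> bool:
        return not self.degenerate and self.p_value <= MARGINAL_P


@dataclass(frozen=True)
class ICCResult:
    model: str  # "two_way_random" | "two_way_mixed"
    value: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_targets: int
    n_raters: int
    degenerate: bool = False
    definition = "absolute_agreement"
    form = "single_measure"

    @property
    def interpretation(self) -> str:
        if self.degenerate:
            return "undefined"
        return icc_interpretation(self.value)


def icc_interpretation(value: float) -> str:
    """Reliability band: <0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, >0.9 excellent."""
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def paired_t_test(a, b) -> TTestResult:
    """Two-sided paired t-test of ``b`` against ``a`` (d = b - a).

    t = mean(d) / (sd(d)/sqrt(n)) with n-1 degrees of freedom; sd is the
    sample standard deviation (ddof=1).  Zero-variance differences yield a
    flagged degenerate result (p = nan) rather than an error, so batch runs
    on synthetic edge cases do not abort.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError("paired samples must be finite")
    d = b - a
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            # identical samples: no difference and no evidence against that
            return TTestResult(0.0, 0.0, 0.0, df, 1.0, degenerate=False)
        return TTestResult(mean, 0.0, math.nan, df, math.nan, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(mean, sd, t, df, p, degenerate=False)


def icc_single_absolute(ratings, model: str = "two_way_random") -> ICCResult:
    """Single-measure absolute-agreement ICC from a targets x raters matrix.

    Computes the two-way ANOVA mean squares (rows = targets, columns =
    raters, interaction/error pooled) and

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    ``model`` records whether raters are a random sample ("two_way_random")
    or the fixed set of interest ("two_way_mixed"); the point estimate is
    identical for both.
    """
    if model not in ("two_way_random", "two_way_mixed"):
        raise ValueError(f"unknown ICC model {model!r}")
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n>=2 by k>=2 matrix")
    if np.any(~np.isfinite(x)):
        raise ValueError("ratings matrix has missing/non-finite cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((col_means - grand) ** 2).sum()) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = float((resid**2).sum()) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        return ICCResult(model, math.nan, msr, msc, mse, n, k, degenerate=True)
    return ICCResult(model, (msr - mse) / denom, msr, msc, mse, n, k)


def summarize_cohort(
    pairs: list[PosePair], exclude_gimbal: bool = True
) -> pd.DataFrame:
    """Per-joint, per-DOF cohort summary of supine/upright angles and deltas.

    Returns a tidy DataFrame with one row per degree of freedom: supine and
    upright mean +/- SD, upright-minus-supine mean delta +/- SD, per-patient
    delta extrema, the paired-t result, and the significance marker
    ('*' p <= .05, '^' p <= .10).  Gimbal-flagged patients are excluded (with
    a note in the 'n' column) unless ``exclude_gimbal`` is False.
    """
    valid = [p for p in pairs if not (exclude_gimbal and p.gimbal_flag)]
    if len(valid) < 2:
        raise InsufficientCohortError(
            f"need >= 2 valid patients, have {len(valid)} "
            f"({len(pairs) - len(valid)} gimbal-excluded)"
        )
    rows = []
    for joint, dofs in (
        ("scapulothoracic", ST_DOFS),
        ("glenohumeral", GH_DOFS),
    ):
        for dof in dofs:
            supine = np.array(
                [getattr(p.angles("supine", joint), dof) for p in valid]
            )
            upright = np.array(
                [getattr(p.angles("upright", joint), dof) for p in valid]
            )
            delta = np.array([p.delta[dof] for p in valid])
            t = paired_t_test(supine, upright)
            marker = "*" if t.significant else ("^" if t.marginal else "")
            rows.append(
                {
                    "joint": joint,
                    "dof": dof,
                    "n": len(valid),
                    "supine_mean": supine.mean(),
                    "supine_sd": supine.std(ddof=1),
                    "upright_mean": upright.mean(),
                    "upright_sd": upright.std(ddof=1),
                    "delta_mean": delta.mean(),
                    "delta_sd": delta.std(ddof=1),
                    "delta_min": delta.min(),
                    "delta_max": delta.max(),
                    "t_stat": t.t_stat,
                    "df": t.df,
                    "p_value": t.p_value,
                    "significance": marker,
                }
            )
    return pd.DataFrame(rows)
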