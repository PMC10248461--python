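"""Cancer-type-level cutoff scan and Chow-test breakpoint detection.

For each candidate universal TMB cutoff, the fraction of TMB-high cases is
computed per cancer type and the objective response rate (ORR) to
anti-PD-(L)1 monotherapy is regressed on that fraction by weighted
ordinary least squares, weights being the geometric mean of the trial and
cohort sample sizes per cancer type.  The strength of association is the
signed square root of the coefficient of determination (R_TMB-ORR).
Sweeping the cutoff over a grid yields a statistic-vs-cutoff curve; the
Chow structural-break test locates the knee of that curve, which is taken
as the optimal universal cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .tmb_core import SampleTMB

logger = logging.getLogger(__name__)

__all__ = [
    "TrialSummary",
    "CancerTypeSummary",
    "WeightedR",
    "ScanCurve",
    "BreakpointResult",
    "filter_eligible",
    "prop_tmb_high",
    "weighted_r",
    "scan",
    "chow_breakpoint",
]


@dataclass(frozen=True)
class TrialSummary:
    """Pooled anti-PD-(L)1 monotherapy trial data for one cancer type."""

    cancer_type: str
    n_trial: int
    orr: float

    def __post_init__(self) -> None:
        if self.n_trial < 1:
            raise ValueError(f"{self.cancer_type}: n_trial must be >= 1")
        if not 0.0 <= self.orr <= 1.0:
            raise ValueError(f"{self.cancer_type}: orr must be in [0, 1]")


@dataclass(frozen=True)
class CancerTypeSummary:
    """Per-cancer-type join of cohort TMB-high proportion and trial ORR.

    ``weight`` is the geometric mean sqrt(n_cohort * n_trial), the weight
    used in the ORR-vs-proportion regression.
    """

    cancer_type: str
    n_cohort: int
    n_trial: int
    orr: float
    prop_high: float
    weight: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_high <= 1.0:
            raise ValueError(f"{self.cancer_type}: prop_high must be in [0, 1]")
        object.__setattr__(self, "weight", math.sqrt(self.n_cohort * self.n_trial))


@dataclass(frozen=True)
class WeightedR:
    """Signed weighted correlation with a Fisher-z confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    slope: float
    n_types: int
    degenerate: bool = False


@dataclass
class ScanCurve:
    """Statistic evaluated along an increasing grid of TMB cutoffs."""

    cutoffs: np.ndarray
    statistic: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.ci_low = np.asarray(self.ci_low, dtype=float)
        self.ci_high = np.asarray(self.ci_high, dtype=float)
        n = len(self.cutoffs)
        if not (len(self.statistic) == len(self.ci_low) == len(self.ci_high) == n):
            raise ValueError("curve arrays must have equal length")
        if np.any(np.diff(self.cutoffs) <= 0):
            raise ValueError("cutoff grid must be strictly increasing")


@dataclass
class BreakpointResult:
    """Chow-test structural breakpoint on a scan curve.

    ``candidates[i]`` is the x value at which the curve is split into a left
    segment (x < candidate) and a right segment (x >= candidate);
    ``f_stats[i]`` the Chow F for that split.  ``breakpoint`` maximises F,
    ties broken toward the smallest cutoff.  The p-value is descriptive
    (F(k, n-2k) reference at the maximising split, unadjusted for the scan).
    """

    breakpoint: float
    f_stats: np.ndarray
    candidates: np.ndarray
    p_value: float
    f_max: float
    infinite_f: bool = False


# scan cutoffs 1..20 mut/Mb; beyond ~20 the TMB-high strata of typical
# cohorts hold only a few percent of samples and the statistic is noise
DEFAULT_GRID = np.arange(1.0, 21.0)


def filter_eligible(
    summaries: Sequence[CancerTypeSummary],
    min_cohort: int = 30,
    min_trial: int = 10,
) -> list[CancerTypeSummary]:
    """Keep cancer types with enough cohort cases and trial participants.

    Defaults mirror the study's eligibility rule: at least 30 cohort cases
    and at least 10 pooled trial participants.
    """
    kept, dropped = [], []
    for s in summaries:
        if s.n_cohort >= min_cohort and s.n_trial >= min_trial:
            kept.append(s)
        else:
            dropped.append(s.cancer_type)
    if dropped:
        logger.info(
            "filter_eligible: excluded %d cancer type(s): %s", len(dropped), dropped
        )
    if not kept:
        raise ValueError(
            "no cancer type passes the eligibility thresholds "
            f"(min_cohort={min_cohort}, min_trial={min_trial}); "
            "the cutoff-scan regression is undefined on an empty table"
        )
    return kept


def prop_tmb_high(tmbs: Sequence[SampleTMB] | np.ndarray, cutoff: float) -> float:
    """Fraction of samples with TMB >= cutoff (boundary inclusive)."""
    if len(tmbs) == 0:
        raise ValueError("prop_tmb_high requires at least one sample")
    if isinstance(tmbs[0], SampleTMB):
        values = np.asarray([t.tmb for t in tmbs], dtype=float)
    else:
        values = np.asarray(tmbs, dtype=float)
    return float(np.mean(values >= cutoff))


def weighted_r(summaries: Sequence[CancerTypeSummary]) -> WeightedR:
    """Signed weighted correlation between ORR and the TMB-high proportion.

    Fits weighted OLS of ORR on the TMB-high proportion with weights
    sqrt(n_cohort * n_trial) and returns R = sign(slope) * sqrt(R^2) with a
    95% CI from the Fisher z-transform using n = number of cancer types.
    A proportion vector with zero variance yields R = 0 with the degenerate
    flag set (the regression slope is unidentified).
    """
    if len(summaries) < 3:
        raise ValueError("weighted_r requires at least 3 cancer types")
    prop = np.array([s.prop_high for s in summaries])
    orr = np.array([s.orr for s in summaries])
    w = np.array([s.weight for s in summaries])
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    n = len(summaries)
    if np.ptp(prop) == 0:
        return WeightedR(0.0, np.nan, np.nan, slope=0.0, n_types=n, degenerate=True)
    fit = sm.WLS(orr, sm.add_constant(prop), weights=w).fit()
    slope = float(fit.params[1])
    r = math.copysign(math.sqrt(max(fit.rsquared, 0.0)), slope)
    ci_low, ci_high = _fisher_ci(r, n)
    return WeightedR(r, ci_low, ci_high, slope=slope, n_types=n)


def _fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def scan(
    tmb_by_type: Mapping[str, np.ndarray],
    trials: Sequence[TrialSummary],
    grid: np.ndarray = DEFAULT_GRID,
    min_cohort: int = 30,
    min_trial: int = 10,
) -> ScanCurve:
    """Evaluate the weighted ORR correlation along a grid of TMB cutoffs.

    ``tmb_by_type`` maps cancer type to the per-sample TMB values of the
    cohort; eligibility filtering is applied once (cohort and trial size
    thresholds), then the TMB-high proportions are recomputed at every grid
    cutoff and fed to :func:`weighted_r`.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("cutoff grid must be strictly increasing")
    trial_map = {t.cancer_type: t for t in trials}
    common = [ct for ct in tmb_by_type if ct in trial_map]
    # eligibility applied once; proportions recomputed per cutoff below
    base = filter_eligible(
        [
            CancerTypeSummary(
                cancer_type=ct,
                n_cohort=len(tmb_by_type[ct]),
                n_trial=trial_map[ct].n_trial,
                orr=trial_map[ct].orr,
                prop_high=0.0,
            )
            for ct in common
        ],
        min_cohort=min_cohort,
        min_trial=min_trial,
    )
    stat = np.empty_like(grid)
    lo = np.empty_like(grid)
    hi = np.empty_like(grid)
    for i, cutoff in enumerate(grid):
        summaries = [
            CancerTypeSummary(
                cancer_type=s.cancer_type,
                n_cohort=s.n_cohort,
                n_trial=s.n_trial,
                orr=s.orr,
                prop_high=prop_tmb_high(np.asarray(tmb_by_type[s.cancer_type]), cutoff),
            )
            for s in base
        ]
        res = weighted_r(summaries)
        stat[i], lo[i], hi[i] = res.r, res.ci_low, res.ci_high
    return ScanCurve(cutoffs=grid, statistic=stat, ci_low=lo, ci_high=hi)


def _ssr_line(x: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of the OLS line (intercept + slope)."""
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def chow_breakpoint(
    curve_x: Sequence[float],
    curve_y: Sequence[float],
    min_segment: int = 3,
) -> BreakpointResult:
    """Locate the structural break of a curve by maximising the Chow F.

    Each candidate split leaves at least ``min_segment`` points per side;
    simple OLS lines (k = 2 parameters) are fitted to the left segment, the
    right segment and the pooled data, and

        F = ((SSR_pooled - SSR_left - SSR_right) / k)
            / ((SSR_left + SSR_right) / (n - 2k))

    The breakpoint is the candidate maximising F, ties broken toward the
    smallest cutoff.  A split with zero combined segment SSR gives infinite
    F and remains eligible (flagged).  The p-value comes from the F(k, n-2k)
    reference distribution at the maximising split and is descriptive only.
    """
    x = np.asarray(curve_x, dtype=float)
    y = np.asarray(curve_y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("curve_x and curve_y must have equal length")
    if n < 2 * min_segment:
        raise ValueError(
            f"Chow scan needs at least {2 * min_segment} points, got {n}"
        )
    k = 2
    ssr_pooled = _ssr_line(x, y)
    # least-squares residues of an exact fit come back as float dust, not
    # zero; anything below this scale-aware floor is treated as zero SSR
    tol = 1e-12 * n * max(float(np.max(np.abs(y))) ** 2, 1e-300)
    split_indices = range(min_segment, n - min_segment + 1)
    candidates = np.array([x[i] for i in split_indices])
    f_stats = np.empty(len(candidates))
    for j, i in enumerate(split_indices):
        ssr_split = _ssr_line(x[:i], y[:i]) + _ssr_line(x[i:], y[i:])
        num = (ssr_pooled - ssr_split) / k
        den = ssr_split / (n - 2 * k)
        if den <= tol:
            f_stats[j] = np.inf if num > tol else 0.0
        else:
            f_stats[j] = num / den
    best = int(np.argmax(f_stats))  # first occurrence wins: smallest cutoff
    f_max = float(f_stats[best])
    infinite = bool(np.isinf(f_max))
    p_value = 0.0 if infinite else float(stats.f.sf(f_max, k, n - 2 * k))
    return BreakpointResult(
        breakpoint=float(candidates[best]),
        f_stats=f_stats,
        candidates=candidates,
        p_value=p_value,
        f_max=f_max,
        infinite_f=infinite,
    )
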