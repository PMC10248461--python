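"""Patient-level survival verification of a candidate TMB cutoff.

The cutoff from the cancer-type-level scan is validated against overall
survival (OS): Cox proportional-hazards models adjusted for age, sex,
panel version and cancer type estimate the hazard ratio of TMB-high vs
TMB-low; a Wald-Z scan over candidate cutoffs with Chow breakpoint
detection re-locates the threshold on patient-level data; the universal
cutoff is compared against per-cancer 80th-percentile cutoffs through
hazard ratios, concordance (C-index) and a TMB-by-cancer-type interaction
test, with a microsatellite-stable-only sensitivity analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index
from scipy import stats

from .cutoff_scan import BreakpointResult, ScanCurve, chow_breakpoint

logger = logging.getLogger(__name__)

__all__ = [
    "CutoffPolicy",
    "CoxResult",
    "CIndexComparison",
    "REQUIRED_COLUMNS",
    "DEFAULT_COVARIATES",
    "read_survival",
    "prepare_complete_case",
    "tmb_high_labels",
    "percentile_cutoffs",
    "fit_cox",
    "z_scan",
    "compare_cindex",
    "interaction_test",
    "subgroup_hrs",
    "mss_sensitivity",
]

REQUIRED_COLUMNS = (
    "sample_id",
    "os_months",
    "os_event",
    "tmb",
    "cancer_type",
)

DEFAULT_COVARIATES = ("age", "sex", "panel_version", "cancer_type")


@dataclass(frozen=True)
class CutoffPolicy:
    """How samples are dichotomised into TMB-high vs TMB-low.

    ``universal``: one cutoff in mut/Mb for every cancer type.
    ``percentile``: a per-cancer-type cutoff at the given quantile of that
    type's TMB distribution (default 0.80, the tumor-specific convention).
    """

    kind: str  # "universal" | "percentile"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("universal", "percentile"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "percentile" and not 0.0 < self.value < 1.0:
            raise ValueError("percentile policy quantile must be in (0, 1)")
        if self.kind == "universal" and self.value < 0:
            raise ValueError("universal cutoff must be nonnegative")


@dataclass(frozen=True)
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    c_index: float
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")


@dataclass(frozen=True)
class CIndexComparison:
    c_a: float
    c_b: float
    delta: float
    p: float
    n_boot: int


def read_survival(path) -> pd.DataFrame:
    """Read a survival TSV and validate the required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survival file {path} is missing column(s): {missing}")
    if (df["os_months"].dropna() < 0).any():
        raise ValueError("os_months must be nonnegative")
    return df


def prepare_complete_case(
    df: pd.DataFrame, covariates: Sequence[str] = DEFAULT_COVARIATES
) -> pd.DataFrame:
    """Drop rows with missing outcome or covariate values (complete-case)."""
    cols = ["os_months", "os_event", "tmb"] + [c for c in covariates if c in df.columns]
    out = df.dropna(subset=cols).copy()
    n_drop = len(df) - len(out)
    if n_drop:
        logger.info("complete-case analysis dropped %d of %d rows", n_drop, len(df))
    return out


def percentile_cutoffs(
    df: pd.DataFrame, q: float = 0.80
) -> dict[str, float]:
    """Per-cancer-type TMB cutoff at quantile ``q``.

    Uses the linear-interpolation quantile convention (interpolating between
    order statistics).  Classification downstream is tmb >= cutoff within
    each cancer type.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    grouped = df.groupby("cancer_type")["tmb"]
    return {ct: float(vals.quantile(q, interpolation="linear")) for ct, vals in grouped}


def tmb_high_labels(df: pd.DataFrame, policy: CutoffPolicy) -> pd.Series:
    """Boolean TMB-high indicator per row under a cutoff policy."""
    if policy.kind == "universal":
        return df["tmb"] >= policy.value
    cutoffs = percentile_cutoffs(df, q=policy.value)
    return df["tmb"] >= df["cancer_type"].map(cutoffs)


def _design_matrix(
    df: pd.DataFrame,
    high: pd.Series,
    covariates: Sequence[str],
    interaction: bool = False,
) -> pd.DataFrame:
    """Cox design: TMB-high indicator plus dummy-coded covariates.

    Categorical covariates are dummy-coded with the most frequent level as
    the reference.  With ``interaction=True``, TMB-high x cancer-type
    product terms are appended (for the likelihood-ratio interaction test).
    """
    parts = {"tmb_high": high.astype(float)}
    for cov in covariates:
        if cov not in df.columns:
            continue
        col = df[cov]
        if cov == "age":
            parts["age"] = col.astype(float)
            continue
        levels = col.value_counts().index.tolist()  # most frequent first
        for lev in levels[1:]:
            parts[f"{cov}={lev}"] = (col == lev).astype(float)
    design = pd.DataFrame(parts, index=df.index)
    if interaction:
        ct = df["cancer_type"]
        ref = ct.value_counts().index[0]
        for lev in ct.value_counts().index[1:]:
            design[f"tmb_high:cancer_type={lev}"] = design["tmb_high"] * (
                ct == lev
            ).astype(float)
    design["os_months"] = df["os_months"].astype(float)
    design["os_event"] = df["os_event"].astype(int)
    # constant columns carry no information and break the fit
    drop = [
        c
        for c in design.columns
        if c not in ("os_months", "os_event") and design[c].nunique() <= 1
    ]
    return design.drop(columns=drop)


def _check_events_per_stratum(high: pd.Series, events: pd.Series, minimum: int = 2):
    ev_high = int(events[high].sum())
    ev_low = int(events[~high].sum())
    if ev_high < minimum or ev_low < minimum:
        raise ValueError(
            f"need >= {minimum} events per TMB stratum; got "
            f"{ev_high} (high) and {ev_low} (low)"
        )


def _fit_cph(design: pd.DataFrame) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(design, duration_col="os_months", event_col="os_event")
        except ConvergenceError as err:
            raise RuntimeError(
                f"Cox model failed to converge: {err}; "
                f"n={len(design)}, events={int(design['os_event'].sum())}, "
                f"columns={[c for c in design.columns if c not in ('os_months', 'os_event')]}"
            ) from err
    return cph


def fit_cox(
    df: pd.DataFrame,
    policy: CutoffPolicy,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> CoxResult:
    """Adjusted Cox model for TMB-high vs TMB-low overall survival.

    The TMB-high indicator is built per the cutoff policy; covariates are
    age (continuous) and dummy-coded sex, panel version and cancer type
    (reference level = most frequent).  Returns the hazard ratio with Wald
    CI and Z, and Harrell's C-index of the fitted model.
    """
    df = prepare_complete_case(df, covariates)
    high = tmb_high_labels(df, policy)
    _check_events_per_stratum(high, df["os_event"].astype(bool))
    design = _design_matrix(df, high, covariates)
    cph = _fit_cph(design)
    row = cph.summary.loc["tmb_high"]
    return CoxResult(
        hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        z=float(row["z"]),
        p=float(row["p"]),
        c_index=float(cph.concordance_index_),
        n=len(design),
        n_events=int(design["os_event"].sum()),
    )


def z_scan(
    df: pd.DataFrame,
    grid: Sequence[float],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    min_segment: int = 3,
) -> tuple[ScanCurve, BreakpointResult]:
    """Wald-Z of the TMB-high coefficient along a grid of universal cutoffs.

    The curve stores Z as estimated (a protective TMB-high effect gives
    negative Z); display code may flip the sign.  Cutoffs leaving fewer than
    two events in either stratum are dropped with a warning; the Chow
    breakpoint is then located on the surviving curve.
    """
    df = prepare_complete_case(df, covariates)
    kept_x, kept_z = [], []
    for cutoff in grid:
        high = df["tmb"] >= cutoff
        try:
            _check_events_per_stratum(high, df["os_event"].astype(bool))
        except ValueError:
            logger.warning("z_scan: cutoff %.3g dropped (too few events)", cutoff)
            continue
        design = _design_matrix(df, high, covariates)
        cph = _fit_cph(design)
        kept_x.append(float(cutoff))
        kept_z.append(float(cph.summary.loc["tmb_high", "z"]))
    if len(kept_x) < 2 * min_segment:
        raise ValueError(
            f"only {len(kept_x)} valid cutoffs; Chow scan needs {2 * min_segment}"
        )
    nan = np.full(len(kept_x), np.nan)
    curve = ScanCurve(np.array(kept_x), np.array(kept_z), nan, nan.copy())
    bp = chow_breakpoint(curve.cutoffs, curve.statistic, min_segment=min_segment)
    return curve, bp


def compare_cindex(
    df: pd.DataFrame,
    policy_a: CutoffPolicy,
    policy_b: CutoffPolicy,
    n_boot: int = 1000,
    seed: int | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> CIndexComparison:
    """Paired patient-level bootstrap comparison of two policies' C-indices.

    Both Cox models are fitted once on identical rows; their linear
    predictors are then held fixed while patients are resampled with
    replacement, and the C-index difference is recomputed per resample.
    The two-sided p-value is the bootstrap tail probability of the
    difference crossing zero.
    """
    if n_boot < 100:
        logger.warning("compare_cindex: n_boot=%d is small; p unstable", n_boot)
    df = prepare_complete_case(df, covariates)
    T = df["os_months"].to_numpy(float)
    E = df["os_event"].to_numpy(int)
    scores = []
    for policy in (policy_a, policy_b):
        high = tmb_high_labels(df, policy)
        _check_events_per_stratum(high, df["os_event"].astype(bool))
        design = _design_matrix(df, high, covariates)
        cph = _fit_cph(design)
        lp = cph.predict_partial_hazard(design).to_numpy(float)
        scores.append(lp)
    c_a = concordance_index(T, -scores[0], E)
    c_b = concordance_index(T, -scores[1], E)
    delta = c_a - c_b
    rng = np.random.default_rng(seed)
    n = len(df)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        # a resample can lack comparable pairs only in degenerate inputs
        deltas[b] = concordance_index(T[idx], -scores[0][idx], E[idx]) - \
            concordance_index(T[idx], -scores[1][idx], E[idx])
    if np.allclose(deltas, 0.0) and delta == 0.0:
        p = 1.0
    else:
        p = 2 * min(float(np.mean(deltas <= 0)), float(np.mean(deltas >= 0)))
        p = min(p, 1.0)
    return CIndexComparison(c_a=c_a, c_b=c_b, delta=delta, p=p, n_boot=n_boot)


def interaction_test(
    df: pd.DataFrame,
    policy: CutoffPolicy,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> float:
    """Likelihood-ratio test for TMB-status-by-cancer-type interaction.

    Compares the adjusted Cox model with and without TMB-high x cancer-type
    product terms.  Returns the chi-square p-value; NaN (with a logged
    diagnostic) if either model fails to converge.
    """
    df = prepare_complete_case(df, covariates)
    high = tmb_high_labels(df, policy)
    types_ok = 0
    for _, sub in df.groupby("cancer_type"):
        h = high.loc[sub.index]
        ev = sub["os_event"].astype(bool)
        if (ev & h).sum() >= 1 and (ev & ~h).sum() >= 1:
            types_ok += 1
    if types_ok < 2:
        raise ValueError(
            "interaction test needs >= 2 cancer types with events in both "
            f"TMB strata; found {types_ok}"
        )
    reduced = _design_matrix(df, high, covariates)
    full = _design_matrix(df, high, covariates, interaction=True)
    extra = full.shape[1] - reduced.shape[1]
    if extra < 1:
        raise ValueError("no estimable interaction terms")
    try:
        ll_reduced = _fit_cph(reduced).log_likelihood_
        ll_full = _fit_cph(full).log_likelihood_
    except RuntimeError as err:
        logger.warning("interaction test not estimable: %s", err)
        return float("nan")
    lr = 2.0 * (ll_full - ll_reduced)
    return float(stats.chi2.sf(max(lr, 0.0), df=extra))


def subgroup_hrs(
    df: pd.DataFrame,
    policy: CutoffPolicy,
    covariates: Sequence[str] = ("age", "sex", "panel_version"),
) -> pd.DataFrame:
    """Per-cancer-type hazard ratios (forest table).

    Each cancer type gets its own Cox fit with the remaining covariates
    (cancer type itself drops out within a stratum).  Types without at
    least two events per TMB stratum — e.g. a type whose few TMB-high
    patients are all alive at last follow-up — are flagged not estimable,
    with the counts reported.
    """
    df = prepare_complete_case(df, list(covariates) + ["cancer_type"])
    high_all = tmb_high_labels(df, policy)
    rows = []
    for ct, sub in df.groupby("cancer_type", sort=True):
        high = high_all.loc[sub.index]
        ev = sub["os_event"].astype(bool)
        rec = {
            "cancer_type": ct,
            "n": len(sub),
            "n_high": int(high.sum()),
            "n_events_high": int((ev & high).sum()),
            "n_events_low": int((ev & ~high).sum()),
            "hr": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
            "estimable": False,
        }
        if rec["n_events_high"] >= 2 and rec["n_events_low"] >= 2:
            try:
                design = _design_matrix(sub, high, covariates)
                cph = _fit_cph(design)
                s = cph.summary.loc["tmb_high"]
                rec.update(
                    hr=float(s["exp(coef)"]),
                    ci_low=float(s["exp(coef) lower 95%"]),
                    ci_high=float(s["exp(coef) upper 95%"]),
                    p=float(s["p"]),
                    estimable=True,
                )
            except (RuntimeError, KeyError) as err:
                logger.warning("subgroup %s not estimable: %s", ct, err)
        rows.append(rec)
    return pd.DataFrame(rows)


def mss_sensitivity(
    df: pd.DataFrame,
    policy: CutoffPolicy,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> CoxResult:
    """Re-run the adjusted Cox fit on microsatellite-stable cases only."""
    if "msi_status" not in df.columns:
        raise ValueError("msi_status column required for the MSS sensitivity run")
    sub = df[df["msi_status"] == "MSS"]
    if sub.empty:
        raise ValueError("no MSS rows in input; sensitivity analysis undefined")
    return fit_cox(sub, policy, covariates)
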