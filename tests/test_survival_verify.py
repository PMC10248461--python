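"""Survival verification: Cox fits, percentile cutoffs, scans, comparisons."""

import numpy as np
import pandas as pd
import pytest

from tmbcut.survival_verify import (
    CutoffPolicy,
    compare_cindex,
    fit_cox,
    interaction_test,
    mss_sensitivity,
    percentile_cutoffs,
    subgroup_hrs,
    tmb_high_labels,
    z_scan,
)

UNIVERSAL10 = CutoffPolicy("universal", 10.0)


def exponential_survival(
    rng, n, hr=0.5, base=0.05, censoring=0.0, p_high=0.5, n_types=1
):
    """Exponential event times with a multiplicative TMB-high effect."""
    high = rng.random(n) < p_high
    tmb = np.where(high, 15.0, 5.0)
    lam = base * np.where(high, hr, 1.0)
    t = rng.exponential(1 / lam)
    censored = rng.random(n) < censoring
    obs = np.where(censored, rng.uniform(0, t), t)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "os_months": obs,
            "os_event": (~censored).astype(int),
            "tmb": tmb,
            "cancer_type": rng.choice([f"ct{j}" for j in range(n_types)], n),
            "age": rng.normal(60, 10, n),
            "sex": rng.choice(["M", "F"], n),
            "panel_version": rng.choice(["v1", "v2"], n),
            "msi_status": "MSS",
        }
    )


class TestPercentileCutoffs:
    def test_linear_interpolation_convention(self):
        df = pd.DataFrame(
            {"cancer_type": ["a"] * 10, "tmb": np.arange(1.0, 11.0)}
        )
        assert percentile_cutoffs(df, q=0.80)["a"] == pytest.approx(8.2)

    def test_constant_group_returns_constant(self):
        df = pd.DataFrame({"cancer_type": ["a"] * 5, "tmb": [4.0] * 5})
        assert percentile_cutoffs(df)["a"] == 4.0

    def test_q_one_is_maximum(self):
        df = pd.DataFrame({"cancer_type": ["a"] * 5, "tmb": [1.0, 9.0, 3.0, 2.0, 7.0]})
        assert percentile_cutoffs(df, q=1.0)["a"] == 9.0

    def test_percentile_policy_labels_about_20_percent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "cancer_type": np.repeat(["a", "b"], 500),
                "tmb": rng.lognormal(1.5, 1.0, 1000),
            }
        )
        labels = tmb_high_labels(df, CutoffPolicy("percentile", 0.80))
        for ct in ("a", "b"):
            frac = labels[df["cancer_type"] == ct].mean()
            assert frac == pytest.approx(0.20, abs=0.01)


class TestFitCox:
    def test_recovers_planted_effect_against_exponential_mle(self):
        """With exponential times and no censoring, the Cox HR should agree
        with the closed-form exponential rate-ratio MLE."""
        rng = np.random.default_rng(1)
        df = exponential_survival(rng, 2000, hr=0.5, censoring=0.0)
        high = df["tmb"] >= 10
        # exponential MLE: rate = events / total time, per stratum
        mle_ratio = (
            high.sum() / df.loc[high, "os_months"].sum()
        ) / ((~high).sum() / df.loc[~high, "os_months"].sum())
        res = fit_cox(df, UNIVERSAL10, covariates=())
        assert res.hr == pytest.approx(mle_ratio, rel=0.05)
        assert res.ci_low < res.hr < res.ci_high

    def test_protective_effect_gives_negative_z(self):
        rng = np.random.default_rng(2)
        df = exponential_survival(rng, 1000, hr=0.4, censoring=0.1)
        res = fit_cox(df, UNIVERSAL10)
        assert res.z < 0 and res.hr < 1

    def test_null_effect_hr_near_one(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            df = exponential_survival(rng, 2000, hr=1.0, censoring=0.2)
            res = fit_cox(df, UNIVERSAL10, covariates=("age", "sex"))
            hits += 0.9 <= res.hr <= 1.1
        assert hits >= 18  # >= 90% of replicates

    def test_zero_events_in_stratum_fatal(self):
        rng = np.random.default_rng(3)
        df = exponential_survival(rng, 100, censoring=0.0)
        df.loc[df["tmb"] >= 10, "os_event"] = 0
        with pytest.raises(ValueError, match="events"):
            fit_cox(df, UNIVERSAL10)


class TestZScan:
    def test_matches_fit_cox_z_at_each_cutoff(self, survival_frame):
        grid = np.array([6.0, 8.0, 10.0, 12.0, 14.0, 16.0])
        curve, _ = z_scan(survival_frame, grid)
        for c, z in zip(curve.cutoffs, curve.statistic):
            res = fit_cox(survival_frame, CutoffPolicy("universal", c))
            assert z == pytest.approx(res.z, abs=1e-9)

    def test_deterministic(self, survival_frame):
        grid = np.arange(4.0, 16.0)
        c1, b1 = z_scan(survival_frame, grid)
        c2, b2 = z_scan(survival_frame, grid)
        np.testing.assert_array_equal(c1.statistic, c2.statistic)
        assert b1.breakpoint == b2.breakpoint

    def test_too_few_valid_cutoffs_fatal(self, survival_frame):
        with pytest.raises(ValueError):
            z_scan(survival_frame, np.array([5.0, 10.0, 15.0]))


class TestCompareCindex:
    def test_identical_policies_delta_zero_p_one(self, survival_frame):
        res = compare_cindex(
            survival_frame, UNIVERSAL10, UNIVERSAL10, n_boot=120, seed=0
        )
        assert res.delta == 0.0 and res.p == 1.0

    def test_informative_marker_beats_random(self):
        """A TMB split aligned with the planted hazard should out-discriminate
        a split on a permuted copy of TMB."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            df = exponential_survival(rng, 500, hr=0.3, censoring=0.1)
            df["tmb_perm"] = rng.permutation(df["tmb"].to_numpy())
            df_b = df.copy()
            df_b["tmb"] = df_b.pop("tmb_perm")
            res_a = fit_cox(df, UNIVERSAL10, covariates=())
            res_b = fit_cox(df_b, UNIVERSAL10, covariates=())
            hits += res_a.c_index > res_b.c_index
        assert hits >= 8

    def test_random_marker_cindex_near_half(self):
        rng = np.random.default_rng(4)
        df = exponential_survival(rng, 1000, hr=1.0, censoring=0.0)
        res = fit_cox(df, UNIVERSAL10, covariates=())
        assert 0.45 <= res.c_index <= 0.55


class TestInteraction:
    def test_single_cancer_type_fatal(self):
        rng = np.random.default_rng(5)
        df = exponential_survival(rng, 300, n_types=1)
        with pytest.raises(ValueError, match="cancer type"):
            interaction_test(df, UNIVERSAL10)

    def test_heterogeneous_effect_detected(self):
        """HR 0.35 in half the types and 1.0 in the rest should reject."""
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(300 + seed)
            n = 1600
            ct = rng.choice(["a", "b", "c", "d"], n)
            high = rng.random(n) < 0.4
            hr = np.where(np.isin(ct, ["a", "b"]) & high, 0.35, 1.0)
            t = rng.exponential(1 / (0.05 * hr))
            df = pd.DataFrame(
                {
                    "sample_id": [f"S{i}" for i in range(n)],
                    "os_months": t,
                    "os_event": 1,
                    "tmb": np.where(high, 15.0, 5.0),
                    "cancer_type": ct,
                    "age": rng.normal(60, 10, n),
                    "sex": rng.choice(["M", "F"], n),
                    "panel_version": "v1",
                    "msi_status": "MSS",
                }
            )
            hits += interaction_test(df, UNIVERSAL10) < 0.05
        assert hits >= 6

    def test_homogeneous_effect_type_i_error_controlled(self):
        rejections = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(400 + seed)
            df = exponential_survival(rng, 800, hr=0.6, censoring=0.1, n_types=3)
            rejections += interaction_test(df, UNIVERSAL10) < 0.05
        assert 0 <= rejections / n_rep <= 0.15


class TestSubgroups:
    def test_planted_uniform_hr_recovered_per_type(self):
        rng = np.random.default_rng(6)
        df = exponential_survival(rng, 3000, hr=0.6, censoring=0.1, n_types=3)
        table = subgroup_hrs(df, UNIVERSAL10)
        assert len(table) == 3
        est = table[table["estimable"]]
        assert (est["hr"] - 0.6).abs().max() < 0.25

    def test_all_censored_high_stratum_flagged(self):
        rng = np.random.default_rng(7)
        df = exponential_survival(rng, 200, n_types=1)
        df.loc[df["tmb"] >= 10, "os_event"] = 0
        table = subgroup_hrs(df, UNIVERSAL10)
        assert not table.loc[0, "estimable"]
        assert table.loc[0, "n_events_high"] == 0

    def test_single_type_gives_one_row(self):
        rng = np.random.default_rng(8)
        df = exponential_survival(rng, 400, n_types=1)
        assert len(subgroup_hrs(df, UNIVERSAL10)) == 1


class TestMssSensitivity:
    def test_all_mss_input_is_identity(self, survival_frame):
        df = survival_frame.copy()
        df["msi_status"] = "MSS"
        full = fit_cox(df, UNIVERSAL10)
        mss = mss_sensitivity(df, UNIVERSAL10)
        assert mss.hr == pytest.approx(full.hr)

    def test_effect_survives_mss_filter(self, survival_frame):
        res = mss_sensitivity(survival_frame, UNIVERSAL10)
        assert res.hr < 1

    def test_no_mss_rows_fatal(self, survival_frame):
        df = survival_frame.copy()
        df["msi_status"] = "MSI-H"
        with pytest.raises(ValueError, match="MSS"):
            mss_sensitivity(df, UNIVERSAL10)


def test_permuting_labels_destroys_effect():
    """Exchangeability: permuting TMB across patients kills the association."""
    rng = np.random.default_rng(9)
    df = exponential_survival(rng, 800, hr=0.4, censoring=0.1)
    zs = []
    for _ in range(15):
        perm = df.copy()
        perm["tmb"] = rng.permutation(perm["tmb"].to_numpy())
        res = fit_cox(perm, UNIVERSAL10, covariates=("age", "sex"))
        zs.append(abs(res.z))
    assert np.median(zs) < 2
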