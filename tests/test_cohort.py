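"""Synthetic cohort generator: determinism, invariants, missingness, I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fedgait.cohort import (
    GAIT_FEATURES,
    MODEL_FEATURES,
    TABLE1_PARTICIPANTS,
    CohortConfig,
    CohortConfigError,
    CohortParseError,
    apply_missingness,
    generate_cohort,
    generate_dataset,
    read_cohort,
    write_cohort,
)


def test_feature_taxonomy():
    """88 gait columns: 22 base measures crossed with 4 bout strata."""
    assert len(GAIT_FEATURES) == 88
    strata = {name.split("_")[1] for name in GAIT_FEATURES}
    assert strata == {"all", "short", "moderate", "long"}
    for stratum in strata:
        assert sum(name.split("_")[1] == stratum for name in GAIT_FEATURES) == 22
    assert len(MODEL_FEATURES) == 91  # + age, sex, bmi


def test_same_config_same_output(default_cohort):
    again = generate_cohort(CohortConfig(seed=0))
    pd.testing.assert_frame_equal(default_cohort, again)


def test_different_seed_differs(default_cohort):
    other = generate_cohort(CohortConfig(seed=1))
    assert not default_cohort.equals(other)


def test_label_invariants(default_cohort):
    assert default_cohort["updrs3"].between(0, 132).all()
    # label constant within each (participant, visit)
    nun = default_cohort.groupby(["participant_id", "visit_month"])["updrs3"].nunique()
    assert (nun == 1).all()
    assert default_cohort["day_index"].between(1, 7).all()


def test_noise_free_limit_is_exact_generative_equation():
    """With all noise and random effects zeroed, features are an exact affine
    function of latent severity and labels reproduce the label equation."""
    cfg = CohortConfig(
        n_participants=6,
        seed=5,
        label_noise_sd=0.0,
        feature_noise_sd=0.0,
        random_effect_sd=0.0,
        domain_daily_sd=0.0,
        feature_random_effect_sd=0.0,
        severity_intercept_sd=0.0,
        severity_slope_sd=0.0,
        bmi_drift_sd=0.0,
    )
    df = generate_cohort(cfg)
    loadings = np.asarray(cfg.feature_loadings)
    visit_index = df["visit_month"].map(
        {m: i for i, m in enumerate(cfg.visit_months)}
    )
    severity = cfg.severity_slope_mean * visit_index.to_numpy()
    expected_feats = loadings[None, :] * severity[:, None]
    np.testing.assert_allclose(
        df[GAIT_FEATURES].to_numpy(), expected_feats, atol=1e-9
    )
    expected_label = np.clip(
        cfg.label_intercept
        + cfg.label_age_coef * (df["age"] - cfg.age_mean)
        + cfg.label_sex_coef * df["sex"]
        + cfg.label_severity_coef * severity,
        0,
        132,
    ).round()
    np.testing.assert_array_equal(df["updrs3"].to_numpy(), expected_label)


def test_loaded_features_correlate_with_label_in_configured_sign(default_cohort):
    """Each feature's sample correlation with the label carries the
    configured loading sign, significantly so over the full cohort.

    Individual gait measures correlate only weakly with severity (the
    panel's aggregate information is deliberately modest), so the check is
    a one-sided significance test of the sign rather than a magnitude bar.
    """
    cfg = CohortConfig()
    for name, sign in [
        ("gait_all_sdStepTime", 1),  # variability rises with severity
        ("gait_all_meanStepVelocity", -1),  # pace declines
    ]:
        loading = cfg.feature_loadings[GAIT_FEATURES.index(name)]
        assert np.sign(loading) == sign
        r, p = stats.pearsonr(default_cohort[name], default_cohort["updrs3"])
        assert np.sign(r) == sign
        assert p < 0.01


def test_invalid_config_rejected():
    with pytest.raises(CohortConfigError):
        generate_cohort(CohortConfig(male_fraction=1.5))
    with pytest.raises(CohortConfigError):
        generate_cohort(CohortConfig(label_noise_sd=-1.0))
    with pytest.raises(CohortConfigError):
        CohortConfig(value_missing_rate=1.2).validate()


class TestMissingness:
    def test_zero_rates_identity(self, default_cohort):
        cfg = CohortConfig(
            seed=0,
            visit_participation=(1.0, 1.0, 1.0, 1.0),
            value_missing_rate=0.0,
            long_bout_low_activity_rate=0.0,
            bmi_missing_rate=0.0,
        )
        out = apply_missingness(default_cohort, cfg)
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), default_cohort.reset_index(drop=True)
        )

    def test_degenerate_visit_rate(self, default_cohort):
        cfg = CohortConfig(seed=0, visit_participation=(1.0, 0.0, 1.0, 1.0))
        out = apply_missingness(default_cohort, cfg)
        assert (out["visit_month"] != 36).all()
        for month in (18, 54, 72):
            assert (
                out[out["visit_month"] == month].shape
                == default_cohort[default_cohort["visit_month"] == month].shape
            )

    def test_no_participant_loses_all_visits(self, default_cohort):
        cfg = CohortConfig(seed=0, visit_participation=(0.05, 0.05, 0.05, 0.05))
        out = apply_missingness(default_cohort, cfg)
        assert set(out["participant_id"]) == set(default_cohort["participant_id"])

    def test_value_rate_within_binomial_ci(self, default_cohort):
        """Observed missing fraction of short/moderate/all-bout gait cells
        (never subject to the low-activity extra masking) is inside the
        binomial 99% CI around the configured rate."""
        rate = 0.1
        cfg = CohortConfig(
            seed=0,
            visit_participation=(1.0, 1.0, 1.0, 1.0),
            value_missing_rate=rate,
            long_bout_low_activity_rate=0.0,
            bmi_missing_rate=0.0,
        )
        out = apply_missingness(default_cohort, cfg)
        cells = out[GAIT_FEATURES].isna().to_numpy()
        n = cells.size
        observed = cells.sum()
        lo, hi = stats.binom.interval(0.99, n, rate)
        assert lo <= observed <= hi

    def test_calibrated_per_visit_counts(self):
        """Expected per-visit participant counts approximate the published
        table; observed counts within the binomial 99% CI."""
        cfg = CohortConfig(seed=11)
        out = generate_dataset(cfg)
        for month, expected_n, p in zip(
            cfg.visit_months, TABLE1_PARTICIPANTS, cfg.visit_participation
        ):
            observed = out[out["visit_month"] == month]["participant_id"].nunique()
            lo, hi = stats.binom.interval(0.99, cfg.n_participants, p)
            assert lo <= observed <= hi, (month, observed, expected_n)


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, small_dataset):
        path = tmp_path / "cohort.csv"
        write_cohort(small_dataset, path)
        back = read_cohort(path)
        a = small_dataset.reset_index(drop=True)
        b = back[a.columns].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False, atol=1e-9)

    def test_empty_dataset(self, tmp_path, small_dataset):
        path = tmp_path / "empty.csv"
        write_cohort(small_dataset.iloc[0:0], path)
        back = read_cohort(path)
        assert back.empty
        assert "updrs3" in back.columns

    def test_missing_column_rejected(self, tmp_path, small_dataset):
        path = tmp_path / "bad.csv"
        small_dataset.drop(columns=["updrs3"]).to_csv(path, index=False)
        with pytest.raises(CohortParseError, match="updrs3"):
            read_cohort(path)

    def test_non_numeric_cell_named(self, tmp_path, small_dataset):
        path = tmp_path / "bad2.csv"
        df = small_dataset.copy()
        df.loc[df.index[3], "age"] = "seventy"
        df.to_csv(path, index=False)
        with pytest.raises(CohortParseError, match="age"):
            read_cohort(path)
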