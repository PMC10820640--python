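"""Total-error validation statistics: bias, precision, tolerance intervals,
risk, matrix effects, dilution integrity, specificity and stability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ivpk import (
    ValidationRun,
    accuracy_profile,
    beta_expectation_interval,
    dilution_integrity,
    ion_ratio_cv,
    is_normalized_mf,
    matrix_effect_summary,
    matrix_factor,
    precision_components,
    relative_bias,
    risk_outside_acceptance,
    simulate_validation_run,
    stability_check,
)


def run_from_series(level, *series_values):
    records = []
    for s, values in enumerate(series_values, start=1):
        records += [(s, level, v) for v in values]
    return ValidationRun.from_records(records)


# ---------------------------------------------------------------------------
# bias and precision


def test_relative_bias_arithmetic():
    assert relative_bias([10.0, 10.0], 10.0) == 0.0
    assert relative_bias([9.0, 9.0, 9.0], 10.0) == pytest.approx(-10.0)
    with pytest.raises(ValueError):
        relative_bias([], 10.0)


def test_relative_bias_recovers_generator_bias():
    run = simulate_validation_run(
        [15.0], n_series=200, n_replicates=25, overall_bias=-3.0, seed=5
    )
    bias = relative_bias(run.at_level(15.0)["measured"].to_numpy(), 15.0)
    assert bias == pytest.approx(-3.0, abs=0.5)


def test_precision_components_hand_anova():
    """Two series {8,8} and {12,12}: MSW = 0, MSB = 16, σ²_B = 8."""
    run = run_from_series(10.0, [8.0, 8.0], [12.0, 12.0])
    rep, ip = precision_components(run, 10.0)
    assert rep == 0.0
    assert ip == pytest.approx(100.0 * math.sqrt(8.0) / 10.0)


def test_precision_components_identical_replicates():
    run = run_from_series(10.0, [10.0, 10.0], [10.0, 10.0])
    assert precision_components(run, 10.0) == (0.0, 0.0)


def test_precision_components_recover_variance_magnitudes():
    """within 4%, between 3% -> repeatability ~4%, IP ~5% (sqrt(9+16)=5)."""
    run = simulate_validation_run(
        [20.0],
        n_series=40,
        n_replicates=30,
        series_bias_sd=3.0,
        within_cv=4.0,
        overall_bias=0.0,
        seed=9,
    )
    rep, ip = precision_components(run, 20.0)
    assert rep == pytest.approx(4.0, abs=0.4)
    assert ip == pytest.approx(5.0, abs=0.5)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_ip_never_below_repeatability(seed):
    run = simulate_validation_run(
        [5.0], series_bias_sd=2.0, within_cv=5.0, seed=seed
    )
    rep, ip = precision_components(run, 5.0)
    assert ip >= rep - 1e-9


# ---------------------------------------------------------------------------
# β-expectation tolerance intervals


def test_tolerance_interval_collapses_without_variance():
    run = run_from_series(10.0, [9.5, 9.5, 9.5], [9.5, 9.5, 9.5])
    ti = beta_expectation_interval(run, 10.0)
    assert ti.lower_pct == ti.upper_pct == pytest.approx(-5.0)


def test_single_series_falls_back_to_student_prediction_interval():
    values = [9.1, 10.3, 9.8, 10.6, 9.7]
    run = run_from_series(10.0, values)
    ti = beta_expectation_interval(run, 10.0, beta=0.95)
    y = np.array(values)
    n = len(y)
    half = stats.t.ppf(0.975, n - 1) * y.std(ddof=1) * math.sqrt(1 + 1 / n)
    assert ti.single_series and ti.method == "student_prediction"
    assert ti.lower_pct == pytest.approx(100 * (y.mean() - half - 10.0) / 10.0)
    assert ti.upper_pct == pytest.approx(100 * (y.mean() + half - 10.0) / 10.0)


def test_tolerance_interval_contains_bias_and_brackets_it():
    run = simulate_validation_run([1.5], overall_bias=-4.0, seed=13)
    ti = beta_expectation_interval(run, 1.5)
    bias = relative_bias(run.at_level(1.5)["measured"].to_numpy(), 1.5)
    assert ti.lower_pct <= bias <= ti.upper_pct


def test_tolerance_interval_narrows_with_replication():
    """Interval width is non-increasing in total replicate count for the
    same underlying variance structure (estimated on matched seeds)."""
    widths = []
    for n_rep in (3, 30):
        run = simulate_validation_run(
            [10.0], n_series=3, n_replicates=n_rep, seed=21
        )
        ti = beta_expectation_interval(run, 10.0)
        widths.append(ti.upper_pct - ti.lower_pct)
    assert widths[1] < widths[0]


def test_tolerance_interval_coverage_is_beta():
    """Monte-Carlo: E[P(future result in interval)] ~ β for known truth."""
    beta = 0.95
    bias, sigma_b, sigma_w = -2.0, 3.0, 4.0  # percent scale
    level = 10.0
    rng = np.random.default_rng(2024)
    p, n = 3, 5
    sigma_tot = level * math.sqrt(sigma_b**2 + sigma_w**2) / 100.0
    mu = level * (1 + bias / 100.0)
    coverages = []
    for _ in range(2000):
        series_eff = rng.normal(0, sigma_b / 100.0, p)
        rows = []
        for s in range(p):
            vals = level * (
                1 + bias / 100.0 + series_eff[s] + rng.normal(0, sigma_w / 100.0, n)
            )
            rows += [(s, level, v) for v in vals]
        ti = beta_expectation_interval(ValidationRun.from_records(rows), level, beta)
        lo = level * (1 + ti.lower_pct / 100.0)
        hi = level * (1 + ti.upper_pct / 100.0)
        coverages.append(
            stats.norm.cdf((hi - mu) / sigma_tot) - stats.norm.cdf((lo - mu) / sigma_tot)
        )
    assert abs(np.mean(coverages) - beta) < 0.02


# ---------------------------------------------------------------------------
# risk of out-of-acceptance results


def test_risk_degenerate_and_normal_quantile():
    assert risk_outside_acceptance(0.0, 0.0, 20.0) == 0.0
    assert risk_outside_acceptance(25.0, 0.0, 20.0) == 100.0
    assert risk_outside_acceptance(0.0, 20.0 / 1.959964, 20.0) == pytest.approx(
        5.0, abs=1e-3
    )


def test_risk_matches_monte_carlo():
    rng = np.random.default_rng(99)
    bias, sd, acc, df = -3.0, 6.0, 20.0, 11.0
    draws = bias + sd * rng.standard_t(df, size=10**6)
    mc = 100.0 * np.mean(np.abs(draws) > acc)
    assert risk_outside_acceptance(bias, sd, acc, df) == pytest.approx(mc, abs=0.1)


@given(
    st.floats(0.0, 15.0),
    st.floats(0.5, 10.0),
    st.floats(0.1, 5.0),
)
@settings(max_examples=50, deadline=None)
def test_risk_monotone_in_bias_and_sd(bias, sd, bump):
    base = risk_outside_acceptance(bias, sd, 20.0, df=10)
    assert risk_outside_acceptance(bias + bump, sd, 20.0, df=10) >= base - 1e-9
    assert risk_outside_acceptance(bias, sd + bump, 20.0, df=10) >= base - 1e-9


# ---------------------------------------------------------------------------
# accuracy profiles


def test_accuracy_profile_zero_noise_is_valid_with_null_bounds():
    run = simulate_validation_run(
        [0.5, 1.5, 15, 50], series_bias_sd=0, within_cv=0, overall_bias=0, seed=0
    )
    prof = accuracy_profile(run, acceptance=20.0)
    assert prof.valid
    for la in prof.levels:
        assert la.tolerance_low == la.tolerance_high == la.relative_bias == 0.0
        assert la.risk_outside == 0.0


def test_accuracy_profile_large_imprecision_fails_everywhere():
    run = simulate_validation_run(
        [0.5, 1.5, 15, 50], series_bias_sd=0, within_cv=25.0, overall_bias=0, seed=4
    )
    prof = accuracy_profile(run, acceptance=20.0)
    assert not prof.valid
    for la in prof.levels:
        assert la.tolerance_high > 20.0 or la.tolerance_low < -20.0


def test_accuracy_profile_study_like_magnitudes_pass_at_20_percent():
    """Bias/precision magnitudes typical of a validated LC-MS/MS assay
    (|bias| ≲ 9%, IP RSD ≲ 8%) keep the profile inside ±20%."""
    run = simulate_validation_run(
        [0.5, 1.5, 15, 50],
        series_bias_sd=3.0,
        within_cv=4.0,
        overall_bias=-3.0,
        seed=17,
    )
    prof = accuracy_profile(run, acceptance=20.0, beta=0.95)
    assert prof.valid
    assert all(la.risk_outside < 17.5 for la in prof.levels)


def test_accuracy_profile_invariant_to_row_order():
    run = simulate_validation_run([0.5, 1.5, 15, 50], seed=23)
    shuffled = ValidationRun(
        run.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
    )
    a = accuracy_profile(run)
    b = accuracy_profile(shuffled)
    assert a.valid == b.valid
    for la, lb in zip(a.levels, b.levels):
        assert la.tolerance_low == pytest.approx(lb.tolerance_low)
        assert la.tolerance_high == pytest.approx(lb.tolerance_high)


# ---------------------------------------------------------------------------
# matrix effects, dilution, specificity, stability


def test_matrix_factor_definitions():
    assert matrix_factor(100.0, 100.0) == 1.0
    res = is_normalized_mf(0.8, 0.9)
    assert res.is_normalized_mf == pytest.approx(0.8 / 0.9)
    assert is_normalized_mf(0.95, 0.95).is_normalized_mf == 1.0
    with pytest.raises(ValueError):
        matrix_factor(100.0, 0.0)


def test_matrix_effect_cv_across_lots_matches_direct_computation():
    rng = np.random.default_rng(31)
    lots = [is_normalized_mf(0.9 * (1 + e), 1.0) for e in rng.normal(0, 0.05, 5)]
    mean, cv = matrix_effect_summary(lots)
    vals = np.array([r.is_normalized_mf for r in lots])
    assert mean == pytest.approx(vals.mean())
    assert cv == pytest.approx(100 * vals.std(ddof=1) / vals.mean())


@pytest.mark.parametrize(
    "deviations, exp_mean, exp_sd",
    [
        ([-9.8, -10.2, -7.1, -9.3, -11.2], -9.5, 1.5),
        ([-4.7, -5.1, -5.0, -1.6, -5.2], -4.3, 1.5),
    ],
)
def test_dilution_integrity_five_fold(deviations, exp_mean, exp_sd):
    """Five-fold dilution replicates: deviations within ±15%, known summary."""
    target = 20.0
    measured = target * (1 + np.array(deviations) / 100.0)
    res = dilution_integrity(measured, target, limit=15.0)
    assert res.passed
    assert round(res.mean_pct, 1) == exp_mean
    assert round(res.sd_pct, 1) == exp_sd
    np.testing.assert_allclose(res.deviations_pct, deviations, atol=1e-9)


def test_dilution_integrity_exact_measurements():
    res = dilution_integrity([20.0, 20.0], 20.0)
    assert res.passed and res.mean_pct == 0.0 and res.sd_pct == 0.0


def test_dilution_integrity_all_vs_mean_criterion():
    measured = [20.0, 20.0, 16.0]  # one replicate at -20%
    assert not dilution_integrity(measured, 20.0, criterion="all").passed
    assert dilution_integrity(measured, 20.0, criterion="mean").passed


def test_ion_ratio_cv():
    assert ion_ratio_cv([1.0, 2.0, 3.0], [0.5, 1.0, 1.5]) == 0.0
    ratios = np.array([1.0, 1.1, 0.9])
    got = ion_ratio_cv(np.ones(3), ratios)
    assert got == pytest.approx(100 * ratios.std(ddof=1) / ratios.mean())
    with pytest.raises(ValueError):
        ion_ratio_cv([1.0, 2.0], [1.0])


def test_ion_ratio_cv_generator_round_trip():
    rng = np.random.default_rng(41)
    quant = rng.uniform(1e4, 1e5, 500)
    qual = 0.4 * quant * (1 + rng.normal(0, 0.06, 500))
    assert ion_ratio_cv(quant, qual) == pytest.approx(6.0, abs=0.6)


@pytest.mark.parametrize(
    "measured, target, passed, dev",
    [
        (100.0, 100.0, True, 0.0),
        (84.9, 100.0, False, -15.1),
        (115.0, 100.0, True, 15.0),  # inclusive boundary
    ],
)
def test_stability_acceptance(measured, target, passed, dev):
    res = stability_check(measured, target, limit=15.0)
    assert res.passed is passed
    assert res.deviation_pct == pytest.approx(dev)
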