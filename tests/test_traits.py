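"""Quantile SMR/MMR estimators, outlier rule, aerobic scope and the ṀO₂ curve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxyscope import (
    FilterConfig,
    ValidationError,
    aerobic_scope,
    estimate_mmr,
    estimate_smr,
    fit_mo2_curve,
    iqr_filter,
    temperature_smr,
)


# --- independent order-statistic oracles -----------------------------------

def oracle_smr(values, trim=0.05, q=0.15):
    x = sorted(values)
    kept = x[int(np.floor(trim * len(x))):]
    return float(np.quantile(kept, q, method="linear"))


def oracle_mmr(values, trim=0.05, upper=0.30):
    x = sorted(values)
    n_drop = int(np.floor(trim * len(x)))
    kept = x[: len(x) - n_drop] if n_drop else x
    thr = float(np.quantile(kept, 1 - upper, method="linear"))
    tail = [v for v in kept if v >= thr]
    return float(np.mean(tail))


def oracle_iqr(values, k_out=1.5, k_ext=3.0):
    x = np.asarray(values, float)
    q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    extreme = (x < q1 - k_ext * iqr) | (x > q3 + k_ext * iqr)
    outlier = ((x < q1 - k_out * iqr) | (x > q3 + k_out * iqr)) & ~extreme
    return x[~outlier & ~extreme], x[outlier], x[extreme]


class TestIqrFilter:
    def test_single_high_artefact_removed(self):
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9, 100]
        kept, out, ext = iqr_filter(values)
        assert 100 not in kept
        assert 100 in np.concatenate([out, ext])

    def test_equal_values_all_kept(self):
        kept, out, ext = iqr_filter([5.0] * 8)
        assert kept.size == 8 and out.size == 0 and ext.size == 0

    def test_low_side_artefact_removed(self):
        kept, out, ext = iqr_filter([-50, 1, 2, 3, 4, 5, 6, 7, 8, 9])
        assert -50 not in kept

    def test_fewer_than_four_values_untouched(self):
        kept, out, ext = iqr_filter([1.0, 2.0, 100.0])
        assert kept.size == 3

    def test_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(4, 30)
            x = rng.lognormal(0, 1, n)
            kept, out, ext = iqr_filter(x)
            ok, oo, oe = oracle_iqr(x)
            np.testing.assert_array_equal(np.sort(kept), np.sort(ok))
            np.testing.assert_array_equal(np.sort(out), np.sort(oo))
            np.testing.assert_array_equal(np.sort(ext), np.sort(oe))


class TestEstimateSmr:
    def test_worked_example_1_to_100(self):
        values = np.arange(1.0, 101.0)
        assert estimate_smr(values) == pytest.approx(20.1)

    def test_constant_sequence(self):
        assert estimate_smr([0.5] * 20) == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            estimate_smr([])

    def test_plain_quantile_mode(self):
        values = np.arange(1.0, 101.0)
        expected = float(np.quantile(values, 0.20, method="linear"))
        assert estimate_smr(values, mode="plain_quantile") == pytest.approx(expected)

    def test_recovers_truth_under_lognormal_activity(self):
        # resting rate 0.5 contaminated by right-skewed activity spikes
        rng = np.random.default_rng(11)
        base = 0.5 * (1 + np.abs(rng.normal(0, 0.02, 90)))
        active = rng.random(90) < 0.4
        base[active] *= 1 + rng.lognormal(0, 0.5, int(active.sum()))
        assert estimate_smr(base) == pytest.approx(0.5, rel=0.10)


class TestEstimateMmr:
    def test_worked_example_1_to_100(self):
        values = np.arange(1.0, 101.0)
        # drop {96..100}; mean of the top-30% tail of {1..95}
        assert estimate_mmr(values) == pytest.approx(81.0)

    def test_constant_sequence(self):
        assert estimate_mmr([3.5] * 20) == pytest.approx(3.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            estimate_mmr([])


class TestEstimatorProperties:
    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(0.01, 100.0, allow_nan=False), min_size=4, max_size=20
        ),
        st.floats(-5.0, 5.0),
        st.floats(0.1, 10.0),
    )
    def test_shift_and_scale_equivariance(self, values, c, k):
        x = np.asarray(values)
        smr = estimate_smr(x)
        mmr = estimate_mmr(x)
        assert estimate_smr(x + c) == pytest.approx(smr + c, abs=1e-9)
        assert estimate_smr(x * k) == pytest.approx(smr * k, rel=1e-9)
        assert estimate_mmr(x + c) == pytest.approx(mmr + c, abs=1e-9)
        assert estimate_mmr(x * k) == pytest.approx(mmr * k, rel=1e-9)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(0.01, 100.0, allow_nan=False),
            min_size=4,
            max_size=20,
            unique=True,
        )
    )
    def test_smr_below_median_below_mmr(self, values):
        x = np.asarray(values)
        med = float(np.median(x))
        assert estimate_smr(x) <= med + 1e-9
        assert estimate_mmr(x) >= med - 1e-9

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(0.01, 100.0, allow_nan=False), min_size=1, max_size=20)
    )
    def test_exhaustive_oracle_agreement(self, values):
        assert estimate_smr(values) == pytest.approx(oracle_smr(values), rel=1e-12)
        assert estimate_mmr(values) == pytest.approx(oracle_mmr(values), rel=1e-12)


class TestTemperatureSmr:
    def test_mean_and_sd(self):
        mean, sd = temperature_smr([0.4, 0.5, 0.6])
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(0.1)

    def test_single_individual_sd_undefined(self):
        mean, sd = temperature_smr([0.5])
        assert mean == 0.5 and np.isnan(sd)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            temperature_smr([])


class TestAerobicScope:
    def test_treatment_level_worked_values(self):
        as_abs, fas = aerobic_scope(0.49, 3.47)
        assert as_abs == pytest.approx(2.98)
        assert fas == pytest.approx(7.08, abs=0.005)

    def test_degenerate_equal_rates(self):
        as_abs, fas = aerobic_scope(1.0, 1.0)
        assert as_abs == 0.0 and fas == 1.0

    def test_negative_scope_returned(self):
        as_abs, fas = aerobic_scope(2.0, 1.0)
        assert as_abs == -1.0

    def test_zero_smr_rejected(self):
        with pytest.raises(ValidationError):
            aerobic_scope(0.0, 1.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(smr=st.floats(0.01, 10.0), mmr=st.floats(0.01, 20.0))
    def test_scope_identity(self, smr, mmr):
        as_abs, fas = aerobic_scope(smr, mmr)
        assert as_abs == pytest.approx(smr * (fas - 1), rel=1e-12, abs=1e-12)


class TestMo2Curve:
    def test_reproduces_linear_signal(self):
        p = np.linspace(2, 20, 15)
        m = 0.1 + 0.05 * p
        curve = fit_mo2_curve(p, m)
        np.testing.assert_allclose(curve(p), m, atol=1e-6)

    def test_quadratic_within_one_percent_of_range(self):
        p = np.linspace(2, 20, 25)
        m = 0.5 + 0.02 * (p - 10) ** 2
        curve = fit_mo2_curve(p, m)
        err = np.max(np.abs(curve(p) - m))
        assert err < 0.01 * (m.max() - m.min())

    def test_oxyregulator_profile_monotone_below_break(self):
        rng = np.random.default_rng(5)
        p = np.linspace(1, 20, 40)
        m = np.minimum(1.0, 0.3 * p) + rng.normal(0, 0.01, 40)
        curve = fit_mo2_curve(p, m)
        grid = np.linspace(1.2, 3.0, 20)
        fitted = curve(grid)
        assert np.all(np.diff(fitted) > -curve.residual_sd)

    def test_too_few_distinct_po2_rejected(self):
        p = np.repeat([1.0, 2.0, 3.0, 4.0], 3)
        with pytest.raises(ValidationError):
            fit_mo2_curve(p, p)

    def test_evaluation_outside_range_rejected(self):
        p = np.linspace(2, 20, 10)
        curve = fit_mo2_curve(p, p * 0.1)
        with pytest.raises(ValidationError):
            curve(25.0)


def test_filter_config_validates_fence_order():
    with pytest.raises(ValidationError):
        FilterConfig(k_outlier=4.0, k_extreme=3.0)
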