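"""Swim protocol, Brett indices, burst metrics and exhaustion detection."""

import numpy as np
import pytest

from oxyscope import (
    FishMeta,
    SwimTrial,
    ValidationError,
    VelocityStep,
    build_protocol,
    burst_metrics,
    exhaustion_detect,
    u_crit,
    u_gait,
)


def make_trial(
    completed_velocities,
    failed=None,
    endured=0.0,
    bursts=None,
    first_burst_s=None,
    t=660.0,
    v=0.15,
):
    """Assemble a SwimTrial from a compact description.

    ``bursts`` maps step index → count; ``first_burst_s`` maps step index
    → seconds into that step of the first burst.
    """
    bursts = bursts or {}
    first_burst_s = first_burst_s or {}
    steps = []
    for k, vel in enumerate(completed_velocities):
        steps.append(
            VelocityStep(
                index=k,
                velocity=vel,
                start_time=k * t,
                duration_completed=t,
                bursts=bursts.get(k, 0),
                burst_time=2.0 * bursts.get(k, 0),
                first_burst_s=first_burst_s.get(k),
            )
        )
    exhausted = failed is not None
    if exhausted:
        k = len(steps)
        steps.append(
            VelocityStep(
                index=k,
                velocity=failed,
                start_time=k * t,
                duration_completed=endured,
                bursts=bursts.get(k, 0),
                burst_time=2.0 * bursts.get(k, 0),
                first_burst_s=first_burst_s.get(k),
            )
        )
    fish = FishMeta(id="S1", body_weight=40.0, total_length=19.7)
    return SwimTrial(
        fish=fish,
        po2_level=100.0,
        steps=steps,
        step_duration_s=t,
        increment=v,
        exhausted=exhausted,
    )


class TestProtocol:
    def test_default_step_ladder(self):
        proto = build_protocol(n_steps=9)
        np.testing.assert_allclose(
            proto.velocities, 1.4 + 0.15 * np.arange(9)
        )
        assert proto.velocities[-1] == pytest.approx(2.6)
        assert proto.step_duration_s == 660.0

    def test_settling_step_precedes_protocol(self):
        proto = build_protocol()
        assert proto.settling_velocity == pytest.approx(1.2)
        assert proto.settling_s == pytest.approx(25 * 60)

    def test_zero_increment_rejected(self):
        with pytest.raises(ValidationError):
            build_protocol(increment=0.0)


class TestUcrit:
    def test_brett_worked_value(self):
        trial = make_trial(np.arange(1.4, 2.61, 0.15), failed=2.75, endured=330.0)
        assert u_crit(trial) == pytest.approx(2.675)

    def test_immediate_failure_collapses_to_umax(self):
        trial = make_trial([1.4, 1.55], failed=1.7, endured=0.0)
        assert u_crit(trial) == pytest.approx(1.55)

    def test_full_endurance_equals_next_step(self):
        trial = make_trial([1.4, 1.55], failed=1.7, endured=660.0)
        assert u_crit(trial) == pytest.approx(1.7)

    def test_no_exhaustion_reports_top_completed_speed(self):
        trial = make_trial([1.4, 1.55, 1.7])
        assert u_crit(trial) == pytest.approx(1.7)

    def test_failure_before_first_full_step_uses_settling_velocity(self):
        trial = make_trial([], failed=1.4, endured=330.0)
        assert u_crit(trial) == pytest.approx(1.2 + 0.15 * 330 / 660)

    def test_bounds_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(1, 8))
            endured = float(rng.uniform(0, 660))
            trial = make_trial(
                1.4 + 0.15 * np.arange(n),
                failed=1.4 + 0.15 * n,
                endured=endured,
            )
            u_max = trial.steps[n - 1].velocity
            assert u_max - 1e-9 <= u_crit(trial) <= u_max + 0.15 + 1e-9

    def test_invariant_to_burst_annotations(self):
        plain = make_trial([1.4, 1.55, 1.7], failed=1.85, endured=100.0)
        bursty = make_trial(
            [1.4, 1.55, 1.7],
            failed=1.85,
            endured=100.0,
            bursts={1: 3, 2: 5},
            first_burst_s={1: 50.0},
        )
        assert u_crit(plain) == u_crit(bursty)


class TestUgait:
    def test_worked_value(self):
        # steady through 2.15; first burst 220 s into the 2.3 step
        vels = np.arange(1.4, 2.31, 0.15)
        k = len(vels) - 1
        trial = make_trial(vels, bursts={k: 4}, first_burst_s={k: 220.0})
        assert u_gait(trial) == pytest.approx(2.2, abs=1e-9)

    def test_no_bursts_undefined_with_flag(self):
        trial = make_trial([1.4, 1.55, 1.7])
        assert u_gait(trial) is None
        assert "no_gait_transition" in trial.flags

    def test_burst_at_step_start_returns_usteady(self):
        trial = make_trial([1.4, 1.55, 1.7], bursts={2: 1}, first_burst_s={2: 0.0})
        assert u_gait(trial) == pytest.approx(1.55)

    def test_burst_at_first_step_uses_settling_velocity(self):
        trial = make_trial([1.4, 1.55], bursts={0: 2}, first_burst_s={0: 100.0})
        assert u_gait(trial) == pytest.approx(1.2 + 0.15 * 100 / 660)
        assert "burst_at_first_step" in trial.flags

    def test_gait_below_ucrit_when_both_defined(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 8))
            kb = int(rng.integers(1, n + 1))
            endured = float(rng.uniform(0, 660))
            # the first burst cannot postdate exhaustion on the failed step
            burst_at = float(rng.uniform(0, endured if kb == n else 660))
            trial = make_trial(
                1.4 + 0.15 * np.arange(n),
                failed=1.4 + 0.15 * n,
                endured=endured,
                bursts={kb: 2},
                first_burst_s={kb: burst_at},
            )
            g = u_gait(trial)
            assert g is not None
            assert g <= u_crit(trial) + 1e-9


class TestBurstMetrics:
    def test_rate_per_active_minute(self):
        trial = make_trial([], failed=1.4, endured=200.0, bursts={0: 10})
        m = burst_metrics(trial)
        assert m.bursts_per_min == pytest.approx(3.0)
        assert m.total_bursts == 10

    def test_zero_bursts_all_zero(self):
        trial = make_trial([1.4, 1.55])
        m = burst_metrics(trial)
        assert m.total_bursts == 0 and m.bursts_per_min == 0.0
        assert m.burst_time_fraction == 0.0

    def test_poisson_trial_recovers_printed_normoxic_rate(self):
        # bursts drawn at the observed normoxic rate of 2.9 bursts/min of
        # active swimming; the metric must recover it within sampling error
        rng = np.random.default_rng(9)
        rate_per_min = 2.9
        vels = 1.4 + 0.15 * np.arange(8)
        counts = {
            k: int(rng.poisson(rate_per_min * 660 / 60)) for k in range(len(vels))
        }
        trial = make_trial(vels, bursts=counts)
        m = burst_metrics(trial)
        total_min = 8 * 660 / 60
        se = np.sqrt(rate_per_min / total_min)
        assert m.bursts_per_min == pytest.approx(rate_per_min, abs=3 * se)


class TestExhaustionDetect:
    def test_long_inactive_run_detected(self):
        activity = np.ones(600)
        activity[330:421] = 0  # 91 s of refusal starting 330 s into the step
        result = exhaustion_detect(activity, t0=0.0, step_start=0.0)
        assert result is not None
        exhausted_time, endured = result
        assert exhausted_time == pytest.approx(330.0)
        assert endured == pytest.approx(330.0)

    def test_continuous_swimming_never_exhausts(self):
        assert exhaustion_detect(np.ones(600)) is None

    @pytest.mark.parametrize("run", [89, 90])
    def test_rule_is_strictly_greater_than_90s(self, run):
        activity = np.ones(400)
        activity[100 : 100 + run] = 0
        assert exhaustion_detect(activity) is None
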