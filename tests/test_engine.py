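"""Target-seeking level integration: rate laws, Euler stepping, experience loop."""

import numpy as np
import pytest

from ihsim.dynamization import TargetSchedule
from ihsim.engine import (
    DelaySpec,
    SimulationConfig,
    StateLevel,
    integrate_level,
    simulate_patient,
    step_rate,
)
from ihsim.cohort import (
    PatientRecord,
    RecordParameter,
    build_patient_model,
)


def _schedule(targets, start=0):
    targets = np.asarray(targets, dtype=float)
    return TargetSchedule("s", np.arange(start, start + len(targets)), targets)


def _config(end, mode="symmetric", experience_delay=1.0):
    return SimulationConfig(start_year=0, end_year=end, rate_cap_mode=mode,
                            experience_delay=experience_delay)


class TestStepRate:
    @pytest.mark.parametrize("mode", ["literal", "symmetric"])
    def test_positive_target_gap_over_delay(self, mode):
        rc = step_rate(0.0, 100.0, DelaySpec(adjustment_time=4), mode)
        assert rc.inflow == pytest.approx(25.0)

    def test_zero_gap_symmetric(self):
        for g in (-50.0, 0.0, 70.0):
            assert step_rate(g, g, DelaySpec(adjustment_time=2), "symmetric").inflow == 0.0

    def test_literal_min_with_negative_target(self):
        # the literal cap picks MIN(-25, -50) = -50: negative targets repel
        rc = step_rate(0.0, -50.0, DelaySpec(adjustment_time=2), "literal")
        assert rc.inflow == -50.0

    def test_symmetric_attracts_negative_target(self):
        rc = step_rate(0.0, -50.0, DelaySpec(adjustment_time=2), "symmetric")
        assert rc.inflow == -25.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            step_rate(float("nan"), 0.0, DelaySpec(adjustment_time=1))


class TestIntegrateLevel:
    def test_closed_form_geometric_approach(self):
        # constant g, IV=0, d=2: PV_t = g(1 - (1-1/d)^t); PV_3 = 87.5
        sched = _schedule([100.0] * 11)
        lv = integrate_level(StateLevel("x"), sched, DelaySpec(adjustment_time=2), _config(10))
        assert lv.trajectory[3] == pytest.approx(87.5)
        t = np.arange(11)
        np.testing.assert_allclose(lv.trajectory, 100 * (1 - 0.5**t), atol=1e-12)

    def test_fixed_point_constant_trajectory(self):
        sched = _schedule([42.0] * 6)
        lv = integrate_level(StateLevel("x", initial_value=42.0), sched,
                             DelaySpec(adjustment_time=3), _config(5))
        assert np.all(lv.trajectory == 42.0)

    def test_small_delay_rate_capped_by_target(self):
        # d=0.05 would overshoot wildly; the symmetric cap limits the step to |g|
        sched = _schedule([10.0] * 6)
        lv = integrate_level(StateLevel("x"), sched, DelaySpec(adjustment_time=0.05), _config(5))
        np.testing.assert_allclose(lv.trajectory, [0, 10, 10, 10, 10, 10])

    def test_window_not_covered_rejected(self):
        sched = _schedule([0.0] * 4)
        with pytest.raises(ValueError, match="cover"):
            integrate_level(StateLevel("x"), sched, DelaySpec(adjustment_time=1), _config(10))

    def test_gap_nonincreasing_symmetric(self):
        # balancing loop: the distance to a constant goal never grows (d >= 1)
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = float(rng.uniform(-100, 100))
            iv = float(rng.uniform(-100, 100))
            d = float(rng.uniform(1, 6))
            sched = _schedule([g] * 13)
            lv = integrate_level(StateLevel("x", initial_value=iv), sched,
                                 DelaySpec(adjustment_time=d), _config(12))
            gaps = np.abs(lv.trajectory - g)
            assert np.all(np.diff(gaps) <= 1e-9)

    @pytest.mark.parametrize("mode", ["symmetric", "literal"])
    def test_matches_year_by_year_replay_oracle(self, mode):
        """Euler trajectories equal an independent replay on random instances."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(2, 15))
            targets = rng.uniform(-100, 100, size=n + 1)
            iv = float(rng.uniform(-100, 100))
            d = float(rng.uniform(0.5, 6))
            sched = _schedule(targets)
            lv = integrate_level(
                StateLevel("x", initial_value=iv), sched,
                DelaySpec(adjustment_time=d), _config(n, mode=mode),
            )
            # independent oracle: direct transcription of the rate law
            pv = iv
            expected = [iv]
            for t in range(n):
                g = targets[t]
                raw = (g - pv) / d
                if mode == "literal":
                    rate = min(raw, g)
                else:
                    rate = np.sign(raw) * min(abs(raw), abs(g)) if g != 0 else raw
                pv = pv + rate
                expected.append(pv)
            np.testing.assert_allclose(lv.trajectory, expected, rtol=0, atol=1e-12)

    def test_modes_differ_only_when_cap_binds_or_target_negative(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            pv = float(rng.uniform(-100, 100))
            g = float(rng.uniform(-100, 100))
            d = float(rng.uniform(0.2, 5))
            lit = step_rate(pv, g, DelaySpec(adjustment_time=d), "literal").inflow
            sym = step_rate(pv, g, DelaySpec(adjustment_time=d), "symmetric").inflow
            raw = (g - pv) / d
            if lit != sym:
                assert abs(raw) > abs(g) or g < 0

    def test_growth_arrest_under_piecewise_target(self):
        # growth toward a high goal, then the goal plateaus: the level's rise halts
        targets = np.array([80.0] * 5 + [30.0] * 6)
        lv = integrate_level(StateLevel("x"), _schedule(targets),
                             DelaySpec(adjustment_time=2), _config(10))
        diffs = np.diff(lv.trajectory)
        assert np.all(diffs[:4] > 0)          # growth phase
        assert diffs[5] < 0                   # arrested by the new regime
        assert lv.trajectory[-1] == pytest.approx(30.0, abs=2.0)


def _record(params, onset=2010, interview=2020, **kw):
    return PatientRecord(
        patient_id="T", onset_year=onset, interview_year=interview,
        parameters=params, **kw,
    )


class TestSimulatePatient:
    def test_all_zero_inputs_zero_experience(self, registry):
        model = build_patient_model(_record({}), registry)
        res = simulate_patient(model)
        assert np.all(res.experience == 0)
        assert all(np.all(v == 0) for v in res.aggregates.values())
        assert len(res.years) == 11

    def test_single_aggregate_lagged_tracking(self, registry):
        # one unit-delay aggregate at +50: experience follows one step behind
        rec = _record(
            {"nap_refreshing_value": RecordParameter(
                first_occurrence_year=2010, max_value=50, perception="positive")}
        )
        model = build_patient_model(rec, registry)
        cfg = SimulationConfig(start_year=2010, end_year=2020, experience_delay=1.0)
        res = simulate_patient(model, cfg)
        naps = res.aggregates["Naps"]
        np.testing.assert_allclose(naps[:3], [0, 50, 50])
        np.testing.assert_allclose(res.experience[:4], [0, 0, 50, 50])

    def test_opposite_aggregates_cancel(self, registry):
        rec = _record(
            {
                "nap_refreshing_value": RecordParameter(
                    first_occurrence_year=2010, max_value=50, perception="positive"),
                "nocturnal_sleep_quality": RecordParameter(
                    first_occurrence_year=2010, max_value=50, perception="negative"),
            }
        )
        model = build_patient_model(rec, registry)
        # equal delays so the transients cancel exactly
        for name in model.aggregate_delays:
            model.aggregate_delays[name] = DelaySpec(adjustment_time=1.0)
        res = simulate_patient(model)
        np.testing.assert_allclose(res.experience, 0, atol=1e-12)

    def test_all_series_share_year_axis(self, small_cohort):
        _, _, results = small_cohort
        for res in results:
            n = len(res.years)
            assert len(res.experience) == n
            assert all(len(v) == n for v in res.aggregates.values())
            assert set(res.aggregates) == {
                "Anxiety", "Depression", "Sleep inertia",
                "Work and social impairment", "Sleepiness", "Fatigue", "Naps",
                "Nocturnal sleep", "Other psychiatric disorders",
                "Somatic pathologies", "Methylphenidate effect", "Modafinil effect",
            }
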