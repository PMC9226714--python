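"""Normalization and target-schedule construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihsim.dynamization import (
    ChangeEvent,
    DynamicParameterSpec,
    MedicationEpisode,
    ParameterKind,
    PolarityRule,
    RawParameter,
    build_medication_schedule,
    build_target_schedule,
    normalize_value,
)


def _param(**kw):
    base = dict(name="p", kind="continuous", scale_min=0.0, scale_max=100.0,
                static_value=0.0, polarity_rule="always_negative")
    base.update(kw)
    return RawParameter(**base)


class TestNormalizeValue:
    @pytest.mark.parametrize(
        "raw,lo,hi,expected",
        [
            (24, 0, 24, 100.0),   # instrument maximum maps to 100
            (12, 0, 24, 50.0),    # midpoint
            (0, 0, 24, 0.0),
            (2, 1, 3, 50.0),      # 3-level ordinal, middle level
        ],
    )
    def test_linear_mapping(self, raw, lo, hi, expected):
        p = _param(scale_min=float(lo), scale_max=float(hi))
        assert normalize_value(raw, p) == pytest.approx(expected)

    def test_ordinal_levels_evenly_spaced(self):
        # even spacing 100*(k-1)/(K-1) over an enumerated 5-level scale
        p = _param(kind="ordinal", scale_min=1.0, scale_max=5.0)
        got = [normalize_value(k, p) for k in range(1, 6)]
        expected = [100.0 * (k - 1) / 4 for k in range(1, 6)]
        assert got == pytest.approx(expected)

    def test_binary_maps_to_endpoints(self):
        p = _param(kind="binary", scale_min=None, scale_max=None)
        assert normalize_value(1, p) == 100.0
        assert normalize_value(0, p) == 0.0

    def test_out_of_range_clamped_with_warning(self, caplog):
        p = _param(scale_min=0.0, scale_max=24.0)
        with caplog.at_level("WARNING"):
            assert normalize_value(30, p) == 100.0
        assert "clamped" in caplog.text

    def test_missing_scale_names_parameter(self):
        p = _param(name="ess", scale_min=None, scale_max=None)
        with pytest.raises(ValueError, match="ess"):
            normalize_value(5, p)

    def test_degenerate_scale_rejected_at_construction(self):
        with pytest.raises(ValueError, match="degenerate"):
            _param(scale_min=5.0, scale_max=5.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 24), min_size=2, max_size=10))
    def test_monotone_nondecreasing(self, raws):
        p = _param(scale_min=0.0, scale_max=24.0)
        raws = sorted(raws)
        vals = [normalize_value(r, p) for r in raws]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestBuildTargetSchedule:
    def test_always_negative_active_window(self):
        # depression-like: active years 5-10, severity 60/100 -> g=-60 there
        p = _param(
            static_value=None,
            dynamic_spec=DynamicParameterSpec(
                first_occurrence_year=5, last_occurrence_year=10, max_value=60
            ),
        )
        s = build_target_schedule(p, 0, 14)
        assert np.all(s.targets[:5] == 0)
        assert np.all(s.targets[5:11] == -60)
        assert np.all(s.targets[11:] == 0)

    def test_static_positive_constant(self):
        p = _param(static_value=40.0, polarity_rule="always_positive")
        s = build_target_schedule(p, 2000, 2010)
        assert np.all(s.targets == 40.0)

    def test_step_change_events(self):
        p = _param(
            static_value=None,
            dynamic_spec=DynamicParameterSpec(
                first_occurrence_year=3,
                max_value=80,
                change_events=[
                    ChangeEvent(year=3, value=80),
                    ChangeEvent(year=6, value=20),
                ],
            ),
            polarity_rule="always_positive",
        )
        s = build_target_schedule(p, 0, 8)
        assert list(s.targets) == [0, 0, 0, 80, 80, 80, 20, 20, 20]

    def test_event_outside_window_rejected(self):
        p = _param(
            static_value=None,
            dynamic_spec=DynamicParameterSpec(
                first_occurrence_year=1, last_occurrence_year=4, max_value=50,
                change_events=[ChangeEvent(year=7, value=10)],
            ),
        )
        with pytest.raises(ValueError, match="outside"):
            build_target_schedule(p, 0, 10)

    def test_data_dependent_needs_perception(self):
        p = _param(
            static_value=None, polarity_rule="data_dependent",
            dynamic_spec=DynamicParameterSpec(first_occurrence_year=0, max_value=50),
        )
        with pytest.raises(ValueError, match="perception"):
            build_target_schedule(p, 0, 5)
        ok = p.model_copy(update={"perception": "positive"})
        s = build_target_schedule(ok, 0, 5)
        assert np.all(s.targets == 50)

    def test_if_df_split_is_exact(self):
        p = _param(static_value=33.3, polarity_rule="always_negative")
        s = build_target_schedule(p, 0, 5)
        np.testing.assert_array_equal(
            s.increasing_component - s.decreasing_component, s.targets
        )
        assert np.all(s.increasing_component >= 0)
        assert np.all(s.decreasing_component >= 0)

    def test_random_specs_match_event_replay_oracle(self):
        """Replaying change events year by year reproduces the schedule."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            first = int(rng.integers(0, 6))
            last = int(rng.integers(first, 12))
            n_ev = int(rng.integers(0, 4))
            ev_years = sorted(int(rng.integers(first, last + 1)) for _ in range(n_ev))
            events = [ChangeEvent(year=y, value=float(rng.uniform(0, 100)))
                      for y in ev_years]
            maxv = float(rng.uniform(0, 100))
            p = _param(
                static_value=None,
                dynamic_spec=DynamicParameterSpec(
                    first_occurrence_year=first, last_occurrence_year=last,
                    max_value=maxv, change_events=events,
                ),
            )
            s = build_target_schedule(p, 0, 14)

            # independent oracle: walk the years, tracking the current target
            expected = []
            for year in range(0, 15):
                if year < first or year > last:
                    expected.append(0.0)
                    continue
                level = maxv
                for ev in events:
                    if ev.year <= year:
                        level = ev.value
                expected.append(-level)
            np.testing.assert_allclose(s.targets, expected, atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        first=st.integers(0, 5),
        span=st.integers(0, 10),
        maxv=st.floats(0, 100),
    )
    def test_targets_bounded(self, first, span, maxv):
        p = _param(
            static_value=None,
            dynamic_spec=DynamicParameterSpec(
                first_occurrence_year=first, last_occurrence_year=first + span,
                max_value=maxv,
            ),
        )
        s = build_target_schedule(p, 0, first + span + 3)
        assert np.all(np.abs(s.targets) <= 100)


class TestMedicationSchedule:
    def test_decay_after_discontinuation(self):
        p = _param(name="modafinil_effect", polarity_rule="always_positive")
        eps = [MedicationEpisode(start_year=10, stop_year=12, perceived_effect=40)]
        s = build_medication_schedule(eps, p, 5, 16)
        by_year = dict(zip(s.years.tolist(), s.targets.tolist()))
        assert by_year[9] == 0
        assert by_year[10] == by_year[12] == 40
        assert by_year[13] == pytest.approx(20.0)  # one persistence year at half strength
        assert by_year[14] == 0

    def test_no_episodes_all_zero(self):
        p = _param(polarity_rule="always_positive")
        s = build_medication_schedule([], p, 0, 10)
        assert np.all(s.targets == 0)

    def test_zero_effect_all_zero(self):
        p = _param(polarity_rule="always_positive")
        eps = [MedicationEpisode(start_year=2, stop_year=4, perceived_effect=0)]
        s = build_medication_schedule(eps, p, 0, 10)
        assert np.all(s.targets == 0)

    def test_overlapping_episodes_rejected(self):
        p = _param(polarity_rule="always_positive")
        eps = [
            MedicationEpisode(start_year=2, stop_year=6, perceived_effect=40),
            MedicationEpisode(start_year=5, stop_year=8, perceived_effect=40),
        ]
        with pytest.raises(ValueError, match="overlap"):
            build_medication_schedule(eps, p, 0, 10)


class TestSpecValidation:
    def test_reversed_occurrence_years_rejected(self):
        with pytest.raises(ValueError):
            DynamicParameterSpec(
                first_occurrence_year=8, last_occurrence_year=3, max_value=10
            )

    def test_unsorted_events_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            DynamicParameterSpec(
                first_occurrence_year=0, max_value=10,
                change_events=[ChangeEvent(year=5, value=1), ChangeEvent(year=2, value=1)],
            )

    def test_static_and_dynamic_mutually_exclusive(self):
        with pytest.raises(ValueError, match="exactly one"):
            RawParameter(
                name="x", static_value=1.0,
                dynamic_spec=DynamicParameterSpec(first_occurrence_year=0, max_value=1),
            )
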