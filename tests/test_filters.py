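"""Unit and property tests of the heart-rate and temperature cascades."""

import math

import pytest
from hypothesis import given, strategies as st

from whdd.filters import (
    BODY_PART_ALPHA,
    FilterConfig,
    FilterStateError,
    HRFilterState,
    TempFilterState,
    hr_error_step,
    hr_filter_step,
    hr_max,
    hr_max_threshold,
    hr_threshold_step,
    hr_window_mean,
    round_half_away,
    skin_to_core,
    temp_compensate,
    temp_filter_step,
    temp_threshold_step,
    temp_window_mean,
)

CFG = FilterConfig()


# --------------------------------------------------------------------------
# maximum heart rate


@pytest.mark.parametrize("age, expected", [(26, 189.8), (40, 180.0)])
def test_hr_max_formula(age, expected):
    assert hr_max(age) == pytest.approx(expected)


def test_hr_max_threshold_rounds_to_integer_bpm():
    assert hr_max_threshold(26) == 190


@pytest.mark.parametrize("age", [0, -5])
def test_hr_max_rejects_non_positive_age(age):
    with pytest.raises(ValueError):
        hr_max(age)


@pytest.mark.parametrize(
    "x, expected", [(0.5, 1), (-0.5, -1), (18.0, 18), (-21.0, -21), (2.4, 2)]
)
def test_rounding_is_half_away_from_zero(x, expected):
    assert round_half_away(x) == expected


# --------------------------------------------------------------------------
# threshold stage


@pytest.mark.parametrize(
    "value, expected",
    [(200.0, 80.0), (120.0, 120.0), (49.0, 80.0), (0.0, 80.0), (50.0, 50.0)],
)
def test_threshold_stage_replaces_out_of_band_with_previous(value, expected):
    state = HRFilterState(relax_hr=80.0)
    assert hr_threshold_step(state, value, CFG) == expected


@given(st.lists(st.floats(min_value=0, max_value=400), min_size=1,
                max_size=150))
def test_threshold_outputs_stay_in_band_given_in_band_seed(values):
    """With slot 0 in [50, 190] every stored value remains in band."""
    state = HRFilterState(relax_hr=70.0)
    for v in values:
        if state.full:
            hr_window_mean(state, CFG)
        out = hr_threshold_step(state, v, CFG)
        assert CFG.hr_lower <= out <= CFG.hr_upper


# --------------------------------------------------------------------------
# error stage


def _state_with_prev(prev: float) -> HRFilterState:
    state = HRFilterState(relax_hr=prev)
    state.count = 1  # pretend the threshold stage just wrote slot 1
    state.window[1] = prev
    return state


@pytest.mark.parametrize(
    "prev, value, expected",
    [
        (100.0, 130.0, 112.0),   # +30 > 25: value - round(30 * 0.6)
        (100.0, 80.0, 101.0),    # -20 < -10: value - round(-20 * 1.05)
        (100.0, 110.0, 110.0),   # dead band identity
    ],
)
def test_error_stage_corrections(prev, value, expected):
    state = _state_with_prev(prev)
    state.window[0] = prev
    assert hr_error_step(state, value, CFG) == expected


@given(
    prev=st.floats(min_value=50, max_value=190),
    error=st.floats(min_value=-10, max_value=25),
)
def test_error_stage_is_identity_on_dead_band(prev, error):
    state = _state_with_prev(prev)
    state.window[0] = prev
    value = prev + error
    assert hr_error_step(state, value, CFG) == value
    assert state.mincount == 0 and state.maxcount == 0


def test_high_budget_exhaustion_repeats_previous_and_resets():
    """The third consecutive high jump repeats the previous slot."""
    state = HRFilterState(relax_hr=100.0)
    outs = []
    for v in [130.0, 145.0, 160.0]:
        thr = hr_threshold_step(state, v, CFG)
        outs.append(hr_error_step(state, thr, CFG))
    # 1st: 130 - round(30*0.6) = 112; 2nd: 145 - round(33*0.6) = 125
    assert outs[0] == 112.0
    assert outs[1] == 125.0
    # 3rd: error 160-125 = 35 > 25, maxcount exceeds budget 2
    assert outs[2] == 125.0
    assert state.maxcount == 0


def test_low_budget_allows_six_consecutive_corrections():
    state = HRFilterState(relax_hr=180.0)
    corrected = 0
    prev = 180.0
    for _ in range(7):
        value = prev - 20.0
        thr = hr_threshold_step(state, value, CFG)
        out = hr_error_step(state, thr, CFG)
        if out != prev:
            corrected += 1
        prev = state.window[state.count]
    assert corrected == 6
    assert state.mincount == 0  # reset after the budget was exceeded


@given(st.lists(st.floats(min_value=0, max_value=300), min_size=1,
                max_size=200))
def test_counter_invariants_under_random_streams(values):
    state = HRFilterState(relax_hr=70.0)
    for v in values:
        hr_filter_step(state, v, CFG)
        assert 0 <= state.count <= CFG.window_len - 1
        assert 0 <= state.mincount <= CFG.low_budget + 1
        assert 0 <= state.maxcount <= CFG.high_budget + 1


# --------------------------------------------------------------------------
# window means


def test_hr_window_mean_of_constant_window():
    state = HRFilterState(relax_hr=120.0)
    for _ in range(59):
        hr_filter_step(state, 120.0, CFG)
    # the 59th sample completes the window inside hr_filter_step
    state2 = HRFilterState(relax_hr=120.0)
    means = [hr_filter_step(state2, 120.0, CFG)[1] for _ in range(59)]
    assert means[-1] == pytest.approx(120.0)
    assert all(m is None for m in means[:-1])


def test_hr_window_mean_matches_brute_force_oracle():
    state = HRFilterState(relax_hr=70.0)
    state.window = [70.0 + i for i in range(60)]  # base + offsets 0..59
    state.count = 59
    expected = sum(state.window) / 60  # independent summation
    assert hr_window_mean(state, CFG) == pytest.approx(expected)
    assert expected == pytest.approx(70.0 + 29.5)


def test_hr_window_mean_requires_full_window():
    state = HRFilterState(relax_hr=70.0)
    with pytest.raises(FilterStateError):
        hr_window_mean(state, CFG)


def test_window_mean_resets_and_reseeds_slot_zero():
    state = HRFilterState(relax_hr=100.0)
    for _ in range(59):
        _, mean = hr_filter_step(state, 120.0, CFG)
    assert state.count == 0
    assert state.window[0] == pytest.approx(mean)


def test_window_overflow_without_reset_raises():
    state = HRFilterState(relax_hr=100.0)
    for _ in range(59):
        hr_threshold_step(state, 120.0, CFG)
    with pytest.raises(FilterStateError):
        hr_threshold_step(state, 120.0, CFG)


@given(st.lists(st.floats(min_value=30, max_value=250), min_size=59,
                max_size=59))
def test_window_mean_lies_within_slot_range(values):
    state = HRFilterState(relax_hr=80.0)
    for v in values[:-1]:
        _, mean = hr_filter_step(state, v, CFG)
        assert mean is None
    hr_threshold_step(state, values[-1], CFG)
    hr_error_step(state, state.window[state.count], CFG)
    snapshot = list(state.window)
    mean = hr_window_mean(state, CFG)
    assert min(snapshot) <= mean <= max(snapshot)


# --------------------------------------------------------------------------
# temperature conversion and compensation


@pytest.mark.parametrize(
    "t_skin, t_amb, alpha, expected",
    [
        (34.0, 28.0, BODY_PART_ALPHA["hand"], 38.599),
        (30.0, 30.0, 0.5, 30.0),
        (33.0, 33.0, BODY_PART_ALPHA["foot"], 33.0),
    ],
)
def test_skin_to_core(t_skin, t_amb, alpha, expected):
    assert skin_to_core(t_skin, t_amb, alpha) == pytest.approx(expected)


@pytest.mark.parametrize(
    "t_core, expected",
    [(33.0, 36.0), (37.0, 37.0), (45.0, 36.0), (31.0, 37.0), (40.0, 36.0),
     (20.0, 36.0), (35.0, 35.0)],
)
def test_temp_compensate_branches(t_core, expected):
    assert temp_compensate(t_core, CFG) == pytest.approx(expected)


@given(st.floats(min_value=-50, max_value=120, allow_nan=False))
def test_temp_compensate_maps_reals_into_body_band(t_core):
    out = temp_compensate(t_core, CFG)
    assert 35.0 <= out < 40.0


def test_temp_compensate_continuous_at_35():
    eps = 1e-9
    below = temp_compensate(35.0 - eps, CFG)
    above = temp_compensate(35.0 + eps, CFG)
    assert below == pytest.approx(35.0, abs=1e-6)
    assert above == pytest.approx(35.0, abs=1e-6)


@given(st.floats(min_value=31, max_value=35))
def test_temp_compensate_affine_with_slope_minus_half(t_core):
    # T + (35 - T) * 1.5 == 52.5 - 0.5 * T on the compensation band
    assert temp_compensate(t_core, CFG) == pytest.approx(52.5 - 0.5 * t_core)


# --------------------------------------------------------------------------
# temperature threshold / hold stage


def test_hold_rule_stores_compensated_then_repeats():
    state = TempFilterState()
    first = temp_threshold_step(state, 33.0, CFG)  # deviation 2 != 0
    assert first == pytest.approx(36.0)
    assert state.temp_diff == pytest.approx(2.0)
    second = temp_threshold_step(state, 33.0, CFG)  # deviation unchanged
    assert second == pytest.approx(first)


def test_temp_fallback_branch():
    state = TempFilterState()
    assert temp_threshold_step(state, 41.0, CFG) == pytest.approx(36.0)


def test_temp_identity_branch():
    state = TempFilterState()
    assert temp_threshold_step(state, 37.2, CFG) == pytest.approx(37.2)


def test_temp_window_mean_constant_and_symmetry():
    state = TempFilterState()
    state.window = [36.5] * 60
    state.count = 59
    assert temp_window_mean(state, CFG) == pytest.approx(36.5)
    state.window = [35.0] * 30 + [37.0] * 30
    state.count = 59
    assert temp_window_mean(state, CFG) == pytest.approx(36.0)


@given(st.lists(st.floats(min_value=35, max_value=39.9), min_size=60,
                max_size=60))
def test_temp_window_mean_matches_summation_oracle(values):
    state = TempFilterState()
    state.window = list(values)
    state.count = 59
    assert temp_window_mean(state, CFG) == pytest.approx(sum(values) / 60)


def test_temp_window_mean_requires_full_window():
    state = TempFilterState()
    with pytest.raises(FilterStateError):
        temp_window_mean(state, CFG)


# --------------------------------------------------------------------------
# full cascades


def test_hr_cascade_idempotent_on_clean_constant_stream():
    state = HRFilterState(relax_hr=120.0)
    for _ in range(200):
        out, mean = hr_filter_step(state, 120.0, CFG)
        assert out == 120.0
        if mean is not None:
            assert mean == pytest.approx(120.0)


def test_temp_cascade_idempotent_on_clean_constant_stream():
    # skin/ambient chosen so the core lands in the identity band
    alpha = CFG.alpha
    t_skin, t_amb = 34.5, 30.0
    core = skin_to_core(t_skin, t_amb, alpha)
    assert 35.0 < core < 40.0
    state = TempFilterState(seed_temp=core)
    for _ in range(200):
        out, mean = temp_filter_step(state, t_skin, t_amb, CFG)
        assert out == pytest.approx(core)
        if mean is not None:
            assert mean == pytest.approx(core)


def test_config_requires_band_continuity():
    with pytest.raises(ValueError):
        FilterConfig(comp_band=(28.0, 34.0))


def test_algorithm_band_variant_available():
    cfg = FilterConfig(comp_band=(28.0, 35.0))
    # 29 degC now falls in the compensation band instead of the fallback
    assert temp_compensate(29.0, cfg) == pytest.approx(29.0 + 6.0 * 1.5)


def test_config_yaml_round_trip(tmp_path):
    from whdd.io import read_filter_config, write_filter_config

    cfg = FilterConfig(hr_lower=45.0, hr_upper=185.0, alpha=0.5067)
    path = tmp_path / "filters.yaml"
    write_filter_config(cfg, path)
    assert read_filter_config(path) == cfg
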