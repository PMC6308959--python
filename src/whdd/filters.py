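"""Heart-rate and body-temperature filter cascades.

The wearable device preprocesses each raw sensor epoch in a fixed order:
threshold filtering, then error filtering, then a 60-slot moving average.

Heart rate
    A raw reading outside the plausible band (50 bpm to the age-predicted
    exercise maximum, 208 - 0.7 * age, rounded) is replaced by the
    previous slot.  The surviving value is then compared with the previous
    slot: a jump below -10 bpm or above +25 bpm is treated as a motion
    artifact and corrected proportionally (gains 1.05 and 0.6), with
    consecutive-artifact budgets (6 low, 2 high) after which the previous
    slot is repeated and the budget counter resets.

Body temperature
    The infrared sensor reads wrist-skin temperature; core temperature is
    estimated as T_skin + alpha * (T_skin - T_ambient) with a body-part
    coefficient alpha (hand: 0.7665).  Sweat depresses the skin reading,
    so estimated cores that fall into [31, 35] degC are compensated by
    T + (35 - T) * 1.5; cores in (35, 40) pass unchanged; anything else is
    replaced by the average human body temperature, 36.0 degC.

Both channels keep a 60-slot window whose slot 0 is seeded (resting heart
rate / 36.0 degC); a step advances the slot index first, so each internal
window absorbs 59 new epochs before its mean is emitted and re-seeds
slot 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "BODY_PART_ALPHA",
    "FilterConfig",
    "FilterStateError",
    "HRFilterState",
    "TempFilterState",
    "hr_max",
    "hr_max_threshold",
    "hr_threshold_step",
    "hr_error_step",
    "hr_filter_step",
    "hr_window_mean",
    "skin_to_core",
    "temp_compensate",
    "temp_threshold_step",
    "temp_filter_step",
    "temp_window_mean",
    "round_half_away",
]

#: Skin-to-core conversion coefficient by measurement site.
BODY_PART_ALPHA: dict[str, float] = {
    "rectal": 0.0699,
    "head": 0.3094,
    "torso": 0.5067,
    "hand": 0.7665,
    "foot": 2.1807,
}


class FilterStateError(RuntimeError):
    """A filter window was advanced past capacity or averaged early."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` is banker's rounding; bpm corrections use
    the everyday convention instead (0.5 -> 1, -0.5 -> -1).
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def hr_max(age: float) -> float:
    """Age-predicted maximum exercise heart rate, 208 - 0.7 * age (bpm).

    Raises ``ValueError`` for non-positive age.
    """
    if age <= 0:
        raise ValueError(f"age must be positive, got {age!r}")
    return 208.0 - 0.7 * age


def hr_max_threshold(age: float) -> int:
    """``hr_max`` rounded to an integer bpm for use as a filter bound."""
    return round_half_away(hr_max(age))


@dataclass(frozen=True)
class FilterConfig:
    """Tunable parameters of both filter cascades.

    Defaults are the device's published constants: heart-rate band
    [50, 190] bpm (190 = rounded maximum for a 26-year-old), error dead
    band [-10, +25] bpm with gains 1.05 / 0.6 and budgets 6 / 2, hand
    coefficient alpha = 0.7665, compensation band [31, 35] degC, identity
    band (35, 40) degC, and 36.0 degC fallback.
    """

    hr_lower: float = 50.0
    hr_upper: float = 190.0
    age: float | None = None  # when set, hr_upper := rounded 208 - 0.7*age
    err_low_threshold: float = -10.0
    err_high_threshold: float = 25.0
    err_low_gain: float = 1.05
    err_high_gain: float = 0.6
    low_budget: int = 6
    high_budget: int = 2
    window_len: int = 60
    reset_counters_on_normal: bool = False
    alpha: float = BODY_PART_ALPHA["hand"]
    comp_band: tuple[float, float] = (31.0, 35.0)
    identity_band: tuple[float, float] = (35.0, 40.0)
    fallback_temp: float = 36.0
    enable_hold_rule: bool = True

    def __post_init__(self) -> None:
        hr_upper = self.hr_upper
        if self.age is not None:
            hr_upper = float(hr_max_threshold(self.age))
            object.__setattr__(self, "hr_upper", hr_upper)
        if not self.hr_lower < hr_upper:
            raise ValueError("hr_lower must be below hr_upper")
        if self.err_low_threshold >= self.err_high_threshold:
            raise ValueError("error dead band is empty")
        if self.window_len < 2:
            raise ValueError("window_len must be at least 2")
        if self.comp_band[0] >= self.comp_band[1]:
            raise ValueError("comp_band must be a nonempty interval")
        if not math.isclose(self.comp_band[1], self.identity_band[0]):
            raise ValueError(
                "comp_band upper edge must meet identity_band lower edge "
                "(continuity of the compensation map)"
            )
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")

    @classmethod
    def from_mapping(cls, data: dict) -> "FilterConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown filter config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("comp_band", "identity_band"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "hr_lower": self.hr_lower,
            "hr_upper": self.hr_upper,
            "age": self.age,
            "err_low_threshold": self.err_low_threshold,
            "err_high_threshold": self.err_high_threshold,
            "err_low_gain": self.err_low_gain,
            "err_high_gain": self.err_high_gain,
            "low_budget": self.low_budget,
            "high_budget": self.high_budget,
            "window_len": self.window_len,
            "reset_counters_on_normal": self.reset_counters_on_normal,
            "alpha": self.alpha,
            "comp_band": list(self.comp_band),
            "identity_band": list(self.identity_band),
            "fallback_temp": self.fallback_temp,
            "enable_hold_rule": self.enable_hold_rule,
        }

    def with_body_part(self, part: str) -> "FilterConfig":
        """Return a copy using the alpha coefficient for ``part``."""
        return replace(self, alpha=BODY_PART_ALPHA[part])


@dataclass
class HRFilterState:
    """Mutable state of the heart-rate cascade.

    ``window[0]`` is seeded with the resting heart rate; ``count`` points
    at the most recently written slot.  ``mincount`` / ``maxcount`` track
    consecutive low / high artifact corrections.
    """

    relax_hr: float
    window_len: int = 60
    window: list[float] = field(init=False)
    count: int = field(init=False, default=0)
    mincount: int = field(init=False, default=0)
    maxcount: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self.window = [0.0] * self.window_len
        self.window[0] = float(self.relax_hr)

    @property
    def full(self) -> bool:
        return self.count == self.window_len - 1


@dataclass
class TempFilterState:
    """Mutable state of the body-temperature cascade.

    Slot 0 is seeded with the 36.0 degC fallback so the hold rule's
    previous-slot reference is defined from the first epoch.  ``temp_diff``
    is the last stored deviation (35 - T_core) from an in-band reading.
    """

    window_len: int = 60
    seed_temp: float = 36.0
    window: list[float] = field(init=False)
    count: int = field(init=False, default=0)
    temp_diff: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        self.window = [0.0] * self.window_len
        self.window[0] = float(self.seed_temp)

    @property
    def full(self) -> bool:
        return self.count == self.window_len - 1


# --------------------------------------------------------------------------
# heart-rate cascade


def hr_threshold_step(
    state: HRFilterState, value: float, config: FilterConfig
) -> float:
    """Threshold stage: advance the slot index and bounds-check ``value``.

    An in-band reading is stored as-is; anything else (including the 0
    that encodes a failed sensor read) repeats the previous slot.  Returns
    the stored value, which the error stage then takes as its input.
    """
    if state.count >= config.window_len - 1:
        raise FilterStateError(
            "window full: emit the window mean before the next step"
        )
    state.count += 1
    if config.hr_lower <= value <= config.hr_upper:
        stored = float(value)
    else:
        stored = state.window[state.count - 1]
    state.window[state.count] = stored
    return stored


def hr_error_step(
    state: HRFilterState, value: float, config: FilterConfig
) -> float:
    """Error stage: correct jumps relative to the previous slot.

    error = value - previous slot.  Below -10 bpm the correction
    value - round(error * 1.05) is applied while the consecutive-low
    budget (6) holds, else the previous slot is repeated and the budget
    resets; above +25 bpm the same with gain 0.6 and budget 2.  Inside
    the dead band the value passes unchanged.
    """
    error = value - state.window[state.count - 1]
    if error < config.err_low_threshold:
        state.mincount += 1
        if state.mincount <= config.low_budget:
            stored = value - round_half_away(error * config.err_low_gain)
        else:
            stored = state.window[state.count - 1]
            state.mincount = 0
    elif error > config.err_high_threshold:
        state.maxcount += 1
        if state.maxcount <= config.high_budget:
            stored = value - round_half_away(error * config.err_high_gain)
        else:
            stored = state.window[state.count - 1]
            state.maxcount = 0
    else:
        stored = float(value)
        if config.reset_counters_on_normal:
            state.mincount = 0
            state.maxcount = 0
    state.window[state.count] = stored
    return stored


def hr_window_mean(state: HRFilterState, config: FilterConfig) -> float:
    """Emit the mean of the 60 slots (the device's HRTrue) and reset.

    After the mean is emitted ``count`` returns to 0 and slot 0 is
    re-seeded with the mean, preserving error-stage continuity across
    windows.  Raises ``FilterStateError`` if the window is not full.
    """
    if state.count != config.window_len - 1:
        raise FilterStateError(
            f"window mean requested at slot {state.count}, "
            f"need {config.window_len - 1}"
        )
    mean = sum(state.window) / config.window_len
    state.count = 0
    state.window[0] = mean
    return mean


def hr_filter_step(
    state: HRFilterState, value: float, config: FilterConfig
) -> tuple[float, float | None]:
    """One full heart-rate epoch: threshold, then error, then (maybe) mean.

    Returns ``(filtered_value, window_mean)`` where ``window_mean`` is
    ``None`` except on the epoch that completes the internal window.
    """
    thresholded = hr_threshold_step(state, value, config)
    filtered = hr_error_step(state, thresholded, config)
    mean = None
    if state.count == config.window_len - 1:
        mean = hr_window_mean(state, config)
    return filtered, mean


# --------------------------------------------------------------------------
# body-temperature cascade


def skin_to_core(t_skin: float, t_ambient: float, alpha: float) -> float:
    """Estimate core temperature from skin and ambient temperature.

    T_core = T_skin + alpha * (T_skin - T_ambient); alpha depends on the
    measurement site (``BODY_PART_ALPHA``).
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    return t_skin + alpha * (t_skin - t_ambient)


def temp_compensate(t_core: float, config: FilterConfig | None = None) -> float:
    """Map an estimated core temperature into the plausible body band.

    In [31, 35] degC the sweat-depressed reading is raised by
    (35 - T) * 1.5; in (35, 40) it passes unchanged; every other input
    (sensor failure, out-of-band) becomes the 36.0 degC fallback.
    """
    cfg = config or _DEFAULT_CONFIG
    lo, hi = cfg.comp_band
    if lo <= t_core <= hi:
        return t_core + (hi - t_core) * 1.5
    ilo, ihi = cfg.identity_band
    if ilo < t_core < ihi:
        return float(t_core)
    return cfg.fallback_temp


def temp_threshold_step(
    state: TempFilterState, t_core: float, config: FilterConfig
) -> float:
    """Store one compensated epoch, applying the hold rule in-band.

    Within the compensation band the compensated value is stored only
    when the deviation 35 - T_core differs from the remembered
    ``temp_diff``; an unchanged deviation repeats the previous slot
    (the device treats a frozen reading as redundant).  Identity and
    fallback branches follow :func:`temp_compensate`.
    """
    if state.count >= config.window_len - 1:
        raise FilterStateError(
            "window full: emit the window mean before the next step"
        )
    state.count += 1
    lo, hi = config.comp_band
    ilo, ihi = config.identity_band
    if lo <= t_core <= hi:
        deviation = hi - t_core
        if not config.enable_hold_rule or deviation != state.temp_diff:
            state.temp_diff = deviation
            stored = t_core + deviation * 1.5
        else:
            stored = state.window[state.count - 1]
    elif ilo < t_core < ihi:
        stored = float(t_core)
    else:
        stored = config.fallback_temp
    state.window[state.count] = stored
    return stored


def temp_window_mean(state: TempFilterState, config: FilterConfig) -> float:
    """Emit the mean of the 60 temperature slots (TBody) and reset."""
    if state.count != config.window_len - 1:
        raise FilterStateError(
            f"window mean requested at slot {state.count}, "
            f"need {config.window_len - 1}"
        )
    mean = sum(state.window) / config.window_len
    state.count = 0
    state.window[0] = mean
    return mean


def temp_filter_step(
    state: TempFilterState,
    t_skin: float,
    t_ambient: float,
    config: FilterConfig,
) -> tuple[float, float | None]:
    """One full temperature epoch: conversion, compensation/hold, mean.

    Returns ``(filtered_value, window_mean)``; the mean is ``None``
    except on the epoch that completes the internal window.
    """
    t_core = skin_to_core(t_skin, t_ambient, config.alpha)
    stored = temp_threshold_step(state, t_core, config)
    mean = None
    if state.count == config.window_len - 1:
        mean = temp_window_mean(state, config)
    return stored, mean


_DEFAULT_CONFIG = FilterConfig()
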