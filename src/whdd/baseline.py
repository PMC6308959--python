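"""Pre-run baseline acquisition.

Before a session the device records one minute (120 samples at 2 Hz) of
heart rate and one minute of skin conductance while the user rests.  The
minute's average becomes the per-user reference (relax heart rate,
resting conductance) that the filter cascade and the fuzzy controller
are anchored to.  An average that is zero (sensor failure), undetectable,
or outside the adult resting range — 50-90 bpm for heart rate, 10-50 uS
for conductance — marks a non-resting minute and triggers a
re-measurement with the next 120 samples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Iterator

__all__ = [
    "BASELINE_SAMPLES",
    "RESTING_RANGES",
    "AcquisitionError",
    "ChannelBaseline",
    "BaselineProfile",
    "acquire_baseline",
    "acquire_profile",
]

#: Samples per acquisition attempt: 1 min at 2 Hz.
BASELINE_SAMPLES = 120

#: Adult resting ranges per channel (inclusive).
RESTING_RANGES: dict[str, tuple[float, float]] = {
    "heart_rate": (50.0, 90.0),
    "gsr": (10.0, 50.0),
}


class AcquisitionError(RuntimeError):
    """All acquisition attempts produced a non-resting average.

    Carries the last attempt's average in ``last_average`` (``nan`` when
    the stream ran out before an attempt completed).
    """

    def __init__(self, channel: str, attempts: int, last_average: float):
        self.channel = channel
        self.attempts = attempts
        self.last_average = last_average
        super().__init__(
            f"baseline acquisition failed for {channel!r} after "
            f"{attempts} attempt(s); last average {last_average:.3f}"
        )


@dataclass(frozen=True)
class ChannelBaseline:
    """A completed single-channel baseline."""

    channel: str
    value: float
    n_samples: int
    valid: bool
    attempts: int


@dataclass(frozen=True)
class BaselineProfile:
    """Per-user resting references for both baseline channels."""

    relax_hr: float
    relax_gsr: float
    n_samples: int
    hr_valid: bool
    gsr_valid: bool
    hr_attempts: int
    gsr_attempts: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BaselineProfile":
        return cls(**json.loads(text))


def _resting(channel: str, average: float) -> bool:
    lo, hi = RESTING_RANGES[channel]
    return math.isfinite(average) and average != 0.0 and lo <= average <= hi


def acquire_baseline(
    stream: Iterable[float], channel: str, max_attempts: int = 3
) -> ChannelBaseline:
    """Average consecutive 120-sample minutes until one looks resting.

    Each attempt consumes exactly 120 samples from ``stream`` and averages
    them; individual zero samples are kept (only the minute's average is
    range-checked).  Raises :class:`AcquisitionError` when every attempt
    is non-resting, and when the stream runs out mid-attempt.
    """
    if channel not in RESTING_RANGES:
        raise ValueError(f"unknown baseline channel {channel!r}")
    if max_attempts < 1:
        raise ValueError("max_attempts must be at least 1")
    it: Iterator[float] = iter(stream)
    average = math.nan
    for attempt in range(1, max_attempts + 1):
        chunk = [float(v) for _, v in zip(range(BASELINE_SAMPLES), it)]
        if len(chunk) < BASELINE_SAMPLES:
            raise AcquisitionError(channel, attempt, math.nan)
        average = sum(chunk) / BASELINE_SAMPLES
        if _resting(channel, average):
            return ChannelBaseline(
                channel=channel,
                value=average,
                n_samples=BASELINE_SAMPLES,
                valid=True,
                attempts=attempt,
            )
    raise AcquisitionError(channel, max_attempts, average)


def acquire_profile(
    hr_stream: Iterable[float],
    gsr_stream: Iterable[float],
    max_attempts: int = 3,
) -> BaselineProfile:
    """Run both channel acquisitions and assemble the user profile."""
    hr = acquire_baseline(hr_stream, "heart_rate", max_attempts)
    gsr = acquire_baseline(gsr_stream, "gsr", max_attempts)
    return BaselineProfile(
        relax_hr=hr.value,
        relax_gsr=gsr.value,
        n_samples=BASELINE_SAMPLES,
        hr_valid=hr.valid,
        gsr_valid=gsr.valid,
        hr_attempts=hr.attempts,
        gsr_attempts=gsr.attempts,
    )
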