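"""Packet assembly, evaluation statistics, and the end-to-end pipeline.

The device gathers filtered epochs and, every 60 samples, packages them
with their window means for transmission to the monitoring end, which
assesses the heat-stroke risk once per packet.  This module reproduces
that composition on a replayed sample stream: baseline -> per-epoch
filtering -> 60-epoch packets -> per-window fuzzy risk assessment, plus
the comparison statistics (signed / absolute error against a reference
instrument) and alert-timing analysis (system Dangerous onset vs first
user feedback) used to evaluate the device.

Windows are sample-indexed: a window is always 60 filtered epochs (30 s
at the nominal 2 Hz), regardless of wall-clock jitter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from whdd.baseline import BaselineProfile
from whdd.filters import (
    FilterConfig,
    HRFilterState,
    TempFilterState,
    hr_filter_step,
    temp_filter_step,
)
from whdd.risk import (
    AlertLevel,
    FuzzyConfig,
    RiskInputs,
    assess_risk,
    danger_coefficient,
    default_fuzzy_config,
)

__all__ = [
    "PACKET_EPOCHS",
    "SamplePacket",
    "ComparisonReport",
    "AlertTimingResult",
    "PipelineResult",
    "pack_window",
    "compare_readings",
    "alert_timing",
    "filter_stream",
    "assess_windows",
    "run_pipeline",
]

#: Filtered epochs per transmitted packet.
PACKET_EPOCHS = 60

_EPOCH_FIELDS = ("t_s", "hr", "body_temp", "gsr", "ambient", "humidity")


@dataclass(frozen=True)
class SamplePacket:
    """One transmission unit: 60 filtered epochs plus their window means."""

    seq: int
    samples: tuple[dict, ...]
    window_hr_mean: float
    window_temp_mean: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SamplePacket":
        data = json.loads(text)
        return cls(
            seq=data["seq"],
            samples=tuple(data["samples"]),
            window_hr_mean=data["window_hr_mean"],
            window_temp_mean=data["window_temp_mean"],
        )


def pack_window(epochs: pd.DataFrame | Sequence[dict], seq: int = 0
                ) -> SamplePacket:
    """Assemble exactly 60 filtered epochs into a packet.

    ``epochs`` rows need the fields t_s, hr, body_temp, gsr, ambient,
    humidity.  Raises ``ValueError`` on any other epoch count.
    """
    if isinstance(epochs, pd.DataFrame):
        rows = epochs.to_dict("records")
    else:
        rows = [dict(r) for r in epochs]
    if len(rows) != PACKET_EPOCHS:
        raise ValueError(
            f"a packet holds exactly {PACKET_EPOCHS} epochs, got {len(rows)}"
        )
    for row in rows:
        missing = set(_EPOCH_FIELDS) - set(row)
        if missing:
            raise ValueError(f"epoch missing fields {sorted(missing)}")
    hr_mean = sum(r["hr"] for r in rows) / PACKET_EPOCHS
    temp_mean = sum(r["body_temp"] for r in rows) / PACKET_EPOCHS
    return SamplePacket(
        seq=seq,
        samples=tuple({k: float(r[k]) for k in _EPOCH_FIELDS} for r in rows),
        window_hr_mean=hr_mean,
        window_temp_mean=temp_mean,
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Paired device-vs-reference readings and their error statistics."""

    device: tuple[float, ...]
    reference: tuple[float, ...]
    errors: tuple[float, ...]
    mean_signed_error: float
    mean_absolute_error: float

    def rounded(self, ndigits: int = 2) -> "ComparisonReport":
        """Copy with display rounding applied (tables print 2 decimals)."""
        return ComparisonReport(
            device=self.device,
            reference=self.reference,
            errors=tuple(round(e, ndigits) for e in self.errors),
            mean_signed_error=round(self.mean_signed_error, ndigits),
            mean_absolute_error=round(self.mean_absolute_error, ndigits),
        )


def compare_readings(device: Sequence[float], reference: Sequence[float]
                     ) -> ComparisonReport:
    """Per-pair signed errors (device - reference) and their means."""
    if len(device) != len(reference):
        raise ValueError(
            f"length mismatch: {len(device)} device vs "
            f"{len(reference)} reference readings"
        )
    if len(device) == 0:
        raise ValueError("need at least one reading pair")
    errors = tuple(float(d) - float(r) for d, r in zip(device, reference))
    return ComparisonReport(
        device=tuple(float(d) for d in device),
        reference=tuple(float(r) for r in reference),
        errors=errors,
        mean_signed_error=sum(errors) / len(errors),
        mean_absolute_error=sum(abs(e) for e in errors) / len(errors),
    )


@dataclass(frozen=True)
class AlertTimingResult:
    """First Dangerous assessment vs first user feedback.

    ``lead_s = feedback_t - onset_t``: positive means the system raised
    the alarm before the user felt discomfort.  Missing occurrences are
    reported as ``None``, never raised.
    """

    onset_t: float | None
    feedback_t: float | None
    lead_s: float | None


def alert_timing(assessments: pd.DataFrame, events: pd.DataFrame
                 ) -> AlertTimingResult:
    """Locate the Dangerous onset and the first feedback event.

    ``assessments`` needs columns t_s and level (time-ordered);
    ``events`` needs t_s and event.
    """
    levels = assessments["level"].astype(str)
    dangerous = assessments.loc[levels == AlertLevel.DANGEROUS.value, "t_s"]
    onset = float(dangerous.iloc[0]) if len(dangerous) else None
    feedback = events.loc[events["event"] == "feedback", "t_s"]
    first_fb = float(feedback.iloc[0]) if len(feedback) else None
    lead = (first_fb - onset) if onset is not None and first_fb is not None \
        else None
    return AlertTimingResult(onset_t=onset, feedback_t=first_fb, lead_s=lead)


@dataclass(frozen=True)
class PipelineResult:
    """Everything the end-to-end run produces."""

    filtered: pd.DataFrame      # per-epoch filtered stream
    packets: tuple[SamplePacket, ...]
    assessments: pd.DataFrame   # one row per packet
    dropped_epochs: int = 0     # final partial window, logged not silently lost


def filter_stream(
    stream: pd.DataFrame,
    baseline: BaselineProfile,
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Run both filter cascades over a replayed sample stream.

    ``stream`` follows the sample CSV schema (t_s, hr_bpm, skin_temp_c,
    gsr_us, amb_temp_c, rh_pct; zeros encode failed readings).  The
    heart-rate cascade is seeded with the baseline's resting heart rate.
    Conductance has no cascade of its own and passes through.
    """
    fcfg = config or FilterConfig()
    hr_state = HRFilterState(relax_hr=baseline.relax_hr,
                             window_len=fcfg.window_len)
    temp_state = TempFilterState(window_len=fcfg.window_len,
                                 seed_temp=fcfg.fallback_temp)
    n = len(stream)
    hr_f = np.empty(n)
    temp_f = np.empty(n)
    hr_raw = stream["hr_bpm"].to_numpy(dtype=float)
    skin = stream["skin_temp_c"].to_numpy(dtype=float)
    amb = stream["amb_temp_c"].to_numpy(dtype=float)
    for i in range(n):
        hr_f[i], _ = hr_filter_step(hr_state, hr_raw[i], fcfg)
        temp_f[i], _ = temp_filter_step(temp_state, skin[i], amb[i], fcfg)
    return pd.DataFrame({
        "t_s": stream["t_s"].to_numpy(dtype=float),
        "hr": hr_f,
        "body_temp": temp_f,
        "gsr": stream["gsr_us"].to_numpy(dtype=float),
        "ambient": amb,
        "humidity": stream["rh_pct"].to_numpy(dtype=float),
    })


def assess_windows(
    filtered: pd.DataFrame,
    baseline: BaselineProfile,
    fuzzy_config: FuzzyConfig | None = None,
) -> tuple[tuple[SamplePacket, ...], pd.DataFrame]:
    """Chunk filtered epochs into packets and assess risk per window.

    Returns the packets and the assessment log (one row per packet,
    stamped with the window's last epoch time).  The trailing partial
    window, if any, is simply not packaged.
    """
    zcfg = fuzzy_config or default_fuzzy_config(relax_hr=baseline.relax_hr)
    n = len(filtered)
    n_packets = n // PACKET_EPOCHS
    packets = []
    records = []
    for seq in range(n_packets):
        chunk = filtered.iloc[seq * PACKET_EPOCHS:(seq + 1) * PACKET_EPOCHS]
        packet = pack_window(chunk, seq=seq)
        packets.append(packet)
        t_s = float(chunk["t_s"].iloc[-1])
        coeff = danger_coefficient(float(chunk["ambient"].mean()),
                                   float(chunk["humidity"].mean()))
        inputs = RiskInputs(
            heart_rate=packet.window_hr_mean,
            body_temp=packet.window_temp_mean,
            gsr_delta=float(chunk["gsr"].mean()) - baseline.relax_gsr,
            danger_coeff=coeff,
        )
        assessment = assess_risk(inputs, zcfg, t_s=t_s)
        records.append({
            "t_s": t_s,
            "hr": inputs.heart_rate,
            "body_temp": inputs.body_temp,
            "gsr_delta": inputs.gsr_delta,
            "danger_coeff": inputs.danger_coeff,
            "risk": assessment.risk,
            "level": assessment.level.value,
        })
    assessments = pd.DataFrame(
        records,
        columns=["t_s", "hr", "body_temp", "gsr_delta", "danger_coeff",
                 "risk", "level"],
    )
    return tuple(packets), assessments


def run_pipeline(
    stream: pd.DataFrame,
    baseline: BaselineProfile,
    filter_config: FilterConfig | None = None,
    fuzzy_config: FuzzyConfig | None = None,
) -> PipelineResult:
    """The end-to-end composition: filter, packetize, assess.

    Deterministic given its inputs; errors from any stage propagate with
    their stage's own exception types.
    """
    filtered = filter_stream(stream, baseline, filter_config)
    packets, assessments = assess_windows(filtered, baseline, fuzzy_config)
    return PipelineResult(
        filtered=filtered,
        packets=packets,
        assessments=assessments,
        dropped_epochs=len(filtered) - len(packets) * PACKET_EPOCHS,
    )
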