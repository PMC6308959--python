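"""Synthetic running sessions: latent physiology plus corrupted sensors.

The treadmill protocol mirrors the device's indoor evaluation: warm-up at
8 km/h for 10 min, acceleration at 10 km/h for 2 min, intense exercise at
12 km/h for 3 min, sampled at 2 Hz in a 28.9 degC / 68.2 % RH room; the
outdoor preset uses the evening-track conditions 23.5 degC / 80 % RH.

Latent dynamics are deliberately simple, encoding only the reaction
ordering observed during exercise (heart rate responds first, body
temperature later, skin conductance last):

* heart rate relaxes first-order (tau ~ 35 s) toward a per-stage target
  between the resting rate and ``fitness`` x the age-predicted maximum;
* core temperature rises monotonically with accumulated workload
  (speed-seconds) toward an asymptote below 40 degC (tau_w ~ 4000);
* conductance declines with cumulative sweat toward a floor
  (tau_w ~ 5000, the slowest channel).

The observation model reproduces the failure modes of a loosening
wrist-worn device: zero dropouts, out-of-band heart-rate spikes, additive
Gaussian noise, and a sweat-induced depression of the measured skin
temperature that grows with cumulative workload.  Skin temperature is
what the infrared sensor would read: the latent core is mapped back
through the inverse of the skin-to-core conversion before corruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from whdd.filters import BODY_PART_ALPHA, hr_max

__all__ = [
    "SessionProtocol",
    "RunnerProfile",
    "ArtifactModel",
    "SessionResult",
    "simulate_session",
    "make_cohort",
    "INDOOR_PROTOCOL",
    "OUTDOOR_PROTOCOL",
    "indoor_preset",
    "outdoor_preset",
]

#: Per-stage reference speed at which a runner hits their full heart-rate
#: response (the protocol's top speed).
_FULL_EFFORT_SPEED = 12.0

_TAU_HR_S = 35.0          # heart-rate relaxation time constant
_TEMP_TAU_W = 4000.0      # workload constant of the temperature rise
_GSR_TAU_W = 5000.0       # workload constant of the conductance decline
_BASE_CORE_C = 36.8       # pre-exercise core temperature
_GSR_DROP_MAX_US = 18.0   # conductance collapse at full sweat rate
_GSR_FLOOR_US = 1.0


@dataclass(frozen=True)
class SessionProtocol:
    """An exercise protocol: staged speeds plus ambient conditions."""

    stages: tuple[tuple[float, float], ...]  # (speed km/h, duration s)
    ambient_temp: float
    humidity: float
    sample_rate: float = 2.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("protocol needs at least one stage")
        if any(d <= 0 for _, d in self.stages):
            raise ValueError("stage durations must be positive")

    @property
    def duration_s(self) -> float:
        return sum(d for _, d in self.stages)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate))

    def speed_at(self, t: np.ndarray) -> np.ndarray:
        """Stage speed as a function of session time (s)."""
        edges = np.cumsum([d for _, d in self.stages])
        speeds = np.asarray([s for s, _ in self.stages])
        idx = np.minimum(np.searchsorted(edges, t, side="left"),
                         len(speeds) - 1)
        return speeds[idx]


INDOOR_PROTOCOL = SessionProtocol(
    stages=((8.0, 600.0), (10.0, 120.0), (12.0, 180.0)),
    ambient_temp=28.9,
    humidity=68.2,
    name="indoor",
)

# A representative evening 2-km track run (the real subjects ran at their
# individual limits; 10 km/h for 12 min covers the distance).
OUTDOOR_PROTOCOL = SessionProtocol(
    stages=((10.0, 720.0),),
    ambient_temp=23.5,
    humidity=80.0,
    name="outdoor",
)


@dataclass(frozen=True)
class RunnerProfile:
    """Per-runner physiology knobs.

    ``fitness`` scales the heart-rate response ceiling (latent heart rate
    never exceeds fitness x HRMax); ``sweat_rate`` scales both the
    conductance decline and the sweat depression of the measured skin
    temperature; ``discomfort_hr_frac`` is the fraction of HRMax at which
    the runner presses the feedback button.
    """

    name: str
    age: float
    relax_hr: float = 70.0
    relax_gsr: float = 25.0
    fitness: float = 0.85
    sweat_rate: float = 0.7
    discomfort_hr_frac: float = 0.95

    def __post_init__(self) -> None:
        if not 50.0 <= self.relax_hr <= 90.0:
            raise ValueError("relax_hr must lie in the resting band [50, 90]")
        if not 10.0 <= self.relax_gsr <= 50.0:
            raise ValueError("relax_gsr must lie in the resting band [10, 50]")
        if not 0.0 < self.fitness <= 1.0:
            raise ValueError("fitness must lie in (0, 1]")
        if self.sweat_rate < 0:
            raise ValueError("sweat_rate must be nonnegative")

    @property
    def hr_ceiling(self) -> float:
        return self.fitness * hr_max(self.age)

    @property
    def discomfort_hr(self) -> float:
        return self.discomfort_hr_frac * hr_max(self.age)


@dataclass(frozen=True)
class ArtifactModel:
    """Sensor corruption parameters.

    Spike ranges straddle the filter's [50, 190] bpm band so the
    threshold stage is actually exercised; ``temp_sweat_bias`` is the
    maximum skin-temperature depression (degC) at full sweat rate.
    """

    dropout_prob: float = 0.01
    spike_prob: float = 0.02
    spike_low: tuple[float, float] = (0.0, 49.0)
    spike_high: tuple[float, float] = (191.0, 220.0)
    temp_sweat_bias: float = 0.8
    noise_sd: dict = field(default_factory=lambda: {
        "hr": 2.0, "skin_temp": 0.15, "gsr": 0.5,
    })
    seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.dropout_prob, self.spike_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("artifact probabilities must lie in [0, 1]")

    @classmethod
    def disabled(cls, seed: int | None = None) -> "ArtifactModel":
        """Observed channels equal the latent truth exactly."""
        return cls(dropout_prob=0.0, spike_prob=0.0, temp_sweat_bias=0.0,
                   noise_sd={"hr": 0.0, "skin_temp": 0.0, "gsr": 0.0},
                   seed=seed)


@dataclass(frozen=True)
class SessionResult:
    """Paired latent/observed streams plus the feedback-event log."""

    runner: RunnerProfile
    protocol: SessionProtocol
    latent: pd.DataFrame    # t_s, hr, core_temp, skin_temp, gsr
    observed: pd.DataFrame  # t_s, hr_bpm, skin_temp_c, gsr_us, amb_temp_c, rh_pct
    events: pd.DataFrame    # t_s, event


def _latent_dynamics(
    protocol: SessionProtocol, runner: RunnerProfile
) -> pd.DataFrame:
    dt = 1.0 / protocol.sample_rate
    n = protocol.n_samples
    t = (np.arange(n) + 1) * dt
    speed = protocol.speed_at(t)
    workload = np.cumsum(speed * dt)

    intensity = np.clip(speed / _FULL_EFFORT_SPEED, 0.0, 1.0)
    target = runner.relax_hr + intensity * (runner.hr_ceiling
                                            - runner.relax_hr)
    hr = np.empty(n)
    level = runner.relax_hr
    gain = 1.0 - np.exp(-dt / _TAU_HR_S)
    for i in range(n):
        level += (target[i] - level) * gain
        hr[i] = level

    temp_amp = 2.8 * runner.fitness  # asymptote stays below 40 degC
    core = _BASE_CORE_C + temp_amp * (1.0 - np.exp(-workload / _TEMP_TAU_W))

    drop = _GSR_DROP_MAX_US * runner.sweat_rate
    gsr = np.maximum(
        runner.relax_gsr - drop * (1.0 - np.exp(-workload / _GSR_TAU_W)),
        _GSR_FLOOR_US,
    )

    alpha = BODY_PART_ALPHA["hand"]
    skin = (core + alpha * protocol.ambient_temp) / (1.0 + alpha)
    return pd.DataFrame({
        "t_s": t, "hr": hr, "core_temp": core, "skin_temp": skin,
        "gsr": gsr, "workload": workload,
    })


def simulate_session(
    protocol: SessionProtocol,
    runner: RunnerProfile,
    artifacts: ArtifactModel,
    seed: int | np.random.SeedSequence | None = None,
) -> SessionResult:
    """Generate one session: latent truth, observed samples, event log.

    ``seed`` overrides ``artifacts.seed``; the seed fans out into
    independent per-channel generators so a channel can be regenerated
    without disturbing the others.  Output length is
    ``sample_rate x total duration`` samples.
    """
    entropy = seed if seed is not None else artifacts.seed
    if isinstance(entropy, np.random.SeedSequence):
        ss = entropy
    else:
        ss = np.random.SeedSequence(entropy)
    rng_hr, rng_temp, rng_gsr = (np.random.default_rng(s)
                                 for s in ss.spawn(3))

    latent = _latent_dynamics(protocol, runner)
    n = len(latent)

    # heart rate: noise, then spikes, then dropouts
    hr_obs = latent["hr"].to_numpy() + rng_hr.normal(
        0.0, artifacts.noise_sd.get("hr", 0.0), n)
    spikes = rng_hr.random(n) < artifacts.spike_prob
    pick_high = rng_hr.random(n) < 0.5
    spike_vals = np.where(
        pick_high,
        rng_hr.uniform(*artifacts.spike_high, n),
        rng_hr.uniform(*artifacts.spike_low, n),
    )
    hr_obs = np.where(spikes, spike_vals, hr_obs)
    hr_obs = np.where(rng_hr.random(n) < artifacts.dropout_prob, 0.0, hr_obs)

    # skin temperature: sweat depression grows with cumulative workload
    saturation = 1.0 - np.exp(-latent["workload"].to_numpy() / _TEMP_TAU_W)
    bias = artifacts.temp_sweat_bias * runner.sweat_rate * saturation
    skin_obs = (latent["skin_temp"].to_numpy() - bias
                + rng_temp.normal(0.0, artifacts.noise_sd.get("skin_temp",
                                                              0.0), n))
    skin_obs = np.where(rng_temp.random(n) < artifacts.dropout_prob,
                        0.0, skin_obs)

    gsr_obs = np.maximum(
        latent["gsr"].to_numpy()
        + rng_gsr.normal(0.0, artifacts.noise_sd.get("gsr", 0.0), n),
        0.0,
    )
    gsr_obs = np.where(rng_gsr.random(n) < artifacts.dropout_prob,
                       0.0, gsr_obs)

    observed = pd.DataFrame({
        "t_s": latent["t_s"],
        "hr_bpm": hr_obs,
        "skin_temp_c": skin_obs,
        "gsr_us": gsr_obs,
        "amb_temp_c": np.full(n, protocol.ambient_temp),
        "rh_pct": np.full(n, protocol.humidity),
    })

    crossed = latent["hr"].to_numpy() >= runner.discomfort_hr
    if crossed.any():
        t_event = float(latent["t_s"].to_numpy()[np.argmax(crossed)])
        events = pd.DataFrame({"t_s": [t_event], "event": ["feedback"]})
    else:
        events = pd.DataFrame({"t_s": pd.Series(dtype=float),
                               "event": pd.Series(dtype=str)})

    return SessionResult(
        runner=runner,
        protocol=protocol,
        latent=latent.drop(columns="workload"),
        observed=observed,
        events=events,
    )


def make_cohort(
    profiles: list[RunnerProfile],
    protocol: SessionProtocol,
    artifacts: ArtifactModel,
    seed: int = 0,
) -> list[SessionResult]:
    """One session per profile, with per-runner seeds derived from ``seed``."""
    if not profiles:
        raise ValueError("profile list is empty")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate profile names in cohort")
    children = np.random.SeedSequence(seed).spawn(len(profiles))
    return [
        simulate_session(protocol, profile,
                         replace(artifacts, seed=None), seed=child)
        for profile, child in zip(profiles, children)
    ]


def indoor_preset() -> list[RunnerProfile]:
    """The four indoor treadmill runners (ages 25, 37, 23, 23).

    Users 1-2 (regular exercisers) are the comfortable profiles — their
    heart-rate response stays well below maximum and they never press the
    feedback button.  Users 3-4 (irregular exercisers) are the strained
    profiles that reported discomfort late in the run.
    """
    return [
        RunnerProfile("user1", age=25, relax_hr=65, relax_gsr=28,
                      fitness=0.75, sweat_rate=0.5, discomfort_hr_frac=1.0),
        RunnerProfile("user2", age=37, relax_hr=62, relax_gsr=24,
                      fitness=0.75, sweat_rate=0.55, discomfort_hr_frac=1.0),
        RunnerProfile("user3", age=23, relax_hr=72, relax_gsr=30,
                      fitness=0.95, sweat_rate=1.0, discomfort_hr_frac=0.88),
        RunnerProfile("user4", age=23, relax_hr=74, relax_gsr=26,
                      fitness=0.93, sweat_rate=0.95, discomfort_hr_frac=0.90),
    ]


def outdoor_preset() -> list[RunnerProfile]:
    """The five outdoor track runners (ages 37, 36, 24, 24, 24)."""
    return [
        RunnerProfile("user1", age=37, relax_hr=60, relax_gsr=26,
                      fitness=0.80, sweat_rate=0.5, discomfort_hr_frac=1.0),
        RunnerProfile("user2", age=36, relax_hr=64, relax_gsr=24,
                      fitness=0.78, sweat_rate=0.5, discomfort_hr_frac=1.0),
        RunnerProfile("user3", age=24, relax_hr=70, relax_gsr=30,
                      fitness=0.85, sweat_rate=0.7, discomfort_hr_frac=0.95),
        RunnerProfile("user4", age=24, relax_hr=72, relax_gsr=28,
                      fitness=0.90, sweat_rate=0.9, discomfort_hr_frac=0.92),
        RunnerProfile("user5", age=24, relax_hr=75, relax_gsr=32,
                      fitness=0.92, sweat_rate=0.9, discomfort_hr_frac=0.90),
    ]
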