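"""Environmental danger coefficient and fuzzy heat-stroke risk inference.

The monitoring end combines four crisp inputs — filtered heart rate,
filtered body temperature, the drop of skin conductance below its resting
baseline, and an environmental danger coefficient — in a Mamdani fuzzy
controller whose defuzzified output is a heat-stroke risk indicator on
[0, 40].  The indicator is partitioned into four alert zones driving the
device's alert modes:

    Safe       [0, 10]    no alert
    Attention  (10, 20]   LED on
    Warning    (20, 30]   LED blinks, slow beep
    Dangerous  (30, 40]   LED blinks, rapid beep

The danger coefficient is a heat-index style scalar, ambient temperature
plus one tenth of relative humidity (23.5 degC at 80 % RH -> 31.5).

The shipped default controller uses three piecewise-linear terms per
input forming a partition of unity, a monotone rule table generated from
a weighted severity score (heart rate weighted above body temperature,
which is weighted above conductance and environment — heart rate reacts
first during exercise, temperature later, sweating last), output terms
centred in the four zones, and centroid defuzzification.  Rule firing
defaults to the product t-norm with activation-scaled additive
aggregation (the product-sum-gravity Mamdani variant), which yields a
smooth risk surface that is monotone in every input for a monotone rule
table; classic min/max composition is available via config.  The whole
controller is data, serialisable to YAML/JSON and replaceable per user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AlertLevel",
    "RiskInputs",
    "RiskAssessment",
    "FuzzyConfig",
    "ConfigurationError",
    "danger_coefficient",
    "level_from_risk",
    "assess_risk",
    "sensitivity_surface",
    "default_fuzzy_config",
    "RISK_UNIVERSE",
]

#: The risk indicator scale.
RISK_UNIVERSE: tuple[float, float] = (0.0, 40.0)

#: Zone upper edges, in level order (Safe closes at 10, ... Dangerous at 40).
_ZONE_EDGES = (10.0, 20.0, 30.0, 40.0)


class AlertLevel(str, Enum):
    SAFE = "Safe"
    ATTENTION = "Attention"
    WARNING = "Warning"
    DANGEROUS = "Dangerous"


class ConfigurationError(ValueError):
    """The fuzzy controller configuration is unusable."""


def danger_coefficient(amb_temp: float, rh: float) -> float:
    """Environmental heat-risk index: ambient temp (degC) + RH (%) / 10.

    Raises ``ValueError`` when relative humidity is outside [0, 100].
    """
    if not 0.0 <= rh <= 100.0:
        raise ValueError(f"relative humidity must be in [0, 100], got {rh!r}")
    return amb_temp + rh / 10.0


def level_from_risk(risk: float) -> AlertLevel:
    """Map a crisp risk value to its alert zone.

    Safe [0, 10], Attention (10, 20], Warning (20, 30], Dangerous
    (30, 40].  Out-of-range risk raises ``ValueError``.
    """
    lo, hi = RISK_UNIVERSE
    if not lo <= risk <= hi:
        raise ValueError(f"risk must be in [{lo}, {hi}], got {risk!r}")
    for edge, level in zip(_ZONE_EDGES, AlertLevel):
        if risk <= edge:
            return level
    return AlertLevel.DANGEROUS  # risk == 40 handled above; unreachable


@dataclass(frozen=True)
class RiskInputs:
    """Crisp controller inputs at one epoch.

    ``gsr_delta`` is current conductance minus the resting baseline, in
    uS; strongly negative means sweating has collapsed.  ``danger_coeff``
    is :func:`danger_coefficient` of the ambient conditions.
    """

    heart_rate: float
    body_temp: float
    gsr_delta: float
    danger_coeff: float

    def __post_init__(self) -> None:
        values = (self.heart_rate, self.body_temp, self.gsr_delta,
                  self.danger_coeff)
        if not all(math.isfinite(v) for v in values):
            raise ValueError("risk inputs must be finite")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if not 35.0 <= self.body_temp < 40.0:
            raise ValueError(
                f"body_temp must lie in [35, 40) degC, got {self.body_temp!r}"
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "heart_rate": self.heart_rate,
            "body_temp": self.body_temp,
            "gsr_delta": self.gsr_delta,
            "danger_coeff": self.danger_coeff,
        }


@dataclass(frozen=True)
class RiskAssessment:
    """Controller output at one epoch."""

    risk: float
    level: AlertLevel
    inputs: RiskInputs
    t_s: float | None = None


def _membership(points: Sequence[Sequence[float]], x: float | np.ndarray):
    """Evaluate a piecewise-linear term; saturates beyond its breakpoints."""
    xs = np.asarray([p[0] for p in points], dtype=float)
    mus = np.asarray([p[1] for p in points], dtype=float)
    return np.interp(x, xs, mus, left=mus[0], right=mus[-1])


@dataclass(frozen=True)
class FuzzyConfig:
    """A complete, data-only Mamdani controller description.

    ``inputs`` maps input name -> {"universe": [lo, hi], "terms":
    {term: [[x, mu], ...]}} with terms listed from benign to severe;
    ``output`` has the same shape over the risk universe; ``rules`` is a
    list of {"if": {input: term, ...}, "then": output_term}.
    """

    inputs: Mapping[str, dict]
    output: dict
    rules: tuple[dict, ...]
    defuzz: str = "centroid"
    tnorm: str = "product"
    aggregation: str = "sum"
    grid_points: int = 801

    def __post_init__(self) -> None:
        if not self.rules:
            raise ConfigurationError("rule table is empty")
        if self.defuzz != "centroid":
            raise ConfigurationError(
                f"unsupported defuzzification {self.defuzz!r}"
            )
        if self.tnorm not in ("product", "min"):
            raise ConfigurationError(f"unsupported t-norm {self.tnorm!r}")
        if self.aggregation not in ("sum", "max"):
            raise ConfigurationError(
                f"unsupported aggregation {self.aggregation!r}"
            )
        lo, hi = self.output["universe"]
        if (lo, hi) != RISK_UNIVERSE:
            raise ConfigurationError(
                f"output universe must be {list(RISK_UNIVERSE)}"
            )
        for name, var in self.inputs.items():
            for term, points in var["terms"].items():
                xs = [p[0] for p in points]
                if xs != sorted(xs):
                    raise ConfigurationError(
                        f"breakpoints of {name}.{term} are not sorted"
                    )
                if any(not 0.0 <= p[1] <= 1.0 for p in points):
                    raise ConfigurationError(
                        f"membership of {name}.{term} leaves [0, 1]"
                    )
        out_terms = set(self.output["terms"])
        for rule in self.rules:
            if rule["then"] not in out_terms:
                raise ConfigurationError(
                    f"rule consequent {rule['then']!r} is not an output term"
                )
            for name, term in rule["if"].items():
                if name not in self.inputs:
                    raise ConfigurationError(f"unknown rule input {name!r}")
                if term not in self.inputs[name]["terms"]:
                    raise ConfigurationError(
                        f"unknown term {term!r} for input {name!r}"
                    )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "inputs": {
                name: {
                    "universe": list(var["universe"]),
                    "terms": {t: [list(p) for p in pts]
                              for t, pts in var["terms"].items()},
                }
                for name, var in self.inputs.items()
            },
            "output": {
                "universe": list(self.output["universe"]),
                "terms": {t: [list(p) for p in pts]
                          for t, pts in self.output["terms"].items()},
            },
            "rules": [dict(r) for r in self.rules],
            "defuzz": self.defuzz,
            "tnorm": self.tnorm,
            "aggregation": self.aggregation,
            "grid_points": self.grid_points,
        }

    @classmethod
    def from_mapping(cls, data: Mapping) -> "FuzzyConfig":
        return cls(
            inputs=data["inputs"],
            output=data["output"],
            rules=tuple(data["rules"]),
            defuzz=data.get("defuzz", "centroid"),
            tnorm=data.get("tnorm", "product"),
            aggregation=data.get("aggregation", "sum"),
            grid_points=int(data.get("grid_points", 801)),
        )

    # -- inference ---------------------------------------------------------
    def fuzzify(self, name: str, x: float) -> dict[str, float]:
        """Membership degree of ``x`` in every term of input ``name``."""
        var = self.inputs[name]
        lo, hi = var["universe"]
        xc = min(max(float(x), lo), hi)
        return {t: float(_membership(pts, xc))
                for t, pts in var["terms"].items()}

    def infer(self, crisp: Mapping[str, float]) -> float:
        """Mamdani inference with centroid defuzzification.

        With the default product t-norm and additive aggregation each
        rule contributes its consequent scaled by its activation; with
        ``tnorm="min"`` / ``aggregation="max"`` this is the classic
        clipped min-max composition.  The centroid normalises out the
        aggregate's total mass, so additive stacking needs no cap.
        """
        degrees = {name: self.fuzzify(name, crisp[name])
                   for name in self.inputs}
        lo, hi = self.output["universe"]
        grid = np.linspace(lo, hi, self.grid_points)
        term_mu = {t: _membership(pts, grid)
                   for t, pts in self.output["terms"].items()}
        aggregate = np.zeros_like(grid)
        for rule in self.rules:
            antecedents = [degrees[name][term]
                           for name, term in rule["if"].items()]
            if self.tnorm == "product":
                activation = float(np.prod(antecedents))
            else:
                activation = min(antecedents)
            if activation <= 0.0:
                continue
            if self.aggregation == "sum":
                aggregate += activation * term_mu[rule["then"]]
            else:
                clipped = np.minimum(activation, term_mu[rule["then"]])
                np.maximum(aggregate, clipped, out=aggregate)
        total = float(np.trapezoid(aggregate, grid))
        if total == 0.0:
            return 0.0
        return float(np.trapezoid(aggregate * grid, grid) / total)


def assess_risk(
    inputs: RiskInputs, config: FuzzyConfig, t_s: float | None = None
) -> RiskAssessment:
    """Fuzzify, fire the rule table, defuzzify, and map to an alert zone."""
    risk = config.infer(inputs.as_dict())
    risk = min(max(risk, RISK_UNIVERSE[0]), RISK_UNIVERSE[1])
    return RiskAssessment(
        risk=risk, level=level_from_risk(risk), inputs=inputs, t_s=t_s
    )


def sensitivity_surface(
    config: FuzzyConfig,
    hr_grid: Sequence[float],
    temp_grid: Sequence[float],
    fixed: RiskInputs,
) -> np.ndarray:
    """Crisp risk over a heart-rate x body-temperature grid.

    The conductance and environment inputs are held at ``fixed``'s
    values.  Returns an array of shape (len(hr_grid), len(temp_grid)).
    """
    surface = np.empty((len(hr_grid), len(temp_grid)))
    for i, hr in enumerate(hr_grid):
        for j, temp in enumerate(temp_grid):
            crisp = {
                "heart_rate": float(hr),
                "body_temp": float(temp),
                "gsr_delta": fixed.gsr_delta,
                "danger_coeff": fixed.danger_coeff,
            }
            surface[i, j] = config.infer(crisp)
    return surface


# --------------------------------------------------------------------------
# default controller


def _partition3(k0: float, k1: float, k2: float, names: Sequence[str]):
    """Three saturating terms over knots k0 < k1 < k2, summing to 1.

    names[0] is full below k0 and vanishes at k1; names[1] is the
    triangle (k0, k1, k2); names[2] rises from k1 and is full above k2.
    """
    return {
        names[0]: [[k0, 1.0], [k1, 0.0]],
        names[1]: [[k0, 0.0], [k1, 1.0], [k2, 0.0]],
        names[2]: [[k1, 0.0], [k2, 1.0]],
    }


#: Severity weights of the default rule generator: the reaction ordering
#: during exercise is heart rate first, body temperature second, sweating
#: (conductance) last; environment modulates but does not dominate.
_SEVERITY_WEIGHTS = {
    "heart_rate": 4,
    "body_temp": 2,
    "gsr_delta": 1,
    "danger_coeff": 1,
}

#: Severity-score upper edges for Safe / Attention / Warning; above the
#: last edge a rule concludes Dangerous.  Max score = 2 * sum(weights) = 16.
_SEVERITY_EDGES = (2, 6, 10)


def default_fuzzy_config(
    relax_hr: float = 70.0,
    age: float = 26.0,
    grid_points: int = 801,
) -> FuzzyConfig:
    """Build the shipped controller, anchored to a user's resting profile.

    Heart-rate terms span resting (relax_hr) to the age-predicted maximum
    208 - 0.7 * age; temperature terms cover the plausible body band
    [35, 40) degC; conductance-drop terms cover a 30 uS collapse; the
    environment terms span comfortable (<25) to oppressive (>38)
    conditions.
    """
    hr_top = 208.0 - 0.7 * age
    hr_mid = relax_hr + 0.5 * (hr_top - relax_hr)
    inputs = {
        "heart_rate": {
            "universe": [50.0, 200.0],
            "terms": _partition3(relax_hr, hr_mid, hr_top,
                                 ["low", "normal", "high"]),
        },
        "body_temp": {
            "universe": [35.0, 40.0],
            "terms": _partition3(36.2, 37.8, 39.4,
                                 ["low", "normal", "high"]),
        },
        # listed benign -> severe: a *drop* in conductance is the danger
        "gsr_delta": {
            "universe": [-30.0, 10.0],
            "terms": {
                "stable": [[-10.0, 0.0], [0.0, 1.0]],
                "mild_drop": [[-20.0, 0.0], [-10.0, 1.0], [0.0, 0.0]],
                "large_drop": [[-20.0, 1.0], [-10.0, 0.0]],
            },
        },
        "danger_coeff": {
            "universe": [20.0, 45.0],
            "terms": _partition3(25.0, 32.0, 38.0,
                                 ["low", "moderate", "high"]),
        },
    }
    output = {
        "universe": list(RISK_UNIVERSE),
        "terms": {
            "safe": [[0.0, 1.0], [5.0, 1.0], [15.0, 0.0]],
            "attention": [[5.0, 0.0], [15.0, 1.0], [25.0, 0.0]],
            "warning": [[15.0, 0.0], [25.0, 1.0], [35.0, 0.0]],
            "dangerous": [[25.0, 0.0], [35.0, 1.0], [40.0, 1.0]],
        },
    }
    out_order = ["safe", "attention", "warning", "dangerous"]
    term_orders = {name: list(var["terms"]) for name, var in inputs.items()}
    rules = []
    names = list(inputs)
    for idx in np.ndindex(*(3,) * len(names)):
        score = sum(_SEVERITY_WEIGHTS[n] * i for n, i in zip(names, idx))
        zone = sum(score > edge for edge in _SEVERITY_EDGES)
        rules.append({
            "if": {n: term_orders[n][i] for n, i in zip(names, idx)},
            "then": out_order[zone],
        })
    return FuzzyConfig(
        inputs=inputs,
        output=output,
        rules=tuple(rules),
        grid_points=grid_points,
    )
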