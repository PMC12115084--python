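"""Weighted multi-criteria invasion risk assessment.

Fourteen expert-assigned indicator scores (0-4 scale) are aggregated into
four component scores and one composite:

* P1, introduction & colonization risk — weighted sum
  0.3*P11 + 0.3*P12 + 0.2*P13 + 0.2*P14
* P2, spread risk — geometric mean (P21*P22*P23*P24)^(1/4)
* P3, potential hazards & impacts — max(P31, P32, P33)
* P4, hazard control difficulty — mean (P41+P42+P43)/3
* P, composite — geometric mean (P1*P2*P3*P4)^(1/4)

The composite maps to three risk levels: [2.8, 4.0] -> level 1 (high),
[1.2, 2.8) -> level 2 (medium), [0, 1.2) -> level 3 (low).  Boundary
values go to the higher-risk level.  Indicator codes and weights are
data-driven so other scoring frameworks can reuse the engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

__all__ = [
    "INDICATOR_CODES",
    "IndicatorScore",
    "RiskScoresheet",
    "RiskResult",
    "score_introduction",
    "score_spread",
    "score_impact",
    "score_control",
    "composite_score",
    "classify_level",
    "assess",
]

INTRO_WEIGHTS = {"P11": 0.3, "P12": 0.3, "P13": 0.2, "P14": 0.2}
SPREAD_CODES = ("P21", "P22", "P23", "P24")
IMPACT_CODES = ("P31", "P32", "P33")
CONTROL_CODES = ("P41", "P42", "P43")
INDICATOR_CODES = tuple(INTRO_WEIGHTS) + SPREAD_CODES + IMPACT_CODES + CONTROL_CODES

#: (lower bound inclusive, level); evaluated top-down.  Upper bound of the
#: scale is the scoresheet scale maximum (4 by default).
LEVEL_THRESHOLDS = ((2.8, 1), (1.2, 2), (0.0, 3))

LEVEL_LABELS = {1: "high", 2: "medium", 3: "low"}


class RiskInputError(ValueError):
    """Raised for malformed or out-of-range scoresheets."""


@dataclass
class IndicatorScore:
    code: str
    value: float
    note: str = ""


@dataclass
class RiskScoresheet:
    """Exactly one score per indicator code, on a fixed scale (default 0-4)."""

    species: str
    indicators: dict[str, float]
    scale: tuple[float, float] = (0.0, 4.0)

    def __post_init__(self) -> None:
        missing = [c for c in INDICATOR_CODES if c not in self.indicators]
        if missing:
            raise RiskInputError(f"missing indicator(s): {missing}")
        extra = [c for c in self.indicators if c not in INDICATOR_CODES]
        if extra:
            raise RiskInputError(f"unknown indicator(s): {extra}")
        lo, hi = self.scale
        for code, v in self.indicators.items():
            if not lo <= v <= hi:
                raise RiskInputError(f"{code}={v} outside scale [{lo}, {hi}]")

    def __getitem__(self, code: str) -> float:
        return self.indicators[code]

    @classmethod
    def from_json(cls, path: str) -> "RiskScoresheet":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            species=data.get("species", ""),
            indicators={k: float(v) for k, v in data["indicators"].items()},
            scale=tuple(data.get("scale", (0.0, 4.0))),
        )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"species": self.species, "scale": list(self.scale),
                 "indicators": self.indicators},
                fh, indent=2,
            )


@dataclass
class RiskResult:
    species: str
    P1: float
    P2: float
    P3: float
    P4: float
    P: float
    level: int

    @property
    def level_label(self) -> str:
        return LEVEL_LABELS[self.level]

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "P1": self.P1, "P2": self.P2, "P3": self.P3, "P4": self.P4,
            "P": self.P, "P_display": round(self.P, 2),
            "level": self.level, "level_label": self.level_label,
        }


def score_introduction(s: RiskScoresheet) -> float:
    """P1: weighted sum of environmental suitability, food suitability,
    growth/reproduction traits and natural-enemy status."""
    return sum(w * s[c] for c, w in INTRO_WEIGHTS.items())


def score_spread(s: RiskScoresheet) -> float:
    """P2: geometric mean of distribution, management, spread capacity
    and suitable-habitat range scores."""
    prod = 1.0
    for c in SPREAD_CODES:
        if s[c] < 0:
            raise RiskInputError(f"{c} negative")
        prod *= s[c]
    return prod ** 0.25


def score_impact(s: RiskScoresheet) -> float:
    """P3: worst of the socio-economic, ecological and affected-target impacts."""
    return max(s[c] for c in IMPACT_CODES)


def score_control(s: RiskScoresheet) -> float:
    """P4: mean difficulty of identification, monitoring and control."""
    return sum(s[c] for c in CONTROL_CODES) / 3.0


def composite_score(P1: float, P2: float, P3: float, P4: float) -> float:
    """Composite P: geometric mean of the four component scores."""
    for name, v in zip(("P1", "P2", "P3", "P4"), (P1, P2, P3, P4)):
        if v < 0:
            raise RiskInputError(f"{name} negative")
    return (P1 * P2 * P3 * P4) ** 0.25


def classify_level(P: float, scale_max: float = 4.0) -> int:
    """Map a composite score to risk level 1 (high) / 2 (medium) / 3 (low).

    Thresholds 2.8 and 1.2 belong to the higher-risk level.
    """
    if not 0.0 <= P <= scale_max:
        raise RiskInputError(f"composite {P} outside [0, {scale_max}]")
    for lower, level in LEVEL_THRESHOLDS:
        if P >= lower:
            return level
    return LEVEL_THRESHOLDS[-1][1]


def assess(s: RiskScoresheet) -> RiskResult:
    """Full assessment: component scores, composite and risk level."""
    p1 = score_introduction(s)
    p2 = score_spread(s)
    p3 = score_impact(s)
    p4 = score_control(s)
    p = composite_score(p1, p2, p3, p4)
    return RiskResult(s.species, p1, p2, p3, p4, p, classify_level(p, s.scale[1]))
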