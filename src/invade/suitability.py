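"""Natural-breaks habitat classification and scenario area accounting.

Continuous suitability surfaces are cut into four levels (non-, low,
medium, highly suitable) with Fisher-Jenks natural breaks — the 1-D
classification minimizing within-class sum of squared deviations, found
exactly by dynamic programming.  Class areas follow as cell count times
cell area; climate scenarios are compared as per-class area deltas and
total-suitable percentage-point changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "BreaksClassification",
    "ClassifiedMap",
    "AreaReport",
    "ScenarioDelta",
    "jenks_breaks",
    "classify",
    "class_areas",
    "scenario_delta",
    "scenario_table",
]

CLASS_LABELS = ("non", "low", "medium", "high")


@dataclass
class BreaksClassification:
    """k-1 ascending thresholds partitioning the value range into k classes.

    Intervals are left-closed/right-open, except the top class which is
    closed at the maximum: with the default four levels
    [0,b1), [b1,b2), [b2,b3), [b3,1].
    """

    breaks: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        b = tuple(self.breaks)
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"breaks must be strictly ascending, got {b}")
        self.breaks = b
        if not self.labels:
            self.labels = (
                CLASS_LABELS if len(b) == 3
                else tuple(f"class_{i}" for i in range(len(b) + 1))
            )
        if len(self.labels) != len(b) + 1:
            raise ValueError("need one label per class")


@dataclass
class ClassifiedMap:
    """Integer class grid (0..3; -1 = nodata) plus its classification."""

    classes: np.ndarray
    breaks: BreaksClassification
    cell_size: float = 1.0

    @property
    def valid(self) -> np.ndarray:
        return self.classes >= 0


@dataclass
class AreaReport:
    """Per-class cell counts, areas and percentages for one scenario."""

    counts: dict[str, int]
    areas_km2: dict[str, float]
    percents: dict[str, float]
    total_valid_km2: float
    total_suitable_pct: float
    scenario: str = "current"
    period: str = ""
    labels: tuple[str, ...] = CLASS_LABELS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(self.labels),
                "cells": [self.counts[c] for c in self.labels],
                "area_km2": [self.areas_km2[c] for c in self.labels],
                "percent": [self.percents[c] for c in self.labels],
            }
        )


@dataclass
class ScenarioDelta:
    """future - current: per-class km^2 and total-suitable points."""

    area_change_km2: dict[str, float]
    total_suitable_change_points: float
    scenario: str = ""
    period: str = ""


def jenks_breaks(values, k: int = 4, max_n: int = 10000, seed: int = 42) -> BreaksClassification:
    """Fisher-Jenks optimal k-class breaks of a 1-D sample.

    Exact dynamic programming on the sorted values minimizing total
    within-class sum of squared deviations.  Inputs larger than ``max_n``
    are subsampled (seeded, reproducible) before the exact DP.  Returns
    the k-1 break values, each the minimum value of the class above it,
    matching the left-closed classification convention.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[~np.isnan(x)]
    if np.unique(x).size < k:
        raise ValueError(f"need >= {k} distinct values, got {np.unique(x).size}")
    if x.size > max_n:
        x = np.random.default_rng(seed).choice(x, size=max_n, replace=False)
    x = np.sort(x)
    n = x.size

    # prefix sums for O(1) within-class SSD of x[i:j] (j exclusive)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    idx = np.arange(n + 1)

    def ssd_to(j: int, i_lo: int) -> np.ndarray:
        """SSD of x[i:j] for all i in [i_lo, j)."""
        i = idx[i_lo:j]
        s = cs[j] - cs[i]
        cnt = j - i
        return (cs2[j] - cs2[i]) - s * s / cnt

    # prev[j]: best cost of splitting x[:j] into c classes
    prev = np.array([0.0] + [float(ssd_to(j, 0)[0]) for j in range(1, n + 1)])
    split = np.zeros((k, n + 1), dtype=int)
    for c in range(2, k + 1):
        cur = np.full(n + 1, np.inf)
        for j in range(c, n + 1):
            cand = prev[c - 1:j] + ssd_to(j, c - 1)
            arg = int(np.argmin(cand))
            cur[j] = cand[arg]
            split[c - 1, j] = arg + c - 1
        prev = cur

    # backtrack the class start indices
    bounds = []
    j = n
    for c in range(k, 1, -1):
        i = split[c - 1, j]
        bounds.append(i)
        j = i
    bounds.reverse()
    breaks = tuple(float(x[i]) for i in bounds)
    return BreaksClassification(breaks=breaks)


def classify(
    surface: np.ndarray,
    breaks: BreaksClassification,
    cell_size: float = 1.0,
) -> ClassifiedMap:
    """Assign each cell to a class by the half-open interval convention;
    nodata (NaN) becomes class -1."""
    surface = np.asarray(surface, dtype=float)
    out = np.full(surface.shape, -1, dtype=int)
    ok = ~np.isnan(surface)
    out[ok] = np.digitize(surface[ok], breaks.breaks)  # left-closed bins
    return ClassifiedMap(classes=out, breaks=breaks, cell_size=cell_size)


def class_areas(
    classified: ClassifiedMap,
    cell_area_km2: float | None = None,
    scenario: str = "current",
    period: str = "",
) -> AreaReport:
    """Cell counts, km^2 areas and percent shares per class.

    The denominator is the valid (non-nodata) cell count; the
    total-suitable percent pools the low, medium and high classes.
    """
    if cell_area_km2 is None:
        cell_area_km2 = classified.cell_size**2
    labels = classified.breaks.labels
    counts = {
        label: int((classified.classes == i).sum()) for i, label in enumerate(labels)
    }
    n_valid = sum(counts.values())
    if n_valid == 0:
        raise ValueError("classified map has no valid cells")
    areas = {c: counts[c] * cell_area_km2 for c in labels}
    percents = {c: 100.0 * counts[c] / n_valid for c in labels}
    suitable = sum(counts[c] for c in labels[1:])
    return AreaReport(
        counts=counts,
        areas_km2=areas,
        percents=percents,
        total_valid_km2=n_valid * cell_area_km2,
        total_suitable_pct=100.0 * suitable / n_valid,
        scenario=scenario,
        period=period,
        labels=labels,
    )


def scenario_delta(current: AreaReport, future: AreaReport) -> ScenarioDelta:
    """Per-class area change (km^2) and total-suitable change (points),
    future minus current; requires the same grid domain."""
    cell = current.total_valid_km2 / max(sum(current.counts.values()), 1)
    if abs(current.total_valid_km2 - future.total_valid_km2) > 0.5 * cell + 1e-9:
        raise ValueError(
            "reports cover different domains: "
            f"{current.total_valid_km2} vs {future.total_valid_km2} km^2"
        )
    return ScenarioDelta(
        area_change_km2={
            c: future.areas_km2[c] - current.areas_km2[c] for c in current.labels
        },
        total_suitable_change_points=future.total_suitable_pct - current.total_suitable_pct,
        scenario=future.scenario,
        period=future.period,
    )


def scenario_table(reports: list[AreaReport]) -> pd.DataFrame:
    """Totals by scenario x period, the maximum total-suitable flagged."""
    if not reports:
        raise ValueError("no reports")
    rows = [
        {
            "scenario": r.scenario,
            "period": r.period,
            "low_km2": r.areas_km2["low"],
            "medium_km2": r.areas_km2["medium"],
            "high_km2": r.areas_km2["high"],
            "total_suitable_km2": sum(r.areas_km2[c] for c in CLASS_LABELS[1:]),
            "total_suitable_pct": r.total_suitable_pct,
        }
        for r in reports
    ]
    df = pd.DataFrame(rows)
    df["is_max"] = df["total_suitable_pct"] == df["total_suitable_pct"].max()
    return df
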