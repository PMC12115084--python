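"""Plot-level community survey statistics.

Works on 1 m x 1 m herbaceous survey plots in which every species was
recorded with its abundance (individual count), mean height (cm) and
cover (fraction of the plot).  Provides the classic community metrics:
relative height / cover / abundance and the importance value (their
mean), the Shannon-Wiener diversity index, species occurrence rates,
family composition, community-type summaries by dominant species, and a
Welch two-sample comparison for growth-dominance contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpeciesObservation",
    "PlotRecord",
    "SpeciesPlotMetrics",
    "PlotDiversity",
    "SurveyFormatError",
    "SurveyValidationError",
    "read_survey",
    "write_survey",
    "relative_metrics",
    "shannon_index",
    "occurrence_rate",
    "family_composition",
    "welch_t_test",
    "significance_tier",
    "community_summary",
]

HABITATS = {"forest", "wetland", "grassland"}

REQUIRED_COLUMNS = [
    "plot_id", "longitude", "latitude", "elevation", "habitat",
    "species", "abundance", "height_cm", "cover_pct",
]


class SurveyFormatError(ValueError):
    """Raised when a survey table is structurally malformed."""


class SurveyValidationError(ValueError):
    """Raised when a survey row violates a field invariant."""


@dataclass
class SpeciesObservation:
    """One species in one plot: count, mean height (cm), cover fraction."""

    species_name: str
    abundance: int
    height: float
    cover: float
    family: str | None = None

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise SurveyValidationError(
                f"{self.species_name}: negative abundance {self.abundance}"
            )
        if self.height < 0:
            raise SurveyValidationError(
                f"{self.species_name}: negative height {self.height}"
            )
        if not 0 <= self.cover <= 1:
            raise SurveyValidationError(
                f"{self.species_name}: cover {self.cover} outside [0, 1]"
            )


@dataclass
class PlotRecord:
    """One survey plot with coordinates, elevation, habitat and observations."""

    plot_id: str
    longitude: float
    latitude: float
    elevation: float
    habitat: str
    observations: list[SpeciesObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [o.species_name for o in self.observations]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SurveyValidationError(
                f"plot {self.plot_id}: duplicated species {dupes}"
            )

    @property
    def species(self) -> list[str]:
        return [o.species_name for o in self.observations]

    def contains(self, species: str) -> bool:
        return any(
            o.species_name == species and o.abundance > 0 for o in self.observations
        )


@dataclass
class SpeciesPlotMetrics:
    species_name: str
    rel_height: float
    rel_cover: float
    rel_abundance: float
    importance: float


@dataclass
class PlotDiversity:
    plot_id: str
    richness: int
    shannon: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_survey(path: str) -> list[PlotRecord]:
    """Parse a plot-survey CSV into PlotRecord objects.

    The file holds one row per (plot, species) with plot metadata repeated
    on each row: plot_id, longitude, latitude, elevation, habitat, species,
    optional family, abundance, height_cm, cover_pct (cover in percent on
    disk; converted to a fraction in memory).  Malformed rows raise with
    their line number (header = line 1).
    """
    df = pd.read_csv(path, dtype={"plot_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"{path}: missing required column(s) {missing}")
    has_family = "family" in df.columns

    plots: dict[str, PlotRecord] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header occupies line 1
        pid = str(row["plot_id"])
        try:
            obs = SpeciesObservation(
                species_name=str(row["species"]),
                abundance=int(row["abundance"]),
                height=float(row["height_cm"]),
                cover=float(row["cover_pct"]) / 100.0,
                family=str(row["family"]) if has_family and pd.notna(row["family"]) else None,
            )
        except SurveyValidationError as exc:
            raise SurveyValidationError(f"{path} line {line} (plot {pid}): {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise SurveyFormatError(f"{path} line {line}: unparseable row ({exc})") from exc
        if pid not in plots:
            plots[pid] = PlotRecord(
                plot_id=pid,
                longitude=float(row["longitude"]),
                latitude=float(row["latitude"]),
                elevation=float(row["elevation"]),
                habitat=str(row["habitat"]),
            )
        if obs.species_name in plots[pid].species:
            raise SurveyValidationError(
                f"{path} line {line}: species {obs.species_name!r} duplicated in plot {pid}"
            )
        plots[pid].observations.append(obs)
    return list(plots.values())


def write_survey(plots: list[PlotRecord], path: str) -> None:
    """Inverse of :func:`read_survey` (cover written back as percent)."""
    rows = []
    for p in plots:
        for o in p.observations:
            rows.append(
                {
                    "plot_id": p.plot_id,
                    "longitude": p.longitude,
                    "latitude": p.latitude,
                    "elevation": p.elevation,
                    "habitat": p.habitat,
                    "species": o.species_name,
                    "family": o.family or "",
                    "abundance": o.abundance,
                    "height_cm": o.height,
                    "cover_pct": o.cover * 100.0,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Community metrics
# ---------------------------------------------------------------------------

def relative_metrics(
    plot: PlotRecord,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> list[SpeciesPlotMetrics]:
    """Relative height / cover / abundance and importance value per species.

    rel_x(s) = x(s) / sum_over_species x; importance is the weighted mean
    of the three relatives (equal weights by default, the standard
    herbaceous importance-value convention).  A metric whose plot total is
    zero yields zero relatives and a warning rather than an error.
    """
    if not plot.observations:
        raise SurveyValidationError(f"plot {plot.plot_id}: no observations")
    h = np.array([o.height for o in plot.observations], dtype=float)
    c = np.array([o.cover for o in plot.observations], dtype=float)
    a = np.array([o.abundance for o in plot.observations], dtype=float)

    def _rel(x: np.ndarray, label: str) -> np.ndarray:
        total = x.sum()
        if total <= 0:
            warnings.warn(
                f"plot {plot.plot_id}: all-zero {label}; relatives set to 0",
                stacklevel=3,
            )
            return np.zeros_like(x)
        return x / total

    rh, rc, ra = _rel(h, "heights"), _rel(c, "covers"), _rel(a, "abundances")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    iv = w[0] * rh + w[1] * rc + w[2] * ra
    return [
        SpeciesPlotMetrics(o.species_name, rh[i], rc[i], ra[i], iv[i])
        for i, o in enumerate(plot.observations)
    ]


def importance_value(plot: PlotRecord, species: str) -> float:
    """Importance value of one species in a plot; 0 when absent."""
    for m in relative_metrics(plot):
        if m.species_name == species:
            return m.importance
    return 0.0


def shannon_index(plot: PlotRecord, base: str = "e") -> PlotDiversity:
    """Shannon-Wiener diversity H = -sum p_i log p_i over abundance shares.

    Natural log by default (``base='e'``); ``base='2'`` gives bits.
    """
    if not plot.observations:
        raise SurveyValidationError(f"plot {plot.plot_id}: no observations")
    a = np.array([o.abundance for o in plot.observations], dtype=float)
    a = a[a > 0]
    if a.size == 0:
        raise SurveyValidationError(f"plot {plot.plot_id}: all abundances zero")
    p = a / a.sum()
    h = float(-(p * np.log(p)).sum())
    if base == "2":
        h /= math.log(2)
    return PlotDiversity(plot.plot_id, richness=int(a.size), shannon=max(h, 0.0))


def occurrence_rate(dataset: list[PlotRecord], species: str) -> dict:
    """Presence count and percent occurrence of a species across plots."""
    if not dataset:
        raise SurveyValidationError("empty dataset")
    presences = sum(1 for p in dataset if p.contains(species))
    rate = 100.0 * presences / len(dataset)
    return {"presences": presences, "plots": len(dataset), "rate": rate}


def family_composition(
    dataset: list[PlotRecord],
    taxonomy: dict[str, str] | None = None,
    merge_below_pct: float = 1.0,
) -> list[tuple[str, float]]:
    """Share of distinct species per family, small families merged.

    ``taxonomy`` maps species -> family and overrides per-observation
    family fields; species mappable to no family fall into ``unknown``
    (flagged with a warning).  Families below ``merge_below_pct`` percent
    of species are pooled into ``others``.  Sorted descending; ``others``
    last.  Percentages sum to 100.
    """
    species_family: dict[str, str] = {}
    for p in dataset:
        for o in p.observations:
            fam = (taxonomy or {}).get(o.species_name) or o.family
            if o.species_name not in species_family or species_family[o.species_name] == "unknown":
                species_family[o.species_name] = fam or "unknown"
    if not species_family:
        raise SurveyValidationError("no species in dataset")
    unmapped = sorted(s for s, f in species_family.items() if f == "unknown")
    if unmapped:
        warnings.warn(f"{len(unmapped)} species without family: {unmapped[:5]}...", stacklevel=2)

    counts: dict[str, int] = {}
    for fam in species_family.values():
        counts[fam] = counts.get(fam, 0) + 1
    n = len(species_family)
    merged: dict[str, float] = {}
    others = 0.0
    for fam, k in counts.items():
        pct = 100.0 * k / n
        if pct < merge_below_pct:
            others += pct
        else:
            merged[fam] = pct
    out = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))
    if others > 0:
        out.append(("others", others))
    return out


def welch_t_test(a, b) -> dict:
    """Welch unequal-variance two-sample t test.

    Returns t, Welch-Satterthwaite df, two-sided p and the significance
    tier string ('***' p<0.001, '**' p<0.01, '*' p<0.05, 'ns').
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SurveyValidationError("each group needs >= 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    if not np.isfinite(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return {"t": t, "df": df, "p": p, "tier": significance_tier(p)}


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def community_summary(dataset: list[PlotRecord], n_companions: int = 3) -> pd.DataFrame:
    """Community types by dominant species (highest importance value).

    One row per type: dominant species, top companion species (ranked by
    within-type plot frequency), plot count, and the dominant species' own
    cover (%) and height (cm) as mean +/- SD.  Ties in importance break
    lexicographically so the grouping is reproducible.  Counts partition
    the dataset.
    """
    groups: dict[str, list[PlotRecord]] = {}
    for p in dataset:
        metrics = relative_metrics(p)
        dominant = min(metrics, key=lambda m: (-m.importance, m.species_name))
        groups.setdefault(dominant.species_name, []).append(p)

    rows = []
    for dom, plots in groups.items():
        covers, heights = [], []
        companions: dict[str, int] = {}
        for p in plots:
            for o in p.observations:
                if o.species_name == dom:
                    covers.append(o.cover * 100.0)
                    heights.append(o.height)
                else:
                    companions[o.species_name] = companions.get(o.species_name, 0) + 1
        top = sorted(companions, key=lambda s: (-companions[s], s))[:n_companions]
        rows.append(
            {
                "dominant_species": dom,
                "companion_species": ", ".join(top),
                "n_plots": len(plots),
                "cover_mean_pct": float(np.mean(covers)),
                "cover_sd_pct": float(np.std(covers, ddof=1)) if len(covers) > 1 else 0.0,
                "height_mean_cm": float(np.mean(heights)),
                "height_sd_cm": float(np.std(heights, ddof=1)) if len(heights) > 1 else 0.0,
            }
        )
    df = pd.DataFrame(rows).sort_values("n_plots", ascending=False, kind="stable")
    return df.reset_index(drop=True)
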