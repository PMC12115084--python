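"""Synthetic study-system generator with known ground truth.

Everything the pipeline consumes can be generated here: spatially smooth
cross-correlated environmental raster stacks on a subtropical-coastal
climate envelope, occurrence points drawn from a known Gibbs suitability
model of those layers, 1 m x 1 m plot surveys in which the invader's
importance value declines with community diversity and with the
coldest-month minimum temperature, risk scoresheets realizing a chosen
risk level, and warming-perturbed future-scenario stacks.  All
generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from . import risk as risk_mod
from .maxent import OccurrenceSet
from .rasters import EnvStack
from .survey import PlotRecord, SpeciesObservation

__all__ = [
    "LandscapeSpec",
    "TruthModel",
    "SurveySpec",
    "gen_landscape",
    "gen_occurrences",
    "gen_survey",
    "gen_risk_scoresheet",
    "perturb_stack",
    "gen_scenario_stacks",
    "COMPANION_POOL",
]

#: (center, spread) per layer, anchored to a subtropical monsoon coastal
#: climate (annual mean ~17.4 C, annual precipitation ~1480 mm);
#: temperatures in degrees C, precipitation in mm.
LAYER_RANGES: dict[str, tuple[float, float]] = {
    "bio1": (17.4, 1.2), "bio2": (7.5, 0.8), "bio3": (25.0, 2.0),
    "bio4": (780.0, 40.0), "bio5": (32.5, 1.5), "bio6": (2.0, 1.5),
    "bio7": (30.5, 1.5), "bio8": (21.5, 1.5), "bio9": (7.0, 1.5),
    "bio10": (27.5, 1.2), "bio11": (6.5, 1.5), "bio12": (1480.0, 120.0),
    "bio13": (210.0, 25.0), "bio14": (45.0, 10.0), "bio15": (55.0, 8.0),
    "bio16": (440.0, 12.0), "bio17": (150.0, 25.0), "bio18": (480.0, 60.0),
    "bio19": (185.0, 25.0), "elev": (120.0, 110.0),
}

DEFAULT_LAYERS = tuple(LAYER_RANGES) + ("landcover",)

#: ruderal herbaceous species pool for companion draws (species, family)
COMPANION_POOL: tuple[tuple[str, str], ...] = (
    ("Setaria viridis", "Poaceae"), ("Digitaria sanguinalis", "Poaceae"),
    ("Phragmites australis", "Poaceae"), ("Spartina alterniflora", "Poaceae"),
    ("Lactuca indica", "Asteraceae"), ("Artemisia indica", "Asteraceae"),
    ("Artemisia argyi", "Asteraceae"), ("Erigeron canadensis", "Asteraceae"),
    ("Erigeron sumatrensis", "Asteraceae"), ("Symphyotrichum subulatum", "Asteraceae"),
    ("Pseudognaphalium affine", "Asteraceae"), ("Vicia sepium", "Fabaceae"),
    ("Trifolium repens", "Fabaceae"), ("Veronica persica", "Plantaginaceae"),
    ("Stellaria media", "Caryophyllaceae"), ("Cerastium glomeratum", "Caryophyllaceae"),
    ("Galium spurium", "Rubiaceae"), ("Geranium carolinianum", "Geraniaceae"),
    ("Oxalis corniculata", "Oxalidaceae"), ("Alternanthera philoxeroides", "Amaranthaceae"),
    ("Humulus scandens", "Cannabaceae"), ("Anthriscus sylvestris", "Apiaceae"),
    ("Rumex japonicus", "Polygonaceae"), ("Polygonum aviculare", "Polygonaceae"),
    ("Plantago asiatica", "Plantaginaceae"), ("Capsella bursa-pastoris", "Brassicaceae"),
    ("Cardamine hirsuta", "Brassicaceae"), ("Mazus pumilus", "Mazaceae"),
    ("Cyperus rotundus", "Cyperaceae"), ("Ranunculus sceleratus", "Ranunculaceae"),
)

INVADER_FAMILY = "Asteraceae"


@dataclass
class LandscapeSpec:
    """Recipe for one synthetic environmental stack."""

    n_rows: int = 60
    n_cols: int = 60
    cell_size_km: float = 0.5
    smoothness: int = 5  # moving-average kernel width, cells
    correlation_plan: tuple[tuple[str, str, float], ...] = (
        ("bio16", "bio12", 0.9),
        ("bio11", "bio1", 0.85),
    )
    layers: tuple[str, ...] = DEFAULT_LAYERS
    landcover_classes: int = 5
    nodata_fraction: float = 0.0
    origin: tuple[float, float] = (0.0, 0.0)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_rows < 20 or self.n_cols < 20:
            raise ValueError("grid must be at least 20 x 20")
        if self.smoothness < 1:
            raise ValueError("smoothness must be >= 1")


@dataclass
class TruthModel:
    """Ground-truth suitability: linear + quadratic terms on raw layers.

    The occurrence generator samples cells with probability proportional
    to exp(eta), the same Gibbs form the SDM fits, so fitted raw-scale
    coefficients are directly comparable with these.
    """

    coef_linear: dict[str, float]
    coef_quadratic: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not self.coef_linear and not self.coef_quadratic:
            raise ValueError("truth model needs at least one active layer")
        for d in (self.coef_linear, self.coef_quadratic):
            if any(not np.isfinite(v) for v in d.values()):
                raise ValueError("non-finite truth coefficients")

    @property
    def variables(self) -> list[str]:
        return sorted(set(self.coef_linear) | set(self.coef_quadratic))

    def predictor_env(self, env: np.ndarray, names: list[str]) -> np.ndarray:
        """Linear predictor eta at env-value rows."""
        idx = {n: i for i, n in enumerate(names)}
        eta = np.full(env.shape[0], self.intercept, dtype=float)
        for v, c in self.coef_linear.items():
            eta += c * env[:, idx[v]]
        for v, c in self.coef_quadratic.items():
            eta += c * env[:, idx[v]] ** 2
        return eta

    def predictor_cells(self, stack: EnvStack):
        """eta over valid cells; returns (eta, rows, cols)."""
        rows, cols = np.where(stack.valid_mask)
        env = stack.values_at_cells(rows, cols, names=self.variables)
        return self.predictor_env(env, self.variables), rows, cols


@dataclass
class SurveySpec:
    """Recipe for a synthetic plot survey with a diversity-resistance
    structure: invader importance declines with Shannon H (beta_shannon
    < 0) and rises with the coldest-month minimum temperature
    (beta_bio6 > 0, i.e. colder plots are less invaded)."""

    n_plots: int = 595
    invader: str = "Solidago canadensis"
    beta0: float = 0.9
    beta_shannon: float = -0.4
    beta_bio6: float = 0.04  # per degree C
    bio6_center: float = 2.0
    sigma: float = 0.20
    richness_range: tuple[int, int] = (2, 10)
    absent_below: float = 0.02  # IV target under this -> invader absent
    seed: int = 42

    def __post_init__(self) -> None:
        if self.beta_shannon >= 0:
            raise ValueError("beta_shannon must be negative (diversity resists invasion)")
        if self.beta_bio6 <= 0:
            raise ValueError("beta_bio6 must be positive (cold limits invasion)")


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], width: int) -> np.ndarray:
    """Standardized moving-average-smoothed white noise."""
    z = rng.standard_normal(shape)
    if width > 1:
        z = uniform_filter(z, size=width, mode="reflect")
    z = z - z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def gen_landscape(spec: LandscapeSpec) -> EnvStack:
    """Generate an aligned stack of smooth, cross-correlated layers.

    Each layer starts as moving-average-smoothed white noise; the
    correlation plan mixes latent fields (child = rho * parent +
    sqrt(1-rho^2) * own noise) before rescaling each layer to its
    climate envelope.  The ``landcover`` layer is a k-class quantile
    quantization of its own latent field.  Optionally a contiguous
    nodata region (lowest values of a smooth latent) is carved out.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_rows, spec.n_cols)
    latents: dict[str, np.ndarray] = {
        name: _smooth_field(rng, shape, spec.smoothness) for name in spec.layers
    }
    for parent, child, rho in spec.correlation_plan:
        if parent in latents and child in latents:
            latents[child] = rho * latents[parent] + np.sqrt(1 - rho**2) * latents[child]
            latents[child] = (latents[child] - latents[child].mean()) / latents[child].std()

    mask = None
    if spec.nodata_fraction > 0:
        sea = _smooth_field(rng, shape, max(spec.smoothness, 3))
        cut = np.quantile(sea, spec.nodata_fraction)
        mask = sea < cut

    layers: dict[str, np.ndarray] = {}
    for name in spec.layers:
        z = latents[name]
        if name == "landcover":
            qs = np.quantile(z, np.linspace(0, 1, spec.landcover_classes + 1)[1:-1])
            arr = np.digitize(z, qs).astype(float) + 1.0  # classes 1..k
        else:
            center, spread = LAYER_RANGES.get(name, (0.0, 1.0))
            arr = center + spread * z
            if name.startswith("bio1") and name not in ("bio1", "bio10", "bio11"):
                arr = np.maximum(arr, 0.0)  # precipitation cannot go negative
        if mask is not None:
            arr = arr.copy()
            arr[mask] = np.nan
        layers[name] = arr
    return EnvStack(
        layers,
        cell_size=spec.cell_size_km,
        origin=spec.origin,
        categorical={"landcover"} if "landcover" in spec.layers else set(),
    )


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

def gen_occurrences(
    stack: EnvStack,
    truth: TruthModel,
    n: int,
    seed: int = 42,
    jitter: bool = False,
) -> OccurrenceSet:
    """Sample n presence points from the Gibbs distribution over valid
    cells (probability proportional to exp(truth predictor)); cells may
    repeat.  Points sit at cell centers unless ``jitter`` spreads them
    uniformly within the cell."""
    rng = np.random.default_rng(seed)
    eta, rows, cols = truth.predictor_cells(stack)
    eta = eta - eta.max()
    p = np.exp(eta)
    p /= p.sum()
    idx = rng.choice(eta.size, size=n, replace=True, p=p)
    x, y = stack.rowcol_to_xy(rows[idx], cols[idx])
    if jitter:
        x = x + (rng.random(n) - 0.5) * stack.cell_size
        y = y + (rng.random(n) - 0.5) * stack.cell_size
    return OccurrenceSet(np.column_stack([x, y]), species="Solidago canadensis")


# ---------------------------------------------------------------------------
# surveys
# ---------------------------------------------------------------------------

def _realized_shannon(abundances: np.ndarray) -> float:
    a = abundances[abundances > 0].astype(float)
    if a.size <= 1:
        return 0.0
    p = a / a.sum()
    return float(-(p * np.log(p)).sum())


def gen_survey(stack: EnvStack, spec: SurveySpec) -> list[PlotRecord]:
    """Generate plot records realizing the configured invasion structure.

    Per plot: a location on a valid cell; companion species drawn from
    the ruderal pool with Dirichlet abundance shares of varying evenness
    (so Shannon H spreads); the invader's abundance is a typical
    companion share (so measured H is insensitive to the noise term) and
    its target importance value
    clip(beta0 + beta_shannon*H + beta_bio6*(bio6 - center) + noise, 0, 0.95)
    is realized through the invader's height and cover shares (clipped to
    [0.005, 0.97]; the documented ±0.05 reconstruction slack covers
    abundance rounding and those clips).  Targets below ``absent_below``
    leave the plot uninvaded.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = np.where(stack.valid_mask)
    if rows.size == 0:
        raise ValueError("stack has no valid cells")
    cell_idx = rng.choice(rows.size, size=spec.n_plots, replace=True)
    r, c = rows[cell_idx], cols[cell_idx]
    x, y = stack.rowcol_to_xy(r, c)
    x = x + (rng.random(spec.n_plots) - 0.5) * stack.cell_size * 0.9
    y = y + (rng.random(spec.n_plots) - 0.5) * stack.cell_size * 0.9
    bio6 = stack.layers["bio6"][r, c] if "bio6" in stack.layers else np.full(spec.n_plots, spec.bio6_center)
    elev = stack.layers["elev"][r, c] if "elev" in stack.layers else np.zeros(spec.n_plots)
    habitats = rng.choice(["grassland", "wetland", "forest"], size=spec.n_plots, p=[0.6, 0.2, 0.2])

    lo, hi = spec.richness_range
    plots: list[PlotRecord] = []
    pool = list(COMPANION_POOL)
    for i in range(spec.n_plots):
        s_comp = int(rng.integers(max(lo - 1, 1), hi))  # companions (invader may add 1)
        picks = rng.choice(len(pool), size=min(s_comp, len(pool)), replace=False)
        alpha = float(np.exp(rng.uniform(np.log(0.3), np.log(3.0))))
        shares = rng.dirichlet(np.full(len(picks), alpha))
        total = int(rng.integers(20, 61))
        comp_ab = np.maximum(np.round(shares * total), 1).astype(int)
        comp_h = rng.uniform(5.0, 80.0, size=len(picks))
        comp_c = rng.uniform(0.02, 0.25, size=len(picks))

        eps = rng.normal(0.0, spec.sigma)

        # the invader's abundance is pinned to a typical companion share so
        # the measured Shannon H is (nearly) independent of the noise; the
        # importance target is then realized through height and cover shares
        inv_ab = max(int(round(np.median(comp_ab))), 1)
        h_real = _realized_shannon(np.append(comp_ab, inv_ab))
        iv = float(np.clip(
            spec.beta0
            + spec.beta_shannon * h_real
            + spec.beta_bio6 * (bio6[i] - spec.bio6_center)
            + eps,
            0.0, 0.95,
        ))
        if iv <= spec.absent_below:
            inv_ab = 0

        obs = [
            SpeciesObservation(
                species_name=pool[k][0],
                family=pool[k][1],
                abundance=int(comp_ab[j]),
                height=float(comp_h[j]),
                cover=float(comp_c[j]),
            )
            for j, k in enumerate(picks)
        ]
        if inv_ab > 0:
            rel_a = inv_ab / (inv_ab + comp_ab.sum())
            # importance = (rel_h + rel_c + rel_a) / 3 -> split the needed
            # height+cover share, respecting that cover cannot exceed the
            # whole plot (rel_c is capped by cover = 1) while height is free
            need = 3.0 * iv - rel_a
            c_max = 1.0 / (1.0 + comp_c.sum())  # rel_c at invader cover = 1
            rel_c = float(np.clip(need / 2.0, 0.005, min(c_max, 0.97)))
            rel_h = float(np.clip(need - rel_c, 0.005, 0.97))
            obs.append(
                SpeciesObservation(
                    species_name=spec.invader,
                    family=INVADER_FAMILY,
                    abundance=inv_ab,
                    height=float(rel_h / (1.0 - rel_h) * comp_h.sum()),
                    cover=float(min(rel_c / (1.0 - rel_c) * comp_c.sum(), 1.0)),
                )
            )
        plots.append(
            PlotRecord(
                plot_id=f"P{i + 1:04d}",
                longitude=float(x[i]),
                latitude=float(y[i]),
                elevation=float(elev[i]),
                habitat=str(habitats[i]),
                observations=obs,
            )
        )
    return plots


# ---------------------------------------------------------------------------
# risk scoresheets
# ---------------------------------------------------------------------------

_LEVEL_PROPOSAL = {1: (2.5, 4.0), 2: (1.0, 3.0), 3: (0.0, 1.4)}


def gen_risk_scoresheet(
    target_level: int,
    seed: int = 42,
    species: str = "Solidago canadensis",
    max_tries: int = 1000,
) -> risk_mod.RiskScoresheet:
    """Sample indicator scores until the assessment lands on the target
    level (bounded rejection from a level-matched proposal range)."""
    if target_level not in (1, 2, 3):
        raise ValueError("target_level must be 1, 2 or 3")
    rng = np.random.default_rng(seed)
    lo, hi = _LEVEL_PROPOSAL[target_level]
    for _ in range(max_tries):
        values = np.round(rng.uniform(lo, hi, size=len(risk_mod.INDICATOR_CODES)) * 2) / 2
        sheet = risk_mod.RiskScoresheet(
            species=species,
            indicators=dict(zip(risk_mod.INDICATOR_CODES, values.tolist())),
        )
        if risk_mod.assess(sheet).level == target_level:
            return sheet
    raise RuntimeError(f"could not realize level {target_level} in {max_tries} tries")


# ---------------------------------------------------------------------------
# future scenarios
# ---------------------------------------------------------------------------

#: (temperature shift degrees C, precipitation scaling) per scenario x period;
#: precipitation changes are kept small relative to the spatial spread of the
#: precipitation layers so scenario responses stay in a plausible range
SCENARIO_SHIFTS = {
    ("SSP1-2.6", "2050s"): (0.9, 1.002), ("SSP1-2.6", "2070s"): (1.1, 1.003),
    ("SSP2-4.5", "2050s"): (1.4, 1.004), ("SSP2-4.5", "2070s"): (1.8, 1.006),
    ("SSP5-8.5", "2050s"): (1.9, 1.008), ("SSP5-8.5", "2070s"): (2.8, 1.012),
}

_TEMP_LAYERS = {"bio1", "bio5", "bio6", "bio8", "bio9", "bio10", "bio11"}
_PRECIP_LAYERS = {"bio12", "bio13", "bio14", "bio16", "bio17", "bio18", "bio19"}


def perturb_stack(
    stack: EnvStack,
    temp_delta: float,
    precip_scale: float,
    seed: int = 42,
    roughness: float = 0.15,
) -> EnvStack:
    """Warming-style perturbation: temperature layers shifted by
    ``temp_delta`` C, precipitation layers scaled by ``precip_scale``,
    each with a smooth spatially varying component (sd ``roughness`` of
    the shift) so scenarios are not constant offsets."""
    rng = np.random.default_rng(seed)
    layers = {}
    for name, arr in stack.layers.items():
        if name in _TEMP_LAYERS:
            wobble = _smooth_field(rng, stack.shape, 7) * roughness * max(abs(temp_delta), 0.5)
            layers[name] = arr + temp_delta + wobble
        elif name in _PRECIP_LAYERS:
            wobble = 1.0 + _smooth_field(rng, stack.shape, 7) * roughness * abs(precip_scale - 1.0)
            layers[name] = np.maximum(arr * precip_scale * wobble, 0.0)
        else:
            layers[name] = arr.copy()
    return EnvStack(
        layers,
        cell_size=stack.cell_size,
        origin=stack.origin,
        categorical=set(stack.categorical),
    )


def gen_scenario_stacks(stack: EnvStack, seed: int = 42) -> dict[tuple[str, str], EnvStack]:
    """One perturbed stack per (SSP scenario, period) combination."""
    out = {}
    for i, ((scen, period), (dt, ps)) in enumerate(sorted(SCENARIO_SHIFTS.items())):
        out[(scen, period)] = perturb_stack(stack, dt, ps, seed=seed + i)
    return out
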