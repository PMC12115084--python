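"""Presence-background maximum-entropy species distribution model.

The model is the Gibbs distribution over landscape cells

    q_lambda(cell) = exp(sum_j lambda_j f_j(cell)) / Z_lambda,

with Z computed over a background sample, fitted by minimizing the
L1-regularized negative log-likelihood of the presence records

    J(lambda) = -mean_presence[f . lambda] + log Z_lambda
                + sum_j beta_j |lambda_j|.

Features are linear, quadratic, hinge and categorical-indicator
transforms of the environmental layers, scaled to [0, 1] over the
background.  The objective is convex; it is minimized by cyclic
coordinate descent with a guaranteed majorizing quadratic (curvature
bound 1/4 for [0,1] features) and a soft-threshold step, so the
objective decreases monotonically.  Per-update likelihood gains are
traced to support percent-contribution accounting.

Diagnostics mirror standard SDM practice: rank-based AUC on a held-out
presence split versus background, percent contribution, permutation
importance, jackknife single-variable gains, response curves, and a
small grid tuner over regularization multipliers and feature classes
scored by AICc on the presence likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .rasters import EnvStack

__all__ = [
    "Feature",
    "FeatureSet",
    "OccurrenceSet",
    "MaxentModel",
    "EvalReport",
    "ContributionReport",
    "sample_background",
    "spearman_screen",
    "fit_maxent",
    "predict",
    "predict_surface",
    "split_train_test",
    "auc",
    "auc_scores",
    "percent_contribution",
    "permutation_importance",
    "jackknife_gains",
    "response_curve",
    "tune_model",
]

#: per-feature-class multipliers on the adaptive L1 penalty
CLASS_BETA = {"linear": 1.0, "quadratic": 1.0, "product": 1.0, "hinge": 0.5, "category": 0.25}

DEFAULT_FEATURE_CLASSES = ("linear", "quadratic", "hinge")


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceSet:
    """Presence points (planar map coordinates) for one species."""

    points: np.ndarray  # (n, 2) x, y
    species: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")

    def __len__(self) -> int:
        return len(self.points)

    def filter_valid(self, stack: EnvStack) -> "OccurrenceSet":
        """Drop points outside the extent or on nodata cells."""
        vals = stack.sample(self.points[:, 0], self.points[:, 1], names=[stack.names[0]])
        ok = ~np.isnan(vals[:, 0])
        return OccurrenceSet(self.points[ok], self.species)

    def thin_to_cells(self, stack: EnvStack) -> "OccurrenceSet":
        """Collapse duplicate presences within one grid cell."""
        row, col = stack.xy_to_rowcol(self.points[:, 0], self.points[:, 1])
        _, keep = np.unique(np.stack([row, col]), axis=1, return_index=True)
        return OccurrenceSet(self.points[np.sort(keep)], self.species)

    @classmethod
    def from_csv(cls, path: str) -> "OccurrenceSet":
        df = pd.read_csv(path)
        for req in ("x", "y"):
            if req not in df.columns:
                raise ValueError(f"{path}: occurrence CSV needs columns species,x,y")
        species = str(df["species"].iloc[0]) if "species" in df.columns and len(df) else ""
        return cls(df[["x", "y"]].to_numpy(dtype=float), species)

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {"species": self.species, "x": self.points[:, 0], "y": self.points[:, 1]}
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

@dataclass
class Feature:
    """One scalar feature: a transform of one (or two) variables.

    ``lo``/``hi`` are the raw-transform bounds over the background used to
    scale the feature to [0, 1].
    """

    kind: str  # linear | quadratic | product | hinge | hinge_rev | category
    variables: tuple[str, ...]
    param: float | None = None  # hinge knot or category code
    lo: float = 0.0
    hi: float = 1.0

    @property
    def variable(self) -> str:
        return self.variables[0]

    def label(self) -> str:
        if self.kind in ("hinge", "hinge_rev"):
            return f"{self.kind}({self.variable}@{self.param:.4g})"
        if self.kind == "category":
            return f"{self.variable}=={self.param:g}"
        if self.kind == "product":
            return f"{self.variables[0]}*{self.variables[1]}"
        return f"{self.kind}({self.variable})"


def _raw_feature(feat: Feature, env: np.ndarray, name_idx: dict[str, int]) -> np.ndarray:
    v = env[:, name_idx[feat.variables[0]]]
    if feat.kind == "linear":
        return v
    if feat.kind == "quadratic":
        return v * v
    if feat.kind == "product":
        return v * env[:, name_idx[feat.variables[1]]]
    if feat.kind == "hinge":
        return np.maximum(v - feat.param, 0.0)
    if feat.kind == "hinge_rev":
        return np.maximum(feat.param - v, 0.0)
    if feat.kind == "category":
        return (v == feat.param).astype(float)
    raise ValueError(f"unknown feature kind {feat.kind!r}")


@dataclass
class FeatureSet:
    """Feature definitions plus the background scaling bounds."""

    names: list[str]
    features: list[Feature]
    categorical: set[str] = field(default_factory=set)

    @classmethod
    def build(
        cls,
        background_env: np.ndarray,
        names: list[str],
        categorical: set[str] | None = None,
        classes: tuple[str, ...] = DEFAULT_FEATURE_CLASSES,
        n_hinge_knots: int = 5,
    ) -> "FeatureSet":
        """Construct features for each variable and scale them over the
        background.

        Continuous variables get the requested classes (hinge knots at
        evenly spaced interior quantiles, both orientations); categorical
        variables get one indicator per observed class.  Constant features
        are dropped.
        """
        categorical = categorical or set()
        name_idx = {n: i for i, n in enumerate(names)}
        feats: list[Feature] = []
        for name in names:
            col = background_env[:, name_idx[name]]
            if name in categorical:
                for code in np.unique(col[~np.isnan(col)]):
                    feats.append(Feature("category", (name,), float(code)))
                continue
            if "linear" in classes:
                feats.append(Feature("linear", (name,)))
            if "quadratic" in classes:
                feats.append(Feature("quadratic", (name,)))
            if "hinge" in classes:
                qs = np.linspace(0, 1, n_hinge_knots + 2)[1:-1]
                for k in np.quantile(col[~np.isnan(col)], qs):
                    feats.append(Feature("hinge", (name,), float(k)))
                    feats.append(Feature("hinge_rev", (name,), float(k)))
        if "product" in classes:
            cont = [n for n in names if n not in categorical]
            for i in range(len(cont)):
                for j in range(i + 1, len(cont)):
                    feats.append(Feature("product", (cont[i], cont[j])))

        kept: list[Feature] = []
        for f in feats:
            raw = _raw_feature(f, background_env, name_idx)
            lo, hi = float(np.nanmin(raw)), float(np.nanmax(raw))
            if hi - lo < 1e-12:
                continue  # constant over background: uninformative
            f.lo, f.hi = lo, hi
            kept.append(f)
        return cls(names=list(names), features=kept, categorical=set(categorical))

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_variables(self) -> list[str]:
        """Owning variable per feature (product features credit the first)."""
        return [f.variable for f in self.features]

    def transform(self, env: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Evaluate all features on an (n, n_vars) env-value matrix, scaled
        to the background's [0, 1] bounds.

        ``clamp`` (default) clips values to those bounds, the standard
        maxent treatment of presences or projection cells more extreme
        than any background cell — without it the presence likelihood
        can be unbounded.
        """
        env = np.atleast_2d(np.asarray(env, dtype=float))
        if env.shape[1] != len(self.names):
            raise ValueError(
                f"env matrix has {env.shape[1]} columns, expected {len(self.names)}"
            )
        if not np.all(np.isfinite(env)):
            raise ValueError("non-finite environmental values")
        name_idx = {n: i for i, n in enumerate(self.names)}
        out = np.empty((env.shape[0], len(self.features)))
        for j, f in enumerate(self.features):
            raw = _raw_feature(f, env, name_idx)
            out[:, j] = (raw - f.lo) / (f.hi - f.lo)
        if clamp:
            np.clip(out, 0.0, 1.0, out=out)
        return out

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "categorical": sorted(self.categorical),
            "features": [
                {"kind": f.kind, "variables": list(f.variables), "param": f.param,
                 "lo": f.lo, "hi": f.hi}
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        return cls(
            names=list(d["names"]),
            categorical=set(d["categorical"]),
            features=[
                Feature(x["kind"], tuple(x["variables"]), x["param"], x["lo"], x["hi"])
                for x in d["features"]
            ],
        )


# ---------------------------------------------------------------------------
# background sampling & screening
# ---------------------------------------------------------------------------

def sample_background(stack: EnvStack, n: int = 10000, seed: int = 42):
    """Uniform background sample (without replacement) over valid cells.

    Returns ``(env_matrix, xy)``: layer values and map coordinates of the
    sampled cells.  If ``n`` is at least the number of valid cells, every
    valid cell is returned (in grid order).
    """
    rows, cols = np.where(stack.valid_mask)
    if n >= rows.size:
        idx = np.arange(rows.size)
    else:
        idx = np.random.default_rng(seed).choice(rows.size, size=n, replace=False)
    r, c = rows[idx], cols[idx]
    env = stack.values_at_cells(r, c)
    x, y = stack.rowcol_to_xy(r, c)
    return env, np.column_stack([x, y])


def _single_factor_gain(
    name: str,
    presence_env: np.ndarray,
    background_env: np.ndarray,
    names: list[str],
    categorical: set[str],
) -> float:
    """Training gain of a model using only one variable (linear+quadratic,
    or indicators for categoricals); used to arbitrate correlated pairs."""
    j = names.index(name)
    classes = ("linear", "quadratic")
    fs = FeatureSet.build(
        background_env[:, [j]], [name],
        categorical=categorical & {name}, classes=classes,
    )
    if len(fs) == 0:
        return 0.0
    model = fit_maxent(
        fs, presence_env[:, [j]], background_env[:, [j]],
        reg_multiplier=1.0, max_iter=500, tol=1e-6,
    )
    return model.gain()


def spearman_screen(
    stack_or_env,
    presence_env: np.ndarray | None = None,
    background_env: np.ndarray | None = None,
    names: list[str] | None = None,
    threshold: float = 0.75,
    categorical: set[str] | None = None,
) -> dict:
    """Screen correlated environmental variables before fitting.

    Pairwise Spearman rho is computed on presence + background values;
    for each pair with |rho| > threshold the member with the lower
    single-variable training gain is dropped.  Constant layers are flagged
    and excluded outright.  Accepts either an EnvStack (env values are
    then sampled internally) or pre-sampled env matrices.
    """
    if isinstance(stack_or_env, EnvStack):
        stack = stack_or_env
        names = names or stack.names
        bg_env, _ = sample_background(stack, n=2000, seed=0)
        bg_env = bg_env[:, [stack.names.index(n) for n in names]]
        if presence_env is None:
            raise ValueError("presence_env (n,2 points env values) required")
        pres_env = presence_env
        categorical = categorical or stack.categorical
    else:
        pres_env = np.asarray(stack_or_env, dtype=float)
        bg_env = np.asarray(background_env, dtype=float)
        if names is None:
            raise ValueError("names required with raw env matrices")
        categorical = categorical or set()

    if len(pres_env) < 3:
        raise ValueError("need >= 3 sample locations")
    combined = np.vstack([pres_env, bg_env])

    constant = [n for i, n in enumerate(names) if np.nanstd(combined[:, i]) == 0]
    active = [n for n in names if n not in constant]
    gains: dict[str, float] = {}

    def gain_of(n: str) -> float:
        if n not in gains:
            gains[n] = _single_factor_gain(n, pres_env, bg_env, list(names), categorical)
        return gains[n]

    retained = list(active)
    dropped = list(constant)
    pairs: list[tuple[str, str, float]] = []
    while True:
        worst = None
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                a, b = retained[i], retained[j]
                rho = stats.spearmanr(
                    combined[:, names.index(a)], combined[:, names.index(b)]
                ).statistic
                if np.isnan(rho):
                    continue
                if abs(rho) > threshold and (worst is None or abs(rho) > abs(worst[2])):
                    worst = (a, b, rho)
        if worst is None:
            break
        a, b, rho = worst
        pairs.append(worst)
        loser = b if gain_of(a) >= gain_of(b) else a
        retained.remove(loser)
        dropped.append(loser)
    return {
        "retained": retained,
        "dropped": dropped,
        "constant": constant,
        "correlated_pairs": pairs,
    }


# ---------------------------------------------------------------------------
# model & fitting
# ---------------------------------------------------------------------------

@dataclass
class MaxentModel:
    """Fitted maximum-entropy model."""

    feature_set: FeatureSet
    weights: np.ndarray
    betas: np.ndarray
    reg_multiplier: float
    log_z: float  # log sum over background of exp(eta)
    entropy: float  # entropy of the raw background distribution (nats)
    n_presence: int
    n_background: int
    transform: str = "cloglog"
    seed: int = 42
    n_iter: int = 0
    converged: bool = True
    final_objective: float = 0.0
    null_objective: float = 0.0
    trace_gain_by_variable: dict[str, float] = field(default_factory=dict)
    objective_trace: list[float] = field(default_factory=list)
    presence_mean_eta: float = 0.0

    def linear_predictor(self, env: np.ndarray) -> np.ndarray:
        return self.feature_set.transform(env) @ self.weights

    def raw(self, env: np.ndarray) -> np.ndarray:
        """Gibbs probability relative to the background normalizer.

        Over the background sample itself these values sum to 1.
        """
        return np.exp(np.minimum(self.linear_predictor(env) - self.log_z, 700.0))

    def gain(self) -> float:
        """Regularized training gain vs. the uniform null model (>= 0)."""
        g = self.null_objective - self.final_objective
        return max(float(g), 0.0)

    def presence_log_likelihood(self) -> float:
        """Sum of log raw probabilities of the presence records."""
        return self.n_presence * (self.presence_mean_eta - self.log_z)

    def raw_coefficients(self) -> dict[str, dict[str, float]]:
        """Fitted weights mapped back to raw-variable scale.

        Only linear and quadratic features translate directly:
        eta = sum lambda_j (raw_j - lo_j) / (hi_j - lo_j), so the raw
        coefficient on v (resp. v^2) is lambda / (hi - lo).
        """
        out: dict[str, dict[str, float]] = {"linear": {}, "quadratic": {}}
        for f, lam in zip(self.feature_set.features, self.weights):
            if f.kind in ("linear", "quadratic"):
                out[f.kind][f.variable] = out[f.kind].get(f.variable, 0.0) + lam / (
                    f.hi - f.lo
                )
        return out

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "feature_set": self.feature_set.to_dict(),
                    "weights": self.weights.tolist(),
                    "betas": self.betas.tolist(),
                    "reg_multiplier": self.reg_multiplier,
                    "log_z": self.log_z,
                    "entropy": self.entropy,
                    "n_presence": self.n_presence,
                    "n_background": self.n_background,
                    "transform": self.transform,
                    "seed": self.seed,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "MaxentModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_set=FeatureSet.from_dict(d["feature_set"]),
            weights=np.asarray(d["weights"], dtype=float),
            betas=np.asarray(d["betas"], dtype=float),
            reg_multiplier=d["reg_multiplier"],
            log_z=d["log_z"],
            entropy=d["entropy"],
            n_presence=d["n_presence"],
            n_background=d["n_background"],
            transform=d["transform"],
            seed=d["seed"],
        )


class ConvergenceError(RuntimeError):
    def __init__(self, gap: float, n_iter: int):
        super().__init__(
            f"maxent optimizer did not converge in {n_iter} iterations "
            f"(final KKT gap {gap:.3g})"
        )
        self.gap = gap


def fit_maxent(
    features: FeatureSet,
    presence_env: np.ndarray,
    background_env: np.ndarray,
    reg_multiplier: float = 1.0,
    seed: int = 42,
    max_iter: int = 5000,
    tol: float = 1e-7,
    kkt_tol: float = 1e-5,
    transform: str = "cloglog",
    error_on_no_convergence: bool = True,
    beta_scale: np.ndarray | None = None,
    l2_penalty: float = 1e-5,
) -> MaxentModel:
    """Fit the L1-regularized Gibbs model by accelerated proximal descent.

    Per-feature penalties are ``beta_j = reg_multiplier * class_beta *
    sd_j(background) / sqrt(n_presence)``, shrinking with sample size as
    in standard maxent practice (``beta_scale`` rescales them feature by
    feature).  Each iteration takes a gradient step on the smooth part
    followed by soft thresholding, with backtracking and Nesterov
    momentum; momentum restarts whenever the accelerated step would
    raise the penalized objective, so the objective is monotone.  The
    iteration's objective drop is credited to variables in proportion
    to each updated feature's first-order share, which feeds the
    percent-contribution diagnostic.  ``l2_penalty`` adds a tiny ridge
    term that keeps the optimum bounded and unique when features are
    (near-)collinear — at its default it is orders of magnitude below
    the L1 penalty for any weight of ordinary size.  Convergence is declared when an
    iteration improves the objective by less than ``tol`` or the L1
    subgradient optimality conditions hold within ``kkt_tol``.
    """
    if len(presence_env) < 5:
        raise ValueError("need >= 5 presence records")
    F_p = features.transform(presence_env)
    F_b = features.transform(background_env)
    if not (np.all(np.isfinite(F_p)) and np.all(np.isfinite(F_b))):
        raise ValueError("non-finite feature values")
    m, n_feat = F_p.shape
    N = F_b.shape[0]
    mu = F_p.mean(axis=0)

    sd = F_b.std(axis=0)
    class_beta = np.array([CLASS_BETA.get(f.kind.replace("_rev", ""), 1.0)
                           for f in features.features])
    betas = reg_multiplier * class_beta * np.maximum(sd, 1e-3) / np.sqrt(m)
    if beta_scale is not None:
        betas = betas * np.asarray(beta_scale, dtype=float)

    owner = features.feature_variables
    var_names = list(dict.fromkeys(owner))
    owner_idx = np.array([var_names.index(v) for v in owner], dtype=int)
    var_gain = np.zeros(len(var_names))

    def smooth(lam_v: np.ndarray, log_z_v: float) -> float:
        return float(-(mu @ lam_v) + log_z_v + 0.5 * l2_penalty * (lam_v @ lam_v))

    def prox(point: np.ndarray, grad: np.ndarray, t: float) -> np.ndarray:
        z = point - t * grad
        return np.sign(z) * np.maximum(np.abs(z) - t * betas, 0.0)

    lam = np.zeros(n_feat)
    eta = np.zeros(N)  # F_b @ lam, maintained incrementally
    lam_prev, eta_prev = lam.copy(), eta.copy()
    log_z = float(np.log(N))
    null_obj = log_z  # lam = 0
    obj = null_obj
    n_iter = 0
    kkt_gap = np.inf
    converged = n_feat == 0
    step = 1.0
    t_mom = 1.0
    obj_trace = [obj]
    for n_iter in range(1, max_iter + 1):
        if n_feat == 0:
            break
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        c = (t_mom - 1.0) / t_next
        for attempt in ("momentum", "restart"):
            if attempt == "momentum" and c > 0:
                y = lam + c * (lam - lam_prev)
                eta_y = eta + c * (eta - eta_prev)
            else:
                y, eta_y = lam, eta
            log_z_y = float(logsumexp(eta_y))
            w = np.exp(eta_y - log_z_y)  # Gibbs weights at y, sum to 1
            grad = F_b.T @ w - mu + l2_penalty * y
            f_y = smooth(y, log_z_y)
            # backtracking: majorization of the smooth part at y
            while True:
                cand = prox(y, grad, step)
                delta = cand - y
                eta_c = eta_y + F_b @ delta
                log_z_c = float(logsumexp(eta_c))
                f_c = smooth(cand, log_z_c)
                quad = f_y + grad @ delta + (delta @ delta) / (2.0 * step)
                if f_c <= quad + 1e-12 or step < 1e-12:
                    break
                step *= 0.5
            obj_c = f_c + float(betas @ np.abs(cand))
            if obj_c <= obj + 1e-12:
                break  # accept (monotone)
            t_next = 1.0  # momentum overshot: restart from lam
        drop = obj - obj_c
        if drop > 0:
            shares = np.abs((cand - lam) * grad)
            total = shares.sum()
            if total > 0:
                var_gain += drop * np.bincount(
                    owner_idx, weights=shares, minlength=len(var_names)
                ) / total
        lam_prev, eta_prev = lam, eta
        lam, eta, log_z, obj = cand, eta_c, log_z_c, obj_c
        obj_trace.append(obj)
        t_mom = t_next
        step = min(step * 1.2, 1e6)
        # KKT residual for the L1 subdifferential, at the new iterate
        w = np.exp(eta - log_z)
        grad_new = F_b.T @ w - mu + l2_penalty * lam
        res = np.where(
            lam != 0,
            np.abs(grad_new + betas * np.sign(lam)),
            np.maximum(np.abs(grad_new) - betas, 0.0),
        )
        kkt_gap = float(res.max())
        if kkt_gap < kkt_tol or 0 <= drop < tol:
            converged = True
            break

    gain_by_var = dict(zip(var_names, var_gain))
    if not converged and error_on_no_convergence:
        raise ConvergenceError(kkt_gap, n_iter)

    p_bg = np.exp(eta - log_z)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-(p_bg * np.where(p_bg > 0, np.log(p_bg), 0.0)).sum())
    return MaxentModel(
        feature_set=features,
        weights=lam,
        betas=betas,
        reg_multiplier=reg_multiplier,
        log_z=log_z,
        entropy=entropy,
        n_presence=m,
        n_background=N,
        transform=transform,
        seed=seed,
        n_iter=n_iter,
        converged=converged,
        final_objective=obj,
        null_objective=null_obj,
        trace_gain_by_variable=gain_by_var,
        objective_trace=obj_trace,
        presence_mean_eta=float(mu @ lam),
    )


# ---------------------------------------------------------------------------
# prediction & evaluation
# ---------------------------------------------------------------------------

def predict(model: MaxentModel, env: np.ndarray, transform: str | None = None) -> np.ndarray:
    """Suitability in [0, 1] at env-value rows.

    ``cloglog`` (default): 1 - exp(-exp(H) * raw), H the background raw
    entropy; ``logistic``: analogous with the inverse-logit; ``raw``:
    background-normalized Gibbs probabilities.
    """
    transform = transform or model.transform
    raw = model.raw(env)
    if transform == "raw":
        return raw
    scaled = np.exp(model.entropy) * raw
    if transform == "cloglog":
        return 1.0 - np.exp(-scaled)
    if transform == "logistic":
        return scaled / (1.0 + scaled)
    raise ValueError(f"unknown transform {transform!r}")


def predict_surface(model: MaxentModel, stack: EnvStack, transform: str | None = None) -> np.ndarray:
    """Suitability grid over a raster stack (NaN preserved at nodata)."""
    out = np.full(stack.shape, np.nan)
    rows, cols = np.where(stack.valid_mask)
    env = stack.values_at_cells(rows, cols, names=model.feature_set.names)
    out[rows, cols] = predict(model, env, transform=transform)
    return out


def split_train_test(points: np.ndarray, ratio: float = 0.75, seed: int = 42):
    """Random disjoint, exhaustive presence split (train fraction ``ratio``).

    Train size is floor(n * ratio), clamped so both sides are non-empty
    when n >= 2.
    """
    points = np.asarray(points)
    n = len(points)
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    n_train = int(n * ratio)
    if n >= 2:
        n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return points[np.sort(perm[:n_train])], points[np.sort(perm[n_train:])]


def auc_scores(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("both score sets must be non-empty")
    allscores = np.concatenate([pres, bg])
    ranks = stats.rankdata(allscores)
    u = ranks[: pres.size].sum() - pres.size * (pres.size + 1) / 2
    return float(u / (pres.size * bg.size))


@dataclass
class EvalReport:
    auc_train: float
    auc_test: float
    split_ratio: float
    seed: int
    n_train: int
    n_test: int


def auc(model: MaxentModel, presence_env: np.ndarray, background_env: np.ndarray) -> float:
    """AUC of model scores: presences vs. background."""
    return auc_scores(
        predict(model, presence_env), predict(model, background_env)
    )


# ---------------------------------------------------------------------------
# variable importance
# ---------------------------------------------------------------------------

@dataclass
class ContributionReport:
    percent_contribution: dict[str, float]
    permutation_importance: dict[str, float]
    jackknife: dict[str, dict[str, float]]  # var -> {with_only, without}

    def to_frame(self) -> pd.DataFrame:
        vars_ = sorted(self.percent_contribution)
        return pd.DataFrame(
            {
                "variable": vars_,
                "percent_contribution": [self.percent_contribution[v] for v in vars_],
                "permutation_importance": [self.permutation_importance[v] for v in vars_],
                "jackknife_with_only": [self.jackknife[v]["with_only"] for v in vars_],
                "jackknife_without": [self.jackknife[v]["without"] for v in vars_],
            }
        )


def percent_contribution(model: MaxentModel) -> dict[str, float]:
    """Share of the accumulated fitting gain credited to each variable.

    Each optimizer iteration's objective drop is split across the
    updated features in proportion to their first-order share and
    credited to the owning variables; the totals are normalized to sum
    to 100.
    """
    gains = model.trace_gain_by_variable
    total = sum(gains.values())
    if total <= 0:
        return {v: 0.0 for v in gains}
    return {v: 100.0 * g / total for v, g in gains.items()}


def permutation_importance(
    model: MaxentModel,
    presence_env: np.ndarray,
    background_env: np.ndarray,
    seed: int = 42,
) -> dict[str, float]:
    """AUC drop per variable under within-column permutation, normalized
    to sum to 100.

    Presence and background values of one variable are pooled, permuted,
    and redistributed before rescoring; variables the model never uses
    (all-zero weights) score exactly 0.
    """
    rng = np.random.default_rng(seed)
    base = auc(model, presence_env, background_env)
    names = model.feature_set.names
    used = {f.variable for f, w in zip(model.feature_set.features, model.weights) if w != 0}
    drops = {}
    m = len(presence_env)
    for i, name in enumerate(names):
        if name not in used:
            drops[name] = 0.0
            continue
        pooled = np.concatenate([presence_env[:, i], background_env[:, i]])
        shuffled = rng.permutation(pooled)
        pres_p = presence_env.copy()
        bg_p = background_env.copy()
        pres_p[:, i] = shuffled[:m]
        bg_p[:, i] = shuffled[m:]
        drops[name] = max(base - auc(model, pres_p, bg_p), 0.0)
    total = sum(drops.values())
    if total <= 0:
        return {v: 0.0 for v in drops}
    return {v: 100.0 * d / total for v, d in drops.items()}


def jackknife_gains(
    features: FeatureSet,
    presence_env: np.ndarray,
    background_env: np.ndarray,
    reg_multiplier: float = 1.0,
    max_iter: int = 1000,
) -> dict[str, dict[str, float]]:
    """With-only and without training gains per variable.

    ``with_only``: the regularized gain of a model restricted to the
    variable's own features; ``without``: the gain of the model with that
    variable's features removed.
    """
    def _fit(sub: list[Feature]) -> float:
        fs = FeatureSet(names=features.names, features=sub, categorical=features.categorical)
        if not fs.features:
            return 0.0
        mdl = fit_maxent(
            fs, presence_env, background_env,
            reg_multiplier=reg_multiplier, max_iter=max_iter, tol=1e-6,
            error_on_no_convergence=False,
        )
        return mdl.gain()

    out: dict[str, dict[str, float]] = {}
    for name in dict.fromkeys(features.feature_variables):
        own = [f for f in features.features if f.variable == name]
        rest = [f for f in features.features if f.variable != name]
        out[name] = {"with_only": _fit(own), "without": _fit(rest)}
    return out


def response_curve(
    model: MaxentModel,
    variable: str,
    background_env: np.ndarray,
    n_points: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal response: sweep one variable over its background range with
    every other variable held at its background mean (categoricals at
    their mode)."""
    names = model.feature_set.names
    if variable not in names:
        raise ValueError(f"unknown variable {variable!r}")
    j = names.index(variable)
    base = np.empty(len(names))
    for i, n in enumerate(names):
        col = background_env[:, i]
        if n in model.feature_set.categorical:
            vals, counts = np.unique(col, return_counts=True)
            base[i] = vals[np.argmax(counts)]
        else:
            base[i] = col.mean()
    xs = np.linspace(background_env[:, j].min(), background_env[:, j].max(), n_points)
    env = np.tile(base, (n_points, 1))
    env[:, j] = xs
    return xs, predict(model, env)


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def tune_model(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    names: list[str],
    categorical: set[str] | None = None,
    reg_multipliers: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
    feature_class_sets: tuple[tuple[str, ...], ...] = (
        ("linear", "quadratic"),
        ("linear", "quadratic", "hinge"),
    ),
    criterion: str = "aicc",
    split_ratio: float = 0.75,
    seed: int = 42,
    max_iter: int = 1000,
) -> dict:
    """Grid search over regularization multipliers and feature classes.

    ``criterion='aicc'`` (default) scores each candidate by the
    sample-size-corrected AIC of the presence likelihood (k = number of
    non-zero weights); ``criterion='auc'`` scores by test AUC on an
    internal presence split.  Returns the winning settings, its fitted
    model, and the full score table.
    """
    if criterion not in ("aicc", "auc"):
        raise ValueError("criterion must be 'aicc' or 'auc'")
    rows = []
    best = None
    m = len(presence_env)
    if criterion == "auc":
        idx_train, idx_test = split_train_test(np.arange(m), ratio=split_ratio, seed=seed)
    for classes in feature_class_sets:
        fs = FeatureSet.build(background_env, names, categorical=categorical, classes=classes)
        for rm in reg_multipliers:
            if criterion == "auc":
                model = fit_maxent(
                    fs, presence_env[idx_train], background_env,
                    reg_multiplier=rm, seed=seed, max_iter=max_iter,
                    error_on_no_convergence=False,
                )
                score = auc(model, presence_env[idx_test], background_env)
                better = best is None or score > best["score"]
            else:
                model = fit_maxent(
                    fs, presence_env, background_env,
                    reg_multiplier=rm, seed=seed, max_iter=max_iter,
                    error_on_no_convergence=False,
                )
                k = int(np.count_nonzero(model.weights))
                ll = model.presence_log_likelihood()
                if m - k - 1 <= 0:
                    score = np.inf
                else:
                    score = -2 * ll + 2 * k + 2 * k * (k + 1) / (m - k - 1)
                better = best is None or score < best["score"]
            row = {
                "feature_classes": "+".join(classes),
                "reg_multiplier": rm,
                "n_features": len(fs),
                "n_nonzero": int(np.count_nonzero(model.weights)),
                criterion: float(score),
            }
            rows.append(row)
            if better:
                best = {
                    "feature_classes": classes,
                    "reg_multiplier": rm,
                    "score": float(score),
                    "model": model,
                }
    return {"best": best, "table": pd.DataFrame(rows)}
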