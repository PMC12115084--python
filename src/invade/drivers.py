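"""Driver analysis: what explains plot-level invader dominance.

Assembles a per-plot table of the invader's importance value (response)
against community diversity (Shannon H) and bioclimatic predictors
sampled from the raster stack at each plot, screens collinear
predictors, standardizes them, and fits a Gaussian identity-link GLM
(ordinary least squares) so coefficient magnitudes are comparable effect
sizes.  Reports per-predictor standardized coefficients, standard
errors, t statistics, p values and significance tiers, plus model R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .rasters import EnvStack
from .survey import PlotRecord, importance_value, shannon_index, significance_tier

__all__ = [
    "DEFAULT_PREDICTORS",
    "GLMFit",
    "build_driver_table",
    "standardize",
    "collinearity_screen",
    "fit_glm",
]

#: climate predictors used alongside Shannon diversity by default:
#: annual mean temperature, coldest-month minimum, wettest-quarter mean
#: temperature, driest- and warmest-quarter precipitation.
DEFAULT_PREDICTORS = ("bio1", "bio6", "bio8", "bio17", "bio18")

RESPONSE = "importance"


@dataclass
class GLMFit:
    """Standardized-coefficient table plus fit summary."""

    table: pd.DataFrame  # index: predictor; columns: coef, std_error, statistic, p_value, tier
    r_squared: float
    n: int
    family: str = "gaussian"

    def to_json_dict(self) -> dict:
        return {
            "family": self.family,
            "r_squared": self.r_squared,
            "n": self.n,
            "coefficients": self.table.reset_index().to_dict(orient="records"),
        }


def build_driver_table(
    dataset: list[PlotRecord],
    env: EnvStack,
    invader: str,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
) -> pd.DataFrame:
    """One row per plot: invader importance, Shannon H and env predictors.

    Predictors are sampled at each plot's grid cell.  The response is the
    invader's importance value, zero where it is absent (absence is
    informative about invasibility).  Plots falling on nodata cells or
    outside the extent are dropped with a warning.
    """
    if not dataset:
        raise ValueError("empty dataset")
    xs = np.array([p.longitude for p in dataset])
    ys = np.array([p.latitude for p in dataset])
    env_vals = env.sample(xs, ys, names=list(predictors))

    rows = []
    dropped = 0
    for i, plot in enumerate(dataset):
        if np.any(np.isnan(env_vals[i])):
            dropped += 1
            continue
        rows.append(
            {
                "plot_id": plot.plot_id,
                RESPONSE: importance_value(plot, invader),
                "shannon": shannon_index(plot).shannon,
                **{v: env_vals[i, j] for j, v in enumerate(predictors)},
            }
        )
    if not rows:
        raise ValueError("all plots fall outside the raster extent or on nodata")
    if dropped:
        warnings.warn(f"dropped {dropped} plot(s) on nodata/out-of-extent cells", stacklevel=2)
    return pd.DataFrame(rows).set_index("plot_id")


def standardize(table: pd.DataFrame, exclude: tuple[str, ...] = (RESPONSE,)) -> pd.DataFrame:
    """Z-score every predictor column (mean 0, population SD 1); the
    response is untouched.

    Raises on constant columns — a constant carries no effect size.
    """
    out = table.copy()
    for col in table.columns:
        if col in exclude:
            continue
        sd = table[col].std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} is constant; cannot standardize")
        out[col] = (table[col] - table[col].mean()) / sd
    return out


def collinearity_screen(
    table: pd.DataFrame,
    response: str = RESPONSE,
    threshold: float = 0.75,
) -> dict:
    """Greedy pairwise-Spearman screen over predictor columns.

    While any pair exceeds |rho| > threshold, drop the member whose
    |Spearman| with the response is lower (ties -> drop the later
    column).  Returns retained names, dropped names and the offending
    pairs with their rho.
    """
    predictors = [c for c in table.columns if c != response]
    y = table[response].to_numpy()
    resp_rho = {
        c: abs(stats.spearmanr(table[c].to_numpy(), y).statistic) for c in predictors
    }
    retained = list(predictors)
    dropped: list[str] = []
    pairs: list[tuple[str, str, float]] = []
    while True:
        worst = None
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                rho = stats.spearmanr(
                    table[retained[i]].to_numpy(), table[retained[j]].to_numpy()
                ).statistic
                if np.isnan(rho):
                    continue
                if abs(rho) > threshold and (worst is None or abs(rho) > abs(worst[2])):
                    worst = (retained[i], retained[j], rho)
        if worst is None:
            break
        a, b, rho = worst
        pairs.append(worst)
        loser = b if resp_rho[a] >= resp_rho[b] else a
        retained.remove(loser)
        dropped.append(loser)
    return {"retained": retained, "dropped": dropped, "correlated_pairs": pairs}


def fit_glm(
    table: pd.DataFrame,
    response: str = RESPONSE,
    family: str = "gaussian",
    standardize_predictors: bool = True,
) -> GLMFit:
    """Fit the driver GLM and return standardized effects.

    ``family='gaussian'`` (default) is an identity-link least-squares
    fit reporting plain R^2; ``family='quasibinomial'`` fits a logit-link
    binomial GLM on the bounded response and reports pseudo-R^2
    (1 - deviance/null deviance).
    """
    predictors = [c for c in table.columns if c != response]
    n, p = len(table), len(predictors)
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} predictors")
    work = standardize(table, exclude=(response,)) if standardize_predictors else table
    X = sm.add_constant(work[predictors].to_numpy())
    y = work[response].to_numpy()

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("singular design matrix: linearly dependent predictors")

    if family == "gaussian":
        res = sm.OLS(y, X).fit()
        r2 = float(res.rsquared)
    elif family == "quasibinomial":
        model = sm.GLM(y, X, family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(scale="X2")
        r2 = float(1.0 - res.deviance / res.null_deviance)
    else:
        raise ValueError(f"unknown family {family!r}")

    names = ["intercept"] + predictors
    tbl = pd.DataFrame(
        {
            "coef": res.params,
            "std_error": res.bse,
            "statistic": res.tvalues,
            "p_value": res.pvalues,
        },
        index=pd.Index(names, name="predictor"),
    )
    tbl["tier"] = [significance_tier(pv) for pv in tbl["p_value"]]
    return GLMFit(table=tbl, r_squared=r2, n=n, family=family)
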