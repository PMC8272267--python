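"""The two regressions on stopover summaries, plus predictor pruning.

* Stopover counts per migration: Gaussian linear mixed model with
  population, season and their interaction as fixed effects and a random
  intercept per individual (statsmodels MixedLM).
* Proportion of activity during stopovers: binomial GLMM (logit link) on
  (active hours, daytime hours) with mean per-stopover weather covariates
  as fixed effects and random intercepts for population and individual
  nested within population (own Laplace fitter, see :mod:`migstops.glmm`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .glmm import GLMMResult, fit_binomial_glmm

#: default ecological-relevance ranking used when pruning collinear predictors
DEFAULT_PREDICTOR_PRIORITY = (
    "thermal_updraft_velocity",
    "temperature",
    "precipitation_fraction",
    "boundary_height",
    "downward_shortwave_radiation",
    "sensible_heat_flux",
    "total_atmospheric_water",
    "wind_speed",
    "surface_pressure",
    "orographic_updraft_velocity",
)


@dataclass
class CountModelResult:
    terms: list[tuple[str, float, float, float]]  # (name, beta, se, t)
    random_effect_sd: dict[str, float]
    n_obs: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.terms, columns=["term", "beta", "se", "t"])


@dataclass
class ActivityModelResult:
    terms: list[tuple[str, float, float, float, float]]  # name, beta, se, z, p
    random_effect_sd: dict[str, float]
    n_obs: int
    converged: bool = True

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.terms, columns=["term", "beta", "se", "z",
                                                 "p_value"])

    def ci95(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name, beta, se, _, _ in self.terms:
            out[name] = (beta - 1.96 * se, beta + 1.96 * se)
        return out


def prune_correlated_predictors(predictor_table: pd.DataFrame,
                                priority_order: list[str] | None = None,
                                threshold: float = 0.6) -> list[str]:
    """Greedy collinearity pruning.

    Walk predictors in priority order; retain one iff its absolute Pearson
    correlation with every already-retained predictor is <= ``threshold``.
    Constant predictors (undefined correlation) are dropped with a warning.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    priority = [c for c in (priority_order or DEFAULT_PREDICTOR_PRIORITY)
                if c in predictor_table.columns]
    priority += [c for c in predictor_table.columns if c not in priority]

    retained: list[str] = []
    for name in priority:
        col = predictor_table[name].to_numpy(float)
        if np.nanstd(col) == 0 or not np.isfinite(col).any():
            warnings.warn(f"predictor {name!r} is constant; dropped")
            continue
        ok = True
        for kept in retained:
            r = _pearson(col, predictor_table[kept].to_numpy(float))
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            retained.append(name)
    return retained


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 3:
        return 0.0
    return float(np.corrcoef(a[m], b[m])[0, 1])


def fit_stopover_count_model(migration_table: pd.DataFrame) -> CountModelResult:
    """LMM: stopovers-per-migration ~ population * season + (1 | individual).

    ``migration_table`` needs columns ``count``, ``population``, ``season``
    and ``individual_id``.  When a factor has a single level the
    corresponding term is dropped with a warning.
    """
    df = migration_table.copy()
    for col in ("count", "population", "season", "individual_id"):
        if col not in df.columns:
            raise ValueError(f"migration table missing column {col!r}")

    terms = []
    if df["population"].nunique() > 1:
        terms.append("C(population)")
    else:
        warnings.warn("single population level; term dropped")
    if df["season"].nunique() > 1:
        terms.append("C(season)")
    else:
        warnings.warn("single season level; term dropped")
    if len(terms) == 2:
        terms.append("C(population):C(season)")
    formula = "count ~ " + (" + ".join(terms) if terms else "1")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["individual_id"])
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=True, method="powell")

    out_terms = []
    for name in fit.fe_params.index:
        out_terms.append((name, float(fit.fe_params[name]),
                          float(fit.bse_fe[name]), float(fit.tvalues[name])))
    re_sd = {"individual_id": float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0)))}
    return CountModelResult(terms=out_terms, random_effect_sd=re_sd,
                            n_obs=int(fit.nobs))


def fit_activity_glmm(stopover_table: pd.DataFrame,
                      retained_predictors: list[str]) -> ActivityModelResult:
    """Binomial GLMM for proportion of activity during stopovers.

    ``stopover_table`` needs ``n_active_h``, ``n_daytime_h`` (> 0),
    ``individual_id``, ``population`` and one column per retained
    predictor (mean per-stopover weather values; coefficients are reported
    on the unscaled predictors).  Random intercepts: population, and
    individual nested within population.
    """
    df = stopover_table.copy()
    needed = ["n_active_h", "n_daytime_h", "individual_id", "population",
              *retained_predictors]
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"stopover table missing column {col!r}")
    df = df[(df["n_daytime_h"] > 0)].dropna(subset=needed).reset_index(drop=True)
    if df["individual_id"].nunique() < 2:
        raise ValueError("need at least 2 individuals for the random effect")

    X = np.column_stack([np.ones(len(df))]
                        + [df[c].to_numpy(float) for c in retained_predictors])
    names = ["Intercept", *retained_predictors]
    pop_codes = pd.Categorical(df["population"]).codes
    ind_pop = df["population"].astype(str) + "/" + df["individual_id"].astype(str)
    ind_codes = pd.Categorical(ind_pop).codes
    groups = {"population": pop_codes, "individual:population": ind_codes}
    if len(np.unique(pop_codes)) < 2:
        groups.pop("population")
        warnings.warn("single population; population random intercept dropped")

    res: GLMMResult = fit_binomial_glmm(
        X, df["n_active_h"].to_numpy(float), df["n_daytime_h"].to_numpy(float),
        groups, names=names)

    terms = [(n, float(b), float(s), float(z), float(p))
             for n, b, s, z, p in zip(res.names, res.beta, res.se, res.z, res.p)]
    return ActivityModelResult(terms=terms, random_effect_sd=res.sigma,
                               n_obs=res.n_obs, converged=res.converged)
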