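"""Survival, growth and recruitment models with climate covariates.

Survival of genet *i* (species *j*, group *g*, year *t*) is Bernoulli with

    logit S = γ_t + φ_g + β·u + ω·w + (crowding×size)·u·w + η·C + Γ·(C·u)

where u is log genet area, w the crowding vector, C the climate covariate
vector. Growth (change in log size, conditional on survival) uses the same
linear-predictor structure for its mean v̄, with a size-dependent variance
about the growth curve

    Var = a · exp(b · v̄).

Recruitment is modelled at the quadrat level: the number y of recruits of
species j arriving in quadrat q follows a negative binomial with size θ and
mean

    λ_j = N′_j · exp(γ_t + φ_g + ω·√N′ + η·C),

a Ricker-type form in the square root of effective cover, where effective
cover N′ = p·N_q + (1−p)·(group mean cover) mixes the focal quadrat with its
group to acknowledge seed input from outside the quadrat.

Fitting uses maximum likelihood with year and group entering as (dummy)
effects; the fitted per-year deviations double as the empirical library of
year effects that the simulation modules draw from. Climate covariates are
chosen by bidirectional stepwise AIC over the five named covariates and,
except for recruitment, the within-year precipitation × temperature
interactions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .data_io import (CLIMATE_COVARIATES, CLIMATE_INTERACTIONS, ClimateTable)

logger = logging.getLogger("quadratdyn")

__all__ = [
    "SurvivalParams", "GrowthParams", "RecruitParams", "ClimateSelection",
    "survival_prob", "growth_moments", "effective_cover", "recruit_intensity",
    "sample_recruits", "fit_survival", "fit_growth", "fit_recruitment",
    "select_climate_covariates", "variance_explained",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class LinearParams:
    """Shared linear-predictor slots for survival and growth."""

    intercept: float = 0.0
    size: float = 0.0                                # β
    year_effects: dict = field(default_factory=dict)       # γ_t deviations
    year_size_slopes: dict = field(default_factory=dict)   # per-year β deviations
    group_effects: dict = field(default_factory=dict)      # φ_g
    crowding: dict = field(default_factory=dict)           # ω per neighbour species
    crowding_size: dict = field(default_factory=dict)      # crowding × size
    climate: dict = field(default_factory=dict)            # η per covariate
    climate_size: dict = field(default_factory=dict)       # Γ per covariate

    def linear_predictor(self, u, C: Mapping[str, float] | None,
                         w: Mapping[str, float] | None,
                         year=None, group=None,
                         year_draw: tuple[float, float] | None = None):
        """Evaluate γ_t + φ_g + βu + ω·w + cs·u·w + η·C + Γ·C·u.

        ``year=None`` evaluates at the marginal (zero) year deviation;
        an unknown year key is a hard error. ``year_draw=(γ_dev, β_dev)``
        overrides the lookup, which is how simulators inject randomly drawn
        year effects.
        """
        u = np.asarray(u, dtype=float)
        lp = np.full(u.shape, self.intercept, dtype=float)
        beta = self.size
        if year_draw is not None:
            lp += year_draw[0]
            beta = beta + year_draw[1]
        elif year is not None:
            if year not in self.year_effects:
                raise KeyError(f"no fitted effect for year {year!r}")
            lp += self.year_effects[year]
            beta = beta + self.year_size_slopes.get(year, 0.0)
        if group is not None:
            if group not in self.group_effects:
                raise KeyError(f"no fitted effect for group {group!r}")
            lp += self.group_effects[group]
        lp += beta * u
        if w:
            for m, wm in w.items():
                om = self.crowding.get(m, 0.0)
                cs = self.crowding_size.get(m, 0.0)
                lp += om * np.asarray(wm) + cs * u * np.asarray(wm)
        if C is not None:
            for c, eta in self.climate.items():
                lp += eta * C[c]
            for c, gam in self.climate_size.items():
                lp += gam * C[c] * u
        return lp

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SurvivalParams(LinearParams):
    pass


@dataclass
class GrowthParams(LinearParams):
    var_a: float = 1.0
    var_b: float = 0.0

    def variance(self, vbar):
        v = self.var_a * np.exp(self.var_b * np.asarray(vbar, dtype=float))
        if np.any(v <= 0):
            raise ValueError("non-positive growth variance")
        return v


@dataclass
class RecruitParams:
    intercept: float = 0.0
    year_effects: dict = field(default_factory=dict)
    group_effects: dict = field(default_factory=dict)
    dd: dict = field(default_factory=dict)        # ω on √effective-cover
    climate: dict = field(default_factory=dict)   # η
    theta: float = 1.0                            # negative-binomial size
    p: float = 1.0                                # cover mixing fraction

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClimateSelection:
    """Outcome of stepwise covariate selection for one vital rate."""

    selected: list[str]
    trace: list[tuple[str, float]]  # (action, AIC) in search order


# ---------------------------------------------------------------------------
# prediction


def survival_prob(u, C, w, params: SurvivalParams, year=None, group=None,
                  year_draw=None):
    """Survival probability: inverse-logit of the linear predictor."""
    return expit(params.linear_predictor(u, C, w, year, group, year_draw))


def growth_moments(u, C, w, params: GrowthParams, year=None, group=None,
                   year_draw=None):
    """Mean and variance of next log size, conditional on survival."""
    vbar = params.linear_predictor(u, C, w, year, group, year_draw)
    return vbar, params.variance(vbar)


def effective_cover(N_q, group_mean, p: float):
    """N′ = p·N_q + (1−p)·group-mean cover (all cm², all ≥ 0)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"mixing fraction p={p} outside [0, 1]")
    return p * np.asarray(N_q, dtype=float) + (1.0 - p) * np.asarray(
        group_mean, dtype=float)


def recruit_intensity(species: str, Nprime: Mapping[str, float],
                      C: Mapping[str, float] | None, params: RecruitParams,
                      year=None, group=None, year_draw: float | None = None
                      ) -> float:
    """Expected recruit count λ_j for the focal species in one quadrat.

    λ is proportional to the species' own effective cover and therefore
    exactly 0 when that cover is 0.
    """
    Nj = float(Nprime[species])
    if Nj < 0:
        raise ValueError("effective cover must be ≥ 0")
    if Nj == 0.0:
        return 0.0
    lp = params.intercept
    if year_draw is not None:
        lp += year_draw
    elif year is not None:
        if year not in params.year_effects:
            raise KeyError(f"no fitted effect for year {year!r}")
        lp += params.year_effects[year]
    if group is not None:
        if group not in params.group_effects:
            raise KeyError(f"no fitted effect for group {group!r}")
        lp += params.group_effects[group]
    for m, om in params.dd.items():
        lp += om * np.sqrt(float(Nprime.get(m, 0.0)))
    if C is not None:
        for c, eta in params.climate.items():
            lp += eta * C[c]
    return Nj * float(np.exp(lp))


def sample_recruits(lam, theta: float, rng: np.random.Generator):
    """Negative-binomial draw with mean λ and variance λ + λ²/θ.

    Uses the gamma–Poisson mixture, which is exact and handles λ = 0.
    """
    lam = np.asarray(lam, dtype=float)
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if np.any(lam < 0):
        raise ValueError("lambda must be ≥ 0")
    mix = rng.gamma(shape=theta, scale=lam / theta)
    return rng.poisson(mix)


# ---------------------------------------------------------------------------
# design-matrix construction (shared by survival and growth)


def _centered_effects(names, coefs, keys, prefix):
    """Convert treatment-coded effects to zero-mean deviations + offset."""
    eff = {k: 0.0 for k in keys}
    for name, c in zip(names, coefs):
        if name.startswith(prefix):
            eff[_parse_key(name[len(prefix):])] = c
    mean = float(np.mean(list(eff.values()))) if eff else 0.0
    return {k: v - mean for k, v in eff.items()}, mean


def _parse_key(text: str):
    try:
        f = float(text)
        return int(f) if f == int(f) else f
    except ValueError:
        return text


def _build_design(df: pd.DataFrame, neighbours: Sequence[str],
                  clim_size_cols: Sequence[str],
                  year_size_slopes: bool) -> tuple[np.ndarray, list[str]]:
    """Stage-1 design: year/group dummies, size, crowding and climate×size.

    Climate *main* effects are deliberately absent: they are constant
    within a year and therefore collinear with the year dummies; they are
    estimated in a second stage from the fitted year deviations (the
    climate × size interactions vary within years and stay in stage 1).
    """
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    u = df["logarea"].to_numpy(float)
    years = sorted(df["year"].unique())
    groups = sorted(df["group"].unique())
    for y in years[1:]:
        cols[f"year_{y}"] = (df["year"] == y).to_numpy(float)
    for g in groups[1:]:
        cols[f"group_{g}"] = (df["group"] == g).to_numpy(float)
    cols["size"] = u
    if year_size_slopes:
        for y in years[1:]:
            cols[f"sizeyear_{y}"] = u * (df["year"] == y).to_numpy(float)
    for m in neighbours:
        wm = df[f"w_{m}"].to_numpy(float)
        cols[f"w_{m}"] = wm
        cols[f"wsize_{m}"] = wm * u
    for c in clim_size_cols:
        cols[f"climsize_{c}"] = df[c].to_numpy(float) * u
    names = list(cols)
    return np.column_stack([cols[n] for n in names]), names


def _extract_linear(res_params: np.ndarray, names: list[str],
                    df: pd.DataFrame, neighbours, clim_size_cols, cls):
    """Map fitted design coefficients back into a params dataclass."""
    coef = dict(zip(names, res_params))
    years = sorted(df["year"].unique())
    groups = sorted(df["group"].unique())
    year_eff, ymean = _centered_effects(names, res_params, years, "year_")
    grp_eff, gmean = _centered_effects(names, res_params, groups, "group_")
    slope_names = [n for n in names if n.startswith("sizeyear_")]
    if slope_names:
        slopes, smean = _centered_effects(names, res_params, years, "sizeyear_")
    else:
        slopes, smean = {}, 0.0
    return cls(
        intercept=coef["const"] + ymean + gmean,
        size=coef["size"] + smean,
        year_effects=year_eff,
        year_size_slopes=slopes,
        group_effects=grp_eff,
        crowding={m: coef[f"w_{m}"] for m in neighbours},
        crowding_size={m: coef[f"wsize_{m}"] for m in neighbours},
        climate={},
        climate_size={c: coef[f"climsize_{c}"] for c in clim_size_cols},
    )


def _stage2_climate(year_effects: Mapping, climate: ClimateTable,
                    covariates: Sequence[str]) -> tuple[dict, dict, dict, float]:
    """Regress fitted per-year deviations on (centered) climate covariates.

    Returns (η estimates, residual year deviations, SEs, stage-2 AICc).
    The residuals replace the raw deviations as the random-year-effect
    library, so simulation draws add climate effects and year effects
    without double counting.
    """
    years = sorted(year_effects)
    y = np.array([year_effects[t] for t in years], dtype=float)
    clim = climate.with_interactions()
    missing = [t for t in years if t not in clim.index]
    if missing:
        raise KeyError(f"no climate rows for fitted years {missing}")
    X = np.column_stack(
        [np.ones(len(years))]
        + [clim.loc[years, c].to_numpy(float)
           - clim.loc[years, c].to_numpy(float).mean() for c in covariates])
    res = sm.OLS(y, X).fit()
    eta = {c: float(b) for c, b in zip(covariates, res.params[1:])}
    se = {c: float(b) for c, b in zip(covariates, res.bse[1:])}
    resid = dict(zip(years, (y - res.fittedvalues).astype(float)))
    k = X.shape[1] + 1  # +1 for the residual variance
    n = len(years)
    aicc = res.aic + (2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0
                      else np.inf)
    # predictions use raw covariates: fold b0 − η·C̄ into the intercept
    shift = float(res.params[0]) - sum(
        eta[c] * clim.loc[years, c].to_numpy(float).mean()
        for c in covariates)
    return eta, resid, se, float(aicc), shift


def climate_selector(year_effects: Mapping, climate: ClimateTable):
    """AICc objective over climate subsets for stepwise selection.

    The year-level sample is small (tens of years), so the small-sample
    corrected AICc is used; with no candidate the objective is the
    intercept-only AICc of the year deviations.
    """
    def fit_fn(subset: Sequence[str]) -> float:
        return _stage2_climate(year_effects, climate, list(subset))[3]
    return fit_fn


def _apply_stage2(params, fitres: "FitResult", climate: ClimateTable | None,
                  covariates: Sequence[str]) -> None:
    if climate is None or not covariates:
        return
    eta, resid, se, _, shift = _stage2_climate(params.year_effects, climate,
                                               covariates)
    params.climate = eta
    params.year_effects = resid
    params.intercept += shift
    for c in covariates:
        fitres.bse[f"clim_{c}"] = se[c]


def _merge_climate(df: pd.DataFrame, climate: ClimateTable | None) -> pd.DataFrame:
    if climate is None:
        return df
    clim = climate.with_interactions()
    return df.join(clim, on="year")


@dataclass
class FitResult:
    params: object
    aic: float
    loglike: float
    converged: bool
    fitted: object = None  # statsmodels results, for diagnostics
    bse: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.converged:
            logger.warning("vital-rate fit did not converge (AIC=%.2f)",
                           self.aic)


# ---------------------------------------------------------------------------
# fitting


def fit_survival(transitions: pd.DataFrame, neighbours: Sequence[str],
                 climate: ClimateTable | None = None,
                 climate_covariates: Sequence[str] = (),
                 climate_size_covariates: Sequence[str] = (),
                 year_size_slopes: bool = False) -> FitResult:
    """Fit the survival model by binomial maximum likelihood.

    ``transitions`` needs columns survives (0/1), logarea, year, group and
    one ``w_<species>`` column per neighbour species; rows with undefined
    survival (census gap ahead) are dropped.
    """
    df = transitions.dropna(subset=["survives"]).copy()
    _require(df, neighbours)
    df = _merge_climate(df, climate)
    X, names = _build_design(df, neighbours, climate_size_covariates,
                             year_size_slopes)
    model = sm.GLM(df["survives"].to_numpy(float), X,
                   family=sm.families.Binomial())
    res = model.fit(maxiter=200)
    params = _extract_linear(res.params, names, df, neighbours,
                             climate_size_covariates, SurvivalParams)
    out = FitResult(params, res.aic, res.llf, res.converged, res,
                    bse=dict(zip(names, res.bse)))
    _apply_stage2(params, out, climate, climate_covariates)
    return out


def fit_growth(transitions: pd.DataFrame, neighbours: Sequence[str],
               climate: ClimateTable | None = None,
               climate_covariates: Sequence[str] = (),
               climate_size_covariates: Sequence[str] = (),
               year_size_slopes: bool = False) -> FitResult:
    """Fit the growth mean by least squares and the variance function
    Var = a·exp(b·v̄) by a gamma fit to the squared residuals."""
    df = transitions.dropna(subset=["logarea_next"]).copy()
    _require(df, neighbours)
    df = _merge_climate(df, climate)
    X, names = _build_design(df, neighbours, climate_size_covariates,
                             year_size_slopes)
    y = df["logarea_next"].to_numpy(float)
    res = sm.OLS(y, X).fit()
    params = _extract_linear(res.params, names, df, neighbours,
                             climate_size_covariates, GrowthParams)
    vbar = res.fittedvalues
    resid2 = (y - vbar) ** 2
    if np.allclose(resid2, 0):
        params.var_a, params.var_b = 1e-12, 0.0
    else:
        # E[e²] = a·exp(b·v̄): gamma GLM, log link, on squared residuals
        Xv = np.column_stack([np.ones_like(vbar), vbar])
        vres = sm.GLM(np.maximum(resid2, 1e-300), Xv,
                      family=sm.families.Gamma(sm.families.links.Log())).fit()
        params.var_a = float(np.exp(vres.params[0]))
        params.var_b = float(vres.params[1])
    if params.var_a <= 0:
        raise ValueError("fitted growth variance is non-positive")
    out = FitResult(params, res.aic, res.llf, True, res,
                    bse=dict(zip(names, res.bse)))
    _apply_stage2(params, out, climate, climate_covariates)
    return out


def _require(df: pd.DataFrame, neighbours: Sequence[str]) -> None:
    missing = [m for m in neighbours if f"w_{m}" not in df.columns]
    if missing:
        raise ValueError(f"missing crowding columns for species {missing}")
    if df["year"].nunique() < 2:
        raise ValueError("need at least 2 years to fit year effects")
    if "species" in df.columns and df["species"].nunique() > 1:
        raise ValueError(
            "transitions mix species; vital-rate coefficients are species-"
            "specific — fit one focal species at a time")


def build_recruit_frame(counts: pd.DataFrame, species: Sequence[str]
                        ) -> pd.DataFrame:
    """Pair quadrat covers at year t with recruit counts at t+1.

    ``counts`` is the per quadrat × year × species output of
    ``tracking.recruit_counts``. Returns one row per quadrat × transition ×
    focal species with the recruit count ``y`` and wide cover columns
    ``cover_<sp>`` / group-mean columns ``gcover_<sp>``. Transitions whose
    arrival year immediately follows a census gap are excluded (restart
    years cannot distinguish recruits from survivors).
    """
    wide = counts.pivot_table(index=["site", "quadrat", "group", "year"],
                              columns="species", values="cover_cm2",
                              aggfunc="sum", fill_value=0.0)
    rec = counts.pivot_table(index=["site", "quadrat", "group", "year"],
                             columns="species", values="recruits",
                             aggfunc="sum", fill_value=0)
    for sp in species:
        if sp not in wide.columns:
            wide[sp] = 0.0
        if sp not in rec.columns:
            rec[sp] = 0
    wide = wide.reset_index()
    gmean = (wide.groupby(["site", "group", "year"])[list(species)]
             .transform("mean"))
    rows = []
    rec = rec.reset_index().set_index(["site", "quadrat", "year"])
    censused = wide.groupby(["site", "quadrat"])["year"].agg(set).to_dict()
    for i, r in wide.iterrows():
        nxt = (r["site"], r["quadrat"], r["year"] + 1)
        if nxt not in rec.index:
            continue
        yrs = censused[(r["site"], r["quadrat"])]
        if r["year"] not in yrs:  # defensive; wide rows come from censuses
            continue
        for sp in species:
            rows.append({
                "site": r["site"], "quadrat": r["quadrat"],
                "group": r["group"], "year": r["year"], "species": sp,
                "y": int(rec.loc[nxt, sp]),
                **{f"cover_{m}": float(r[m]) for m in species},
                **{f"gcover_{m}": float(gmean.loc[i, m]) for m in species},
            })
    return pd.DataFrame(rows)


def _recruit_design(df: pd.DataFrame, species: Sequence[str], p: float):
    Np = {m: effective_cover(df[f"cover_{m}"], df[f"gcover_{m}"], p)
          for m in species}
    focal = df["species"].to_numpy()
    Nj = np.array([Np[sp][pos] for pos, sp in enumerate(focal)])
    keep = Nj > 0
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    years = sorted(df["year"].unique())
    groups = sorted(df["group"].unique())
    for ycat in years[1:]:
        cols[f"year_{ycat}"] = (df["year"] == ycat).to_numpy(float)
    for g in groups[1:]:
        cols[f"group_{g}"] = (df["group"] == g).to_numpy(float)
    for m in species:
        cols[f"dd_{m}"] = np.sqrt(np.asarray(Np[m], dtype=float))
    names = list(cols)
    X = np.column_stack([cols[n] for n in names])
    return X[keep], names, np.log(Nj[keep]), df.loc[keep, "y"].to_numpy(int), keep


def fit_recruitment(recruit_frame: pd.DataFrame, focal: str,
                    species: Sequence[str],
                    climate: ClimateTable | None = None,
                    climate_covariates: Sequence[str] = (),
                    p_grid: Sequence[float] | None = None) -> FitResult:
    """Fit the negative-binomial recruitment model for one focal species.

    The mixing fraction p is profiled over ``p_grid`` (default 0…1 in steps
    of 0.1), refitting the count regression at each p and keeping the
    maximum-likelihood value. Climate effects are estimated in the same
    second stage as survival and growth: from a regression of the fitted
    per-year intercept deviations on the (year-level) covariates.
    """
    if p_grid is None:
        p_grid = np.linspace(0.0, 1.0, 11)
    df = recruit_frame[recruit_frame["species"] == focal].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no recruitment rows for species {focal!r}")
    best = None
    for p in p_grid:
        X, names, offset, y, keep = _recruit_design(df, species, p)
        if len(y) == 0:
            continue
        model = sm.NegativeBinomial(y, X, offset=offset)
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:  # singular design at this p
            continue
        if best is None or res.llf > best[1].llf:
            best = (p, res, names, df[keep])
    if best is None:
        raise RuntimeError("recruitment fit failed at every mixing fraction")
    p, res, names, dfk = best
    coef = dict(zip(names, res.params))
    years = sorted(dfk["year"].unique())
    groups = sorted(dfk["group"].unique())
    year_eff, ymean = _centered_effects(names, res.params, years, "year_")
    grp_eff, gmean = _centered_effects(names, res.params, groups, "group_")
    alpha = float(res.params[-1])  # statsmodels NB2 dispersion = 1/θ
    params = RecruitParams(
        intercept=coef["const"] + ymean + gmean,
        year_effects=year_eff,
        group_effects=grp_eff,
        dd={m: coef[f"dd_{m}"] for m in species},
        climate={},
        theta=1.0 / max(alpha, 1e-8),
        p=float(p),
    )
    converged = bool(res.mle_retvals.get("converged", True)) \
        if hasattr(res, "mle_retvals") else True
    out = FitResult(params, res.aic, res.llf, converged, res,
                    bse=dict(zip(names, res.bse)))
    if climate is not None and climate_covariates:
        eta, resid, se, _, shift = _stage2_climate(params.year_effects,
                                                   climate,
                                                   list(climate_covariates))
        params.climate = eta
        params.year_effects = resid
        params.intercept += shift
        for c in climate_covariates:
            out.bse[f"clim_{c}"] = se[c]
    return out


# ---------------------------------------------------------------------------
# stepwise climate-covariate selection


def candidate_climate_terms(include_interactions: bool = True) -> list[str]:
    terms = list(CLIMATE_COVARIATES)
    if include_interactions:
        terms += list(CLIMATE_INTERACTIONS)
    return terms


def select_climate_covariates(fit_fn: Callable[[Sequence[str]], float],
                              candidates: Sequence[str] | None = None,
                              include_interactions: bool = True
                              ) -> ClimateSelection:
    """Bidirectional stepwise AIC search over climate covariate subsets.

    ``fit_fn(subset)`` refits the vital-rate model with that covariate
    subset and returns its AIC. Interaction terms respect marginality: an
    interaction may enter only when both parents are present, and a parent
    may leave only after its interactions have left. Deterministic given
    the data.
    """
    if candidates is None:
        candidates = candidate_climate_terms(include_interactions)
    current: list[str] = []
    best_aic = fit_fn(current)
    trace = [("start", best_aic)]
    while True:
        moves: list[tuple[float, str, list[str]]] = []
        for c in candidates:
            if c in current:
                continue
            parents = CLIMATE_INTERACTIONS.get(c)
            if parents and not all(par in current for par in parents):
                continue
            moves.append((fit_fn(current + [c]), f"+{c}", current + [c]))
        for c in current:
            if any(c in par and inter in current
                   for inter, par in CLIMATE_INTERACTIONS.items()):
                continue
            reduced = [x for x in current if x != c]
            moves.append((fit_fn(reduced), f"-{c}", reduced))
        if not moves:
            break
        aic, action, subset = min(moves, key=lambda t: t[0])
        if aic >= best_aic - 1e-9:
            break
        best_aic, current = aic, subset
        trace.append((action, aic))
    return ClimateSelection(selected=current, trace=trace)


# ---------------------------------------------------------------------------
# share of interannual variation explained by climate


def variance_explained(X_constant: float, X_climate: float, X_full: float
                       ) -> float:
    """Proportion of temporal variability attributed to climate covariates:
    (X_constant − X_climate) / (X_constant − X_full), where X is the
    residual sum of squares (growth) or residual deviance (survival,
    recruitment) of the constant / climate-only / full model triplet.

    Clipped to [0, 1] with a warning when sampling noise inverts an
    expected ordering; NaN when constant and full models tie.
    """
    denom = X_constant - X_full
    if denom == 0:
        logger.warning("variance_explained undefined: X_constant == X_full")
        return float("nan")
    ratio = (X_constant - X_climate) / denom
    if not 0.0 <= ratio <= 1.0:
        logger.warning("variance_explained %.3f outside [0,1]; clipping", ratio)
        ratio = min(max(ratio, 0.0), 1.0)
    return float(ratio)


def _triplet_design(df: pd.DataFrame, neighbours: Sequence[str],
                    clim_cols: Sequence[str], mode: str) -> np.ndarray:
    """Design for the constant / climate / full model triplet.

    constant: no temporal terms at all; climate: climate main effects only;
    full: year dummies (which subsume any year-level covariate).
    """
    cols = [np.ones(len(df))]
    u = df["logarea"].to_numpy(float)
    for g in sorted(df["group"].unique())[1:]:
        cols.append((df["group"] == g).to_numpy(float))
    cols.append(u)
    for m in neighbours:
        wm = df[f"w_{m}"].to_numpy(float)
        cols.extend([wm, wm * u])
    if mode == "climate":
        for c in clim_cols:
            cols.append(df[c].to_numpy(float))
    elif mode == "full":
        for y in sorted(df["year"].unique())[1:]:
            cols.append((df["year"] == y).to_numpy(float))
    return np.column_stack(cols)


def fit_variance_explained(kind: str, data: pd.DataFrame,
                           neighbours: Sequence[str],
                           climate: ClimateTable,
                           climate_covariates: Sequence[str],
                           focal: str | None = None,
                           p: float = 1.0) -> dict:
    """Share of interannual vital-rate variation explained by climate.

    Fits the model triplet — (i) constant (no temporal terms), (ii)
    climate-only, (iii) full (year effects) — and applies the deviance-
    reduction ratio. ``data`` is a transition table for kind
    "survival"/"growth" or a recruit frame (with ``focal``) for
    "recruitment". X is the residual sum of squares for growth and the
    residual deviance (−2·loglik up to a constant) for the count models.
    """
    X = {}
    if kind in ("survival", "growth"):
        col = "survives" if kind == "survival" else "logarea_next"
        df = data.dropna(subset=[col]).copy()
        df = _merge_climate(df, climate)
        y = df[col].to_numpy(float)
        for mode in ("constant", "climate", "full"):
            D = _triplet_design(df, neighbours, climate_covariates, mode)
            if kind == "survival":
                res = sm.GLM(y, D, family=sm.families.Binomial()).fit(
                    maxiter=200)
                X[mode] = float(res.deviance)
            else:
                res = sm.OLS(y, D).fit()
                X[mode] = float(res.ssr)
    elif kind == "recruitment":
        if focal is None:
            raise ValueError("recruitment triplet needs a focal species")
        df = data[data["species"] == focal].reset_index(drop=True)
        df = _merge_climate(df, climate)
        species = neighbours
        Xd, names, offset, y, keep = _recruit_design(df, species, p)
        dfk = df[keep].reset_index(drop=True)
        base = [n for n in names if not n.startswith("year_")]
        idx = {n: i for i, n in enumerate(names)}
        for mode in ("constant", "climate", "full"):
            keep_cols = list(names) if mode == "full" else list(base)
            D = Xd[:, [idx[n] for n in keep_cols]]
            if mode == "climate":
                clim = climate.with_interactions()
                D = np.column_stack(
                    [D] + [dfk["year"].map(clim[c]).to_numpy(float)
                           for c in climate_covariates])
            res = sm.NegativeBinomial(y, D, offset=offset).fit(disp=0,
                                                               maxiter=200)
            X[mode] = float(-2.0 * res.llf)
    else:
        raise ValueError(f"unknown vital rate kind {kind!r}")
    prop = variance_explained(X["constant"], X["climate"], X["full"])
    return {"X_constant": X["constant"], "X_climate": X["climate"],
            "X_full": X["full"], "proportion": prop}


# ---------------------------------------------------------------------------
# serialization


def params_to_yaml_dict(params) -> dict:
    d = params.to_dict()
    d["kind"] = type(params).__name__
    return d


def params_from_yaml_dict(d: dict):
    kinds = {"SurvivalParams": SurvivalParams, "GrowthParams": GrowthParams,
             "RecruitParams": RecruitParams}
    d = dict(d)
    cls = kinds[d.pop("kind")]
    return cls(**d)
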