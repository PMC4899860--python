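"""Climate-perturbation experiments and the full/direct/indirect
decomposition of species' responses.

A perturbation raises the means of the precipitation or temperature
covariates by a small amount (1% by default) or inflates the variability
of all covariates (variance × 1.10 by default, means unchanged). For each
community:

* the **full effect** of a perturbation is the change in a species'
  equilibrium cover when every species experiences the perturbed climate;
* the **direct effect** is the change when only the focal species
  experiences the perturbed climate while its competitors see the observed
  climate;
* the **indirect effect** — mediated by competitors' responses — is the
  difference, indirect = full − direct, which holds exactly because all
  paired simulations share the same sequence of randomly drawn climate
  years and year-effect years (common random numbers).

Raw effects (cover units) are rescaled by each species' baseline
equilibrium cover to give proportional effects, and compared through
log(|proportional indirect| / |proportional direct|): positive log ratios
mean indirect effects dominate. Across communities, variation in the
magnitude of raw indirect effects is synthesized with a linear mixed
model whose fixed effects are the NFD slope and the community-level
variance of raw direct effects, with random intercepts for site and for
perturbation nested within site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .data_io import (ClimateTable, PRECIP_COVARIATES, TEMP_COVARIATES,
                      CLIMATE_COVARIATES)
from .ipm import IPM

logger = logging.getLogger("quadratdyn")

PERTURBATION_KINDS = ("precip-mean", "temp-mean", "variability")


@dataclass(frozen=True)
class Perturbation:
    kind: str                 # precip-mean | temp-mean | variability
    magnitude_pct: float      # 1 for mean shifts, 10 for variance inflation
    temp_mode: str = "additive"

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.magnitude_pct < 0:
            raise ValueError("perturbation magnitude must be ≥ 0")


def perturb_climate(table: ClimateTable, p: Perturbation) -> ClimateTable:
    """Return a perturbed copy of the climate table.

    precip-mean: precipitation covariates scaled by (1 + pct/100).
    temp-mean: temperature covariates shifted by pct/100 of their observed
    site mean (additive, since multiplicative °C scaling is origin-
    dependent; ``temp_mode="multiplicative"`` scales instead).
    variability: every covariate x → mean + √(1+pct/100)·(x − mean),
    which multiplies each sample variance by exactly (1+pct/100) and
    leaves every mean unchanged. Interaction columns are always recomputed
    downstream from the perturbed base covariates.
    """
    data = table.data.copy()
    f = p.magnitude_pct / 100.0
    if p.kind == "precip-mean":
        for c in PRECIP_COVARIATES:
            data[c] = data[c] * (1.0 + f)
    elif p.kind == "temp-mean":
        for c in TEMP_COVARIATES:
            if p.temp_mode == "additive":
                data[c] = data[c] + f * data[c].mean()
            else:
                data[c] = data[c] * (1.0 + f)
    else:
        scale = np.sqrt(1.0 + f)
        for c in CLIMATE_COVARIATES:
            mu = data[c].mean()
            data[c] = mu + scale * (data[c] - mu)
    return ClimateTable(site=table.site, data=data)


@dataclass
class PerturbationResult:
    species: str
    perturbation: str
    baseline_cover: float
    full: float
    direct: float
    indirect: float
    prop_full: float
    prop_direct: float
    prop_indirect: float
    log_ratio: float  # log(|prop indirect| / |prop direct|); NaN if direct=0


def decompose(species: str, perturbation: str, full: float, direct: float,
              baseline: float) -> PerturbationResult:
    """Assemble a PerturbationResult: indirect = full − direct exactly,
    proportional effects divide by baseline cover, and the log ratio is
    positive when indirect effects are stronger than direct effects."""
    if not baseline > 0:
        raise ValueError("baseline cover must be > 0")
    indirect = full - direct
    prop_full = full / baseline
    prop_direct = direct / baseline
    prop_indirect = indirect / baseline
    if prop_direct == 0.0:
        log_ratio = float("nan")
        logger.warning("direct effect is 0 for %s/%s: log ratio undefined",
                       species, perturbation)
    elif prop_indirect == 0.0:
        log_ratio = -np.inf
    else:
        log_ratio = float(np.log(abs(prop_indirect) / abs(prop_direct)))
    return PerturbationResult(species, perturbation, baseline, full, direct,
                              indirect, prop_full, prop_direct, prop_indirect,
                              log_ratio)


class PerturbationExperiment:
    """Paired baseline / full / direct simulations for one community.

    All simulations replay the same pre-drawn sequence of climate-year and
    year-effect-year indices (common random numbers), so a zero-magnitude
    perturbation produces exactly zero effects and the decomposition
    identity holds to machine precision.
    """

    def __init__(self, ipm: IPM, climate: ClimateTable,
                 year_effect_years: Sequence | None = None,
                 burn_in: int = 500, window: int = 2000,
                 init_cover: float = 1.0):
        self.ipm = ipm
        self.climate = climate
        self.year_effect_years = year_effect_years
        self.burn_in = burn_in
        self.window = window
        self.init_cover = init_cover

    def _draw_sequences(self, rng: np.random.Generator):
        n = self.burn_in + self.window
        climate_idx = rng.integers(len(self.climate.years), size=n)
        if self.year_effect_years is None:
            effect_idx = None
        else:
            effect_idx = rng.integers(len(self.year_effect_years), size=n)
        return climate_idx, effect_idx

    def _run(self, tables: Mapping[str, ClimateTable] | ClimateTable,
             climate_idx: np.ndarray, effect_idx: np.ndarray | None
             ) -> dict[str, float]:
        """Equilibrium covers under per-species (or shared) climate tables,
        replaying the common random-number sequences."""
        ipm = self.ipm
        from .ibm import YearDraw
        state = ipm.low_density_state(self.init_cover)
        sums = {sp: 0.0 for sp in ipm.species}
        shared = isinstance(tables, ClimateTable)
        for t in range(self.burn_in + self.window):
            yr_pos = climate_idx[t]
            if shared:
                C = tables.row(tables.years[yr_pos])
            else:
                C = {sp: tab.row(tab.years[yr_pos])
                     for sp, tab in tables.items()}
            if effect_idx is None:
                draw = YearDraw.zero(ipm.species)
            else:
                draw = YearDraw.from_year(
                    ipm.params, self.year_effect_years[effect_idx[t]])
            state = ipm.step(state, C, draw)
            if t >= self.burn_in:
                for sp, c in ipm.cover(state).items():
                    sums[sp] += c
        return {sp: s / self.window for sp, s in sums.items()}

    def run(self, perturbations: Sequence[Perturbation],
            rng: np.random.Generator) -> pd.DataFrame:
        """Baseline, full and per-focal direct simulations for each
        perturbation; returns one PerturbationResult row per species ×
        perturbation, with the community-level variance of raw direct
        effects attached identically to every species row."""
        climate_idx, effect_idx = self._draw_sequences(rng)
        baseline = self._run(self.climate, climate_idx, effect_idx)
        for sp, c in baseline.items():
            if c <= 0:
                raise RuntimeError(f"species {sp} extinct at baseline")
        rows = []
        for p in perturbations:
            perturbed = perturb_climate(self.climate, p)
            full_cover = self._run(perturbed, climate_idx, effect_idx)
            direct = {}
            for focal in self.ipm.species:
                tables = {sp: (perturbed if sp == focal else self.climate)
                          for sp in self.ipm.species}
                mixed = self._run(tables, climate_idx, effect_idx)
                direct[focal] = mixed[focal] - baseline[focal]
            results = [decompose(sp, p.kind,
                                 full_cover[sp] - baseline[sp],
                                 direct[sp], baseline[sp])
                       for sp in self.ipm.species]
            var_direct = direct_effect_variance(
                [r.direct for r in results])
            for r in results:
                d = r.__dict__.copy()
                d["var_direct"] = var_direct
                rows.append(d)
        return pd.DataFrame(rows)


def direct_effect_variance(direct_effects: Sequence[float]) -> float:
    """Sample (n−1) variance of raw direct effects across the species of
    one site × perturbation; NaN with fewer than two species."""
    if len(direct_effects) < 2:
        return float("nan")
    return float(np.var(direct_effects, ddof=1))


def indirect_effects_model(results: pd.DataFrame,
                           response: str = "abs_indirect",
                           allow_fallback: bool = True):
    """Mixed-effects synthesis across sites: |raw indirect| ~ NFD slope +
    variance of raw direct effects, with random intercepts for site and for
    perturbation nested within site, fit by maximum likelihood.

    ``results`` needs columns ``abs_indirect`` (or ``indirect``), ``nfd``,
    ``var_direct``, ``site`` and ``perturbation``. Returns a coefficient
    table (estimate, SE, df, t, p) for the intercept and the two fixed
    effects. A singular random-effect fit falls back, with a warning, to
    site-only random intercepts and finally to ordinary least squares.
    """
    df = results.copy()
    if response not in df.columns:
        df[response] = df["indirect"].abs()
    df["site_pert"] = (df["site"].astype(str) + ":"
                       + df["perturbation"].astype(str))
    fixed = response + " ~ nfd + var_direct"
    attempts = [
        ("site + perturbation-in-site", dict(
            groups="site", re_formula="1",
            vc_formula={"pert": "0 + C(site_pert)"})),
        ("site-only", dict(groups="site", re_formula="1")),
    ]
    fitted = None
    import warnings as _warnings
    for label, kw in attempts:
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                model = smf.mixedlm(fixed, df, **kw)
                res = model.fit(reml=False)
            if np.all(np.isfinite(res.bse_fe)):
                fitted = (label, res)
                break
            logger.warning("mixed model (%s) singular; falling back", label)
        except Exception as exc:
            logger.warning("mixed model (%s) failed (%s); falling back",
                           label, exc)
        if not allow_fallback:
            break
    if fitted is not None:
        label, res = fitted
        names = list(res.fe_params.index)
        est, se = res.fe_params.to_numpy(), res.bse_fe.to_numpy()
        # residual df after fixed effects and grouping levels
        dof = len(df) - len(names) - df["site"].nunique()
        tval = est / se
        from scipy.stats import t as tdist
        pval = 2 * tdist.sf(np.abs(tval), dof)
        out = pd.DataFrame({"term": names, "estimate": est, "se": se,
                            "df": dof, "t": tval, "p": pval})
        out.attrs["structure"] = label
        return out
    logger.warning("falling back to ordinary least squares")
    res = smf.ols(fixed, df).fit()
    out = pd.DataFrame({"term": res.params.index, "estimate": res.params.values,
                        "se": res.bse.values, "df": res.df_resid,
                        "t": res.tvalues.values, "p": res.pvalues.values})
    out.attrs["structure"] = "ols"
    return out
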