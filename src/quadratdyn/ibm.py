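"""Spatially explicit, demographically stochastic individual-based model.

The IBM simulates every genet in a quadrat: survival is a Bernoulli draw on
the fitted survival probability, surviving genets draw a new log size from
a normal with the fitted growth mean and size-dependent variance, and
per-species recruit counts are negative-binomial draws on the fitted
recruitment intensity, with each recruit placed at a uniform-random
location at the point-plant size (0.25 cm²). Crowding is recomputed from
the current plant geometry every step with absorbing boundaries: there is
no wraparound, neighbours outside the quadrat simply do not exist, and
recruits land strictly inside.

Used to validate the fitted models against observed cover trajectories
(historical mode) and as the ground-truth generator behind the synthetic
chart-quadrat archives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crowding import AlphaMatrix
from .data_io import ClimateTable, QUADRAT_CM
from .tracking import POINT_AREA_CM2
from .vital_rates import (GrowthParams, RecruitParams, SurvivalParams,
                          recruit_intensity, sample_recruits, survival_prob)

logger = logging.getLogger("quadratdyn")

RECRUIT_LOG_SIZE = float(np.log(POINT_AREA_CM2))


@dataclass
class SpeciesParams:
    survival: SurvivalParams
    growth: GrowthParams
    recruit: RecruitParams


@dataclass
class CommunityParams:
    """Fitted (or ground-truth) parameters for every species at one site."""

    species: dict[str, SpeciesParams]
    alphas: AlphaMatrix

    def codes(self) -> list[str]:
        return list(self.species)


@dataclass
class YearDraw:
    """One jointly drawn set of year effects for every species/vital rate.

    ``survival``/``growth`` map species → (intercept deviation, size-slope
    deviation); ``recruit`` maps species → intercept deviation. The zero
    draw gives the "climatic covariates only" simulation mode.
    """

    survival: dict[str, tuple[float, float]] = field(default_factory=dict)
    growth: dict[str, tuple[float, float]] = field(default_factory=dict)
    recruit: dict[str, float] = field(default_factory=dict)

    @classmethod
    def zero(cls, species: Sequence[str]) -> "YearDraw":
        return cls(survival={s: (0.0, 0.0) for s in species},
                   growth={s: (0.0, 0.0) for s in species},
                   recruit={s: 0.0 for s in species})

    @classmethod
    def from_year(cls, params: CommunityParams, year) -> "YearDraw":
        out = cls()
        for sp, p in params.species.items():
            out.survival[sp] = (p.survival.year_effects.get(year, 0.0),
                                p.survival.year_size_slopes.get(year, 0.0))
            out.growth[sp] = (p.growth.year_effects.get(year, 0.0),
                              p.growth.year_size_slopes.get(year, 0.0))
            out.recruit[sp] = p.recruit.year_effects.get(year, 0.0)
        return out


@dataclass
class IBMState:
    """All modelled plants in one quadrat at one time step."""

    species: np.ndarray            # object array of species codes
    genet_id: np.ndarray           # int
    u: np.ndarray                  # log area (cm², natural log)
    x: np.ndarray
    y: np.ndarray
    extent_cm: float = QUADRAT_CM
    step: int = 0
    next_id: int = 0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.u) and not np.all(np.isfinite(self.u)):
            raise ValueError("non-finite sizes in IBM state")

    def __len__(self) -> int:
        return len(self.u)

    @classmethod
    def empty(cls, extent_cm: float = QUADRAT_CM) -> "IBMState":
        z = np.array([])
        return cls(np.array([], dtype=object), np.array([], dtype=int),
                   z, z.copy(), z.copy(), extent_cm)

    @classmethod
    def from_records(cls, records: pd.DataFrame,
                     extent_cm: float = QUADRAT_CM) -> "IBMState":
        return cls(records["species"].to_numpy(object),
                   records["genet_id"].to_numpy(int),
                   np.log(records["area_cm2"].to_numpy(float)),
                   records["x"].to_numpy(float),
                   records["y"].to_numpy(float),
                   extent_cm,
                   next_id=int(records["genet_id"].max()) + 1 if len(records) else 0)


def cover_of(state: IBMState) -> dict[str, float]:
    """Per-species cover: Σ exp(u) over the species' individuals (cm²)."""
    out: dict[str, float] = {}
    for sp in np.unique(state.species):
        out[str(sp)] = float(np.exp(state.u[state.species == sp]).sum())
    return out


def cover_fraction(state: IBMState) -> dict[str, float]:
    area = state.extent_cm ** 2
    return {sp: c / area for sp, c in cover_of(state).items()}


def _crowding_vectors(state: IBMState, alphas: AlphaMatrix,
                      species: Sequence[str]) -> dict[str, np.ndarray]:
    """w_<m> for every individual, vectorized over the pairwise d² matrix."""
    n = len(state)
    w = {m: np.zeros(n) for m in species}
    if n < 2:
        return w
    dx = state.x[:, None] - state.x[None, :]
    dy = state.y[:, None] - state.y[None, :]
    d2 = dx * dx + dy * dy
    np.fill_diagonal(d2, np.inf)
    area = np.exp(state.u)
    for m in species:
        mask = state.species == m
        if not mask.any():
            continue
        for j in np.unique(state.species):
            a = alphas.get(str(j), m)
            rows = state.species == j
            w[m][rows] = (area[mask] *
                          np.exp(-a * d2[np.ix_(rows, mask)])).sum(axis=1)
    return w


def ibm_step(state: IBMState, params: CommunityParams,
             C: Mapping[str, float] | None, year_draw: YearDraw,
             rng: np.random.Generator, group=None) -> IBMState:
    """Advance the IBM one annual transition.

    Recruitment intensities are computed from the time-t community (a
    recruit's parents are the plants present before mortality acts), with
    effective cover taken as the quadrat's own cover.
    """
    species = params.codes()
    covers = cover_of(state)
    Nprime = {sp: covers.get(sp, 0.0) for sp in species}

    keep_sp, keep_id, keep_u, keep_x, keep_y = [], [], [], [], []
    if len(state):
        w = _crowding_vectors(state, params.alphas, species)
        for sp in species:
            rows = np.flatnonzero(state.species == sp)
            if not len(rows):
                continue
            p = params.species[sp]
            u = state.u[rows]
            wi = {m: w[m][rows] for m in species}
            s_prob = survival_prob(u, C, wi, p.survival, group=group,
                                   year_draw=year_draw.survival[sp])
            alive = rows[rng.random(len(rows)) < s_prob]
            if not len(alive):
                continue
            ua = state.u[alive]
            wa = {m: w[m][alive] for m in species}
            vbar = p.growth.linear_predictor(ua, C, wa, group=group,
                                             year_draw=year_draw.growth[sp])
            var = p.growth.variance(vbar)
            new_u = rng.normal(vbar, np.sqrt(var))
            keep_sp.append(state.species[alive])
            keep_id.append(state.genet_id[alive])
            keep_u.append(new_u)
            keep_x.append(state.x[alive])
            keep_y.append(state.y[alive])

    next_id = state.next_id
    for sp in species:
        p = params.species[sp]
        lam = recruit_intensity(sp, Nprime, C, p.recruit, group=group,
                                year_draw=year_draw.recruit[sp])
        n_rec = int(sample_recruits(lam, p.recruit.theta, rng))
        if n_rec == 0:
            continue
        keep_sp.append(np.full(n_rec, sp, dtype=object))
        keep_id.append(np.arange(next_id, next_id + n_rec))
        next_id += n_rec
        keep_u.append(np.full(n_rec, RECRUIT_LOG_SIZE))
        keep_x.append(rng.uniform(0, state.extent_cm, n_rec))
        keep_y.append(rng.uniform(0, state.extent_cm, n_rec))

    if keep_sp:
        new = IBMState(np.concatenate(keep_sp), np.concatenate(keep_id),
                       np.concatenate(keep_u), np.concatenate(keep_x),
                       np.concatenate(keep_y), state.extent_cm,
                       state.step + 1, next_id)
    else:
        new = IBMState.empty(state.extent_cm)
        new.step = state.step + 1
        new.next_id = next_id
    return new


def run_free(state: IBMState, params: CommunityParams,
             climate: ClimateTable | None, n_steps: int,
             rng: np.random.Generator, year_effect_years: Sequence | None = None,
             climate_only: bool = False, group=None) -> list[IBMState]:
    """Free-running IBM: each step draws a random observed climate year and,
    independently, one set of random year effects."""
    species = params.codes()
    traj = [state]
    for _ in range(n_steps):
        C = None
        if climate is not None:
            yr = rng.choice(climate.years)
            C = climate.row(yr)
        if climate_only or year_effect_years is None:
            draw = YearDraw.zero(species)
        else:
            draw = YearDraw.from_year(
                params, year_effect_years[rng.integers(len(year_effect_years))])
        state = ibm_step(state, params, C, draw, rng, group=group)
        traj.append(state)
    return traj


def simulate_historical(records: pd.DataFrame, params: CommunityParams,
                        climate: ClimateTable, n_reps: int = 50,
                        rng: np.random.Generator | None = None,
                        climate_only: bool = False,
                        extent_cm: float = QUADRAT_CM) -> pd.DataFrame:
    """Hindcast one quadrat's observed cover series with the IBM.

    The IBM is initialized with the plants observed in the first census
    year and projected forward drawing the year-specific fitted effects in
    chronological order (or zero year effects in ``climate_only`` mode);
    after a census gap it is re-initialized from the first observation
    following the gap. Returns per-year per-species mean predicted cover
    (averaged over ``n_reps`` replicates) alongside observed cover.
    """
    if rng is None:
        rng = np.random.default_rng()
    years = np.sort(records["year"].unique())
    group = records["group"].iloc[0] if "group" in records else None
    species = params.codes()
    for yr in years[:-1]:
        if yr + 1 not in years:
            continue
        if yr not in climate.years:
            raise KeyError(f"no climate row for historical year {yr}")
        if not climate_only:
            for sp, p in params.species.items():
                if yr not in p.survival.year_effects:
                    raise KeyError(
                        f"no fitted year effect for {sp} in year {yr}")

    preds = {yr: {sp: [] for sp in species} for yr in years}
    for _ in range(n_reps):
        state = None
        for i, yr in enumerate(years):
            if state is None or years[i - 1] != yr - 1:
                obs = records[records["year"] == yr]
                state = IBMState.from_records(obs, extent_cm)
            cov = cover_of(state)
            for sp in species:
                preds[yr][sp].append(cov.get(sp, 0.0))
            if i + 1 < len(years) and years[i + 1] == yr + 1:
                draw = (YearDraw.zero(species) if climate_only
                        else YearDraw.from_year(params, yr))
                state = ibm_step(state, params, climate.row(yr), draw, rng,
                                 group=group)
            else:
                state = None

    rows = []
    obs_cover = (records.groupby(["year", "species"])["area_cm2"].sum()
                 .to_dict())
    for yr in years:
        for sp in species:
            rows.append({"year": int(yr), "species": sp,
                         "predicted_cover": float(np.mean(preds[yr][sp])),
                         "observed_cover": float(obs_cover.get((yr, sp), 0.0))})
    return pd.DataFrame(rows)
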