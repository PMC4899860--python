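"""Invasion growth rates, equilibrium frequencies, and the negative-
frequency-dependence (NFD) slope used as a community-level niche-difference
proxy.

A species' per-capita growth rate is 1 (zero on the log scale) at its
equilibrium frequency. The NFD slope is the slope of the line through the
two points the simulations pin down: (frequency ≈ 0, invasion growth rate)
and (equilibrium frequency, 0); the more negative the slope, the stronger
the stabilizing niche difference between the focal species and the rest of
the community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import ClimateTable
from .ipm import IPM, IPMState

logger = logging.getLogger("quadratdyn")


@dataclass
class NFDResult:
    species: str
    equilibrium_frequency: float
    invasion_growth_rate: float   # log scale, per step
    igr_se: float                 # Monte-Carlo SE of the IGR estimate
    nfd_slope: float


def equilibrium_frequency(species: str, covers: dict[str, float]) -> float:
    """Relative cover of one species in the community; NaN if empty."""
    total = sum(covers.values())
    if total <= 0:
        return float("nan")
    return covers[species] / total


def nfd_slope(f_eq: float, igr: float) -> float:
    """Slope of the line through (≈0, IGR) and (f_eq, 0): −IGR / f_eq."""
    if not f_eq > 0:
        return float("nan")
    return -igr / f_eq


def invasion_growth_rate(ipm: IPM, focal: str,
                         rng: np.random.Generator,
                         climate: ClimateTable | None = None,
                         year_effect_years: Sequence | None = None,
                         n_steps: int = 1000,
                         burn_in: int = 500,
                         invasion_cover: float = 1e-6
                         ) -> tuple[float, float, IPMState]:
    """Estimate the focal species' invasion growth rate against residents.

    The community minus the focal species is first run to its stochastic
    equilibrium. The focal is then introduced at a cover of
    ``invasion_cover`` (initially as a recruit-size point mass); at each of
    ``n_steps`` steps the whole community advances one transition under a
    random climate/year-effect draw, the focal's log cover ratio
    log(C_{t+1}/C_t) is recorded, and its cover is rescaled back to
    ``invasion_cover`` — preserving its evolved size structure — so it never
    influences the residents or itself. The IGR is the arithmetic mean of
    the step log growth rates (the log of the geometric mean growth rate);
    the second return value is its naive Monte-Carlo standard error.
    """
    residents = [sp for sp in ipm.species if sp != focal]
    if residents:
        state = ipm.low_density_state(species=residents)
        state = ipm.run_stochastic(state, burn_in, rng, climate,
                                   year_effect_years)
        if all(ipm.cover(state)[sp] < 1e-12 for sp in residents):
            raise RuntimeError("resident community collapsed before invasion")
    else:
        state = ipm.zero_state()
    state = dict(state)
    state[focal] = ipm.point_mass(focal, invasion_cover)

    log_rates = []
    for _ in range(n_steps):
        C, draw = ipm.draw_environment(climate, year_effect_years, rng)
        new = ipm.step(state, C, draw)
        c_new = ipm.cover(new)[focal]
        if c_new <= 0:
            log_rates.append(-np.inf)
            state = new
            state[focal] = ipm.point_mass(focal, invasion_cover)
            continue
        log_rates.append(float(np.log(c_new / invasion_cover)))
        # rescale the focal back to invasion cover, keeping its structure
        state = new
        state[focal] = new[focal] * (invasion_cover / c_new)
        if residents and all(ipm.cover(state)[sp] < 1e-12 for sp in residents):
            raise RuntimeError("resident community collapsed during invasion")
    log_rates = np.asarray(log_rates)
    igr = float(np.mean(log_rates))
    se = float(np.std(log_rates, ddof=1) / np.sqrt(len(log_rates)))
    return igr, se, state


def resident_growth_rate(ipm: IPM, rng: np.random.Generator,
                         climate: ClimateTable | None = None,
                         year_effect_years: Sequence | None = None,
                         burn_in: int = 500, n_steps: int = 1000
                         ) -> dict[str, tuple[float, float]]:
    """Mean per-step log cover growth of each resident at stochastic
    equilibrium, with its Monte-Carlo SE.

    At its equilibrium frequency a species' per-capita growth rate is 1
    (zero on the log scale), so these means should all be ≈ 0 — the anchor
    point of the negative-frequency-dependence line.
    """
    state = ipm.low_density_state()
    state = ipm.run_stochastic(state, burn_in, rng, climate,
                               year_effect_years)
    rates = {sp: [] for sp in ipm.species}
    for _ in range(n_steps):
        C, draw = ipm.draw_environment(climate, year_effect_years, rng)
        before = ipm.cover(state)
        state = ipm.step(state, C, draw)
        after = ipm.cover(state)
        for sp in ipm.species:
            if before[sp] > 0 and after[sp] > 0:
                rates[sp].append(np.log(after[sp] / before[sp]))
    return {sp: (float(np.mean(r)),
                 float(np.std(r, ddof=1) / np.sqrt(len(r))))
            for sp, r in rates.items()}


def nfd_analysis(ipm: IPM, rng: np.random.Generator,
                 climate: ClimateTable | None = None,
                 year_effect_years: Sequence | None = None,
                 n_steps: int = 1000, burn_in: int | None = None,
                 window: int | None = None,
                 invasion_cover: float = 1e-6) -> list[NFDResult]:
    """Full NFD workflow: equilibrium frequencies from a community run,
    then one invasion experiment per species."""
    kw = {}
    if burn_in is not None:
        kw["burn_in"] = burn_in
    if window is not None:
        kw["window"] = window
    eq = ipm.equilibrium_cover(rng, climate, year_effect_years, **kw)
    results = []
    for sp in ipm.species:
        f_eq = equilibrium_frequency(sp, eq.cover)
        igr, se, _ = invasion_growth_rate(
            ipm, sp, rng, climate, year_effect_years, n_steps=n_steps,
            burn_in=kw.get("burn_in", 500), invasion_cover=invasion_cover)
        results.append(NFDResult(sp, f_eq, igr, se, nfd_slope(f_eq, igr)))
        logger.info("NFD %s: f_eq=%.3f IGR=%.4f slope=%.3f",
                    sp, f_eq, igr, nfd_slope(f_eq, igr))
    return results
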