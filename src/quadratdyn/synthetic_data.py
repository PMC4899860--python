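"""Ground-truth-parameterized synthetic inputs for every pipeline stage.

The generator emulates the two kinds of study inputs: (a) per-site climate
covariate series — five covariates drawn independently per year, with
controllable means and variances and no autocorrelation, matching the
simulation protocol's independent annual draws; and (b) chart-quadrat map
archives — produced by running the spatially explicit IBM from known
("ground truth") vital-rate parameters and rendering each genet's circle
into the polygon table dialect, keeping the true identities aside so that
the tracking algorithm can be scored against them.

Scenario registry (all pre-validated to persist over 100 IBM steps):

* ``symmetric-2sp`` — two identical species with interspecific interaction
  coefficients weaker than intraspecific ones; equilibrium frequencies 0.5.
* ``neutral-2sp`` — identical species with inter = intra everywhere; an
  invader is demographically indistinguishable from the resident, so the
  self-invasion growth rate is ≈ 0.
* ``niche-partitioned`` — strongly reduced interspecific coefficients;
  strong negative frequency dependence expected.
* ``neutral-ish`` — interspecific coefficients close to intraspecific;
  weak negative frequency dependence expected.
* ``pure-indirect`` — a climate-insensitive focal species strongly
  suppressed by a climate-sensitive competitor: climate perturbations
  reach the focal almost entirely through the competitor.
* ``variance-gradient`` — two species with opposite-signed climate
  effects, so one responds positively and the other negatively to the
  same perturbation.
* ``single-species`` — one species alone (full effect = direct effect).
* ``sparse-tracking`` — a single sparse, slowly recruiting species whose
  genets do not move, used to score identity tracking.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, box

from .crowding import AlphaMatrix
from .data_io import CLIMATE_COVARIATES, ClimateTable, QuadratMap, QUADRAT_CM
from .ibm import CommunityParams, IBMState, SpeciesParams, YearDraw, ibm_step
from .tracking import POINT_AREA_CM2
from .vital_rates import (GrowthParams, RecruitParams, SurvivalParams,
                          growth_moments, survival_prob)

logger = logging.getLogger("quadratdyn")

#: realistic semi-arid covariate targets (mm for precipitation, °C for
#: temperature): prior water-year total, critical-season amounts in years
#: 1 and 2, critical-season mean temperatures in years 1 and 2
DEFAULT_CLIMATE_MEANS = {"pptLag": 300.0, "ppt1": 150.0, "ppt2": 150.0,
                         "T1": 10.0, "T2": 16.0}
DEFAULT_CLIMATE_SDS = {"pptLag": 60.0, "ppt1": 40.0, "ppt2": 40.0,
                       "T1": 1.2, "T2": 1.2}


def generate_climate(n_years: int,
                     means: Mapping[str, float] | None = None,
                     sds: Mapping[str, float] | None = None,
                     rng: np.random.Generator | None = None,
                     site: str = "synthetic", start_year: int = 2000
                     ) -> ClimateTable:
    """Independent normal draws per covariate per year (no autocorrelation)."""
    means = dict(DEFAULT_CLIMATE_MEANS if means is None else means)
    sds = dict(DEFAULT_CLIMATE_SDS if sds is None else sds)
    if any(s < 0 for s in sds.values()):
        raise ValueError("climate sds must be ≥ 0")
    if rng is None:
        rng = np.random.default_rng()
    years = np.arange(start_year, start_year + n_years)
    data = {c: means[c] + sds[c] * rng.standard_normal(n_years)
            for c in CLIMATE_COVARIATES}
    return ClimateTable(site=site,
                        data=pd.DataFrame(data, index=pd.Index(years,
                                                               name="year")))


@dataclass
class GroundTruth:
    """A pre-validated parameter set plus its climate-generator settings."""

    name: str
    community: CommunityParams
    climate_means: dict = field(default_factory=lambda: dict(DEFAULT_CLIMATE_MEANS))
    climate_sds: dict = field(default_factory=lambda: dict(DEFAULT_CLIMATE_SDS))
    #: SDs of the normal year-effect deviations per vital rate
    year_sd: dict = field(default_factory=lambda: {
        "survival": 0.25, "growth": 0.12, "recruit": 0.35})
    group_sd: float = 0.1
    init_per_species: int = 20
    init_log_size: tuple[float, float] = (np.log(5.0), 0.8)
    #: identical-species scenarios share one year-effect draw across species
    #: (clones must respond identically to the same year)
    shared_year_effects: bool = False


def _base_species(neighbours: Sequence[str], intra: str,
                  surv_inter: float, grow_inter: float, rec_inter: float,
                  eta_s: Mapping[str, float] | None = None,
                  eta_g: Mapping[str, float] | None = None,
                  eta_r: Mapping[str, float] | None = None,
                  means: Mapping[str, float] = DEFAULT_CLIMATE_MEANS
                  ) -> SpeciesParams:
    """Baseline perennial-grass parameter set.

    Intercepts are adjusted so that the stated values hold at the mean
    climate (climate covariates enter on their natural scales)."""
    eta_s = dict(eta_s or {})
    eta_g = dict(eta_g or {})
    eta_r = dict(eta_r or {})

    def at_mean(base, eta):
        return base - sum(v * means[c] for c, v in eta.items())

    crowd_s = {m: (-0.02 if m == intra else surv_inter) for m in neighbours}
    crowd_g = {m: (-0.008 if m == intra else grow_inter) for m in neighbours}
    dd = {m: (-0.12 if m == intra else rec_inter) for m in neighbours}
    surv = SurvivalParams(intercept=at_mean(1.5, eta_s), size=0.8,
                          crowding=crowd_s,
                          crowding_size={m: 0.0 for m in neighbours},
                          climate=eta_s, climate_size={})
    grow = GrowthParams(intercept=at_mean(0.35, eta_g), size=0.9,
                        crowding=crowd_g,
                        crowding_size={m: 0.0 for m in neighbours},
                        climate=eta_g, climate_size={},
                        var_a=0.15, var_b=0.0)
    rec = RecruitParams(intercept=at_mean(1.0, eta_r), dd=dd,
                        climate=eta_r, theta=2.0, p=1.0)
    return SpeciesParams(surv, grow, rec)


def two_species_overlap(rho: float, alpha: float = 0.05,
                        eta_scale: float = 1.0) -> GroundTruth:
    """Two identical species whose interspecific coefficients are ``rho``
    times the intraspecific ones (ρ → 1 approaches neutrality; small ρ
    gives strong niche partitioning)."""
    spp = ["A", "B"]
    eta_s = {"ppt1": 0.004 * eta_scale}
    eta_g = {"ppt1": 0.003 * eta_scale}
    eta_r = {"pptLag": 0.003 * eta_scale}
    community = CommunityParams(
        species={sp: _base_species(spp, sp, -0.02 * rho, -0.008 * rho,
                                   -0.12 * rho, eta_s, eta_g, eta_r)
                 for sp in spp},
        alphas=AlphaMatrix.uniform(spp, alpha))
    return GroundTruth(name=f"overlap-{rho:g}", community=community,
                       shared_year_effects=True)


def _pure_indirect() -> GroundTruth:
    spp = ["FOC", "CMP"]
    # focal: climate-blind, suppressed by the competitor (but persisting)
    focal = _base_species(spp, "FOC", surv_inter=-0.008, grow_inter=-0.003,
                          rec_inter=-0.012)
    # competitor: climate-sensitive, barely affected by the focal
    comp = _base_species(spp, "CMP", surv_inter=-0.002, grow_inter=-0.001,
                         rec_inter=-0.01,
                         eta_s={"ppt1": 0.008}, eta_g={"ppt1": 0.006},
                         eta_r={"pptLag": 0.006})
    community = CommunityParams(species={"FOC": focal, "CMP": comp},
                                alphas=AlphaMatrix.uniform(spp, 0.05))
    return GroundTruth(name="pure-indirect", community=community)


def _variance_gradient() -> GroundTruth:
    spp = ["UP", "DN"]
    up = _base_species(spp, "UP", -0.008, -0.003, -0.05,
                       eta_s={"ppt1": 0.005}, eta_g={"ppt1": 0.004},
                       eta_r={"pptLag": 0.004})
    dn = _base_species(spp, "DN", -0.008, -0.003, -0.05,
                       eta_s={"ppt1": -0.005}, eta_g={"ppt1": -0.004},
                       eta_r={"pptLag": -0.004})
    community = CommunityParams(species={"UP": up, "DN": dn},
                                alphas=AlphaMatrix.uniform(spp, 0.05))
    return GroundTruth(name="variance-gradient", community=community)


def _single_species() -> GroundTruth:
    spp = ["SOLO"]
    community = CommunityParams(
        species={"SOLO": _base_species(spp, "SOLO", 0.0, 0.0, 0.0,
                                       eta_s={"ppt1": 0.004},
                                       eta_g={"ppt1": 0.003},
                                       eta_r={"pptLag": 0.003})},
        alphas=AlphaMatrix.uniform(spp, 0.05))
    return GroundTruth(name="single-species", community=community)


def _sparse_tracking() -> GroundTruth:
    spp = ["SPRS"]
    surv = SurvivalParams(intercept=3.5, size=0.0,
                          crowding={"SPRS": 0.0},
                          crowding_size={"SPRS": 0.0})
    grow = GrowthParams(intercept=0.14, size=0.9,
                        crowding={"SPRS": 0.0},
                        crowding_size={"SPRS": 0.0},
                        var_a=0.02, var_b=0.0)
    rec = RecruitParams(intercept=-2.0, dd={"SPRS": -0.48}, theta=5.0, p=1.0)
    community = CommunityParams(
        species={"SPRS": SpeciesParams(surv, grow, rec)},
        alphas=AlphaMatrix.uniform(spp, 0.05))
    return GroundTruth(name="sparse-tracking", community=community,
                       year_sd={"survival": 0.0, "growth": 0.0,
                                "recruit": 0.0},
                       group_sd=0.0, init_per_species=6,
                       init_log_size=(np.log(4.0), 0.3))


_SCENARIOS = {
    "symmetric-2sp": lambda: two_species_overlap(0.4),
    "neutral-2sp": lambda: two_species_overlap(1.0),
    "niche-partitioned": lambda: two_species_overlap(0.15),
    "neutral-ish": lambda: two_species_overlap(0.9),
    "pure-indirect": _pure_indirect,
    "variance-gradient": _variance_gradient,
    "single-species": _single_species,
    "sparse-tracking": _sparse_tracking,
}


def scenario(name: str) -> GroundTruth:
    """Return the named pre-validated ground-truth parameter set."""
    try:
        factory = _SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; choose from "
                       f"{sorted(_SCENARIOS)}") from None
    truth = factory()
    truth.name = name
    return truth


def scenario_names() -> list[str]:
    return sorted(_SCENARIOS)


def generate_transitions(survival: "SurvivalParams", growth: "GrowthParams",
                         climate: ClimateTable, n: int,
                         rng: np.random.Generator,
                         groups: Sequence[str] = ("g0", "g1"),
                         size_dist: tuple[float, float] = (1.5, 1.0),
                         crowding_dist: tuple[float, float] = (2.0, 4.0),
                         species: str = "A") -> pd.DataFrame:
    """Direct generative draws from the survival and growth models.

    Bypasses the IBM: sizes are normal, crowding is gamma-distributed, and
    fates are drawn straight from the two regressions. Used for fitting
    calibration where the estimand must match the generative model exactly.
    ``survival``/``growth`` must carry year (and group) effects for every
    climate year.
    """
    years = [int(y) for y in climate.years]
    rows = []
    for i in range(n):
        year = int(rng.choice(years))
        group = groups[i % len(groups)]
        u = float(rng.normal(*size_dist))
        w = {species: float(rng.gamma(*crowding_dist))}
        C = climate.row(year)
        s = survival_prob(u, C, w, survival, year=year, group=group)
        alive = rng.random() < s
        vbar, var = growth_moments(u, C, w, growth, year=year, group=group)
        rows.append({"site": "S", "quadrat": "q", "group": group,
                     "species": species, "genet_id": i, "year": year,
                     "logarea": u, f"w_{species}": w[species],
                     "survives": float(alive),
                     "logarea_next":
                         float(rng.normal(vbar, np.sqrt(var)))
                         if alive else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IBM-backed archive generation


def draw_year_effects(truth: GroundTruth, years: Sequence[int],
                      rng: np.random.Generator) -> CommunityParams:
    """Deep-copy the community params with per-year effect deviations drawn
    Normal(0, sd) for every species and vital rate (shared across quadrats,
    as real interannual effects are)."""
    community = copy.deepcopy(truth.community)
    shared = None
    if truth.shared_year_effects:
        shared = {int(yr): (float(rng.normal(0.0, truth.year_sd["survival"])),
                            float(rng.normal(0.0, truth.year_sd["growth"])),
                            float(rng.normal(0.0, truth.year_sd["recruit"])))
                  for yr in years}
    for sp, p in community.species.items():
        for yr in years:
            if shared is not None:
                s, g, r = shared[int(yr)]
            else:
                s = float(rng.normal(0.0, truth.year_sd["survival"]))
                g = float(rng.normal(0.0, truth.year_sd["growth"]))
                r = float(rng.normal(0.0, truth.year_sd["recruit"]))
            p.survival.year_effects[int(yr)] = s
            p.growth.year_effects[int(yr)] = g
            p.recruit.year_effects[int(yr)] = r
    return community


def assign_group_effects(community: CommunityParams, groups: Sequence[str],
                         group_sd: float, rng: np.random.Generator) -> None:
    for p in community.species.values():
        for vr in (p.survival, p.growth, p.recruit):
            draws = rng.normal(0.0, group_sd, len(groups))
            draws -= draws.mean()  # identifiable: deviations sum to zero
            vr.group_effects = {g: float(d) for g, d in zip(groups, draws)}


def _init_state(truth: GroundTruth, rng: np.random.Generator) -> IBMState:
    spp, ids, us, xs, ys = [], [], [], [], []
    nid = 0
    mu, sd = truth.init_log_size
    for sp in truth.community.codes():
        n = truth.init_per_species
        spp.extend([sp] * n)
        ids.extend(range(nid, nid + n))
        nid += n
        us.extend(rng.normal(mu, sd, n))
        xs.extend(rng.uniform(0, QUADRAT_CM, n))
        ys.extend(rng.uniform(0, QUADRAT_CM, n))
    return IBMState(np.array(spp, dtype=object), np.array(ids, dtype=int),
                    np.array(us, float), np.array(xs, float),
                    np.array(ys, float), QUADRAT_CM, next_id=nid)


@dataclass
class SyntheticArchive:
    """One generated chart-quadrat archive plus everything needed to score
    downstream stages against the truth."""

    maps: list[QuadratMap]
    truth_records: pd.DataFrame   # includes true genet ids and recruit flags
    climate: ClimateTable
    community: CommunityParams    # with the drawn year/group effects filled in
    truth: GroundTruth


def generate_quadrat_series(truth: GroundTruth, n_quadrats: int,
                            n_years: int, rng: np.random.Generator,
                            site: str = "synthetic", n_groups: int = 2,
                            start_year: int = 2000, max_retries: int = 5,
                            circle_segments: int = 12) -> SyntheticArchive:
    """Run the ground-truth IBM and emit polygon-table quadrat maps.

    Each quadrat starts from a random initial community and is stepped
    through the same climate series and (shared) year-effect draws; genets
    are rendered as circle polygons clipped to the quadrat. A quadrat whose
    community goes extinct is regenerated with fresh demographic draws up
    to ``max_retries`` times before failing loudly.
    """
    climate = generate_climate(n_years, truth.climate_means, truth.climate_sds,
                               rng, site=site, start_year=start_year)
    years = [int(y) for y in climate.years]
    community = draw_year_effects(truth, years, rng)
    groups = [f"g{i}" for i in range(n_groups)]
    assign_group_effects(community, groups, truth.group_sd, rng)

    quadrat_box = box(0.0, 0.0, QUADRAT_CM, QUADRAT_CM)
    maps: list[QuadratMap] = []
    records: list[dict] = []
    for q in range(n_quadrats):
        group = groups[q % n_groups]
        for attempt in range(max_retries):
            states, ok = [], True
            state = _init_state(truth, rng)
            for i, yr in enumerate(years):
                states.append((yr, state))
                if i + 1 == len(years):
                    break
                draw = YearDraw.from_year(community, yr)
                state = ibm_step(state, community, climate.row(yr), draw,
                                 rng, group=group)
                covers = {sp: float(np.exp(state.u[state.species == sp]).sum())
                          for sp in community.codes()}
                if any(c <= 0 for c in covers.values()):
                    ok = False
                    break
            if ok:
                break
        else:
            raise RuntimeError(
                f"community extinct in quadrat {q} after {max_retries} tries")

        prev_ids: set[int] = set()
        for yr, st in states:
            qmap = QuadratMap(site=site, quadrat=f"q{q}", group=group, year=yr)
            for k in range(len(st)):
                area = float(np.exp(st.u[k]))
                if area <= POINT_AREA_CM2:
                    geom = Point(st.x[k], st.y[k])
                else:
                    r = np.sqrt(area / np.pi)
                    geom = (Point(st.x[k], st.y[k])
                            .buffer(r, quad_segs=circle_segments)
                            .intersection(quadrat_box))
                    if geom.is_empty:
                        continue
                qmap.features.append((str(st.species[k]), geom))
                records.append({
                    "site": site, "quadrat": f"q{q}", "group": group,
                    "species": str(st.species[k]),
                    "genet_id": int(st.genet_id[k]), "year": yr,
                    "area_cm2": area, "x": float(st.x[k]),
                    "y": float(st.y[k]),
                    "is_recruit": bool(yr != years[0]
                                       and st.genet_id[k] not in prev_ids)})
            maps.append(qmap)
            prev_ids = set(int(g) for g in st.genet_id)
    truth_df = pd.DataFrame(records)
    logger.info("generated %d quadrat-years, %d genet-years (%s)",
                len(maps), len(truth_df), truth.name)
    return SyntheticArchive(maps, truth_df, climate, community, truth)
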