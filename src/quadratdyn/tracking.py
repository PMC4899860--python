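"""Track genet identities through yearly quadrat maps.

Perennial grasses mapped as basal-cover polygons can fragment, coalesce and
"move" short distances between censuses via resprouting, and the pantograph
introduces mapping error. Identities are therefore resolved by a buffering /
overlap rule: every year-(t−1) polygon of the focal species is dilated by a
fixed buffer (default 5 cm); a year-t polygon inherits the identity of the
buffered conspecific with which it shares the greatest overlap area, and is
labelled a new recruit if it overlaps none of them.

Each tracked genet-year is then summarised as a circle: area equal to the
summed area of its member polygons, located at their area-weighted centroid.
Plants mapped as points are given an area of 0.25 cm².
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.validation import make_valid

from .data_io import QuadratMap

logger = logging.getLogger("quadratdyn")

POINT_AREA_CM2 = 0.25
#: radius of the nominal circle representing a point-mapped plant
POINT_RADIUS_CM = float(np.sqrt(POINT_AREA_CM2 / np.pi))


@dataclass(frozen=True)
class GenetRecord:
    """One genet in one census year, reduced to its circle representation."""

    site: str
    quadrat: str
    group: str
    species: str
    genet_id: int
    year: int
    area_cm2: float
    x: float
    y: float
    is_recruit: bool = False

    @property
    def log_area(self) -> float:
        return float(np.log(self.area_cm2))


def _as_polygon(geom: Polygon | Point) -> Polygon:
    if isinstance(geom, Point):
        return geom.buffer(POINT_RADIUS_CM, quad_segs=16)
    return geom


def buffer_polygons(features: Sequence[Polygon | Point], buffer_cm: float,
                    repair: bool = True) -> list[Polygon]:
    """Dilate each feature by ``buffer_cm``; points become discs.

    Invalid (self-intersecting) polygons are repaired with ``make_valid``
    when ``repair`` is set, otherwise rejected with a ``ValueError``.
    """
    if buffer_cm < 0:
        raise ValueError("buffer must be ≥ 0")
    out = []
    for geom in features:
        poly = _as_polygon(geom)
        if not poly.is_valid:
            if not repair:
                raise ValueError("invalid polygon and repair disabled")
            poly = make_valid(poly)
        out.append(poly if buffer_cm == 0 else poly.buffer(buffer_cm))
    return out


def track_genets(prev_features: Sequence[tuple[int, Polygon | Point]],
                 curr_features: Sequence[Polygon | Point],
                 buffer_cm: float = 5.0,
                 prev_areas: Sequence[float] | None = None,
                 repair: bool = True) -> list[int | None]:
    """Assign year-t features to year-(t−1) genet identities for one species.

    ``prev_features`` pairs each antecedent genet id with its (possibly
    multi-part) geometry; geometries sharing an id are handled by passing one
    entry per polygon. Returns, per ``curr_features`` entry, the inherited
    genet id, or ``None`` for a new recruit (zero overlap with every buffered
    conspecific antecedent). Ties on greatest overlap are broken by larger
    antecedent area, then lower genet id, so output is deterministic.
    """
    prev_geoms = buffer_polygons([g for _, g in prev_features], buffer_cm,
                                 repair=repair)
    prev_ids = [gid for gid, _ in prev_features]
    if prev_areas is None:
        prev_areas = [_as_polygon(g).area for _, g in prev_features]
    assignments: list[int | None] = []
    for geom in curr_features:
        poly = _as_polygon(geom)
        if not poly.is_valid:
            if not repair:
                raise ValueError("invalid polygon and repair disabled")
            poly = make_valid(poly)
        best: tuple | None = None
        for gid, bgeom, barea in zip(prev_ids, prev_geoms, prev_areas):
            overlap = poly.intersection(bgeom).area
            if overlap <= 0:
                continue
            # maximise overlap; tie-break on larger antecedent, lower id
            key = (overlap, barea, -gid)
            if best is None or key > best[0]:
                best = (key, gid)
        assignments.append(None if best is None else best[1])
    return assignments


def genets_to_circles(polygons: Sequence[Polygon | Point]) -> tuple[float, float, float]:
    """Summarise one genet-year's polygons as (area, centroid x, centroid y).

    Area is the sum of member-polygon areas (0.25 cm² for a point) and the
    location is the area-weighted centroid of the members.
    """
    if not polygons:
        raise ValueError("genet-year with no polygons")
    areas, xs, ys = [], [], []
    for geom in polygons:
        if isinstance(geom, Point):
            areas.append(POINT_AREA_CM2)
            xs.append(geom.x)
            ys.append(geom.y)
        else:
            areas.append(geom.area)
            c = geom.centroid
            xs.append(c.x)
            ys.append(c.y)
    areas = np.asarray(areas)
    total = float(areas.sum())
    return (total,
            float(np.average(xs, weights=areas)),
            float(np.average(ys, weights=areas)))


def track_quadrat_series(maps: Sequence[QuadratMap], buffer_cm: float = 5.0,
                         repair: bool = True) -> list[GenetRecord]:
    """Track all species through one quadrat's yearly map series.

    Years must be increasing; transitions are only resolved between
    consecutive calendar years — across a census gap every plant restarts
    as a new genet id (demographic transitions spanning gaps are excluded
    downstream by :func:`build_transitions`).
    """
    maps = sorted(maps, key=lambda m: m.year)
    years = [m.year for m in maps]
    if len(set(years)) != len(years):
        raise ValueError("duplicate census year in quadrat series")

    records: list[GenetRecord] = []
    next_id = itertools.count(0)
    # per species: list of (genet_id, raw geometry) in the previous year
    prev: dict[str, list[tuple[int, Polygon | Point]]] = {}
    prev_year: int | None = None

    for qmap in maps:
        by_species: dict[str, list[Polygon | Point]] = {}
        for species, geom in qmap.features:
            by_species.setdefault(species, []).append(geom)
        curr: dict[str, list[tuple[int, Polygon | Point]]] = {}
        consecutive = prev_year is not None and qmap.year == prev_year + 1
        for species, geoms in by_species.items():
            if consecutive and species in prev:
                assign = track_genets(prev[species], geoms, buffer_cm,
                                      repair=repair)
            else:
                assign = [None] * len(geoms)
            # coalescence: fragments sharing an antecedent share an id
            ids = [next(next_id) if a is None else a for a in assign]
            members: dict[int, list] = {}
            flags: dict[int, bool] = {}
            for gid, a, geom in zip(ids, assign, geoms):
                members.setdefault(gid, []).append(geom)
                flags[gid] = flags.get(gid, True) and a is None
            for gid, geoms_g in members.items():
                area, x, y = genets_to_circles(geoms_g)
                records.append(GenetRecord(
                    site=qmap.site, quadrat=qmap.quadrat, group=qmap.group,
                    species=species, genet_id=gid, year=qmap.year,
                    area_cm2=area, x=x, y=y, is_recruit=flags[gid]))
                curr.setdefault(species, []).extend(
                    (gid, g) for g in geoms_g)
        prev = curr
        prev_year = qmap.year
    logger.info("tracked %d genet-years across %d censuses",
                len(records), len(maps))
    return records


def records_to_frame(records: Iterable[GenetRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    if len(df):
        df["logarea"] = np.log(df["area_cm2"])
    return df


def build_transitions(records: Sequence[GenetRecord]) -> pd.DataFrame:
    """Materialize genet transitions t → t+1 from tracked records.

    Returns one row per genet-year with columns ``survives`` (0/1, NaN when
    year t+1 was not censused), ``logarea``, ``logarea_next`` (NaN unless
    survived). Recruits contribute to the per-quadrat recruit counts of
    :func:`recruit_counts` rather than to survival at t.
    """
    df = records_to_frame(records)
    if df.empty:
        return df
    dup = df.duplicated(["site", "quadrat", "species", "genet_id", "year"])
    if dup.any():
        raise ValueError("duplicate genet id within species-quadrat-year")
    out = df[["site", "quadrat", "group", "species", "genet_id", "year",
              "logarea", "area_cm2", "x", "y", "is_recruit"]].copy()
    nxt = df[["site", "quadrat", "species", "genet_id", "year",
              "logarea"]].copy()
    nxt["year"] -= 1
    nxt = nxt.rename(columns={"logarea": "logarea_next"})
    out = out.merge(nxt, how="left",
                    on=["site", "quadrat", "species", "genet_id", "year"])
    censused = df[["site", "quadrat", "year"]].drop_duplicates().copy()
    censused["year"] -= 1
    censused["has_next_census"] = True
    out = out.merge(censused, how="left", on=["site", "quadrat", "year"])
    has_next = out.pop("has_next_census").notna().to_numpy()
    survives = np.where(out["logarea_next"].notna(), 1.0, 0.0)
    survives[~has_next] = np.nan
    out["survives"] = survives
    out.loc[~has_next, "logarea_next"] = np.nan
    return out[["site", "quadrat", "group", "species", "genet_id", "year",
                "logarea", "area_cm2", "x", "y", "is_recruit",
                "survives", "logarea_next"]]


def recruit_counts(records: Sequence[GenetRecord]) -> pd.DataFrame:
    """Per quadrat × year × species: recruit count y and total cover.

    Cover (cm²) in the *parent* year t pairs with recruits arriving at t+1;
    the pairing itself is done by the recruitment fitting code, which also
    excludes counts that immediately follow a census gap (those plants are
    restarts, not recruits).
    """
    df = records_to_frame(records)
    if df.empty:
        return df
    grp = df.groupby(["site", "quadrat", "group", "year", "species"])
    out = grp.agg(recruits=("is_recruit", "sum"),
                  cover_cm2=("area_cm2", "sum")).reset_index()
    return out
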