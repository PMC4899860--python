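"""Tabular I/O, registries, and run configuration for the quadrat pipeline.

All on-disk formats are plain delimited text with header rows so that runs
are diffable and portable:

* polygon dialect: ``site,quadrat,group,year,species,feature_id,vertex_index,x,y``
* genet dialect:   ``site,quadrat,group,year,species,genet_id,area_cm2,x,y``
* climate:         ``site,year,pptLag,ppt1,ppt2,T1,T2``

Coordinates are quadrat-local centimetres, origin at the lower-left corner,
y increasing upward, inside a 1-m² (100 cm × 100 cm) quadrat.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, Polygon

logger = logging.getLogger("quadratdyn")

QUADRAT_CM = 100.0
#: the five named climate covariates: prior water-year precipitation, and
#: critical-season precipitation / temperature in year 1 and 2 of a transition
CLIMATE_COVARIATES = ("pptLag", "ppt1", "ppt2", "T1", "T2")
PRECIP_COVARIATES = ("pptLag", "ppt1", "ppt2")
TEMP_COVARIATES = ("T1", "T2")
#: within-year precipitation × temperature interactions
CLIMATE_INTERACTIONS = {"ppt1T1": ("ppt1", "T1"), "ppt2T2": ("ppt2", "T2")}

POLYGON_COLUMNS = ["site", "quadrat", "group", "year", "species",
                   "feature_id", "vertex_index", "x", "y"]
GENET_COLUMNS = ["site", "quadrat", "group", "year", "species",
                 "genet_id", "area_cm2", "x", "y"]


class FormatError(ValueError):
    """A file violated its declared schema."""


@dataclass
class QuadratMap:
    """All mapped features of one quadrat in one census year.

    ``features`` holds ``(species, geometry)`` pairs where geometry is a
    shapely Polygon (mapped basal/canopy cover) or Point (very small plant).
    """

    site: str
    quadrat: str
    group: str
    year: int
    features: list[tuple[str, Polygon | Point]] = field(default_factory=list)

    def species(self) -> list[str]:
        return sorted({sp for sp, _ in self.features})


@dataclass
class ClimateTable:
    """Per-year climate covariate vectors for one site.

    ``data`` is indexed by transition year and holds exactly the five named
    covariates; interaction columns are computed on demand as products.
    """

    site: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLIMATE_COVARIATES if c not in self.data.columns]
        if missing:
            raise FormatError(f"climate table missing covariates: {missing}")
        if self.data.index.duplicated().any():
            raise FormatError("duplicate year key in climate table")
        if self.data[list(CLIMATE_COVARIATES)].isna().any().any():
            raise FormatError("missing covariate values in climate table")
        self.data = self.data[list(CLIMATE_COVARIATES)].sort_index()

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def with_interactions(self) -> pd.DataFrame:
        """Covariate table extended with precip × temp interaction columns."""
        out = self.data.copy()
        for name, (a, b) in CLIMATE_INTERACTIONS.items():
            out[name] = out[a] * out[b]
        return out

    def row(self, year: int, interactions: bool = True) -> pd.Series:
        table = self.with_interactions() if interactions else self.data
        return table.loc[year]

    def copy(self) -> "ClimateTable":
        return ClimateTable(self.site, self.data.copy())


@dataclass
class SpeciesInfo:
    code: str
    site: str = ""
    #: Gaussian-kernel spatial scales (cm⁻²) of this species' sensitivity to
    #: each neighbour species, per vital rate
    alpha: dict[str, dict[str, float]] = field(default_factory=dict)
    is_shrub: bool = False


@dataclass
class SpeciesRegistry:
    """Species codes and their interaction spatial scales for one site."""

    species: dict[str, SpeciesInfo] = field(default_factory=dict)

    def add(self, info: SpeciesInfo) -> None:
        if info.code in self.species:
            raise ValueError(f"duplicate species code {info.code!r}")
        self.species[info.code] = info

    def codes(self) -> list[str]:
        return list(self.species)

    def __contains__(self, code: str) -> bool:
        return code in self.species

    def __getitem__(self, code: str) -> SpeciesInfo:
        return self.species[code]


def _check_coord(value: float, what: str) -> None:
    if not (0.0 <= value <= QUADRAT_CM):
        raise FormatError(f"{what} {value} outside [0, {QUADRAT_CM}] cm")


def read_quadrat_maps(path: str | Path, dialect: str = "polygon-table"
                      ) -> list[QuadratMap]:
    """Read mapped-quadrat data into :class:`QuadratMap` objects.

    ``dialect`` is ``"polygon-table"`` (one row per polygon vertex) or
    ``"genet-table"`` (one row per genet, rendered as its circle).
    Malformed geometries are rejected row-wise with a logged warning;
    out-of-range coordinates are a hard error.
    """
    if dialect not in ("polygon-table", "genet-table"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    cols = POLYGON_COLUMNS if dialect == "polygon-table" else GENET_COLUMNS
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    for axis in ("x", "y"):
        bad = df[(df[axis] < 0) | (df[axis] > QUADRAT_CM)]
        if len(bad):
            raise FormatError(
                f"{path}: coordinate {axis}={bad[axis].iloc[0]} outside quadrat")

    maps: dict[tuple, QuadratMap] = {}
    keys = ["site", "quadrat", "group", "year"]
    if dialect == "polygon-table":
        grouped = df.groupby(keys + ["species", "feature_id"], sort=True)
        for (site, quadrat, group, year, species, fid), rows in grouped:
            rows = rows.sort_values("vertex_index")
            verts = list(zip(rows["x"], rows["y"]))
            if len(verts) == 1:
                geom: Polygon | Point = Point(verts[0])
            else:
                if len(verts) < 3:
                    logger.warning("rejecting degenerate feature %s (%d vertices)",
                                   fid, len(verts))
                    continue
                geom = Polygon(verts)
                if not geom.is_valid or geom.area <= 0:
                    geom = geom.buffer(0)
                    if geom.is_empty or geom.area <= 0:
                        logger.warning("rejecting invalid polygon %s", fid)
                        continue
            key = (site, quadrat, group, int(year))
            qmap = maps.setdefault(key, QuadratMap(site, quadrat, group, int(year)))
            qmap.features.append((species, geom))
    else:
        for _, row in df.iterrows():
            area = float(row["area_cm2"])
            if area <= 0:
                logger.warning("rejecting genet %s with area %g",
                               row["genet_id"], area)
                continue
            radius = np.sqrt(area / np.pi)
            geom = Point(row["x"], row["y"]).buffer(radius, quad_segs=16)
            key = (row["site"], row["quadrat"], row["group"], int(row["year"]))
            qmap = maps.setdefault(key, QuadratMap(*key))
            qmap.features.append((row["species"], geom))
    out = sorted(maps.values(), key=lambda m: (m.site, m.quadrat, m.year))
    logger.info("read %d quadrat-year maps from %s", len(out), path)
    return out


def write_quadrat_maps(maps: Iterable[QuadratMap], path: str | Path) -> None:
    """Write maps in the polygon dialect (points emit a single vertex row)."""
    rows = []
    for qmap in maps:
        for fid, (species, geom) in enumerate(qmap.features):
            if isinstance(geom, Point):
                coords = [(geom.x, geom.y)]
            else:
                coords = list(geom.exterior.coords)[:-1]  # drop closing vertex
            for vi, (x, y) in enumerate(coords):
                rows.append((qmap.site, qmap.quadrat, qmap.group, qmap.year,
                             species, fid, vi, x, y))
    pd.DataFrame(rows, columns=POLYGON_COLUMNS).to_csv(path, index=False)


def read_climate(path: str | Path) -> ClimateTable:
    """Read a per-year climate covariate table for one site."""
    df = pd.read_csv(path)
    missing = [c for c in ("site", "year", *CLIMATE_COVARIATES)
               if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    sites = df["site"].unique()
    if len(sites) != 1:
        raise FormatError(f"{path}: expected one site, found {list(sites)}")
    if df["year"].duplicated().any():
        raise FormatError(f"{path}: duplicate year key")
    years = np.sort(df["year"].to_numpy())
    gaps = np.setdiff1d(np.arange(years[0], years[-1] + 1), years)
    if len(gaps):
        raise FormatError(f"{path}: missing years within modelled span: {gaps}")
    data = df.set_index("year")[list(CLIMATE_COVARIATES)]
    return ClimateTable(site=str(sites[0]), data=data)


def write_climate(table: ClimateTable, path: str | Path) -> None:
    df = table.data.reset_index()
    df.insert(0, "site", table.site)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PerturbationConfig:
    mean_pct: float = 1.0      # % increase applied to covariate means
    variance_pct: float = 10.0  # % increase applied to covariate variances
    temp_mode: str = "additive"  # additive (+pct of site mean) vs multiplicative


@dataclass
class MeshConfig:
    nodes: int = 100
    lower_cm2: float = 0.2     # lower size limit, below the 0.25 cm² point size
    upper_pad: float = 1.0     # added to log(max observed area)


@dataclass
class SimulationConfig:
    burn_in: int = 500
    window: int = 2000
    invasion_steps: int = 1000
    invasion_cover: float = 1e-6
    ibm_reps: int = 50


@dataclass
class Config:
    """Run configuration; every results artifact embeds a serialized copy."""

    seed: int = 0
    buffer_cm: float = 5.0
    point_area_cm2: float = 0.25
    quadrat_cm: float = QUADRAT_CM
    repair_polygons: bool = True
    mesh: MeshConfig = field(default_factory=MeshConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)

    def __post_init__(self) -> None:
        if self.mesh.nodes < 2:
            raise ValueError(f"mesh nodes must be ≥ 2, got {self.mesh.nodes}")
        if self.buffer_cm < 0:
            raise ValueError("buffer_cm must be ≥ 0")
        if self.perturbation.temp_mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown temp_mode {self.perturbation.temp_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_NESTED = {"mesh": MeshConfig, "simulation": SimulationConfig,
           "perturbation": PerturbationConfig}


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML config, filling documented defaults.

    Unknown keys are a hard error so that typos never silently fall back to
    defaults.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("config must be a YAML mapping")
    kwargs: dict = {}
    top_fields = {f.name for f in dataclasses.fields(Config)}
    for key, value in raw.items():
        if key not in top_fields:
            raise FormatError(f"unknown config key {key!r}")
        if key in _NESTED:
            cls = _NESTED[key]
            sub_fields = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - sub_fields
            if unknown:
                raise FormatError(f"unknown config key {key}.{unknown.pop()!r}")
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    return Config(**kwargs)


def write_run_metadata(path: str | Path, config: Config, seed: int,
                       extra: dict | None = None) -> None:
    """Sidecar metadata written next to every results table for provenance."""
    meta = {"config": config.to_dict(), "seed": int(seed)}
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
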