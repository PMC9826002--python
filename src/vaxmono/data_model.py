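"""Domain types, file readers/writers, and input validation.

The observational unit is the survey cluster: a (displaced) coordinate with a
handful of sampled children and, per child, whether each of the three vaccine
doses was received.  Cluster tables, prediction grids and admin summaries are
all exchanged as UTF-8 delimited text with a header row; admin-unit polygons
are GeoJSON FeatureCollections handled with shapely.

Counts are stored as reals: simulated datasets and ratio-based pseudo counts
are fractional by construction.  Integer-ness can be enforced with the
``integer_counts`` flag on :func:`read_cluster_table`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as _geojson_shape

logger = logging.getLogger("vaxmono")

__all__ = [
    "FormatError",
    "IntegrityError",
    "ClusterRecord",
    "ClusterDataset",
    "PredictionGrid",
    "AdminUnit",
    "read_cluster_table",
    "write_cluster_table",
    "filter_clusters",
    "read_grid_table",
    "read_admin_geojson",
    "read_grid_and_admin",
    "assign_cells_to_units",
    "write_outputs",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout (eg missing columns)."""


class IntegrityError(ValueError):
    """Values violate a domain invariant (eg non-monotone dose counts)."""


REQUIRED_CLUSTER_COLUMNS = ("cluster_id", "x", "y", "n", "y1", "y2", "y3")
REQUIRED_GRID_COLUMNS = ("cell_id", "x", "y", "population")


@dataclass(frozen=True)
class ClusterRecord:
    """One survey cluster: location, trial size and per-dose success counts."""

    cluster_id: str
    location: tuple[float, float]
    n: float
    y1: float
    y2: float
    y3: float
    covariates: dict[str, float]


@dataclass
class ClusterDataset:
    """Vectorised collection of clusters sharing one covariate set.

    Invariants (checked by :meth:`validate`): unique cluster ids, finite
    coordinates, and monotone counts ``n >= y1 >= y2 >= y3 >= 0`` per cluster.
    """

    cluster_id: np.ndarray          # (m,) str
    coords: np.ndarray              # (m, 2) float
    n: np.ndarray                   # (m,) float
    y: np.ndarray                   # (m, 3) float — successes for doses 1..3
    covariates: np.ndarray          # (m, p) float
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cluster_id = np.asarray(self.cluster_id, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates.reshape(len(self.n), -1)
        self.validate()

    def __len__(self) -> int:
        return len(self.cluster_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClusterDataset):
            return NotImplemented
        return (
            list(self.cluster_id) == list(other.cluster_id)
            and self.covariate_names == other.covariate_names
            and np.allclose(self.coords, other.coords, atol=1e-6)
            and np.allclose(self.n, other.n, atol=1e-6)
            and np.allclose(self.y, other.y, atol=1e-6)
            and np.allclose(self.covariates, other.covariates, atol=1e-6)
        )

    def validate(self) -> None:
        ids = list(self.cluster_id)
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate cluster ids: {dupes[:5]}")
        if not np.all(np.isfinite(self.coords)):
            raise IntegrityError("non-finite cluster coordinates")
        if np.any(np.isnan(self.covariates)):
            bad = np.where(np.isnan(self.covariates).any(axis=1))[0]
            raise IntegrityError(
                f"missing covariate values for clusters {list(self.cluster_id[bad[:5]])}"
            )
        counts = np.column_stack([self.n, self.y])
        if np.any(counts < -1e-12):
            raise IntegrityError("negative counts")
        drops = np.diff(counts, axis=1)
        bad = np.where(drops > 1e-9)[0]
        if bad.size:
            i = int(bad[0])
            raise IntegrityError(
                f"non-monotone counts for cluster {self.cluster_id[i]!r}: "
                f"n={self.n[i]}, y={tuple(self.y[i])} violate n >= y1 >= y2 >= y3"
            )
        if self.covariates.shape != (len(self.n), len(self.covariate_names)):
            raise FormatError(
                f"covariate matrix shape {self.covariates.shape} does not match "
                f"{len(self.n)} clusters x {len(self.covariate_names)} names"
            )

    @property
    def records(self) -> list[ClusterRecord]:
        return [
            ClusterRecord(
                cluster_id=self.cluster_id[i],
                location=(float(self.coords[i, 0]), float(self.coords[i, 1])),
                n=float(self.n[i]),
                y1=float(self.y[i, 0]),
                y2=float(self.y[i, 1]),
                y3=float(self.y[i, 2]),
                covariates=dict(zip(self.covariate_names, self.covariates[i])),
            )
            for i in range(len(self))
        ]

    def subset(self, mask: np.ndarray) -> "ClusterDataset":
        return ClusterDataset(
            cluster_id=self.cluster_id[mask],
            coords=self.coords[mask],
            n=self.n[mask],
            y=self.y[mask],
            covariates=self.covariates[mask],
            covariate_names=list(self.covariate_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cluster_id": self.cluster_id,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "n": self.n,
                "y1": self.y[:, 0],
                "y2": self.y[:, 1],
                "y3": self.y[:, 2],
            }
        )
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df


@dataclass
class PredictionGrid:
    """Prediction-grid cells: centroids, covariates and child population.

    The population column is a proxy for the modelled age group and weights
    the admin-level aggregation; it never enters the likelihood.
    """

    cell_id: np.ndarray             # (L,)
    coords: np.ndarray              # (L, 2)
    covariates: np.ndarray          # (L, p)
    population: np.ndarray          # (L,)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cell_id = np.asarray(self.cell_id, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        ids = list(self.cell_id)
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate grid cell ids")
        if np.any(self.population < 0):
            raise IntegrityError("negative cell population")
        if np.any(np.isnan(self.covariates)):
            raise IntegrityError("missing covariate values on the grid")

    def __len__(self) -> int:
        return len(self.cell_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "population": self.population,
            }
        )
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df


@dataclass
class AdminUnit:
    """One administrative polygon at a named level, with its member grid cells."""

    unit_id: str
    level: str
    geometry: shapely.Geometry
    member_cells: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers


def read_cluster_table(
    path,
    covariate_names: Sequence[str] | None = None,
    integer_counts: bool = False,
) -> ClusterDataset:
    """Read a delimited cluster table.

    Expected columns: ``cluster_id,x,y,n,y1,y2,y3,<covariates...>``.  When
    ``covariate_names`` is None every extra column is treated as a covariate.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cluster table {path} missing columns {missing}")
    if covariate_names is None:
        covariate_names = [c for c in df.columns if c not in REQUIRED_CLUSTER_COLUMNS]
    else:
        covariate_names = list(covariate_names)
        absent = [c for c in covariate_names if c not in df.columns]
        if absent:
            raise FormatError(f"cluster table {path} missing covariates {absent}")
    if integer_counts:
        counts = df[["n", "y1", "y2", "y3"]].to_numpy(float)
        if not np.allclose(counts, np.round(counts), atol=1e-9):
            raise IntegrityError("integer_counts set but counts are fractional")
    return ClusterDataset(
        cluster_id=df["cluster_id"].astype(str).to_numpy(object),
        coords=df[["x", "y"]].to_numpy(float),
        n=df["n"].to_numpy(float),
        y=df[["y1", "y2", "y3"]].to_numpy(float),
        covariates=df[covariate_names].to_numpy(float).reshape(len(df), -1),
        covariate_names=covariate_names,
    )


def write_cluster_table(ds: ClusterDataset, path) -> None:
    ds.to_frame().to_csv(path, index=False)


def filter_clusters(ds: ClusterDataset, min_n: float = 2) -> ClusterDataset:
    """Drop clusters with fewer than ``min_n`` sampled children.

    Surveys routinely drop single-child clusters (default ``min_n=2``): a
    lone child carries no within-cluster information and its displaced
    coordinate is disproportionately noisy.
    """
    keep = ds.n >= min_n
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_clusters: removed %d of %d clusters with n < %s",
                    removed, len(ds), min_n)
    if not keep.any():
        raise IntegrityError(f"no clusters left after requiring n >= {min_n}")
    if removed == 0:
        return ds
    return ds.subset(keep)


def read_grid_table(path, covariate_names: Sequence[str] | None = None) -> PredictionGrid:
    """Read a delimited prediction grid: ``cell_id,x,y,population,<covariates...>``."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_GRID_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"grid table {path} missing columns {missing}")
    if covariate_names is None:
        covariate_names = [c for c in df.columns if c not in REQUIRED_GRID_COLUMNS]
    else:
        covariate_names = list(covariate_names)
    return PredictionGrid(
        cell_id=df["cell_id"].astype(str).to_numpy(object),
        coords=df[["x", "y"]].to_numpy(float),
        covariates=df[covariate_names].to_numpy(float).reshape(len(df), -1),
        population=df["population"].to_numpy(float),
        covariate_names=list(covariate_names),
    )


def read_admin_geojson(path) -> list[AdminUnit]:
    """Read admin polygons from a GeoJSON FeatureCollection.

    Each feature must carry ``unit_id`` and ``level`` properties.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    units = []
    for feat in gj["features"]:
        props = feat.get("properties", {})
        if "unit_id" not in props or "level" not in props:
            raise FormatError(f"{path}: feature missing unit_id/level properties")
        units.append(
            AdminUnit(
                unit_id=str(props["unit_id"]),
                level=str(props["level"]),
                geometry=_geojson_shape(feat["geometry"]),
            )
        )
    return units


def assign_cells_to_units(grid: PredictionGrid, units: list[AdminUnit]) -> np.ndarray:
    """Assign each grid cell to at most one unit per level, by centroid.

    Uses closed (``covers``) point-in-polygon tests so centroids on a shared
    boundary go to the first unit that covers them — the assignment per level
    is always a function.  Returns a boolean mask of cells inside no unit at
    any level (flagged and excluded from aggregation downstream).
    """
    pts = shapely.points(grid.coords[:, 0], grid.coords[:, 1])
    # sanity check that the two inputs plausibly share a coordinate system
    ux0, uy0, ux1, uy1 = shapely.union_all([u.geometry for u in units]).bounds
    gx0, gy0 = grid.coords.min(axis=0)
    gx1, gy1 = grid.coords.max(axis=0)
    if gx1 < ux0 or gx0 > ux1 or gy1 < uy0 or gy0 > uy1:
        raise FormatError(
            "grid and admin polygons do not overlap — coordinate system mismatch?"
        )
    levels = sorted({u.level for u in units})
    assigned_any = np.zeros(len(grid), dtype=bool)
    for level in levels:
        taken = np.zeros(len(grid), dtype=bool)
        for unit in [u for u in units if u.level == level]:
            inside = shapely.covers(unit.geometry, pts) & ~taken
            unit.member_cells = list(grid.cell_id[inside])
            taken |= inside
            if not inside.any():
                warnings.warn(f"admin unit {unit.unit_id!r} ({level}) contains no grid cells")
        assigned_any |= taken
    outside = ~assigned_any
    if outside.any():
        logger.info("assign_cells_to_units: %d cells outside all polygons", int(outside.sum()))
    return outside


def read_grid_and_admin(grid_path, admin_path, covariate_names=None):
    """Read grid + admin inputs and wire the centroid-in-polygon membership."""
    grid = read_grid_table(grid_path, covariate_names)
    units = read_admin_geojson(admin_path)
    assign_cells_to_units(grid, units)
    return grid, units


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    surfaces: Mapping[str, pd.DataFrame],
    summaries: Mapping[str, pd.DataFrame],
    out_dir,
) -> dict[str, str]:
    """Write grid surfaces and admin summaries as delimited text.

    Returns a manifest mapping file name to its SHA-256 content checksum; the
    manifest itself is written alongside as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, df in dict(surfaces).items():
        p = out / f"surface_{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        manifest[p.name] = _sha256(p)
    for name, df in dict(summaries).items():
        p = out / f"summary_{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        manifest[p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
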