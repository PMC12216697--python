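"""Buffer-based spatial predictors at sites and grid cells.

Conventions (shared with the test oracles):

* closed disks — distance <= radius counts as inside;
* raster statistics use the cell-center-in-disk rule, not area weighting;
* empty count/length buffers are genuine zeros, an empty raster-mean disk is
  a structural error;
* the same code path produces site features and prediction-grid features, so
  the two matrices share one column schema by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point
from shapely.ops import unary_union
from shapely.strtree import STRtree

from ._grid import RasterGrid
from .synthetic_city import (
    LAND_COVER_CLASSES,
    POI_KINDS,
    ROAD_CLASSES,
    CovariateRasters,
    VectorLayers,
)

__all__ = [
    "ALLOWED_RADII",
    "PredictorSpec",
    "default_predictor_specs",
    "line_length_in_buffer",
    "point_count_in_buffer",
    "raster_mean_in_buffer",
    "landcover_composition_in_buffer",
    "distance_to_nearest_major_road",
    "build_feature_matrix",
]

ALLOWED_RADII = (50, 100, 200, 500)

_BUFFER_QUAD_SEGS = 64  # polygonal disk approximation, rel. error ~1e-4


class EmptyBufferError(ValueError):
    """A raster statistic was requested over a disk containing no cell center."""


@dataclass(frozen=True)
class PredictorSpec:
    """Declaration of one predictor variable.

    Attributes
    ----------
    name
        Column stem; multi-radius variables expand to ``name@radius``.
    source
        One of ``roads, pois, waterways, buildings`` (vector layers) or
        ``ndvi, pop_density, land_cover, elevation`` (raster layers).
    statistic
        ``length_sum | count | raster_mean | composition_share |
        distance_nearest | point_value``.
    layer_filter
        Road class / POI kind / land-cover class restriction; ``'all'`` or
        ``None`` for no restriction.
    radii
        Buffer radii in meters; empty for distance_nearest / point_value.
    period
        ``day | night | both`` — when the variable is considered sound
        producing (a-priori inclusion rule).
    """

    name: str
    source: str
    statistic: str
    layer_filter: str | None = None
    radii: tuple[int, ...] = ()
    period: str = "both"

    def __post_init__(self) -> None:
        if self.statistic in ("distance_nearest", "point_value"):
            if self.radii:
                raise ValueError(f"{self.name}: {self.statistic} takes no radius")
        else:
            if not self.radii:
                raise ValueError(f"{self.name}: radii required for {self.statistic}")
            bad = [r for r in self.radii if r not in ALLOWED_RADII]
            if bad:
                raise ValueError(
                    f"{self.name}: radii {bad} not in allowed set {ALLOWED_RADII}"
                )
        if self.period not in ("day", "night", "both"):
            raise ValueError(f"{self.name}: bad period {self.period!r}")

    def columns(self) -> list[str]:
        if self.radii:
            return [f"{self.name}@{r}" for r in self.radii]
        return [self.name]


def load_predictor_specs(path) -> list[PredictorSpec]:
    """Read a predictor inventory from a YAML list of spec mappings."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        PredictorSpec(**{**entry, "radii": tuple(entry.get("radii") or ())})
        for entry in raw
    ]


def default_predictor_specs() -> list[PredictorSpec]:
    """The full default predictor inventory, shipped as package data.

    Road length per class plus all roads, bus stations and pooled
    human-activity places (with schools, markets and bars additionally
    broken out; schools and markets are day-only), NDVI and population
    means, land-cover shares, building counts, waterway length, elevation
    at the point, and distance to the nearest major road.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("soundlur").joinpath("data/default_specs.yaml")
    ) as path:
        return load_predictor_specs(path)


#: POI kinds pooled under the 'human_activity' filter (bus stations are kept
#: separate as a road-transport indicator).
HUMAN_ACTIVITY_KINDS = tuple(k for k in POI_KINDS if k != "bus_station")


# ---------------------------------------------------------------------------
# elementary buffer operations
# ---------------------------------------------------------------------------


def _check_radius(radius: float) -> None:
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")


def line_length_in_buffer(lines, center: tuple[float, float], radius: float) -> float:
    """Total length (m) of ``lines`` inside the closed disk around ``center``."""
    _check_radius(radius)
    if not lines:
        return 0.0
    disk = Point(center).buffer(radius, quad_segs=_BUFFER_QUAD_SEGS)
    return float(sum(line.intersection(disk).length for line in lines))


def point_count_in_buffer(points, center: tuple[float, float], radius: float) -> int:
    """Number of points at Euclidean distance <= radius (boundary inclusive)."""
    _check_radius(radius)
    if len(points) == 0:
        return 0
    coords = np.array(
        [(p.x, p.y) if isinstance(p, Point) else tuple(p) for p in points]
    )
    d = np.hypot(coords[:, 0] - center[0], coords[:, 1] - center[1])
    return int(np.sum(d <= radius))


def _disk_cell_values(grid: RasterGrid, center: tuple[float, float], radius: float) -> np.ndarray:
    """Values of cells whose centers lie inside the closed disk."""
    cx, cy = center
    cs = grid.cell_size
    j0 = max(0, int(np.floor((cx - radius - grid.x0) / cs)))
    j1 = min(grid.nx, int(np.ceil((cx + radius - grid.x0) / cs)) + 1)
    i0 = max(0, int(np.floor((cy - radius - grid.y0) / cs)))
    i1 = min(grid.ny, int(np.ceil((cy + radius - grid.y0) / cs)) + 1)
    if i0 >= i1 or j0 >= j1:
        return np.empty(0)
    xs = grid.x0 + (np.arange(j0, j1) + 0.5) * cs
    ys = grid.y0 + (np.arange(i0, i1) + 0.5) * cs
    xg, yg = np.meshgrid(xs, ys)
    inside = (xg - cx) ** 2 + (yg - cy) ** 2 <= radius**2
    return grid.values[i0:i1, j0:j1][inside]


def raster_mean_in_buffer(grid: RasterGrid, center: tuple[float, float], radius: float) -> float:
    """Mean of cell values whose centers fall inside the disk."""
    _check_radius(radius)
    vals = _disk_cell_values(grid, center, radius)
    if vals.size == 0:
        raise EmptyBufferError(
            f"no cell centers within {radius} m of {center}; radius below cell pitch?"
        )
    return float(np.mean(vals))


def landcover_composition_in_buffer(
    grid: RasterGrid, center: tuple[float, float], radius: float
) -> dict[str, float]:
    """Per-class share of in-disk cell centers; shares sum to 1."""
    _check_radius(radius)
    classes = grid.classes or LAND_COVER_CLASSES
    vals = _disk_cell_values(grid, center, radius)
    if vals.size == 0:
        raise EmptyBufferError(f"no cell centers within {radius} m of {center}")
    return {
        cls: float(np.mean(vals.astype(int) == k)) for k, cls in enumerate(classes)
    }


def distance_to_nearest_major_road(center: tuple[float, float], roads) -> float:
    """Minimum Euclidean distance (m) from center to any major-road polyline.

    ``roads`` is either a VectorLayers or an iterable of major-road
    LineStrings.
    """
    if isinstance(roads, VectorLayers):
        lines = roads.roads_by_class("major")
    else:
        lines = list(roads)
    if not lines:
        raise ValueError("no major roads present")
    pt = Point(center)
    return float(min(line.distance(pt) for line in lines))


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------


class _LayerIndexes:
    """Per-source spatial indexes reused across targets."""

    def __init__(self, rasters: CovariateRasters, vectors: VectorLayers):
        self.rasters = rasters
        self.vectors = vectors
        self._trees: dict = {}
        self._kdtrees: dict = {}

    def lines(self, source: str, layer_filter: str | None) -> list[LineString]:
        if source == "roads":
            return self.vectors.roads_by_class(layer_filter or "all")
        if source == "waterways":
            return list(self.vectors.waterways)
        raise KeyError(f"no line layer {source!r}")

    def line_tree(self, source: str, layer_filter: str | None) -> tuple[STRtree, list]:
        key = ("line", source, layer_filter)
        if key not in self._trees:
            geoms = self.lines(source, layer_filter)
            self._trees[key] = (STRtree(geoms) if geoms else None, geoms)
        return self._trees[key]

    def point_coords(self, source: str, layer_filter: str | None) -> np.ndarray:
        key = ("pts", source, layer_filter)
        if key not in self._kdtrees:
            if source == "pois":
                if layer_filter == "human_activity":
                    pts = [
                        g
                        for k, g in self.vectors.pois
                        if k in HUMAN_ACTIVITY_KINDS
                    ]
                else:
                    pts = self.vectors.pois_by_kind(layer_filter or "all")
            elif source == "buildings":
                pts = list(self.vectors.buildings)
            else:
                raise KeyError(f"no point layer {source!r}")
            coords = (
                np.array([(p.x, p.y) for p in pts]) if pts else np.empty((0, 2))
            )
            tree = cKDTree(coords) if len(coords) else None
            self._kdtrees[key] = (tree, coords)
        return self._kdtrees[key]

    def raster(self, source: str) -> RasterGrid:
        try:
            return getattr(self.rasters, source)
        except AttributeError:
            raise KeyError(f"no raster layer {source!r}") from None


def _column_values(
    spec: PredictorSpec,
    radius: int | None,
    targets: np.ndarray,
    idx: _LayerIndexes,
) -> np.ndarray:
    n = len(targets)
    stat = spec.statistic
    if stat == "length_sum":
        tree, geoms = idx.line_tree(spec.source, spec.layer_filter)
        out = np.zeros(n)
        if tree is None:
            return out
        disks = shapely.buffer(
            shapely.points(targets[:, 0], targets[:, 1]),
            radius,
            quad_segs=_BUFFER_QUAD_SEGS,
        )
        for t in range(n):
            hits = tree.query(disks[t])
            if len(hits):
                out[t] = sum(geoms[h].intersection(disks[t]).length for h in hits)
        return out
    if stat == "count":
        tree, _ = idx.point_coords(spec.source, spec.layer_filter)
        if tree is None:
            return np.zeros(n)
        # cKDTree uses distance <= r, matching the closed-disk convention
        counts = tree.query_ball_point(targets, r=float(radius), return_length=True)
        return np.asarray(counts, dtype=float)
    if stat == "raster_mean":
        grid = idx.raster(spec.source)
        return np.array(
            [raster_mean_in_buffer(grid, tuple(t), radius) for t in targets]
        )
    if stat == "composition_share":
        grid = idx.raster(spec.source)
        cls = spec.layer_filter
        classes = grid.classes or LAND_COVER_CLASSES
        code = classes.index(cls)
        out = np.empty(n)
        for t in range(n):
            vals = _disk_cell_values(grid, tuple(targets[t]), radius)
            if vals.size == 0:
                raise EmptyBufferError(f"empty disk at {tuple(targets[t])}")
            out[t] = float(np.mean(vals.astype(int) == code))
        return out
    if stat == "point_value":
        grid = idx.raster(spec.source)
        return np.array([float(grid.value_at(*t)) for t in targets])
    if stat == "distance_nearest":
        geoms = idx.lines(spec.source, spec.layer_filter)
        if not geoms:
            raise ValueError(f"{spec.name}: no features in {spec.source}/{spec.layer_filter}")
        merged = unary_union(geoms)
        pts = shapely.points(targets[:, 0], targets[:, 1])
        return shapely.distance(pts, merged)
    raise ValueError(f"unknown statistic {stat!r}")


def build_feature_matrix(
    targets: pd.DataFrame,
    rasters: CovariateRasters,
    vectors: VectorLayers,
    specs: list[PredictorSpec] | None = None,
    id_column: str = "site_id",
) -> pd.DataFrame:
    """Feature matrix for sites or grid cells.

    Parameters
    ----------
    targets
        Frame with an id column plus ``x`` and ``y`` (planar meters).
    specs
        Predictor declarations; defaults to the full inventory.

    Returns
    -------
    Frame indexed by the id column with one column per (variable, radius)
    in deterministic spec order.
    """
    if specs is None:
        specs = default_predictor_specs()
    for col in (id_column, "x", "y"):
        if col not in targets.columns:
            raise ValueError(f"targets missing column {col!r}")
    idx = _LayerIndexes(rasters, vectors)
    pts = targets[["x", "y"]].to_numpy(dtype=float)
    data: dict[str, np.ndarray] = {}
    for spec in specs:
        radii = spec.radii if spec.radii else (None,)
        for r in radii:
            col = f"{spec.name}@{r}" if r is not None else spec.name
            data[col] = _column_values(spec, r, pts, idx)
    out = pd.DataFrame(data, index=pd.Index(targets[id_column], name=id_column))
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"feature matrix contains missing values in {bad}")
    return out
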