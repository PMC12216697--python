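"""Masked 50 m prediction surfaces and zonal summaries.

A cell is excluded (masked) when it matches any of the out-of-sample rules:
no road polyline intersects it, it is fully covered by a water body, or its
land cover is entirely the natural 'other' class with no road. Reasons
accumulate per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.ops import unary_union
from shapely.strtree import STRtree

from ._grid import RasterGrid
from .lur import FittedLUR
from .synthetic_city import LAND_COVER_CLASSES, VectorLayers

__all__ = [
    "PredictionGrid",
    "Surface",
    "build_grid",
    "compute_mask",
    "predict_surface",
    "summarize_surface",
    "road_proximity_zones",
]

MASK_REASONS = ("no_roads", "water", "natural_only")


@dataclass
class PredictionGrid:
    """Regular cell tiling of the extent with per-cell mask bookkeeping."""

    extent_m: tuple[float, float]
    cell_size: float
    mask_reasons: list[frozenset] | None = None

    def __post_init__(self) -> None:
        w, h = self.extent_m
        cs = self.cell_size
        if round(w / cs) * cs != w or round(h / cs) * cs != h:
            raise ValueError(f"extent {self.extent_m} not divisible by cell size {cs}")
        self.nx = int(round(w / cs))
        self.ny = int(round(h / cs))

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_frame(self) -> pd.DataFrame:
        """cell_id, i, j and center coordinates of every cell."""
        ii, jj = np.meshgrid(np.arange(self.ny), np.arange(self.nx), indexing="ij")
        i = ii.ravel()
        j = jj.ravel()
        return pd.DataFrame(
            {
                "cell_id": i * self.nx + j,
                "i": i,
                "j": j,
                "x": (j + 0.5) * self.cell_size,
                "y": (i + 0.5) * self.cell_size,
            }
        )

    def cell_polygons(self) -> np.ndarray:
        cf = self.cell_frame()
        cs = self.cell_size
        return shapely.box(
            cf["j"].to_numpy() * cs,
            cf["i"].to_numpy() * cs,
            (cf["j"].to_numpy() + 1) * cs,
            (cf["i"].to_numpy() + 1) * cs,
        )

    @property
    def mask(self) -> np.ndarray:
        """Boolean (n_cells,) — True where the cell is excluded."""
        if self.mask_reasons is None:
            return np.zeros(self.n_cells, dtype=bool)
        return np.array([len(r) > 0 for r in self.mask_reasons])

    def mask_grid(self) -> RasterGrid:
        """Mask as a bitmask raster (bit k set = reason MASK_REASONS[k])."""
        codes = np.zeros(self.n_cells, dtype=float)
        if self.mask_reasons is not None:
            for idx, reasons in enumerate(self.mask_reasons):
                codes[idx] = sum(1 << MASK_REASONS.index(r) for r in reasons)
        return RasterGrid(codes.reshape(self.ny, self.nx), 0.0, 0.0, self.cell_size)


@dataclass
class Surface:
    """Predicted prevalence (%) per unmasked cell; NaN on masked cells."""

    category: str
    period: str
    values: np.ndarray  # (ny, nx), NaN = masked
    grid: PredictionGrid

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("surface values must lie in [0, 100]")

    def unmasked_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    def raster(self) -> RasterGrid:
        return RasterGrid(self.values, 0.0, 0.0, self.grid.cell_size)


def build_grid(extent_m: tuple[float, float], cell_size: float = 50.0) -> PredictionGrid:
    """Cell tiling of the extent with centers at cell midpoints."""
    return PredictionGrid(tuple(extent_m), cell_size)


def compute_mask(
    grid: PredictionGrid,
    vectors: VectorLayers,
    land_cover: RasterGrid,
    road_predicate: str = "intersects",
    road_distance_m: float = 0.0,
) -> PredictionGrid:
    """Apply the out-of-sample exclusion rules to every cell.

    * ``no_roads`` — no road polyline intersects the cell polygon (or comes
      within ``road_distance_m`` when ``road_predicate='distance'``);
    * ``water`` — the cell is fully covered by a water-body polygon;
    * ``natural_only`` — every land-cover cell inside it is class 'other'
      and no road intersects.
    """
    cells = grid.cell_polygons()
    n = grid.n_cells

    road_geoms = [g for _, g in vectors.roads]
    has_road = np.zeros(n, dtype=bool)
    if road_geoms:
        tree = STRtree(road_geoms)
        if road_predicate == "intersects":
            hit_cells, _ = tree.query(cells, predicate="intersects")
            has_road[np.unique(hit_cells)] = True
        elif road_predicate == "distance":
            hit_cells, _ = tree.query(
                cells, predicate="dwithin", distance=road_distance_m
            )
            has_road[np.unique(hit_cells)] = True
        else:
            raise ValueError(f"unknown road predicate {road_predicate!r}")

    water = np.zeros(n, dtype=bool)
    if vectors.water_bodies:
        wunion = unary_union(vectors.water_bodies)
        cand = STRtree([wunion]).query(cells, predicate="intersects")[0]
        for idx in np.unique(cand):
            water[idx] = bool(shapely.covers(wunion, cells[idx]))

    # natural_only: all land-cover cells with centers inside the cell polygon
    # are 'other'. With the default co-registered 50 m land-cover raster this
    # is the single coincident cell.
    other_code = (land_cover.classes or LAND_COVER_CLASSES).index("other")
    cf = grid.cell_frame()
    lc_vals = np.array(
        [_landcover_all_other(land_cover, x, y, grid.cell_size, other_code)
         for x, y in zip(cf["x"], cf["y"])]
    )
    natural = lc_vals & ~has_road

    reasons = []
    for idx in range(n):
        r = set()
        if not has_road[idx]:
            r.add("no_roads")
        if water[idx]:
            r.add("water")
        if natural[idx]:
            r.add("natural_only")
        reasons.append(frozenset(r))
    return PredictionGrid(grid.extent_m, grid.cell_size, mask_reasons=reasons)


def _landcover_all_other(
    land_cover: RasterGrid, cx: float, cy: float, cell_size: float, other_code: int
) -> bool:
    half = cell_size / 2.0
    cs = land_cover.cell_size
    j0 = max(0, int(np.floor((cx - half - land_cover.x0) / cs)))
    j1 = min(land_cover.nx, int(np.ceil((cx + half - land_cover.x0) / cs)))
    i0 = max(0, int(np.floor((cy - half - land_cover.y0) / cs)))
    i1 = min(land_cover.ny, int(np.ceil((cy + half - land_cover.y0) / cs)))
    block = land_cover.values[i0:max(i1, i0 + 1), j0:max(j1, j0 + 1)]
    return bool(np.all(block.astype(int) == other_code))


def predict_surface(
    model: FittedLUR, grid_features: pd.DataFrame, grid: PredictionGrid
) -> Surface:
    """Model predictions on unmasked cells; masked cells carry NaN.

    ``grid_features`` is indexed by cell_id and must contain the model's
    column schema (identical to the training schema by construction when
    produced by ``features.build_feature_matrix``).
    """
    missing = [c for c in model.columns if c not in grid_features.columns]
    if missing:
        raise ValueError(f"grid features missing model columns: {missing}")
    mask = grid.mask
    values = np.full(grid.n_cells, np.nan)
    unmasked_ids = np.flatnonzero(~mask)
    feats = grid_features.loc[unmasked_ids]
    values[unmasked_ids] = model.predict(feats)
    return Surface(
        category=model.spec.category,
        period=model.spec.period,
        values=values.reshape(grid.ny, grid.nx),
        grid=grid,
    )


def summarize_surface(
    surface: Surface, zones: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Order statistics of unmasked cell values per zone.

    ``zones`` maps a zone name to a boolean selector over cells (flat,
    length n_cells). Fully masked zones are flagged and produce no row.
    """
    flat = surface.values.ravel()
    rows = []
    flagged = []
    for name, selector in zones.items():
        vals = flat[np.asarray(selector, dtype=bool)]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            flagged.append(name)
            continue
        rows.append(
            {
                "zone": name,
                "category": surface.category,
                "period": surface.period,
                "n_cells": int(vals.size),
                "min": float(vals.min()),
                "q1": float(np.percentile(vals, 25)),
                "median": float(np.median(vals)),
                "q3": float(np.percentile(vals, 75)),
                "max": float(vals.max()),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["empty_zones"] = flagged
    return out


def road_proximity_zones(
    grid: PredictionGrid, vectors: VectorLayers, max_distance_m: float = 100.0
) -> dict[str, np.ndarray]:
    """Non-exclusive zones: cells within ``max_distance_m`` of each road class."""
    cf = grid.cell_frame()
    pts = shapely.points(cf["x"].to_numpy(), cf["y"].to_numpy())
    zones: dict[str, np.ndarray] = {}
    for cls in ("major", "secondary_tertiary", "minor"):
        lines = vectors.roads_by_class(cls)
        if not lines:
            zones[f"near_{cls}"] = np.zeros(grid.n_cells, dtype=bool)
            continue
        merged = unary_union(lines)
        zones[f"near_{cls}"] = shapely.distance(pts, merged) <= max_distance_m
    return zones
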