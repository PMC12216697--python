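"""Serialization of run artifacts: GeoJSON vectors, ASCII-grid rasters,
CSV tables, YAML configs. Everything is plain text and deterministic."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from ._grid import RasterGrid, read_ascii_grid, write_ascii_grid
from .synthetic_city import CovariateRasters, VectorLayers

__all__ = [
    "write_vectors",
    "read_vectors",
    "write_rasters",
    "read_rasters",
    "write_clips",
    "read_clips",
    "write_ontology",
    "read_ontology",
]


def _feature(geom, properties: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": properties}


def write_vectors(vectors: VectorLayers, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layers = {
        "roads.geojson": [
            _feature(g, {"road_class": c}) for c, g in vectors.roads
        ],
        "pois.geojson": [_feature(g, {"kind": k}) for k, g in vectors.pois],
        "waterways.geojson": [_feature(g, {}) for g in vectors.waterways],
        "water_bodies.geojson": [_feature(g, {}) for g in vectors.water_bodies],
        "buildings.geojson": [_feature(g, {}) for g in vectors.buildings],
    }
    for fname, feats in layers.items():
        doc = {"type": "FeatureCollection", "features": feats}
        (out_dir / fname).write_text(json.dumps(doc, sort_keys=True))


def _read_layer(path: Path) -> list[tuple[dict, object]]:
    doc = json.loads(path.read_text())
    return [(f["properties"], shape(f["geometry"])) for f in doc["features"]]


def read_vectors(in_dir: str | Path) -> VectorLayers:
    in_dir = Path(in_dir)
    return VectorLayers(
        roads=[(p["road_class"], g) for p, g in _read_layer(in_dir / "roads.geojson")],
        pois=[(p["kind"], g) for p, g in _read_layer(in_dir / "pois.geojson")],
        waterways=[g for _, g in _read_layer(in_dir / "waterways.geojson")],
        water_bodies=[g for _, g in _read_layer(in_dir / "water_bodies.geojson")],
        buildings=[g for _, g in _read_layer(in_dir / "buildings.geojson")],
    )


def write_rasters(rasters: CovariateRasters, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("ndvi", "pop_density", "land_cover", "elevation"):
        write_ascii_grid(getattr(rasters, name), out_dir / f"{name}.asc")


def read_rasters(in_dir: str | Path) -> CovariateRasters:
    from .synthetic_city import LAND_COVER_CLASSES

    in_dir = Path(in_dir)
    grids = {
        name: read_ascii_grid(in_dir / f"{name}.asc")
        for name in ("ndvi", "pop_density", "land_cover", "elevation")
    }
    lc = grids["land_cover"]
    grids["land_cover"] = RasterGrid(
        lc.values.astype(int), lc.x0, lc.y0, lc.cell_size, LAND_COVER_CLASSES
    )
    return CovariateRasters(**grids)


def write_clips(clips: pd.DataFrame, path: str | Path) -> None:
    clips.to_csv(path, index=False)


def read_clips(path: str | Path) -> pd.DataFrame:
    clips = pd.read_csv(path, keep_default_na=False)
    clips["timestamp"] = pd.to_datetime(clips["timestamp"])
    return clips


def write_ontology(ontology: dict[str, str], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(ontology, sort_keys=True))


def read_ontology(path: str | Path) -> dict[str, str]:
    return yaml.safe_load(Path(path).read_text())
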