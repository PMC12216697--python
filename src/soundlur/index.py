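"""Composite SoundType Index: geometric aggregation of min-max-normalized
sound levels with sound-type presence proportions, per category and period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._grid import RasterGrid
from .predict import Surface

__all__ = [
    "NormalizationParams",
    "IndexSpec",
    "IndexSurface",
    "fit_normalization",
    "normalize_levels",
    "prevalence_to_proportion",
    "geometric_index",
    "build_index_surface",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Min-max parameters of a level surface, stored with the output so the
    index remains interpretable outside its fitting domain."""

    period: str
    data_min: float
    data_range: float

    def __post_init__(self) -> None:
        if self.data_range <= 0:
            raise ValueError("data_range must be positive")


@dataclass(frozen=True)
class IndexSpec:
    category: str
    period: str
    w_level: float = 0.5
    w_prevalence: float = 0.5

    def __post_init__(self) -> None:
        if self.w_level < 0 or self.w_prevalence < 0:
            raise ValueError("weights must be non-negative")
        if not np.isclose(self.w_level + self.w_prevalence, 1.0):
            raise ValueError("weights must sum to 1")


@dataclass
class IndexSurface:
    category: str
    period: str
    values: np.ndarray  # (ny, nx) in [0, 1], NaN = masked
    params: NormalizationParams
    spec: IndexSpec

    def raster(self, cell_size: float = 50.0) -> RasterGrid:
        return RasterGrid(self.values, 0.0, 0.0, cell_size)


def fit_normalization(levels: np.ndarray, period: str) -> NormalizationParams:
    """Min/range over the finite (unmasked) cells of a level surface."""
    finite = np.asarray(levels, dtype=float)
    finite = finite[np.isfinite(finite)]
    if finite.size == 0:
        raise ValueError("no unmasked level cells to fit normalization on")
    rng = float(finite.max() - finite.min())
    if rng == 0:
        raise ValueError("level surface has zero range")
    return NormalizationParams(period=period, data_min=float(finite.min()), data_range=rng)


def normalize_levels(levels, params: NormalizationParams) -> np.ndarray:
    """(x - data_min) / data_range; 0 at the fitted minimum, 1 at the maximum."""
    return (np.asarray(levels, dtype=float) - params.data_min) / params.data_range


def prevalence_to_proportion(prevalence):
    """Percentage in [0, 100] -> proportion in [0, 1]."""
    arr = np.asarray(prevalence, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 100):
        raise ValueError("prevalence out of [0, 100]")
    out = arr / 100.0
    return float(out) if np.isscalar(prevalence) else out


def geometric_index(norm_level, proportion, spec: IndexSpec):
    """Weighted geometric mean norm_level^w_level * proportion^w_prevalence.

    With equal weights this is sqrt(norm_level * proportion). Inputs in
    [0, 1] give an index in [0, 1]; a zero in either input annihilates it.
    """
    nl = np.asarray(norm_level, dtype=float)
    pr = np.asarray(proportion, dtype=float)
    for name, arr in (("norm_level", nl), ("proportion", pr)):
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError(f"{name} out of [0, 1]")
    out = nl**spec.w_level * pr**spec.w_prevalence
    return float(out) if (np.isscalar(norm_level) and np.isscalar(proportion)) else out


def build_index_surface(
    level_surface: RasterGrid | np.ndarray,
    prevalence_surface: Surface,
    spec: IndexSpec,
    params: NormalizationParams | None = None,
    normalize_jointly_with: np.ndarray | None = None,
) -> IndexSurface:
    """Cell-wise index on the intersection of unmasked cells.

    Normalization parameters default to a per-period fit on the level
    surface's unmasked cells (pass ``normalize_jointly_with`` — the other
    period's levels — to fit min/range over both periods jointly, the
    alternative reading).
    """
    levels = (
        level_surface.values if isinstance(level_surface, RasterGrid) else np.asarray(level_surface)
    )
    prev = prevalence_surface.values
    if levels.shape != prev.shape:
        raise ValueError(
            f"grid mismatch: levels {levels.shape} vs prevalence {prev.shape}"
        )
    common = np.isfinite(levels) & np.isfinite(prev)
    if params is None:
        fit_on = levels[common]
        if normalize_jointly_with is not None:
            fit_on = np.concatenate([fit_on, np.asarray(normalize_jointly_with).ravel()])
        params = fit_normalization(fit_on, spec.period)

    values = np.full(levels.shape, np.nan)
    nl = np.clip(normalize_levels(levels[common], params), 0.0, 1.0)
    pr = prevalence_to_proportion(prev[common])
    values[common] = geometric_index(nl, pr, spec)
    return IndexSurface(
        category=spec.category,
        period=spec.period,
        values=values,
        params=params,
        spec=spec,
    )
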