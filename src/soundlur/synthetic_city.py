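"""Synthetic study area, monitoring campaign and ground-truth sound process.

Everything downstream (prevalence tables, buffer features, forest models,
prediction surfaces, the composite index) can be exercised end-to-end on the
outputs of this module without any external data. The generated city has the
spatial structure the analysis assumes: a dense low-vegetation core, a greener
sparse periphery, a road network with three classes, points of interest
concentrated in built-up land, and a per-clip sound process that is logistic
in local covariates with separate day and night regimes.

All geometry lives in a single planar frame in meters.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

from ._grid import RasterGrid

__all__ = [
    "CityConfig",
    "CovariateRasters",
    "VectorLayers",
    "Site",
    "GroundTruth",
    "ClipLabel",
    "LAND_COVER_CLASSES",
    "ROAD_CLASSES",
    "POI_KINDS",
    "FINE_CLASSES",
    "CATEGORIES",
    "generate_covariate_rasters",
    "generate_vector_layers",
    "sample_sites",
    "site_covariates",
    "expected_prevalence",
    "simulate_clip_labels",
    "simulate_level_surface",
    "default_ground_truth",
    "in_core",
]

LAND_COVER_CLASSES = ("formal_residential", "informal_residential", "cbi", "other")
ROAD_CLASSES = ("major", "secondary_tertiary", "minor")
POI_KINDS = (
    "church",
    "mosque",
    "hospital",
    "school",
    "restaurant",
    "market",
    "bar",
    "bus_station",
)

#: Modelled sound categories plus the two the analysis drops as targets.
CATEGORIES = (
    "road_transport",
    "animal_insect",
    "music",
    "speech",
    "geophysical_nature",
    "aircraft",
)

#: Stand-in fine-class vocabulary emitted by the simulated classifier.
FINE_CLASSES: dict[str, tuple[str, ...]] = {
    "road_transport": ("vehicle_engine", "honking", "motorbike", "truck_rumble"),
    "animal_insect": ("birdsong", "insect_chirp", "dog_bark", "rooster_crow"),
    "music": ("radio_music", "singing", "drumming"),
    "speech": ("talking", "laughter", "shouting"),
    "geophysical_nature": ("rain", "wind", "thunder"),
    "aircraft": ("airplane_engine",),
    "other": ("clatter", "alarm", "smash", "ambient"),
}

DAY_START_HOUR = 6
DAY_END_HOUR = 22  # exclusive; [06:00, 22:00) is day, the rest night


class ConfigurationError(ValueError):
    """Raised for inconsistent city configurations."""


@dataclass
class CityConfig:
    """Parameters of the synthetic city and monitoring campaign."""

    extent_m: tuple[float, float] = (5000.0, 5000.0)
    cell_size_m: float = 50.0
    n_fixed_sites: int = 9
    n_rotating_sites: int = 120
    core_fraction: float = 0.5
    strata_weights: dict[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in LAND_COVER_CLASSES}
    )
    campaign_days_fixed: int = 45
    campaign_days_rotating: int = 7
    start_date: dt.date = dt.date(2019, 4, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.extent_m
        cs = self.cell_size_m
        if w <= 0 or h <= 0 or cs <= 0:
            raise ConfigurationError("extent and cell size must be positive")
        if (round(w / cs) * cs != w) or (round(h / cs) * cs != h):
            raise ConfigurationError(
                f"extent {self.extent_m} not divisible by cell size {cs}"
            )
        if not (0.0 <= self.core_fraction <= 1.0):
            raise ConfigurationError("core_fraction must lie in [0, 1]")
        if isinstance(self.start_date, str):
            self.start_date = dt.date.fromisoformat(self.start_date)

    @property
    def shape(self) -> tuple[int, int]:
        w, h = self.extent_m
        return int(round(h / self.cell_size_m)), int(round(w / self.cell_size_m))

    @property
    def center(self) -> tuple[float, float]:
        return self.extent_m[0] / 2.0, self.extent_m[1] / 2.0


def in_core(x, y, config: CityConfig):
    """True inside the central "core" zone (central square, 25% of the area)."""
    cx, cy = config.center
    w, h = config.extent_m
    return (np.abs(np.asarray(x) - cx) <= w / 4.0) & (
        np.abs(np.asarray(y) - cy) <= h / 4.0
    )


@dataclass
class CovariateRasters:
    ndvi: RasterGrid
    pop_density: RasterGrid
    land_cover: RasterGrid  # integer codes into LAND_COVER_CLASSES
    elevation: RasterGrid

    def __post_init__(self) -> None:
        ref = self.ndvi
        for name in ("pop_density", "land_cover", "elevation"):
            if not getattr(self, name).registered_with(ref):
                raise ValueError(f"raster {name!r} not registered with ndvi grid")


@dataclass
class VectorLayers:
    """Vector geometry of the synthetic city (shapely, planar meters)."""

    roads: list[tuple[str, LineString]]
    pois: list[tuple[str, Point]]
    waterways: list[LineString]
    water_bodies: list[Polygon]
    buildings: list[Point]

    def roads_by_class(self, road_class: str) -> list[LineString]:
        if road_class == "all":
            return [g for _, g in self.roads]
        if road_class not in ROAD_CLASSES:
            raise KeyError(f"unknown road class {road_class!r}")
        return [g for c, g in self.roads if c == road_class]

    def pois_by_kind(self, kind: str) -> list[Point]:
        if kind == "all":
            return [g for _, g in self.pois]
        return [g for k, g in self.pois if k == kind]


@dataclass(frozen=True)
class Site:
    site_id: str
    x: float
    y: float
    site_type: str  # 'fixed' | 'rotating'
    stratum: str
    in_core: bool


@dataclass
class GroundTruth:
    """Logistic presence model per category x period, plus the level model.

    ``coefficients[(category, period)]`` maps covariate name -> log-odds
    coefficient; ``intercepts[(category, period)]`` is the log-odds intercept.
    Covariates are the ones returned by :func:`site_covariates`.
    """

    intercepts: dict[tuple[str, str], float]
    coefficients: dict[tuple[str, str], dict[str, float]]
    other_rate: float = 0.20  # flat per-clip probability of a miscellaneous sound
    level_base_dba: float = 48.0
    level_road_gain_dba: float = 16.0
    level_tau_m: float = 300.0
    level_night_offset_dba: float = 7.0
    level_noise_sd_dba: float = 1.5


def default_ground_truth() -> GroundTruth:
    """Ground truth with the qualitative structure reported for real cities:
    road sound tracks the road network and falls with vegetation; animal
    sound is the mirror image and rises at night; music/speech track
    population density; geophysical sound is rare everywhere (zero-inflated).
    """
    spec = {
        "road_transport": {
            "day": (-1.2, {"road_km_200": 4.0, "ndvi": -2.5, "log_pop": 0.25}),
            "night": (-2.0, {"road_km_200": 4.0, "ndvi": -2.5, "log_pop": 0.25}),
        },
        "animal_insect": {
            "day": (-0.5, {"road_km_200": -3.0, "ndvi": 3.0, "log_pop": -0.15}),
            "night": (0.3, {"road_km_200": -3.0, "ndvi": 3.0, "log_pop": -0.15}),
        },
        "music": {
            "day": (-3.2, {"road_km_200": 0.5, "ndvi": 0.0, "log_pop": 0.6}),
            "night": (-3.6, {"road_km_200": 0.5, "ndvi": 0.0, "log_pop": 0.6}),
        },
        "speech": {
            "day": (-3.0, {"road_km_200": 0.0, "ndvi": -0.5, "log_pop": 0.8}),
            "night": (-4.5, {"road_km_200": 0.0, "ndvi": -0.5, "log_pop": 0.8}),
        },
        "geophysical_nature": {
            "day": (-5.0, {"road_km_200": 0.0, "ndvi": 1.5, "log_pop": 0.0}),
            "night": (-4.8, {"road_km_200": 0.0, "ndvi": 1.5, "log_pop": 0.0}),
        },
        "aircraft": {
            "day": (-4.5, {}),
            "night": (-5.0, {}),
        },
    }
    intercepts = {}
    coefficients = {}
    for cat, per_period in spec.items():
        for period, (b0, coefs) in per_period.items():
            intercepts[(cat, period)] = b0
            coefficients[(cat, period)] = dict(coefs)
    return GroundTruth(intercepts=intercepts, coefficients=coefficients)


@dataclass(frozen=True)
class ClipLabel:
    site_id: str
    timestamp: dt.datetime
    detected_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (1 <= len(self.detected_classes) <= 3):
            raise ValueError("a clip carries between 1 and 3 detected classes")


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


def _smooth_noise(rng: np.random.Generator, ny: int, nx: int, block: int = 8) -> np.ndarray:
    """Low-frequency noise field in roughly [-1, 1] via block upsampling."""
    coarse = rng.normal(size=(ny // block + 2, nx // block + 2))
    fine = np.kron(coarse, np.ones((block, block)))
    # cheap smoothing: average the four block-shifted copies
    sm = (
        fine[:-block, :-block]
        + fine[block:, :-block]
        + fine[:-block, block:]
        + fine[block:, block:]
    ) / 4.0
    return sm[:ny, :nx]


def generate_covariate_rasters(config: CityConfig) -> CovariateRasters:
    """Generate registered NDVI / population / land-cover / elevation grids.

    The core is dense and little vegetated, the periphery is the reverse,
    giving the urban gradient the downstream models rely on.
    """
    ny, nx = config.shape
    cs = config.cell_size_m
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    xs = (np.arange(nx) + 0.5) * cs
    ys = (np.arange(ny) + 0.5) * cs
    xg, yg = np.meshgrid(xs, ys)
    cx, cy = config.center
    d = np.hypot(xg - cx, yg - cy)
    d_norm = d / np.hypot(cx, cy)  # 0 at center, 1 at corners

    ndvi = -0.05 + 0.75 * d_norm + 0.08 * _smooth_noise(rng, ny, nx) + rng.normal(
        0.0, 0.02, size=(ny, nx)
    )
    ndvi = np.clip(ndvi, -1.0, 1.0)

    pop = 28000.0 * np.exp(-3.2 * d_norm) * np.exp(
        0.35 * _smooth_noise(rng, ny, nx) + rng.normal(0.0, 0.15, size=(ny, nx))
    )
    pop = np.clip(pop, 0.0, None)

    score = d_norm + 0.12 * _smooth_noise(rng, ny, nx)
    land = np.full((ny, nx), LAND_COVER_CLASSES.index("other"), dtype=int)
    land[score < 0.72] = LAND_COVER_CLASSES.index("formal_residential")
    land[score < 0.45] = LAND_COVER_CLASSES.index("informal_residential")
    land[score < 0.22] = LAND_COVER_CLASSES.index("cbi")

    elev = (
        40.0
        + 35.0 * (xg / config.extent_m[0])
        + 12.0 * (yg / config.extent_m[1])
        + 4.0 * _smooth_noise(rng, ny, nx)
    )

    mk = lambda v, cls=None: RasterGrid(v, 0.0, 0.0, cs, cls)
    return CovariateRasters(
        ndvi=mk(ndvi),
        pop_density=mk(pop),
        land_cover=mk(land, LAND_COVER_CLASSES),
        elevation=mk(elev),
    )


# ---------------------------------------------------------------------------
# vectors
# ---------------------------------------------------------------------------


def _clip_to_extent(line: LineString, w: float, h: float) -> LineString | None:
    box = Polygon([(0, 0), (w, 0), (w, h), (0, h)])
    clipped = line.intersection(box)
    if clipped.is_empty or clipped.geom_type != "LineString":
        return None
    return clipped


def generate_vector_layers(config: CityConfig, rasters: CovariateRasters) -> VectorLayers:
    """Roads in three classes, POIs weighted toward built-up land, a river,
    a lake, and building points tracking population density."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    w, h = config.extent_m
    cx, cy = config.center

    roads: list[tuple[str, LineString]] = []
    # two crossing arterials through the core
    roads.append(("major", LineString([(0, cy), (w, cy)])))
    roads.append(("major", LineString([(cx, 0), (cx, h)])))
    # ring-like secondary/tertiary grid
    for frac in (0.25, 0.75):
        roads.append(("secondary_tertiary", LineString([(0, h * frac), (w, h * frac)])))
        roads.append(("secondary_tertiary", LineString([(w * frac, 0), (w * frac, h)])))

    # minor roads: short random segments concentrated in built-up cells
    land = rasters.land_cover.values
    built = np.isin(
        land,
        [
            LAND_COVER_CLASSES.index("cbi"),
            LAND_COVER_CLASSES.index("informal_residential"),
            LAND_COVER_CLASSES.index("formal_residential"),
        ],
    )
    ny, nx = land.shape
    cs = config.cell_size_m
    n_minor = max(20, int(w * h / 8.0e5))
    weights = np.where(built, 1.0, 0.1).ravel()
    weights = weights / weights.sum()
    cells = rng.choice(ny * nx, size=n_minor, replace=False, p=weights)
    for cell in cells:
        i, j = divmod(int(cell), nx)
        x0 = (j + 0.5) * cs + rng.uniform(-cs / 2, cs / 2)
        y0 = (i + 0.5) * cs + rng.uniform(-cs / 2, cs / 2)
        length = rng.uniform(150.0, 450.0)
        ang = rng.uniform(0, 2 * np.pi)
        line = LineString(
            [(x0, y0), (x0 + length * np.cos(ang), y0 + length * np.sin(ang))]
        )
        clipped = _clip_to_extent(line, w, h)
        if clipped is not None:
            roads.append(("minor", clipped))

    # POIs weighted toward cbi / informal land
    kind_weight = {
        "cbi": 6.0,
        "informal_residential": 3.0,
        "formal_residential": 2.0,
        "other": 0.3,
    }
    wcell = np.array(
        [kind_weight[LAND_COVER_CLASSES[k]] for k in land.ravel()], dtype=float
    )
    wcell /= wcell.sum()
    n_pois = max(80, int(w * h / 2.5e4))
    poi_cells = rng.choice(ny * nx, size=n_pois, replace=True, p=wcell)
    pois: list[tuple[str, Point]] = []
    for cell in poi_cells:
        i, j = divmod(int(cell), nx)
        x = np.clip((j + rng.uniform()) * cs, 0, w)
        y = np.clip((i + rng.uniform()) * cs, 0, h)
        kind = POI_KINDS[rng.integers(len(POI_KINDS))]
        pois.append((kind, Point(x, y)))

    # one meandering river across the top third, one lake in the periphery
    t = np.linspace(0, 1, 60)
    river = LineString(
        np.column_stack([t * w, 0.8 * h + 0.08 * h * np.sin(t * 4 * np.pi)])
    )
    lake_center = Point(0.85 * w, 0.15 * h)
    lake = lake_center.buffer(min(w, h) * 0.045, quad_segs=32)

    n_bld = max(200, int(w * h / 1.0e4))
    pvals = rasters.pop_density.values.ravel().astype(float)
    pvals = pvals / pvals.sum()
    bcells = rng.choice(ny * nx, size=n_bld, replace=True, p=pvals)
    bi, bj = np.divmod(bcells, nx)
    bx = np.clip((bj + rng.uniform(size=n_bld)) * cs, 0, w)
    by = np.clip((bi + rng.uniform(size=n_bld)) * cs, 0, h)
    buildings = [Point(x, y) for x, y in zip(bx, by)]

    return VectorLayers(
        roads=roads,
        pois=pois,
        waterways=[river],
        water_bodies=[lake],
        buildings=buildings,
    )


# ---------------------------------------------------------------------------
# sites
# ---------------------------------------------------------------------------


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of `total` proportional to `weights`."""
    weights = np.asarray(weights, dtype=float)
    shares = total * weights / weights.sum()
    counts = np.floor(shares).astype(int)
    rem = shares - counts
    for idx in np.argsort(-rem)[: total - counts.sum()]:
        counts[idx] += 1
    return counts


def sample_sites(config: CityConfig, rasters: CovariateRasters) -> list[Site]:
    """Stratified random site sample with core oversampling.

    Rotating sites are allocated across the land-cover strata according to
    ``strata_weights`` and ``round(core_fraction * n_rotating)`` of them are
    forced into the core zone (spilled between strata when a stratum has no
    core cells). Fixed sites are spread round-robin across strata.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    land = rasters.land_cover.values
    ny, nx = land.shape
    cs = config.cell_size_m

    strata = list(config.strata_weights)
    for s in strata:
        if s not in LAND_COVER_CLASSES:
            raise ConfigurationError(f"unknown stratum {s!r}")
        if not np.any(land == LAND_COVER_CLASSES.index(s)):
            raise ConfigurationError(f"stratum {s!r} absent from land-cover raster")

    xs = (np.arange(nx) + 0.5) * cs
    ys = (np.arange(ny) + 0.5) * cs
    xg, yg = np.meshgrid(xs, ys)
    core_mask = in_core(xg, yg, config)

    counts = _largest_remainder(
        config.n_rotating_sites, np.array([config.strata_weights[s] for s in strata])
    )
    core_target = int(round(config.core_fraction * config.n_rotating_sites))

    core_flat = core_mask.ravel()
    land_flat = land.ravel()

    # phase 1: draw the per-stratum counts anywhere in the stratum
    chosen: dict[str, np.ndarray] = {}
    for s, n_s in zip(strata, counts):
        pool = np.flatnonzero(land_flat == LAND_COVER_CLASSES.index(s))
        if n_s > len(pool):
            raise ConfigurationError(
                f"stratum {s!r} has only {len(pool)} cells for {n_s} sites"
            )
        chosen[s] = rng.choice(pool, size=int(n_s), replace=False)

    # phase 2: swap sites within their stratum between core and periphery
    # until the core count matches the target (as far as availability allows)
    def _core_count() -> int:
        return int(sum(core_flat[c].sum() for c in chosen.values()))

    for direction in (1, -1):  # 1: need more core sites, -1: fewer
        for s in strata:
            while direction * (_core_count() - core_target) < 0:
                cells = chosen[s]
                want_core = direction > 0
                movable = cells[core_flat[cells] != want_core]
                pool = np.flatnonzero(
                    (land_flat == LAND_COVER_CLASSES.index(s))
                    & (core_flat == want_core)
                )
                pool = np.setdiff1d(pool, cells)
                if len(movable) == 0 or len(pool) == 0:
                    break
                out_cell = movable[rng.integers(len(movable))]
                in_cell = pool[rng.integers(len(pool))]
                cells = cells.copy()
                cells[np.flatnonzero(cells == out_cell)[0]] = in_cell
                chosen[s] = cells

    sites: list[Site] = []
    r_idx = 1
    for s in strata:
        for cell in sorted(int(c) for c in chosen[s]):
            i, j = divmod(cell, nx)
            x = (j + rng.uniform()) * cs
            y = (i + rng.uniform()) * cs
            # core membership is a property of the sampling frame (the cell),
            # so jitter across the zone boundary cannot change it
            sites.append(
                Site(f"R{r_idx:03d}", x, y, "rotating", s, bool(core_flat[cell]))
            )
            r_idx += 1

    f_idx = 1
    for k in range(config.n_fixed_sites):
        s = strata[k % len(strata)]
        pool = np.flatnonzero(land_flat == LAND_COVER_CLASSES.index(s))
        cell = int(rng.choice(pool))
        i, j = divmod(cell, nx)
        x = (j + rng.uniform()) * cs
        y = (i + rng.uniform()) * cs
        sites.append(Site(f"F{f_idx:03d}", x, y, "fixed", s, bool(in_core(x, y, config))))
        f_idx += 1
    return sites


def sites_to_frame(sites: list[Site]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "x": s.x,
                "y": s.y,
                "site_type": s.site_type,
                "stratum": s.stratum,
                "in_core": s.in_core,
            }
            for s in sites
        ]
    )


# ---------------------------------------------------------------------------
# sound process
# ---------------------------------------------------------------------------


def site_covariates(
    x: float, y: float, rasters: CovariateRasters, vectors: VectorLayers
) -> dict[str, float]:
    """Local covariates driving the ground-truth logistic model."""
    road_len = 0.0
    disk = Point(x, y).buffer(200.0, quad_segs=64)
    for cls in ("major", "secondary_tertiary"):
        for line in vectors.roads_by_class(cls):
            if line.distance(Point(x, y)) <= 200.0:
                road_len += line.intersection(disk).length
    pop = float(rasters.pop_density.value_at(x, y))
    return {
        "ndvi": float(rasters.ndvi.value_at(x, y)),
        "road_km_200": road_len / 1000.0,
        "log_pop": float(np.log10(pop + 1.0)),
    }


def _logistic(z: float) -> float:
    from scipy.special import expit

    return float(expit(z))


def presence_probability(
    ground_truth: GroundTruth, covariates: dict[str, float], category: str, period: str
) -> float:
    z = ground_truth.intercepts[(category, period)]
    for name, coef in ground_truth.coefficients[(category, period)].items():
        z += coef * covariates[name]
    return float(_logistic(z))


def expected_prevalence(
    ground_truth: GroundTruth, covariates: dict[str, float], category: str, period: str
) -> float:
    """Closed-form expected prevalence (%) implied by the logistic model."""
    return 100.0 * presence_probability(ground_truth, covariates, category, period)


def _clip_minutes() -> np.ndarray:
    """Minute offsets of the 144 scheduled clips of a day (every 10 min)."""
    return np.arange(0, 24 * 60, 10)


def simulate_clip_labels(
    sites: list[Site],
    ground_truth: GroundTruth,
    rasters: CovariateRasters,
    vectors: VectorLayers,
    config: CityConfig,
) -> pd.DataFrame:
    """Simulate the per-clip classifier output for the whole campaign.

    Each category fires independently per clip with its logistic probability;
    present categories draw a prominence and the top three survive, each
    emitting one representative fine-class label. Clips with no category
    present emit a single ``ambient`` label.

    Returns a frame with columns ``site_id, timestamp, class1, class2, class3``
    (class2/class3 empty strings when fewer classes were kept).
    """
    if not sites:
        return pd.DataFrame(columns=["site_id", "timestamp", "class1", "class2", "class3"])

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    minutes = _clip_minutes()
    hours = minutes // 60
    is_day = (hours >= DAY_START_HOUR) & (hours < DAY_END_HOUR)

    cats = list(CATEGORIES) + ["other"]
    n_cat = len(cats)

    records: list[tuple[str, dt.datetime, str, str, str]] = []
    for site in sites:
        covs = site_covariates(site.x, site.y, rasters, vectors)
        p = np.empty((2, n_cat))  # rows: night, day
        for c_idx, cat in enumerate(cats):
            if cat == "other":
                p[:, c_idx] = ground_truth.other_rate
            else:
                p[0, c_idx] = presence_probability(ground_truth, covs, cat, "night")
                p[1, c_idx] = presence_probability(ground_truth, covs, cat, "day")
        n_days = (
            config.campaign_days_fixed
            if site.site_type == "fixed"
            else config.campaign_days_rotating
        )
        p_clip = p[is_day.astype(int)]  # (144, n_cat)
        for day in range(n_days):
            date = config.start_date + dt.timedelta(days=day)
            present = rng.random((len(minutes), n_cat)) < p_clip
            prominence = rng.random((len(minutes), n_cat))
            fine_pick = rng.random((len(minutes), n_cat))
            for m_idx, minute in enumerate(minutes):
                fired = np.flatnonzero(present[m_idx])
                if fired.size == 0:
                    labels = ["ambient"]
                else:
                    if fired.size > 3:
                        keep = fired[np.argsort(-prominence[m_idx, fired])[:3]]
                        keep = np.sort(keep)
                    else:
                        keep = fired
                    labels = []
                    for c_idx in keep:
                        vocab = FINE_CLASSES[cats[c_idx]]
                        labels.append(vocab[int(fine_pick[m_idx, c_idx] * len(vocab))])
                ts = dt.datetime.combine(date, dt.time(0)) + dt.timedelta(
                    minutes=int(minute)
                )
                labels += [""] * (3 - len(labels))
                records.append((site.site_id, ts, labels[0], labels[1], labels[2]))

    frame = pd.DataFrame(
        records, columns=["site_id", "timestamp", "class1", "class2", "class3"]
    )
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    return frame


def simulate_level_surface(
    rasters: CovariateRasters,
    vectors: VectorLayers,
    ground_truth: GroundTruth,
    seed: int = 0,
) -> dict[str, RasterGrid]:
    """L_day / L_night surfaces (dBA): base + road-proximity gain + noise.

    The same noise field is shared between periods, so with zero noise (or in
    expectation) ``L_day - L_night`` equals the night offset everywhere.
    """
    import shapely

    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    grid = rasters.ndvi
    xs, ys = grid.cell_centers()
    xg, yg = np.meshgrid(xs, ys)
    pts = shapely.points(xg.ravel(), yg.ravel())
    major = unary_union(vectors.roads_by_class("major"))
    dist = shapely.distance(pts, major).reshape(xg.shape)

    gt = ground_truth
    signal = gt.level_base_dba + gt.level_road_gain_dba * np.exp(-dist / gt.level_tau_m)
    noise = rng.normal(0.0, gt.level_noise_sd_dba, size=signal.shape) if gt.level_noise_sd_dba > 0 else 0.0
    l_day = signal + noise
    l_night = signal - gt.level_night_offset_dba + noise
    return {"day": grid.copy_with(l_day), "night": grid.copy_with(l_night)}
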