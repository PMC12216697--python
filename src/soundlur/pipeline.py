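"""End-to-end orchestration: simulate -> prevalence -> features -> fit ->
predict -> index, with validated YAML config, derived per-stage seeds and a
deterministic run manifest (SHA-256 of every written artifact).

Wall-clock times go to ``run.log``, which is deliberately outside the
determinism contract; the manifest itself is byte-identical across re-runs
with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import index as index_mod
from . import io as slio
from . import lur, predict, prevalence
from . import synthetic_city as syn
from ._grid import write_ascii_grid

__all__ = ["PipelineConfig", "StageError", "validate_config", "load_config", "run_all"]

log = logging.getLogger("soundlur")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class ConfigError(ValueError):
    pass


_DEFAULTS = {
    "seed": 0,
    "out_dir": "runs/out",
    "city": {f.name: None for f in dataclasses.fields(syn.CityConfig)},
    "prevalence": {
        "subsample_fixed_days": 30,
        "min_clip_fraction": 0.5,
        "collapse": "site_date",
    },
    "lur": {
        "n_trees": 500,
        "cv_folds": 10,
        "n_permutations": 10,
        "radii": list(feat.ALLOWED_RADII),
        "categories": list(prevalence.MODELLED_CATEGORIES),
    },
    "mask": {"road_predicate": "intersects", "road_distance_m": 0.0},
    # fitted but not reported by default: the rare, zero-inflated category
    "predict_exclude_categories": ["geophysical_nature"],
    "index": {"weights": [0.5, 0.5], "normalize_jointly": False},
}


@dataclasses.dataclass
class PipelineConfig:
    seed: int
    out_dir: Path
    city: syn.CityConfig
    prevalence: dict
    lur: dict
    mask: dict
    index: dict
    predict_exclude_categories: list[str] = dataclasses.field(
        default_factory=lambda: ["geophysical_nature"]
    )

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        )


def _merge(defaults: dict, given: dict, errors: list[str], prefix: str = "") -> dict:
    out = dict(defaults)
    for key, value in given.items():
        if key not in defaults:
            errors.append(f"unknown key {prefix}{key!r}")
            continue
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, errors, f"{prefix}{key}.")
        else:
            out[key] = value
    return out


def validate_config(raw: dict) -> PipelineConfig:
    """Fill defaults and reject contradictions, listing every violation."""
    errors: list[str] = []
    merged = _merge(_DEFAULTS, raw or {}, errors)

    bad_radii = [r for r in merged["lur"]["radii"] if r not in feat.ALLOWED_RADII]
    if bad_radii:
        errors.append(
            f"lur.radii {bad_radii} outside allowed set {list(feat.ALLOWED_RADII)}"
        )
    weights = merged["index"]["weights"]
    if len(weights) != 2 or any(w < 0 for w in weights):
        errors.append("index.weights must be two non-negative numbers")
    elif not np.isclose(sum(weights), 1.0):
        errors.append(f"index.weights {weights} do not sum to 1")
    if merged["lur"]["n_trees"] < 1:
        errors.append("lur.n_trees must be >= 1")
    if merged["lur"]["cv_folds"] < 2:
        errors.append("lur.cv_folds must be >= 2")
    if not (0 <= merged["prevalence"]["min_clip_fraction"] <= 1):
        errors.append("prevalence.min_clip_fraction must lie in [0, 1]")
    unknown_cats = [
        c
        for c in merged["lur"]["categories"]
        if c not in prevalence.MODELLED_CATEGORIES
    ]
    if unknown_cats:
        errors.append(f"lur.categories {unknown_cats} not modellable")

    city_kwargs = {k: v for k, v in merged["city"].items() if v is not None}
    if "extent_m" in city_kwargs:
        city_kwargs["extent_m"] = tuple(city_kwargs["extent_m"])
    city_kwargs.setdefault("seed", merged["seed"])
    try:
        city = syn.CityConfig(**city_kwargs)
    except (TypeError, syn.ConfigurationError) as exc:
        errors.append(f"city: {exc}")
        city = None
    if errors:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))
    return PipelineConfig(
        seed=int(merged["seed"]),
        out_dir=Path(merged["out_dir"]),
        city=city,
        prevalence=merged["prevalence"],
        lur=merged["lur"],
        mask=merged["mask"],
        index=merged["index"],
        predict_exclude_categories=list(merged["predict_exclude_categories"]),
    )


def load_config(path: str | Path) -> PipelineConfig:
    return validate_config(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _model_seed(global_seed: int, category: str, period: str) -> int:
    return int(
        np.random.SeedSequence(
            [global_seed, zlib.crc32(f"{category}:{period}".encode())]
        ).generate_state(1)[0]
    )


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``manifest.json``). Any stage failure aborts with a stage-tagged error;
    outputs of completed stages are left in place."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}
    timings: list[str] = []

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": {
                    str(p.relative_to(out)): _sha256(p) for p in sorted(paths)
                },
            }
        )

    def run_stage(stage: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        timings.append(f"{stage}: {time.perf_counter() - t0:.2f}s")
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
        return result

    # --- simulate ---------------------------------------------------------
    state: dict = {}

    def _simulate():
        city = config.city
        rasters = syn.generate_covariate_rasters(city)
        vectors = syn.generate_vector_layers(city, rasters)
        sites = syn.sample_sites(city, rasters)
        gt = syn.default_ground_truth()
        clips = syn.simulate_clip_labels(sites, gt, rasters, vectors, city)
        levels = syn.simulate_level_surface(rasters, vectors, gt, seed=city.seed)
        sim_dir = out / "simulated"
        slio.write_rasters(rasters, sim_dir)
        slio.write_vectors(vectors, sim_dir)
        sites_df = syn.sites_to_frame(sites)
        sites_df.to_csv(sim_dir / "sites.csv", index=False)
        slio.write_clips(clips, sim_dir / "clips.csv")
        write_ascii_grid(levels["day"], sim_dir / "l_day.asc")
        write_ascii_grid(levels["night"], sim_dir / "l_night.asc")
        state.update(
            rasters=rasters, vectors=vectors, sites=sites, sites_df=sites_df,
            clips=clips, gt=gt, levels=levels,
        )
        record("simulate", sorted(sim_dir.glob("*")))

    run_stage("simulate", _simulate)

    # --- prevalence -------------------------------------------------------
    def _prevalence():
        ontology = prevalence.default_ontology()
        prev = prevalence.compute_prevalence(
            state["clips"],
            ontology,
            min_clip_fraction=config.prevalence["min_clip_fraction"],
        )
        table = prevalence.build_model_table(
            prev,
            state["sites_df"],
            categories=tuple(config.lur["categories"]),
            collapse=config.prevalence["collapse"],
        )
        if config.prevalence["collapse"] == "site_date":
            table = prevalence.subsample_fixed_site_days(
                table,
                n_days=config.prevalence["subsample_fixed_days"],
                seed=config.stage_seed("subsample"),
            )
        prev_dir = out / "prevalence"
        prev_dir.mkdir(exist_ok=True)
        prev.to_csv(prev_dir / "prevalence.csv", index=False)
        table.to_csv(prev_dir / "model_table.csv", index=False)
        slio.write_ontology(ontology, prev_dir / "ontology.yaml")
        state.update(prev=prev, table=table)
        record("prevalence", sorted(prev_dir.glob("*")))

    run_stage("prevalence", _prevalence)

    # --- features ---------------------------------------------------------
    def _features():
        specs = feat.default_predictor_specs()
        matrix = feat.build_feature_matrix(
            state["sites_df"], state["rasters"], state["vectors"], specs
        )
        feat_dir = out / "features"
        feat_dir.mkdir(exist_ok=True)
        matrix.to_csv(feat_dir / "site_features.csv")
        sidecar = {
            "columns": list(matrix.columns),
            "specs": [dataclasses.asdict(s) for s in specs],
        }
        (feat_dir / "site_features.json").write_text(
            json.dumps(sidecar, sort_keys=True, indent=1)
        )
        state.update(specs=specs, matrix=matrix)
        record("features", sorted(feat_dir.glob("*")))

    run_stage("features", _features)

    # --- fit --------------------------------------------------------------
    def _fit():
        import joblib

        models: dict[tuple[str, str], lur.FittedLUR] = {}
        cv_preds: dict[tuple[str, str], pd.DataFrame] = {}
        fit_dir = out / "models"
        fit_dir.mkdir(exist_ok=True)
        rep_dir = out / "reports"
        rep_dir.mkdir(exist_ok=True)
        written: list[Path] = []
        for category in config.lur["categories"]:
            for period in ("day", "night"):
                sub = state["table"]
                sub = sub[(sub["category"] == category) & (sub["period"] == period)]
                sub = sub.reset_index(drop=True)
                if sub.empty:
                    raise ValueError(f"no training rows for {category}/{period}")
                spec = lur.LURSpec(
                    category=category,
                    period=period,
                    n_trees=config.lur["n_trees"],
                    seed=_model_seed(config.seed, category, period),
                    cv_folds=config.lur["cv_folds"],
                    n_permutations=config.lur["n_permutations"],
                )
                candidates = []
                for s in lur.apriori_filter(state["specs"], period):
                    for c in s.columns():
                        if "@" in c and int(c.rsplit("@", 1)[1]) not in config.lur["radii"]:
                            continue
                        candidates.append(c)
                selection = lur.select_buffer_radii(
                    sub, state["matrix"], spec, candidate_columns=candidates
                )
                fitted = lur.fit_lur(sub, state["matrix"], spec, selection)
                report = lur.site_grouped_cv(sub, state["matrix"], spec, selection)
                models[(category, period)] = fitted
                cv_preds[(category, period)] = report.predictions
                mpath = fit_dir / f"{category}_{period}.joblib"
                joblib.dump(fitted, mpath)
                rpath = rep_dir / f"cv_{category}_{period}.json"
                rpath.write_text(
                    json.dumps(
                        {
                            "category": category,
                            "period": period,
                            "unreliable": fitted.unreliable,
                            "selection": {
                                k: v for k, v in fitted.selection.chosen.items()
                            },
                            "pooled": report.pooled,
                            "per_fold": report.per_fold.to_dict(orient="records"),
                        },
                        sort_keys=True,
                        indent=1,
                    )
                )
                written.extend([rpath])

        # residual diagnostics per period
        site_xy = state["sites_df"].set_index("site_id")[["x", "y"]]
        for period in ("day", "night"):
            per_site = {}
            for (cat, per), preds in cv_preds.items():
                if per != period:
                    continue
                resid = (
                    preds.assign(resid=preds["predicted"] - preds["observed"])
                    .groupby("site_id")["resid"]
                    .mean()
                )
                per_site[cat] = resid
            shared = None
            for s in per_site.values():
                shared = s.index if shared is None else shared.intersection(s.index)
            per_site = {k: v.loc[shared] for k, v in per_site.items()}
            moran = {}
            for cat, resid in per_site.items():
                coords = site_xy.loc[resid.index].to_numpy()
                try:
                    mres = lur.morans_i(resid.to_numpy(), coords)
                    moran[cat] = dataclasses.asdict(mres)
                except ValueError as exc:
                    moran[cat] = {"error": str(exc)}
            diag = pd.DataFrame(
                {f"me_{cat}": resid for cat, resid in per_site.items()}
            )
            if len(per_site) >= 2:
                diag["combined_score"] = lur.combined_residual_score(per_site, period)
            dpath = rep_dir / f"diagnostics_{period}.csv"
            diag.to_csv(dpath)
            mopath = rep_dir / f"morans_i_{period}.json"
            mopath.write_text(json.dumps(moran, sort_keys=True, indent=1))
            written.extend([dpath, mopath])
        state.update(models=models)
        record("fit", sorted(written))

    run_stage("fit", _fit)

    # --- predict ----------------------------------------------------------
    def _predict():
        grid = predict.build_grid(config.city.extent_m, config.city.cell_size_m)
        grid = predict.compute_mask(
            grid,
            state["vectors"],
            state["rasters"].land_cover,
            road_predicate=config.mask["road_predicate"],
            road_distance_m=config.mask["road_distance_m"],
        )
        needed = sorted({c for m in state["models"].values() for c in m.columns})
        specs = _specs_for_columns(state["specs"], needed)
        cf = grid.cell_frame()
        grid_features = feat.build_feature_matrix(
            cf, state["rasters"], state["vectors"], specs, id_column="cell_id"
        )
        surf_dir = out / "surfaces"
        surf_dir.mkdir(exist_ok=True)
        write_ascii_grid(grid.mask_grid(), surf_dir / "mask.asc")
        surfaces = {}
        summaries = []
        zones = {"gama": np.ones(grid.n_cells, dtype=bool)}
        zones["core"] = syn.in_core(
            cf["x"].to_numpy(), cf["y"].to_numpy(), config.city
        )
        zones.update(predict.road_proximity_zones(grid, state["vectors"]))
        excluded = set(config.predict_exclude_categories)
        for (category, period), model in state["models"].items():
            if model.unreliable or category in excluded:
                log.warning(
                    "not reporting surface for %s/%s (%s)",
                    category,
                    period,
                    "unreliable" if model.unreliable else "excluded by config",
                )
                continue
            surface = predict.predict_surface(model, grid_features, grid)
            surfaces[(category, period)] = surface
            write_ascii_grid(surface.raster(), surf_dir / f"{category}_{period}.asc")
            summaries.append(predict.summarize_surface(surface, zones))
        pd.concat(summaries, ignore_index=True).to_csv(
            surf_dir / "summaries.csv", index=False
        )
        state.update(grid=grid, surfaces=surfaces, grid_features=grid_features)
        record("predict", sorted(surf_dir.glob("*")))

    run_stage("predict", _predict)

    # --- index ------------------------------------------------------------
    def _index():
        idx_dir = out / "index"
        idx_dir.mkdir(exist_ok=True)
        w_level, w_prev = config.index["weights"]
        mask2d = state["grid"].mask.reshape(state["grid"].ny, state["grid"].nx)
        params_doc = {}
        for (category, period), surface in state["surfaces"].items():
            levels = state["levels"][period].values.copy()
            levels[mask2d] = np.nan
            other = None
            if config.index["normalize_jointly"]:
                other_period = "night" if period == "day" else "day"
                other = state["levels"][other_period].values[~mask2d]
            spec = index_mod.IndexSpec(category, period, w_level, w_prev)
            isurf = index_mod.build_index_surface(
                levels, surface, spec, normalize_jointly_with=other
            )
            write_ascii_grid(
                isurf.raster(config.city.cell_size_m),
                idx_dir / f"{category}_{period}.asc",
            )
            params_doc[f"{category}_{period}"] = {
                "data_min": isurf.params.data_min,
                "data_range": isurf.params.data_range,
                "weights": [w_level, w_prev],
            }
        (idx_dir / "params.json").write_text(
            json.dumps(params_doc, sort_keys=True, indent=1)
        )
        state["index_params"] = params_doc
        record("index", sorted(idx_dir.glob("*")))

    run_stage("index", _index)

    import sklearn

    manifest["versions"] = {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    (out / "run.log").write_text("\n".join(timings) + "\n")
    return manifest


def _specs_for_columns(
    specs: list[feat.PredictorSpec], columns: list[str]
) -> list[feat.PredictorSpec]:
    """Shrink the spec list to exactly the requested columns."""
    out = []
    for spec in specs:
        if spec.radii:
            keep = tuple(
                r for r in spec.radii if f"{spec.name}@{r}" in columns
            )
            if keep:
                out.append(dataclasses.replace(spec, radii=keep))
        elif spec.name in columns:
            out.append(spec)
    return out
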