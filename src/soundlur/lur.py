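"""Random-forest land-use-regression with buffer selection, site-grouped
cross-validation and spatial residual diagnostics.

One model is fitted per sound category x period. Buffer radii compete inside
a single forest containing every candidate column; the radius with the
largest mean permutation importance (increase in MAE over seeded shuffles)
wins, ties going to the smaller (more local) radius. Cross-validation holds
out whole sites: all rows of a held-out site leave the training data
together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .features import PredictorSpec

__all__ = [
    "LURSpec",
    "BufferSelection",
    "FittedLUR",
    "CVReport",
    "apriori_filter",
    "permutation_importance",
    "select_buffer_radii",
    "fit_lur",
    "site_grouped_cv",
    "cv_metrics",
    "morans_i",
    "MoranResult",
    "combined_residual_score",
    "grouped_residual_summary",
]


class DegenerateFitWarning(UserWarning):
    pass


@dataclass
class LURSpec:
    """Configuration of one category x period model."""

    category: str
    period: str
    n_trees: int = 500
    seed: int = 0
    cv_folds: int = 10
    n_permutations: int = 10

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.period not in ("day", "night"):
            raise ValueError(f"period must be day|night, got {self.period!r}")


@dataclass
class BufferSelection:
    """Chosen radius per multi-radius variable plus the importance scores."""

    chosen: dict[str, int | None]  # variable -> radius (None for no-radius vars)
    scores: dict[str, float]  # column -> mean permutation importance

    def selected_columns(self) -> list[str]:
        cols = []
        for var, radius in self.chosen.items():
            cols.append(var if radius is None else f"{var}@{radius}")
        return cols


@dataclass
class FittedLUR:
    spec: LURSpec
    selection: BufferSelection
    model: RandomForestRegressor
    columns: list[str]
    y_min: float
    y_max: float
    train_index: list = field(default_factory=list)
    unreliable: bool = False

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in features.columns]
        if missing:
            raise ValueError(f"feature matrix missing model columns: {missing}")
        return self.model.predict(features[self.columns].to_numpy())


@dataclass
class CVReport:
    per_fold: pd.DataFrame  # fold, n_sites, n_rows, mdae, mae, me, r
    pooled: dict[str, float | None]
    predictions: pd.DataFrame  # site_id, observed, predicted, fold


def apriori_filter(specs: list[PredictorSpec], period: str) -> list[PredictorSpec]:
    """Drop predictors not considered sound producing in ``period``."""
    if period not in ("day", "night"):
        raise ValueError(f"period must be day|night, got {period!r}")
    kept = [s for s in specs if s.period in ("both", period)]
    if not kept:
        raise ValueError(f"no predictors applicable to period {period!r}")
    return kept


def cv_metrics(observed, predicted) -> dict[str, float | None]:
    """Deviation and bias metrics of predictions against observations.

    ME = mean(pred - obs) (bias), MAE/MdAE = mean/median absolute error,
    r = Pearson correlation (None when either vector is constant).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and predicted must be equal-length vectors, n >= 2")
    resid = pred - obs
    out = {
        "me": float(np.mean(resid)),
        "mae": float(np.mean(np.abs(resid))),
        "mdae": float(np.median(np.abs(resid))),
    }
    if np.std(obs) == 0 or np.std(pred) == 0:
        out["r"] = None
    else:
        out["r"] = float(stats.pearsonr(obs, pred).statistic)
    return out


def permutation_importance(
    model: RandomForestRegressor,
    X: pd.DataFrame,
    y: np.ndarray,
    n_permutations: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Mean increase in MAE when one column is shuffled, per column.

    Returns a Series indexed by column, sorted descending (rank 1 first).
    """
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    base = np.mean(np.abs(model.predict(Xv) - y))
    scores = np.zeros(Xv.shape[1])
    for j in range(Xv.shape[1]):
        col = Xv[:, j].copy()
        deltas = np.empty(n_permutations)
        for p in range(n_permutations):
            Xv[:, j] = rng.permutation(col)
            deltas[p] = np.mean(np.abs(model.predict(Xv) - y)) - base
        Xv[:, j] = col
        scores[j] = deltas.mean()
    return pd.Series(scores, index=X.columns).sort_values(ascending=False)


def _join_rows(table: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """One feature row per table row, looked up by site_id."""
    return features.loc[table["site_id"].to_numpy()]


def _variable_of(column: str) -> tuple[str, int | None]:
    if "@" in column:
        var, radius = column.rsplit("@", 1)
        return var, int(radius)
    return column, None


def select_buffer_radii(
    table: pd.DataFrame,
    features: pd.DataFrame,
    spec: LURSpec,
    candidate_columns: list[str] | None = None,
    refit_per_radius: bool = False,
) -> BufferSelection:
    """Pick one buffer radius per variable by permutation importance.

    A single forest containing every candidate column is fitted and each
    variable keeps the radius whose column scores the highest mean
    importance; ties break toward the smaller radius. ``refit_per_radius``
    instead refits one forest per radius choice of each variable and keeps
    the radius with the lowest in-sample MAE (slower alternative reading).
    """
    cols = list(candidate_columns) if candidate_columns is not None else list(features.columns)
    X = _join_rows(table, features)[cols]
    y = table["prevalence"].to_numpy(dtype=float)

    groups: dict[str, list[tuple[int | None, str]]] = {}
    for c in cols:
        var, radius = _variable_of(c)
        groups.setdefault(var, []).append((radius, c))

    if refit_per_radius:
        return _select_by_refit(X, y, groups, spec)

    forest = RandomForestRegressor(
        n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1
    )
    forest.fit(X.to_numpy(), y)
    scores = permutation_importance(
        forest, X, y, n_permutations=spec.n_permutations, seed=spec.seed
    )
    chosen: dict[str, int | None] = {}
    for var, members in groups.items():
        if len(members) == 1 and members[0][0] is None:
            chosen[var] = None
            continue
        # max score, ties toward the smaller radius
        best = sorted(
            members, key=lambda rc: (-scores[rc[1]], rc[0] if rc[0] is not None else 0)
        )[0]
        chosen[var] = best[0]
    return BufferSelection(chosen=chosen, scores=scores.to_dict())


def _select_by_refit(X, y, groups, spec: LURSpec) -> BufferSelection:
    chosen: dict[str, int | None] = {
        var: members[0][0] for var, members in groups.items()
    }
    scores: dict[str, float] = {}
    for var, members in groups.items():
        if len(members) == 1:
            continue
        best_mae, best_radius = np.inf, None
        for radius, col in sorted(members, key=lambda rc: rc[0]):
            cols = [col if v == var else ms[0][1] for v, ms in groups.items()]
            forest = RandomForestRegressor(
                n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1
            )
            forest.fit(X[cols].to_numpy(), y)
            mae = np.mean(np.abs(forest.predict(X[cols].to_numpy()) - y))
            scores[col] = -mae
            if mae < best_mae:
                best_mae, best_radius = mae, radius
        chosen[var] = best_radius
    return BufferSelection(chosen=chosen, scores=scores)


def fit_lur(
    table: pd.DataFrame,
    features: pd.DataFrame,
    spec: LURSpec,
    selection: BufferSelection | None = None,
) -> FittedLUR:
    """Train the final forest on the selected columns.

    Predictions of the returned model are bounded by the training-response
    range (forest averaging), asserted in the tests rather than clamped here.
    A model whose training rows are >80% zeros is flagged ``unreliable``
    (the zero-inflated failure mode of rare categories).
    """
    cols = selection.selected_columns() if selection is not None else list(features.columns)
    X = _join_rows(table, features)[cols]
    y = table["prevalence"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        warnings.warn(
            f"{spec.category}/{spec.period}: <2 distinct response values, "
            "degenerate fit",
            DegenerateFitWarning,
            stacklevel=2,
        )
    forest = RandomForestRegressor(
        n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1
    )
    forest.fit(X.to_numpy(), y)
    unreliable = bool(np.mean(y == 0.0) > 0.8)
    if unreliable:
        warnings.warn(
            f"{spec.category}/{spec.period}: >80% zero training rows; "
            "model flagged unreliable",
            UserWarning,
            stacklevel=2,
        )
    return FittedLUR(
        spec=spec,
        selection=selection if selection is not None else BufferSelection({_variable_of(c)[0]: _variable_of(c)[1] for c in cols}, {}),
        model=forest,
        columns=cols,
        y_min=float(y.min()),
        y_max=float(y.max()),
        train_index=list(table.index),
        unreliable=unreliable,
    )


def site_folds(site_ids: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Disjoint site partition into ``n_folds`` groups of ~equal size."""
    sites = np.unique(site_ids)
    if len(sites) < n_folds:
        raise ValueError(
            f"need at least {n_folds} distinct sites, got {len(sites)}"
        )
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(sites), n_folds)


def site_grouped_cv(
    table: pd.DataFrame,
    features: pd.DataFrame,
    spec: LURSpec,
    selection: BufferSelection | None = None,
) -> CVReport:
    """10-fold cross-validation holding out ~10% of sites per fold.

    Sites are partitioned into disjoint folds covering every site exactly
    once; all rows of a held-out site leave together. Metrics are computed
    per fold and on the pooled held-out predictions.
    """
    cols = selection.selected_columns() if selection is not None else list(features.columns)
    folds = site_folds(table["site_id"].to_numpy(), spec.cv_folds, spec.seed)
    rows = []
    preds = []
    for k, held in enumerate(folds):
        test_mask = table["site_id"].isin(held).to_numpy()
        train = table[~test_mask]
        test = table[test_mask]
        forest = RandomForestRegressor(
            n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1
        )
        forest.fit(
            _join_rows(train, features)[cols].to_numpy(),
            train["prevalence"].to_numpy(dtype=float),
        )
        yhat = forest.predict(_join_rows(test, features)[cols].to_numpy())
        fold_metrics = cv_metrics(test["prevalence"].to_numpy(dtype=float), yhat)
        rows.append(
            {"fold": k, "n_sites": len(held), "n_rows": len(test), **fold_metrics}
        )
        preds.append(
            pd.DataFrame(
                {
                    "site_id": test["site_id"].to_numpy(),
                    "observed": test["prevalence"].to_numpy(dtype=float),
                    "predicted": yhat,
                    "fold": k,
                }
            )
        )
    predictions = pd.concat(preds, ignore_index=True)
    pooled = cv_metrics(predictions["observed"], predictions["predicted"])
    return CVReport(per_fold=pd.DataFrame(rows), pooled=pooled, predictions=predictions)


# ---------------------------------------------------------------------------
# residual diagnostics
# ---------------------------------------------------------------------------


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    n: int


def _inverse_distance_weights(coords: np.ndarray) -> np.ndarray:
    d = np.sqrt(
        ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    )
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    if np.isinf(w).any():
        raise ValueError("duplicate coordinates give infinite inverse-distance weight")
    return w


def morans_i(
    residuals,
    coords: np.ndarray | None = None,
    weights: np.ndarray | str = "inverse_distance",
    row_standardize: bool = True,
) -> MoranResult:
    """Global Moran's I with analytic normality-based inference.

    I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centered
    residuals; E[I] = -1/(n-1); the variance is the standard
    normality-assumption expression, giving a two-sided z-test p-value.

    ``weights`` is either a precomputed (n, n) matrix (zero diagonal) or
    the string ``'inverse_distance'`` built from ``coords``; the default is
    row-standardized inverse distance with no cutoff.
    """
    z = np.asarray(residuals, dtype=float)
    n = len(z)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 observations")
    if np.std(z) == 0:
        raise ValueError("residuals have zero variance")
    if isinstance(weights, str):
        if weights != "inverse_distance":
            raise ValueError(f"unknown weight scheme {weights!r}")
        if coords is None:
            raise ValueError("coords required for inverse-distance weights")
        W = _inverse_distance_weights(np.asarray(coords, dtype=float))
    else:
        W = np.asarray(weights, dtype=float).copy()
        if W.shape != (n, n):
            raise ValueError("weight matrix shape mismatch")
        np.fill_diagonal(W, 0.0)
    if row_standardize:
        rowsum = W.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        W = W / rowsum

    z = z - z.mean()
    s0 = W.sum()
    num = z @ W @ z
    I = (n / s0) * num / (z @ z)

    expected = -1.0 / (n - 1)
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    # normality-assumption variance
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - expected**2
    zscore = (I - expected) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return MoranResult(float(I), float(expected), float(var), float(zscore), float(p), n)


def combined_residual_score(
    residuals_by_model: dict[str, pd.Series], period: str | None = None
) -> pd.Series:
    """Sum of min-max-scaled absolute residuals across models, per site.

    Each model's |residuals| are scaled to [0, 1] over the shared sites; a
    model with constant |residuals| contributes 0 everywhere (warned). The
    result lies in [0, n_models].
    """
    if len(residuals_by_model) < 2:
        raise ValueError("need residuals from at least 2 models")
    frame = pd.DataFrame(residuals_by_model).abs()
    if frame.isna().any().any():
        raise ValueError("models must share the same site set")
    scaled = pd.DataFrame(index=frame.index)
    for model_name in frame.columns:
        col = frame[model_name]
        rng_ = col.max() - col.min()
        if rng_ == 0:
            warnings.warn(
                f"{model_name}: constant |residuals|, scaled to 0", stacklevel=2
            )
            scaled[model_name] = 0.0
        else:
            scaled[model_name] = (col - col.min()) / rng_
    score = scaled.sum(axis=1)
    score.name = f"combined_score_{period}" if period else "combined_score"
    return score


def grouped_residual_summary(
    predictions: pd.DataFrame, dates: pd.Series, by: str = "weekday"
) -> pd.DataFrame:
    """Descriptive residual summary over time intervals (no formal test)."""
    resid = predictions["predicted"] - predictions["observed"]
    ts = pd.to_datetime(pd.Series(dates).reset_index(drop=True))
    if by == "weekday":
        group = ts.dt.day_name()
    elif by == "month":
        group = ts.dt.month_name()
    else:
        raise ValueError("by must be 'weekday' or 'month'")
    frame = pd.DataFrame({"group": group.to_numpy(), "residual": resid.to_numpy()})
    return (
        frame.groupby("group")["residual"]
        .agg(["count", "mean", "median", "std"])
        .reset_index()
    )
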