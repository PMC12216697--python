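import numpy as np
import pandas as pd
import pytest

from soundlur import lur
from soundlur.features import PredictorSpec


def make_design(n_sites=60, rows_per_site=3, seed=0, noise=2.0, signal_col="roads@200"):
    """Synthetic regression design: nested-radius columns correlated like
    real buffer features, response driven by one column only."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 10, n_sites)
    cols = {}
    for r, mix in zip((50, 100, 200, 500), (0.45, 0.7, 1.0, 0.75)):
        cols[f"roads@{r}"] = mix * base + (1 - mix) * rng.uniform(0, 10, n_sites)
    cols["noise@50"] = rng.normal(size=n_sites)
    cols["noise@100"] = rng.normal(size=n_sites)
    features = pd.DataFrame(cols, index=pd.Index([f"s{k}" for k in range(n_sites)], name="site_id"))
    rows = []
    for k in range(n_sites):
        for _ in range(rows_per_site):
            y = 5.0 * cols[signal_col][k] + rng.normal(0, noise)
            rows.append({"site_id": f"s{k}", "prevalence": float(np.clip(y, 0, 100))})
    return pd.DataFrame(rows), features


class TestAprioriFilter:
    SPECS = [
        PredictorSpec("school_n", "pois", "count", "school", (50,), period="day"),
        PredictorSpec("road_major_len", "roads", "length_sum", "major", (50,)),
        PredictorSpec("bar_n", "pois", "count", "bar", (50,)),
    ]

    def test_day_only_excluded_at_night(self):
        kept = lur.apriori_filter(self.SPECS, "night")
        assert all(s.name != "school_n" for s in kept)

    def test_both_retained_everywhere(self):
        for period in ("day", "night"):
            kept = {s.name for s in lur.apriori_filter(self.SPECS, period)}
            assert {"road_major_len", "bar_n"} <= kept

    def test_empty_result_errors(self):
        day_only = [s for s in self.SPECS if s.period == "day"]
        with pytest.raises(ValueError):
            lur.apriori_filter(day_only, "night")


class TestCVMetrics:
    def test_hand_computed(self):
        obs = np.array([0.0, 1.0, 0.0])
        pred = obs + np.array([1.0, -1.0, 3.0])
        m = lur.cv_metrics(obs, pred)
        assert m["me"] == pytest.approx(1.0)
        assert m["mae"] == pytest.approx(5.0 / 3.0)
        assert m["mdae"] == pytest.approx(1.0)

    def test_perfect_predictions(self):
        m = lur.cv_metrics([0, 10, 20], [0, 10, 20])
        assert m["me"] == m["mae"] == m["mdae"] == 0.0
        assert m["r"] == pytest.approx(1.0)

    def test_constant_obs_r_flagged_none(self):
        m = lur.cv_metrics([5, 5, 5], [4, 5, 6])
        assert m["r"] is None

    def test_row_permutation_invariant(self, rng):
        obs = rng.uniform(0, 100, 50)
        pred = rng.uniform(0, 100, 50)
        perm = rng.permutation(50)
        a = lur.cv_metrics(obs, pred)
        b = lur.cv_metrics(obs[perm], pred[perm])
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-12)


class TestPermutationImportance:
    def _fit(self, table, features, n_trees=150, seed=0):
        spec = lur.LURSpec("road_transport", "day", n_trees=n_trees, seed=seed)
        return lur.fit_lur(table, features, spec), spec

    def test_sole_signal_ranks_first(self):
        table, features = make_design(seed=1)
        fitted, spec = self._fit(table, features)
        X = features.loc[table["site_id"]]
        scores = lur.permutation_importance(
            fitted.model, X, table["prevalence"].to_numpy(), 10, seed=0
        )
        assert scores.index[0] == "roads@200"

    def test_duplicated_noise_leaves_signal_on_top(self):
        table, features = make_design(seed=2)
        features = features.copy()
        features["noise_dup@50"] = features["noise@50"]
        fitted, spec = self._fit(table, features)
        X = features.loc[table["site_id"]]
        scores = lur.permutation_importance(
            fitted.model, X, table["prevalence"].to_numpy(), 10, seed=0
        )
        assert scores.index[0] == "roads@200"

    def test_same_seed_identical(self):
        table, features = make_design(seed=3)
        fitted, _ = self._fit(table, features)
        X = features.loc[table["site_id"]]
        y = table["prevalence"].to_numpy()
        a = lur.permutation_importance(fitted.model, X, y, 5, seed=4)
        b = lur.permutation_importance(fitted.model, X, y, 5, seed=4)
        pd.testing.assert_series_equal(a, b)


class TestBufferSelection:
    def test_recovers_generating_radius(self):
        hits = 0
        for rep in range(5):
            table, features = make_design(seed=100 + rep, noise=3.0)
            spec = lur.LURSpec("road_transport", "day", n_trees=100, seed=rep)
            sel = lur.select_buffer_radii(table, features, spec)
            hits += sel.chosen["roads"] == 200
        assert hits >= 4

    def test_pure_noise_importance_near_zero(self):
        table, features = make_design(seed=7)
        spec = lur.LURSpec("road_transport", "day", n_trees=100, seed=7)
        sel = lur.select_buffer_radii(table, features, spec)
        signal_score = sel.scores["roads@200"]
        noise_scores = [sel.scores["noise@50"], sel.scores["noise@100"]]
        assert all(abs(s) < 0.1 * signal_score for s in noise_scores)

    def test_deterministic(self):
        table, features = make_design(seed=8)
        spec = lur.LURSpec("road_transport", "day", n_trees=60, seed=8)
        a = lur.select_buffer_radii(table, features, spec)
        b = lur.select_buffer_radii(table, features, spec)
        assert a.chosen == b.chosen
        assert a.scores == b.scores

    def test_one_radius_per_variable(self):
        table, features = make_design(seed=9)
        spec = lur.LURSpec("road_transport", "day", n_trees=60, seed=9)
        sel = lur.select_buffer_radii(table, features, spec)
        assert set(sel.chosen) == {"roads", "noise"}
        assert sel.chosen["roads"] in (50, 100, 200, 500)
        cols = sel.selected_columns()
        assert len(cols) == 2


class TestFitLUR:
    def test_constant_response_predicts_constant(self):
        table, features = make_design(seed=10)
        table = table.copy()
        table["prevalence"] = 40.0
        spec = lur.LURSpec("music", "day", n_trees=50, seed=0)
        with pytest.warns(lur.DegenerateFitWarning):
            fitted = lur.fit_lur(table, features, spec)
        pred = fitted.predict(features)
        np.testing.assert_allclose(pred, 40.0)

    def test_predictions_within_training_range(self):
        table, features = make_design(seed=11)
        spec = lur.LURSpec("music", "day", n_trees=100, seed=0)
        fitted = lur.fit_lur(table, features, spec)
        pred = fitted.predict(features)
        assert pred.min() >= fitted.y_min - 1e-9
        assert pred.max() <= fitted.y_max + 1e-9

    def test_seeded_determinism(self):
        table, features = make_design(seed=12)
        spec = lur.LURSpec("music", "day", n_trees=80, seed=3)
        a = lur.fit_lur(table, features, spec).predict(features)
        b = lur.fit_lur(table, features, spec).predict(features)
        np.testing.assert_array_equal(a, b)

    def test_zero_inflated_flagged_unreliable(self):
        table, features = make_design(seed=13)
        table = table.copy()
        table.loc[table.index[: int(0.9 * len(table))], "prevalence"] = 0.0
        spec = lur.LURSpec("geophysical_nature", "day", n_trees=30, seed=0)
        with pytest.warns(UserWarning, match="unreliable"):
            fitted = lur.fit_lur(table, features, spec)
        assert fitted.unreliable


class TestSiteGroupedCV:
    def test_folds_disjoint_and_cover(self):
        table, features = make_design(n_sites=40, seed=14)
        folds = lur.site_folds(table["site_id"].to_numpy(), 10, seed=0)
        all_sites = np.concatenate(folds)
        assert len(all_sites) == len(set(all_sites)) == 40

    def test_fewer_sites_than_folds_errors(self):
        table, features = make_design(n_sites=5, seed=15)
        spec = lur.LURSpec("music", "day", n_trees=10, seed=0, cv_folds=10)
        with pytest.raises(ValueError):
            lur.site_grouped_cv(table, features, spec)

    def test_no_leakage_under_row_shuffle(self):
        table, features = make_design(n_sites=30, seed=16)
        spec = lur.LURSpec("music", "day", n_trees=10, seed=5, cv_folds=5)
        a = lur.site_grouped_cv(table, features, spec)
        shuffled = table.sample(frac=1.0, random_state=9).reset_index(drop=True)
        b = lur.site_grouped_cv(shuffled, features, spec)
        fold_a = a.predictions.groupby("site_id")["fold"].first()
        fold_b = b.predictions.groupby("site_id")["fold"].first()
        pd.testing.assert_series_equal(fold_a, fold_b)

    def test_learnable_step_function(self):
        # noiseless response = step in one feature -> pooled r >= 0.95
        rng = np.random.default_rng(17)
        n_sites = 60
        x = rng.uniform(0, 10, n_sites)
        features = pd.DataFrame(
            {"x@50": x, "junk@50": rng.normal(size=n_sites)},
            index=pd.Index([f"s{k}" for k in range(n_sites)], name="site_id"),
        )
        table = pd.DataFrame(
            {
                "site_id": [f"s{k}" for k in range(n_sites)],
                "prevalence": np.where(x > 5, 80.0, 20.0),
            }
        )
        spec = lur.LURSpec("music", "day", n_trees=100, seed=0, cv_folds=10)
        report = lur.site_grouped_cv(table, features, spec)
        assert report.pooled["r"] >= 0.95


class TestMoransI:
    def test_expected_value_n5(self, rng):
        coords = rng.uniform(0, 100, (5, 2))
        res = lur.morans_i(rng.normal(size=5), coords)
        assert res.expected == pytest.approx(-0.25)

    def test_rook_checkerboard_is_minus_one(self):
        # 2x2 lattice, rook adjacency, residuals (+1,-1,-1,+1)
        W = np.array(
            [
                [0, 1, 1, 0],
                [1, 0, 0, 1],
                [1, 0, 0, 1],
                [0, 1, 1, 0],
            ],
            dtype=float,
        )
        res = lur.morans_i([1.0, -1.0, -1.0, 1.0], weights=W)
        assert res.I == pytest.approx(-1.0)

    def test_two_clusters_positive_autocorrelation(self, rng):
        a = rng.normal(0, 1, (10, 2))
        b = rng.normal(0, 1, (10, 2)) + 1000.0
        coords = np.vstack([a, b])
        residuals = np.r_[np.full(10, 2.0), np.full(10, -2.0)]
        residuals += rng.normal(0, 0.1, 20)
        res = lur.morans_i(residuals, coords)
        assert res.I > 0
        assert res.p_value < 0.05

    def test_constant_residuals_error(self, rng):
        with pytest.raises(ValueError):
            lur.morans_i(np.ones(5), rng.uniform(0, 1, (5, 2)))

    def test_too_few_points_error(self, rng):
        with pytest.raises(ValueError):
            lur.morans_i([1.0, -1.0], rng.uniform(0, 1, (2, 2)))


class TestCombinedResidualScore:
    def test_two_model_sum(self):
        r1 = pd.Series([0.0, 2.0, 10.0], index=["a", "b", "c"])
        r2 = pd.Series([0.0, 3.0, 10.0], index=["a", "b", "c"])
        score = lur.combined_residual_score({"m1": r1, "m2": r2})
        assert score["a"] == 0.0
        assert score["c"] == 2.0
        assert score["b"] == pytest.approx(0.2 + 0.3)

    def test_max_everywhere_hits_n_models(self):
        idx = ["a", "b"]
        models = {f"m{k}": pd.Series([1.0, 5.0], index=idx) for k in range(4)}
        score = lur.combined_residual_score(models)
        assert score["b"] == pytest.approx(4.0)
        assert score.between(0, 4).all()

    def test_constant_model_scaled_to_zero(self):
        r1 = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        r2 = pd.Series([0.0, 1.0, 2.0], index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            score = lur.combined_residual_score({"m1": r1, "m2": r2})
        assert score["a"] == 0.0

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            lur.combined_residual_score({"m1": pd.Series([1.0])})


def test_grouped_residual_summary():
    preds = pd.DataFrame({"observed": [10.0, 20.0, 30.0], "predicted": [12.0, 18.0, 33.0]})
    dates = pd.Series(["2019-05-06", "2019-05-07", "2019-05-13"])  # Mon, Tue, Mon
    out = lur.grouped_residual_summary(preds, dates, by="weekday")
    monday = out[out["group"] == "Monday"].iloc[0]
    assert monday["count"] == 2
    assert monday["mean"] == pytest.approx((2.0 + 3.0) / 2)
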