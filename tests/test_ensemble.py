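"""ANN ensembling of selected models and the formulation optimizer."""

import numpy as np
import pandas as pd
import pytest

import mediadoe as md
from mediadoe.ensemble import (
    EnsembleANNRegressor,
    build_model_features,
    predict_and_rank,
    sample_formulations,
    export_recipe,
)
from mediadoe.model_search import CandidateModel, fit_candidate, search


@pytest.fixture(scope="module")
def selected(run_means9):
    X_run, y_run = run_means9
    sr = search(X_run, y_run, max_terms=3, threshold=4.0)
    return sr.selected


class TestModelFeatures:
    def test_one_column_per_model(self, selected, run_means9):
        X_run, _ = run_means9
        feats = build_model_features(selected, X_run)
        assert feats.shape == (56, len(selected))

    def test_intercept_only_model_gives_constant(self, run_means9):
        X_run, y_run = run_means9
        m = fit_candidate(X_run, y_run, ())
        feats = build_model_features([m], X_run)
        assert np.allclose(feats.iloc[:, 0], y_run.mean())

    def test_columns_equal_refit_predictions(self, selected, run_means9):
        X_run, y_run = run_means9
        feats = build_model_features(selected, X_run)
        for j, m in enumerate(selected):
            refit = fit_candidate(X_run, y_run, m.terms)
            assert np.allclose(feats.iloc[:, j], refit.predict(X_run),
                               atol=1e-8)

    def test_unresolvable_term_named(self, run_means9):
        X_run, _ = run_means9
        bogus = CandidateModel(terms=("unobtainium",), k=3, loglik=0.0,
                               aicc=0.0, coef={"(intercept)": 0.0,
                                               "unobtainium": 1.0})
        with pytest.raises(KeyError, match="unobtainium"):
            build_model_features([bogus], X_run)


class TestEnsembleANN:
    def test_realizable_linear_target(self, rng):
        x = rng.normal(size=60)
        X = pd.DataFrame({"f": x})
        y = 0.4 + 0.3 * x
        ann = EnsembleANNRegressor(holdback_n=15, random_state=0).fit(X, y)
        assert ann.r2_train_ >= 0.999
        assert ann.r2_validation_ >= 0.999

    def test_partition_sizes(self, selected, run_means9):
        X_run, y_run = run_means9
        feats = build_model_features(selected, X_run)
        ann = EnsembleANNRegressor(holdback_n=19, random_state=1).fit(
            feats, y_run)
        assert len(ann.holdback_idx_) == 19
        assert len(ann.train_idx_) == 37
        assert not set(ann.holdback_idx_) & set(ann.train_idx_)

    def test_deterministic_given_seed(self, selected, run_means9):
        X_run, y_run = run_means9
        feats = build_model_features(selected, X_run)
        a = EnsembleANNRegressor(random_state=7).fit(feats, y_run)
        b = EnsembleANNRegressor(random_state=7).fit(feats, y_run)
        assert np.array_equal(a.theta_, b.theta_)
        assert np.array_equal(a.holdback_idx_, b.holdback_idx_)

    def test_constant_validation_targets_give_nan_r2(self, rng):
        X = pd.DataFrame({"f": np.arange(25.0)})
        y = np.ones(25)
        ann = EnsembleANNRegressor(holdback_n=5, random_state=0).fit(X, y)
        assert np.isnan(ann.r2_validation_)

    def test_no_gross_overfit_in_aggregate(self, space9):
        # median train-validation R^2 gap over 20 seeded replications
        gaps = []
        for s in range(20):
            design = md.make_custom_design(space9, 56, 7, seed=500 + s,
                                           n_starts=3)
            truth = md.default_truth(space9, seed=1000 + s)
            resp = md.simulate_response(design, truth, 3, 2)
            X, y, g = md.build_predictor_matrix(design, resp, "all")
            run_means = resp.groupby("run_id")["delta_od600"].mean()
            Xr = X.copy()
            Xr["run_id"] = g
            X_run = Xr.groupby("run_id").first()
            sr = search(X_run, run_means.to_numpy(), max_terms=3,
                        mains=design.factor_names)
            feats = build_model_features(sr.selected, X_run)
            ann = EnsembleANNRegressor(holdback_n=19,
                                       random_state=3000 + s).fit(
                feats, run_means.to_numpy())
            gaps.append(ann.r2_train_ - ann.r2_validation_)
        assert np.median(gaps) < 0.35

    def test_tanh_option(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=40)})
        y = X["f"].to_numpy() ** 2
        ann = EnsembleANNRegressor(activation="tanh", holdback_n=0,
                                   random_state=0).fit(X, y)
        assert ann.r2_train_ > 0.9


class TestSampler:
    def test_exact_count_and_pinning(self, space9):
        cands = sample_formulations(space9, 5000,
                                    pinned={"yeast_extract": 0.0}, seed=3)
        assert len(cands) == 5000
        assert (cands["yeast_extract"] == 0.0).all()

    def test_bounds_respected(self, space9):
        cands = sample_formulations(space9, 100_000, seed=4)
        for f in space9:
            assert cands[f.name].between(f.low, f.high).all()

    def test_seeded_reproducibility(self, space9):
        a = sample_formulations(space9, 100, seed=9)
        b = sample_formulations(space9, 100, seed=9)
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def ranked(selected, run_means9, space9, Xy9):
    X_run, y_run = run_means9
    X, y, _ = Xy9
    feats = build_model_features(selected, X_run)
    ann = EnsembleANNRegressor(holdback_n=19, random_state=2).fit(
        feats, y_run)
    pls = md.NIPALSPLSRegression(n_components=4).fit(X, y)
    cands = sample_formulations(space9, 2000,
                                pinned={"yeast_extract": 0.0}, seed=5)
    return cands, predict_and_rank(cands, ann, selected, pls, space9)


class TestOptimizer:
    def test_single_candidate_is_best(self, selected, run_means9, space9, Xy9):
        X_run, y_run = run_means9
        X, y, _ = Xy9
        feats = build_model_features(selected, X_run)
        ann = EnsembleANNRegressor(holdback_n=19, random_state=2).fit(
            feats, y_run)
        pls = md.NIPALSPLSRegression(n_components=4).fit(X, y)
        cands = sample_formulations(space9, 1, seed=6)
        res = predict_and_rank(cands, ann, selected, pls, space9)
        assert res.best_index == 0
        assert res.n_candidates == 1

    def test_best_attains_maximum(self, ranked):
        _, res = ranked
        assert res.predicted_delta_od_ann == res.ann_predictions.max()
        assert np.all(res.ann_predictions <= res.predicted_delta_od_ann)

    def test_both_predictions_attached(self, ranked):
        cands, res = ranked
        assert len(res.ann_predictions) == len(cands)
        assert len(res.pls_predictions) == len(cands)
        assert np.isfinite(res.predicted_delta_od_pls)

    def test_recipe_layout(self, ranked, space9):
        _, res = ranked
        recipe = export_recipe(res.best, space9)
        assert list(recipe.columns) == ["ingredient", "concentration", "units"]
        assert "glucose" in set(recipe["ingredient"])
        row = recipe.set_index("ingredient").loc["glucose"]
        assert row["concentration"] == 10.0 and row["units"] == "g/L"
        ye = recipe.set_index("ingredient").loc["yeast_extract"]
        assert ye["concentration"] == 0.0
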