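"""NIPALS-PLS: oracle equivalences, VIP identities, CV/LV selection."""

import numpy as np
import pandas as pd
import pytest

import mediadoe as md
from mediadoe.pls import NIPALSPLSRegression, cross_validate, vip_report


class TestBuildPredictorMatrix:
    def test_nine_mains_all_interactions(self, Xy9):
        X, y, groups = Xy9
        assert X.shape[1] == 45  # 9 + C(9,2)
        assert len(y) == len(groups) == 56 * 3

    def test_interaction_is_product_before_scaling(self, custom_design, responses9):
        X, _, _ = md.build_predictor_matrix(custom_design, responses9, "all")
        names = custom_design.factor_names
        a, b = names[0], names[1]
        assert np.allclose(X[f"{a}*{b}"], X[a] * X[b])

    def test_block_indicators_appended(self, custom_design, responses9):
        X, _, _ = md.build_predictor_matrix(
            custom_design, responses9, "all", include_blocks=True
        )
        assert X.shape[1] == 45 + 7
        blocks = [c for c in X.columns if c.startswith("block_")]
        assert np.allclose(X[blocks].sum(axis=1), 1.0)

    def test_technical_replicates_averaged(self, custom_design, responses9):
        _, y, groups = md.build_predictor_matrix(custom_design, responses9, "none")
        manual = responses9.groupby(["run_id", "bio_rep"])["delta_od600"].mean()
        assert np.allclose(np.sort(y), np.sort(manual.to_numpy()))

    def test_constant_column_dropped_with_name(self, custom_design, responses9, caplog):
        import logging

        df = custom_design.to_frame()
        df["inert"] = 1
        from mediadoe.io import FrameDesign

        d = FrameDesign(df)
        with caplog.at_level(logging.WARNING, logger="mediadoe.pls"):
            X, _, _ = md.build_predictor_matrix(d, responses9, "none")
        assert "inert" not in X.columns
        assert "inert" in caplog.text


class TestNIPALSFit:
    def test_single_predictor_equals_simple_regression(self, rng):
        x = rng.normal(size=40)
        y = 1.5 + 2.0 * x + rng.normal(scale=0.1, size=40)
        X = pd.DataFrame({"x": x})
        fit = NIPALSPLSRegression(n_components=1).fit(X, y)
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.coef_raw_[0] == pytest.approx(slope)
        assert fit.intercept_ == pytest.approx(intercept)
        assert fit.vip_[0] == pytest.approx(1.0)

    def test_full_rank_equals_ols(self, rng):
        n, p = 50, 6
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"x{i}" for i in range(p)])
        y = rng.normal(size=n)
        fit = NIPALSPLSRegression(n_components=p).fit(X, y)
        Z = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.lstsq(Z, y, rcond=None)[0]
        assert np.max(np.abs(fit.predict(X) - Z @ beta)) < 1e-8

    def test_matches_sklearn_pls(self, Xy9):
        # independent cross-check against the reference NIPALS in sklearn
        from sklearn.cross_decomposition import PLSRegression

        X, y, _ = Xy9
        ours = NIPALSPLSRegression(n_components=4).fit(X, y)
        ref = PLSRegression(n_components=4, scale=True).fit(
            X.to_numpy(), np.asarray(y)
        )
        assert np.allclose(ours.predict(X), ref.predict(X.to_numpy()).ravel(),
                           atol=1e-8)

    def test_scores_orthogonal(self, Xy9):
        X, y, _ = Xy9
        fit = NIPALSPLSRegression(n_components=6).fit(X, y)
        T = fit.x_scores_
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        norms = np.sqrt(np.outer(np.diag(G), np.diag(G)))
        assert np.max(np.abs(off) / norms) < 1e-8

    def test_pct_var_y_nondecreasing(self, Xy9):
        X, y, _ = Xy9
        fit = NIPALSPLSRegression(n_components=8).fit(X, y)
        assert np.all(np.diff(fit.pct_var_y_) >= -1e-10)

    def test_noiseless_linear_response_fully_explained(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 5)),
                         columns=list("abcde"))
        direction = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        y = X.to_numpy() @ direction
        fit = NIPALSPLSRegression(n_components=5).fit(X, y)
        assert fit.pct_var_y_[-1] == pytest.approx(100.0, abs=1e-6)

    def test_rank_one_x_explained_by_single_lv(self, rng):
        # all predictors proportional to one direction: 1 LV reaches 100%
        base = rng.normal(size=30)
        X = pd.DataFrame({f"x{i}": base * c
                          for i, c in enumerate([1.0, -0.5, 2.0])})
        y = 3.0 * base + 1.0
        fit = NIPALSPLSRegression(n_components=1).fit(X, y)
        assert fit.pct_var_y_[0] == pytest.approx(100.0, abs=1e-8)

    def test_components_beyond_rank_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        y = rng.normal(size=10)
        with pytest.raises(ValueError, match="rank"):
            NIPALSPLSRegression(n_components=4).fit(X, y)


class TestVIP:
    def test_normalization_identity_across_seeds(self):
        # mean of squared VIPs over predictors is exactly 1
        for seed in range(50):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(25, 8)),
                             columns=[f"x{i}" for i in range(8)])
            y = r.normal(size=25)
            fit = NIPALSPLSRegression(n_components=3).fit(X, y)
            assert (fit.vip_ ** 2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_threshold_classification(self, Xy9):
        X, y, _ = Xy9
        rep = vip_report(NIPALSPLSRegression(n_components=4).fit(X, y))
        assert set(rep.columns) == {"predictor", "vip", "coefficient",
                                    "significant"}
        # the conventional 0.8 cut: scores like 1.98 flag, 0.46 do not
        assert rep.loc[rep.vip >= 0.8, "significant"].all()
        assert not rep.loc[rep.vip < 0.8, "significant"].any()
        assert (rep.vip >= 0).all()


class TestCrossValidate:
    def test_report_has_one_row_per_lv(self, Xy9):
        X, y, groups = Xy9
        cv = cross_validate(X, y, a_max=15, K=7, seed=3, groups=groups)
        assert len(cv.table) == 15
        assert (cv.table["press"] >= 0).all()
        assert cv.table["vdv_p"].between(0, 1).all()
        assert np.allclose(cv.table["root_mean_press"],
                           np.sqrt(cv.table["press"] / len(y)))

    def test_vdv_p_is_one_at_optimum(self, Xy9):
        X, y, groups = Xy9
        cv = cross_validate(X, y, a_max=10, K=7, seed=3, groups=groups)
        assert cv.table.loc[cv.a_opt - 1, "vdv_p"] == pytest.approx(1.0)
        assert cv.a_selected <= cv.a_opt

    def test_noiseless_rank_one_selects_one_lv(self, rng):
        base = rng.normal(size=42)
        X = pd.DataFrame({f"x{i}": base * c
                          for i, c in enumerate([1.0, 0.7, -1.3, 2.0])})
        y = 2.0 * base
        cv = cross_validate(X, y, a_max=5, K=7, seed=0)
        assert cv.a_selected == 1

    def test_selected_press_close_to_deepest(self, Xy9):
        X, y, groups = Xy9
        cv = cross_validate(X, y, a_max=15, K=7, seed=3, groups=groups)
        press = cv.table["press"].to_numpy()
        assert press[cv.a_selected - 1] <= press[-1] * 1.5

    def test_k_exceeding_n_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="K"):
            cross_validate(X, rng.normal(size=5), a_max=2, K=7)

    def test_folds_stratify_whole_runs(self, rng):
        # folds are formed over distinct runs, so 3 runs cannot feed 7 folds
        X = pd.DataFrame(rng.normal(size=(9, 2)), columns=["a", "b"])
        groups = np.repeat([1, 2, 3], 3)
        with pytest.raises(ValueError, match="distinct runs"):
            cross_validate(X, rng.normal(size=9), a_max=2, K=7, groups=groups)
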