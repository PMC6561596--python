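"""Single-response partial least squares by NIPALS, with KFold
cross-validation, van der Voet T^2 latent-variable selection and VIP
(Variable Importance in Projection) factor screening.

This is the screening engine of the media-development pipeline: both
design iterations are modelled as Delta-OD600 against coded ingredient
levels, their pairwise interactions and (optionally) block indicators.
Predictors and response are autoscaled; VIP >= 0.8 flags a predictor as
influential and the sign of its centred-and-scaled coefficient gives the
direction of the effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NIPALSPLSRegression",
    "CVReport",
    "build_predictor_matrix",
    "cross_validate",
    "vip_report",
]

logger = logging.getLogger(__name__)

VIP_THRESHOLD = 0.8


def build_predictor_matrix(
    design,
    responses: pd.DataFrame,
    include_interactions="all",
    include_blocks: bool = False,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Assemble the (unscaled) predictor matrix and response vector.

    Technical replicates are averaged, biological replicates kept as rows:
    the returned objects have one row per (run, biological replicate).
    Interaction columns are elementwise products of coded main-effect
    columns and are labelled ``A*B``; block indicator columns (one per
    block label) are appended when ``include_blocks`` is set.  Columns with
    zero variance are dropped with a warning naming them.

    Returns
    -------
    X : DataFrame, y : Series, groups : ndarray of run ids (for
    run-stratified cross-validation folds).
    """
    ddf = design.to_frame()
    names = design.factor_names
    required = {"run_id", "bio_rep", "tech_rep", "delta_od600"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    runs_missing = set(ddf["run_id"]) - set(responses["run_id"])
    if runs_missing:
        raise ValueError(f"responses missing design runs: {sorted(runs_missing)[:5]}")

    mean_resp = (
        responses.groupby(["run_id", "bio_rep"], as_index=False)["delta_od600"].mean()
    )
    merged = mean_resp.merge(ddf, on="run_id", how="left")

    X = merged[names].astype(float).copy()
    if include_interactions == "all":
        pairs = [
            (a, b) for i, a in enumerate(names) for b in names[i + 1:]
        ]
    elif include_interactions in (None, "none"):
        pairs = []
    else:
        pairs = []
        for lab in include_interactions:
            a, b = lab.split("*")
            pairs.append((a, b))
    for a, b in pairs:
        X[f"{a}*{b}"] = merged[a].astype(float) * merged[b].astype(float)
    if include_blocks:
        for b in sorted(pd.unique(merged["block"])):
            X[f"block_{b}"] = (merged["block"] == b).astype(float)

    constant = [c for c in X.columns if X[c].std(ddof=0) < 1e-12]
    if constant:
        logger.warning("dropping zero-variance predictors: %s", constant)
        X = X.drop(columns=constant)
    y = merged["delta_od600"].rename("delta_od600")
    return X, y, merged["run_id"].to_numpy()


class NIPALSPLSRegression(BaseEstimator, RegressorMixin):
    """Partial least squares regression (single response) via NIPALS.

    Predictors and response are autoscaled internally (column mean 0,
    SD 1); coefficients are reported on the autoscaled scale (``coef_``)
    and the raw scale (``coef_raw_``, ``intercept_``).

    Parameters
    ----------
    n_components : int
        Number of latent variables (LVs) to extract.

    Attributes
    ----------
    x_weights_, x_scores_, x_loadings_ : per-LV NIPALS quantities.
    y_loadings_ : ndarray of shape (n_components,)
    coef_ : autoscaled regression coefficients.
    vip_ : Variable Importance in Projection per predictor
        (mean squared VIP over predictors is exactly 1).
    pct_var_x_, pct_var_y_ : cumulative percent variation explained.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns.astype(str))
        Xv = X.to_numpy(dtype=float)
        yv = np.asarray(y, dtype=float).ravel()
        n, p = Xv.shape
        if n != yv.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        a = int(self.n_components)
        rank = np.linalg.matrix_rank(Xv - Xv.mean(axis=0))
        if not 1 <= a <= rank:
            raise ValueError(
                f"n_components must be between 1 and rank(X) = {rank}, got {a}"
            )

        self.x_mean_ = Xv.mean(axis=0)
        self.x_std_ = Xv.std(axis=0, ddof=1)
        if np.any(self.x_std_ < 1e-12):
            bad = self.feature_names_in_[self.x_std_ < 1e-12]
            raise ValueError(f"zero-variance predictors: {list(bad)}")
        self.y_mean_ = yv.mean()
        self.y_std_ = yv.std(ddof=1)
        if self.y_std_ < 1e-12:
            self.y_std_ = 1.0
        Xs = (Xv - self.x_mean_) / self.x_std_
        ys = (yv - self.y_mean_) / self.y_std_

        ss_x_total = (Xs ** 2).sum()
        ss_y_total = (ys ** 2).sum()
        W = np.zeros((p, a))
        T = np.zeros((n, a))
        P = np.zeros((p, a))
        q = np.zeros(a)
        Xd, yd = Xs.copy(), ys.copy()
        for comp in range(a):
            w = Xd.T @ yd
            nw = np.linalg.norm(w)
            if nw < 1e-14:
                raise ValueError(
                    f"NIPALS deflation exhausted covariance at component {comp + 1}"
                )
            w /= nw
            t = Xd @ w
            tt = t @ t
            pvec = Xd.T @ t / tt
            qc = (yd @ t) / tt
            Xd -= np.outer(t, pvec)
            yd -= qc * t
            W[:, comp], T[:, comp], P[:, comp], q[comp] = w, t, pvec, qc

        self.x_weights_, self.x_scores_, self.x_loadings_, self.y_loadings_ = W, T, P, q
        # coefficient path: coefficients using the first a' components
        self.coef_path_ = np.zeros((p, a))
        for comp in range(a):
            Wa, Pa, qa = W[:, : comp + 1], P[:, : comp + 1], q[: comp + 1]
            self.coef_path_[:, comp] = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
        self.coef_ = self.coef_path_[:, -1]
        self.coef_raw_ = self.coef_ * self.y_std_ / self.x_std_
        self.intercept_ = float(self.y_mean_ - self.coef_raw_ @ self.x_mean_)

        ss_comp_x = (T ** 2).sum(axis=0) * (P ** 2).sum(axis=0)
        ss_comp_y = q ** 2 * (T ** 2).sum(axis=0)
        self.pct_var_x_ = 100.0 * np.cumsum(ss_comp_x) / ss_x_total
        self.pct_var_y_ = 100.0 * np.cumsum(ss_comp_y) / ss_y_total

        # VIP_j = sqrt(p * sum_a (w_ja/||w_a||)^2 SS_a / sum_a SS_a);
        # NIPALS weights are already unit norm.
        denom = ss_comp_y.sum()
        self.vip_ = np.sqrt(p * (W ** 2 @ ss_comp_y) / denom)
        return self

    def _predict_path(self, X) -> np.ndarray:
        """Predictions for every component count 1..n_components (n x a)."""
        check_is_fitted(self, "coef_path_")
        Xv = pd.DataFrame(X).to_numpy(dtype=float)
        Xs = (Xv - self.x_mean_) / self.x_std_
        return self.y_mean_ + self.y_std_ * (Xs @ self.coef_path_)

    def predict(self, X):
        return self._predict_path(X)[:, -1]


def vip_report(
    fit: NIPALSPLSRegression, threshold: float = VIP_THRESHOLD
) -> pd.DataFrame:
    """VIP score, autoscaled coefficient and significance flag per predictor."""
    check_is_fitted(fit, "vip_")
    return pd.DataFrame({
        "predictor": fit.feature_names_in_,
        "vip": fit.vip_,
        "coefficient": fit.coef_,
        "significant": fit.vip_ >= threshold,
    })


@dataclass
class CVReport:
    """Cross-validation trace over latent-variable counts.

    ``table`` has one row per LV count: PRESS, Root Mean PRESS
    (sqrt(PRESS/n)), the van der Voet T^2 p-value against the
    PRESS-minimizing count, and a ``selected`` flag on the chosen row.
    """

    K: int
    table: pd.DataFrame
    a_opt: int
    a_selected: int
    alpha: float
    seed: int


def _fold_assignments(groups: np.ndarray, K: int, rng: np.random.Generator):
    """Run-stratified folds: whole runs held out together, sizes within 1."""
    uniq = np.unique(groups)
    if K > len(uniq):
        raise ValueError(f"K = {K} exceeds the {len(uniq)} distinct runs")
    perm = rng.permutation(uniq)
    folds = [perm[i::K] for i in range(K)]
    return folds


def cross_validate(
    X,
    y,
    a_max: int = 15,
    K: int = 7,
    seed: int = 0,
    groups: np.ndarray | None = None,
    alpha: float = 0.10,
    n_perm: int = 2000,
) -> CVReport:
    """KFold cross-validation of the LV count with van der Voet selection.

    PLS models extracting 1..a_max LVs are scored by PRESS pooled over K
    seeded, run-stratified folds.  The optimum count minimizes PRESS; the
    selected count is the smallest one whose squared held-out residuals
    are not significantly worse than the optimum's under the van der Voet
    T^2 sign-flip randomization test (p > alpha).
    """
    X = pd.DataFrame(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = len(yv)
    if groups is None:
        groups = np.arange(n)
    groups = np.asarray(groups)
    if K > n:
        raise ValueError(f"K = {K} exceeds n = {n}")
    rng = np.random.default_rng(seed)
    folds = _fold_assignments(groups, K, rng)

    a_cap = a_max
    preds = np.full((n, a_max), np.nan)
    for fold_groups in folds:
        test = np.isin(groups, fold_groups)
        train = ~test
        Xtr = X.loc[train]
        rank = np.linalg.matrix_rank(
            Xtr.to_numpy(dtype=float) - Xtr.to_numpy(dtype=float).mean(axis=0)
        )
        a_fit = min(a_max, rank)
        a_cap = min(a_cap, a_fit)
        fit = NIPALSPLSRegression(n_components=a_fit).fit(Xtr, yv[train])
        path = fit._predict_path(X.loc[test])
        preds[test, :a_fit] = path
        # pad: beyond attainable rank reuse the deepest model
        preds[test, a_fit:] = path[:, [-1]]
    if a_cap < a_max:
        logger.info("LV path capped at %d by training-fold rank", a_cap)

    resid2 = (preds - yv[:, None]) ** 2
    press = resid2.sum(axis=0)
    root_mean_press = np.sqrt(press / n)
    a_opt = int(np.argmin(press)) + 1

    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    pvals = np.ones(a_max)
    d_opt = resid2[:, a_opt - 1]
    for a in range(a_max):
        d = resid2[:, a] - d_opt
        t_obs = d.sum()
        t_perm = signs @ d
        pvals[a] = (1 + np.sum(t_perm >= t_obs)) / (n_perm + 1)

    selected_mask = pvals > alpha
    a_selected = int(np.flatnonzero(selected_mask)[0]) + 1

    table = pd.DataFrame({
        "n_lv": np.arange(1, a_max + 1),
        "press": press,
        "root_mean_press": root_mean_press,
        "vdv_p": pvals,
        "selected": np.arange(1, a_max + 1) == a_selected,
    })
    return CVReport(K=K, table=table, a_opt=a_opt, a_selected=a_selected,
                    alpha=alpha, seed=seed)
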