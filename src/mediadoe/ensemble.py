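"""ANN-weighted ensembling of selected regression models and the
in-silico formulation optimizer.

The ensemble is a small feed-forward network — one hidden layer of three
sigmoid nodes, linear output — whose inputs are the predictions of the
AICc-selected regression models (not the raw ingredients).  Training uses
full-batch L-BFGS on squared error from a seeded initialization, with a
randomly chosen holdback partition (default 19 rows) withheld as a
validation set.  The optimizer samples candidate media uniformly within
each ingredient's concentration range (with pinned ingredients, e.g.
yeast extract = 0, held fixed), ranks them by the ensemble prediction and
exports the best candidate as a recipe table.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .designs import GLUCOSE_G_PER_L
from .factors import FactorSpace
from .model_search import CandidateModel

__all__ = [
    "EnsembleANNRegressor",
    "OptimizationResult",
    "build_model_features",
    "sample_formulations",
    "predict_and_rank",
    "export_recipe",
]

logger = logging.getLogger(__name__)


def build_model_features(
    selected_models: list[CandidateModel], X_design: pd.DataFrame
) -> pd.DataFrame:
    """One feature column per selected model: its prediction at each row.

    ``X_design`` must resolve every model term (mains and ``A*B``
    interaction columns on the coded scale).
    """
    feats = {}
    for i, m in enumerate(selected_models, start=1):
        feats[f"model_{i}"] = m.predict(X_design)
    return pd.DataFrame(feats, index=X_design.index)


def _logistic(z):
    return expit(z)


class EnsembleANNRegressor(BaseEstimator, RegressorMixin):
    """Single-hidden-layer neural network with holdback validation.

    Parameters
    ----------
    n_hidden : int
        Hidden nodes (default 3).
    activation : {"logistic", "tanh"}
        Hidden activation; the logistic sigmoid is the default.
    holdback_n : int
        Rows randomly withheld from training as a validation partition
        (default 19).  Set to 0 to train on everything.
    random_state : int
        Seeds both the holdback draw and the weight initialization.
    max_iter, tol : L-BFGS iteration cap and gradient tolerance.
    alpha : float
        L2 penalty on connection weights (not biases); a small ridge
        keeps the tiny unregularized net from fitting wiggly or inverted
        shapes between its few training points.
    n_restarts : int
        Seeded random initializations; the restart with the lowest
        penalized training loss wins.

    Attributes
    ----------
    holdback_idx_ : indices of the validation rows.
    r2_train_, r2_validation_ : coefficient of determination per partition
        (NaN when a partition's response is constant).
    """

    def __init__(self, n_hidden: int = 3, activation: str = "logistic",
                 holdback_n: int = 19, random_state: int = 0,
                 max_iter: int = 5000, tol: float = 1e-8,
                 alpha: float = 1e-3, n_restarts: int = 10):
        self.n_hidden = n_hidden
        self.activation = activation
        self.holdback_n = holdback_n
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.alpha = alpha
        self.n_restarts = n_restarts

    def _act(self, z):
        if self.activation == "logistic":
            a = _logistic(z)
            return a, a * (1.0 - a)
        if self.activation == "tanh":
            a = np.tanh(z)
            return a, 1.0 - a ** 2
        raise ValueError(f"unknown activation {self.activation!r}")

    def _unpack(self, theta, p):
        h = self.n_hidden
        i = 0
        W1 = theta[i:i + h * p].reshape(h, p); i += h * p
        b1 = theta[i:i + h]; i += h
        w2 = theta[i:i + h]; i += h
        b2 = theta[i]
        return W1, b1, w2, b2

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns.astype(str))
        Xv = X.to_numpy(dtype=float)
        yv = np.asarray(y, dtype=float).ravel()
        n, p = Xv.shape
        if not 0 <= self.holdback_n < n:
            raise ValueError(
                f"holdback_n must be in [0, n); got {self.holdback_n} with n={n}"
            )
        rng = np.random.default_rng(self.random_state)
        idx = rng.choice(n, size=self.holdback_n, replace=False)
        self.holdback_idx_ = np.sort(idx)
        train_mask = np.ones(n, dtype=bool)
        train_mask[self.holdback_idx_] = False
        self.train_idx_ = np.flatnonzero(train_mask)

        self.x_mean_ = Xv.mean(axis=0)
        self.x_std_ = Xv.std(axis=0, ddof=0)
        self.x_std_[self.x_std_ < 1e-12] = 1.0
        self.y_mean_ = yv.mean()
        self.y_std_ = yv.std(ddof=0) or 1.0
        Xs = (Xv - self.x_mean_) / self.x_std_
        ys = (yv - self.y_mean_) / self.y_std_
        Xtr, ytr = Xs[train_mask], ys[train_mask]

        h = self.n_hidden
        n_theta = h * p + h + h + 1
        # penalty mask: connection weights only, biases free
        pen = np.zeros(n_theta)
        pen[: h * p] = self.alpha
        pen[h * p + h: h * p + h + h] = self.alpha

        def loss_grad(theta):
            W1, b1, w2, b2 = self._unpack(theta, p)
            Z = Xtr @ W1.T + b1
            A, dA = self._act(Z)
            yhat = A @ w2 + b2
            r = yhat - ytr
            loss = 0.5 * float(r @ r) + 0.5 * float(pen @ theta ** 2)
            g_b2 = r.sum()
            g_w2 = A.T @ r
            delta = (r[:, None] * w2[None, :]) * dA
            g_b1 = delta.sum(axis=0)
            g_W1 = delta.T @ Xtr
            grad = np.concatenate([g_W1.ravel(), g_b1, g_w2, [g_b2]]) + pen * theta
            return loss, grad

        best = None
        for _ in range(max(1, self.n_restarts)):
            theta0 = rng.normal(0.0, 0.1, size=n_theta)
            res = minimize(loss_grad, theta0, jac=True, method="L-BFGS-B",
                           options={"maxiter": self.max_iter, "gtol": self.tol,
                                    "ftol": 1e-14})
            if best is None or res.fun < best.fun:
                best = res
        self.opt_result_ = best
        self.theta_ = best.x
        self.n_features_in_ = p

        yhat = self._forward(Xs)
        self.train_targets_min_ = float(yv[train_mask].min())
        self.train_targets_max_ = float(yv[train_mask].max())
        self.train_targets_sd_ = float(yv[train_mask].std(ddof=0))
        self.r2_train_ = self._r2(yv[train_mask], yhat[train_mask])
        if self.holdback_n:
            self.r2_validation_ = self._r2(
                yv[self.holdback_idx_], yhat[self.holdback_idx_]
            )
        else:
            self.r2_validation_ = np.nan
        return self

    @staticmethod
    def _r2(y, yhat) -> float:
        sst = float(((y - y.mean()) ** 2).sum())
        if sst == 0:
            return np.nan  # R^2 undefined on a constant partition
        return 1.0 - float(((y - yhat) ** 2).sum()) / sst

    def _forward(self, Xs) -> np.ndarray:
        W1, b1, w2, b2 = self._unpack(self.theta_, self.n_features_in_)
        A, _ = self._act(Xs @ W1.T + b1)
        return self.y_mean_ + self.y_std_ * (A @ w2 + b2)

    def predict(self, X):
        check_is_fitted(self, "theta_")
        Xv = pd.DataFrame(X).to_numpy(dtype=float)
        Xs = (Xv - self.x_mean_) / self.x_std_
        yhat = self._forward(Xs)
        lo = self.train_targets_min_ - 3.0 * self.train_targets_sd_
        hi = self.train_targets_max_ + 3.0 * self.train_targets_sd_
        if np.any((yhat < lo) | (yhat > hi)):
            warnings.warn(
                "ensemble prediction outside the training-target sanity "
                f"envelope [{lo:.3g}, {hi:.3g}]", RuntimeWarning,
            )
        return yhat

    def to_dict(self) -> dict:
        """JSON-serializable dump (weights, scaling, holdback, seed)."""
        check_is_fitted(self, "theta_")
        W1, b1, w2, b2 = self._unpack(self.theta_, self.n_features_in_)
        return {
            "n_hidden": self.n_hidden,
            "activation": self.activation,
            "W1": W1.tolist(), "b1": b1.tolist(),
            "w2": w2.tolist(), "b2": float(b2),
            "x_mean": self.x_mean_.tolist(), "x_std": self.x_std_.tolist(),
            "y_mean": float(self.y_mean_), "y_std": float(self.y_std_),
            "holdback_idx": self.holdback_idx_.tolist(),
            "r2_train": float(self.r2_train_),
            "r2_validation": float(self.r2_validation_),
            "random_state": self.random_state,
            "feature_names": list(self.feature_names_in_),
        }


def sample_formulations(
    space: FactorSpace, n: int, pinned: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw candidate media: concentrations uniform on [low, high] per
    ingredient, with the pinned map applied to every candidate."""
    pinned = pinned or {}
    rng = np.random.default_rng(seed)
    cols = {}
    for f in space:
        if f.name in pinned:
            cols[f.name] = np.full(n, float(pinned[f.name]))
        elif f.pinned is not None:
            cols[f.name] = np.full(n, f.pinned)
        else:
            cols[f.name] = rng.uniform(f.low, f.high, size=n)
    return pd.DataFrame(cols)


def _encode_candidates(candidates: pd.DataFrame, space: FactorSpace) -> pd.DataFrame:
    coded = {}
    free = [f for f in space if f.pinned is None]
    for f in free:
        coded[f.name] = np.array([f.encode(v) for v in candidates[f.name]])
    df = pd.DataFrame(coded)
    names = list(df.columns)
    for a, b in itertools.combinations(names, 2):
        df[f"{a}*{b}"] = df[a] * df[b]
    return df


@dataclass
class OptimizationResult:
    """The formulation the ensemble ranks highest among the candidates."""

    best: pd.Series
    best_index: int
    predicted_delta_od_ann: float
    predicted_delta_od_pls: float
    n_candidates: int
    ann_predictions: np.ndarray
    pls_predictions: np.ndarray
    seed: int


def predict_and_rank(
    candidates: pd.DataFrame,
    ensemble: EnsembleANNRegressor,
    selected_models: list[CandidateModel],
    pls_fit,
    space: FactorSpace,
    seed: int = 0,
) -> OptimizationResult:
    """Attach ANN and PLS predictions to every candidate and pick the
    ANN argmax (ties broken by first occurrence, logged)."""
    coded = _encode_candidates(candidates, space)
    feats = build_model_features(selected_models, coded)
    ann_pred = ensemble.predict(feats)
    pls_cols = [c for c in pls_fit.feature_names_in_ if c in coded.columns]
    if len(pls_cols) != len(pls_fit.feature_names_in_):
        missing = set(pls_fit.feature_names_in_) - set(coded.columns)
        raise ValueError(f"candidates cannot be encoded for PLS terms: {sorted(missing)[:5]}")
    pls_pred = pls_fit.predict(coded[list(pls_fit.feature_names_in_)])
    best_idx = int(np.argmax(ann_pred))
    ties = np.flatnonzero(ann_pred == ann_pred[best_idx])
    if len(ties) > 1:
        logger.info("ANN argmax tie among %d candidates; keeping the first", len(ties))
    return OptimizationResult(
        best=candidates.iloc[best_idx],
        best_index=best_idx,
        predicted_delta_od_ann=float(ann_pred[best_idx]),
        predicted_delta_od_pls=float(pls_pred[best_idx]),
        n_candidates=len(candidates),
        ann_predictions=ann_pred,
        pls_predictions=pls_pred,
        seed=seed,
    )


def export_recipe(
    best: pd.Series, space: FactorSpace, add_glucose: bool = True
) -> pd.DataFrame:
    """Recipe table (`ingredient,concentration,units`) for one candidate,
    with pinned stock solutions and glucose at 10 g/L appended."""
    rows = []
    for f in space:
        conc = f.pinned if f.pinned is not None else float(best[f.name])
        rows.append((f.name, conc, f.units))
    if add_glucose and "glucose" not in {r[0] for r in rows}:
        rows.append(("glucose", GLUCOSE_G_PER_L, "g/L"))
    return pd.DataFrame(rows, columns=["ingredient", "concentration", "units"])
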