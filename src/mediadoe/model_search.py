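"""Exhaustive all-subsets linear regression scored by small-sample AICc.

Candidate models draw terms from the main effects and all pairwise
interactions of the coded design factors, up to a maximum term count
(default 6).  Every candidate is fit by ordinary least squares through a
cached Gram matrix (each subset reduces to a <= (max_terms+1)-dimensional
solve, batched over contiguous chunks of the enumeration), scored by

    AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1),        k = |terms| + 2

(intercept and error variance counted in k), and the models within
delta_i = AICc_i - AICc_min < 2.0 of the best are retained.  With 9 main
effects and a 6-term cap the unrestricted enumeration visits 9,531,039
models; optional strong heredity admits an interaction only when both
parent main effects are present.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "CandidateModel",
    "SearchResult",
    "AICcSubsetSearch",
    "count_models",
    "aicc",
    "gaussian_loglik",
    "fit_candidate",
    "search",
]

logger = logging.getLogger(__name__)

_RSS_FLOOR = 1e-12
_CHUNK = 200_000


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1); requires n - k - 1 > 0.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n - k - 1 <= 0)")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximized Gaussian log-likelihood with sigma^2 = RSS/n."""
    rss = max(float(rss), _RSS_FLOOR)
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def interaction_labels(mains: list[str]) -> list[str]:
    return [f"{a}*{b}" for i, a in enumerate(mains) for b in mains[i + 1:]]


def count_models(n_main: int, max_terms: int = 6, heredity: str = "none") -> int:
    """Number of candidate models with 1..max_terms terms.

    ``heredity='none'``: closed form, sum_k C(n_main + C(n_main,2), k).
    ``heredity='strong'``: counted by enumerating admissible subsets
    (an interaction requires both parents present).
    """
    if max_terms < 1:
        raise ValueError("max_terms must be >= 1")
    n_terms = n_main + math.comb(n_main, 2)
    if heredity == "none":
        return sum(math.comb(n_terms, k) for k in range(1, max_terms + 1))
    if heredity != "strong":
        raise ValueError(f"unknown heredity mode {heredity!r}")
    parents = _term_parents(n_main)
    total = 0
    for size in range(1, max_terms + 1):
        for combo in itertools.combinations(range(n_terms), size):
            if _heredity_ok(combo, parents, n_main):
                total += 1
    return total


def _term_parents(n_main: int) -> np.ndarray:
    """(n_terms, 2) parent main indices; mains have parents (-1, -1)."""
    rows = [(-1, -1)] * n_main
    for i, j in itertools.combinations(range(n_main), 2):
        rows.append((i, j))
    return np.array(rows, dtype=np.int64)


def _heredity_ok(combo, parents: np.ndarray, n_main: int) -> bool:
    present = {t for t in combo if t < n_main}
    for t in combo:
        if t >= n_main:
            i, j = parents[t]
            if i not in present or j not in present:
                return False
    return True


@dataclass
class CandidateModel:
    """One scored subset-regression model."""

    terms: tuple[str, ...]
    k: int
    loglik: float
    aicc: float
    delta_i: float = np.nan
    coef: dict | None = None  # term -> coefficient, "(intercept)" included

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.coef is None:
            raise ValueError("model has no stored coefficients")
        yhat = np.full(len(X), self.coef["(intercept)"], dtype=float)
        for term, c in self.coef.items():
            if term == "(intercept)":
                continue
            if term not in X.columns:
                raise KeyError(f"term {term!r} not resolvable in design columns")
            yhat += c * X[term].to_numpy(dtype=float)
        return yhat


@dataclass
class SearchResult:
    n_enumerated: int
    n_excluded: int
    selected: list[CandidateModel]
    threshold: float
    heredity: str
    max_terms: int
    aicc_min: float


def fit_candidate(X_full: pd.DataFrame, y, terms) -> CandidateModel:
    """OLS fit of one term subset, with Gaussian log-likelihood and AICc."""
    terms = tuple(terms)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    Z = np.column_stack(
        [np.ones(n)] + [X_full[t].to_numpy(dtype=float) for t in terms]
    )
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1]:
        raise np.linalg.LinAlgError(f"rank-deficient subset {terms}")
    rss = float(((y - Z @ beta) ** 2).sum())
    ll = gaussian_loglik(rss, n)
    k = len(terms) + 2
    coef = {"(intercept)": float(beta[0])}
    coef.update({t: float(b) for t, b in zip(terms, beta[1:])})
    return CandidateModel(terms=terms, k=k, loglik=ll, aicc=aicc(ll, k, n), coef=coef)


class AICcSubsetSearch(BaseEstimator):
    """Streaming exhaustive subset search over mains + pairwise interactions.

    Parameters
    ----------
    max_terms : int
        Largest model size enumerated (default 6).
    heredity : {"none", "strong"}
        ``"none"`` enumerates every subset of the term basis (9 mains with
        a 6-term cap gives 9,531,039 candidates); ``"strong"`` admits an
        interaction only when both parent mains are present.
    threshold : float
        delta_i cutoff for the selected set (default 2.0).

    Attributes
    ----------
    n_enumerated_, n_excluded_ : enumeration bookkeeping.
    aicc_min_ : best AICc found.
    selected_ : list of CandidateModel with delta_i < threshold, sorted
        ascending by (delta_i, terms) so ties break lexicographically.
    """

    def __init__(self, max_terms: int = 6, heredity: str = "none",
                 threshold: float = 2.0, chunk_size: int = _CHUNK):
        self.max_terms = max_terms
        self.heredity = heredity
        self.threshold = threshold
        self.chunk_size = chunk_size

    def fit(self, X, y, mains: list[str] | None = None):
        """Run the full enumeration against a term basis built from X.

        X must contain one column per main effect and per interaction
        (labelled ``A*B``); ``mains`` defaults to the columns without an
        asterisk.
        """
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        if mains is None:
            mains = [c for c in X.columns if "*" not in c]
        labels = list(mains) + interaction_labels(list(mains))
        missing = [t for t in labels if t not in X.columns]
        if missing:
            raise ValueError(f"X lacks term columns: {missing[:5]}")
        if self.heredity not in ("none", "strong"):
            raise ValueError(f"unknown heredity mode {self.heredity!r}")
        nt = len(labels)
        n_main = len(mains)
        parents = _term_parents(n_main)

        M = X[labels].to_numpy(dtype=float)
        Z = np.column_stack([np.ones(n), M])
        G = Z.T @ Z
        gy = Z.T @ y
        yty = float(y @ y)

        best_aicc = np.inf
        kept: list[tuple[float, tuple[int, ...]]] = []
        n_enum = 0
        n_excl = 0
        next_log = 1_000_000

        for size in range(1, self.max_terms + 1):
            k = size + 2
            if n - k - 1 <= 0:
                remaining = (
                    math.comb(nt, s) for s in range(size, self.max_terms + 1)
                )
                n_skip = sum(remaining)
                logger.warning(
                    "AICc unscorable for %d-term models at n=%d; excluding "
                    "%d candidates", size, n, n_skip,
                )
                n_enum += n_skip
                n_excl += n_skip
                break
            it = itertools.combinations(range(nt), size)
            while True:
                chunk = list(itertools.islice(it, self.chunk_size))
                if not chunk:
                    break
                C = np.array(chunk, dtype=np.int64)
                if self.heredity == "strong":
                    mask = np.array(
                        [_heredity_ok(c, parents, n_main) for c in chunk]
                    )
                    n_enum += int(mask.sum())
                    C = C[mask]
                    if not len(C):
                        continue
                else:
                    n_enum += len(C)
                idx = np.concatenate(
                    [np.zeros((len(C), 1), dtype=np.int64), C + 1], axis=1
                )
                A = G[idx[:, :, None], idx[:, None, :]]
                b = gy[idx]
                try:
                    beta = np.linalg.solve(A, b[..., None])[..., 0]
                    rss = yty - np.einsum("ij,ij->i", beta, b)
                    bad = ~np.isfinite(rss)
                except np.linalg.LinAlgError:
                    beta = np.full_like(b, np.nan)
                    rss = np.full(len(C), np.nan)
                    for r in range(len(C)):
                        try:
                            beta_r = np.linalg.solve(A[r], b[r])
                            rss[r] = yty - beta_r @ b[r]
                        except np.linalg.LinAlgError:
                            pass
                    bad = ~np.isfinite(rss)
                n_excl += int(bad.sum())
                rss = np.clip(rss, _RSS_FLOOR, None)
                ll = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
                a = -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
                a[bad] = np.inf
                cut = best_aicc + self.threshold
                good = np.flatnonzero(a < cut)
                for r in good:
                    kept.append((float(a[r]), tuple(C[r])))
                if len(good):
                    best_aicc = min(best_aicc, float(a[good].min()))
                    cut = best_aicc + self.threshold
                    kept = [kv for kv in kept if kv[0] < cut]
                if n_enum >= next_log:
                    logger.info("enumerated %d models (best AICc %.3f)",
                                n_enum, best_aicc)
                    next_log += 1_000_000

        kept = [kv for kv in kept if kv[0] < best_aicc + self.threshold]
        selected = []
        for a_val, combo in kept:
            terms = tuple(labels[t] for t in combo)
            cm = fit_candidate(X[labels], y, terms)
            cm.delta_i = a_val - best_aicc
            selected.append(cm)
        selected.sort(key=lambda m: (m.delta_i, m.terms))

        self.term_labels_ = labels
        self.n_enumerated_ = n_enum
        self.n_excluded_ = n_excl
        self.aicc_min_ = best_aicc
        self.selected_ = selected
        self.result_ = SearchResult(
            n_enumerated=n_enum, n_excluded=n_excl, selected=selected,
            threshold=self.threshold, heredity=self.heredity,
            max_terms=self.max_terms, aicc_min=best_aicc,
        )
        return self


def search(
    X_full, y, max_terms: int = 6, heredity: str = "none", threshold: float = 2.0,
    mains: list[str] | None = None,
) -> SearchResult:
    """Functional wrapper around :class:`AICcSubsetSearch`."""
    est = AICcSubsetSearch(max_terms=max_terms, heredity=heredity,
                           threshold=threshold)
    est.fit(X_full, y, mains=mains)
    return est.result_


def selected_models_frame(result: SearchResult) -> pd.DataFrame:
    """Selected-models table: rank, terms, k, loglik, aicc, delta_i."""
    return pd.DataFrame({
        "rank": np.arange(1, len(result.selected) + 1),
        "terms": ["+".join(m.terms) for m in result.selected],
        "k": [m.k for m in result.selected],
        "loglik": [m.loglik for m in result.selected],
        "aicc": [m.aicc for m in result.selected],
        "delta_i": [m.delta_i for m in result.selected],
    })
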