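"""Synthetic growth responses with known ground truth.

The generator emulates the statistical structure of microplate Delta-OD600
endpoint data from a blocked factorial media experiment: a linear model on
the coded factor levels (main effects of both signs, a few two-factor
interactions), additive per-block batch effects, replicate noise and a
saturating optical-density ceiling.  Ground-truth coefficients are known,
so screening, subset-regression and optimization stages can be judged
against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factors import FactorSpace

__all__ = [
    "GroundTruth",
    "GrowthCurveParams",
    "default_truth",
    "simulate_response",
    "simulate_growth_curve",
]


@dataclass
class GroundTruth:
    """Data-generating model on the coded (-1/+1) factor scale.

    The latent growth potential of a run is

        u = beta0 + sum_j beta_main[j] x_j
              + sum_{(i,j)} beta_int[(i,j)] x_i x_j + block_effect + eps,

    eps ~ Normal(0, sigma^2), and the emitted response is the saturating
    transform ``od_max * max(u, 0) / (od_max + max(u, 0))`` (a Monod-like
    bounded monotone map; ``transform="linear"`` emits u unchanged).
    """

    factor_names: list[str]
    beta0: float = 0.0
    beta_main: dict[str, float] = field(default_factory=dict)
    beta_int: dict[tuple[str, str], float] = field(default_factory=dict)
    block_effects: dict[int, float] = field(default_factory=dict)
    sigma: float = 0.05
    od_max: float = 2.0
    transform: str = "saturating"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.od_max <= 0:
            raise ValueError("od_max must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.transform not in ("saturating", "linear"):
            raise ValueError("transform must be 'saturating' or 'linear'")
        known = set(self.factor_names)
        unknown = set(self.beta_main) - known
        unknown |= {n for pair in self.beta_int for n in pair} - known
        if unknown:
            raise ValueError(f"effects reference unknown factors: {sorted(unknown)}")

    def latent(self, coded: np.ndarray) -> np.ndarray:
        """Noise- and block-free latent mean for coded rows (n x k)."""
        coded = np.asarray(coded, dtype=float)
        idx = {n: j for j, n in enumerate(self.factor_names)}
        u = np.full(coded.shape[0], self.beta0)
        for name, b in self.beta_main.items():
            u += b * coded[:, idx[name]]
        for (a, b_), bi in self.beta_int.items():
            u += bi * coded[:, idx[a]] * coded[:, idx[b_]]
        return u

    def emit(self, u: np.ndarray) -> np.ndarray:
        if self.transform == "linear":
            return u
        up = np.maximum(u, 0.0)
        return self.od_max * up / (self.od_max + up)

    def restrict(self, kept: list[str]) -> "GroundTruth":
        """Truth for a follow-up design over a factor subset.

        Dropped factors sit at their low level (coded -1), so their main
        effects fold into the baseline and interactions with a dropped
        factor fold into the surviving parent's main effect.
        """
        kept_set = set(kept)
        beta0 = self.beta0
        beta_main = {n: b for n, b in self.beta_main.items() if n in kept_set}
        beta_int: dict[tuple[str, str], float] = {}
        for n, b in self.beta_main.items():
            if n not in kept_set:
                beta0 -= b
        for (a, b_), bi in self.beta_int.items():
            in_a, in_b = a in kept_set, b_ in kept_set
            if in_a and in_b:
                beta_int[(a, b_)] = bi
            elif in_a:
                beta_main[a] = beta_main.get(a, 0.0) - bi
            elif in_b:
                beta_main[b_] = beta_main.get(b_, 0.0) - bi
            else:
                beta0 += bi
        return GroundTruth(
            factor_names=list(kept), beta0=beta0, beta_main=beta_main,
            beta_int=beta_int, block_effects=dict(self.block_effects),
            sigma=self.sigma, od_max=self.od_max, transform=self.transform,
            seed=self.seed,
        )


def default_truth(space: FactorSpace, seed: int = 0) -> GroundTruth:
    """Default ground-truth preset for a factor space.

    One strong positive bionutrient-like factor, two strong negative
    chelator-like factors, two moderate positives, two true two-factor
    interactions, remaining factors null; block effects are drawn once
    from Normal(0, 0.05^2).  Effect sizes are set so that paper-scale
    replication (3 biological x 2 technical) cleanly separates non-null
    factors in PLS screening.
    """
    names = [f.name for f in space.free]
    rng = np.random.default_rng(seed)

    def pick(preferred: str, fallback_idx: int) -> str:
        return preferred if preferred in names else names[fallback_idx]

    pos_strong = pick("yeast_extract", 0)
    neg1 = pick("citric_acid", 1)
    neg2 = pick("edta", 2)
    remaining = [n for n in names if n not in (pos_strong, neg1, neg2)]
    mod1, mod2 = remaining[0], remaining[1]

    beta_main = {
        pos_strong: 0.45,
        neg1: -0.35,
        neg2: -0.30,
        mod1: 0.22,
        mod2: 0.18,
    }
    # a synergy between the two moderate positives and an antagonism
    # between the stronger chelator and a positive factor; interaction
    # sizes account for the saturating ceiling's attenuation of products
    beta_int = {(mod1, mod2): 0.25, (neg1, mod1): -0.22}
    # extra mild positives so a screening iteration retains a workable set
    if len(remaining) > 8:
        for n, b in zip(remaining[2:6], (0.15, 0.13, 0.12, 0.10)):
            beta_main[n] = b
    block_effects = {b: float(rng.normal(0.0, 0.05)) for b in range(1, 9)}
    return GroundTruth(
        factor_names=names, beta0=0.55, beta_main=beta_main,
        beta_int=beta_int, block_effects=block_effects,
        sigma=0.05, od_max=2.0, seed=seed,
    )


def simulate_response(
    design, truth: GroundTruth, n_bio: int = 3, n_tech: int = 2
) -> pd.DataFrame:
    """Simulate a Delta-OD600 response table for every run of a design.

    Columns: ``run_id, bio_rep, tech_rep, block, delta_od600``; one row per
    run x biological replicate x technical replicate, deterministic given
    ``truth.seed``.
    """
    names = design.factor_names
    if list(truth.factor_names) != list(names):
        raise ValueError(
            f"truth is dimensioned for factors {truth.factor_names}, "
            f"design has {names}"
        )
    rng = np.random.default_rng(truth.seed)
    base = truth.latent(design.runs)
    blocks = np.asarray(design.block)
    rows = []
    for i in range(design.n_runs):
        b_eff = truth.block_effects.get(int(blocks[i]), 0.0)
        for bio in range(1, n_bio + 1):
            for tech in range(1, n_tech + 1):
                eps = rng.normal(0.0, truth.sigma) if truth.sigma else 0.0
                u = base[i] + b_eff + eps
                rows.append((i + 1, bio, tech, int(blocks[i]), float(truth.emit(np.array([u]))[0])))
    return pd.DataFrame(
        rows, columns=["run_id", "bio_rep", "tech_rep", "block", "delta_od600"]
    )


@dataclass
class GrowthCurveParams:
    """Hill-shaped growth-curve parameters (times in hours)."""

    top: float
    t50: float
    hill: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.top, self.t50, self.hill) <= 0:
            raise ValueError("top, t50 and hill must all be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_growth_curve(
    params: GrowthCurveParams, times: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Delta-OD600 series along ``times`` (h) from a Hill-shaped curve.

    OD(t) = top * t^h / (t50^h + t^h) + Normal(0, noise_sd^2); the value at
    t = 0 is pure noise.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    with np.errstate(divide="ignore", invalid="ignore"):
        y = params.top * t ** params.hill / (params.t50 ** params.hill + t ** params.hill)
    y = np.nan_to_num(y, nan=0.0)
    if params.noise_sd:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, params.noise_sd, size=t.shape)
    return y
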