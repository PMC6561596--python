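"""End-to-end pipeline: screening design -> PLS factor screen -> custom
design -> PLS + exhaustive AICc subset regression -> ANN ensemble ->
in-silico formulation optimization.

The stages run in the order of the original media-development study, on
synthetic growth data with known ground truth.  A single top-level seed
fans out to per-stage seeds through a fixed derivation so each stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import designs, ensemble, io, model_search, pls
from .factors import FactorSpace
from .synthetic import GroundTruth, default_truth, simulate_response

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "stage_seeds"]

logger = logging.getLogger(__name__)

_STAGES = (
    "screen_design", "screen_sim", "screen_pls", "custom_design",
    "custom_sim", "custom_pls", "search", "ensemble", "optimize",
)


def stage_seeds(seed: int) -> dict[str, int]:
    """Fixed fan-out of one top-level seed into per-stage seeds (< 2^31)."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2 ** 31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class RunConfig:
    """Pipeline settings; every stage defaults to the study's values.

    Screening: 8 blocks x 8 runs over the 21-factor space; second
    iteration: 56 runs in 7 blocks.  PLS: K = 7 folds, up to 15 latent
    variables, VIP threshold 0.8, van der Voet alpha 0.10.  Subset search:
    max 6 terms, delta_i < 2.0.  Ensemble: 3 sigmoid hidden nodes, 19-row
    holdback.  Optimizer: 5,000 uniform candidates with the bionutrient
    pinned to zero.
    """

    seed: int = 0
    n_bio: int = 3
    n_tech: int = 2
    screen_blocks: int = 8
    screen_runs_per_block: int = 8
    custom_runs: int = 56
    custom_blocks: int = 7
    kfold: int = 7
    max_lv: int = 15
    vip_threshold: float = 0.8
    vdv_alpha: float = 0.10
    max_terms: int = 6
    heredity: str = "none"
    delta_threshold: float = 2.0
    n_hidden: int = 3
    holdback_n: int = 19
    n_formulations: int = 5000
    pinned: dict = field(default_factory=dict)  # default: bionutrients -> 0
    design_starts: int = 20
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_seeds"] = stage_seeds(self.seed)
        return d


@dataclass
class PipelineResult:
    config: RunConfig
    screen_design: designs.ScreeningDesign
    screen_truth: GroundTruth
    screen_vip: pd.DataFrame
    retained: list[str]
    custom_design: designs.CustomDesign
    custom_truth: GroundTruth
    custom_cv: pls.CVReport
    custom_pls: pls.NIPALSPLSRegression
    custom_vip: pd.DataFrame
    search_result: model_search.SearchResult
    ensemble_model: ensemble.EnsembleANNRegressor
    optimization: ensemble.OptimizationResult
    recipe: pd.DataFrame


def _screen_and_retain(cfg: RunConfig, seeds, space, truth):
    """Iteration 1: blocked screening fraction, PLS on mains + blocks,
    retention of factors that help growth."""
    design = designs.make_screening_design(
        space, cfg.screen_blocks, cfg.screen_runs_per_block,
        seed=seeds["screen_design"],
    )
    resp = simulate_response(design, truth, n_bio=cfg.n_bio, n_tech=cfg.n_tech)
    X, y, groups = pls.build_predictor_matrix(
        design, resp, include_interactions="none", include_blocks=True,
    )
    cv = pls.cross_validate(
        X, y, a_max=min(cfg.max_lv, X.shape[1]), K=cfg.kfold,
        seed=seeds["screen_pls"], groups=groups, alpha=cfg.vdv_alpha,
    )
    fit = pls.NIPALSPLSRegression(n_components=cv.a_selected).fit(X, y)
    vip = pls.vip_report(fit, threshold=cfg.vip_threshold)

    # Retention rule: keep factors whose coefficient is positive and VIP
    # clears the threshold; significant negatives (chelator-like) and
    # non-significant factors are dropped.  Blocks never carry forward.
    factor_rows = vip[vip["predictor"].isin(design.factor_names)]
    retained = factor_rows[
        (factor_rows["significant"]) & (factor_rows["coefficient"] > 0)
    ]["predictor"].tolist()
    dropped = [n for n in design.factor_names if n not in retained]
    logger.info("screening retained %d/%d factors; dropped %s",
                len(retained), len(design.factor_names), dropped)
    if len(retained) < 2:
        raise RuntimeError(
            "stage screen_pls: fewer than 2 factors retained; "
            "screening signal too weak to continue"
        )
    return design, resp, cv, fit, vip, retained


def run_pipeline(config: RunConfig, space: FactorSpace | None = None,
                 truth: GroundTruth | None = None) -> PipelineResult:
    """Run every stage on synthetic data and (optionally) write artifacts.

    ``space`` defaults to the 21-ingredient screening space and ``truth``
    to the default ground-truth preset on it.
    """
    cfg = config
    seeds = stage_seeds(cfg.seed)
    if space is None:
        from .factors import default_screening_space
        space = default_screening_space()
    if truth is None:
        truth = default_truth(space, seed=seeds["screen_sim"])

    screen_design, screen_resp, screen_cv, screen_fit, screen_vip, retained = (
        _screen_and_retain(cfg, seeds, space, truth)
    )

    # Iteration 2: custom D-optimal design over the retained factors.
    custom_space = space.subset(retained)
    custom_truth = truth.restrict(retained)
    custom_truth.seed = seeds["custom_sim"]
    custom = designs.make_custom_design(
        custom_space, cfg.custom_runs, cfg.custom_blocks,
        seed=seeds["custom_design"], n_starts=cfg.design_starts,
    )
    custom_resp = simulate_response(custom, custom_truth,
                                    n_bio=cfg.n_bio, n_tech=cfg.n_tech)

    X2, y2, groups2 = pls.build_predictor_matrix(
        custom, custom_resp, include_interactions="all", include_blocks=False,
    )
    a_cap = min(cfg.max_lv, np.linalg.matrix_rank(
        X2.to_numpy() - X2.to_numpy().mean(axis=0)))
    cv2 = pls.cross_validate(
        X2, y2, a_max=a_cap, K=cfg.kfold, seed=seeds["custom_pls"],
        groups=groups2, alpha=cfg.vdv_alpha,
    )
    fit2 = pls.NIPALSPLSRegression(n_components=cv2.a_selected).fit(X2, y2)
    vip2 = pls.vip_report(fit2, threshold=cfg.vip_threshold)

    # Subset regression on per-run means (n = custom_runs).
    run_means = custom_resp.groupby("run_id", sort=True)["delta_od600"].mean()
    Xr = X2.copy()
    Xr["run_id"] = groups2
    X_run = Xr.groupby("run_id", sort=True).first().loc[run_means.index]
    sr = model_search.search(
        X_run, run_means.to_numpy(), max_terms=cfg.max_terms,
        heredity=cfg.heredity, threshold=cfg.delta_threshold,
        mains=custom.factor_names,
    )
    logger.info("subset search: %d enumerated, %d selected (delta_i < %.1f)",
                sr.n_enumerated, len(sr.selected), cfg.delta_threshold)

    feats = ensemble.build_model_features(sr.selected, X_run)
    ann = ensemble.EnsembleANNRegressor(
        n_hidden=cfg.n_hidden, holdback_n=cfg.holdback_n,
        random_state=seeds["ensemble"],
    ).fit(feats, run_means.to_numpy())

    pinned = dict(cfg.pinned)
    if not pinned:
        pinned = {f.name: 0.0 for f in custom_space if f.role == "bionutrient"}
    candidates = ensemble.sample_formulations(
        custom_space, cfg.n_formulations, pinned=pinned, seed=seeds["optimize"],
    )
    opt = ensemble.predict_and_rank(
        candidates, ann, sr.selected, fit2, custom_space, seed=seeds["optimize"],
    )
    recipe = ensemble.export_recipe(opt.best, custom_space)

    result = PipelineResult(
        config=cfg, screen_design=screen_design, screen_truth=truth,
        screen_vip=screen_vip, retained=retained, custom_design=custom,
        custom_truth=custom_truth, custom_cv=cv2, custom_pls=fit2,
        custom_vip=vip2, search_result=sr, ensemble_model=ann,
        optimization=opt, recipe=recipe,
    )
    if cfg.out_dir:
        _write_artifacts(result, custom_resp, screen_resp)
    return result


def _write_artifacts(res: PipelineResult, custom_resp, screen_resp) -> None:
    out = Path(res.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_design(res.screen_design, out / "screen_design.csv")
    designs.decode_design(res.screen_design, FactorSpace(res.screen_design.factors)) \
        .to_csv(out / "screen_design_decoded.csv", index=False)
    io.write_responses(screen_resp, out / "screen_responses.csv")
    res.screen_vip.to_csv(out / "screen_vip.csv", index=False)
    io.write_design(res.custom_design, out / "custom_design.csv")
    io.write_responses(custom_resp, out / "custom_responses.csv")
    res.custom_cv.table.to_csv(out / "custom_cv.csv", index=False)
    res.custom_vip.to_csv(out / "custom_vip.csv", index=False)
    io.write_models(res.search_result.selected, out / "selected_models.json")
    io.write_json(res.ensemble_model.to_dict(), out / "ensemble.json")
    io.write_recipe(res.recipe, out / "recipe.csv")
    io.write_json(res.config.resolved(), out / "config_resolved.json")
    logger.info("artifacts written to %s", out)
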