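"""CSV/JSON readers and writers for the pipeline's artifacts.

All tables are plain UTF-8 CSV with strict header validation; model and
ensemble objects round-trip through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import PLATE_COLS, PLATE_ROWS, PlateLayout
from .factors import Factor, FactorSpace
from .model_search import CandidateModel

__all__ = [
    "read_factors",
    "write_factors",
    "read_design",
    "write_design",
    "read_responses",
    "write_responses",
    "write_plate",
    "read_plate",
    "write_recipe",
    "write_models",
    "read_models",
]

FACTOR_COLUMNS = ["name", "low", "high", "units", "role", "pinned"]
RESPONSE_COLUMNS = ["run_id", "bio_rep", "tech_rep", "block", "delta_od600"]


def _require(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def read_factors(path) -> FactorSpace:
    df = pd.read_csv(path)
    _require(df, ["name", "low", "high", "units"], "factor table")
    factors = []
    for _, row in df.iterrows():
        pinned = row.get("pinned")
        if pinned is not None and (pd.isna(pinned) or pinned == ""):
            pinned = None
        factors.append(Factor(
            name=str(row["name"]), low=float(row["low"]), high=float(row["high"]),
            units=str(row["units"]), role=str(row.get("role", "chemical")),
            pinned=None if pinned is None else float(pinned),
        ))
    return FactorSpace(factors)


def write_factors(space: FactorSpace, path) -> None:
    pd.DataFrame([{
        "name": f.name, "low": f.low, "high": f.high, "units": f.units,
        "role": f.role, "pinned": f.pinned,
    } for f in space]).to_csv(path, index=False)


def write_design(design, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["run_id", "block"], "design table")
    if df.shape[1] < 3:
        raise ValueError("design table has no factor columns")
    return df


class FrameDesign:
    """Adapter giving a design DataFrame the design-object interface."""

    def __init__(self, df: pd.DataFrame, factors: list[Factor] | None = None):
        self.df = df.reset_index(drop=True)
        names = [c for c in df.columns if c not in ("run_id", "block")]
        if factors is None:
            factors = [Factor(n, 1.0, 0.0) for n in names]
        self.factors = [f for f in factors if f.name in names]

    @property
    def factor_names(self):
        return [f.name for f in self.factors]

    @property
    def runs(self):
        return self.df[self.factor_names].to_numpy(dtype=float)

    @property
    def block(self):
        return self.df["block"].to_numpy()

    @property
    def n_runs(self):
        return len(self.df)

    def to_frame(self) -> pd.DataFrame:
        return self.df.copy()


def read_responses(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, RESPONSE_COLUMNS, "response table")
    return df


def write_responses(responses: pd.DataFrame, path) -> None:
    _require(responses, RESPONSE_COLUMNS, "response table")
    responses.to_csv(path, index=False)


def write_plate(layout: PlateLayout, path) -> None:
    layout.to_frame().to_csv(path, index_label="row")


def read_plate(path) -> PlateLayout:
    df = pd.read_csv(path, index_col="row")
    if list(df.index) != list(PLATE_ROWS) or [int(c) for c in df.columns] != PLATE_COLS:
        raise ValueError("plate map must have rows A-H and columns 1-12")
    return PlateLayout(grid=df.to_numpy(dtype=object))


def write_recipe(recipe: pd.DataFrame, path) -> None:
    _require(recipe, ["ingredient", "concentration", "units"], "recipe table")
    recipe.to_csv(path, index=False)


def write_models(models: list[CandidateModel], path) -> None:
    payload = [{
        "terms": list(m.terms), "k": m.k, "loglik": m.loglik,
        "aicc": m.aicc, "delta_i": m.delta_i, "coef": m.coef,
    } for m in models]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_models(path) -> list[CandidateModel]:
    payload = json.loads(Path(path).read_text())
    out = []
    for rec in payload:
        out.append(CandidateModel(
            terms=tuple(rec["terms"]), k=int(rec["k"]),
            loglik=float(rec["loglik"]), aicc=float(rec["aicc"]),
            delta_i=float(rec["delta_i"]), coef=rec["coef"],
        ))
    return out


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_np_default))


def _np_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
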