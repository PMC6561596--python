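"""Experimental designs: blocked two-level screening fractions, D-optimal
custom designs and Latin-rectangle microplate layouts.

Screening designs are regular 2^(k-p) fractions built from the log2(n)
basis columns of a full factorial: every factor column is the elementwise
product of a subset of basis columns.  Factors are assigned to odd-weight
subsets first, which guarantees resolution >= IV (no main effect aliased
with any two-factor interaction) whenever k <= n/2, and block-defining
contrasts are taken from the highest-order even-weight subsets so that
blocks are confounded only with high-order interactions.

Custom designs are found by coordinate exchange maximizing the determinant
of the information matrix for an intercept + main effects + all two-factor
interactions + block-contrast model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factors import Factor, FactorSpace

__all__ = [
    "ScreeningDesign",
    "CustomDesign",
    "PlateLayout",
    "make_screening_design",
    "alias_structure",
    "make_custom_design",
    "decode_design",
    "encode_design",
    "make_plate_layout",
    "validate_plate_layout",
    "custom_model_matrix",
]

logger = logging.getLogger(__name__)

# Plate geometry: rows A-H x columns 1-12; interior = B-G x 2-11.
PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = list(range(1, 13))
WATER = "H2O"
EMPTY = "EMPTY"


# ---------------------------------------------------------------------------
# regular two-level fractions
# ---------------------------------------------------------------------------

@dataclass
class ScreeningDesign:
    """A blocked regular two-level fraction.

    ``runs`` holds coded levels in {-1, +1}, one row per treatment, in the
    randomized within-block run order.  ``generators`` maps each factor
    name to the tuple of basis-column indices whose product generates its
    column, so the alias structure is fully reproducible.
    """

    factors: list[Factor]
    runs: np.ndarray
    block: np.ndarray
    generators: dict[str, tuple[int, ...]]
    block_generators: list[tuple[int, ...]]
    seed: int

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.runs.astype(int), columns=self.factor_names)
        df.insert(0, "block", self.block)
        df.insert(0, "run_id", np.arange(1, self.n_runs + 1))
        return df


@dataclass
class CustomDesign:
    """A D-optimal two-level design for mains + all 2-factor interactions."""

    factors: list[Factor]
    runs: np.ndarray
    block: np.ndarray
    model_terms: list[str]
    d_criterion: float  # det(X'X) at convergence, log scale reported too
    log_det: float
    seed: int

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.runs.astype(int), columns=self.factor_names)
        df.insert(0, "block", self.block)
        df.insert(0, "run_id", np.arange(1, self.n_runs + 1))
        return df


def _basis_matrix(m: int) -> np.ndarray:
    """Full 2^m factorial in standard order, columns = basis contrasts."""
    n = 2 ** m
    cols = [np.tile(np.repeat([-1.0, 1.0], 2 ** j), n // 2 ** (j + 1)) for j in range(m)]
    return np.column_stack(cols)


def _subsets_by_weight(m: int, parity: int):
    """Subsets of range(m) of the given parity (1=odd, 0=even, nonempty),
    ordered by increasing weight then lexicographically."""
    for w in range(1, m + 1):
        if w % 2 != parity:
            continue
        yield from itertools.combinations(range(m), w)


def _column_for(subset: tuple[int, ...], basis: np.ndarray) -> np.ndarray:
    return basis[:, list(subset)].prod(axis=1)


def make_screening_design(
    space: FactorSpace,
    n_blocks: int,
    runs_per_block: int,
    seed: int = 0,
) -> ScreeningDesign:
    """Generate a blocked regular two-level screening fraction.

    The total run count ``n_blocks * runs_per_block`` must be a power of
    two, as must ``n_blocks``.  Factors are mapped to odd-weight products
    of basis columns (resolution >= IV while factor count <= n/2); block
    contrasts use the highest-order unused even-weight products.

    Raises
    ------
    ValueError
        If the run budget is not a power of two or cannot accommodate the
        requested number of factors.
    """
    factors = space.free
    k = len(factors)
    n = n_blocks * runs_per_block
    if n < 2 or n & (n - 1):
        raise ValueError(f"total run count must be a power of two, got {n}")
    if n_blocks & (n_blocks - 1):
        raise ValueError(f"block count must be a power of two, got {n_blocks}")
    if k > n - 1:
        raise ValueError(
            f"capacity error: {k} factors cannot be estimated in {n} runs; "
            f"need at least {2 ** int(np.ceil(np.log2(k + 1)))} runs"
        )
    m = int(np.log2(n))
    basis = _basis_matrix(m)

    odd = list(_subsets_by_weight(m, 1))
    even = list(_subsets_by_weight(m, 0))
    if k <= len(odd):
        assignment = odd[:k]
    else:
        # more factors than odd-weight columns: resolution drops to III
        assignment = odd + even[: k - len(odd)]
        logger.warning(
            "factor count %d exceeds %d odd-weight columns; design is resolution III",
            k, len(odd),
        )

    used = set(assignment)
    n_block_gen = int(np.log2(n_blocks))
    block_gens: list[tuple[int, ...]] = []
    if n_block_gen:
        # prefer highest-order even words; keep the chosen set independent
        chosen_span = {frozenset()}
        for cand in sorted(even, key=lambda s: (-len(s), s)):
            if cand in used or frozenset(cand) in chosen_span:
                continue
            block_gens.append(cand)
            chosen_span |= {frozenset(cand) ^ s for s in chosen_span}
            if len(block_gens) == n_block_gen:
                break
        if len(block_gens) < n_block_gen:
            raise ValueError(
                f"capacity error: cannot find {n_block_gen} independent block "
                f"contrasts unaliased with main effects in {n} runs"
            )

    runs = np.column_stack([_column_for(s, basis) for s in assignment])
    if block_gens:
        signs = np.column_stack([_column_for(s, basis) > 0 for s in block_gens])
        block_idx = signs @ (2 ** np.arange(len(block_gens)))
    else:
        block_idx = np.zeros(n, dtype=int)
    block = block_idx.astype(int) + 1

    # randomize run order within each block
    rng = np.random.default_rng(seed)
    order = np.concatenate(
        [rng.permutation(np.flatnonzero(block == b)) for b in np.unique(block)]
    )
    runs, block = runs[order], block[order]

    generators = {f.name: s for f, s in zip(factors, assignment)}
    return ScreeningDesign(
        factors=list(factors), runs=runs, block=block,
        generators=generators, block_generators=block_gens, seed=seed,
    )


def alias_structure(design: ScreeningDesign, order: int = 2) -> dict[str, list[str]]:
    """Alias table for all effects up to the given interaction order.

    Effects whose generating subsets have equal symmetric difference share
    a contrast column and are mutually aliased.  Works only for regular
    fractions (which :func:`make_screening_design` always produces).
    """
    names = design.factor_names
    gens = design.generators
    signature: dict[frozenset, list[str]] = {}
    for r in range(1, order + 1):
        for combo in itertools.combinations(names, r):
            sig = frozenset()
            for nm in combo:
                sig = sig ^ frozenset(gens[nm])
            label = "*".join(combo)
            signature.setdefault(sig, []).append(label)
    table: dict[str, list[str]] = {}
    for sig, labels in signature.items():
        for lab in labels:
            aliases = [x for x in labels if x != lab]
            if sig == frozenset():
                aliases = aliases + ["(intercept)"]
            table[lab] = aliases
    return table


def estimable_interactions(design: ScreeningDesign) -> list[str]:
    """Two-factor interactions whose columns are unaliased with any main
    effect (the interactions a screening fit can include)."""
    table = alias_structure(design, order=2)
    mains = set(design.factor_names)
    out = []
    for lab, aliases in table.items():
        if "*" not in lab:
            continue
        if not (set(aliases) & mains) and "(intercept)" not in aliases:
            out.append(lab)
    return out


# ---------------------------------------------------------------------------
# D-optimal custom design by coordinate exchange
# ---------------------------------------------------------------------------

def _block_labels(n_runs: int, n_blocks: int) -> np.ndarray:
    sizes = np.full(n_blocks, n_runs // n_blocks)
    sizes[: n_runs % n_blocks] += 1
    return np.repeat(np.arange(1, n_blocks + 1), sizes)


def custom_model_matrix(
    runs: np.ndarray, block: np.ndarray, names: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Model matrix [1 | mains | all 2FIs | block contrasts] with sum-to-zero
    block coding (last block is the reference)."""
    n, k = runs.shape
    if names is None:
        names = [f"x{i + 1}" for i in range(k)]
    cols = [np.ones(n)]
    labels = ["(intercept)"]
    cols.extend(runs.T)
    labels.extend(names)
    for i, j in itertools.combinations(range(k), 2):
        cols.append(runs[:, i] * runs[:, j])
        labels.append(f"{names[i]}*{names[j]}")
    blocks = np.unique(block)
    for b in blocks[:-1]:
        c = np.where(block == b, 1.0, 0.0) - np.where(block == blocks[-1], 1.0, 0.0)
        cols.append(c)
        labels.append(f"block_{b}")
    return np.column_stack(cols), labels


def _interaction_pairs(k: int) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(k), 2))


def _model_row(x: np.ndarray, pairs, n_block_cols: int, block_row: np.ndarray) -> np.ndarray:
    inter = np.array([x[i] * x[j] for i, j in pairs]) if pairs else np.empty(0)
    return np.concatenate([[1.0], x, inter, block_row])


def make_custom_design(
    space: FactorSpace,
    n_runs: int,
    n_blocks: int,
    seed: int = 0,
    n_starts: int = 20,
    max_passes: int = 100,
) -> CustomDesign:
    """D-optimal two-level design for mains + all 2FIs + block contrasts.

    Coordinate exchange over coded levels {-1, +1}: every (run, factor)
    cell is flipped in turn and the flip kept when it increases
    log det(X'X); a start terminates when a full pass makes no swap, and
    the best of ``n_starts`` seeded random starts is returned.
    """
    factors = space.free
    k = len(factors)
    p_model = 1 + k + k * (k - 1) // 2 + (n_blocks - 1)
    if n_runs < p_model:
        raise ValueError(
            f"capacity error: {n_runs} runs cannot support "
            f"{p_model} model parameters; minimum feasible n_runs = {p_model}"
        )
    block = _block_labels(n_runs, n_blocks)
    pairs = _interaction_pairs(k)
    blocks = np.unique(block)
    block_rows = np.zeros((n_runs, n_blocks - 1))
    for j, b in enumerate(blocks[:-1]):
        block_rows[:, j] = np.where(block == b, 1.0, 0.0) - np.where(
            block == blocks[-1], 1.0, 0.0
        )

    rng = np.random.default_rng(seed)
    best_logdet = -np.inf
    best_runs = None
    for _ in range(n_starts):
        runs = rng.choice([-1.0, 1.0], size=(n_runs, k))
        M = np.array([
            _model_row(runs[i], pairs, n_blocks - 1, block_rows[i])
            for i in range(n_runs)
        ])
        G = M.T @ M
        sign, logdet = np.linalg.slogdet(G)
        cur = logdet if sign > 0 else -np.inf
        for _ in range(max_passes):
            improved = False
            for i in range(n_runs):
                for j in range(k):
                    old_row = M[i].copy()
                    runs[i, j] = -runs[i, j]
                    new_row = _model_row(runs[i], pairs, n_blocks - 1, block_rows[i])
                    G_try = G - np.outer(old_row, old_row) + np.outer(new_row, new_row)
                    sign, logdet = np.linalg.slogdet(G_try)
                    if sign > 0 and logdet > cur + 1e-10:
                        M[i] = new_row
                        G = G_try
                        cur = logdet
                        improved = True
                    else:
                        runs[i, j] = -runs[i, j]
            if not improved:
                break
            G = M.T @ M  # refresh against accumulated round-off
        if cur > best_logdet:
            best_logdet = cur
            best_runs = runs.copy()

    if best_runs is None or not np.isfinite(best_logdet):
        raise ValueError("coordinate exchange failed to find a non-singular design")

    names = [f.name for f in factors]
    _, labels = custom_model_matrix(best_runs, block, names)
    return CustomDesign(
        factors=list(factors), runs=best_runs, block=block,
        model_terms=labels, d_criterion=float(np.exp(best_logdet)),
        log_det=float(best_logdet), seed=seed,
    )


# ---------------------------------------------------------------------------
# coded <-> concentration
# ---------------------------------------------------------------------------

GLUCOSE_G_PER_L = 10.0


def decode_design(design, space: FactorSpace, add_glucose: bool = True) -> pd.DataFrame:
    """Concentration table for every run: coded -1 -> low (absent by
    default), +1 -> high; pinned factors at their fixed value; glucose
    appended at 10 g/L to every recipe unless already a factor."""
    df = design.to_frame()
    out = pd.DataFrame({"run_id": df["run_id"], "block": df["block"]})
    for f in design.factors:
        out[f.name] = [f.decode(c) for c in df[f.name]]
    for f in space:
        if f.pinned is not None and f.name not in out.columns:
            out[f.name] = f.pinned
    if add_glucose and "glucose" not in out.columns:
        out["glucose"] = GLUCOSE_G_PER_L
    return out


def encode_design(decoded: pd.DataFrame, design) -> np.ndarray:
    """Inverse of :func:`decode_design` for the design's free factors."""
    return np.column_stack(
        [[f.encode(v) for v in decoded[f.name]] for f in design.factors]
    )


# ---------------------------------------------------------------------------
# Latin-rectangle plate layout
# ---------------------------------------------------------------------------

@dataclass
class PlateLayout:
    """96-well plate assignment grid (8 rows x 12 columns).

    Cell values: ``T<id>.<rep>`` for treatment replicates, ``POS``/``NEG``
    controls (with ``.rep`` suffix when replicated), ``H2O`` for periphery
    water wells, ``EMPTY`` for unused interior wells.
    """

    grid: np.ndarray  # dtype object, shape (8, 12)
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.grid, index=list(PLATE_ROWS), columns=PLATE_COLS)


def _interior_wells():
    return [(r, c) for r in range(1, 7) for c in range(1, 11)]


def _item_key(value: str) -> str:
    """Treatment identity ignoring the technical-replicate suffix."""
    return value.split(".")[0]


def make_plate_layout(
    treatments: list,
    tech_reps: int = 2,
    controls: dict[str, int] | None = None,
    seed: int = 0,
    max_attempts: int = 500,
) -> PlateLayout:
    """Randomized Latin-rectangle layout for one microplate.

    All 36 periphery wells hold water (evaporation guard); treatment and
    control replicates are placed in the 60 interior wells so that no
    replicate of the same item occupies an interior row or column twice.
    """
    if controls is None:
        controls = {"POS": 2, "NEG": 2}
    items: list[str] = []
    for t in treatments:
        for r in range(1, tech_reps + 1):
            items.append(f"T{t}.{r}")
    for name, count in controls.items():
        if count == 1:
            items.append(name)
        else:
            items.extend(f"{name}.{r}" for r in range(1, count + 1))
    interior = _interior_wells()
    if len(items) > len(interior):
        raise ValueError(
            f"capacity error: {len(items)} wells requested but only "
            f"{len(interior)} interior wells available"
        )
    max_per_item = max(
        [tech_reps] + [c for c in controls.values()]
    )
    if max_per_item > 6:
        raise ValueError(
            "capacity error: more than 6 replicates of one item cannot "
            "satisfy the Latin-rectangle row constraint (6 interior rows)"
        )

    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        grid = np.full((8, 12), "", dtype=object)
        grid[0, :] = WATER
        grid[7, :] = WATER
        grid[:, 0] = WATER
        grid[:, 11] = WATER
        wells = interior.copy()
        rng.shuffle(wells)
        order = list(items)
        rng.shuffle(order)
        row_used: dict[int, set] = {r: set() for r in range(1, 7)}
        col_used: dict[int, set] = {c: set() for c in range(1, 11)}
        ok = True
        for item in order:
            key = _item_key(item)
            placed = False
            for w in wells:
                r, c = w
                if key not in row_used[r] and key not in col_used[c]:
                    grid[r, c] = item
                    row_used[r].add(key)
                    col_used[c].add(key)
                    wells.remove(w)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            for r, c in wells:
                grid[r, c] = EMPTY
            return PlateLayout(grid=grid, seed=seed)
    raise ValueError(
        "could not find a Latin-rectangle placement; relax replicate counts"
    )


def validate_plate_layout(layout: PlateLayout) -> list[str]:
    """Return the list of violated constraints (empty list = valid)."""
    g = layout.grid
    violations: list[str] = []
    if g.shape != (8, 12):
        return [f"grid shape {g.shape} != (8, 12)"]
    for r in range(8):
        for c in range(12):
            on_edge = r in (0, 7) or c in (0, 11)
            if on_edge and g[r, c] != WATER:
                violations.append(
                    f"periphery well {PLATE_ROWS[r]}{c + 1} is {g[r, c]!r}, not water"
                )
    for r in range(1, 7):
        keys = [_item_key(v) for v in g[r, 1:11] if v not in ("", WATER, EMPTY)]
        for key in sorted({k for k in keys if keys.count(k) > 1}):
            violations.append(f"item {key} appears {keys.count(key)}x in row {PLATE_ROWS[r]}")
    for c in range(1, 11):
        keys = [_item_key(v) for v in g[1:7, c] if v not in ("", WATER, EMPTY)]
        for key in sorted({k for k in keys if keys.count(k) > 1}):
            violations.append(f"item {key} appears {keys.count(key)}x in column {c + 1}")
    return violations
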