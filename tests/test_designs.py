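"""Screening fractions, alias structure and D-optimal custom designs."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mediadoe as md
from mediadoe.designs import (
    custom_model_matrix,
    _basis_matrix,
    _block_labels,
)
from mediadoe.factors import Factor, FactorSpace


def _space(k, prefix="f"):
    return FactorSpace([Factor(f"{prefix}{i + 1}", 1.0) for i in range(k)])


class TestScreeningDesign:
    def test_paper_scale_shape(self, screening_design):
        d = screening_design
        assert d.runs.shape == (64, 21)
        assert len(np.unique(d.block)) == 8
        assert all((d.block == b).sum() == 8 for b in np.unique(d.block))

    def test_column_balance(self, screening_design):
        assert np.all(screening_design.runs.sum(axis=0) == 0)

    def test_full_factorial_small_case(self):
        d = md.make_screening_design(_space(3), 1, 8, seed=0)
        rows = {tuple(r) for r in d.runs.astype(int)}
        assert rows == set(itertools.product([-1, 1], repeat=3))

    def test_regular_fraction_property(self, screening_design):
        # the first 6 factors carry the basis columns (singleton
        # generators); every other column must equal the row-wise product
        # of its generator's basis columns, across all 64 runs
        d = screening_design
        for i in range(6):
            assert d.generators[d.factor_names[i]] == (i,)
        for name, subset in d.generators.items():
            col = d.runs[:, d.factor_names.index(name)]
            prod = d.runs[:, list(subset)].prod(axis=1)
            assert np.array_equal(col, prod)

    def test_no_main_effect_aliasing(self, screening_design):
        # brute-force column products: no main column equals +/- another
        M = screening_design.runs
        for i, j in itertools.combinations(range(M.shape[1]), 2):
            assert np.abs(M[:, i] @ M[:, j]) < M.shape[0]

    def test_capacity_errors(self):
        with pytest.raises(ValueError, match="power of two"):
            md.make_screening_design(_space(3), 1, 6, seed=0)
        with pytest.raises(ValueError, match="capacity"):
            md.make_screening_design(_space(9), 1, 8, seed=0)

    def test_run_order_randomized_but_blocks_contiguous(self, space21):
        d1 = md.make_screening_design(space21, 8, 8, seed=1)
        d2 = md.make_screening_design(space21, 8, 8, seed=2)
        assert not np.array_equal(d1.runs, d2.runs)
        # same fraction regardless of seed: identical row multisets
        assert sorted(map(tuple, d1.runs)) == sorted(map(tuple, d2.runs))


class TestAliasStructure:
    def test_full_factorial_no_aliases(self):
        d = md.make_screening_design(_space(3), 1, 8, seed=0)
        table = md.alias_structure(d, order=2)
        assert all(v == [] for v in table.values())

    def test_half_fraction_c_equals_ab(self):
        # hand-built 2^(3-1) with C = A*B
        d = md.make_screening_design(_space(3), 1, 4, seed=0)
        assert set(d.generators["f3"]) == {0, 1}
        table = md.alias_structure(d, order=2)
        assert table["f3"] == ["f1*f2"]
        assert table["f1*f2"] == ["f3"]

    def test_paper_scale_interactions_clear_of_mains(self, screening_design):
        # every estimable interaction has an alias set disjoint from mains
        from mediadoe.designs import estimable_interactions

        table = md.alias_structure(screening_design, order=2)
        mains = set(screening_design.factor_names)
        est = estimable_interactions(screening_design)
        assert len(est) > 0
        for lab in est:
            assert not set(table[lab]) & mains


class TestCustomDesign:
    def test_paper_scale_rank(self, custom_design):
        d = custom_design
        assert d.runs.shape == (56, 9)
        assert len(np.unique(d.block)) == 7
        M, labels = custom_model_matrix(d.runs, d.block, d.factor_names)
        assert M.shape[1] == 52  # 1 + 9 + 36 + 6
        assert np.linalg.matrix_rank(M) == 52

    def test_two_point_design_det_four(self):
        d = md.make_custom_design(_space(1), 2, 1, seed=0, n_starts=3)
        assert set(d.runs.ravel().astype(int)) == {-1, 1}
        assert d.d_criterion == pytest.approx(4.0)

    def test_small_case_matches_brute_force(self):
        # 2 factors + interaction, 4 runs: enumerate all 3^8 designs over
        # levels {-1,0,+1} and compare determinants
        space = _space(2)
        best = -np.inf
        for flat in itertools.product([-1.0, 0.0, 1.0], repeat=8):
            runs = np.array(flat).reshape(4, 2)
            M = np.column_stack([np.ones(4), runs, runs[:, 0] * runs[:, 1]])
            best = max(best, np.linalg.det(M.T @ M))
        d = md.make_custom_design(space, 4, 1, seed=0, n_starts=5)
        assert d.d_criterion == pytest.approx(best, rel=1e-9)
        # the optimum is the full 2x2 factorial
        assert sorted(map(tuple, d.runs.astype(int))) == sorted(
            itertools.product([-1, 1], repeat=2)
        )

    def test_beats_random_designs(self, space9, rng):
        d = md.make_custom_design(space9, 56, 7, seed=0, n_starts=3)
        block = _block_labels(56, 7)
        for _ in range(100):
            runs = rng.choice([-1.0, 1.0], size=(56, 9))
            M, _ = custom_model_matrix(runs, block)
            sign, logdet = np.linalg.slogdet(M.T @ M)
            assert sign <= 0 or logdet <= d.log_det + 1e-9

    def test_capacity_error_names_minimum(self):
        with pytest.raises(ValueError, match="minimum feasible n_runs = 52"):
            md.make_custom_design(_space(9), 40, 7, seed=0)

    def test_deterministic_given_seed(self, space9):
        d1 = md.make_custom_design(space9, 56, 7, seed=5, n_starts=3)
        d2 = md.make_custom_design(space9, 56, 7, seed=5, n_starts=3)
        assert np.array_equal(d1.runs, d2.runs)


class TestDecode:
    def test_decode_levels(self, space9, custom_design):
        decoded = md.decode_design(custom_design, space9)
        ye = space9["yeast_extract"]
        coded = custom_design.to_frame()["yeast_extract"].to_numpy()
        expect = np.where(coded > 0, ye.high, ye.low)
        assert np.allclose(decoded["yeast_extract"], expect)
        assert ye.high == 1.0  # 1 g/L ceiling for the bionutrient
        assert np.all(decoded["glucose"] == 10.0)

    def test_round_trip(self, space9, custom_design):
        from mediadoe.designs import encode_design

        decoded = md.decode_design(custom_design, space9)
        assert np.allclose(encode_design(decoded, custom_design),
                           custom_design.runs)

    @settings(derandomize=True, max_examples=100)
    @given(low=st.floats(0.0, 10.0), span=st.floats(0.1, 100.0),
           coded=st.floats(-1.0, 1.0))
    def test_encode_decode_inverse_on_any_range(self, low, span, coded):
        f = Factor("x", low + span, low=low)
        assert f.encode(f.decode(coded)) == pytest.approx(coded, abs=1e-9)

    def test_pinned_factor_constant(self, custom_design):
        space = FactorSpace(
            [Factor("biotin", 1.0, units="uM", pinned=19.0)]
            + list(custom_design.factors)
        )
        decoded = md.decode_design(custom_design, space)
        assert np.all(decoded["biotin"] == 19.0)
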