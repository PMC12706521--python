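"""Randomization algorithms, null-test machinery and CANAPE rules."""

import itertools

import numpy as np
import pytest

import phylogrid as pg
from phylogrid.community import CommunityMatrix
from phylogrid.grid import GridSpec
from phylogrid.nullmodels import (
    CanapeResult,
    NullResult,
    canape_classify,
    convergence_diagnostic,
    null_test,
    randomize_curveball,
    randomize_r0,
    randomize_swap,
)

from conftest import random_community


def enumerate_fixed_marginal(rows, cols):
    """All binary matrices with the given row and column sums (brute force)."""
    n, m = len(rows), len(cols)
    out = []
    for bits in itertools.product([0, 1], repeat=n * m):
        a = np.array(bits).reshape(n, m)
        if np.array_equal(a.sum(1), rows) and np.array_equal(a.sum(0), cols):
            out.append(a)
    return out


class TestSwap:
    def test_two_by_two_flips(self):
        out = randomize_swap(np.array([[1, 0], [0, 1]]), n_itr=1, seed=0)
        assert np.array_equal(out, [[0, 1], [1, 0]])

    def test_marginals_preserved(self, rng):
        m = (rng.random((10, 15)) < 0.4).astype(np.uint8)
        out = randomize_swap(m, n_itr=5000, seed=1)
        assert np.array_equal(out.sum(0), m.sum(0))
        assert np.array_equal(out.sum(1), m.sum(1))

    def test_no_checkerboard_returns_input_with_warning(self):
        nested = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]], dtype=np.uint8)
        with pytest.warns(UserWarning, match="checkerboard"):
            out = randomize_swap(nested, n_itr=10, seed=0)
        assert np.array_equal(out, nested)

    def test_uniform_over_reachable_states(self):
        # permutation-matrix class: every state has the same number of
        # checkerboard units, so the successful-swap chain is symmetric and
        # its stationary distribution uniform over the k=6 states
        start = np.eye(3, dtype=np.uint8)
        states = enumerate_fixed_marginal(np.ones(3, int), np.ones(3, int))
        assert len(states) == 6
        counts = np.zeros(6, int)
        n_chains = 3000
        for seed in range(n_chains):
            # each successful swap is a transposition, so a fixed chain
            # length reaches only one permutation parity; alternate lengths
            out = randomize_swap(start, n_itr=20 + seed % 2, seed=seed)
            counts[[np.array_equal(out, s) for s in states].index(True)] += 1
        p = 1 / 6
        se = np.sqrt(p * (1 - p) / n_chains)
        assert np.all(np.abs(counts / n_chains - p) < 3 * se + 1e-12)


class TestCurveball:
    def test_identical_rows_trade_is_noop(self):
        m = np.array([[1, 0, 1], [1, 0, 1]], dtype=np.uint8)
        out = randomize_curveball(m, n_itr=100, seed=0)
        assert np.array_equal(out, m)

    def test_marginals_preserved_long_chain(self, rng):
        m = (rng.random((12, 20)) < 0.35).astype(np.uint8)
        out = randomize_curveball(m, n_itr=100_000, seed=2)
        assert np.array_equal(out.sum(0), m.sum(0))
        assert np.array_equal(out.sum(1), m.sum(1))

    def test_uniform_over_reachable_states(self):
        start = np.eye(3, dtype=np.uint8)
        states = enumerate_fixed_marginal(np.ones(3, int), np.ones(3, int))
        counts = np.zeros(len(states), int)
        n_chains = 3000
        for seed in range(n_chains):
            out = randomize_curveball(start, n_itr=25, seed=seed)
            counts[[np.array_equal(out, s) for s in states].index(True)] += 1
        p = 1 / len(states)
        se = np.sqrt(p * (1 - p) / n_chains)
        assert np.all(np.abs(counts / n_chains - p) < 3 * se + 1e-12)


class TestR0:
    def test_degenerate_rows_unchanged(self):
        m = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.uint8)
        out = randomize_r0(m, seed=0)
        assert np.array_equal(out, m)

    def test_row_sums_preserved_columns_free(self, rng):
        m = (rng.random((8, 12)) < 0.5).astype(np.uint8)
        out = randomize_r0(m, seed=3)
        assert np.array_equal(out.sum(1), m.sum(1))

    def test_per_column_occupancy_is_hypergeometric(self):
        # a row of sum k hits any given column with probability k/S
        m = np.zeros((1, 8), dtype=np.uint8)
        m[0, :3] = 1
        hits = np.zeros(8)
        n_draws = 10_000
        for seed in range(n_draws):
            hits += randomize_r0(m, seed=seed)[0]
        p = 3 / 8
        se = np.sqrt(p * (1 - p) / n_draws)
        assert np.all(np.abs(hits / n_draws - p) < 3 * se)


class TestConvergenceDiagnostic:
    def test_zero_iterations_identical(self, rng, small_grid):
        cm = random_community(rng, small_grid, [f"s{i}" for i in range(10)])
        df = convergence_diagnostic(cm, "curveball", (0, 50, 200), n_chains=3, seed=0)
        assert df["similarity"].iloc[0] == 1.0

    def test_similarity_decreases_and_deterministic(self, rng, small_grid):
        cm = random_community(rng, small_grid, [f"s{i}" for i in range(10)])
        df1 = convergence_diagnostic(cm, "curveball", (0, 20, 100, 500), n_chains=8, seed=5)
        df2 = convergence_diagnostic(cm, "curveball", (0, 20, 100, 500), n_chains=8, seed=5)
        assert df1.equals(df2)
        sims = df1["similarity"].to_numpy()
        assert sims[0] >= sims[1] >= sims[-1] - 0.05  # mixing with slack
        assert df1.attrs["recommended_n_itr"] in df1["n_itr"].to_numpy()


class TestNullTest:
    def test_degenerate_swap_null_gives_p_one(self, small_tree):
        # a perfectly nested matrix has no checkerboard: swap nulls equal
        # the observation and the upper-tail p is 1
        grid = GridSpec(3, 1, 1.0)
        m = np.zeros((3, 10), dtype=np.uint8)
        m[0, :] = 1
        m[1, :5] = 1
        m[2, :2] = 1
        cm = CommunityMatrix(grid, small_tree.tip_labels, m)
        nr = null_test(cm, small_tree, "swap", n_reps=1, n_itr=10, seed=0)
        assert np.allclose(nr.p_upper("pd"), 1.0)

    def test_deterministic_under_seed(self, rng, small_tree, small_grid):
        cm = random_community(rng, small_grid, small_tree.tip_labels)
        a = null_test(cm, small_tree, "curveball", n_reps=20, n_itr=50, seed=9)
        b = null_test(cm, small_tree, "curveball", n_reps=20, n_itr=50, seed=9)
        for k in a.obs:
            assert np.array_equal(a.n_ge[k], b.n_ge[k])

    def test_branch_length_scaling_leaves_categories_unchanged(self, rng, small_grid):
        tree = pg.simulate_phylogeny(12, 1.0, seed=21)
        cm = random_community(rng, small_grid, tree.tip_labels)
        scaled = tree.with_lengths(tree.lengths * 37.0)
        r1 = canape_classify(null_test(cm, tree, "curveball", 99, 200, seed=4))
        r2 = canape_classify(null_test(cm, scaled, "curveball", 99, 200, seed=4))
        assert np.array_equal(r1.category, r2.category)


def _mk_null_result(n_reps, num_up, den_up, rpe_up, rpe_lo):
    """NullResult with one cell and prescribed tail counts."""
    z = lambda v: {k: np.array([v], dtype=float) for k in ("pd", "rpd", "pe_num", "pe_den", "rpe")}
    n_ge = z(n_reps)
    n_le = z(n_reps)
    n_ge["pe_num"][0] = num_up
    n_ge["pe_den"][0] = den_up
    n_ge["rpe"][0] = rpe_up
    n_le["rpe"][0] = rpe_lo
    return NullResult(obs=z(1.0), null_mean=z(0.0), null_sd=z(0.0),
                      n_ge={k: v.astype(int) for k, v in n_ge.items()},
                      n_le={k: v.astype(int) for k, v in n_le.items()},
                      n_reps=n_reps, algorithm="curveball", n_itr=1, seed=0,
                      nonempty=np.array([True]))


class TestCanapeRules:
    def test_no_candidate_is_not_significant(self):
        nr = _mk_null_result(999, num_up=500, den_up=500, rpe_up=500, rpe_lo=500)
        assert canape_classify(nr).category[0] == "not_significant"

    def test_super_requires_both_components_at_stricter_alpha(self):
        nr = _mk_null_result(999, num_up=4, den_up=4, rpe_up=500, rpe_lo=500)
        assert canape_classify(nr).category[0] == "super"
        # only alpha=0.05 significance -> mixed, not super
        nr2 = _mk_null_result(999, num_up=30, den_up=30, rpe_up=500, rpe_lo=500)
        assert canape_classify(nr2).category[0] == "mixed"

    def test_low_rpe_candidate_is_neo_high_is_paleo(self):
        neo = _mk_null_result(999, num_up=10, den_up=500, rpe_up=990, rpe_lo=5)
        assert canape_classify(neo).category[0] == "neo"
        paleo = _mk_null_result(999, num_up=10, den_up=500, rpe_up=5, rpe_lo=990)
        assert canape_classify(paleo).category[0] == "paleo"

    def test_candidate_without_conditions_stays_not_significant(self):
        # candidate via numerator only, RPE non-significant, denominator not
        # high -> fails the mixed condition
        nr = _mk_null_result(999, num_up=10, den_up=500, rpe_up=300, rpe_lo=300)
        assert canape_classify(nr).category[0] == "not_significant"

    def test_super_implies_mixed_condition_at_stricter_alpha(self, rng, small_grid):
        tree = pg.simulate_phylogeny(15, 1.0, seed=2)
        cm = random_community(rng, small_grid, tree.tip_labels)
        nr = null_test(cm, tree, "curveball", n_reps=199, n_itr=300, seed=0)
        res = canape_classify(nr)
        sup = res.category == "super"
        assert np.all(nr.p_upper("pe_num")[sup] <= 0.01)
        assert np.all(nr.p_upper("pe_den")[sup] <= 0.01)
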