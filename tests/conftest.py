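"""Shared fixtures and independent oracles used across the suite."""

import dendropy
import numpy as np
import pytest

from phylogrid import CommunityMatrix, GridSpec, simulate_phylogeny, write_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_community(rng, grid: GridSpec, species, p=0.4) -> CommunityMatrix:
    """Bernoulli occupancy; re-draws all-zero columns so every species occurs."""
    n = grid.n_cells
    m = (rng.random((n, len(species))) < p).astype(np.uint8)
    for j in np.flatnonzero(m.sum(axis=0) == 0):
        m[rng.integers(n), j] = 1
    return CommunityMatrix(grid, list(species), m)


def star_tree_newick(labels, length=1.0) -> str:
    return "(" + ",".join(f"{lab}:{length:g}" for lab in labels) + "):0;"


# ---- dendropy-based oracles (independent of the package's tree arrays) ----


def _dendropy_tree(tree):
    return dendropy.Tree.get(data=write_newick(tree), schema="newick")


def oracle_pd_pe(tree, cm) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force PD and PE: enumerate every branch of a dendropy parse of
    the tree, test descendant-tip intersection per cell, and accumulate
    lengths (PD) and lengths / branch cell counts (PE)."""
    dt = _dendropy_tree(tree)
    sp_col = {s: j for j, s in enumerate(cm.species)}
    branches = []
    for node in dt.preorder_node_iter():
        if node.parent_node is None:
            continue
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        cols = [sp_col[l] for l in leaves if l in sp_col]
        branches.append((node.edge.length, cols))
    pd_vals = np.zeros(cm.n_cells)
    pe_vals = np.zeros(cm.n_cells)
    pres = cm.presence.astype(bool)
    for length, cols in branches:
        if not cols:
            continue
        in_cell = pres[:, cols].any(axis=1)
        r_b = int(in_cell.sum())
        pd_vals[in_cell] += length
        if r_b:
            pe_vals[in_cell] += length / r_b
    return pd_vals, pe_vals


def oracle_tild(tree, cm) -> np.ndarray:
    """Step-function integration of ln N(t) on the dendropy-extracted
    induced subtree of each cell, counting edge crossings per interval."""
    dt = _dendropy_tree(tree)
    out = np.zeros(cm.n_cells)
    for cell in range(cm.n_cells):
        labels = [s for s, v in zip(cm.species, cm.presence[cell]) if v]
        if len(labels) < 2:
            continue
        sub = dt.extract_tree_with_taxa_labels(labels)
        sub.calc_node_ages(ultrametricity_precision=1e-6)
        # integrate from the MRCA of the cell's species
        root_age = max(n.age for n in sub if len(n.child_nodes()) >= 2)
        ages = sorted({n.age for n in sub} | {0.0, root_age})
        total = 0.0
        for lo, hi in zip(ages[:-1], ages[1:]):
            if hi > root_age:
                break
            mid = 0.5 * (lo + hi)
            n_lin = sum(
                1
                for e in sub.preorder_edge_iter()
                if e.head_node is not None and e.tail_node is not None
                and e.head_node.age <= mid < e.tail_node.age
            )
            total += np.log(max(n_lin, 1)) * (hi - lo)
        out[cell] = total
    return out


@pytest.fixture
def small_tree():
    return simulate_phylogeny(10, birth_rate=1.0, seed=42)


@pytest.fixture
def small_grid():
    return GridSpec(6, 8, 10.0)
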