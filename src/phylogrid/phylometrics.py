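"""Tree handling and per-cell phylogenetic diversity metrics.

A :class:`Phylogeny` is a rooted tree with branch lengths, stored as flat
parent/length arrays for fast vectorized metric computation over many grid
cells (and many null-model replicates).  Newick parsing and writing are
delegated to dendropy; the flat representation is what the metrics run on.

Metrics
-------
PD (Faith)
    Total branch length of the rooted subtree spanning a cell's species,
    including the path to the root (so a single-species cell has PD equal
    to that tip's root-to-tip distance).
PE (Rosauer)
    PD with each branch length divided by the branch's range R_b — the
    number of cells occupied by at least one of its descendant tips.
RPD / RPE
    PD (PE) on the original tree divided by the same metric on a
    *comparison tree*: identical topology with every branch set to the
    mean branch length, preserving total tree length.  Values above 1 mark
    concentrations of longer-than-average (older) branches.
TILD
    Time-Integrated Lineage Diversity: the integral of ln N(t) over time
    from the cell subtree's own root to the present, where N(t) is the
    number of lineages of the cell's induced subtree at age t.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
import pandas as pd

from .community import CommunityMatrix, species_richness, weighted_endemism
from .errors import InvalidInputError, MissingTaxonError, NewickParseError

__all__ = [
    "Phylogeny",
    "parse_newick",
    "write_newick",
    "comparison_tree",
    "faith_pd",
    "phylogenetic_endemism",
    "relative_metrics",
    "tild",
    "metric_table",
    "BranchIncidence",
]


class Phylogeny:
    """Rooted phylogeny with branch lengths in flat-array form.

    Nodes are indexed 0..n_nodes-1 with tips first (0..n_tips-1, matching
    ``tip_labels``).  Every non-root node carries the length of the edge to
    its parent; the set of those edges is the branch set used by all
    metrics.
    """

    def __init__(self, parent: np.ndarray, lengths: np.ndarray, tip_labels: list[str]):
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.tip_labels = list(tip_labels)
        self.n_nodes = len(self.parent)
        self.n_tips = len(tip_labels)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise InvalidInputError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if len(set(tip_labels)) != self.n_tips:
            dupes = sorted({t for t in tip_labels if tip_labels.count(t) > 1})
            raise NewickParseError(f"duplicate tip labels: {', '.join(dupes)}")
        nonroot = np.arange(self.n_nodes) != self.root
        if np.any(~np.isfinite(self.lengths[nonroot])):
            raise NewickParseError("every non-root edge needs a branch length")
        if np.any(self.lengths[nonroot] <= 0):
            bad = np.flatnonzero(nonroot & (self.lengths <= 0))
            raise InvalidInputError(
                f"zero/negative branch lengths at nodes {bad.tolist()}; collapse "
                "zero-length edges into polytomies before analysis"
            )
        # branches = non-root nodes, identified by their child-node index
        self.branch_nodes = np.flatnonzero(nonroot)
        self.branch_lengths = self.lengths[self.branch_nodes]
        self._children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if i != self.root:
                self._children[self.parent[i]].append(i)
        self._postorder = self._compute_postorder()
        self._tipset: np.ndarray | None = None

    def _compute_postorder(self) -> np.ndarray:
        order, stack = [], [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self._children[node]:
                    stack.append((c, False))
        return np.array(order, dtype=int)

    @property
    def children(self) -> list[list[int]]:
        return self._children

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    def descendant_tips(self) -> np.ndarray:
        """(n_nodes, n_tips) boolean matrix: tip j descends from node i."""
        if self._tipset is None:
            m = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
            for i in range(self.n_tips):
                m[i, i] = True
            for node in self._postorder:
                for c in self._children[node]:
                    m[node] |= m[c]
            self._tipset = m
        return self._tipset

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths (root edge excluded)."""
        depth = np.zeros(self.n_nodes)
        for node in self._postorder[::-1]:  # preorder
            if node != self.root:
                depth[node] = depth[self.parent[node]] + self.lengths[node]
        return depth[: self.n_tips]

    def node_ages(self, rtol: float = 1e-6) -> np.ndarray:
        """Ages (time before present) of all nodes; requires an ultrametric tree."""
        depth = np.zeros(self.n_nodes)
        for node in self._postorder[::-1]:
            if node != self.root:
                depth[node] = depth[self.parent[node]] + self.lengths[node]
        height = depth[: self.n_tips].max()
        tip_depths = depth[: self.n_tips]
        if height > 0 and np.max(np.abs(tip_depths - height)) > rtol * height:
            raise InvalidInputError("tree is not ultrametric: tip depths differ")
        return height - depth

    def with_lengths(self, new_lengths: np.ndarray) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), np.asarray(new_lengths, float), list(self.tip_labels))


# ---- Newick I/O -------------------------------------------------------


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required) into a Phylogeny."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various error classes
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    return _from_dendropy(dtree)


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    nodes = list(dtree.preorder_node_iter())
    tips = [n for n in nodes if n.is_leaf()]
    internals = [n for n in nodes if not n.is_leaf()]
    labels = []
    for t in tips:
        lab = t.taxon.label if t.taxon is not None else t.label
        if lab is None:
            raise NewickParseError("unlabeled tip in tree")
        labels.append(lab)
    index = {id(n): i for i, n in enumerate(tips)}
    index.update({id(n): len(tips) + i for i, n in enumerate(internals)})
    parent = np.full(len(nodes), -1, dtype=int)
    lengths = np.full(len(nodes), np.nan)
    for n in nodes:
        i = index[id(n)]
        if n.parent_node is not None:
            parent[i] = index[id(n.parent_node)]
            if n.edge.length is None:
                raise NewickParseError(f"missing branch length on edge above {labels[i] if i < len(tips) else 'an internal node'}")
            lengths[i] = n.edge.length
        else:
            lengths[i] = n.edge.length if n.edge.length is not None else 0.0
    return Phylogeny(parent, lengths, labels)


def write_newick(tree: Phylogeny) -> str:
    """Serialize a Phylogeny to a rooted Newick string with branch lengths."""

    def _sub(node: int) -> str:
        if node < tree.n_tips:
            body = tree.tip_labels[node]
        else:
            body = "(" + ",".join(_sub(c) for c in tree.children[node]) + ")"
        if node == tree.root:
            L = tree.lengths[node]
            return body + (f":{L:.10g}" if np.isfinite(L) and L != 0 else "")
        return body + f":{tree.lengths[node]:.10g}"

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * tree.n_nodes + 100))
    try:
        return _sub(tree.root) + ";"
    finally:
        sys.setrecursionlimit(old)


def comparison_tree(tree: Phylogeny) -> Phylogeny:
    """Equal-branch-length comparison tree preserving total tree length.

    Every branch is set to (total length / number of branches); RPD and RPE
    are ratios of metrics on the original vs. this tree, so they are
    dimensionless and centred near 1.
    """
    mean_len = tree.total_length / len(tree.branch_nodes)
    new = tree.lengths.copy()
    new[tree.branch_nodes] = mean_len
    new[tree.root] = 0.0
    return tree.with_lengths(new)


# ---- branch incidence engine ------------------------------------------


class BranchIncidence:
    """Precomputed branch x species incidence for one (community, tree) pair.

    Lets PD/PE be recomputed for thousands of randomized matrices as two
    matrix products: a branch is in a cell's spanning subtree iff the cell
    holds at least one of the branch's descendant tips.
    """

    def __init__(self, cm: CommunityMatrix, tree: Phylogeny):
        missing = set(cm.species) - set(tree.tip_labels)
        if missing:
            raise MissingTaxonError(missing)
        tip_index = {lab: i for i, lab in enumerate(tree.tip_labels)}
        cols = np.array([tip_index[s] for s in cm.species], dtype=int)
        desc = tree.descendant_tips()[tree.branch_nodes][:, cols]
        # (n_branches, n_cm_species) as float for fast matmul
        self.branch_by_species = desc.astype(np.float64)
        self.lengths = tree.branch_lengths
        self.comp_lengths = comparison_tree(tree).branch_lengths
        self.tree = tree
        self.cm = cm

    def branch_presence(self, presence: np.ndarray) -> np.ndarray:
        """(n_cells, n_branches) bool: branch in cell's spanning subtree."""
        return (presence.astype(np.float64) @ self.branch_by_species.T) > 0

    def pd(self, presence: np.ndarray, lengths: np.ndarray | None = None) -> np.ndarray:
        L = self.lengths if lengths is None else lengths
        return self.branch_presence(presence) @ L

    def pe(self, presence: np.ndarray, lengths: np.ndarray | None = None) -> np.ndarray:
        L = self.lengths if lengths is None else lengths
        B = self.branch_presence(presence)
        R = B.sum(axis=0)
        w = np.divide(L, R, out=np.zeros_like(L, dtype=float), where=R > 0)
        return B @ w

    def all_metrics(self, presence: np.ndarray) -> dict[str, np.ndarray]:
        """PD, RPD, PE numerator/denominator and RPE for one occupancy matrix."""
        B = self.branch_presence(presence)
        R = B.sum(axis=0)
        w_num = np.divide(self.lengths, R, out=np.zeros_like(self.lengths), where=R > 0)
        w_den = np.divide(self.comp_lengths, R, out=np.zeros_like(self.comp_lengths), where=R > 0)
        pd_obs = B @ self.lengths
        pd_comp = B @ self.comp_lengths
        pe_num = B @ w_num
        pe_den = B @ w_den
        with np.errstate(invalid="ignore", divide="ignore"):
            rpd = np.where(pd_comp > 0, pd_obs / pd_comp, np.nan)
            rpe = np.where(pe_den > 0, pe_num / pe_den, np.nan)
        return {"pd": pd_obs, "rpd": rpd, "pe_num": pe_num, "pe_den": pe_den, "rpe": rpe}


# ---- public per-cell metrics ------------------------------------------


def faith_pd(cm: CommunityMatrix, tree: Phylogeny) -> np.ndarray:
    """Per-cell Faith PD under the rooted convention; empty cells get 0."""
    return BranchIncidence(cm, tree).pd(cm.presence)


def phylogenetic_endemism(cm: CommunityMatrix, tree: Phylogeny) -> np.ndarray:
    """Per-cell Rosauer PE: spanning branch lengths weighted by 1 / R_b."""
    return BranchIncidence(cm, tree).pe(cm.presence)


def relative_metrics(cm: CommunityMatrix, tree: Phylogeny) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (RPD, RPE); NaN for empty cells or zero denominators."""
    m = BranchIncidence(cm, tree).all_metrics(cm.presence)
    empty = cm.richness() == 0
    rpd, rpe = m["rpd"].copy(), m["rpe"].copy()
    rpd[empty] = np.nan
    rpe[empty] = np.nan
    if np.any(np.isnan(rpd[~empty])) or np.any(np.isnan(rpe[~empty])):
        warnings.warn("zero comparison-tree denominator in some non-empty cells; flagged NaN")
    return rpd, rpe


def tild(cm: CommunityMatrix, tree: Phylogeny) -> np.ndarray:
    """Per-cell Time-Integrated Lineage Diversity.

    For each cell, N(t) counts the lineages of the induced subtree of the
    cell's species at age t (piecewise constant between nodes); TILD is
    the integral of ln N(t) from the induced subtree's root (the MRCA of
    the cell's species) to the present.  Single-species and empty cells
    give 0.  Requires an ultrametric tree.
    """
    ages = tree.node_ages()  # raises for non-ultrametric input
    missing = set(cm.species) - set(tree.tip_labels)
    if missing:
        raise MissingTaxonError(missing)
    tip_index = {lab: i for i, lab in enumerate(tree.tip_labels)}
    cols = np.array([tip_index[s] for s in cm.species], dtype=int)
    desc = tree.descendant_tips()[:, cols]

    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    # per (internal node, child): does the child's subtree reach the cell?
    child_hits = {
        v: (cm.presence.astype(bool) @ np.array([desc[c] for c in tree.children[v]]).T)
        for v in internals
    }
    out = np.zeros(cm.n_cells)
    for cell in range(cm.n_cells):
        events = []  # (age, lineages added)
        for v in internals:
            c = int(child_hits[v][cell].sum())
            if c >= 2:
                events.append((ages[v], c - 1))
        if not events:
            continue  # 0 or 1 species: N(t)=1 throughout, ln 1 = 0
        events.sort(key=lambda e: -e[0])
        n_lineages, acc = 1, 0.0
        for k, (age, mult) in enumerate(events):
            n_lineages += mult
            nxt = events[k + 1][0] if k + 1 < len(events) else 0.0
            acc += np.log(n_lineages) * (age - nxt)
        out[cell] = acc
    return out


def metric_table(cm: CommunityMatrix, tree: Phylogeny) -> pd.DataFrame:
    """Per-cell table of SR, WE, PD, PE, RPD, RPE and TILD, keyed by cell id."""
    rpd, rpe = relative_metrics(cm, tree)
    centers = cm.grid.cell_centers()
    return pd.DataFrame(
        {
            "cell_id": np.arange(cm.n_cells),
            "x": centers[:, 0],
            "y": centers[:, 1],
            "SR": species_richness(cm),
            "WE": weighted_endemism(cm),
            "PD": faith_pd(cm, tree),
            "PE": phylogenetic_endemism(cm, tree),
            "RPD": rpd,
            "RPE": rpe,
            "TILD": tild(cm, tree),
        }
    )
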