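"""Pairwise phylogenetic beta diversity and K-means regionalization.

For a pair of cells with spanning-subtree branch lengths A (shared), B and
C (exclusive to either cell):

* PhyloSor similarity = 2A / (2A + B + C);
* total dissimilarity beta_sor = (B + C) / (2A + B + C) = 1 - PhyloSor;
* turnover component beta_sim = min(B, C) / (A + min(B, C)) (Simpson);
* nestedness component beta_sne = beta_sor - beta_sim.

On a star tree with unit branches these reduce exactly to the classical
taxonomic Sorensen and Simpson indices.  Regionalization runs K-means on
the rows of a dissimilarity matrix and picks K at the elbow of the
within-cluster sum of squares (WSS) curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .community import CommunityMatrix
from .errors import InvalidInputError, InvalidParameterError
from .phylometrics import BranchIncidence, Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "DistMatrix",
    "phylosor",
    "phylosor_matrix",
    "phylo_beta_pair",
    "kmeans_regions",
    "elbow",
]


@dataclass
class DistMatrix:
    """Symmetric pairwise matrix over cells, similarity or dissimilarity kind."""

    cell_ids: np.ndarray
    values: np.ndarray
    kind: str  # similarity | dissimilarity

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("similarity", "dissimilarity"):
            raise InvalidParameterError("kind must be similarity or dissimilarity")
        if self.values.shape[0] != self.values.shape[1]:
            raise InvalidInputError("matrix must be square")
        finite = np.isfinite(self.values)
        if not np.allclose(self.values[finite], self.values.T[finite.T], atol=1e-12):
            raise InvalidInputError("matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.cell_ids)


def _pairwise_abc(cm: CommunityMatrix, tree: Phylogeny):
    """Shared branch length A_ij and per-cell PD; NaN handling left to callers."""
    engine = BranchIncidence(cm, tree)
    B = engine.branch_presence(cm.presence).astype(float)
    shared = (B * engine.lengths) @ B.T  # A_ij
    pd_cell = B @ engine.lengths
    return shared, pd_cell


def phylosor(cm: CommunityMatrix, tree: Phylogeny, cell_i: int, cell_j: int) -> float:
    """PhyloSor similarity of two cells; NaN if either cell is empty."""
    return float(phylosor_matrix(cm, tree).values[cell_i, cell_j])


def phylosor_matrix(cm: CommunityMatrix, tree: Phylogeny) -> DistMatrix:
    """All-pairs PhyloSor similarity; empty cells get NaN rows/columns."""
    shared, pd_cell = _pairwise_abc(cm, tree)
    bc = pd_cell[:, None] + pd_cell[None, :] - 2 * shared  # B + C
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 2 * shared / (2 * shared + bc)
    empty = cm.richness() == 0
    sim[empty, :] = np.nan
    sim[:, empty] = np.nan
    np.fill_diagonal(sim, np.where(empty, np.nan, 1.0))
    return DistMatrix(np.arange(cm.n_cells), sim, "similarity")


def phylo_beta_pair(cm: CommunityMatrix, tree: Phylogeny) -> dict[str, DistMatrix]:
    """Baselga decomposition of phylogenetic dissimilarity on branch lengths.

    Returns ``{"total": beta_sor, "turnover": beta_sim, "nestedness": beta_sne}``.
    """
    shared, pd_cell = _pairwise_abc(cm, tree)
    b = pd_cell[:, None] - shared
    c = pd_cell[None, :] - shared
    mn = np.minimum(b, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        sor = (b + c) / (2 * shared + b + c)
        sim = mn / (shared + mn)
    sne = sor - sim
    empty = cm.richness() == 0
    out = {}
    for name, vals in (("total", sor), ("turnover", sim), ("nestedness", sne)):
        v = vals.copy()
        v[empty, :] = np.nan
        v[:, empty] = np.nan
        np.fill_diagonal(v, np.where(empty, np.nan, 0.0))
        out[name] = DistMatrix(np.arange(cm.n_cells), v, "dissimilarity")
    return out


def kmeans_regions(
    dm: DistMatrix, K: int, n_starts: int = 25, seed: int = 0
) -> tuple[dict[int, int], float]:
    """Cluster cells by K-means on the dissimilarity-matrix rows.

    Rows containing NaN (pairs with an empty cell) are excluded with a
    logged report.  Returns ``(labels, wss)`` where ``labels`` maps cell id
    to cluster and ``wss`` is the within-cluster sum of squares of the best
    of ``n_starts`` restarts.
    """
    if K < 1:
        raise InvalidParameterError("K must be >= 1")
    if dm.kind != "dissimilarity":
        raise InvalidParameterError("kmeans_regions expects a dissimilarity matrix")
    valid = ~np.isnan(dm.values).any(axis=1)
    if valid.sum() < K:
        raise InvalidParameterError("K exceeds the number of usable cells")
    if (~valid).any():
        logger.info("excluding %d cells with undefined dissimilarities", int((~valid).sum()))
    X = dm.values[np.ix_(valid, valid)]
    km = KMeans(n_clusters=K, n_init=n_starts, random_state=seed).fit(X)
    labels = {int(cid): int(lab) for cid, lab in zip(dm.cell_ids[valid], km.labels_)}
    return labels, float(km.inertia_)


def elbow(wss_by_K: dict[int, float] | pd.Series) -> tuple[int, pd.Series]:
    """Pick K at the elbow of a WSS curve over consecutive K values.

    The elbow is the interior K maximizing the discrete second difference
    WSS(K-1) - 2*WSS(K) + WSS(K+1) (the sharpest drop in the rate of
    decrease); ties break toward smaller K.  Returns (K*, the full curve).
    """
    curve = pd.Series(dict(wss_by_K)).sort_index()
    ks = curve.index.to_numpy()
    if len(ks) < 3:
        raise InvalidInputError("need WSS for at least 3 consecutive K values")
    if not np.array_equal(np.diff(ks), np.ones(len(ks) - 1, dtype=ks.dtype)):
        raise InvalidInputError("K values must be consecutive integers")
    w = curve.to_numpy()
    second = w[:-2] - 2 * w[1:-1] + w[2:]
    best = int(ks[1:-1][int(np.argmax(second))])  # argmax takes first (smallest K) on ties
    return best, curve


def plot_wss(curve: pd.Series, k_star: int | None = None, path=None):
    """Elbow plot of the WSS curve (matplotlib optional dependency)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.index, curve.values, "o-")
    if k_star is not None:
        ax.axvline(k_star, color="crimson", ls="--", label=f"elbow K = {k_star}")
        ax.legend()
    ax.set_xlabel("K")
    ax.set_ylabel("within-cluster sum of squares")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
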