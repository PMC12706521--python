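"""Community-matrix randomization, null-model significance, and CANAPE.

Randomization algorithms
------------------------
``swap``
    Fixed-fixed: repeatedly swaps 2x2 checkerboard submatrices, preserving
    both row (cell richness) and column (species range) totals.  ``n_itr``
    counts *successful* swaps; non-checkerboard candidates are skipped
    without counting.
``curveball``
    Fixed-fixed: each iteration picks two random rows and redistributes the
    species unique to either row between them ("trade"), preserving both
    marginals.
``r0``
    Fixed-equiprobable: each row is replaced by a uniform random species
    subset of the same size; row sums preserved, column sums free.

Significance and CANAPE
-----------------------
``null_test`` re-randomizes the observed matrix ``n_reps`` times and, per
cell, ranks observed PD, RPD, PE (numerator: original tree), PE on the
equal-branch comparison tree (denominator) and their ratio RPE against the
null distribution.  Monte-Carlo p-values use the +1 rank correction,
p_upper = (1 + #{null >= obs}) / (n_reps + 1).

``canape_classify`` then categorizes cells: candidates are cells whose PE
numerator or denominator is significantly *high* (one-tailed alpha);
among candidates, a significantly high RPE (two-tailed, alpha/2 per tail)
marks paleo-endemism (long rare branches), a significantly low RPE marks
neo-endemism (short rare branches), and a non-significant RPE with both
components high marks mixed endemism — upgraded to super endemism when
both components are high at the stricter alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .errors import InvalidInputError, InvalidParameterError
from .phylometrics import BranchIncidence, Phylogeny

__all__ = [
    "randomize_swap",
    "randomize_curveball",
    "randomize_r0",
    "convergence_diagnostic",
    "null_test",
    "canape_classify",
    "NullResult",
    "CanapeResult",
    "CANAPE_CATEGORIES",
]

CANAPE_CATEGORIES = ("not_significant", "neo", "paleo", "mixed", "super")
METRICS = ("pd", "rpd", "pe_num", "pe_den", "rpe")


def _as_array(cm) -> np.ndarray:
    return cm.presence if isinstance(cm, CommunityMatrix) else np.asarray(cm, dtype=np.uint8)


def _wrap_like(cm, arr: np.ndarray):
    if isinstance(cm, CommunityMatrix):
        return CommunityMatrix(cm.grid, list(cm.species), arr, dict(cm.meta))
    return arr


def _has_checkerboard(m: np.ndarray) -> bool:
    """True iff some 2x2 checkerboard submatrix exists (swap can move)."""
    a = m.astype(bool)
    for i in range(a.shape[0]):
        for j in range(i + 1, a.shape[0]):
            if (a[i] & ~a[j]).any() and (~a[i] & a[j]).any():
                return True
    return False


def _swap_inplace(m: np.ndarray, n_itr: int, rng: np.random.Generator) -> None:
    nr, nc = m.shape
    done = 0
    chunk = max(1024, 4 * n_itr)
    guard = 0
    while done < n_itr:
        r = rng.integers(0, nr, size=(chunk, 2))
        c = rng.integers(0, nc, size=(chunk, 2))
        for (r1, r2), (c1, c2) in zip(r, c):
            if r1 == r2 or c1 == c2:
                continue
            a, b = m[r1, c1], m[r1, c2]
            if a == b or m[r2, c1] != b or m[r2, c2] != a:
                continue
            m[r1, c1], m[r1, c2] = b, a
            m[r2, c1], m[r2, c2] = a, b
            done += 1
            if done == n_itr:
                return
        guard += chunk
        if guard > 5_000_000 * max(1, n_itr // 1000):
            raise RuntimeError("swap sampler failed to find checkerboards")


def randomize_swap(cm, n_itr: int = 1000, seed: int = 0):
    """Fixed-fixed swap randomization; returns a matrix of the same type.

    If the matrix contains no 2x2 checkerboard the input is returned
    unchanged with a warning (it is the only member of its marginal class
    reachable by swaps).
    """
    m = _as_array(cm).copy()
    if not _has_checkerboard(m):
        warnings.warn("matrix has no checkerboard unit; swap returns input unchanged")
        return _wrap_like(cm, m)
    _swap_inplace(m, n_itr, np.random.default_rng(seed))
    return _wrap_like(cm, m)


def _curveball_inplace(m: np.ndarray, n_itr: int, rng: np.random.Generator) -> None:
    # rows packed into Python big-ints: a trade is a few bit operations plus
    # a sequential hypergeometric draw of which unique species go to row 1
    nr, nc = m.shape
    rows = [int.from_bytes(np.packbits(m[i], bitorder="little").tobytes(), "little")
            for i in range(nr)]
    pair_idx = rng.integers(0, nr, size=(n_itr, 2))
    buf = rng.random(max(1024, 4 * n_itr))
    bi = 0
    for t in range(n_itr):
        r1, r2 = pair_idx[t]
        if r1 == r2:
            continue
        a, b = rows[r1], rows[r2]
        shared = a & b
        pool = (a | b) ^ shared
        need = (a ^ shared).bit_count()
        remaining = pool.bit_count()
        if need == 0 or need == remaining:
            continue
        sel = 0
        x = pool
        while need and remaining > need:
            bit = x & -x
            x ^= bit
            if bi == len(buf):
                buf = rng.random(len(buf))
                bi = 0
            if buf[bi] * remaining < need:
                sel |= bit
                need -= 1
            bi += 1
            remaining -= 1
        if need:
            sel |= x  # all leftover bits must go to row 1
        rows[r1] = shared | sel
        rows[r2] = shared | (pool ^ sel)
    nbytes = (nc + 7) // 8
    for i in range(nr):
        packed = np.frombuffer(rows[i].to_bytes(nbytes, "little"), dtype=np.uint8)
        m[i] = np.unpackbits(packed, count=nc, bitorder="little")


def randomize_curveball(cm, n_itr: int = 1000, seed: int = 0):
    """Fixed-fixed curveball randomization (one row-pair trade per iteration)."""
    m = _as_array(cm).copy()
    _curveball_inplace(m, n_itr, np.random.default_rng(seed))
    return _wrap_like(cm, m)


def randomize_r0(cm, seed: int = 0):
    """Fixed-equiprobable randomization: uniform species subsets per row."""
    m = _as_array(cm)
    out = np.zeros_like(m)
    rng = np.random.default_rng(seed)
    n_sp = m.shape[1]
    for i, k in enumerate(m.sum(axis=1)):
        if k:
            out[i, rng.choice(n_sp, size=int(k), replace=False)] = 1
    return _wrap_like(cm, out)


def _randomize_array(m: np.ndarray, algorithm: str, n_itr: int, rng: np.random.Generator) -> np.ndarray:
    out = m.copy()
    if algorithm == "swap":
        if _has_checkerboard(out):
            _swap_inplace(out, n_itr, rng)
    elif algorithm == "curveball":
        _curveball_inplace(out, n_itr, rng)
    elif algorithm == "r0":
        res = np.zeros_like(out)
        n_sp = out.shape[1]
        for i, k in enumerate(out.sum(axis=1)):
            if k:
                res[i, rng.choice(n_sp, size=int(k), replace=False)] = 1
        out = res
    else:
        raise InvalidParameterError(f"unknown algorithm {algorithm!r}")
    return out


def convergence_diagnostic(
    cm,
    algorithm: str = "curveball",
    n_itr_grid=(0, 10, 30, 100, 300, 1000),
    n_chains: int = 10,
    seed: int = 0,
    tol: float = 0.01,
) -> pd.DataFrame:
    """Similarity-to-original vs. iteration count, with a plateau detector.

    For each ``n_itr`` in the grid, runs ``n_chains`` independent chains
    from the observed matrix and records the mean proportion of entries
    identical to the original.  The result table carries the smallest
    ``n_itr`` whose similarity is within ``tol`` of the final grid value in
    ``df.attrs['recommended_n_itr']``.
    """
    if algorithm not in ("swap", "curveball"):
        raise InvalidParameterError("convergence diagnostic applies to swap/curveball")
    m = _as_array(cm)
    rng = np.random.default_rng(seed)
    rows = []
    for n_itr in n_itr_grid:
        sims = []
        for _ in range(n_chains):
            null = _randomize_array(m, algorithm, int(n_itr), rng)
            sims.append(float((null == m).mean()))
        rows.append({"n_itr": int(n_itr), "similarity": float(np.mean(sims))})
    df = pd.DataFrame(rows)
    final = df["similarity"].iloc[-1]
    ok = df[df["similarity"] <= final + tol]
    df.attrs["recommended_n_itr"] = int(ok["n_itr"].iloc[0]) if len(ok) else int(df["n_itr"].iloc[-1])
    return df


# ---- null testing -----------------------------------------------------


@dataclass
class NullResult:
    """Per-cell null-model summary for each metric.

    ``obs``, ``null_mean``, ``null_sd``, ``n_ge`` (count of null >= obs) and
    ``n_le`` are dicts keyed by metric name over arrays of length n_cells.
    """

    obs: dict[str, np.ndarray]
    null_mean: dict[str, np.ndarray]
    null_sd: dict[str, np.ndarray]
    n_ge: dict[str, np.ndarray]
    n_le: dict[str, np.ndarray]
    n_reps: int
    algorithm: str
    n_itr: int
    seed: int
    nonempty: np.ndarray = field(default=None)

    def p_upper(self, metric: str) -> np.ndarray:
        """One-tailed upper Monte-Carlo p with +1 rank correction."""
        return (1.0 + self.n_ge[metric]) / (self.n_reps + 1.0)

    def p_lower(self, metric: str) -> np.ndarray:
        return (1.0 + self.n_le[metric]) / (self.n_reps + 1.0)

    def to_frame(self) -> pd.DataFrame:
        cols = {"cell_id": np.arange(len(self.nonempty))}
        for m in METRICS:
            cols[f"{m}_obs"] = self.obs[m]
            cols[f"{m}_p_upper"] = self.p_upper(m)
            cols[f"{m}_p_lower"] = self.p_lower(m)
        return pd.DataFrame(cols)


def null_test(
    cm: CommunityMatrix,
    tree: Phylogeny,
    algorithm: str = "curveball",
    n_reps: int = 999,
    n_itr: int = 1000,
    seed: int = 0,
) -> NullResult:
    """Rank observed PD/RPD/PE/RPE against ``n_reps`` independent nulls.

    Every replicate re-randomizes the *original* matrix (independent
    randomizations, not a thinned chain).  NaN metrics (empty cells) never
    count toward either tail.
    """
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    engine = BranchIncidence(cm, tree)
    obs = engine.all_metrics(cm.presence)
    rng = np.random.default_rng(seed)
    m = cm.presence
    n_cells = m.shape[0]
    n_ge = {k: np.zeros(n_cells, dtype=int) for k in METRICS}
    n_le = {k: np.zeros(n_cells, dtype=int) for k in METRICS}
    s1 = {k: np.zeros(n_cells) for k in METRICS}
    s2 = {k: np.zeros(n_cells) for k in METRICS}
    for _ in range(n_reps):
        null = _randomize_array(m, algorithm, n_itr, rng)
        nm = engine.all_metrics(null)
        for k in METRICS:
            with np.errstate(invalid="ignore"):
                n_ge[k] += np.where(np.isnan(nm[k]) | np.isnan(obs[k]), 0, nm[k] >= obs[k])
                n_le[k] += np.where(np.isnan(nm[k]) | np.isnan(obs[k]), 0, nm[k] <= obs[k])
            vals = np.nan_to_num(nm[k])
            s1[k] += vals
            s2[k] += vals ** 2
    mean = {k: s1[k] / n_reps for k in METRICS}
    var = {k: np.maximum(s2[k] / n_reps - mean[k] ** 2, 0.0) for k in METRICS}
    return NullResult(
        obs=obs,
        null_mean=mean,
        null_sd={k: np.sqrt(var[k]) for k in METRICS},
        n_ge=n_ge,
        n_le=n_le,
        n_reps=n_reps,
        algorithm=algorithm,
        n_itr=n_itr,
        seed=seed,
        nonempty=cm.richness() > 0,
    )


# ---- CANAPE -----------------------------------------------------------


@dataclass
class CanapeResult:
    """Per-cell endemism category plus the significance levels used."""

    category: np.ndarray  # of strings from CANAPE_CATEGORIES
    alpha: float
    alpha_super: float

    def counts(self) -> dict[str, int]:
        return {c: int((self.category == c).sum()) for c in CANAPE_CATEGORIES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": np.arange(len(self.category)),
                             "category": self.category})


def canape_classify(nr: NullResult, alpha: float = 0.05, alpha_super: float = 0.01) -> CanapeResult:
    """Categorical analysis of neo- and paleo-endemism from null-test ranks.

    Cells empty in the observed matrix are excluded (``not_significant``).
    """
    for k in ("pe_num", "pe_den", "rpe"):
        if k not in nr.obs:
            raise InvalidInputError(f"NullResult lacks metric {k!r}")
    num_hi = nr.p_upper("pe_num") <= alpha
    den_hi = nr.p_upper("pe_den") <= alpha
    num_hi_s = nr.p_upper("pe_num") <= alpha_super
    den_hi_s = nr.p_upper("pe_den") <= alpha_super
    rpe_hi = nr.p_upper("rpe") <= alpha / 2
    rpe_lo = nr.p_lower("rpe") <= alpha / 2

    n = len(num_hi)
    cat = np.array(["not_significant"] * n, dtype=object)
    candidate = (num_hi | den_hi) & nr.nonempty
    cat[candidate & rpe_hi] = "paleo"
    cat[candidate & rpe_lo & ~rpe_hi] = "neo"
    mixed = candidate & ~rpe_hi & ~rpe_lo & num_hi & den_hi
    cat[mixed] = "mixed"
    cat[mixed & num_hi_s & den_hi_s] = "super"
    return CanapeResult(category=cat.astype(str), alpha=alpha, alpha_super=alpha_super)
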