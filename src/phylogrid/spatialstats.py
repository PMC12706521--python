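"""Environmental-correlate inference for gridded diversity metrics.

Workflow: screen correlated predictors (drop until all pairwise Pearson
|r| < 0.5), fit OLS, check residual spatial autocorrelation with Moran's I
correlograms, build distance-band spatial weights up to the first
non-significant distance class, refit with simultaneous autoregressive
(SAR) error and lag models by maximum likelihood, and rank everything by
AIC.

The SAR error model is ``y = X b + u, u = lam W u + e``; the lag model is
``y = rho W y + X b + e``.  Both are fit by concentrating b and the error
variance out of the Gaussian likelihood and optimizing the spatial
parameter on its admissible interval, with ``ln|I - lam W|`` computed from
the eigenvalues of W (real, because row-standardized weights from a
symmetric neighbor relation are similar to a symmetric matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    NumericalFailureError,
    UndefinedMetricError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialWeights",
    "SarFit",
    "screen_predictors",
    "morans_i",
    "correlogram",
    "build_weights",
    "fit_ols",
    "fit_sar",
    "model_select",
]


@dataclass
class SpatialWeights:
    """Distance-band neighbor weights over point (cell-center) coordinates."""

    coords: np.ndarray
    W: sp.csr_matrix
    style: str  # binary | row-standardized
    d_max: float
    islands: np.ndarray  # indices of observations with no neighbor

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def matrix(self) -> sp.csr_matrix:
        return self.W

    def dense(self) -> np.ndarray:
        return self.W.toarray()

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W (via the symmetric similar matrix when
        row-standardized)."""
        if self.style == "row-standardized":
            deg = np.asarray((self.W > 0).sum(axis=1)).ravel().astype(float)
            with np.errstate(divide="ignore"):
                dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
            B = (self.W > 0).astype(float)
            S = sp.diags(dinv) @ B @ sp.diags(dinv)
            return np.linalg.eigvalsh(S.toarray())
        return np.linalg.eigvalsh(self.W.toarray())


def build_weights(coords: np.ndarray, d_max: float, style: str = "row-standardized") -> SpatialWeights:
    """Neighbors = all pairs with 0 < distance <= d_max.

    Rows of isolated observations (islands) stay zero and are reported;
    row standardization divides each remaining row by its neighbor count.
    """
    if d_max <= 0:
        raise InvalidParameterError("d_max must be positive")
    if style not in ("binary", "row-standardized"):
        raise InvalidParameterError("style must be binary or row-standardized")
    coords = np.asarray(coords, dtype=float)
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    pairs = tree.query_pairs(d_max, output_type="ndarray")
    n = len(coords)
    if len(pairs) == 0:
        raise InvalidInputError("all observations are isolated at this d_max")
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    W = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(W.sum(axis=1)).ravel()
    islands = np.flatnonzero(deg == 0)
    if len(islands):
        logger.info("%d island observations have no neighbor within %.3g", len(islands), d_max)
    if style == "row-standardized":
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
        W = sp.diags(inv) @ W
    return SpatialWeights(coords, sp.csr_matrix(W), style, float(d_max), islands)


# ---- screening and Moran's I ------------------------------------------


def screen_predictors(table: pd.DataFrame, threshold: float = 0.5):
    """Greedy collinearity screen: keep predictors with all pairwise |r| < threshold.

    While any pair violates the threshold, the predictor with the largest
    mean absolute correlation to the others is dropped.  Zero-variance
    columns are dropped first with a warning.  Returns
    ``(kept_names, dropped_names, correlation_matrix)``.
    """
    if table.shape[1] < 2:
        raise InvalidParameterError("need at least 2 predictors to screen")
    dropped = []
    work = table.copy()
    zero_var = [c for c in work.columns if work[c].std(ddof=0) == 0]
    for c in zero_var:
        logger.warning("dropping zero-variance predictor %r", c)
        dropped.append(c)
    work = work.drop(columns=zero_var)
    corr_full = work.corr()
    while work.shape[1] > 1:
        corr = work.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if corr.values.max() < threshold:
            break
        mean_abs = corr.mean(axis=0)
        # restrict to predictors involved in some violating pair
        involved = corr.index[(corr >= threshold).any(axis=0)]
        victim = mean_abs.loc[involved].idxmax()
        dropped.append(victim)
        work = work.drop(columns=[victim])
    return list(work.columns), dropped, corr_full


def morans_i(x: np.ndarray, W: SpatialWeights | sp.spmatrix | np.ndarray) -> dict:
    """Moran's I with moments under the normality assumption.

    Returns ``{"I", "expected", "variance", "z", "p"}`` with a two-sided p
    from the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise InvalidParameterError("Moran's I needs n >= 3")
    if isinstance(W, SpatialWeights):
        Wm = W.matrix()
    else:
        Wm = sp.csr_matrix(W)
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise UndefinedMetricError("Moran's I undefined for constant x")
    s0 = float(Wm.sum())
    if s0 == 0:
        raise InvalidParameterError("weights matrix has no nonzero entries")
    num = float(z @ (Wm @ z))
    I = (n / s0) * num / denom

    Wd = Wm + Wm.T
    s1 = 0.5 * float(Wd.multiply(Wd).sum())
    row = np.asarray(Wm.sum(axis=1)).ravel()
    col = np.asarray(Wm.sum(axis=0)).ravel()
    s2 = float(((row + col) ** 2).sum())
    e_i = -1.0 / (n - 1)
    var = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e_i ** 2
    var = max(var, 0.0)
    zscore = (I - e_i) / np.sqrt(var) if var > 0 else np.nan
    p = 2 * stats.norm.sf(abs(zscore)) if np.isfinite(zscore) else np.nan
    return {"I": I, "expected": e_i, "variance": var, "z": zscore, "p": p}


def correlogram(x: np.ndarray, coords: np.ndarray, n_classes: int = 10, alpha: float = 0.05) -> pd.DataFrame:
    """Moran's I per equal-width distance class up to half the max distance.

    Binary weights link pairs whose distance falls in the class.  The
    returned table has one row per non-empty class (``d_lo``, ``d_hi``,
    ``I``, ``p``, ``n_pairs``); ``df.attrs['first_nonsignificant_d']`` is
    the upper edge of the last class before the first p >= alpha (the
    recommended distance band for the spatial weights).
    """
    if n_classes < 2:
        raise InvalidParameterError("need at least 2 distance classes")
    coords = np.asarray(coords, dtype=float)
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(coords))
    d_half = D.max() / 2.0
    edges = np.linspace(0, d_half, n_classes + 1)
    rows = []
    hit_nonsig = False
    prev_edge = None
    for k in range(n_classes):
        lo, hi = edges[k], edges[k + 1]
        mask = (D > lo) & (D <= hi)
        np.fill_diagonal(mask, False)
        n_pairs = int(mask.sum()) // 2
        if n_pairs == 0:
            logger.info("distance class (%.3g, %.3g] empty; skipped", lo, hi)
            continue
        res = morans_i(x, sp.csr_matrix(mask.astype(float)))
        rows.append({"d_lo": lo, "d_hi": hi, "I": res["I"], "z": res["z"],
                     "p": res["p"], "n_pairs": n_pairs})
        if not hit_nonsig:
            if res["p"] >= alpha:
                hit_nonsig = True  # prev_edge = last class before first p >= alpha
            else:
                prev_edge = hi
    df = pd.DataFrame(rows)
    df.attrs["first_nonsignificant_d"] = prev_edge
    return df


# ---- regression models ------------------------------------------------


@dataclass
class SarFit:
    """One fitted regression model (OLS or SAR) on a common response."""

    model: str  # ols | sar_error | sar_lag
    names: list[str]
    beta: np.ndarray
    spatial_param: float | None
    sigma2: float
    loglik: float
    aic: float
    residuals: np.ndarray
    n: int
    k: int  # parameters counted in the AIC
    response: str = "y"
    beta_se: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({"coef": self.beta}, index=self.names)
        if self.beta_se is not None:
            df["se"] = self.beta_se
            df["z"] = df["coef"] / df["se"]
            df["p"] = 2 * stats.norm.sf(np.abs(df["z"]))
        return df


def _design(X, add_intercept: bool):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    if add_intercept:
        Xa = np.column_stack([np.ones(len(Xa)), Xa])
        names = ["intercept"] + names
    return Xa, names


def _check_rank(X: np.ndarray, names: list[str]):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name candidate collinear columns by inspecting the null space
        _, s, vt = np.linalg.svd(X)
        bad = np.abs(vt[-1]) > 1e-8
        culprits = [n for n, b in zip(names, bad) if b]
        raise InvalidInputError(f"design matrix rank deficient; collinear columns: {culprits}")


def fit_ols(y: np.ndarray, X, add_intercept: bool = True, response: str = "y") -> SarFit:
    """Gaussian OLS with maximum-likelihood sigma^2 and AIC = 2k - 2 logL.

    k counts the regression coefficients plus the error variance, so AIC is
    directly comparable with the SAR fits below.
    """
    y = np.asarray(y, dtype=float)
    Xa, names = _design(X, add_intercept)
    _check_rank(Xa, names)
    beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    resid = y - Xa @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    k = Xa.shape[1] + 1
    XtX_inv = np.linalg.inv(Xa.T @ Xa)
    se = np.sqrt(np.diag(XtX_inv) * (resid @ resid) / max(n - Xa.shape[1], 1))
    return SarFit("ols", names, beta, None, sigma2, loglik, 2 * k - 2 * loglik,
                  resid, n, k, response, se)


def _sar_concentrated(y, Xa, W, eigs, model):
    """Return f(lam) -> (negative concentrated loglik, beta, sigma2, resid)."""
    n = len(y)
    Wy = W @ y
    WX = W @ Xa

    def pieces(lam: float):
        logdet = float(np.log(1.0 - lam * eigs).sum())
        if model == "error":
            ys = y - lam * Wy
            Xs = Xa - lam * WX
            beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
            resid_t = ys - Xs @ beta  # transformed residuals = eps
            resid = y - Xa @ beta  # u, reported
        else:  # lag
            ys = y - lam * Wy
            beta, *_ = np.linalg.lstsq(Xa, ys, rcond=None)
            resid_t = ys - Xa @ beta
            resid = resid_t
        sigma2 = float(resid_t @ resid_t) / n
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1) + logdet
        return loglik, beta, sigma2, resid

    return pieces


def fit_sar(
    y: np.ndarray,
    X,
    W: SpatialWeights,
    model: str = "error",
    add_intercept: bool = True,
    response: str = "y",
) -> SarFit:
    """Maximum-likelihood SAR fit (error or lag) with profiled beta, sigma^2.

    The spatial parameter is optimized on the admissible interval
    ``(1/min(eig W), 1/max(eig W))``; ``ln|I - lam W|`` uses the (real)
    eigenvalues of W.
    """
    if model not in ("error", "lag"):
        raise InvalidParameterError("model must be 'error' or 'lag'")
    y = np.asarray(y, dtype=float)
    Xa, names = _design(X, add_intercept)
    _check_rank(Xa, names)
    eigs = W.eigenvalues()
    e_min, e_max = eigs.min(), eigs.max()
    if e_max <= 0 or e_min >= 0:
        raise NumericalFailureError("weights eigenvalues do not bracket zero")
    lo, hi = 1.0 / e_min, 1.0 / e_max
    eps = 1e-6 * (hi - lo)
    pieces = _sar_concentrated(y, Xa, W.matrix(), eigs, model)

    res = optimize.minimize_scalar(
        lambda lam: -pieces(lam)[0], bounds=(lo + eps, hi - eps), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise NumericalFailureError(
            f"SAR likelihood optimization failed: {res.message}; "
            f"profile interval ({lo:.4f}, {hi:.4f})"
        )
    lam = float(res.x)
    loglik, beta, sigma2, resid = pieces(lam)
    k = Xa.shape[1] + 2  # beta, sigma2, spatial parameter
    return SarFit(f"sar_{model}", names, beta, lam, sigma2, loglik,
                  2 * k - 2 * loglik, resid, len(y), k, response)


def model_select(fits: list[SarFit]) -> pd.DataFrame:
    """Rank fits of one response by AIC (ties broken by fewer parameters)."""
    if len(fits) < 2:
        raise InvalidParameterError("need at least 2 fits to rank")
    if len({f.response for f in fits}) != 1:
        raise InvalidInputError("fits compare different responses")
    rows = [
        {"model": f.model, "k": f.k, "loglik": f.loglik, "aic": f.aic,
         "spatial_param": f.spatial_param}
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values(["aic", "k"], kind="mergesort").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df
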