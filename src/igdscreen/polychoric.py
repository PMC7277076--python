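"""Two-stage polychoric correlation estimation for ordinal items.

Stage 1 fixes per-item thresholds at the normal quantiles of the empirical
cumulative category proportions; stage 2 maximizes, for each item pair, the
bivariate-normal cell-probability log-likelihood over the latent correlation
rho in [-0.999, 0.999] with thresholds held fixed.  This is the standard
two-stage estimator used in categorical structural equation modelling.

Rectangle probabilities use the Owen's-T closed form of the bivariate
normal CDF (numerically stable, vectorized); cell probabilities below
1e-12 are floored before taking logs.  Empty categories are collapsed
toward the nearest non-empty neighbour with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri, owens_t

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSet",
    "PolychoricMatrix",
    "bvn_cdf",
    "estimate_thresholds",
    "polychoric_pair",
    "polychoric_matrix",
]

RHO_BOUND = 0.999
_CELL_FLOOR = 1e-12


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Closed form via Owen's T function; vectorized over h, k.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    if abs(rho) < 1e-14:
        return ndtr(h) * ndtr(k)
    if abs(rho) >= 1.0:
        rho = np.sign(rho) * (1.0 - 1e-15)
    h_inf_pos, k_inf_pos = h == np.inf, k == np.inf
    h_inf_neg, k_inf_neg = h == -np.inf, k == -np.inf
    both_zero = (h == 0.0) & (k == 0.0)
    # finite working copies; exact zeros nudged off the removable singularity
    hs = np.where(np.isinf(h), 0.0, h)
    ks = np.where(np.isinf(k), 0.0, k)
    hs = np.where(hs == 0.0, 1e-13, hs)
    ks = np.where(ks == 0.0, 1e-13, ks)

    denom = np.sqrt(1.0 - rho * rho)
    ah = (ks - rho * hs) / (denom * hs)
    ak = (hs - rho * ks) / (denom * ks)
    val = 0.5 * (ndtr(hs) + ndtr(ks)) - owens_t(hs, ah) - owens_t(ks, ak)
    # subtract 1/2 on the quadrant-crossing branch
    val = val - 0.5 * (hs * ks < 0)
    val = np.where(both_zero, 0.25 + np.arcsin(rho) / (2.0 * np.pi), val)
    # infinite arguments reduce to univariate margins (any -inf wins)
    val = np.where(h_inf_pos, ndtr(k), val)
    val = np.where(k_inf_pos, ndtr(h), val)
    val = np.where(h_inf_pos & k_inf_pos, 1.0, val)
    val = np.where(h_inf_neg | k_inf_neg, 0.0, val)
    return np.clip(val, 0.0, 1.0)


@dataclass
class ThresholdSet:
    """Per-item ordered cutpoints (length = n_categories - 1)."""

    cutpoints: dict[str, np.ndarray]
    collapsed: list[str] = field(default_factory=list)

    def __getitem__(self, item: str) -> np.ndarray:
        return self.cutpoints[item]


@dataclass
class PolychoricMatrix:
    """Item x item latent correlation matrix with its threshold sets.

    ``weights`` holds, per pair, the inverse asymptotic variance of the
    correlation estimate (observed Fisher information at the optimum),
    used as DWLS weights downstream.
    """

    matrix: pd.DataFrame
    thresholds: ThresholdSet
    n_persons: int
    weights: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        if not np.allclose(m, m.T):
            raise ValueError("polychoric matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("polychoric matrix must have unit diagonal")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        if np.any(np.abs(off) > RHO_BOUND + 1e-9):
            raise ValueError(f"entries must lie in [-{RHO_BOUND}, {RHO_BOUND}]")

    @property
    def items(self) -> list[str]:
        return list(self.matrix.columns)

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)


def estimate_thresholds(responses, item: str = "item") -> np.ndarray:
    """Normal-quantile cutpoints from one item's empirical margins.

    Cutpoint ``c = Phi^{-1}(cumulative proportion below category c+1)``.
    Categories observed zero times are collapsed into their neighbour
    (the corresponding cutpoint is dropped) with a warning.
    """
    codes = np.asarray(responses)
    if codes.size == 0:
        raise ValueError(f"item {item}: no observations")
    counts = np.bincount(codes.astype(int), minlength=int(codes.max()) + 1)
    n = counts.sum()
    cum = np.cumsum(counts)[:-1] / n
    interior = cum[(cum > 0.0) & (cum < 1.0)]
    if interior.size == 0:
        raise ValueError(
            f"item {item} is constant (single observed category); "
            "it cannot enter the model")
    if interior.size < cum.size:
        logger.warning("item %s: empty category collapsed into neighbour", item)
    return ndtri(np.unique(interior))


def _cell_probabilities(rho: float, tau_a: np.ndarray, tau_b: np.ndarray) -> np.ndarray:
    """Rectangle probabilities of the (len(tau_a)+1) x (len(tau_b)+1) grid."""
    a = np.concatenate([[-np.inf], tau_a, [np.inf]])
    b = np.concatenate([[-np.inf], tau_b, [np.inf]])
    hh, kk = np.meshgrid(a, b, indexing="ij")
    big = bvn_cdf(hh, kk, rho)
    return np.diff(np.diff(big, axis=0), axis=1)


def _pair_nll(rho: float, table: np.ndarray,
              tau_a: np.ndarray, tau_b: np.ndarray) -> float:
    p = np.maximum(_cell_probabilities(rho, tau_a, tau_b), _CELL_FLOOR)
    return -float(np.sum(table * np.log(p)))


def polychoric_pair(contingency, thresholds_a, thresholds_b,
                    return_avar: bool = False):
    """ML estimate of the latent correlation for one pair, thresholds fixed.

    Maximizes the bivariate-normal cell log-likelihood over
    rho in [-0.999, 0.999].  Estimates at the bound are clipped there
    (near-singular tables).  With ``return_avar`` the asymptotic variance
    from the observed information (numerical second derivative) is also
    returned; ``None`` when the optimum is at the bound or the curvature
    is non-positive.
    """
    table = np.asarray(contingency, dtype=float)
    if table.sum() <= 0:
        raise ValueError("contingency table must have positive total")
    tau_a = np.asarray(thresholds_a, dtype=float)
    tau_b = np.asarray(thresholds_b, dtype=float)
    if table.shape != (tau_a.size + 1, tau_b.size + 1):
        raise ValueError(
            f"table shape {table.shape} does not match thresholds "
            f"({tau_a.size + 1} x {tau_b.size + 1} expected)")

    nll = lambda r: _pair_nll(r, table, tau_a, tau_b)
    res = optimize.minimize_scalar(nll, bounds=(-RHO_BOUND, RHO_BOUND),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    rho, best = float(res.x), float(res.fun)
    # bounded Brent never lands exactly on a bound; check the endpoints
    for endpoint in (-RHO_BOUND, RHO_BOUND):
        v = nll(endpoint)
        if v < best - 1e-10:
            rho, best = endpoint, v
    if not np.isfinite(best):
        raise ValueError("no correlation gives positive probability to all "
                         "occupied cells")
    if not return_avar:
        return rho
    avar = None
    if abs(rho) < RHO_BOUND - 1e-6:
        h = 1e-4
        info = (nll(rho + h) - 2.0 * best + nll(rho - h)) / (h * h)
        if info > 0:
            avar = 1.0 / info
    return rho, avar


def polychoric_matrix(responses) -> PolychoricMatrix:
    """Pairwise polychoric correlation matrix of an ordinal item set.

    Accepts an :class:`~igdscreen.synthetic.ItemResponseMatrix` or a plain
    person x item DataFrame.  Raises if any item is constant, listing all
    offenders.
    """
    data = getattr(responses, "data", responses)
    if isinstance(data, pd.DataFrame) and hasattr(responses, "items") \
            and not isinstance(responses, pd.DataFrame):
        data = data[responses.items]
    items = list(data.columns)
    if len(items) < 2:
        raise ValueError("need at least two items")
    codes = {}
    constant = []
    for item in items:
        col = data[item].to_numpy().astype(int)
        # recode to consecutive observed categories (collapse empties)
        observed = np.unique(col)
        if observed.size < 2:
            constant.append(item)
            continue
        codes[item] = np.searchsorted(observed, col)
    if constant:
        raise ValueError(f"constant items cannot enter the model: {constant}")

    cutpoints = {}
    collapsed = []
    for item in items:
        cutpoints[item] = estimate_thresholds(codes[item], item=item)
        if np.unique(codes[item]).size <= int(data[item].max()):
            collapsed.append(item)
    thresholds = ThresholdSet(cutpoints=cutpoints, collapsed=collapsed)

    p = len(items)
    mat = np.eye(p)
    wts = np.full((p, p), np.nan)
    n = len(data)
    for i in range(p):
        for j in range(i + 1, p):
            a, b = codes[items[i]], codes[items[j]]
            table = np.zeros((a.max() + 1, b.max() + 1))
            np.add.at(table, (a, b), 1.0)
            rho, avar = polychoric_pair(table, cutpoints[items[i]],
                                        cutpoints[items[j]], return_avar=True)
            mat[i, j] = mat[j, i] = rho
            if avar is not None and avar > 0:
                # weight = inverse variance of sqrt(n)*(rho_hat - rho), so the
                # DWLS discrepancy stays on the chi-square scale after (n-1)*F
                wts[i, j] = wts[j, i] = 1.0 / (n * avar)
    matrix = pd.DataFrame(mat, index=items, columns=items)
    weights = pd.DataFrame(wts, index=items, columns=items)
    return PolychoricMatrix(matrix=matrix, thresholds=thresholds,
                            n_persons=n, weights=weights)
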