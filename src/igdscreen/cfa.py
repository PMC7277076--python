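"""Confirmatory factor analysis on polychoric correlations.

Fits the second-order measurement model (items -> nine subconstructs -> one
general factor) and its one-factor and independence comparison models by
least squares on the polychoric correlation matrix:

    F(theta) = sum over the strict lower triangle of w_ik (s_ik - sigma_ik(theta))^2

with ``sigma(theta)`` the model-implied correlation.  ``dwls`` weights each
residual by the inverse asymptotic variance of the corresponding polychoric
estimate (delta-method observed information); ``uls`` uses unit weights.
The chi-square statistic is the naive ``(n - 1) * F_min``; no
mean-and-variance adjustment of the test statistic is applied, so fit
indices are comparable in spirit but not bit-compatible with full WLSMV
software.  Validation of this module therefore rests on parameter recovery
and model-ordering properties rather than on matching any published index.

Thresholds are not refitted here (two-stage convention): the CFA consumes
the correlation matrix only, so the degrees of freedom are
``p(p-1)/2 - n_free``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .polychoric import PolychoricMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MeasurementModel",
    "FitIndices",
    "CFAResult",
    "implied_correlation",
    "fit_model",
    "fit_indices",
    "fit_independence_baseline",
]

LOADING_BOUND = 0.999
MAX_ITER = 500
_START = 0.7


@dataclass
class MeasurementModel:
    """Second-order measurement structure with (optionally) estimates.

    ``model_kind`` is one of ``second_order`` (items on subconstructs,
    subconstructs on one general factor), ``one_factor`` (the gamma == 1
    submodel: all factors collapse onto the general factor), or
    ``independence`` (all correlations zero).
    """

    factor_map: dict[str, list[str]]
    loadings: dict[str, float] = field(default_factory=dict)
    second_order: dict[str, float] = field(default_factory=dict)
    model_kind: str = "second_order"

    def __post_init__(self) -> None:
        if self.model_kind not in ("second_order", "one_factor", "independence"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        seen: set[str] = set()
        for factor, items in self.factor_map.items():
            dup = seen.intersection(items)
            if dup:
                raise ValueError(f"factor_map does not partition items: {sorted(dup)}")
            seen.update(items)
        # models may state perfect indicators (|loading| = 1); the tighter
        # LOADING_BOUND applies only inside the optimizer
        for item, lam in self.loadings.items():
            if abs(lam) > 1.0:
                raise ValueError(f"loading for {item} outside [-1, 1]: {lam}")
        for factor, gam in self.second_order.items():
            if abs(gam) > 1.0:
                raise ValueError(f"second-order loading for {factor} outside [-1, 1]")

    @property
    def items(self) -> list[str]:
        return [i for items in self.factor_map.values() for i in items]

    @property
    def factors(self) -> list[str]:
        return list(self.factor_map)

    def item_factor_index(self) -> np.ndarray:
        idx = []
        for j, items in enumerate(self.factor_map.values()):
            idx.extend([j] * len(items))
        return np.asarray(idx)

    @property
    def n_free(self) -> int:
        if self.model_kind == "independence":
            return 0
        n = len(self.items)
        if self.model_kind == "second_order":
            n += len(self.factor_map)
        return n

    def r_squared(self) -> dict[str, float]:
        """Variance of each subconstruct explained by the general factor."""
        return {f: g * g for f, g in self.second_order.items()}

    def to_table(self) -> pd.DataFrame:
        rows = []
        for factor, items in self.factor_map.items():
            gam = self.second_order.get(factor, np.nan)
            for item in items:
                rows.append({
                    "item": item,
                    "factor": factor,
                    "loading": self.loadings.get(item, np.nan),
                    "second_order_loading": gam,
                    "r_squared": gam * gam if np.isfinite(gam) else np.nan,
                })
        return pd.DataFrame(rows)


@dataclass
class FitIndices:
    discrepancy_min: float
    chi_square: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")
        if self.srmr < 0 or self.rmsea < 0 or self.discrepancy_min < -1e-12:
            raise ValueError("fit indices out of range")


@dataclass
class CFAResult:
    model: MeasurementModel
    discrepancy: float
    converged: bool
    n_iterations: int
    sample: pd.DataFrame | None = None        # the s matrix fitted
    implied: pd.DataFrame | None = None
    weights: pd.DataFrame | None = None
    fit: FitIndices | None = None

    @property
    def df(self) -> int:
        p = len(self.model.items)
        return p * (p - 1) // 2 - self.model.n_free

    @property
    def residuals(self) -> pd.DataFrame | None:
        if self.sample is None or self.implied is None:
            return None
        return self.sample - self.implied


def _implied_from_arrays(lam: np.ndarray, gam: np.ndarray,
                         fidx: np.ndarray) -> np.ndarray:
    """sigma_ik = lam_i lam_k (same factor) or lam_i lam_k gam_j gam_l."""
    g_item = gam[fidx]
    cross = np.outer(lam * g_item, lam * g_item)
    same = np.equal.outer(fidx, fidx)
    within = np.outer(lam, lam)
    sigma = np.where(same, within, cross)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def implied_correlation(model: MeasurementModel) -> pd.DataFrame:
    """Model-implied item correlation matrix (unit diagonal).

    Same-factor pairs: ``lambda_i * lambda_k``; cross-factor pairs:
    ``lambda_i * lambda_k * gamma_j * gamma_l`` (standardized factors,
    Phi = gamma gamma' + diag(1 - gamma^2)).  The one-factor model is the
    gamma == 1 special case; independence implies the identity matrix.
    """
    items = model.items
    p = len(items)
    if model.model_kind == "independence":
        return pd.DataFrame(np.eye(p), index=items, columns=items)
    lam = np.array([model.loadings[i] for i in items])
    if model.model_kind == "one_factor":
        gam = np.ones(len(model.factor_map))
    else:
        gam = np.array([model.second_order[f] for f in model.factor_map])
    sigma = _implied_from_arrays(lam, gam, model.item_factor_index())
    return pd.DataFrame(sigma, index=items, columns=items)


def _repair_psd(s: np.ndarray) -> tuple[np.ndarray, bool]:
    vals, vecs = np.linalg.eigh(s)
    if vals.min() >= 1e-6:
        return s, False
    vals = np.clip(vals, 1e-6, None)
    rep = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(rep))
    rep = rep / np.outer(d, d)
    return rep, True


def _resolve_matrix(s, spec: MeasurementModel, estimator: str):
    """Return (s ndarray, weight ndarray lower-tri) ordered by spec items."""
    items = spec.items
    if isinstance(s, PolychoricMatrix):
        mat = s.matrix.loc[items, items].to_numpy()
        wts = None
        if estimator == "dwls":
            if s.weights is None:
                logger.warning("dwls requested but no weights available; using uls")
            else:
                wts = s.weights.loc[items, items].to_numpy()
    else:
        mat = pd.DataFrame(s).loc[items, items].to_numpy() if isinstance(s, pd.DataFrame) \
            else np.asarray(s, dtype=float)
        wts = None
        if estimator == "dwls":
            logger.warning("dwls requested on a bare matrix; using unit weights")
    mat, repaired = _repair_psd(mat)
    if repaired:
        logger.warning("sample matrix repaired to positive semidefinite "
                       "(eigenvalues clipped at 1e-6)")
    p = mat.shape[0]
    tri = np.tril_indices(p, k=-1)
    if wts is None:
        w = np.ones(len(tri[0]))
    else:
        w = wts[tri]
        w = np.where(np.isfinite(w) & (w > 0), w, np.nanmedian(w[np.isfinite(w)]))
    return mat, w, tri


def fit_model(s, spec: MeasurementModel, estimator: str = "dwls") -> CFAResult:
    """Estimate the model by (diagonally) weighted least squares on s.

    ``s`` may be a :class:`PolychoricMatrix` (supplies DWLS weights) or a
    plain correlation matrix.  Identification requires >= 3 items per
    factor.  Convergence: gradient norm < 1e-6 or parameter change < 1e-8.
    Non-convergence is flagged on the result; Heywood-adjacent estimates
    (|loading| at the 0.999 bound) are logged.
    """
    if estimator not in ("uls", "dwls"):
        raise ValueError(f"unknown estimator {estimator!r}")
    for factor, items in spec.factor_map.items():
        if len(items) < 3:
            raise ValueError(f"factor {factor} has < 3 items; model not identified")
    if spec.model_kind == "independence":
        return fit_independence_baseline(s)

    mat, w, tri = _resolve_matrix(s, spec, estimator)
    s_vec = mat[tri]
    fidx = spec.item_factor_index()
    n_items = len(spec.items)
    n_fac = len(spec.factor_map)
    second = spec.model_kind == "second_order"
    n_par = n_items + (n_fac if second else 0)

    def unpack(theta):
        lam = theta[:n_items]
        gam = theta[n_items:] if second else np.ones(n_fac)
        return lam, gam

    def objective(theta):
        lam, gam = unpack(theta)
        sigma = _implied_from_arrays(lam, gam, fidx)
        resid = s_vec - sigma[tri]
        return float(np.sum(w * resid * resid))

    x0 = np.full(n_par, _START)
    bounds = [(-LOADING_BOUND, LOADING_BOUND)] * n_par
    res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": MAX_ITER, "ftol": 1e-14,
                                     "gtol": 1e-8})
    lam, gam = unpack(res.x)
    converged = bool(res.success or np.linalg.norm(res.jac) < 1e-6)
    if not converged:
        logger.warning("CFA did not converge after %d iterations", res.nit)
    if np.any(np.abs(res.x) >= LOADING_BOUND - 1e-6):
        logger.warning("Heywood-adjacent estimate: loading at the %.3f bound",
                       LOADING_BOUND)

    fitted = replace(spec,
                     loadings={i: float(l) for i, l in zip(spec.items, lam)},
                     second_order={f: float(g) for f, g in
                                   zip(spec.factor_map, gam)} if second else {})
    items = spec.items
    implied = pd.DataFrame(_implied_from_arrays(lam, gam, fidx),
                           index=items, columns=items)
    wfull = np.zeros_like(mat)
    wfull[tri] = w
    wfull = wfull + wfull.T
    return CFAResult(model=fitted, discrepancy=float(res.fun), converged=converged,
                     n_iterations=int(res.nit),
                     sample=pd.DataFrame(mat, index=items, columns=items),
                     implied=implied,
                     weights=pd.DataFrame(wfull, index=items, columns=items))


def fit_independence_baseline(s, spec: MeasurementModel | None = None,
                              estimator: str = "dwls") -> CFAResult:
    """Zero-correlation baseline: F_b = sum w_ik s_ik^2, df = p(p-1)/2."""
    if spec is None:
        if isinstance(s, PolychoricMatrix):
            items = s.items
        else:
            items = list(pd.DataFrame(s).columns)
        spec = MeasurementModel(factor_map={"ALL": items},
                                model_kind="independence")
    base = replace(spec, model_kind="independence", loadings={}, second_order={})
    mat, w, tri = _resolve_matrix(s, base, estimator)
    disc = float(np.sum(w * mat[tri] ** 2))
    items = base.items
    return CFAResult(model=base, discrepancy=disc, converged=True, n_iterations=0,
                     sample=pd.DataFrame(mat, index=items, columns=items),
                     implied=pd.DataFrame(np.eye(len(items)), index=items,
                                          columns=items))


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90):
    """Noncentral-chi-square inversion for the RMSEA interval (best effort)."""
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2

    def bound(q):
        if stats.chi2.cdf(chi2, df) < q:  # no admissible noncentrality
            return 0.0
        f = lambda nc: stats.ncx2.cdf(chi2, df, nc) - q
        hi = max(chi2 * 2, 10.0)
        while f(hi) > 0:
            hi *= 2
        return optimize.brentq(f, 0.0, hi)

    try:
        lam_lo, lam_hi = bound(lo_q), bound(hi_q)
    except Exception:   # pragma: no cover - numerical fallback
        return (np.nan, np.nan)
    scale = df * (n - 1)
    return (float(np.sqrt(max(lam_lo, 0.0) / scale)),
            float(np.sqrt(max(lam_hi, 0.0) / scale)))


def fit_indices(result: CFAResult, baseline: CFAResult, n_persons: int) -> FitIndices:
    """Chi-square and the CFI / TLI / RMSEA / SRMR battery.

    chi2 = (n-1) * F_min; CFI and TLI from the independence baseline with
    the usual max-protection; RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1)));
    SRMR = root mean square residual over the strict lower triangle.
    """
    if not result.converged:
        raise ValueError("fit indices require a converged model")
    if not baseline.converged:
        raise ValueError("fit indices require a converged baseline")
    n = n_persons
    chi_m = (n - 1) * result.discrepancy
    chi_b = (n - 1) * baseline.discrepancy
    df_m, df_b = result.df, baseline.df
    if df_m <= 0 or df_b <= 0:
        raise ValueError("non-positive degrees of freedom")
    num = max(chi_m - df_m, 0.0)
    den = max(chi_b - df_b, chi_m - df_m, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    ratio_b, ratio_m = chi_b / df_b, chi_m / df_m
    tli = (ratio_b - ratio_m) / (ratio_b - 1.0) if ratio_b != 1.0 else np.nan
    rmsea = float(np.sqrt(max(chi_m - df_m, 0.0) / (df_m * (n - 1))))
    resid = result.residuals.to_numpy()
    tri = np.tril_indices(resid.shape[0], k=-1)
    srmr = float(np.sqrt(np.mean(resid[tri] ** 2)))
    return FitIndices(discrepancy_min=result.discrepancy,
                      chi_square=float(chi_m), df=df_m,
                      cfi=float(cfi), tli=float(tli),
                      rmsea=rmsea, rmsea_ci=_rmsea_ci(chi_m, df_m, n),
                      srmr=srmr)
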