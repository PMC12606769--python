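"""Correlation matrices over composite scores.

Provides Spearman and Pearson matrices on complete rows, and a two-step
polychoric estimator: thresholds from inverse-normal cumulative marginals,
then, per pair, univariate maximum likelihood for the latent bivariate
normal correlation, with an asymptotic variance from the inverse observed
information.  The polychoric matrix and its asymptotic variances are the
inputs to diagonally weighted least squares factor analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtri

from .exceptions import EstimationError, ValidationError
from .scoring import CompositeTable

_INF = 7.5  # effective infinity on the probit scale


@dataclass
class CorrelationSet:
    method: str  # spearman | pearson | polychoric
    matrix: pd.DataFrame
    asymptotic_variances: pd.DataFrame | None = None
    n_effective: int = 0
    repaired: bool = False  # nearest-PD repair applied

    @property
    def terms(self) -> list[str]:
        return list(self.matrix.columns)

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)


def _complete_scores(composites: CompositeTable | pd.DataFrame) -> pd.DataFrame:
    df = composites.scores if isinstance(composites, CompositeTable) else composites
    return df.dropna(axis=0, how="any")


def _rank_matrix(df: pd.DataFrame, method: str) -> CorrelationSet:
    data = _complete_scores(df)
    if len(data) < 3:
        raise ValidationError("need at least 3 complete rows")
    zero_var = data.std(ddof=0) == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance columns {list(data.columns[zero_var])}: correlations set to missing",
            stacklevel=3,
        )
    mat = data.corr(method=method)
    np.fill_diagonal(mat.values, 1.0)
    return CorrelationSet(method=method, matrix=mat, n_effective=len(data))


def spearman_matrix(composites: CompositeTable | pd.DataFrame) -> CorrelationSet:
    """Spearman rank correlations (average-rank ties) on complete rows."""
    return _rank_matrix(composites, "spearman")


def pearson_matrix(composites: CompositeTable | pd.DataFrame) -> CorrelationSet:
    """Pearson correlations on complete rows."""
    return _rank_matrix(composites, "pearson")


def bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF P(X <= h, Y <= k; rho).

    Uses the single-integral representation
    Phi2 = Phi(h) Phi(k) + (1/2pi) int_0^rho phi2(h, k; r) dr
    evaluated with fixed Gauss-Legendre quadrature, which is smooth in rho
    and vectorizes over a grid of (h, k).
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    base = stats.norm.cdf(h) * stats.norm.cdf(k)
    if rho == 0.0:
        return base
    nodes, weights = np.polynomial.legendre.leggauss(48)
    r = 0.5 * rho * (nodes + 1.0)  # map [-1,1] -> [0, rho]
    w = 0.5 * rho * weights
    r = r[:, None]
    hh = h.ravel()[None, :]
    kk = k.ravel()[None, :]
    expo = np.exp(-(hh**2 - 2.0 * r * hh * kk + kk**2) / (2.0 * (1.0 - r**2)))
    integ = (w[:, None] * expo / np.sqrt(1.0 - r**2)).sum(axis=0) / (2.0 * np.pi)
    return base + integ.reshape(h.shape)


def _thresholds_from_margin(counts: np.ndarray) -> np.ndarray:
    """Inverse-normal thresholds from marginal counts (interior cutpoints)."""
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return ndtri(cum)


def _cell_probabilities(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    ax = np.concatenate(([-_INF], tau_x, [_INF]))
    ay = np.concatenate(([-_INF], tau_y, [_INF]))
    H, K = np.meshgrid(ax, ay, indexing="ij")
    F = bvn_cdf(H, K, rho)
    P = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(P, 1e-12, None)


def polychoric_pair(
    x: np.ndarray,
    y: np.ndarray,
    continuity_correction: bool = True,
) -> tuple[float, float]:
    """Two-step polychoric correlation and its asymptotic variance.

    x, y are integer-coded ordinal vectors (no missing values).  Returns
    (rho_hat, avar) where avar is the inverse observed information of the
    profile likelihood in rho at the maximum.
    """
    xc, x_codes = np.unique(x, return_inverse=True)
    yc, y_codes = np.unique(y, return_inverse=True)
    if len(xc) < 2 or len(yc) < 2:
        raise EstimationError("polychoric pair needs >= 2 observed categories per variable")
    table = np.zeros((len(xc), len(yc)))
    np.add.at(table, (x_codes, y_codes), 1.0)
    if continuity_correction and (table == 0).any():
        table = table + np.where(table == 0, 0.5, 0.0)

    tau_x = _thresholds_from_margin(table.sum(axis=1))
    tau_y = _thresholds_from_margin(table.sum(axis=0))

    def nll(rho: float) -> float:
        P = _cell_probabilities(tau_x, tau_y, rho)
        return -float(np.sum(table * np.log(P)))

    res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise EstimationError("polychoric likelihood maximization failed to converge")
    rho_hat = float(res.x)

    h = 1e-4
    lo = max(rho_hat - h, -0.9989)
    hi = min(rho_hat + h, 0.9989)
    d2 = (nll(hi) - 2.0 * nll(rho_hat) + nll(lo)) / ((0.5 * (hi - lo)) ** 2)
    avar = 1.0 / d2 if d2 > 0 else np.inf
    return rho_hat, float(avar)


def nearest_positive_definite(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipping repair, rescaled back to unit diagonal."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, eps, None)
    repaired = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def polychoric_matrix(
    composites: CompositeTable | pd.DataFrame,
    continuity_correction: bool = True,
) -> CorrelationSet:
    """Pairwise two-step polychoric correlation matrix with asymptotic variances.

    Complete rows only (the intended flow imputes first).  Categories never
    observed in a column are collapsed implicitly, since thresholds come from
    the observed marginal distribution; a warning notes any column using
    fewer than 4 interior thresholds.
    """
    data = _complete_scores(composites)
    if len(data) < 3:
        raise ValidationError("need at least 3 complete rows")
    cols = list(data.columns)
    arr = data.to_numpy()
    for j, c in enumerate(cols):
        n_cat = len(np.unique(arr[:, j]))
        if n_cat < 2:
            raise EstimationError(f"column {c!r} has a single observed category")
        if n_cat < 4:
            warnings.warn(
                f"column {c!r}: only {n_cat} observed categories; absent categories collapsed",
                stacklevel=2,
            )
    p = len(cols)
    R = np.eye(p)
    V = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            try:
                rho, avar = polychoric_pair(arr[:, i], arr[:, j], continuity_correction)
            except EstimationError as err:
                raise EstimationError(f"pair ({cols[i]!r}, {cols[j]!r}): {err}") from err
            R[i, j] = R[j, i] = rho
            V[i, j] = V[j, i] = avar

    repaired = False
    if np.linalg.eigvalsh((R + R.T) / 2.0).min() < 1e-8:
        warnings.warn("polychoric matrix not positive definite; nearest-PD repair applied",
                      stacklevel=2)
        R = nearest_positive_definite(R)
        repaired = True

    return CorrelationSet(
        method="polychoric",
        matrix=pd.DataFrame(R, index=cols, columns=cols),
        asymptotic_variances=pd.DataFrame(V, index=cols, columns=cols),
        n_effective=len(data),
        repaired=repaired,
    )
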