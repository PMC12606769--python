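"""One-factor ordinal CFA by diagonally weighted least squares (DWLS).

The model is fitted to the lower triangle of a polychoric correlation
matrix: each observed correlation r_ab is matched against the model-implied
value lambda_a * lambda_b * psi (plus a residual covariance for explicitly
freed pairs), weighted by the inverse asymptotic variance of the
corresponding polychoric estimate.  Identification fixes the first
indicator's unstandardized loading to 1 and leaves the factor variance psi
free; the standardized solution is derived afterwards as
l_i = lambda_i * sqrt(psi).

The discrepancy at the minimum yields the chi-square statistic
(n - 1) * F_min; incremental fit indices use the independence model (all
correlations zero) evaluated with the same weights.  Reliability of the
average score is summarized by McDonald's omega computed from the
standardized loadings, with coefficient alpha available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .correlation import CorrelationSet
from .exceptions import EstimationError, HeywoodError, JustIdentifiedError, ValidationError
from .scoring import CompositeTable


@dataclass
class FitIndices:
    chi_square: float
    df: int
    p_value: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    srmr: float

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
            "cfi": self.cfi,
            "tli": self.tli,
            "rmsea": self.rmsea,
            "rmsea_ci90": list(self.rmsea_ci90),
            "srmr": self.srmr,
        }


@dataclass
class FactorSolution:
    terms: list[str]
    loadings_unstd: pd.Series  # first indicator fixed to 1
    loadings_std: pd.Series
    factor_variance: float
    residual_covariances: list[tuple[tuple[str, str], float]]
    fit: FitIndices | None  # None when just-identified
    residual_matrix: pd.DataFrame  # r_obs - r_model, zero diagonal
    omega: float | None
    n: int
    status: str = "ok"  # ok | just_identified
    f_min: float = 0.0
    baseline: tuple[float, int] = (np.nan, 0)  # (chi2_b, df_b)
    factor_scores_: pd.Series | None = None


def _triangle(p: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(p, k=1)


def dwls_degrees_of_freedom(p: int, n_residual_pairs: int = 0) -> int:
    """df = p(p-1)/2 - [(p-1) loadings + 1 factor variance + freed pairs]."""
    return p * (p - 1) // 2 - p - n_residual_pairs


def fit_cfa(
    poly: CorrelationSet,
    n: int | None = None,
    residual_pairs: list[tuple[str, str]] | None = None,
    allow_heywood: bool = False,
) -> FactorSolution:
    """Fit the one-factor DWLS model to a polychoric correlation matrix.

    ``residual_pairs`` frees residual covariances between the named term
    pairs.  Raises :class:`HeywoodError` when the standardized solution is
    inadmissible (some |l_i| >= 1, i.e. a negative residual variance),
    unless ``allow_heywood`` is set for diagnostic use.
    """
    terms = poly.terms
    p = len(terms)
    if p < 3:
        raise ValidationError("one-factor CFA needs p >= 3 indicators")
    n = n if n is not None else poly.n_effective
    residual_pairs = list(residual_pairs or [])

    R = poly.values()
    if poly.asymptotic_variances is not None:
        # weights use the asymptotic variance of sqrt(n)(rho_hat - rho), the
        # scale on which (n - 1) * F_min is a chi-square statistic
        gamma = poly.asymptotic_variances.to_numpy(dtype=float) * max(n, 2)
        with np.errstate(divide="ignore"):
            W = np.where(gamma > 0, 1.0 / gamma, 0.0)
    else:
        W = np.ones((p, p))  # unweighted least squares fallback
    iu, ju = _triangle(p)
    r = R[iu, ju]
    w = W[iu, ju]
    if not np.all(np.isfinite(w)):
        raise EstimationError("non-finite DWLS weights")

    idx_of = {t: i for i, t in enumerate(terms)}
    res_idx = []
    for a, b in residual_pairs:
        if a not in idx_of or b not in idx_of:
            raise ValidationError(f"residual pair ({a!r}, {b!r}) references unknown terms")
        res_idx.append(tuple(sorted((idx_of[a], idx_of[b]))))
    if len(set(res_idx)) != len(res_idx):
        raise ValidationError("duplicate residual pairs")

    df = dwls_degrees_of_freedom(p, len(res_idx))
    if df < 0:
        raise EstimationError(f"negative degrees of freedom (df={df})")

    # position of each freed pair within the vectorized triangle
    tri_pos = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(iu, ju))}
    res_pos = np.array([tri_pos[pair] for pair in res_idx], dtype=int)

    # initialize loadings from the first eigenvector of R
    vals, vecs = np.linalg.eigh(R)
    v1 = vecs[:, -1] * np.sqrt(max(vals[-1], 1e-6))
    if v1.sum() < 0:
        v1 = -v1
    v1 = np.clip(v1, 0.05, 0.95)
    lam0 = v1 / v1[0]
    x0 = np.concatenate([lam0[1:], [v1[0] ** 2], np.zeros(len(res_idx))])

    def unpack(x):
        lam = np.concatenate([[1.0], x[: p - 1]])
        psi = x[p - 1]
        theta = x[p:]
        return lam, psi, theta

    def model_vec(lam, psi, theta):
        m = lam[iu] * lam[ju] * psi
        if len(theta):
            m = m.copy()
            m[res_pos] += theta
        return m

    def objective(x):
        lam, psi, theta = unpack(x)
        diff = r - model_vec(lam, psi, theta)
        f = np.sum(w * diff**2)
        # gradient
        g = np.zeros_like(x)
        wd = -2.0 * w * diff
        # d m / d lam_k  (k >= 1): psi * lam_other on pairs containing k
        for k in range(1, p):
            mask_i = iu == k
            mask_j = ju == k
            g[k - 1] = psi * (np.sum(wd[mask_i] * lam[ju[mask_i]]) + np.sum(wd[mask_j] * lam[iu[mask_j]]))
        g[p - 1] = np.sum(wd * lam[iu] * lam[ju])
        if len(theta):
            g[p:] = wd[res_pos]
        return f, g

    bounds = [(-10.0, 10.0)] * (p - 1) + [(1e-8, 10.0)] + [(-1.0, 1.0)] * len(res_idx)
    best = None
    for scale in (1.0, 0.5, 1.5):
        start = x0.copy()
        start[p - 1] *= scale
        res = optimize.minimize(
            objective, start, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise EstimationError("DWLS minimization failed")
    lam, psi, theta = unpack(best.x)
    f_min = float(best.fun)

    loadings_std = lam * np.sqrt(psi)
    resid_var = 1.0 - loadings_std**2
    heywood = np.any(np.abs(loadings_std) >= 1.0) or np.any(resid_var < 0)

    m = model_vec(lam, psi, theta)
    resid = np.zeros((p, p))
    resid[iu, ju] = r - m
    resid += resid.T

    chi2 = max(n - 1, 1) * f_min
    chi2_b = max(n - 1, 1) * float(np.sum(w * r**2))
    df_b = p * (p - 1) // 2

    solution = FactorSolution(
        terms=terms,
        loadings_unstd=pd.Series(lam, index=terms, name="loading_unstd"),
        loadings_std=pd.Series(loadings_std, index=terms, name="loading_std"),
        factor_variance=float(psi),
        residual_covariances=[((terms[a], terms[b]), float(t)) for (a, b), t in zip(res_idx, theta)],
        fit=None,
        residual_matrix=pd.DataFrame(resid, index=terms, columns=terms),
        omega=None,
        n=n,
        f_min=f_min,
        baseline=(chi2_b, df_b),
    )

    if heywood and not allow_heywood:
        worst = terms[int(np.argmax(np.abs(loadings_std)))]
        raise HeywoodError(
            f"inadmissible solution: negative residual variance for {worst!r} "
            f"(standardized loading {loadings_std[int(np.argmax(np.abs(loadings_std)))]:.3f})",
            loadings=solution.loadings_std,
        )

    if df == 0:
        solution.status = "just_identified"
    else:
        solution.fit = compute_fit_indices(
            chi_square=chi2, df=df, chi_square_baseline=chi2_b, df_baseline=df_b,
            n=n, residuals=r - m,
        )
    if not heywood:
        solution.omega = mcdonald_omega(loadings_std)
    return solution


def compute_fit_indices(
    chi_square: float,
    df: int,
    chi_square_baseline: float,
    df_baseline: int,
    n: int,
    residuals: np.ndarray,
) -> FitIndices:
    """CFI, TLI, RMSEA (with 90% CI from the noncentral chi-square), SRMR."""
    if df < 1:
        raise JustIdentifiedError("fit indices undefined for df < 1")
    if df_baseline <= 0:
        raise EstimationError("baseline degrees of freedom must be positive")

    d = max(chi_square - df, 0.0)
    d_b = max(chi_square_baseline - df_baseline, 0.0)
    denom = max(d_b, d)
    cfi = 1.0 if denom == 0 else 1.0 - d / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))

    ratio_b = chi_square_baseline / df_baseline
    ratio_m = chi_square / df
    tli = 1.0 if ratio_b <= 1.0 else (ratio_b - ratio_m) / (ratio_b - 1.0)

    nm1 = max(n - 1, 1)
    rmsea = float(np.sqrt(d / (df * nm1)))
    rmsea_ci = _rmsea_ci(chi_square, df, nm1)

    srmr = float(np.sqrt(np.mean(np.asarray(residuals) ** 2)))
    p_value = float(stats.chi2.sf(chi_square, df))
    return FitIndices(
        chi_square=float(chi_square), df=int(df), p_value=p_value,
        cfi=cfi, tli=float(tli), rmsea=rmsea, rmsea_ci90=rmsea_ci, srmr=srmr,
    )


def _rmsea_ci(chi2: float, df: int, nm1: int, level: float = 0.90) -> tuple[float, float]:
    """Invert the noncentral chi-square CDF for the RMSEA confidence bounds."""
    alpha = (1.0 - level) / 2.0

    def ncp_for(prob: float) -> float:
        # find ncp with P(X_{df, ncp} <= chi2) = prob
        if stats.ncx2.cdf(chi2, df, 0.0) <= prob:
            return 0.0
        hi = max(10.0, chi2 * 2)
        while stats.ncx2.cdf(chi2, df, hi) > prob and hi < 1e7:
            hi *= 2
        return float(optimize.brentq(lambda l: stats.ncx2.cdf(chi2, df, l) - prob, 0.0, hi))

    lo_ncp = ncp_for(1.0 - alpha)
    hi_ncp = ncp_for(alpha)
    return (float(np.sqrt(lo_ncp / (df * nm1))), float(np.sqrt(hi_ncp / (df * nm1))))


def residual_screen(solution: FactorSolution, threshold: float = 0.20) -> list[tuple[str, str]]:
    """Term pairs with |residual correlation| >= threshold, largest first.

    Intended to seed respecified models that free residual covariances for
    locally dependent pairs.
    """
    resid = solution.residual_matrix.to_numpy()
    terms = solution.terms
    iu, ju = np.triu_indices(len(terms), k=1)
    vals = resid[iu, ju]
    hits = np.flatnonzero(np.abs(vals) >= threshold)
    hits = hits[np.argsort(-np.abs(vals[hits]))]
    return [(terms[iu[h]], terms[ju[h]]) for h in hits]


def factor_scores(
    solution: FactorSolution,
    composites: CompositeTable | pd.DataFrame,
    orient_with: pd.Series | None = None,
) -> pd.Series:
    """Regression-method factor scores from standardized composite scores.

    scores = Z Sigma^-1 l where Sigma is the standardized model-implied
    correlation matrix.  Oriented so the correlation with ``orient_with``
    (default: the row mean of the composites, an ACS surrogate) is positive.
    """
    df = composites.scores if isinstance(composites, CompositeTable) else composites
    data = df[solution.terms].dropna(axis=0, how="any")
    l = solution.loadings_std.to_numpy()
    if np.any(np.abs(l) >= 1.0):
        raise HeywoodError("factor scores undefined for an inadmissible solution")
    p = len(l)
    sigma = np.outer(l, l) + np.diag(1.0 - l**2)
    idx_of = {t: i for i, t in enumerate(solution.terms)}
    for (a, b), t in solution.residual_covariances:
        ia, ib = idx_of[a], idx_of[b]
        sigma[ia, ib] += t
        sigma[ib, ia] += t
    try:
        weights = np.linalg.solve(sigma, l)
    except np.linalg.LinAlgError as err:
        raise EstimationError("singular model-implied correlation matrix") from err
    sd = data.std(ddof=1).to_numpy()
    sd[sd == 0] = 1.0
    z = (data.to_numpy() - data.mean().to_numpy()) / sd
    scores = z @ weights
    ref = (
        orient_with.reindex(data.index).to_numpy()
        if orient_with is not None
        else data.mean(axis=1).to_numpy()
    )
    if np.std(ref) > 0 and np.std(scores) > 0 and np.corrcoef(scores, ref)[0, 1] < 0:
        scores = -scores
    out = pd.Series(scores, index=data.index, name="factor_score")
    solution.factor_scores_ = out
    return out


def mcdonald_omega(loadings_std: np.ndarray | pd.Series) -> float:
    """McDonald's omega: (sum l)^2 / ((sum l)^2 + sum(1 - l^2))."""
    l = np.asarray(loadings_std, dtype=float)
    if np.any(np.abs(l) >= 1.0):
        raise HeywoodError("omega undefined: some |standardized loading| >= 1")
    s = l.sum()
    if s == 0:
        return 0.0
    return float(s**2 / (s**2 + np.sum(1.0 - l**2)))


def coefficient_alpha(composites: CompositeTable | pd.DataFrame) -> float:
    """Cronbach's coefficient alpha on complete rows of composite scores."""
    df = composites.scores if isinstance(composites, CompositeTable) else composites
    data = df.dropna(axis=0, how="any")
    p = data.shape[1]
    if p < 2:
        raise ValidationError("coefficient alpha needs >= 2 terms")
    item_var = data.var(ddof=1).sum()
    total_var = data.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise EstimationError("zero total-score variance")
    return float(p / (p - 1) * (1.0 - item_var / total_var))
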