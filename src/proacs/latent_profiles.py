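"""Latent profile analysis of composite scores via EM on Gaussian mixtures.

Classes are unobserved patient subgroups with class-specific mean profiles
over the per-term composite scores.  The default covariance structure is
diagonal with variances shared across classes (the common LPA default);
class-varying diagonal variances are available behind a flag.  Rows with
missing cells contribute their marginal likelihood over the observed
coordinates, the full-information treatment appropriate for diagonal
covariance models.  Class labels are canonicalized by ascending ACS of the
class mean profile so solutions are comparable across seeds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import EstimationError, ValidationError
from .scoring import CompositeTable

# Variances are floored at 0.05 composite-units^2: composite scores have a
# resolution of one unit, and without a floor the EM can lock classes onto
# exact discrete response patterns and diverge toward zero-variance optima.
_VAR_FLOOR = 0.05


@dataclass
class LPASolution:
    n_classes: int
    mixing: np.ndarray
    class_means: pd.DataFrame  # classes x terms
    variances: pd.DataFrame  # classes x terms (rows identical when shared)
    posteriors: pd.DataFrame  # patients x classes
    log_likelihood: float
    aic: float
    bic: float
    entropy: float | None  # None for k = 1
    avg_posterior: np.ndarray  # per class, over modally assigned patients
    assignments: pd.Series
    n_params: int
    converged: bool = True
    shared_variances: bool = True
    data_fingerprint: str = ""
    ll_history: list = field(default_factory=list)

    @property
    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments.to_numpy(), minlength=self.n_classes)


def _fingerprint(arr: np.ndarray) -> str:
    return hashlib.md5(np.ascontiguousarray(np.nan_to_num(arr, nan=-1.0)).tobytes()).hexdigest()


def _loglik_matrix(X, M, means, variances, log_mixing):
    """log [pi_c * N(x_i | mu_c, diag sigma_c^2)] over observed coordinates."""
    k = means.shape[0]
    out = np.empty((X.shape[0], k))
    for c in range(k):
        var = variances[c]
        ll = -0.5 * (np.log(2.0 * np.pi * var)[None, :] + (X - means[c]) ** 2 / var[None, :])
        out[:, c] = (ll * M).sum(axis=1) + log_mixing[c]
    return out


def _kmeanspp_means(Xf, k, rng):
    n = Xf.shape[0]
    centers = [Xf[rng.integers(n)]]
    for _ in range(k - 1):
        d2 = np.min([((Xf - c) ** 2).sum(axis=1) for c in centers], axis=0)
        total = d2.sum()
        probs = d2 / total if total > 0 else np.full(n, 1.0 / n)
        centers.append(Xf[rng.choice(n, p=probs)])
    return np.array(centers)


def _em_once(X, M, k, rng, shared_variances, tol, max_iter):
    n, p = X.shape
    col_n = M.sum(axis=0).astype(float)
    col_mean = (X * M).sum(axis=0) / col_n
    col_var = ((X - col_mean) ** 2 * M).sum(axis=0) / col_n
    col_var = np.clip(col_var, _VAR_FLOOR, None)

    Xf = np.where(M, X, col_mean)  # filled copy, seeding only
    means = _kmeanspp_means(Xf, k, rng)
    variances = np.tile(col_var, (k, 1))
    mixing = np.full(k, 1.0 / k)

    ll_prev = -np.inf
    converged = False
    history: list[float] = []
    for _ in range(max_iter):
        logm = _loglik_matrix(X, M, means, variances, np.log(mixing))
        lse = logsumexp(logm, axis=1)
        ll = float(lse.sum())
        history.append(ll)
        resp = np.exp(logm - lse[:, None])

        mixing = resp.mean(axis=0)
        if np.any(mixing < 1.0 / n):
            return None  # degenerate class; caller restarts
        RM = resp.T @ M  # k x p effective counts
        means = (resp.T @ (X * M)) / np.clip(RM, 1e-12, None)
        sq = np.empty((k, p))
        for c in range(k):
            sq[c] = (resp[:, c][:, None] * M * (X - means[c]) ** 2).sum(axis=0)
        if shared_variances:
            v = sq.sum(axis=0) / col_n
            variances = np.tile(np.clip(v, _VAR_FLOOR, None), (k, 1))
        else:
            variances = np.clip(sq / np.clip(RM, 1e-12, None), _VAR_FLOOR, None)

        if ll - ll_prev < tol * max(abs(ll_prev), 1.0) and np.isfinite(ll_prev):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll

    logm = _loglik_matrix(X, M, means, variances, np.log(mixing))
    lse = logsumexp(logm, axis=1)
    ll = float(lse.sum())
    history.append(ll)
    resp = np.exp(logm - lse[:, None])
    return means, variances, mixing, resp, ll, converged, history


def fit_lpa(
    composites: CompositeTable | pd.DataFrame,
    k: int,
    starts: int = 50,
    seed: int = 0,
    shared_variances: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> LPASolution:
    """Fit a k-class latent profile model by EM, best of ``starts`` inits."""
    df = composites.scores if isinstance(composites, CompositeTable) else composites
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n < 10 * k:
        raise ValidationError(f"need n >= 10k rows (n={n}, k={k})")
    M = ~np.isnan(X)
    if not M.any(axis=1).all():
        raise ValidationError("rows with no observed composite scores")
    Xz = np.nan_to_num(X, nan=0.0)
    terms = list(df.columns)

    if k == 1:
        col_n = M.sum(axis=0).astype(float)
        mu = (Xz * M).sum(axis=0) / col_n
        var = np.clip(((Xz - mu) ** 2 * M).sum(axis=0) / col_n, _VAR_FLOOR, None)
        ll = float(
            (-0.5 * (np.log(2 * np.pi * var)[None, :] + (Xz - mu) ** 2 / var[None, :]) * M).sum()
        )
        means = mu[None, :]
        variances = var[None, :]
        mixing = np.ones(1)
        resp = np.ones((n, 1))
        converged = True
        history = [ll]
    else:
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(starts):
            out = _em_once(Xz, M, k, rng, shared_variances, tol, max_iter)
            if out is None:
                continue
            if best is None or out[4] > best[4]:
                best = out
        if best is None:
            raise EstimationError(
                f"all {starts} EM starts produced a degenerate class (mixing < 1/n)"
            )
        means, variances, mixing, resp, ll, converged, history = best

    # canonical label order: ascending ACS of the class mean profile
    order = np.argsort(means.mean(axis=1))
    means, variances, mixing, resp = means[order], variances[order], mixing[order], resp[:, order]

    n_params = (k - 1) + k * p + (p if shared_variances else k * p)
    aic = -2.0 * ll + 2.0 * n_params
    bic = -2.0 * ll + n_params * np.log(n)
    assignments = resp.argmax(axis=1)
    avg_post = np.array(
        [resp[assignments == c, c].mean() if (assignments == c).any() else np.nan for c in range(k)]
    )
    return LPASolution(
        n_classes=k,
        mixing=mixing,
        class_means=pd.DataFrame(means, columns=terms),
        variances=pd.DataFrame(variances, columns=terms),
        posteriors=pd.DataFrame(resp, index=df.index, columns=range(k)),
        log_likelihood=ll,
        aic=float(aic),
        bic=float(bic),
        entropy=entropy_statistic(resp) if k >= 2 else None,
        avg_posterior=avg_post,
        assignments=pd.Series(assignments, index=df.index, name="class"),
        n_params=n_params,
        converged=converged,
        shared_variances=shared_variances,
        data_fingerprint=_fingerprint(X),
        ll_history=list(history),
    )


def entropy_statistic(posteriors: np.ndarray | pd.DataFrame) -> float | None:
    """Relative entropy E = 1 - sum(-p log p) / (n log k); None for k = 1."""
    P = np.asarray(posteriors, dtype=float)
    n, k = P.shape
    if k == 1:
        return None
    Pc = np.clip(P, 1e-300, 1.0)
    raw = float(-(P * np.log(Pc)).sum())
    return 1.0 - raw / (n * np.log(k))


def selection_table(solutions: list[LPASolution]) -> pd.DataFrame:
    """Model-selection report across class counts fitted on identical data.

    Flags the BIC-minimal row; the final class-count choice remains with the
    analyst (interpretability and class sizes also matter).
    """
    if not solutions:
        raise ValidationError("no solutions supplied")
    fps = {s.data_fingerprint for s in solutions}
    if len(fps) != 1:
        raise ValidationError("solutions were not fitted on identical data")
    rows = []
    for s in sorted(solutions, key=lambda s: s.n_classes):
        rows.append(
            {
                "n_classes": s.n_classes,
                "log_likelihood": s.log_likelihood,
                "aic": s.aic,
                "bic": s.bic,
                "entropy": np.nan if s.entropy is None else s.entropy,
                "avg_posterior_min": np.nanmin(s.avg_posterior),
                "avg_posterior_max": np.nanmax(s.avg_posterior),
                "class_sizes": ",".join(str(int(c)) for c in s.class_sizes),
                "converged": s.converged,
            }
        )
    out = pd.DataFrame(rows)
    out["bic_minimal"] = out["bic"] == out["bic"].min()
    return out


@dataclass
class BlrtResult:
    p_value: float
    statistic: float
    replicates: int
    n_nonconverged: int
    flagged: bool = False


def bootstrap_lrt(
    composites: CompositeTable | pd.DataFrame,
    k: int,
    replicates: int = 99,
    seed: int = 0,
    starts: int = 5,
    shared_variances: bool = True,
) -> BlrtResult:
    """Bootstrapped likelihood-ratio test of k classes against k - 1.

    Parametric bootstrap: simulate from the fitted (k-1)-class model, refit
    both models on each replicate, and report the Monte Carlo p-value
    p = (1 + #{T_b >= T_obs}) / (B + 1).
    """
    if k < 2:
        raise ValidationError("bootstrap LRT needs k >= 2")
    if replicates < 19:
        raise ValidationError("need at least 19 bootstrap replicates")
    df = composites.scores if isinstance(composites, CompositeTable) else composites
    n, p = df.shape
    rng = np.random.default_rng(seed)

    null = fit_lpa(df, k - 1, starts=starts, seed=int(rng.integers(2**31)),
                   shared_variances=shared_variances)
    alt = fit_lpa(df, k, starts=starts, seed=int(rng.integers(2**31)),
                  shared_variances=shared_variances)
    t_obs = 2.0 * (alt.log_likelihood - null.log_likelihood)

    means = null.class_means.to_numpy()
    sds = np.sqrt(null.variances.to_numpy())
    mixing = null.mixing
    exceed = 0
    n_fail = 0
    for _ in range(replicates):
        classes = rng.choice(k - 1, size=n, p=mixing)
        sim = means[classes] + rng.standard_normal((n, p)) * sds[classes]
        sim_df = pd.DataFrame(sim, columns=df.columns)
        try:
            b_null = fit_lpa(sim_df, k - 1, starts=starts, seed=int(rng.integers(2**31)),
                             shared_variances=shared_variances)
            b_alt = fit_lpa(sim_df, k, starts=starts, seed=int(rng.integers(2**31)),
                            shared_variances=shared_variances)
        except EstimationError:
            n_fail += 1
            continue
        if not (b_null.converged and b_alt.converged):
            n_fail += 1
            continue
        t_b = 2.0 * (b_alt.log_likelihood - b_null.log_likelihood)
        if t_b >= t_obs:
            exceed += 1
    done = replicates - n_fail
    p_value = (1.0 + exceed) / (done + 1.0)
    return BlrtResult(
        p_value=float(p_value),
        statistic=float(t_obs),
        replicates=done,
        n_nonconverged=n_fail,
        flagged=n_fail > 0.2 * replicates,
    )


@dataclass
class AcsByClass:
    table: pd.DataFrame  # per-class ACS mean/sd and size
    profile_distance: pd.DataFrame  # pairwise max |delta class mean| per term


def acs_by_class(solution: LPASolution, composites: CompositeTable) -> AcsByClass:
    """Per-class ACS summaries and pairwise profile distinctness.

    The profile distance between two classes is the maximum absolute
    difference of their per-term mean profiles (in composite-score units),
    which exposes classes that share an overall burden level but trade
    symptoms.
    """
    if composites.acs is None:
        raise ValidationError("compute the ACS before summarizing by class")
    acs = composites.acs.reindex(solution.assignments.index)
    k = solution.n_classes
    rows = []
    for c in range(k):
        members = solution.assignments == c
        vals = acs[members].dropna()
        if len(vals) == 0:
            import warnings

            warnings.warn(f"class {c} is empty; excluded from the ACS summary", stacklevel=2)
            rows.append({"class": c, "n": 0, "acs_mean": np.nan, "acs_sd": np.nan})
            continue
        rows.append(
            {"class": c, "n": int(members.sum()), "acs_mean": float(vals.mean()),
             "acs_sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
        )
    means = solution.class_means.to_numpy()
    dist = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            dist[a, b] = np.max(np.abs(means[a] - means[b])) if a != b else 0.0
    return AcsByClass(
        table=pd.DataFrame(rows).set_index("class"),
        profile_distance=pd.DataFrame(dist, index=range(k), columns=range(k)),
    )
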