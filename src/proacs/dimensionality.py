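"""Eigenvalue-ratio factor retention and principal component extraction.

The retention rule looks for the sharpest drop in the eigenvalue spectrum
of a correlation matrix: for each leading index i it forms the ratio
R_i = lambda_i / lambda_{i+1} and retains the number of components at the
index maximizing R_i.  PC1 scores summarize the shared variation across
composite scores and are compared with the ACS downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import CorrelationSet
from .exceptions import ValidationError
from .scoring import CompositeTable

_EIG_FLOOR = 1e-10


@dataclass
class DimensionalityResult:
    eigenvalues: np.ndarray  # descending
    variance_explained: np.ndarray
    ratios: np.ndarray  # R_i = lambda_i / lambda_{i+1}, NaN past the floor
    retained: int | None = None
    pc_loadings: pd.DataFrame | None = None  # p x k, eigenvectors * sqrt(lambda)
    pc1_scores: pd.Series | None = None


def _eigen(corr: CorrelationSet) -> tuple[np.ndarray, np.ndarray]:
    mat = corr.values()
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValidationError("correlation matrix must be symmetric")
    vals, vecs = np.linalg.eigh(mat)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def eigenvalue_ratio_test(corr: CorrelationSet) -> DimensionalityResult:
    """Retain the component index maximizing lambda_i / lambda_{i+1}.

    Ratios with denominators below the eigenvalue floor are undefined and
    excluded; ties break toward the smaller index.
    """
    p = corr.matrix.shape[0]
    if p < 3:
        raise ValidationError("eigenvalue ratio test needs p >= 3")
    vals, _ = _eigen(corr)
    ratios = np.full(p - 1, np.nan)
    for i in range(p - 1):
        if vals[i + 1] > _EIG_FLOOR:
            ratios[i] = vals[i] / vals[i + 1]
    if np.all(np.isnan(ratios)):
        raise ValidationError("all eigenvalue ratios undefined (degenerate spectrum)")
    retained = int(np.nanargmax(ratios)) + 1
    return DimensionalityResult(
        eigenvalues=vals,
        variance_explained=vals / vals.sum(),
        ratios=ratios,
        retained=retained,
    )


def pca_extract(
    corr: CorrelationSet,
    composites: CompositeTable | pd.DataFrame | None = None,
    k: int = 1,
) -> DimensionalityResult:
    """Extract the top-k principal components of a correlation matrix.

    Loadings are eigenvectors scaled by sqrt(lambda).  If composite scores
    are supplied, PC1 scores are the standardized complete rows projected on
    the first eigenvector, oriented so that PC1 correlates positively with
    the row mean of the composites (a deterministic sign convention).
    """
    p = corr.matrix.shape[0]
    if k > p or k < 1:
        raise ValidationError(f"k={k} must lie in 1..{p}")
    vals, vecs = _eigen(corr)
    loadings = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0.0, None))[None, :]
    result = DimensionalityResult(
        eigenvalues=vals,
        variance_explained=vals / vals.sum(),
        ratios=np.full(p - 1, np.nan),
        retained=k,
        pc_loadings=pd.DataFrame(
            loadings, index=corr.terms, columns=[f"PC{i + 1}" for i in range(k)]
        ),
    )
    if composites is not None:
        df = composites.scores if isinstance(composites, CompositeTable) else composites
        data = df[corr.terms].dropna(axis=0, how="any")
        sd = data.std(ddof=1).to_numpy()
        sd[sd == 0] = 1.0
        z = (data.to_numpy() - data.mean().to_numpy()) / sd
        scores = z @ vecs[:, 0]
        rowmean = data.mean(axis=1).to_numpy()
        if np.std(rowmean) > 0 and np.corrcoef(scores, rowmean)[0, 1] < 0:
            scores = -scores
        result.pc1_scores = pd.Series(scores, index=data.index, name="pc1")
    return result


def scree_table(result: DimensionalityResult) -> pd.DataFrame:
    """Scree data (component, eigenvalue, variance fraction) for export."""
    p = len(result.eigenvalues)
    return pd.DataFrame(
        {
            "component": np.arange(1, p + 1),
            "eigenvalue": result.eigenvalues,
            "variance_fraction": result.variance_explained,
        }
    )
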