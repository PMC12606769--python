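"""Sequential term-removal robustness analysis.

Starting from the full term set, terms are removed one at a time in a given
order (least-endorsed first by default, or ascending factor loading) until
only three remain.  At each step the pipeline quantities are recomputed on
the reduced set: eigenvalue-ratio retention, PC1 variance share, McDonald's
omega, the one-factor DWLS fit, and the correlations between the reduced-set
ACS and PC1 scores, factor scores, an external criterion, and the full-set
ACS.  Estimation failures that are expected near the bottom of the trace
(just-identified three-indicator models, Heywood cases) are recorded as
markers rather than aborting the trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import correlation, dimensionality, factor_model, scoring
from .exceptions import EstimationError, HeywoodError, ValidationError
from .scoring import CompositeTable


@dataclass
class ReductionStep:
    removed_term: str | None  # None for the step-0 full set
    remaining_terms: list[str]
    retained: int | None
    pc1_variance_fraction: float
    omega: float | None  # None marks a Heywood failure
    fit: factor_model.FitIndices | None
    status: str  # ok | just_identified | heywood | error:<msg>
    r_acs_pc1: float
    r_acs_factor: float | None
    r_acs_criterion: float | None
    r_acs_fullset: float


@dataclass
class ReductionTrace:
    steps: list[ReductionStep]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            fit = s.fit
            rows.append(
                {
                    "removed_term": s.removed_term or "",
                    "n_remaining": len(s.remaining_terms),
                    "retained": s.retained,
                    "pc1_variance_pct": 100.0 * s.pc1_variance_fraction,
                    "omega": np.nan if s.omega is None else s.omega,
                    "chi_square": fit.chi_square if fit else np.nan,
                    "df": fit.df if fit else np.nan,
                    "p_value": fit.p_value if fit else np.nan,
                    "cfi": fit.cfi if fit else np.nan,
                    "tli": fit.tli if fit else np.nan,
                    "rmsea": fit.rmsea if fit else np.nan,
                    "srmr": fit.srmr if fit else np.nan,
                    "status": s.status,
                    "r_acs_pc1": s.r_acs_pc1,
                    "r_acs_factor": np.nan if s.r_acs_factor is None else s.r_acs_factor,
                    "r_acs_criterion": np.nan if s.r_acs_criterion is None else s.r_acs_criterion,
                    "r_acs_fullset": s.r_acs_fullset,
                }
            )
        return pd.DataFrame(rows)


def _pearson(a: pd.Series, b: pd.Series) -> float:
    joined = pd.concat([a, b], axis=1).dropna()
    return float(joined.iloc[:, 0].corr(joined.iloc[:, 1]))


def _evaluate_set(
    scores: pd.DataFrame,
    full_acs: pd.Series,
    criterion: pd.Series | None,
    residual_threshold: float | None,
) -> ReductionStep:
    terms = list(scores.columns)
    table = scoring.compute_acs(CompositeTable(scores=scores), min_coverage=1.0)
    acs = table.acs

    pear = correlation.pearson_matrix(scores)
    dim = dimensionality.eigenvalue_ratio_test(pear)
    pca = dimensionality.pca_extract(pear, composites=scores, k=1)
    r_pc1 = _pearson(acs, pca.pc1_scores)

    omega = None
    fit = None
    r_factor = None
    status = "ok"
    try:
        poly = correlation.polychoric_matrix(scores)
        solution = factor_model.fit_cfa(poly, n=len(scores.dropna()))
        if residual_threshold is not None and solution.fit is not None:
            pairs = factor_model.residual_screen(solution, threshold=residual_threshold)
            if pairs and factor_model.dwls_degrees_of_freedom(len(terms), len(pairs)) >= 1:
                solution = factor_model.fit_cfa(poly, n=len(scores.dropna()), residual_pairs=pairs)
        omega = solution.omega
        status = solution.status
        fit = solution.fit
        fscores = factor_model.factor_scores(solution, scores, orient_with=acs)
        r_factor = _pearson(acs, fscores)
    except HeywoodError:
        status = "heywood"
    except EstimationError as err:
        status = f"error:{err}"

    r_crit = _pearson(acs, criterion) if criterion is not None else None
    return ReductionStep(
        removed_term=None,
        remaining_terms=terms,
        retained=dim.retained,
        pc1_variance_fraction=float(dim.variance_explained[0]),
        omega=omega,
        fit=fit,
        status=status,
        r_acs_pc1=r_pc1,
        r_acs_factor=r_factor,
        r_acs_criterion=r_crit,
        r_acs_fullset=_pearson(acs, full_acs),
    )


def run_reduction(
    composites: CompositeTable,
    order: list[str],
    criterion: pd.Series | None = None,
    min_terms: int = 3,
    residual_threshold: float | None = 0.20,
) -> ReductionTrace:
    """Remove terms in ``order`` until ``min_terms`` remain, re-evaluating
    the full metric panel at each step (step 0 is the intact set)."""
    scores = composites.scores
    all_terms = list(scores.columns)
    unknown = [t for t in order if t not in all_terms]
    if unknown:
        raise ValidationError(f"removal order references unknown terms {unknown}")
    if len(all_terms) - len(order) < min_terms:
        order = order[: len(all_terms) - min_terms]
    if len(all_terms) < min_terms:
        raise ValidationError(f"fewer than {min_terms} terms to start with")

    full = scoring.compute_acs(composites, min_coverage=1.0)
    full_acs = full.acs

    steps = []
    current = list(all_terms)
    step0 = _evaluate_set(scores[current], full_acs, criterion, residual_threshold)
    steps.append(step0)
    for term in order:
        current = [t for t in current if t != term]
        step = _evaluate_set(scores[current], full_acs, criterion, residual_threshold)
        step.removed_term = term
        steps.append(step)
    return ReductionTrace(steps=steps)


def removal_order_by_endorsement(composites: CompositeTable, min_terms: int = 3) -> list[str]:
    """Terms sorted ascending by endorsement (fraction of patients with a
    nonzero composite); ties break lexicographically.  The returned order
    stops when ``min_terms`` would remain."""
    scores = composites.scores
    endorsement = (scores > 0).sum() / scores.notna().sum()
    order = sorted(scores.columns, key=lambda t: (endorsement[t], t))
    return order[: max(len(order) - min_terms, 0)]


def removal_order_by_loading(solution: factor_model.FactorSolution, min_terms: int = 3) -> list[str]:
    """Terms sorted ascending by standardized loading; lexicographic ties."""
    l = solution.loadings_std
    order = sorted(l.index, key=lambda t: (l[t], t))
    return order[: max(len(order) - min_terms, 0)]
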