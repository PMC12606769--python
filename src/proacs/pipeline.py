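"""End-to-end orchestration: impute -> score -> validate -> reduce -> profile.

The pipeline mirrors a cross-sectional psychometric validation of the ACS:
missing-by-design item responses are imputed, composites and the ACS are
computed, then the internal structure (correlations, dimensionality, the
one-factor DWLS model with residual respecification, omega and alpha),
concurrent validity against an external criterion, the term-reduction
robustness trace, and the latent profile analysis are run in sequence.
All randomness funnels through the single seed recorded in the report.

The imputer here is a deliberately simple round-robin conditional-mode
imputer built on classification trees; it is NOT the random-forest
imputation some studies use, and reports label it accordingly so users
know results under heavy missingness are method-dependent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from . import correlation, dimensionality, factor_model, latent_profiles, reduction, scoring
from .exceptions import EstimationError, HeywoodError, ValidationError
from .scoring import TermDefinition


def impute_simple(items: pd.DataFrame, seed: int = 0, max_cycles: int = 10) -> pd.DataFrame:
    """Round-robin conditional imputation of ordinal item responses.

    Initializes missing cells with the per-column mode, then cycles through
    columns predicting each from all others with a depth-limited
    classification tree until no imputed cell changes or ``max_cycles`` is
    reached.  Outputs stay in the observed 0-4 category range and the
    procedure is deterministic under ``seed``.
    """
    X = items.copy()
    mask = X.isna()
    if not mask.to_numpy().any():
        return X
    frac = mask.mean()
    too_missing = frac[frac >= 0.6]
    if len(too_missing):
        raise ValidationError(
            f"columns with >= 60% missingness cannot be imputed: {list(too_missing.index)}"
        )
    if (frac == 1.0).any():
        raise ValidationError("fully missing column")

    for c in X.columns:
        if mask[c].any():
            X.loc[mask[c], c] = X[c].mode().iloc[0]

    cols = [c for c in X.columns if mask[c].any()]
    order = sorted(cols, key=lambda c: mask[c].sum())  # least missing first
    for cycle in range(max_cycles):
        changed = 0
        for j, c in enumerate(order):
            rows = mask[c]
            features = [k for k in X.columns if k != c]
            tree = DecisionTreeClassifier(max_depth=6, random_state=seed + cycle * 1000 + j)
            tree.fit(X.loc[~rows, features], X.loc[~rows, c].astype(int))
            pred = tree.predict(X.loc[rows, features]).astype(float)
            changed += int((pred != X.loc[rows, c].to_numpy()).sum())
            X.loc[rows, c] = pred
        if changed == 0:
            break
    return X


@dataclass
class AnalysisConfig:
    """Settings for :func:`run_validation`."""

    terms: list[TermDefinition]
    grid_source: str | None = None
    imputation: str = "simple_iterative"  # or "none"
    pca_input: str = "pearson"  # or "polychoric"
    residual_threshold: float = 0.20
    min_coverage: float = 1.0
    concurrent_threshold: float = 0.80
    with_reduction: bool = True
    with_lpa: bool = True
    lpa_k_range: tuple[int, int] = (1, 6)
    lpa_starts: int = 20
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.lpa_k_range
        if not (1 <= lo <= hi <= 10):
            raise ValidationError("lpa_k_range must lie within [1, 10]")
        if not (0 < self.residual_threshold < 1):
            raise ValidationError("residual_threshold must lie in (0, 1)")
        if self.imputation not in ("none", "simple_iterative"):
            raise ValidationError(f"unknown imputation mode {self.imputation!r}")
        if self.pca_input not in ("pearson", "polychoric"):
            raise ValidationError(f"unknown pca_input {self.pca_input!r}")


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.md5(
        np.ascontiguousarray(np.nan_to_num(df.to_numpy(dtype=float), nan=-9.0)).tobytes()
    ).hexdigest()


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def run_validation(
    items: pd.DataFrame,
    config: AnalysisConfig,
    criterion: pd.Series | None = None,
) -> dict:
    """Execute the full validation pipeline and return a JSON-ready report.

    Stage failures are caught and recorded under the failing stage's name;
    earlier blocks are preserved.
    """
    config.validate()
    report: dict = {
        "header": {
            "seed": config.seed,
            "imputation": config.imputation,
            "imputer_note": "simple round-robin tree imputer (not random-forest imputation)",
            "pca_input": config.pca_input,
            "n_patients": int(len(items)),
            "n_terms": len(config.terms),
        }
    }
    stage = "impute"
    try:
        if config.imputation == "simple_iterative":
            imputed = impute_simple(items, seed=config.seed)
        else:
            imputed = items
        report["header"]["missing_fraction_raw"] = float(items.isna().mean().mean())

        stage = "composites"
        grid = scoring.load_composite_grid(config.grid_source)
        table = scoring.compute_composites(imputed, config.terms, grid)
        table = scoring.compute_acs(table, min_coverage=config.min_coverage)
        acs = table.acs
        report["composites_hash"] = _hash_frame(table.scores)
        report["acs"] = {
            "mean": _round(float(acs.mean())),
            "sd": _round(float(acs.std(ddof=1))),
            "min": _round(float(acs.min())),
            "max": _round(float(acs.max())),
        }

        stage = "correlation"
        spear = correlation.spearman_matrix(table)
        off = spear.values()[np.triu_indices(len(spear.terms), k=1)]
        report["correlation"] = {
            "spearman_mean": _round(float(np.nanmean(off))),
            "spearman_min": _round(float(np.nanmin(off))),
            "spearman_max": _round(float(np.nanmax(off))),
            "n_effective": spear.n_effective,
        }
        poly = correlation.polychoric_matrix(table)

        stage = "dimensionality"
        corr_for_pca = poly if config.pca_input == "polychoric" else correlation.pearson_matrix(table)
        dim = dimensionality.eigenvalue_ratio_test(corr_for_pca)
        pca = dimensionality.pca_extract(corr_for_pca, composites=table, k=max(dim.retained, 1))
        r_acs_pc1 = float(pd.concat([acs, pca.pc1_scores], axis=1).dropna().corr().iloc[0, 1])
        report["dimensionality"] = {
            "eigenvalues": [_round(float(v)) for v in dim.eigenvalues],
            "ratios": [None if np.isnan(v) else _round(float(v)) for v in dim.ratios],
            "retained": dim.retained,
            "pc1_variance_fraction": _round(float(dim.variance_explained[0])),
            "r_acs_pc1": _round(r_acs_pc1),
        }

        stage = "cfa"
        solution = factor_model.fit_cfa(poly, n=poly.n_effective)
        respecified_pairs: list = []
        if solution.fit is not None:
            pairs = factor_model.residual_screen(solution, threshold=config.residual_threshold)
            if pairs and factor_model.dwls_degrees_of_freedom(len(solution.terms), len(pairs)) >= 1:
                solution = factor_model.fit_cfa(poly, n=poly.n_effective, residual_pairs=pairs)
                respecified_pairs = [list(p) for p in pairs]
        fscores = factor_model.factor_scores(solution, table, orient_with=acs)
        r_acs_factor = float(pd.concat([acs, fscores], axis=1).dropna().corr().iloc[0, 1])
        report["cfa"] = {
            "loadings_std": {t: _round(float(v)) for t, v in solution.loadings_std.items()},
            "loadings_unstd": {t: _round(float(v)) for t, v in solution.loadings_unstd.items()},
            "factor_variance": _round(solution.factor_variance),
            "fit": solution.fit.to_dict() if solution.fit else None,
            "status": solution.status,
            "respecified_pairs": respecified_pairs,
            "r_acs_factor": _round(r_acs_factor),
        }

        stage = "reliability"
        report["reliability"] = {
            "omega": _round(solution.omega) if solution.omega is not None else None,
            "alpha": _round(factor_model.coefficient_alpha(table)),
        }

        stage = "concurrent_validity"
        if criterion is not None:
            joined = pd.concat([acs, criterion], axis=1).dropna()
            r = float(joined.corr().iloc[0, 1])
            report["concurrent_validity"] = {
                "r_acs_criterion": _round(r),
                "meets_threshold": bool(r >= config.concurrent_threshold),
                "threshold": config.concurrent_threshold,
            }

        if config.with_reduction:
            stage = "reduction"
            order = reduction.removal_order_by_endorsement(table)
            trace = reduction.run_reduction(
                table, order, criterion=criterion, residual_threshold=config.residual_threshold
            )
            report["reduction"] = json.loads(
                trace.to_frame().round(6).to_json(orient="records")
            )

        if config.with_lpa:
            stage = "lpa"
            lo, hi = config.lpa_k_range
            solutions = [
                latent_profiles.fit_lpa(
                    table, k, starts=config.lpa_starts, seed=config.seed + 7919 * k
                )
                for k in range(lo, hi + 1)
            ]
            sel = latent_profiles.selection_table(solutions)
            best_k = int(sel.loc[sel["bic_minimal"], "n_classes"].iloc[0])
            best = next(s for s in solutions if s.n_classes == best_k)
            by_class = latent_profiles.acs_by_class(best, table)
            report["lpa"] = {
                "selection": json.loads(sel.round(4).to_json(orient="records")),
                "bic_minimal_k": best_k,
                "class_means": json.loads(best.class_means.round(4).to_json(orient="split")),
                "acs_by_class": json.loads(by_class.table.round(4).to_json(orient="split")),
                "max_profile_distance": _round(float(by_class.profile_distance.to_numpy().max())),
            }
    except (ValidationError, EstimationError, HeywoodError) as err:
        report["error"] = {"stage": stage, "message": str(err)}
    return report


def load_term_definitions(path: str | Path) -> list[TermDefinition]:
    """Read a term-definition CSV (``term_id,attributes``; attributes
    pipe-separated, e.g. ``severity|interference``)."""
    df = pd.read_csv(path)
    if not {"term_id", "attributes"}.issubset(df.columns):
        raise ValidationError("term-definition CSV needs columns term_id,attributes")
    return [
        TermDefinition(row["term_id"], tuple(str(row["attributes"]).split("|")))
        for _, row in df.iterrows()
    ]
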