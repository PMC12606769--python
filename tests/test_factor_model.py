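"""DWLS one-factor model: closed forms, df arithmetic, fit indices, reliability."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import proacs as pa
from proacs.exceptions import EstimationError, HeywoodError, JustIdentifiedError, ValidationError
from proacs.factor_model import dwls_degrees_of_freedom

DATA_DIR = Path(__file__).parent / "data"


def plain_corr(mat, names=None):
    names = names or [f"t{i}" for i in range(mat.shape[0])]
    return pa.CorrelationSet(
        method="polychoric",
        matrix=pd.DataFrame(mat, index=names, columns=names),
        n_effective=500,
    )


class TestDegreesOfFreedom:
    @pytest.mark.parametrize("p,expected", [(8, 20), (16, 104), (17, 119)])
    def test_one_factor_df_accounting(self, p, expected):
        assert dwls_degrees_of_freedom(p) == expected

    def test_freed_residual_pairs_reduce_df(self):
        assert dwls_degrees_of_freedom(16, 3) == 101
        assert dwls_degrees_of_freedom(17, 5) == 114


class TestTriadClosedForm:
    def test_equal_triad_loadings(self):
        """All off-diagonals 0.49 imply standardized loadings
        sqrt(0.49 * 0.49 / 0.49) = 0.7 exactly, with zero discrepancy."""
        m = np.full((3, 3), 0.49)
        np.fill_diagonal(m, 1.0)
        sol = pa.fit_cfa(plain_corr(m), n=500)
        assert np.allclose(sol.loadings_std, 0.7, atol=1e-4)
        assert sol.f_min == pytest.approx(0.0, abs=1e-10)
        assert sol.status == "just_identified"
        assert sol.fit is None

    def test_unequal_triad_matches_formula(self):
        r12, r13, r23 = 0.56, 0.48, 0.42
        m = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
        sol = pa.fit_cfa(plain_corr(m), n=500)
        lam1 = np.sqrt(r12 * r13 / r23)
        lam2 = np.sqrt(r12 * r23 / r13)
        lam3 = np.sqrt(r13 * r23 / r12)
        assert np.allclose(sol.loadings_std, [lam1, lam2, lam3], atol=1e-5)

    def test_heywood_triad_raises(self):
        # r12*r13/r23 > 1 -> standardized loading > 1
        m = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.3], [0.8, 0.3, 1.0]])
        with pytest.raises(HeywoodError):
            pa.fit_cfa(plain_corr(m), n=500)

    def test_too_few_indicators_rejected(self):
        with pytest.raises(ValidationError):
            pa.fit_cfa(plain_corr(np.eye(2)), n=100)


class TestFitIndices:
    def test_chi_square_equal_df_gives_zero_rmsea(self):
        fit = pa.compute_fit_indices(
            chi_square=20.0, df=20, chi_square_baseline=500.0, df_baseline=28,
            n=200, residuals=np.full(28, 0.01),
        )
        assert fit.rmsea == 0.0
        assert fit.rmsea_ci90[0] == 0.0

    def test_perfect_fit(self):
        fit = pa.compute_fit_indices(
            chi_square=0.0, df=5, chi_square_baseline=300.0, df_baseline=10,
            n=200, residuals=np.zeros(10),
        )
        assert fit.srmr == 0.0
        assert fit.cfi == 1.0

    def test_df_zero_rejected(self):
        with pytest.raises(JustIdentifiedError):
            pa.compute_fit_indices(1.0, 0, 10.0, 3, 100, np.zeros(3))

    def test_baseline_df_required(self):
        with pytest.raises(EstimationError):
            pa.compute_fit_indices(1.0, 2, 10.0, 0, 100, np.zeros(3))

    def test_rmsea_ci_brackets_point_estimate(self, lung_cfa):
        _, sol = lung_cfa
        lo, hi = sol.fit.rmsea_ci90
        assert lo <= sol.fit.rmsea <= hi or sol.fit.rmsea == 0.0


class TestRecovery:
    def test_loadings_recovered_from_synthetic_lung_cohort(self, lung_dataset, lung_cfa):
        cfg, _ = lung_dataset
        _, sol = lung_cfa
        assert np.all(np.abs(sol.loadings_std.to_numpy() - cfg.loadings) < 0.07)

    def test_matches_reference_dwls_implementation(self):
        """Standardized loadings within 0.02 of an independent DWLS fit
        (frozen reference outputs) on 5 seeded synthetic datasets."""
        ref = pd.read_csv(DATA_DIR / "lavaan_dwls_reference.csv")
        for seed in range(5):
            cfg = pa.preset_config("lung8", n_patients=300, seed=seed)
            ds = pa.generate_dataset(cfg)
            table = pa.compute_composites(ds.items, cfg.terms)
            poly = pa.polychoric_matrix(table, continuity_correction=False)
            sol = pa.fit_cfa(poly, n=poly.n_effective)
            expected = ref[ref.seed == seed].set_index("term")["loading_std"]
            assert (sol.loadings_std - expected).abs().max() < 0.02

    def test_factor_scores_track_truth_and_acs(self, lung_dataset, lung_composites, lung_cfa):
        _, ds = lung_dataset
        _, sol = lung_cfa
        scores = pa.factor_scores(sol, lung_composites, orient_with=lung_composites.acs)
        assert np.corrcoef(scores, ds.truth.factor)[0, 1] >= 0.85
        assert np.corrcoef(scores, lung_composites.acs)[0, 1] >= 0.95

    def test_freeing_residuals_never_increases_chi_square(self, lung_cfa):
        poly, sol = lung_cfa
        pairs = pa.residual_screen(sol, threshold=0.05)[:2]
        if not pairs:
            pytest.skip("no residual pairs above threshold in this draw")
        re_sol = pa.fit_cfa(poly, n=poly.n_effective, residual_pairs=pairs)
        assert re_sol.fit.chi_square <= sol.fit.chi_square + 1e-6
        assert re_sol.fit.df == sol.fit.df - len(pairs)


class TestResidualScreen:
    def _solution_with_residuals(self, mat):
        terms = [f"t{i}" for i in range(mat.shape[0])]
        return pa.FactorSolution(
            terms=terms,
            loadings_unstd=pd.Series(np.ones(len(terms)), index=terms),
            loadings_std=pd.Series(np.full(len(terms), 0.7), index=terms),
            factor_variance=0.49,
            residual_covariances=[],
            fit=None,
            residual_matrix=pd.DataFrame(mat, index=terms, columns=terms),
            omega=None,
            n=100,
        )

    def test_small_residuals_give_empty_list(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 0.09
        assert pa.residual_screen(self._solution_with_residuals(m)) == []

    def test_single_large_residual_identified(self):
        m = np.zeros((4, 4))
        m[1, 3] = m[3, 1] = 0.25
        assert pa.residual_screen(self._solution_with_residuals(m)) == [("t1", "t3")]

    def test_correlated_error_pair_ranked_first(self):
        """A generator with one correlated-error pair should surface that
        pair at the top of the residual screen in most replicates."""
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(3000 + rep)
            n, p = 600, 10
            f = rng.standard_normal(n)
            lam = np.full(p, 0.6)
            eps = rng.standard_normal((n, p)) * np.sqrt(1 - lam**2)
            # correlated errors between terms 1 and 4
            shared = rng.standard_normal(n)
            for j in (1, 4):
                eps[:, j] = np.sqrt(0.6) * eps[:, j] + np.sqrt(0.4 * (1 - lam[j] ** 2)) * shared
            latent = f[:, None] * lam + eps
            resp = np.searchsorted(np.array([-0.6, 0.3, 1.2]), latent, side="right")
            df = pd.DataFrame(resp.astype(float), columns=[f"t{i}" for i in range(p)])
            poly = pa.polychoric_matrix(df)
            sol = pa.fit_cfa(poly, n=n, allow_heywood=True)
            pairs = pa.residual_screen(sol, threshold=0.10)
            if pairs and set(pairs[0]) == {"t1", "t4"}:
                hits += 1
        assert hits / reps >= 0.9


class TestReliability:
    def test_omega_closed_form(self):
        assert pa.mcdonald_omega([0.7, 0.7, 0.7, 0.7]) == pytest.approx(7.84 / 9.88, abs=1e-12)

    def test_omega_zero_and_limit(self):
        assert pa.mcdonald_omega([0.0, 0.0, 0.0]) == 0.0
        assert pa.mcdonald_omega([0.999] * 5) > 0.99

    def test_omega_heywood_rejected(self):
        with pytest.raises(HeywoodError):
            pa.mcdonald_omega([0.5, 1.0])

    def test_alpha_perfectly_correlated_items(self):
        x = np.arange(10, dtype=float)
        df = pd.DataFrame({"a": x, "b": x})
        assert pa.coefficient_alpha(df) == pytest.approx(1.0)

    def test_alpha_independent_items_near_zero(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.integers(0, 4, size=(5000, 4)).astype(float),
                          columns=list("abcd"))
        assert abs(pa.coefficient_alpha(df)) < 0.05

    def test_alpha_close_to_omega_under_tau_equivalence(self):
        """With equal loadings (tau-equivalence), coefficient alpha and
        McDonald's omega estimate the same reliability."""
        terms = [pa.TermDefinition(f"t{i}", ("severity",)) for i in range(6)]
        cfg = pa.GeneratorConfig(
            n_patients=4000, terms=terms, loadings=np.full(6, 0.65), seed=17,
            attribute_noise_var=0.0,
        )
        ds = pa.generate_dataset(cfg)
        table = pa.compute_composites(ds.items, cfg.terms)
        alpha = pa.coefficient_alpha(table)
        poly = pa.polychoric_matrix(table)
        sol = pa.fit_cfa(poly, n=poly.n_effective)
        # alpha is computed on the ordinal composites (attenuated), so
        # compare against omega of their Pearson-scale loadings
        pear = pa.pearson_matrix(table)
        sol_pear = pa.fit_cfa(pear, n=pear.n_effective)
        omega_pear = pa.mcdonald_omega(sol_pear.loadings_std)
        assert alpha == pytest.approx(omega_pear, abs=0.02)
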