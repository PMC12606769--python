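"""Latent profile EM: edge cases, recovery, selection, entropy, BLRT."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

import proacs as pa
from proacs.exceptions import ValidationError
from proacs.synthetic_data import wellsep_lpa_config


@pytest.fixture(scope="module")
def wellsep_table():
    cfg = wellsep_lpa_config(n_patients=500, seed=4)
    ds = pa.generate_dataset(cfg)
    table = pa.compute_acs(pa.compute_composites(ds.items, cfg.terms))
    return cfg, ds, table


def two_class_frame(n=500, sep=4.0, seed=0):
    """Two diagonal-Gaussian classes separated by ``sep`` SD on every column."""
    rng = np.random.default_rng(seed)
    z = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 4)) + z[:, None] * sep
    return pd.DataFrame(X, columns=list("abcd")), z


class TestFitLpa:
    def test_single_class_matches_column_moments(self, wellsep_table):
        _, _, table = wellsep_table
        sol = pa.fit_lpa(table, 1)
        assert np.allclose(sol.class_means.iloc[0], table.scores.mean(), atol=1e-10)
        assert sol.entropy is None
        assert np.isfinite(sol.bic)

    def test_determinism_under_seed(self, wellsep_table):
        _, _, table = wellsep_table
        s1 = pa.fit_lpa(table, 3, starts=8, seed=42)
        s2 = pa.fit_lpa(table, 3, starts=8, seed=42)
        assert s1.log_likelihood == s2.log_likelihood
        pd.testing.assert_frame_equal(s1.class_means, s2.class_means)

    def test_well_separated_two_classes_recovered(self):
        df, z = two_class_frame(sep=4.0, seed=1)
        sol = pa.fit_lpa(df, 2, starts=10, seed=0)
        assert adjusted_rand_score(z, sol.assignments) >= 0.95

    def test_posterior_rows_sum_to_one(self, wellsep_table):
        _, _, table = wellsep_table
        sol = pa.fit_lpa(table, 4, starts=10, seed=3)
        assert np.allclose(sol.posteriors.sum(axis=1), 1.0, atol=1e-10)

    def test_loglik_monotone_within_em(self, wellsep_table):
        _, _, table = wellsep_table
        sol = pa.fit_lpa(table, 3, starts=5, seed=9)
        diffs = np.diff(sol.ll_history)
        assert np.all(diffs >= -1e-6 * np.abs(sol.log_likelihood))

    def test_rows_with_missing_cells_use_observed_coordinates(self):
        df, z = two_class_frame(sep=4.0, seed=2)
        df_missing = df.copy()
        rng = np.random.default_rng(3)
        mask = rng.random(df.shape) < 0.15
        mask[mask.all(axis=1), 0] = False  # keep >= 1 observed cell per row
        df_missing[mask] = np.nan
        sol = pa.fit_lpa(df_missing, 2, starts=10, seed=0)
        assert adjusted_rand_score(z, sol.assignments) >= 0.9

    def test_matches_sklearn_loglik_on_complete_data(self):
        """Independent mixture implementation as oracle: with class-varying
        diagonal covariances our EM should find a log-likelihood at least as
        good as sklearn's GaussianMixture (both at their best of 10 starts),
        up to convergence slack."""
        df, _ = two_class_frame(sep=3.0, seed=5)
        ours = pa.fit_lpa(df, 2, starts=10, seed=1, shared_variances=False)
        gm = GaussianMixture(2, covariance_type="diag", n_init=10, random_state=1,
                             tol=1e-6, max_iter=500, reg_covar=0.05).fit(df.to_numpy())
        sk_ll = gm.score(df.to_numpy()) * len(df)
        assert ours.log_likelihood >= sk_ll - 1.0

    def test_k_too_large_for_n_rejected(self):
        df, _ = two_class_frame(n=30, seed=6)
        with pytest.raises(ValidationError):
            pa.fit_lpa(df, 4)


class TestEntropy:
    def test_degenerate_posteriors_give_one(self):
        P = np.zeros((50, 3))
        P[np.arange(50), np.arange(50) % 3] = 1.0
        assert pa.entropy_statistic(P) == pytest.approx(1.0)

    def test_uniform_posteriors_give_zero(self):
        P = np.full((50, 4), 0.25)
        assert pa.entropy_statistic(P) == pytest.approx(0.0)

    def test_single_class_not_applicable(self):
        assert pa.entropy_statistic(np.ones((10, 1))) is None

    def test_high_entropy_for_separated_classes(self, wellsep_table):
        _, _, table = wellsep_table
        sol = pa.fit_lpa(table, 4, starts=10, seed=5)
        assert sol.entropy >= 0.85


class TestSelection:
    def test_loglik_nondecreasing_in_k(self, wellsep_table):
        _, _, table = wellsep_table
        sols = [pa.fit_lpa(table, k, starts=10, seed=100 + k) for k in range(1, 5)]
        sel = pa.selection_table(sols)
        assert np.all(np.diff(sel["log_likelihood"]) >= -1e-6)

    def test_avg_posterior_bounds(self, wellsep_table):
        _, _, table = wellsep_table
        sol = pa.fit_lpa(table, 3, starts=10, seed=2)
        assert np.all(sol.avg_posterior >= 1.0 / 3 - 1e-12)
        assert np.all(sol.avg_posterior <= 1.0)

    def test_mismatched_data_rejected(self, wellsep_table):
        _, _, table = wellsep_table
        df, _ = two_class_frame(seed=7)
        s1 = pa.fit_lpa(table, 2, starts=5, seed=0)
        s2 = pa.fit_lpa(df, 2, starts=5, seed=0)
        with pytest.raises(ValidationError):
            pa.selection_table([s1, s2])

    def test_bic_identifies_four_classes_in_wellsep_regime(self, wellsep_table):
        _, _, table = wellsep_table
        sols = [pa.fit_lpa(table, k, starts=15, seed=50 + k) for k in range(1, 7)]
        sel = pa.selection_table(sols)
        assert int(sel.loc[sel["bic_minimal"], "n_classes"].iloc[0]) == 4


class TestBlrt:
    def test_deterministic_under_seed(self):
        df, _ = two_class_frame(n=120, sep=0.0, seed=8)
        r1 = pa.bootstrap_lrt(df, k=2, replicates=19, seed=5, starts=3)
        r2 = pa.bootstrap_lrt(df, k=2, replicates=19, seed=5, starts=3)
        assert r1.p_value == r2.p_value

    def test_detects_true_extra_class(self):
        df, _ = two_class_frame(n=300, sep=3.0, seed=9)
        res = pa.bootstrap_lrt(df, k=2, replicates=19, seed=1, starts=4)
        assert res.p_value <= 0.05

    def test_k_one_rejected(self):
        df, _ = two_class_frame(seed=10)
        with pytest.raises(ValidationError):
            pa.bootstrap_lrt(df, k=1)


class TestAcsByClass:
    def test_identical_class_means_give_zero_distance(self, wellsep_table):
        _, _, table = wellsep_table
        sol = pa.fit_lpa(table, 2, starts=5, seed=0)
        sol.class_means.iloc[1] = sol.class_means.iloc[0]
        out = pa.acs_by_class(sol, table)
        assert out.profile_distance.loc[0, 1] == 0.0

    def test_trading_classes_share_acs_but_differ_in_profile(self, wellsep_table):
        """Classes trading predominant symptoms at equal total burden have
        nearly identical mean ACS yet clearly distinct mean profiles."""
        _, _, table = wellsep_table
        sols = [pa.fit_lpa(table, k, starts=15, seed=70 + k) for k in range(1, 7)]
        sel = pa.selection_table(sols)
        best = next(s for s in sols if s.n_classes == 4)
        out = pa.acs_by_class(best, table)
        ordered = out.table.sort_values("acs_mean")
        c3, c4 = ordered.index[1], ordered.index[2]
        assert abs(ordered["acs_mean"].iloc[1] - ordered["acs_mean"].iloc[2]) < 0.15
        assert out.profile_distance.loc[c3, c4] > 1.0

    def test_parameter_recovery_at_larger_n(self):
        """At n=1000 the four-class fit recovers mixing proportions within
        0.05 and class mean profiles within 0.2 composite units."""
        cfg = wellsep_lpa_config(n_patients=1000, seed=77)
        ds = pa.generate_dataset(cfg)
        table = pa.compute_acs(pa.compute_composites(ds.items, cfg.terms))
        sol = pa.fit_lpa(table, 4, starts=15, seed=5)
        truth_means = table.scores.groupby(ds.truth.classes).mean()
        order = np.argsort(truth_means.mean(axis=1).to_numpy())
        assert np.abs(sol.class_means.to_numpy() - truth_means.to_numpy()[order]).max() < 0.2
        props = np.array([c.proportion for c in cfg.class_spec])[order]
        assert np.abs(sol.mixing - props).max() < 0.05

    def test_class_sizes_match_generator_proportions(self, wellsep_table):
        cfg, ds, table = wellsep_table
        sol = pa.fit_lpa(table, 4, starts=15, seed=6)
        sizes = np.sort(sol.class_sizes)
        expected = np.sort([c.proportion for c in cfg.class_spec]) * cfg.n_patients
        assert np.all(np.abs(sizes - expected) <= 0.05 * cfg.n_patients)
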