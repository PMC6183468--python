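"""Grouping, standardization, covariance model, Bayes factors and the
RDA outlier pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from flounderscape.coalescent import DemographicParams, simulate_snp_panel
from flounderscape.envscan import (CovarianceModel, assign_groups, bf_scan,
                                   bf_permutation_null, env_bayes_factor,
                                   estimate_covariance, group_allele_freqs,
                                   outlier_env_regression,
                                   rda_fit, rda_outliers,
                                   rda_permutation_null, standardize_env,
                                   DEFAULT_BF_G)
from flounderscape.errors import InvalidParameterError
from flounderscape.genotypes import hwe_pvalues
from flounderscape.study import SimStudyConfig, simulate_study
from tests.conftest import make_matrix

BREAKS = [33.9, 35.25, 38.0, 40.1]


def study_fixture(seed=0, n_loci=300, n_clinal=8, slope=2.0):
    sd = simulate_study(SimStudyConfig(n_loci=n_loci, n_clinal_loci=n_clinal,
                                       cline_slope=slope, seed=seed))
    lat = sd.matrix.samples["lat"].to_numpy()
    grouping = assign_groups(lat, BREAKS)
    env_num = sd.env.drop(columns="id")
    return sd, grouping, env_num


class TestAssignGroups:
    def test_no_breaks_single_group(self):
        g = assign_groups([30.0, 35.0, 40.0], [])
        assert g.n_groups == 1

    def test_individual_on_break_goes_north(self):
        g = assign_groups([34.0, 35.25, 36.0], [35.25])
        # northern side = larger index (index counts breaks at or south)
        assert g.group_index.tolist() == [0, 1, 1]

    def test_synthetic_five_group_counts(self):
        rng = np.random.default_rng(0)
        lats = np.concatenate([rng.uniform(lo, hi, n) for (lo, hi, n) in [
            (29, 33.8, 37), (34.0, 35.2, 60), (35.3, 37.9, 41),
            (38.1, 40.0, 54), (40.2, 41.5, 40)]])
        g = assign_groups(lats, BREAKS)
        assert g.sizes().tolist() == [37, 60, 41, 54, 40]

    def test_empty_group_dropped_with_reindex(self):
        g = assign_groups([30.0, 30.5, 41.0], [35.0, 36.0])
        assert g.n_groups == 2
        assert g.group_index.tolist() == [0, 0, 1]


class TestStandardizeEnv:
    def grouping(self, idx):
        from flounderscape.envscan import PopulationGrouping
        return PopulationGrouping(np.array([]), np.asarray(idx))

    def test_identical_group_means_error(self):
        env = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(InvalidParameterError, match="x"):
            standardize_env(env, self.grouping([0, 0, 1, 1]))

    def test_two_groups_give_plus_minus_one(self):
        env = pd.DataFrame({"x": [1.0, 3.0, 10.0, 14.0]})
        out = standardize_env(env, self.grouping([0, 0, 1, 1]))
        assert out.standardized["x"].tolist() == [-1.0, 1.0]

    def test_five_groups_closed_form(self):
        env = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        out = standardize_env(env, self.grouping([0, 1, 2, 3, 4]))
        z = (np.arange(1, 6) - 3.0) / np.std(np.arange(1, 6))
        assert np.allclose(out.standardized["x"], z, atol=1e-12)

    def test_standardized_moments_exact(self):
        rng = np.random.default_rng(1)
        env = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        out = standardize_env(env, self.grouping(np.repeat(np.arange(5), 8)))
        assert np.allclose(out.standardized.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(out.standardized.std(axis=0, ddof=0), 1,
                           atol=1e-12)


class TestCovariance:
    def test_identical_frequencies_give_ridge_identity(self):
        freqs = np.tile(np.linspace(0.2, 0.8, 50), (4, 1))
        cov = estimate_covariance(freqs, ridge=0.01)
        assert np.allclose(cov.omega, 0.01 * np.eye(4), atol=1e-12)

    def test_positive_definite_for_random_input(self):
        rng = np.random.default_rng(0)
        freqs = rng.uniform(0.05, 0.95, (5, 200))
        cov = estimate_covariance(freqs)
        np.linalg.cholesky(cov.omega)     # raises if not PD
        W = cov.whitener()
        assert np.allclose(W @ cov.omega @ W, np.eye(5), atol=1e-8)

    def test_weakly_related_groups_have_small_cross_covariance(self):
        """Near-independent samples show only the structural
        anti-correlation (-1/(P-1)) induced by centering on the
        across-group mean, not genuine shared drift."""
        ratios = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            G = simulate_snp_panel((40, 40),
                                   DemographicParams(1000, 1000, 0.25),
                                   400, maf_cutoff=0.05, rng=rng)
            m = make_matrix(G)
            labels = np.repeat(np.arange(4), 20)
            freqs = np.array([m.take_individuals(
                np.flatnonzero(labels == g)).alt_allele_freq()
                for g in range(4)])
            cov = estimate_covariance(freqs, ridge=0.0)
            off = cov.omega[0, 1]
            diag = np.sqrt(cov.omega[0, 0] * cov.omega[1, 1])
            ratios.append(off / diag)
        # structural expectation -1/3 under exchangeable sampling noise
        assert abs(np.mean(ratios) + 1 / 3) < 0.15
        assert np.max(np.abs(ratios)) < 0.6


class TestBayesFactor:
    def cov(self, P=5):
        return CovarianceModel(np.eye(P), 0.0, 100)

    def test_no_association_closed_form(self):
        P = 5
        e = np.array([-1.2, -0.6, 0.0, 0.6, 1.2])
        bf = env_bayes_factor(np.zeros(P), e, self.cov(), g=7.0)
        assert bf == pytest.approx((1 + 7.0) ** -0.5, abs=1e-12)
        assert bf < 1

    def test_matches_quadrature_of_marginal_likelihood(self):
        """Numerical integration over the slope prior reproduces the
        closed form to 1e-6."""
        rng = np.random.default_rng(0)
        P = 5
        omega = np.diag(rng.uniform(0.005, 0.03, P))
        omega += 0.002
        cov = CovarianceModel(omega, 0.0, 500)
        x = rng.normal(0, 0.15, P)
        e = np.array([-1.5, -0.5, 0.0, 0.5, 1.5])
        g = DEFAULT_BF_G
        W = cov.whitener()
        y = W @ x
        X = W @ np.column_stack([np.ones(P), e])
        # project out the whitened intercept (flat prior, shared by both
        # models), then integrate the Gaussian slope prior numerically
        q, _ = np.linalg.qr(X[:, :1])
        M = np.eye(P) - q @ q.T
        yp = M @ y
        ep = M @ X[:, 1]
        s2 = g / (ep @ ep)

        def integrand(beta):
            return (np.exp(-0.5 * ((yp - beta * ep) ** 2).sum())
                    * np.exp(-0.5 * beta ** 2 / s2)
                    / np.sqrt(2 * np.pi * s2))

        num, _ = quad(integrand, -10, 10, epsabs=1e-12, limit=200)
        den = np.exp(-0.5 * (yp ** 2).sum())
        oracle = num / den
        got = env_bayes_factor(x, e, cov, g=g)
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_invariant_to_allele_label_swap(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5)
        e = rng.normal(size=5)
        cov = self.cov()
        assert env_bayes_factor(x, e, cov) == pytest.approx(
            env_bayes_factor(-x, e, cov), rel=1e-12)

    def test_too_few_groups_errors(self):
        with pytest.raises(InvalidParameterError):
            env_bayes_factor(np.zeros(2), np.zeros(2), self.cov(2))

    def test_bf_increases_with_association_amplitude(self):
        e = np.array([-1.2, -0.6, 0.0, 0.6, 1.2])
        cov = self.cov()
        bfs = [env_bayes_factor(a * e, e, cov) for a in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(bfs) > 0)


class TestBfScan:
    def scan_setup(self, seed=0):
        sd, grouping, env_num = study_fixture(seed=seed)
        env_tab = standardize_env(env_num, grouping)
        freqs = group_allele_freqs(sd.matrix, grouping)
        keep = hwe_pvalues(sd.matrix) >= 0.01
        cov = estimate_covariance(freqs[:, keep])
        return sd, grouping, env_num, env_tab, cov

    def test_infinite_threshold_flags_nothing(self):
        sd, grouping, _, env_tab, cov = self.scan_setup()
        scan = bf_scan(sd.matrix, grouping, env_tab, cov,
                       threshold=np.inf)
        hit_cols = [c for c in scan.columns if c.endswith("_hit")]
        assert not scan[hit_cols].to_numpy().any()

    def test_scan_bf_matches_single_locus_function(self):
        sd, grouping, _, env_tab, cov = self.scan_setup()
        scan = bf_scan(sd.matrix, grouping, env_tab, cov)
        freqs = group_allele_freqs(sd.matrix, grouping)
        pbar = freqs.mean(axis=0)
        j = 4
        x = (freqs[:, j] - pbar[j]) / np.sqrt(pbar[j] * (1 - pbar[j]))
        e = env_tab.standardized["bottom_temp"].to_numpy()
        assert scan["bf_bottom_temp"].iloc[j] == pytest.approx(
            env_bayes_factor(x, e, cov), rel=1e-10)

    def test_clinal_loci_flagged_for_their_variable(self):
        sd, grouping, _, env_tab, cov = self.scan_setup(seed=3)
        scan = bf_scan(sd.matrix, grouping, env_tab, cov)
        hits = scan["bottom_temp_hit"].to_numpy()
        assert hits[sd.clinal_mask].sum() >= 6          # of 8
        assert hits[~sd.clinal_mask].mean() <= 0.02

    def test_permuting_group_labels_destroys_clinal_flags(self):
        sd, grouping, env_num, env_tab, cov = self.scan_setup(seed=4)
        rng = np.random.default_rng(0)
        perm_env = env_num.iloc[rng.permutation(len(env_num))].reset_index(
            drop=True)
        perm_tab = standardize_env(perm_env, grouping)
        scan_p = bf_scan(sd.matrix, grouping, perm_tab, cov)
        hits = scan_p["bottom_temp_hit"].to_numpy()
        assert hits[sd.clinal_mask].sum() <= 2


class TestBfPermutationNull:
    def test_observed_env_as_its_own_permutation_gives_ks_identity(self):
        sd, grouping, env_num = study_fixture(seed=1, n_loci=120, n_clinal=0)
        env_tab = standardize_env(env_num, grouping)
        freqs = group_allele_freqs(sd.matrix, grouping)
        cov = estimate_covariance(freqs)
        scan = bf_scan(sd.matrix, grouping, env_tab, cov)
        bf = scan["bf_bottom_temp"].to_numpy()
        d, p = stats.ks_2samp(bf, np.concatenate([bf, bf]))
        assert d == 0.0 and p == 1.0

    def test_binomial_exact_matches_summation_oracle(self):
        from fractions import Fraction
        from math import comb
        k, n = 10, 1137
        p0 = Fraction(2, 1137)
        oracle = float(sum(Fraction(comb(n, i)) * p0 ** i
                           * (1 - p0) ** (n - i)
                           for i in range(k, n + 1)))
        got = stats.binomtest(k, n, float(p0), alternative="greater").pvalue
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_null_summary_columns_and_ranges(self):
        sd, grouping, env_num = study_fixture(seed=2, n_loci=150, n_clinal=0)
        freqs = group_allele_freqs(sd.matrix, grouping)
        cov = estimate_covariance(freqs)
        out = bf_permutation_null(sd.matrix, grouping, env_num, cov,
                                  n_perm=3, rng=np.random.default_rng(0))
        assert set(out.columns) == {"variable", "observed_count",
                                    "expected_count", "ks_stat", "ks_p",
                                    "binom_p"}
        assert ((out["binom_p"] >= 0) & (out["binom_p"] <= 1)).all()


class TestRda:
    def test_response_orthogonal_to_predictors_gives_zero_axes(self):
        rng = np.random.default_rng(0)
        n = 60
        X = rng.normal(size=(n, 2))
        X -= X.mean(axis=0)
        noise = rng.normal(size=(n, 30))
        noise -= noise.mean(axis=0)
        # remove any projection of the (centered) response on X
        q, _ = np.linalg.qr(X)
        Y = noise - q @ (q.T @ noise)
        res = rda_fit(Y, X)
        assert res.singular_values.max() < 1e-8

    def test_single_predictor_ranking_equals_slope_ranking(self):
        rng = np.random.default_rng(1)
        n, L = 50, 40
        x = rng.normal(size=(n, 1))
        Y = rng.normal(size=(n, L))
        Y -= Y.mean(axis=0)
        xc = x - x.mean()
        res = rda_fit(Y, xc)
        slopes = np.abs((xc.T @ Y).ravel() / (xc.T @ xc).item())
        got = np.argsort(np.abs(res.locus_scores[:, 0]))
        assert np.array_equal(got, np.argsort(slopes))

    def test_locus_scores_match_eigen_oracle(self):
        rng = np.random.default_rng(2)
        n, L = 40, 25
        X = rng.normal(size=(n, 3))
        Y = X @ rng.normal(size=(3, L)) + 0.5 * rng.normal(size=(n, L))
        Y -= Y.mean(axis=0)
        X -= X.mean(axis=0)
        res = rda_fit(Y, X)
        Yhat = X @ np.linalg.lstsq(X, Y, rcond=None)[0]
        w, v = np.linalg.eigh(Yhat.T @ Yhat)
        order = np.argsort(w)[::-1][:3]
        for a in range(3):
            oracle = v[:, order[a]] * np.sqrt(w[order[a]])
            got = res.locus_scores[:, a]
            assert (np.allclose(got, oracle, atol=1e-8)
                    or np.allclose(got, -oracle, atol=1e-8))

    def test_collinear_predictor_named(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])
        Y = rng.normal(size=(30, 10))
        with pytest.raises(InvalidParameterError, match="salinity"):
            rda_fit(Y - Y.mean(0), X, env_names=["dist", "temp", "salinity"])

    def test_constrained_variance_bounded_by_total(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 3))
        Y = rng.normal(size=(50, 20))
        res = rda_fit(Y - Y.mean(0), X - X.mean(0))
        assert 0 < res.prop_constrained < 1


class TestRdaOutliers:
    def test_constant_scores_no_flags(self):
        scores = np.ones((30, 3))
        assert not rda_outliers(scores).any()

    def test_extreme_locus_on_second_axis_flagged(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(200, 3))
        mu, sd = scores[:, 1].mean(), scores[:, 1].std()
        scores[7, 1] = mu + 6 * sd
        flags = rda_outliers(scores)
        assert flags[7]

    def test_flags_invariant_to_axis_sign_flip(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(100, 3))
        scores[3, 0] = 10.0
        f1 = rda_outliers(scores)
        flipped = scores.copy()
        flipped[:, 0] *= -1
        assert np.array_equal(f1, rda_outliers(flipped))

    def test_fewer_axes_than_requested_warns_and_uses_all(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(50, 2))
        flags = rda_outliers(scores, k_axes=3)
        assert flags.shape == (50,)


class TestOutlierRegression:
    def test_constant_frequency_not_significant(self):
        m = make_matrix(np.ones((30, 2), np.int8))
        env = pd.DataFrame({"temp": np.linspace(0, 1, 30)})
        out = outlier_env_regression(m, env, np.array([True, False]))
        assert out["r2"].iloc[0] == 0.0
        assert not out["significant"].iloc[0]

    def test_perfect_collinearity(self):
        dos = np.tile([0, 1, 2], 10)[:30]
        m = make_matrix(dos.reshape(-1, 1).astype(np.int8))
        env = pd.DataFrame({"temp": dos / 2.0})
        out = outlier_env_regression(m, env, np.array([True]))
        assert out["r2"].iloc[0] == pytest.approx(1.0)
        assert out["significant"].iloc[0]

    def test_matches_closed_form_t_test(self):
        rng = np.random.default_rng(0)
        n = 30
        dos = rng.integers(0, 3, (n, 1)).astype(np.int8)
        m = make_matrix(dos)
        x = rng.normal(size=n)
        env = pd.DataFrame({"temp": x})
        out = outlier_env_regression(m, env, np.array([True]))
        y = dos[:, 0] / 2.0
        r = np.corrcoef(x, y)[0, 1]
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert out["r2"].iloc[0] == pytest.approx(r ** 2, abs=1e-10)
        assert out["p"].iloc[0] == pytest.approx(p, abs=1e-10)

    def test_zero_variance_env_errors(self):
        m = make_matrix(np.ones((10, 1), np.int8))
        env = pd.DataFrame({"temp": np.zeros(10)})
        with pytest.raises(InvalidParameterError):
            outlier_env_regression(m, env, np.array([True]))


class TestRdaPermutationNull:
    def test_clinal_signal_gives_small_association_p(self):
        sd, grouping, env_num = study_fixture(seed=5, n_loci=300,
                                              n_clinal=8, slope=2.0)
        out = rda_permutation_null(sd.matrix, env_num, n_perm=200,
                                   rng=np.random.default_rng(0))
        assert out["p_significant_count"] < 0.05
        assert 0 < out["p_outlier_count"] <= 1

    def test_pvalue_formula_lower_bound(self):
        sd, grouping, env_num = study_fixture(seed=6, n_loci=120, n_clinal=0)
        out = rda_permutation_null(sd.matrix, env_num, n_perm=30,
                                   rng=np.random.default_rng(1))
        assert out["p_outlier_count"] >= 1 / 31
        assert len(out["perm_outliers"]) == 30
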