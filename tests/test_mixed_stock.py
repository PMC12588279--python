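import math

import numpy as np
import pytest

from finmix.mixed_stock import (
    BaselineMatrix,
    MixtureCounts,
    gelman_rubin,
    mixture_log_likelihood,
    msa_em,
    msa_gibbs,
    summarize_contributions,
)


class TestBaselineMatrix:
    def test_rejects_zero_row(self):
        with pytest.raises(ValueError, match="zero total"):
            BaselineMatrix(["a", "b"], ["x"], np.array([[3], [0]]))

    def test_rejects_empty_column(self):
        with pytest.raises(ValueError, match="nowhere"):
            BaselineMatrix(["a"], ["x", "y"], np.array([[3, 0]]))

    def test_frequencies_are_row_mles(self):
        b = BaselineMatrix(["a", "b"], ["x", "y"], np.array([[3, 1], [2, 2]]))
        np.testing.assert_allclose(b.frequencies(), [[0.75, 0.25], [0.5, 0.5]])

    def test_csv_roundtrip(self, tmp_path):
        b = BaselineMatrix(["a", "b"], ["x", "y"], np.array([[3, 1], [2, 2]]))
        path = tmp_path / "b.csv"
        b.to_csv(path)
        back = BaselineMatrix.from_csv(path)
        assert back.sources == b.sources and back.haplotypes == b.haplotypes
        assert (back.counts == b.counts).all()


class TestGelmanRubin:
    def test_hand_computed_example(self):
        # chains {1,2,3} and {2,3,4}: W = mean(1, 1) = 1,
        # B/n = var([2, 3], ddof=1) = 0.5, var+ = (2/3)*1 + 0.5 = 7/6,
        # R = sqrt(7/6)
        rhat = gelman_rubin(np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]]))
        assert rhat == pytest.approx(math.sqrt(7 / 6), abs=1e-12)

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(5)
        chains = rng.normal(size=(2, 5000))
        rhat = gelman_rubin(chains)
        assert 1.0 <= rhat <= 1.05

    def test_divergent_constant_chains_flagged(self):
        rhat = gelman_rubin(np.array([[0.0] * 5, [10.0] * 5]))
        assert math.isinf(rhat)

    def test_degenerate_equal_constant_chains_converged(self):
        rhat = gelman_rubin(np.array([[2.0] * 5, [2.0] * 5]))
        assert rhat == 1.0

    def test_requires_two_chains(self):
        with pytest.raises(ValueError, match="two chains"):
            gelman_rubin(np.array([[1.0, 2.0]]))

    def test_per_parameter_shape(self):
        rng = np.random.default_rng(0)
        rhat = gelman_rubin(rng.normal(size=(3, 100, 4)))
        assert rhat.shape == (4,)


class TestMsaEm:
    def test_diagnostic_closed_form(self, diagnostic_baseline, diagnostic_mixture):
        theta = msa_em(diagnostic_baseline, diagnostic_mixture)
        np.testing.assert_allclose(theta, [0.3, 0.7], atol=1e-8)

    def test_matches_grid_search_with_shared_haplotypes(self):
        baseline = BaselineMatrix(
            ["A", "B"], ["x", "y", "z"],
            np.array([[60, 30, 10], [10, 30, 60]]),
        )
        mixture = MixtureCounts(["x", "y", "z"], np.array([40, 35, 25]))
        theta = msa_em(baseline, mixture)
        # brute-force likelihood grid over theta in [0, 1], step 1e-4
        q = baseline.frequencies()
        x = mixture.counts
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        lls = [
            mixture_log_likelihood(np.array([t, 1 - t]), q, x) for t in grid
        ]
        best = grid[int(np.argmax(lls))]
        assert theta[0] == pytest.approx(best, abs=1e-3)

    def test_boundary_mle(self):
        baseline = BaselineMatrix(
            ["A", "B"], ["x", "y"], np.array([[30, 10], [10, 30]])
        )
        # mixture exactly proportional to source A's frequency row
        mixture = MixtureCounts(["x", "y"], np.array([75, 25]))
        theta = msa_em(baseline, mixture)
        # EM approaches the boundary geometrically; 1e-4 reflects the stop rule
        np.testing.assert_allclose(theta, [1.0, 0.0], atol=1e-4)

    def test_loglik_monotone_by_construction(self, diagnostic_baseline):
        # the assertion inside msa_em fires on any decrease; a run completing
        # on an awkward mixture is the property check
        mixture = MixtureCounts(["X", "Y"], np.array([1, 99]))
        theta = msa_em(diagnostic_baseline, mixture)
        assert theta.sum() == pytest.approx(1.0)

    def test_label_permutation_invariance(self):
        baseline = BaselineMatrix(
            ["A", "B", "C"], ["x", "y", "z"],
            np.array([[60, 30, 10], [10, 60, 30], [5, 15, 80]]),
        )
        mixture = MixtureCounts(["x", "y", "z"], np.array([40, 35, 25]))
        theta = msa_em(baseline, mixture)
        perm = [2, 0, 1]
        baseline_p = BaselineMatrix(
            [baseline.sources[i] for i in perm],
            baseline.haplotypes,
            baseline.counts[perm],
        )
        theta_p = msa_em(baseline_p, mixture)
        np.testing.assert_allclose(theta_p, theta[perm], atol=1e-9)


class TestMsaGibbs:
    def test_single_source_degenerate(self):
        baseline = BaselineMatrix(["only"], ["x", "y"], np.array([[5, 5]]))
        mixture = MixtureCounts(["x", "y"], np.array([3, 7]))
        post = msa_gibbs(baseline, mixture, n_iter=200, burn_in=100,
                         n_chains=2, seed=0)
        assert (post.draws == 1.0).all()
        np.testing.assert_allclose(post.point, [1.0])
        np.testing.assert_allclose(post.ci95, [[1.0, 1.0]])

    def test_diagnostic_matches_analytic_dirichlet_posterior(
        self, diagnostic_baseline, diagnostic_mixture
    ):
        # with diagnostic haplotypes and baseline frequencies pinned
        # (alpha_q -> 0), assignments are deterministic and
        # theta | data ~ Dirichlet(alpha + 30, alpha + 70)
        alpha = 0.5
        post = msa_gibbs(
            diagnostic_baseline, diagnostic_mixture,
            n_iter=6000, burn_in=1000, n_chains=4, seed=7,
            alpha_theta=alpha, alpha_q=1e-9,
        )
        expected = (alpha + 30) / (2 * alpha + 100)
        chain_means = post.draws[:, :, 0].mean(axis=1)
        mc_se = chain_means.std(ddof=1) / math.sqrt(len(chain_means))
        assert abs(post.point[0] - expected) < 3 * max(mc_se, 1e-4)

    def test_gibbs_agrees_with_em_on_diagnostic_problem(
        self, diagnostic_baseline, diagnostic_mixture
    ):
        em = msa_em(diagnostic_baseline, diagnostic_mixture)
        post = msa_gibbs(
            diagnostic_baseline, diagnostic_mixture,
            n_iter=6000, burn_in=1000, n_chains=4, seed=8, alpha_q=1e-9,
        )
        chain_means = post.draws[:, :, 0].mean(axis=1)
        mc_se = chain_means.std(ddof=1) / 2
        # posterior mean shrinks toward the prior by ~alpha/(n + S*alpha)
        assert abs(post.point[0] - em[0]) < 3 * max(mc_se, 1e-4) + 0.01

    def test_draws_on_simplex(self, preset_baseline, preset_mixture):
        baseline, _ = preset_baseline
        post = msa_gibbs(baseline, preset_mixture, n_iter=600, burn_in=300,
                         n_chains=2, seed=1)
        totals = post.draws.sum(axis=2)
        np.testing.assert_allclose(totals, 1.0, atol=1e-12)
        assert (post.draws >= 0).all()

    def test_ci_brackets_point(self, preset_baseline, preset_mixture):
        baseline, _ = preset_baseline
        post = msa_gibbs(baseline, preset_mixture, n_iter=2000, burn_in=500,
                         n_chains=2, seed=2)
        assert (post.ci95[:, 0] <= post.point).all()
        assert (post.point <= post.ci95[:, 1]).all()

    def test_seeded_reproducibility(self, diagnostic_baseline, diagnostic_mixture):
        kw = dict(n_iter=500, burn_in=200, n_chains=2, seed=5)
        p1 = msa_gibbs(diagnostic_baseline, diagnostic_mixture, **kw)
        p2 = msa_gibbs(diagnostic_baseline, diagnostic_mixture, **kw)
        assert (p1.draws == p2.draws).all()

    def test_unknown_haplotypes_excluded_with_count(self, diagnostic_baseline):
        mixture = MixtureCounts(["X", "Y", "GHOST"], np.array([30, 60, 10]))
        post = msa_gibbs(diagnostic_baseline, mixture, n_iter=400, burn_in=200,
                         n_chains=2, seed=0)
        assert post.excluded_haplotypes == {"GHOST": 10}

    def test_all_unknown_rejected(self, diagnostic_baseline):
        mixture = MixtureCounts(["GHOST"], np.array([10]))
        with pytest.raises(ValueError, match="no mixture haplotype"):
            msa_gibbs(diagnostic_baseline, mixture, n_iter=400, burn_in=200,
                      n_chains=2, seed=0)

    def test_single_chain_flagged_unconverged(
        self, diagnostic_baseline, diagnostic_mixture
    ):
        post = msa_gibbs(diagnostic_baseline, diagnostic_mixture, n_iter=400,
                         burn_in=200, n_chains=1, seed=0)
        assert post.psrf is None and not post.converged

    def test_invalid_iteration_budget(self, diagnostic_baseline, diagnostic_mixture):
        with pytest.raises(ValueError, match="exceed"):
            msa_gibbs(diagnostic_baseline, diagnostic_mixture, n_iter=100,
                      burn_in=100, n_chains=2, seed=0)

    def test_preset_smoke_converges(self, preset_baseline, preset_mixture):
        baseline, _ = preset_baseline
        post = msa_gibbs(baseline, preset_mixture, n_iter=10_000, burn_in=5_000,
                         n_chains=4, seed=11)
        assert post.psrf is not None
        assert post.max_psrf() < 1.2
        assert post.converged


class TestSummarizeContributions:
    def _post(self, seed=0):
        baseline = BaselineMatrix(
            ["A", "B", "C"], ["x", "y", "z"],
            np.array([[50, 0, 0], [0, 50, 0], [0, 0, 50]]),
        )
        mixture = MixtureCounts(["x", "y", "z"], np.array([80, 20, 0]))
        return msa_gibbs(baseline, mixture, n_iter=4000, burn_in=1000,
                         n_chains=2, seed=seed, alpha_q=1e-9)

    def test_all_mass_in_reporting_sources(self):
        summary = summarize_contributions(
            self._post(), {"A", "B"}, detection_floor=0.01
        )
        assert summary.detected_unreported == []
        assert set(summary.detected) == {"A", "B"}

    def test_empty_reporting_set_complement(self):
        summary = summarize_contributions(self._post(), set(),
                                          detection_floor=0.01)
        assert summary.detected_unreported == summary.detected

    def test_unknown_reporting_source_rejected(self):
        with pytest.raises(ValueError, match="not in the baseline"):
            summarize_contributions(self._post(), {"Z"})

    def test_detected_but_unreported_recovery(self):
        # six true contributors, three of them in regions with reported trade
        rng_seed = 21
        sources = [f"S{i}" for i in range(9)]
        haps = [f"h{i}" for i in range(9)]
        counts = np.diag([50] * 9)
        baseline = BaselineMatrix(sources, haps, counts)
        theta_true = np.array([0.2, 0.2, 0.15, 0.15, 0.15, 0.15, 0, 0, 0])
        rng = np.random.default_rng(rng_seed)
        x = rng.multinomial(500, theta_true)  # diagnostic: haplotype = source
        mixture = MixtureCounts(haps, x)
        post = msa_gibbs(baseline, mixture, n_iter=4000, burn_in=1000,
                         n_chains=2, seed=3, alpha_q=1e-9)
        summary = summarize_contributions(
            post, {"S0", "S1", "S2"}, detection_floor=0.01
        )
        assert set(summary.detected) == {"S0", "S1", "S2", "S3", "S4", "S5"}
        assert set(summary.detected_unreported) == {"S3", "S4", "S5"}
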