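"""Stage II: augmentation simulation, EM fitting, labeling, PR/APR, calls."""

import numpy as np
import pytest
from scipy import stats

import augcall
from augcall import stage1, stage2
from augcall.containers import ClusterModel, PrerequisiteError, RunConfig


def _toy_model(sep=10.0, sd=1.0):
    means = np.array([[sep, 0.0], [sep / 2, sep / 2], [0.0, sep]])
    covs = np.array([np.eye(2) * sd**2] * 3)
    return ClusterModel(
        snp_id="toy", means=means, covs=covs, counts=[5, 5, 5], source="G1-direct"
    )


def _draw(model, counts, seed):
    rng = np.random.default_rng(seed)
    return np.vstack(
        [
            rng.multivariate_normal(model.means[k], model.covs[k], size=c)
            for k, c in enumerate(counts)
        ]
    )


class TestAugmentationSimulation:
    def test_equal_counts_per_component(self, default_geometry_model):
        xy, labels = stage2.simulate_augmented_samples(default_geometry_model, 600, 1)
        assert xy.shape == (600, 2)
        assert [int((labels == k).sum()) for k in range(3)] == [200, 200, 200]

    def test_zero_m_gives_empty_block(self, default_geometry_model):
        xy, labels = stage2.simulate_augmented_samples(default_geometry_model, 0, 1)
        assert xy.shape == (0, 2)
        assert labels.size == 0

    def test_non_divisible_m_rejected(self, default_geometry_model):
        with pytest.raises(ValueError, match="multiple of 3"):
            stage2.simulate_augmented_samples(default_geometry_model, 100, 1)

    def test_deterministic_under_seed(self, default_geometry_model):
        a, _ = stage2.simulate_augmented_samples(default_geometry_model, 30, 9)
        b, _ = stage2.simulate_augmented_samples(default_geometry_model, 30, 9)
        np.testing.assert_array_equal(a, b)

    def test_component_means_match_model(self, default_geometry_model):
        # Monte-Carlo check: per-component sample mean within 4 standard errors
        m = 30000
        xy, labels = stage2.simulate_augmented_samples(default_geometry_model, m, 7)
        for k in range(3):
            block = xy[labels == k]
            se = np.sqrt(np.diag(default_geometry_model.covs[k]) / len(block))
            np.testing.assert_array_less(
                np.abs(block.mean(axis=0) - default_geometry_model.means[k]), 4 * se
            )


class TestEm:
    def test_responsibilities_normalised_every_iteration(self):
        model = _toy_model()
        data = _draw(model, [20, 20, 20], seed=3)
        fit = stage2.em_fit_gmm(data, model, tol=1e-10, max_iter=100)
        np.testing.assert_allclose(fit.resp.sum(axis=1), 1.0, atol=1e-9)

    def test_symmetric_equal_clusters_recover_uniform_weights(self):
        model = _toy_model(sep=20.0)
        data = _draw(model, [50, 50, 50], seed=4)
        fit = stage2.em_fit_gmm(data, model, tol=1e-12, max_iter=500)
        assert fit.converged
        np.testing.assert_allclose(fit.weights, [1 / 3] * 3, atol=1e-6)

    def test_non_finite_data_rejected(self):
        model = _toy_model()
        data = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError, match="non-finite"):
            stage2.em_fit_gmm(data, model)

    def test_component_collapse_flagged(self):
        # no data anywhere near the third component
        model = _toy_model(sep=1000.0, sd=0.1)
        data = _draw(model, [30, 30, 0], seed=5)
        fit = stage2.em_fit_gmm(data, model, tol=1e-8, max_iter=100)
        assert fit.collapsed
        assert not fit.converged

    def test_matches_reference_em_implementation(self):
        # independent oracle: scikit-learn's EM from the identical start
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(123)
        for trial in range(20):
            sep = rng.uniform(8, 20)
            model = _toy_model(sep=sep, sd=1.0)
            counts = rng.integers(15, 40, size=3)
            data = _draw(model, counts, seed=1000 + trial)
            fit = stage2.em_fit_gmm(data, model, tol=1e-12, max_iter=1000)
            gm = GaussianMixture(
                n_components=3,
                covariance_type="full",
                weights_init=np.full(3, 1 / 3),
                means_init=model.means,
                precisions_init=np.array(
                    [np.linalg.inv(c) for c in model.covs]
                ),
                tol=1e-12,
                reg_covar=0.0,
                max_iter=1000,
            )
            gm.fit(data)
            np.testing.assert_allclose(fit.weights, gm.weights_, atol=1e-6)
            np.testing.assert_allclose(fit.means, gm.means_, atol=1e-6)
            np.testing.assert_allclose(fit.covs, gm.covariances_, atol=1e-5)


class TestLabeling:
    def _fit(self, means):
        return stage2.GmmFit(
            snp_id="t",
            weights=np.full(3, 1 / 3),
            means=np.asarray(means, dtype=float),
            covs=np.array([np.eye(2)] * 3),
            resp=np.full((3, 3), 1 / 3),
            log_likelihood=[0.0],
            converged=True,
        )

    def test_contrast_ordering(self):
        labels, tie = stage2.map_components_to_genotypes(
            self._fit([[10, 1], [5, 5], [1, 10]])
        )
        assert labels == {0: "AA", 1: "AB", 2: "BB"}
        assert not tie

    def test_permutation_gives_semantically_identical_labels(self):
        labels, _ = stage2.map_components_to_genotypes(
            self._fit([[1, 10], [10, 1], [5, 5]])
        )
        assert labels == {1: "AA", 2: "AB", 0: "BB"}

    def test_exact_tie_flagged_and_broken_by_index(self):
        labels, tie = stage2.map_components_to_genotypes(
            self._fit([[5, 5], [6, 6], [1, 10]])
        )
        assert tie
        assert labels[0] == "AA" and labels[1] == "AB"

    def test_two_zero_total_means_error(self):
        with pytest.raises(stage2.LabelingError):
            stage2.map_components_to_genotypes(self._fit([[0, 0], [0, 0], [1, 1]]))


class TestPosteriorRates:
    def _fit_with_resp(self, resp):
        return stage2.GmmFit(
            snp_id="t",
            weights=np.full(3, 1 / 3),
            means=np.array([[10.0, 1.0], [5.0, 5.0], [1.0, 10.0]]),
            covs=np.array([np.eye(2)] * 3),
            resp=np.asarray(resp, dtype=float),
            log_likelihood=[0.0],
            converged=True,
        )

    def test_one_hot_gives_unit_rates(self):
        fit = self._fit_with_resp(np.eye(3)[[0, 1, 2, 0]])
        _, pr, apr, _ = stage2.posterior_rates(fit, n=4)
        np.testing.assert_allclose(pr, 1.0)
        assert apr == pytest.approx(1.0)

    def test_uniform_gives_one_third(self):
        fit = self._fit_with_resp(np.full((5, 3), 1 / 3))
        _, pr, apr, _ = stage2.posterior_rates(fit, n=5)
        np.testing.assert_allclose(pr, 1 / 3)
        assert apr == pytest.approx(1 / 3)

    def test_mixed_instance_matches_hand_sum(self):
        resp = np.array(
            [[0.9, 0.05, 0.05], [0.2, 0.7, 0.1], [0.1, 0.1, 0.8], [0.5, 0.3, 0.2]]
        )
        fit = self._fit_with_resp(resp)
        assigned, pr, apr, apr_obs = stage2.posterior_rates(fit, n=2)
        # hand evaluation: assigned posteriors 0.9, 0.7, 0.8, 0.5
        np.testing.assert_allclose(pr, [0.9, 0.7, 0.8, 0.5])
        assert apr == pytest.approx((0.9 + 0.7 + 0.8 + 0.5) / 4)
        assert apr_obs == pytest.approx((0.9 + 0.7) / 2)
        assert list(assigned) == [0, 1, 2, 0]


class TestAssignment:
    def _fit_with_resp(self, resp):
        return TestPosteriorRates._fit_with_resp(self, resp)

    def test_apr_gate_fails_whole_snp(self):
        resp = np.full((4, 3), 1 / 3)  # APR = 1/3 < 0.85
        genotypes, _, apr, _, snp_pass = stage2.assign_genotypes(
            self._fit_with_resp(resp), {0: "AA", 1: "AB", 2: "BB"}, 0.85, 0.85, n=4
        )
        assert not snp_pass
        assert genotypes == ["NoCall"] * 4

    def test_boundary_apr_not_strictly_above_fails(self):
        resp = np.zeros((4, 3))
        resp[:, 0] = 0.84
        resp[:, 1] = 0.16
        genotypes, _, apr, _, snp_pass = stage2.assign_genotypes(
            self._fit_with_resp(resp), {0: "AA", 1: "AB", 2: "BB"}, 0.85, 0.85, n=4
        )
        assert apr == pytest.approx(0.84)
        assert not snp_pass

    def test_confident_subject_called_diffuse_subject_nocall(self):
        resp = np.array([[1.0, 0.0, 0.0], [0.8, 0.15, 0.05], [0.0, 1.0, 0.0]])
        genotypes, pr, _, _, snp_pass = stage2.assign_genotypes(
            self._fit_with_resp(resp), {0: "AA", 1: "AB", 2: "BB"}, 0.85, 0.85, n=3
        )
        assert snp_pass  # APR = (1 + 0.8 + 1)/3 = 0.933
        assert genotypes == ["AA", "NoCall", "AB"]


class TestCallPanel:
    def test_deterministic_under_seed(self, easy_bundle):
        panel, known, _ = easy_bundle
        config = RunConfig(m=60, seed=77)
        a = augcall.call_panel(panel, known, config)
        b = augcall.call_panel(panel, known, config)
        assert a.calls.equals(b.calls)
        assert a.snp_report.equals(b.snp_report)

    def test_empty_known_table_is_prerequisite_error(self, easy_bundle):
        panel, _, _ = easy_bundle
        empty = augcall.KnownGenotypeTable(sample_ids=[], genotypes={})
        with pytest.raises(PrerequisiteError, match="known genotypes"):
            augcall.call_panel(panel, empty, RunConfig(m=60, seed=1))

    def test_simulated_subjects_never_emitted(self, easy_bundle):
        panel, known, _ = easy_bundle
        calls = augcall.call_panel(panel, known, RunConfig(m=60, seed=77))
        assert set(calls.calls["sample_id"]) <= set(panel.sample_ids)
        assert len(calls.calls) == panel.n_samples * panel.n_snps

    def test_easy_panel_high_accuracy(self, easy_bundle):
        panel, known, truth = easy_bundle
        calls = augcall.call_panel(panel, known, RunConfig(m=600, seed=77))
        table = truth.as_known_table()
        truth_list = [
            table.get(s, p)
            for s, p in zip(calls.calls["sample_id"], calls.calls["snp_id"])
        ]
        acc = augcall.concordance(list(calls.calls["genotype"]), truth_list)
        counts = augcall.GenotypeCounts.from_calls(calls.calls["genotype"])
        assert acc >= 0.99
        assert augcall.call_rate(counts) >= 0.99


class TestAugmentationProperties:
    def test_loglik_monotone_on_random_instances(self):
        rng = np.random.default_rng(55)
        for trial in range(25):
            sep = rng.uniform(2, 12)  # includes poorly-separated regimes
            model = _toy_model(sep=sep, sd=1.0)
            counts = rng.integers(5, 30, size=3)
            data = _draw(model, counts, seed=2000 + trial)
            fit = stage2.em_fit_gmm(data, model, tol=1e-10, max_iter=200)
            diffs = np.diff(fit.log_likelihood)
            assert np.all(diffs >= -1e-8 * np.maximum(1.0, np.abs(fit.log_likelihood[:-1])))

    def test_augmentation_preserves_major_homozygote(self):
        # equal per-cluster augmentation cannot flip which observed
        # homozygote cluster is the larger one
        rng = np.random.default_rng(99)
        for trial in range(20):
            model = _toy_model(sep=15.0)
            n_aa = int(rng.integers(50, 90))
            n_bb = int(rng.integers(0, 10))
            data = _draw(model, [n_aa, 5, n_bb], seed=3000 + trial)
            sim, _ = stage2.simulate_augmented_samples(model, 600, 4000 + trial)
            n_obs = len(data)

            def observed_homozygote_margin(fit):
                labels, _ = stage2.map_components_to_genotypes(fit)
                assigned, _, _, _ = stage2.posterior_rates(fit, n_obs)
                obs = assigned[:n_obs]
                by_label = {labels[k]: int((obs == k).sum()) for k in range(3)}
                return by_label["AA"] - by_label["BB"]

            plain = stage2.em_fit_gmm(data, model, tol=1e-8, max_iter=200)
            aug = stage2.em_fit_gmm(
                np.vstack([data, sim]), model, tol=1e-8, max_iter=200
            )
            assert observed_homozygote_margin(plain) > 0
            assert observed_homozygote_margin(aug) > 0
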