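import numpy as np
import pytest

from ramanced import (
    CohortSpec,
    ConfigurationError,
    generate_cohort,
    mean_replicate_correlation,
    pca_fit,
    replicate_correlation_matrix,
    variability_profile,
    zscore_standardize,
)
from ramanced.synth import DIFFERENTIAL_BANDS


def brute_force_pca(x):
    """Independent oracle: dense eigendecomposition of the sample covariance."""
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    ratios = evals / evals.sum()
    scores = xc @ evecs
    return ratios, evecs.T, scores


class TestZscore:
    def test_columns_become_standard(self):
        x = np.array([[1.0, 10.0], [2.0, 30.0], [3.0, 20.0]])
        z = zscore_standardize(x)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_constant_column_zeroed_and_flagged(self):
        x = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        z, mean, sd, flat = zscore_standardize(x, return_params=True)
        assert flat.tolist() == [False, True]
        np.testing.assert_allclose(z[:, 1], 0)

    def test_round_trip_with_stored_params(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 5)) * 3 + 2
        z, mean, sd, flat = zscore_standardize(x, return_params=True)
        np.testing.assert_allclose(z * sd + mean, x, atol=1e-10)

    def test_single_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            zscore_standardize(np.ones((1, 4)))


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=12)
        x = np.outer(rng.normal(size=10), direction) + 5.0
        res = pca_fit(x, 0.85)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)
        assert res.n_retained == 1

    def test_ratios_sum_to_one(self):
        rng = np.random.default_rng(2)
        res = pca_fit(rng.normal(size=(20, 6)))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 12))
        res = pca_fit(x, 0.85)
        ratios, loadings, scores = brute_force_pca(x)
        k = res.components.shape[0]
        np.testing.assert_allclose(res.explained_variance_ratio, ratios[:k], atol=1e-10)
        for i in range(k):
            dot = float(loadings[i] @ res.components[i])
            np.testing.assert_allclose(res.components[i], np.sign(dot) * loadings[i], atol=1e-8)
            np.testing.assert_allclose(res.scores[:, i], np.sign(dot) * scores[:, i], atol=1e-8)

    def test_retained_count_is_smallest_k_reaching_target(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 8))
        res = pca_fit(x, 0.6)
        cum = np.cumsum(res.explained_variance_ratio)
        k = res.n_retained
        assert cum[k - 1] >= 0.6
        assert k == 1 or cum[k - 2] < 0.6

    def test_reconstruction_error_bounded_by_unretained_variance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(25, 10)) @ np.diag(np.linspace(3, 0.3, 10))
        res = pca_fit(x, 0.85)
        recon = res.retained_scores @ res.retained_components + res.mean
        total = np.sum((x - x.mean(axis=0)) ** 2)
        err = np.sum((x - recon) ** 2)
        unretained = 1.0 - np.sum(res.explained_variance_ratio[: res.n_retained])
        assert err / total <= unretained + 1e-10

    def test_loading_sign_convention(self):
        rng = np.random.default_rng(6)
        res = pca_fit(rng.normal(size=(15, 7)))
        for comp in res.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ConfigurationError, match="variance"):
            pca_fit(np.ones((5, 4)))


class TestReplicateCorrelation:
    def test_identical_replicates_all_ones(self):
        cohort = generate_cohort(
            CohortSpec(n_ced=1, n_control=1, replicate_noise_sd=0.0, seed=0)
        )
        corr = replicate_correlation_matrix(cohort, cohort.patient_ids[0])
        np.testing.assert_allclose(corr, 1.0, atol=1e-13)

    def test_anticorrelated_pair(self):
        from ramanced import Spectrum, WavenumberGrid
        from ramanced.synth import Cohort

        grid = WavenumberGrid(500, 700, 2)
        x = np.sin(np.linspace(0, 10, len(grid)))
        cohort = Cohort(
            [Spectrum("p", "CeD", 1, grid, x), Spectrum("p", "CeD", 2, grid, -x)],
            CohortSpec(grid=grid, peaks=()),
        )
        corr = replicate_correlation_matrix(cohort, "p")
        assert corr[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_default_generator_meets_qc(self, default_cohort):
        assert mean_replicate_correlation(default_cohort) >= 0.99


class TestVariabilityProfile:
    def test_zero_variance_channel_has_zero_sd(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 6))
        x[:, 3] = 2.0
        prof = variability_profile(x, pca_fit(x))
        assert prof.wavenumber_sd[3] == 0.0

    def test_sd_profile_peaks_at_differential_bands(self):
        """With class effects dominating noise, cross-cohort SD concentrates
        at the class-differential wavenumbers."""
        cohort = generate_cohort(
            CohortSpec(replicate_noise_sd=0.005, patient_noise_sd=0.0,
                       patient_scale_sigma=0.0, seed=8)
        )
        from ramanced import average_replicates

        avg = average_replicates(cohort)
        mat = avg.intensity_matrix() - cohort.spec.baseline()
        w = cohort.spec.grid.values
        prof = variability_profile(mat, pca_fit(mat))
        top = w[np.argmax(prof.wavenumber_sd)]
        assert min(abs(top - c) for c in DIFFERENTIAL_BANDS) <= 10

    def test_contribution_vectors_unit_norm(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(10, 8))
        prof = variability_profile(x, pca_fit(x))
        # loadings come unit-norm from the decomposition
        assert np.linalg.norm(prof.pc1_contribution) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(prof.pc2_contribution) == pytest.approx(1.0, abs=1e-10)
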