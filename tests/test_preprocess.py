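import numpy as np
import pytest

from ramanced import (
    CohortSpec,
    ConfigurationError,
    GridMismatchError,
    PreprocessConfig,
    Spectrum,
    WavenumberGrid,
    airpls_baseline,
    average_replicates,
    fft_filter,
    generate_cohort,
    normalize,
    preprocess_pipeline,
    savgol_smooth,
)
from ramanced.synth import Cohort


@pytest.fixture(scope="module")
def noise_free_cohort():
    """Known truth: polynomial + broad-Gaussian baseline under sharp peaks."""
    return generate_cohort(
        CohortSpec(n_ced=1, n_control=1, replicates_per_patient=1,
                   replicate_noise_sd=0.0, patient_noise_sd=0.0,
                   patient_scale_sigma=0.0, seed=0)
    )


class TestAirPLS:
    def test_straight_line_is_its_own_baseline(self):
        x = np.linspace(3.0, 7.0, 400)
        z = airpls_baseline(x)
        assert np.abs(z - x).max() < 1e-6 * np.abs(x).max()

    def test_recovers_known_baseline_under_peaks(self, noise_free_cohort):
        true_base = noise_free_cohort.spec.baseline()
        x = noise_free_cohort.spectra[0].intensities
        z = airpls_baseline(x)
        rel_rms = np.sqrt(np.mean((z - true_base) ** 2)) / np.sqrt(np.mean(true_base**2))
        assert rel_rms < 0.02

    def test_baseline_stays_below_positive_peaks(self, noise_free_cohort):
        spec = noise_free_cohort.spec
        peaks_only = noise_free_cohort.spectra[0].intensities - spec.baseline()
        z = airpls_baseline(peaks_only)
        assert np.all(z <= peaks_only + 0.02 * peaks_only.max())

    def test_second_pass_changes_little(self, noise_free_cohort):
        x = noise_free_cohort.spectra[0].intensities
        z1 = airpls_baseline(x)
        corrected = x - z1
        z2 = airpls_baseline(corrected)
        first_pass_rms = np.sqrt(np.mean(z1**2))
        assert np.sqrt(np.mean(z2**2)) < 0.01 * first_pass_rms

    def test_rejects_bad_input(self):
        with pytest.raises(ConfigurationError):
            airpls_baseline(np.array([1.0, np.nan, 2.0, 3.0, 4.0]))
        with pytest.raises(ConfigurationError):
            airpls_baseline(np.ones(100), lam=0.0)


class TestSavgol:
    def test_exact_on_quadratic(self):
        t = np.linspace(0, 1, 200)
        x = 3.0 - 2.0 * t + 5.0 * t**2
        np.testing.assert_allclose(savgol_smooth(x, 5, 2), x, atol=1e-12)

    def test_constant_preserved(self):
        x = np.full(50, 4.2)
        np.testing.assert_allclose(savgol_smooth(x), x, atol=1e-13)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        assert savgol_smooth(x).var() < x.var()

    def test_invalid_window_rejected(self):
        with pytest.raises(ConfigurationError):
            savgol_smooth(np.ones(20), window=4, polyorder=2)
        with pytest.raises(ConfigurationError):
            savgol_smooth(np.ones(20), window=3, polyorder=3)


class TestFFTFilter:
    def test_wide_open_lowpass_is_identity(self):
        # odd length: the highest bin sits below Nyquist, inside the pass band
        rng = np.random.default_rng(1)
        x = rng.normal(size=255)
        np.testing.assert_allclose(fft_filter(x, "lowpass", 0.999), x, atol=1e-9)

    def test_highpass_annihilates_constant(self):
        out = fft_filter(np.full(128, 3.0), "highpass", 0.1)
        assert np.abs(out).max() < 1e-12

    def test_lowpass_separates_known_frequencies(self):
        n = 1000
        t = np.arange(n)
        slow = np.sin(2 * np.pi * 10 * t / n)  # 0.02 x Nyquist
        fast = np.sin(2 * np.pi * 200 * t / n)  # 0.4 x Nyquist
        out = fft_filter(slow + fast, "lowpass", 0.1)
        amp = lambda sig, ref: np.abs(sig @ ref) / (ref @ ref)
        assert amp(out, slow) == pytest.approx(1.0, abs=0.01)
        assert amp(out, fast) < 0.01
    def test_lowpass_never_increases_power(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=512)
        out = fft_filter(x, "lowpass", 0.3)
        assert np.sum(out**2) <= np.sum(x**2)

    def test_bandpass_and_bad_cutoffs(self):
        x = np.ones(64)
        assert np.abs(fft_filter(x, "bandpass", (0.1, 0.5))).max() < 1e-12
        with pytest.raises(ConfigurationError):
            fft_filter(x, "lowpass", 1.5)
        with pytest.raises(ConfigurationError):
            fft_filter(x, "sideways", 0.5)


class TestNormalize:
    def test_minmax_affine_map(self):
        np.testing.assert_allclose(
            normalize(np.array([2.0, 4.0, 6.0]), "minmax"), [0.0, 0.5, 1.0]
        )

    def test_vector_unit_norm(self):
        rng = np.random.default_rng(3)
        out = normalize(rng.normal(size=77), "vector")
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)

    def test_area_unit_sum(self):
        out = normalize(np.abs(np.random.default_rng(4).normal(size=50)) + 0.1, "area")
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_minmax_rejected(self):
        with pytest.raises(ConfigurationError):
            normalize(np.ones(10), "minmax")


class TestAverageReplicates:
    def test_default_cohort_averages_to_59_patients(self, default_cohort):
        avg = average_replicates(default_cohort)
        assert len(avg) == 59

    def test_identical_replicates_average_to_themselves(self):
        cohort = generate_cohort(
            CohortSpec(n_ced=1, n_control=1, replicate_noise_sd=0.0, seed=2)
        )
        avg = average_replicates(cohort)
        np.testing.assert_allclose(
            avg.replicates_of(cohort.patient_ids[0])[0].intensities,
            cohort.replicates_of(cohort.patient_ids[0])[0].intensities,
        )

    def test_symmetric_perturbations_cancel_exactly(self):
        grid = WavenumberGrid(500, 700, 2)
        x = np.linspace(0, 1, len(grid))
        delta = np.sin(np.linspace(0, 7, len(grid)))
        spectra = [
            Spectrum("p1", "CeD", i + 1, grid, v)
            for i, v in enumerate([x, x + delta, x - delta])
        ]
        cohort = Cohort(spectra, CohortSpec(n_ced=1, n_control=1, grid=grid, peaks=()))
        avg = average_replicates(cohort)
        np.testing.assert_allclose(avg.spectra[0].intensities, x, atol=1e-15)

    def test_grid_mismatch_rejected(self):
        g1, g2 = WavenumberGrid(500, 700, 2), WavenumberGrid(500, 700, 4)
        spectra = [
            Spectrum("p1", "CeD", 1, g1, np.zeros(len(g1))),
            Spectrum("p1", "CeD", 2, g2, np.zeros(len(g2))),
        ]
        cohort = Cohort(spectra, CohortSpec(n_ced=1, n_control=1, grid=g1, peaks=()))
        with pytest.raises(GridMismatchError, match="p1"):
            average_replicates(cohort)


class TestPipeline:
    def test_identity_configuration_returns_input(self, default_cohort):
        config = PreprocessConfig(
            airpls=False, smoothing=False, fft_mode="off",
            normalization="none", average="off",
        )
        out = preprocess_pipeline(default_cohort, config)
        np.testing.assert_array_equal(
            out.intensity_matrix(), default_cohort.intensity_matrix()
        )

    def test_default_run_gives_59_unit_interval_spectra(self, preprocessed_default):
        assert len(preprocessed_default) == 59
        mat = preprocessed_default.intensity_matrix()
        assert mat.min() >= 0.0 and mat.max() <= 1.0

    def test_stage_log_records_stages_in_order(self, preprocessed_default):
        log = [e["stage"] for e in preprocessed_default.spectra[0].stage_log]
        assert log == ["airpls", "savgol", "fft", "average", "normalize"]

    def test_pipeline_deterministic_for_same_input(self, default_cohort):
        a = preprocess_pipeline(default_cohort).intensity_matrix()
        b = preprocess_pipeline(default_cohort).intensity_matrix()
        np.testing.assert_array_equal(a, b)

    def test_average_after_normalize_position(self, default_cohort):
        config = PreprocessConfig(average="after_normalize")
        out = preprocess_pipeline(default_cohort, config)
        assert len(out) == 59
        log = [e["stage"] for e in out.spectra[0].stage_log]
        assert log == ["airpls", "savgol", "fft", "normalize", "average"]
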