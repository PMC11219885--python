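import numpy as np
import pytest

from ramanced import CohortSpec, PeakModel, WavenumberGrid, generate_cohort, preprocess_pipeline


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort: 29 CeD + 30 control patients, triplicates."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def preprocessed_default(default_cohort):
    """Default cohort through the default cleanup chain (59 averaged spectra)."""
    return preprocess_pipeline(default_cohort)


def toy_separable_spec(seed: int = 0, n_per_class: int = 10) -> CohortSpec:
    """Tiny noise-free cohort with one strong band per class: linearly separable."""
    grid = WavenumberGrid(500, 1012, 4)  # 129 channels
    peaks = (
        PeakModel(center=600, width=10, base_amplitude=1.0, class_effect=5.0),
        PeakModel(center=900, width=10, base_amplitude=1.0, class_effect=0.2),
    )
    return CohortSpec(
        n_ced=n_per_class,
        n_control=n_per_class,
        replicates_per_patient=1,
        grid=grid,
        peaks=peaks,
        baseline_coeffs=(0.0,),
        broad_background_amplitude=0.0,
        replicate_noise_sd=0.0,
        patient_noise_sd=0.0,
        patient_scale_sigma=0.0,
        seed=seed,
    )


def patient_matrix(cohort, patients):
    wanted = set(patients)
    rows = [s for s in cohort.spectra if s.patient_id in wanted]
    x = np.stack([s.intensities for s in rows])
    y = np.array([1 if s.group == "CeD" else 0 for s in rows])
    return x, y
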