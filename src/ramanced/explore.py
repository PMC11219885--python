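"""Exploratory analyses: z-score standardization, PCA, replicate QC, variability.

PCA retains the smallest number of components whose cumulative explained
variance reaches a target fraction (default 0.85). Loading signs follow a
fixed convention — the largest-magnitude element of each loading is made
positive — so scores and loadings are reproducible across runs and BLAS
builds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .errors import ConfigurationError
from .synth import Cohort

__all__ = [
    "PCAResult",
    "VariabilityProfile",
    "zscore_standardize",
    "pca_fit",
    "replicate_correlation_matrix",
    "mean_replicate_correlation",
    "variability_profile",
]


@dataclass
class PCAResult:
    components: np.ndarray  # (n_components, n_channels), unit-norm rows
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (n_samples, n_components)
    n_retained: int
    retained_variance_target: float
    mean: np.ndarray

    @property
    def retained_components(self) -> np.ndarray:
        return self.components[: self.n_retained]

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.n_retained]


@dataclass
class VariabilityProfile:
    wavenumber_sd: np.ndarray
    pc1_contribution: np.ndarray
    pc2_contribution: np.ndarray


def zscore_standardize(
    matrix: np.ndarray, return_params: bool = False, ddof: int = 1
):
    """Standardize each wavenumber column to mean 0 and SD 1 (unbiased SD).

    Columns with zero spread are left centered at zero and reported in the
    flag vector. With ``return_params`` the per-column mean/SD come back for
    exact inversion.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ConfigurationError("zscore_standardize needs >= 2 samples (rows)")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    flat = sd == 0
    safe_sd = np.where(flat, 1.0, sd)
    z = (x - mean) / safe_sd
    if return_params:
        return z, mean, sd, flat
    return z


def pca_fit(matrix: np.ndarray, retained_variance_target: float = 0.85) -> PCAResult:
    """Principal component analysis via SVD of the centered data matrix.

    ``n_retained`` is the smallest k whose cumulative explained-variance
    ratio reaches the target. The full decomposition is kept so ratios sum
    to one over all components.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ConfigurationError("pca_fit needs >= 2 samples (rows)")
    if not 0 < retained_variance_target <= 1:
        raise ConfigurationError("retained_variance_target must lie in (0, 1]")
    if np.allclose(x, x[0]):
        raise ConfigurationError("pca_fit: zero total variance (all rows identical)")

    model = _SkPCA(n_components=min(x.shape[0] - 1, x.shape[1]), svd_solver="full")
    scores = model.fit_transform(x)
    components = model.components_.copy()

    # sign convention: largest-|.| element of each loading made positive
    for k in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] = -components[k]
            scores[:, k] = -scores[:, k]

    ratios = model.explained_variance_ratio_
    cumulative = np.cumsum(ratios)
    n_retained = int(np.searchsorted(cumulative, retained_variance_target - 1e-12) + 1)
    n_retained = min(n_retained, ratios.size)
    return PCAResult(
        components=components,
        explained_variance_ratio=ratios,
        scores=scores,
        n_retained=n_retained,
        retained_variance_target=retained_variance_target,
        mean=model.mean_.copy(),
    )


def replicate_correlation_matrix(cohort: Cohort, patient_id: str) -> np.ndarray:
    """Pearson correlation matrix among one patient's replicate spectra."""
    reps = cohort.replicates_of(patient_id)
    if len(reps) < 2:
        raise ConfigurationError(f"patient {patient_id!r} has < 2 replicates")
    stack = np.stack([r.intensities for r in reps])
    if np.any(stack.std(axis=1) == 0):
        raise ConfigurationError(
            f"patient {patient_id!r}: constant replicate, correlation undefined"
        )
    return np.corrcoef(stack)


def mean_replicate_correlation(cohort: Cohort) -> float:
    """Mean within-patient pairwise Pearson correlation over the cohort."""
    values = []
    for pid in cohort.patient_ids:
        if len(cohort.replicates_of(pid)) < 2:
            continue
        corr = replicate_correlation_matrix(cohort, pid)
        iu = np.triu_indices_from(corr, k=1)
        values.extend(corr[iu])
    if not values:
        raise ConfigurationError("no patient has >= 2 replicates")
    return float(np.mean(values))


def variability_profile(matrix: np.ndarray, pca: PCAResult) -> VariabilityProfile:
    """Per-wavenumber SD of the data plus the first two PCA loading profiles."""
    if pca.components.shape[0] < 2:
        raise ConfigurationError("variability_profile needs >= 2 PCA components")
    x = np.asarray(matrix, dtype=float)
    return VariabilityProfile(
        wavenumber_sd=x.std(axis=0, ddof=1),
        pc1_contribution=pca.components[0].copy(),
        pc2_contribution=pca.components[1].copy(),
    )
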