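"""Spectral cleanup chain.

The pipeline applies, in order: airPLS baseline removal, Savitzky–Golay
smoothing (window 5, order 2 by default), Fourier-domain filtering, then
per-patient replicate averaging and per-spectrum normalization. Averaging
defaults to after filtering and before normalization; the position is
configurable and recorded in each spectrum's stage log.

airPLS (adaptive iteratively reweighted penalized least squares) estimates
the smooth fluorescence background with a Whittaker smoother whose point
weights are driven to zero wherever the signal rises above the current
baseline estimate, i.e. at Raman peaks, so only valley/background points
constrain the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .errors import ConfigurationError, GridMismatchError
from .synth import Cohort, Spectrum

__all__ = [
    "PreprocessConfig",
    "PreprocessedSpectrum",
    "airpls_baseline",
    "savgol_smooth",
    "fft_filter",
    "normalize",
    "average_replicates",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """All filter and normalization parameters for one pipeline run."""

    airpls: bool = True
    airpls_lambda: float = 1e5
    airpls_max_iter: int = 15
    airpls_ratio: float = 1e-3
    smoothing: bool = True
    sg_window: int = 5
    sg_polyorder: int = 2
    fft_mode: Literal["lowpass", "highpass", "bandpass", "off"] = "lowpass"
    fft_cutoff: float | tuple[float, float] = 0.15
    normalization: Literal["minmax", "vector", "area", "none"] = "minmax"
    average: Literal["after_filter", "after_normalize", "off"] = "after_filter"

    def __post_init__(self) -> None:
        if self.airpls_lambda <= 0:
            raise ConfigurationError("airpls_lambda must be > 0")
        if self.airpls_max_iter < 1:
            raise ConfigurationError("airpls_max_iter must be >= 1")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigurationError(
                "sg_window must be odd and greater than sg_polyorder"
            )
        if self.fft_mode not in ("lowpass", "highpass", "bandpass", "off"):
            raise ConfigurationError(f"unknown fft_mode {self.fft_mode!r}")
        if self.fft_mode == "bandpass":
            lo, hi = self.fft_cutoff  # type: ignore[misc]
            if not (0 < lo < hi < 1):
                raise ConfigurationError("bandpass fft_cutoff must be 0 < lo < hi < 1")
        elif self.fft_mode != "off" and not (0 < float(self.fft_cutoff) < 1):
            raise ConfigurationError("fft_cutoff must lie in (0, 1)")
        if self.normalization not in ("minmax", "vector", "area", "none"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        if self.average not in ("after_filter", "after_normalize", "off"):
            raise ConfigurationError(f"unknown average position {self.average!r}")


@dataclass(eq=False)
class PreprocessedSpectrum(Spectrum):
    """A spectrum carrying its estimated baseline and an ordered stage log."""

    stage_log: list[dict] = field(default_factory=list)
    estimated_baseline: np.ndarray | None = None


def airpls_baseline(
    intensities: Sequence[float],
    lam: float = 1e5,
    max_iter: int = 15,
    ratio: float = 1e-3,
) -> np.ndarray:
    """Estimate the smooth background of one spectrum with airPLS.

    Solves the weighted Whittaker system ``(W + lam * D'D) z = W x`` with a
    second-difference penalty ``D``. After each solve the weights are set to
    0 where the residual ``d = x - z`` is non-negative (peak region) and to
    ``exp(t * |d_i| / |d|_-)`` where it is negative, ``t`` being the
    iteration index and ``|d|_-`` the total magnitude of negative residuals.
    Iteration stops when ``|d|_- < ratio * sum|x|`` or at ``max_iter``.
    """
    x = np.asarray(intensities, dtype=float)
    if x.ndim != 1 or x.size < 5:
        raise ConfigurationError("airpls_baseline needs a 1-D signal of length >= 5")
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("airpls_baseline: non-finite input")
    if lam <= 0:
        raise ConfigurationError("airpls lambda must be > 0")

    n = x.size
    diff2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (diff2.T @ diff2)
    w = np.ones(n)
    z = x.copy()
    abs_sum = np.abs(x).sum()
    for t in range(1, max_iter + 1):
        weights = sparse.diags(w, format="csc")
        z = spsolve((weights + penalty).tocsc(), w * x)
        d = x - z
        neg = d < 0
        dssn = float(np.abs(d[neg]).sum())
        if dssn < ratio * abs_sum or t == max_iter:
            break
        w[~neg] = 0.0
        w[neg] = np.exp(t * np.abs(d[neg]) / dssn)
    return z


def savgol_smooth(
    intensities: Sequence[float], window: int = 5, polyorder: int = 2
) -> np.ndarray:
    """Savitzky–Golay local polynomial smoothing (length-preserving).

    Boundaries use a polynomial fit over the edge window, so polynomials up
    to ``polyorder`` pass through unchanged everywhere.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ConfigurationError("sg window must be odd and greater than polyorder")
    x = np.asarray(intensities, dtype=float)
    return savgol_filter(x, window_length=window, polyorder=polyorder, mode="interp")


def fft_filter(
    intensities: Sequence[float],
    mode: str = "lowpass",
    cutoff: float | tuple[float, float] = 0.15,
) -> np.ndarray:
    """Fourier-domain filtering by zeroing stop-band bins of the real FFT.

    ``cutoff`` is a fraction of the Nyquist frequency; ``bandpass`` takes a
    ``(low, high)`` pair. The output is real and has the input's length.
    """
    x = np.asarray(intensities, dtype=float)
    n = x.size
    spectrum = np.fft.rfft(x)
    # bin k corresponds to normalized frequency 2k/n in Nyquist units
    frac = np.arange(spectrum.size) * 2.0 / n
    if mode == "lowpass":
        c = float(cutoff)  # type: ignore[arg-type]
        if not 0 < c < 1:
            raise ConfigurationError("fft cutoff must lie in (0, 1)")
        spectrum[frac > c] = 0.0
    elif mode == "highpass":
        c = float(cutoff)  # type: ignore[arg-type]
        if not 0 < c < 1:
            raise ConfigurationError("fft cutoff must lie in (0, 1)")
        spectrum[frac < c] = 0.0
    elif mode == "bandpass":
        lo, hi = cutoff  # type: ignore[misc]
        if not 0 < lo < hi < 1:
            raise ConfigurationError("bandpass cutoff must satisfy 0 < lo < hi < 1")
        spectrum[(frac < lo) | (frac > hi)] = 0.0
    else:
        raise ConfigurationError(f"unknown fft mode {mode!r}")
    return np.fft.irfft(spectrum, n=n)


def normalize(intensities: Sequence[float], method: str = "minmax") -> np.ndarray:
    """Per-spectrum normalization: minmax to [0,1], unit vector, or unit area."""
    x = np.asarray(intensities, dtype=float)
    if method == "none":
        return x.copy()
    if method == "minmax":
        rng = x.max() - x.min()
        if rng == 0:
            raise ConfigurationError("minmax normalization undefined for constant input")
        return (x - x.min()) / rng
    if method == "vector":
        norm = float(np.linalg.norm(x))
        if norm == 0:
            raise ConfigurationError("vector normalization undefined for zero input")
        return x / norm
    if method == "area":
        area = float(np.abs(x).sum())
        if area == 0:
            raise ConfigurationError("area normalization undefined for zero input")
        return x / area
    raise ConfigurationError(f"unknown normalization {method!r}")


def average_replicates(cohort: Cohort) -> Cohort:
    """Pointwise mean over each patient's replicates: one spectrum per patient."""
    averaged: list[Spectrum] = []
    for pid in cohort.patient_ids:
        reps = cohort.replicates_of(pid)
        grids = {r.grid for r in reps}
        if len(grids) != 1:
            raise GridMismatchError(f"patient {pid}: replicates on different grids")
        mean = np.mean([r.intensities for r in reps], axis=0)
        proto = reps[0]
        if isinstance(proto, PreprocessedSpectrum):
            out: Spectrum = PreprocessedSpectrum(
                patient_id=pid,
                group=proto.group,
                replicate_index=1,
                grid=proto.grid,
                intensities=mean,
                stage_log=list(proto.stage_log)
                + [{"stage": "average", "n_replicates": len(reps)}],
                estimated_baseline=proto.estimated_baseline,
            )
        else:
            out = Spectrum(
                patient_id=pid,
                group=proto.group,
                replicate_index=1,
                grid=proto.grid,
                intensities=mean,
            )
        averaged.append(out)
    return Cohort(spectra=averaged, spec=cohort.spec, provenance=dict(cohort.provenance))


def _preprocess_one(
    s: Spectrum, config: PreprocessConfig
) -> PreprocessedSpectrum:
    x = s.intensities.copy()
    log: list[dict] = []
    baseline = None
    if config.airpls:
        baseline = airpls_baseline(
            x, config.airpls_lambda, config.airpls_max_iter, config.airpls_ratio
        )
        x = x - baseline
        log.append(
            {
                "stage": "airpls",
                "lambda": config.airpls_lambda,
                "max_iter": config.airpls_max_iter,
                "ratio": config.airpls_ratio,
            }
        )
    if config.smoothing:
        x = savgol_smooth(x, config.sg_window, config.sg_polyorder)
        log.append(
            {
                "stage": "savgol",
                "window": config.sg_window,
                "polyorder": config.sg_polyorder,
            }
        )
    if config.fft_mode != "off":
        x = fft_filter(x, config.fft_mode, config.fft_cutoff)
        log.append(
            {"stage": "fft", "mode": config.fft_mode, "cutoff": config.fft_cutoff}
        )
    return PreprocessedSpectrum(
        patient_id=s.patient_id,
        group=s.group,
        replicate_index=s.replicate_index,
        grid=s.grid,
        intensities=x,
        stage_log=log,
        estimated_baseline=baseline,
    )


def _normalize_cohort(cohort: Cohort, method: str) -> Cohort:
    out = []
    for s in cohort.spectra:
        assert isinstance(s, PreprocessedSpectrum)
        out.append(
            PreprocessedSpectrum(
                patient_id=s.patient_id,
                group=s.group,
                replicate_index=s.replicate_index,
                grid=s.grid,
                intensities=normalize(s.intensities, method),
                stage_log=s.stage_log + [{"stage": "normalize", "method": method}],
                estimated_baseline=s.estimated_baseline,
            )
        )
    return Cohort(spectra=out, spec=cohort.spec, provenance=dict(cohort.provenance))


def preprocess_pipeline(cohort: Cohort, config: PreprocessConfig | None = None) -> Cohort:
    """Run the full cleanup chain over a cohort.

    Stage order: airPLS subtraction, Savitzky–Golay smoothing, Fourier
    filtering (all per spectrum), then replicate averaging and
    normalization in the configured order. Every output spectrum carries a
    stage log naming each applied stage and its parameters.
    """
    config = config or PreprocessConfig()
    filtered = Cohort(
        spectra=[_preprocess_one(s, config) for s in cohort.spectra],
        spec=cohort.spec,
        provenance=dict(cohort.provenance),
    )
    result = filtered
    if config.average == "after_filter":
        result = average_replicates(result)
    if config.normalization != "none":
        result = _normalize_cohort(result, config.normalization)
    if config.average == "after_normalize":
        result = average_replicates(result)
    return result
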