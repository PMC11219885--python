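"""Synthetic plasma-Raman cohort generation.

The clinical spectra behind the celiac-disease (CeD) versus healthy-control
classification task are not publicly available, so this module generates
cohorts with the statistical structure the downstream analysis assumes:

* two classes — CeD and control — with 29 and 30 patients by default,
  three replicate spectra per patient;
* sharp Raman lines (Lorentzian by default) on a wavenumber grid covering
  500–2500 cm^-1, with class-dependent amplitudes at the seven
  literature-reported discriminating bands (CeD higher at 1402, 1477, 1518,
  1545, 1715 and 1772 cm^-1; lower at 1445 cm^-1) plus class-neutral bands
  shared by both groups;
* a smooth fluorescence background (cubic polynomial plus one broad
  Gaussian) common to all patients;
* patient-level variability (log-normal global intensity scale and a
  per-patient channel offset shared across replicates) and independent
  per-replicate measurement noise calibrated so that within-patient
  replicate Pearson correlation is about 0.99.

Everything is reproducible bit-for-bit from ``CohortSpec.seed``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "WavenumberGrid",
    "PeakModel",
    "CohortSpec",
    "Spectrum",
    "Cohort",
    "build_default_peak_set",
    "render_clean_spectrum",
    "generate_cohort",
    "DIFFERENTIAL_BANDS",
]

#: Discriminating wavenumbers (cm^-1) and the direction of the class effect:
#: factor > 1 means higher intensity in CeD plasma, < 1 means lower.
DIFFERENTIAL_BANDS: dict[float, float] = {
    1402.0: 1.15,  # methyl bending modes
    1445.0: 0.85,  # CH2 deformation — the one band lower in CeD
    1477.0: 1.15,  # calcium oxalate
    1518.0: 1.15,  # cytosine
    1545.0: 1.15,  # NADH / tryptophan
    1715.0: 1.20,  # C=O lipids
    1772.0: 1.20,  # C=O
}


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber axis in cm^-1."""

    start: float = 500.0
    stop: float = 2500.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ConfigurationError("grid.start must be >= 0")
        if self.step <= 0:
            raise ConfigurationError("grid.step must be > 0")
        if self.stop <= self.start:
            raise ConfigurationError("grid.stop must exceed grid.start")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return float(self.start) + float(self.step) * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1


@dataclass(frozen=True)
class PeakModel:
    """One Raman line.

    ``width`` is the half-width at half-maximum (cm^-1) for both line
    shapes; the peak evaluates to exactly ``base_amplitude`` at its center.
    ``class_effect`` multiplies the amplitude for CeD spectra only.
    """

    center: float
    width: float = 8.0
    base_amplitude: float = 1.0
    class_effect: float = 1.0
    shape: Literal["lorentzian", "gaussian"] = "lorentzian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError("peak.width must be > 0")
        if self.base_amplitude < 0:
            raise ConfigurationError("peak.base_amplitude must be >= 0")
        if self.class_effect <= 0:
            raise ConfigurationError("peak.class_effect must be > 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ConfigurationError(f"unknown peak shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-amplitude line profile on ``wavenumbers``."""
        d = wavenumbers - self.center
        if self.shape == "lorentzian":
            return 1.0 / (1.0 + (d / self.width) ** 2)
        # Gaussian with matching half-width at half-maximum
        return np.exp(-np.log(2.0) * (d / self.width) ** 2)


# Class-neutral plasma bands (phenylalanine 1002, amide I 1655, amide III
# 1250, tyrosine/tryptophan lines, lipid C-C etc.) so that the two classes
# overlap at most channels and are not separable from any single band.
_SHARED_PEAKS: tuple[tuple[float, float, float], ...] = (
    # (center, width, amplitude)
    (621.0, 7.0, 0.30),
    (643.0, 7.0, 0.30),
    (757.0, 7.0, 0.40),
    (852.0, 8.0, 0.55),
    (877.0, 8.0, 0.40),
    (1002.0, 6.0, 1.50),
    (1031.0, 7.0, 0.60),
    (1083.0, 9.0, 0.50),
    (1156.0, 8.0, 0.70),
    (1208.0, 8.0, 0.40),
    (1250.0, 10.0, 0.60),
    (1340.0, 9.0, 0.50),
    (1585.0, 8.0, 0.40),
    (1655.0, 10.0, 1.20),
    (2120.0, 12.0, 0.15),
    (2330.0, 12.0, 0.12),
)

_DIFFERENTIAL_AMPLITUDES: dict[float, float] = {
    1402.0: 0.90,
    1445.0: 1.30,
    1477.0: 0.80,
    1518.0: 0.70,
    1545.0: 0.70,
    1715.0: 0.50,
    1772.0: 0.40,
}


def build_default_peak_set(
    include_shared: bool = True,
    shape: Literal["lorentzian", "gaussian"] = "lorentzian",
) -> list[PeakModel]:
    """Default peak set: 7 class-differential bands plus shared bands.

    The differential bands carry ``class_effect`` > 1 (higher in CeD)
    everywhere except 1445 cm^-1, where the effect is < 1. Shared bands
    have ``class_effect`` = 1 so the classes are not trivially separable
    at every channel.
    """
    peaks = [
        PeakModel(
            center=c,
            width=8.0,
            base_amplitude=_DIFFERENTIAL_AMPLITUDES[c],
            class_effect=e,
            shape=shape,
        )
        for c, e in DIFFERENTIAL_BANDS.items()
    ]
    if include_shared:
        peaks.extend(
            PeakModel(center=c, width=w, base_amplitude=a, shape=shape)
            for c, w, a in _SHARED_PEAKS
        )
    return sorted(peaks, key=lambda p: p.center)


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_ced: int = 29
    n_control: int = 30
    replicates_per_patient: int = 3
    grid: WavenumberGrid = field(default_factory=WavenumberGrid)
    peaks: tuple[PeakModel, ...] = field(
        default_factory=lambda: tuple(build_default_peak_set())
    )
    #: Cubic fluorescence baseline: coefficients of 1, u, u^2, u^3 in the
    #: normalized coordinate u = (w - start)/(stop - start), intensity units.
    baseline_coeffs: tuple[float, ...] = (6.0, -4.0, 1.0, 0.5)
    broad_background_amplitude: float = 3.0
    broad_background_center: float = 1100.0
    broad_background_sigma: float = 400.0
    replicate_noise_sd: float = 0.05
    patient_noise_sd: float = 0.02
    patient_scale_sigma: float = 0.1
    noise_model: Literal["additive", "shot"] = "additive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ced < 1:
            raise ConfigurationError("n_ced must be >= 1")
        if self.n_control < 1:
            raise ConfigurationError("n_control must be >= 1")
        if self.replicates_per_patient < 1:
            raise ConfigurationError("replicates_per_patient must be >= 1")
        if self.replicate_noise_sd < 0:
            raise ConfigurationError("replicate_noise_sd must be >= 0")
        if self.patient_noise_sd < 0:
            raise ConfigurationError("patient_noise_sd must be >= 0")
        if self.patient_scale_sigma < 0:
            raise ConfigurationError("patient_scale_sigma must be >= 0")
        if self.noise_model not in ("additive", "shot"):
            raise ConfigurationError(f"unknown noise_model {self.noise_model!r}")
        object.__setattr__(self, "peaks", tuple(self.peaks))
        object.__setattr__(
            self, "baseline_coeffs", tuple(float(c) for c in self.baseline_coeffs)
        )

    def with_(self, **changes) -> "CohortSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def parameter_hash(self) -> str:
        payload = json.dumps(_spec_to_dict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def baseline(self) -> np.ndarray:
        """Shared smooth background evaluated on the grid."""
        w = self.grid.values
        u = (w - self.grid.start) / (self.grid.stop - self.grid.start)
        base = np.polynomial.polynomial.polyval(u, self.baseline_coeffs)
        broad = self.broad_background_amplitude * np.exp(
            -0.5 * ((w - self.broad_background_center) / self.broad_background_sigma) ** 2
        )
        return np.asarray(base + broad, dtype=float)


@dataclass
class Spectrum:
    """One intensity trace with its patient/group/replicate metadata."""

    patient_id: str
    group: Literal["CeD", "control"]
    replicate_index: int
    grid: WavenumberGrid
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.grid),):
            raise ConfigurationError(
                f"spectrum {self.patient_id}: {self.intensities.size} intensities "
                f"on a {len(self.grid)}-point grid"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ConfigurationError(
                f"spectrum {self.patient_id}: non-finite intensities"
            )
        if self.group not in ("CeD", "control"):
            raise ConfigurationError(f"unknown group {self.group!r}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.group == other.group
            and self.replicate_index == other.replicate_index
            and self.grid == other.grid
            and np.array_equal(self.intensities, other.intensities)
        )


@dataclass
class Cohort:
    """A collection of spectra plus the recipe and provenance that made it."""

    spectra: list[Spectrum]
    spec: CohortSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for s in self.spectra:
            counts[s.patient_id] = counts.get(s.patient_id, 0) + 1

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    def patient_groups(self) -> dict[str, str]:
        return {s.patient_id: s.group for s in self.spectra}

    def replicates_of(self, patient_id: str) -> list[Spectrum]:
        return [s for s in self.spectra if s.patient_id == patient_id]

    def intensity_matrix(self) -> np.ndarray:
        """Spectra stacked as a (n_spectra, n_channels) array."""
        return np.stack([s.intensities for s in self.spectra])

    def labels(self) -> np.ndarray:
        """Binary labels with CeD as the positive class (1)."""
        return np.array([1 if s.group == "CeD" else 0 for s in self.spectra])

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.spectra == other.spectra
            and self.spec == other.spec
            and self.provenance == other.provenance
        )


def render_clean_spectrum(
    grid: WavenumberGrid,
    peaks: Sequence[PeakModel],
    group: str,
    patient_scale: float = 1.0,
) -> np.ndarray:
    """Noise- and background-free forward model: the sum of peak profiles.

    Each peak contributes ``base_amplitude * class_effect`` (CeD) or
    ``base_amplitude`` (control), times the patient's global scale.
    Deterministic in its arguments; an empty peak list yields zeros.
    """
    if patient_scale <= 0:
        raise ConfigurationError("patient_scale must be > 0")
    w = grid.values
    out = np.zeros_like(w)
    for p in peaks:
        amp = p.base_amplitude * (p.class_effect if group == "CeD" else 1.0)
        out += amp * p.profile(w)
    return out * patient_scale


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort from its spec, reproducibly from the seed.

    Draw order is fixed (CeD patients first, then controls; per patient:
    global scale, patient channel offset, then one noise vector per
    replicate), so identical specs give bit-identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    baseline = spec.baseline()
    n = len(spec.grid)
    spectra: list[Spectrum] = []

    width = max(2, len(str(max(spec.n_ced, spec.n_control))))
    roster: list[tuple[str, str]] = [
        (f"ced{i + 1:0{width}d}", "CeD") for i in range(spec.n_ced)
    ] + [(f"ctl{i + 1:0{width}d}", "control") for i in range(spec.n_control)]

    for patient_id, group in roster:
        scale = float(np.exp(rng.normal(0.0, spec.patient_scale_sigma)))
        clean = render_clean_spectrum(spec.grid, spec.peaks, group, scale)
        patient_dev = rng.normal(0.0, spec.patient_noise_sd, n)
        signal = clean + baseline + patient_dev
        for rep in range(1, spec.replicates_per_patient + 1):
            if spec.noise_model == "shot":
                local_sd = spec.replicate_noise_sd * np.sqrt(
                    np.maximum(signal, 0.0) / max(signal.max(), 1e-12)
                )
                noise = rng.normal(0.0, 1.0, n) * local_sd
            else:
                noise = rng.normal(0.0, spec.replicate_noise_sd, n)
            spectra.append(
                Spectrum(
                    patient_id=patient_id,
                    group=group,
                    replicate_index=rep,
                    grid=spec.grid,
                    intensities=signal + noise,
                )
            )

    provenance = {
        "seed": spec.seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "parameter_hash": spec.parameter_hash(),
        "generator": "ramanced.synth.generate_cohort",
    }
    return Cohort(spectra=spectra, spec=spec, provenance=provenance)


def _spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "n_ced": spec.n_ced,
        "n_control": spec.n_control,
        "replicates_per_patient": spec.replicates_per_patient,
        "grid": {"start": spec.grid.start, "stop": spec.grid.stop, "step": spec.grid.step},
        "peaks": [
            {
                "center": p.center,
                "width": p.width,
                "base_amplitude": p.base_amplitude,
                "class_effect": p.class_effect,
                "shape": p.shape,
            }
            for p in spec.peaks
        ],
        "baseline_coeffs": list(spec.baseline_coeffs),
        "broad_background_amplitude": spec.broad_background_amplitude,
        "broad_background_center": spec.broad_background_center,
        "broad_background_sigma": spec.broad_background_sigma,
        "replicate_noise_sd": spec.replicate_noise_sd,
        "patient_noise_sd": spec.patient_noise_sd,
        "patient_scale_sigma": spec.patient_scale_sigma,
        "noise_model": spec.noise_model,
        "seed": spec.seed,
    }


def _spec_from_dict(d: dict) -> CohortSpec:
    grid = WavenumberGrid(**d["grid"])
    peaks = tuple(PeakModel(**p) for p in d["peaks"])
    return CohortSpec(
        n_ced=d["n_ced"],
        n_control=d["n_control"],
        replicates_per_patient=d["replicates_per_patient"],
        grid=grid,
        peaks=peaks,
        baseline_coeffs=tuple(d["baseline_coeffs"]),
        broad_background_amplitude=d["broad_background_amplitude"],
        broad_background_center=d["broad_background_center"],
        broad_background_sigma=d["broad_background_sigma"],
        replicate_noise_sd=d["replicate_noise_sd"],
        patient_noise_sd=d["patient_noise_sd"],
        patient_scale_sigma=d["patient_scale_sigma"],
        noise_model=d["noise_model"],
        seed=d["seed"],
    )
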