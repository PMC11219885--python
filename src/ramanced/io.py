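"""Reading and writing cohorts as plain-text CSV.

Two dialects are supported:

* wide — first column ``wavenumber``, one column per spectrum with header
  ``<patient_id>_<group>_<replicate>``;
* long — columns ``patient_id, group, replicate, wavenumber, intensity``.

A JSON sidecar ``<stem>.provenance.json`` next to the CSV carries the full
generation spec and provenance so the round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .synth import Cohort, CohortSpec, Spectrum, WavenumberGrid, _spec_from_dict, _spec_to_dict

__all__ = ["write_cohort", "read_cohort", "sidecar_path"]


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".provenance.json")


def write_cohort(cohort: Cohort, path: str | Path, layout: str = "wide") -> Path:
    """Write a cohort CSV plus its provenance sidecar; returns the CSV path."""
    path = Path(path)
    if layout == "wide":
        data = {"wavenumber": cohort.spec.grid.values}
        for s in cohort.spectra:
            data[f"{s.patient_id}_{s.group}_{s.replicate_index}"] = s.intensities
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")
    elif layout == "long":
        frames = []
        for s in cohort.spectra:
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": s.patient_id,
                        "group": s.group,
                        "replicate": s.replicate_index,
                        "wavenumber": s.grid.values,
                        "intensity": s.intensities,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(
            path, index=False, float_format="%.10g"
        )
    else:
        raise ParseError(f"unknown layout {layout!r} (expected 'wide' or 'long')")

    with open(sidecar_path(path), "w") as fh:
        json.dump(
            {"spec": _spec_to_dict(cohort.spec), "provenance": cohort.provenance},
            fh,
            indent=1,
        )
    return path


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV (wide or long, auto-detected) and its sidecar."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed CSV ({exc})") from exc
    if frame.isna().any().any():
        bad = int(np.argmax(frame.isna().any(axis=1).to_numpy()))
        raise ParseError(f"{path}: missing values (mismatched row length near row {bad + 2})")

    long_cols = {"patient_id", "group", "replicate", "wavenumber", "intensity"}
    if long_cols <= set(frame.columns):
        spectra = _spectra_from_long(frame, path)
    elif "wavenumber" in frame.columns:
        spectra = _spectra_from_wide(frame, path)
    else:
        raise ParseError(f"{path}: missing required column 'wavenumber'")

    spec, provenance = _read_sidecar(path, spectra)
    return Cohort(spectra=spectra, spec=spec, provenance=provenance)


def _grid_from_values(values: np.ndarray, path: Path) -> WavenumberGrid:
    steps = np.diff(values)
    if values.size < 2 or steps.min() <= 0:
        raise ParseError(f"{path}: wavenumber column must be strictly increasing")
    return WavenumberGrid(
        start=float(values[0]), stop=float(values[-1]), step=float(steps.mean())
    )


def _spectra_from_wide(frame: pd.DataFrame, path: Path) -> list[Spectrum]:
    grid = _grid_from_values(frame["wavenumber"].to_numpy(float), path)
    spectra = []
    for col in frame.columns:
        if col == "wavenumber":
            continue
        parts = col.rsplit("_", 2)
        if len(parts) != 3:
            raise ParseError(
                f"{path}: column {col!r} does not encode patient_group_replicate "
                "(missing group or replicate field)"
            )
        pid, group, rep = parts
        if group not in ("CeD", "control"):
            raise ParseError(f"{path}: column {col!r}: unknown group {group!r}")
        try:
            rep_i = int(rep)
        except ValueError as exc:
            raise ParseError(f"{path}: column {col!r}: bad replicate index") from exc
        spectra.append(
            Spectrum(
                patient_id=pid,
                group=group,  # type: ignore[arg-type]
                replicate_index=rep_i,
                grid=grid,
                intensities=frame[col].to_numpy(float),
            )
        )
    if not spectra:
        raise ParseError(f"{path}: no spectrum columns found")
    return spectra


def _spectra_from_long(frame: pd.DataFrame, path: Path) -> list[Spectrum]:
    spectra = []
    for (pid, group, rep), sub in frame.groupby(
        ["patient_id", "group", "replicate"], sort=False
    ):
        sub = sub.sort_values("wavenumber")
        grid = _grid_from_values(sub["wavenumber"].to_numpy(float), path)
        if group not in ("CeD", "control"):
            raise ParseError(f"{path}: unknown group {group!r} for patient {pid}")
        spectra.append(
            Spectrum(
                patient_id=str(pid),
                group=group,
                replicate_index=int(rep),
                grid=grid,
                intensities=sub["intensity"].to_numpy(float),
            )
        )
    return spectra


def _read_sidecar(path: Path, spectra: list[Spectrum]) -> tuple[CohortSpec, dict]:
    side = sidecar_path(path)
    if side.exists():
        try:
            payload = json.loads(side.read_text())
            return _spec_from_dict(payload["spec"]), payload.get("provenance", {})
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise ParseError(f"{side}: malformed provenance sidecar ({exc})") from exc
    # No sidecar: reconstruct a minimal spec from the data itself.
    groups = {s.patient_id: s.group for s in spectra}
    reps = max(s.replicate_index for s in spectra)
    spec = CohortSpec(
        n_ced=max(1, sum(1 for g in groups.values() if g == "CeD")),
        n_control=max(1, sum(1 for g in groups.values() if g == "control")),
        replicates_per_patient=reps,
        grid=spectra[0].grid,
        peaks=(),
    )
    return spec, {}
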