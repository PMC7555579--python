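"""Spatial data model and NIfTI / manifest I/O.

All pipeline stages exchange three containers: :class:`ImageVolume` (one 3-D
scalar grid with voxel spacing), :class:`DWISeries` (the per-patient,
per-timepoint set of b-value volumes), and :class:`CohortManifest` (file
locations and Lugano response labels for a whole cohort).

Conventions
-----------
* Volumes are stored axis-order ``(x, y, z)`` with ``spacing = (dx, dy, dz)``
  in mm.  Orientation is recorded as a tag but never resampled: all volumes of
  one patient/timepoint must already live on the same grid.
* One stitched whole-body volume per b-value per timepoint is assumed.
* Intensities are passed through unmodified at I/O time; thresholding
  semantics live in :mod:`wbdwi.tumor_load`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import yaml

from .errors import (
    EmptyCohortError,
    LabelError,
    ManifestError,
    MetadataError,
    ShapeMismatchError,
)

LUGANO_LABELS = ("CMR", "PMR", "SMD", "PMD")

#: Timepoints: 0 = baseline, 1 = interim (after two chemo cycles), 2 = EOT.
TIMEPOINTS = (0, 1, 2)


@dataclass
class ImageVolume:
    """A 3-D scalar grid with voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values; arbitrary units for DWI signal, x1e-6 mm^2/s for ADC.
    spacing : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in mm, each > 0.
    orientation_tag : str
        Label recording the axis-order convention (informational only).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    orientation_tag: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeMismatchError(
                f"expected a 3-D grid, got ndim={self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise ShapeMismatchError(f"degenerate grid shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def like(self, data: np.ndarray) -> "ImageVolume":
        """A new volume on this grid carrying ``data``."""
        return ImageVolume(data, self.spacing, self.orientation_tag)


@dataclass
class DWISeries:
    """All b-value volumes of one patient at one timepoint.

    ``volumes`` maps b-value (s/mm^2) to :class:`ImageVolume`.  At least two
    distinct b-values are required and all volumes must share grid shape and
    spacing.
    """

    patient_id: str
    timepoint: int
    volumes: dict[int, ImageVolume]

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ManifestError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint}")
        if len(self.volumes) < 2:
            raise ManifestError(
                f"series {self.patient_id}/T{self.timepoint} needs >=2 b-values, "
                f"got {sorted(self.volumes)}"
            )
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) > 1:
            raise ShapeMismatchError(
                f"series {self.patient_id}/T{self.timepoint}: b-value volumes have "
                f"mismatched shapes {sorted(shapes)}"
            )
        spacings = {v.spacing for v in self.volumes.values()}
        if len(spacings) > 1:
            raise ShapeMismatchError(
                f"series {self.patient_id}/T{self.timepoint}: b-value volumes have "
                f"mismatched spacings {sorted(spacings)}"
            )

    @property
    def b_values(self) -> tuple[int, ...]:
        return tuple(sorted(self.volumes))

    @property
    def spacing(self) -> tuple[float, float, float]:
        return next(iter(self.volumes.values())).spacing


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1, encoding spacing on the affine diagonal."""
    path = Path(path)
    affine = np.diag((*volume.spacing, 1.0))
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI volume; spacing is taken from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise MetadataError(f"{path}: missing or invalid voxel spacing {zooms}")
    return ImageVolume(data, tuple(float(z) for z in zooms))


def read_series(
    paths: Mapping[int, str | Path], patient_id: str, timepoint: int
) -> DWISeries:
    """Load one patient/timepoint series from per-b-value file locations.

    Signal values are passed through unmodified; grid consistency across
    b-values is enforced by the :class:`DWISeries` invariants.
    """
    volumes = {int(b): read_volume(p) for b, p in paths.items()}
    return DWISeries(patient_id=str(patient_id), timepoint=int(timepoint), volumes=volumes)


@dataclass
class PatientEntry:
    """Manifest row: series file locations at T0/T1/T2 plus response labels."""

    patient_id: str
    series_paths: dict[int, dict[int, Path]]  # timepoint -> {b-value: path}
    label_t1: str
    label_t2: str

    def label_at(self, timepoint: int) -> str:
        if timepoint == 1:
            return self.label_t1
        if timepoint == 2:
            return self.label_t2
        raise ManifestError(f"no response label is defined at T{timepoint}")


@dataclass
class CohortManifest:
    """Ordered cohort of :class:`PatientEntry`.  Order is preserved from file."""

    patients: list[PatientEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def labels(self, timepoint: int) -> dict[str, str]:
        return {p.patient_id: p.label_at(timepoint) for p in self.patients}

    def label_counts(self, timepoint: int) -> dict[str, int]:
        counts = dict.fromkeys(LUGANO_LABELS, 0)
        for p in self.patients:
            counts[p.label_at(timepoint)] += 1
        return counts

    def label_percentages(self, timepoint: int) -> dict[str, float]:
        """Per-label share of the cohort in percent (Lugano summary table)."""
        n = len(self.patients)
        if n == 0:
            raise EmptyCohortError("cannot compute percentages of an empty cohort")
        return {k: 100.0 * v / n for k, v in self.label_counts(timepoint).items()}


_MANIFEST_COLUMNS = (
    "patient_id",
    "t0_b50", "t0_b800", "t1_b50", "t1_b800", "t2_b50", "t2_b800",
    "label_t1", "label_t2",
)


def _entry_from_record(
    rec: Mapping[str, object], base: Path, b_low: int, b_high: int, problems: list[str]
) -> PatientEntry | None:
    pid = str(rec.get("patient_id", "")).strip()
    if not pid:
        problems.append("record with missing patient_id")
        return None
    series_paths: dict[int, dict[int, Path]] = {}
    for t in TIMEPOINTS:
        paths = {}
        for b, col in ((b_low, f"t{t}_b{b_low}"), (b_high, f"t{t}_b{b_high}")):
            raw = rec.get(col)
            if raw in (None, ""):
                problems.append(f"{pid}: missing column {col}")
                continue
            p = Path(str(raw))
            if not p.is_absolute():
                p = base / p
            paths[b] = p
        series_paths[t] = paths
    labels = {}
    for key in ("label_t1", "label_t2"):
        lab = str(rec.get(key, "")).strip().upper()
        if lab not in LUGANO_LABELS:
            problems.append(
                f"{pid}: {key}={lab!r} is not a Lugano category {LUGANO_LABELS}"
            )
            lab = ""
        labels[key] = lab
    if any(len(series_paths[t]) != 2 for t in TIMEPOINTS) or "" in labels.values():
        return None
    return PatientEntry(pid, series_paths, labels["label_t1"], labels["label_t2"])


def load_manifest(
    config_file: str | Path,
    *,
    b_low: int = 50,
    b_high: int = 800,
    check_files: bool = False,
) -> CohortManifest:
    """Load a cohort manifest from YAML (``patients:`` list) or CSV.

    Relative volume paths resolve against the manifest's directory.  All
    validation problems are aggregated into a single :class:`ManifestError`;
    unknown response labels raise :class:`LabelError` naming the patient.
    """
    config_file = Path(config_file)
    base = config_file.parent
    if config_file.suffix.lower() in (".yaml", ".yml"):
        with open(config_file) as fh:
            doc = yaml.safe_load(fh) or {}
        records = doc.get("patients", doc if isinstance(doc, list) else [])
    else:
        with open(config_file, newline="") as fh:
            records = list(csv.DictReader(fh))

    if not records:
        raise EmptyCohortError(f"{config_file}: manifest contains no patients")

    problems: list[str] = []
    patients = []
    for rec in records:
        entry = _entry_from_record(rec, base, b_low, b_high, problems)
        if entry is not None:
            patients.append(entry)

    if check_files:
        for p in patients:
            for t, paths in p.series_paths.items():
                for b, path in paths.items():
                    if not path.exists():
                        problems.append(f"{p.patient_id}: missing file T{t} b{b}: {path}")

    if problems:
        msg = f"{config_file}: {len(problems)} manifest problem(s):\n  " + "\n  ".join(problems)
        if any("Lugano" in p for p in problems):
            raise LabelError(msg)
        raise ManifestError(msg)
    return CohortManifest(patients)


def save_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    """Write a manifest as YAML with paths relative to the output directory."""
    path = Path(path)
    base = path.parent

    def _rel(p: Path) -> str:
        try:
            return str(p.relative_to(base))
        except ValueError:
            return str(p)

    records = []
    for pat in manifest:
        rec: dict[str, str] = {"patient_id": pat.patient_id}
        for t in TIMEPOINTS:
            for b, p in sorted(pat.series_paths[t].items()):
                rec[f"t{t}_b{b}"] = _rel(p)
        rec["label_t1"] = pat.label_t1
        rec["label_t2"] = pat.label_t2
        records.append(rec)
    with open(path, "w") as fh:
        yaml.safe_dump({"patients": records}, fh, sort_keys=False)
    return path
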