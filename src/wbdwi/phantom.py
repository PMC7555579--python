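"""Synthetic whole-body DWI phantom cohorts with ground truth.

The phantom is a stylized torso, not an anatomical atlas: an elliptic-
cylinder body of soft tissue inside an air background, a brain at the top,
two kidneys, a spleen, and a vertical bone-marrow stripe (spine).  These are
exactly the structures that confound unedited threshold segmentation of
high-b-value images — the brain, kidneys and spleen are physiologically
hyperintense, and chemotherapy-activated marrow brightens at follow-up — so
the simulated cohorts exercise the same failure modes the automatic
tumor-load procedure faces on real data.

Signal model per voxel and b-value: ``S(b) = S0 * exp(-b * ADC)`` with the
voxelwise ADC drawn once per phantom from a region-specific normal
distribution (negative draws clipped to zero), then independent Rician noise
per b-value volume, matching the magnitude statistics of MR data:
``S_noisy = sqrt((S + n1)^2 + n2^2)``, ``n1, n2 ~ N(0, sigma^2)``.

Longitudinal response scenarios scale the lesions between timepoints:
responders shrink (volume factor applied to radii as its cube root) and
their ADC rises as cellularity drops; partial responders do both far less.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyCohortError, ParameterError
from .volumes import (
    CohortManifest,
    DWISeries,
    ImageVolume,
    PatientEntry,
    save_manifest,
    write_volume,
)

# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class TissueParams:
    """Per-region signal parameters: S0 (a.u.), ADC mean/sd (1e-6 mm^2/s)."""

    s0: float
    adc_mean: float
    adc_sd: float


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal lymphoma lesion: hypercellular, hence bright at b800."""

    center: tuple[float, float, float]  # mm
    radii: tuple[float, float, float]  # mm, semi-axes
    adc_mean: float = 900.0
    adc_sd: float = 150.0
    s0: float = 1000.0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ParameterError(f"lesion radii must be positive, got {self.radii}")
        if self.adc_sd < 0 or self.s0 <= 0:
            raise ParameterError("lesion needs adc_sd >= 0 and s0 > 0")


@dataclass(frozen=True)
class OrganSpec:
    """A fixed anatomical region: ellipsoid or (elliptic) cylinder in mm."""

    name: str
    kind: str  # "ellipsoid" | "cylinder" | "elliptic_cylinder"
    center: tuple[float, float]  # (cx, cy) mm; ellipsoids add cz via z_extent
    size: tuple[float, ...]  # radii (rx, ry[, rz]) mm
    z_extent: tuple[float, float]  # mm along z
    tissue: TissueParams


@dataclass(frozen=True)
class PhantomSpec:
    """Complete ground-truth description of one simulated acquisition."""

    shape: tuple[int, int, int] = (96, 96, 220)
    spacing: tuple[float, float, float] = (2.0, 2.0, 5.0)
    background: TissueParams = TissueParams(300.0, 1600.0, 200.0)
    organs: tuple[OrganSpec, ...] = ()
    lesions: tuple[LesionSpec, ...] = ()
    noise_sigma: float = 10.0
    seed: int = 0
    body_semi_axes: tuple[float, float] | None = None  # None -> tissue fills grid

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        extent = self.extent_mm
        for les in self.lesions:
            for c, r, e in zip(les.center, les.radii, extent):
                if c - r < 0 or c + r > e:
                    raise ParameterError(
                        f"lesion at {les.center} mm (radii {les.radii}) exceeds grid extent {extent}"
                    )

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]


@dataclass(frozen=True)
class ResponseScenario:
    """Per-timepoint lesion evolution for one Lugano response class.

    ``volume_factors``/``adc_factors`` are (T1, T2) multipliers relative to
    baseline: lesion volume scales radii by the factor's cube root; the ADC
    factor multiplies both the lesion ADC mean and sd (the whole distribution
    shifts and broadens as cellularity falls).  Marrow activation raises the
    bone-marrow S0 at T1/T2, emulating chemotherapy-stimulated marrow.
    """

    label: str
    volume_factors: tuple[float, float]
    adc_factors: tuple[float, float]
    marrow_activation: bool = True
    marrow_s0_factor: float = 1.6

    def __post_init__(self) -> None:
        if self.label not in ("CMR", "PMR"):
            raise ParameterError(f"scenario label must be CMR or PMR, got {self.label}")
        if any(not (0 < v <= 1) for v in self.volume_factors):
            raise ParameterError("volume factors must lie in (0, 1]")


#: Default response biology: complete responders lose 75% of lesion volume by
#: interim and 95% by EOT with a 30-45% ADC rise; partial responders change
#: far less.  Order-of-magnitude clinical choices, exposed as parameters.
CMR_SCENARIO = ResponseScenario("CMR", volume_factors=(0.25, 0.05), adc_factors=(1.30, 1.45))
PMR_SCENARIO = ResponseScenario("PMR", volume_factors=(0.70, 0.50), adc_factors=(1.05, 1.10))
DEFAULT_SCENARIOS = {"CMR": CMR_SCENARIO, "PMR": PMR_SCENARIO}


def default_organs(extent: tuple[float, float, float]) -> tuple[OrganSpec, ...]:
    """Hyperintense-organ layout scaled to the grid extent (mm)."""
    ex, ey, ez = extent
    cx, cy = ex / 2, ey / 2
    s = min(ex / 192.0, ey / 192.0, ez / 1100.0)  # relative to the default torso

    def _z(frac_lo: float, frac_hi: float) -> tuple[float, float]:
        return (frac_lo * ez, frac_hi * ez)

    return (
        OrganSpec("brain", "ellipsoid", (cx, cy), (55 * s, 55 * s, 50 * s),
                  _z(0.90, 1.0), TissueParams(900.0, 800.0, 100.0)),
        OrganSpec("kidney_left", "ellipsoid", (cx - 36 * s, cy), (20 * s, 20 * s, 38 * s),
                  _z(0.44, 0.52), TissueParams(950.0, 1800.0, 150.0)),
        OrganSpec("kidney_right", "ellipsoid", (cx + 36 * s, cy), (20 * s, 20 * s, 38 * s),
                  _z(0.44, 0.52), TissueParams(950.0, 1800.0, 150.0)),
        OrganSpec("spleen", "ellipsoid", (cx + 44 * s, cy - 26 * s), (26 * s, 22 * s, 38 * s),
                  _z(0.50, 0.58), TissueParams(850.0, 850.0, 100.0)),
        OrganSpec("bone_marrow", "cylinder", (cx, cy + 44 * s), (11 * s,),
                  _z(0.08, 0.86), TissueParams(500.0, 600.0, 100.0)),
    )


def default_torso_spec(
    shape: tuple[int, int, int] = (96, 96, 220),
    spacing: tuple[float, float, float] = (2.0, 2.0, 5.0),
    lesions: tuple[LesionSpec, ...] = (),
    noise_sigma: float = 10.0,
    seed: int = 0,
    include_organs: bool = True,
) -> PhantomSpec:
    """A torso phantom with the default organ set on the requested grid."""
    extent = tuple(n * s for n, s in zip(shape, spacing))
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        organs=default_organs(extent) if include_organs else (),
        lesions=tuple(lesions),
        noise_sigma=noise_sigma,
        seed=seed,
        body_semi_axes=(0.42 * extent[0], 0.37 * extent[1]),
    )


# ---------------------------------------------------------------------------
# rendering

AIR, BACKGROUND = 0, 1
ORGAN_BASE, LESION_BASE = 2, 100


@dataclass
class PhantomTruth:
    """Ground truth rendered alongside the series."""

    label_volume: ImageVolume  # int codes: 0 air, 1 tissue, 2+ organs, 100+ lesions
    adc_volume: ImageVolume  # the drawn noiseless ADC field, 1e-6 mm^2/s
    lesion_volumes_cm3: list[float]  # voxel-count volumes per lesion
    region_names: dict[int, str]

    @property
    def total_lesion_volume_cm3(self) -> float:
        return float(sum(self.lesion_volumes_cm3))

    def lesion_mask(self) -> np.ndarray:
        return self.label_volume.data >= LESION_BASE


def _voxel_centers(shape, spacing):
    return [
        (np.arange(n, dtype=np.float64) + 0.5) * s for n, s in zip(shape, spacing)
    ]


def _region_mask(spec: PhantomSpec, organ: OrganSpec) -> np.ndarray:
    xs, ys, zs = _voxel_centers(spec.shape, spec.spacing)
    x = xs[:, None, None]
    y = ys[None, :, None]
    z = zs[None, None, :]
    z_lo, z_hi = organ.z_extent
    cx, cy = organ.center
    if organ.kind == "ellipsoid":
        cz = (z_lo + z_hi) / 2
        rx, ry, rz = organ.size
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0
    if organ.kind == "cylinder":
        (r,) = organ.size
        return (((x - cx) ** 2 + (y - cy) ** 2) <= r * r) & (z >= z_lo) & (z <= z_hi)
    if organ.kind == "elliptic_cylinder":
        rx, ry = organ.size
        return (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0) & (z >= z_lo) & (z <= z_hi)
    raise ParameterError(f"unknown region kind {organ.kind!r}")


def _lesion_mask(spec: PhantomSpec, les: LesionSpec) -> np.ndarray:
    xs, ys, zs = _voxel_centers(spec.shape, spec.spacing)
    cx, cy, cz = les.center
    rx, ry, rz = les.radii
    return (
        ((xs[:, None, None] - cx) / rx) ** 2
        + ((ys[None, :, None] - cy) / ry) ** 2
        + ((zs[None, None, :] - cz) / rz) ** 2
        <= 1.0
    )


def render_phantom(
    spec: PhantomSpec,
    patient_id: str = "phantom",
    timepoint: int = 0,
    b_values: tuple[int, ...] = (50, 800),
) -> tuple[DWISeries, PhantomTruth]:
    """Render the b-value volumes of a phantom plus its ground truth.

    Deterministic given ``spec.seed``.  Lesions take precedence over organs;
    overlapping voxels are relabelled as lesion with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.full(spec.shape, BACKGROUND, dtype=np.int32)
    region_names = {AIR: "air", BACKGROUND: "background"}

    if spec.body_semi_axes is not None:
        ex, ey, _ = spec.extent_mm
        body = OrganSpec(
            "body", "elliptic_cylinder", (ex / 2, ey / 2), spec.body_semi_axes,
            (0.0, spec.extent_mm[2]), spec.background,
        )
        labels[~_region_mask(spec, body)] = AIR

    tissues: dict[int, TissueParams] = {BACKGROUND: spec.background}
    for i, organ in enumerate(spec.organs):
        code = ORGAN_BASE + i
        labels[_region_mask(spec, organ) & (labels != AIR)] = code
        tissues[code] = organ.tissue
        region_names[code] = organ.name

    lesion_volumes = []
    vox_cm3 = math.prod(spec.spacing) / 1000.0
    for i, les in enumerate(spec.lesions):
        code = LESION_BASE + i
        m = _lesion_mask(spec, les)
        n_organ_overlap = int((m & (labels >= ORGAN_BASE) & (labels < LESION_BASE)).sum())
        if n_organ_overlap:
            warnings.warn(
                f"lesion {i} overlaps organ voxels (n={n_organ_overlap}); lesion takes precedence",
                stacklevel=2,
            )
        labels[m] = code
        tissues[code] = TissueParams(les.s0, les.adc_mean, les.adc_sd)
        lesion_volumes.append(int(m.sum()) * vox_cm3)
        region_names[code] = f"lesion_{i}"

    adc = np.zeros(spec.shape, dtype=np.float64)
    s0 = np.zeros(spec.shape, dtype=np.float64)
    for code in sorted(tissues):
        sel = labels == code
        n = int(sel.sum())
        if n == 0:
            continue
        t = tissues[code]
        adc[sel] = np.maximum(rng.normal(t.adc_mean, t.adc_sd, size=n), 0.0)
        s0[sel] = t.s0

    volumes = {}
    for b in b_values:
        signal = s0 * np.exp(-b * 1.0e-6 * adc)
        if spec.noise_sigma > 0:
            n1 = rng.normal(0.0, spec.noise_sigma, size=spec.shape)
            n2 = rng.normal(0.0, spec.noise_sigma, size=spec.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
        volumes[b] = ImageVolume(signal, spec.spacing)

    series = DWISeries(patient_id=patient_id, timepoint=timepoint, volumes=volumes)
    truth = PhantomTruth(
        label_volume=ImageVolume(labels, spec.spacing),
        adc_volume=ImageVolume(adc, spec.spacing),
        lesion_volumes_cm3=lesion_volumes,
        region_names=region_names,
    )
    return series, truth


# ---------------------------------------------------------------------------
# longitudinal scenarios


def apply_scenario(spec: PhantomSpec, scenario: ResponseScenario) -> dict[int, PhantomSpec]:
    """Per-timepoint specs {0: baseline, 1: interim, 2: EOT} under a scenario.

    Baseline is returned unchanged; follow-up specs scale each lesion's radii
    by the cube root of the volume factor and its ADC distribution by the ADC
    factor, and (if flagged) raise the bone-marrow S0.  Each timepoint gets
    its own noise seed derived from the baseline seed.
    """
    out = {0: spec}
    for t, (vf, af) in enumerate(zip(scenario.volume_factors, scenario.adc_factors), start=1):
        r_scale = vf ** (1.0 / 3.0)
        lesions = tuple(
            replace(
                les,
                radii=tuple(r * r_scale for r in les.radii),
                adc_mean=les.adc_mean * af,
                adc_sd=les.adc_sd * af,
            )
            for les in spec.lesions
        )
        organs = spec.organs
        if scenario.marrow_activation:
            organs = tuple(
                replace(o, tissue=replace(o.tissue, s0=o.tissue.s0 * scenario.marrow_s0_factor))
                if o.name == "bone_marrow"
                else o
                for o in organs
            )
        out[t] = replace(spec, lesions=lesions, organs=organs, seed=spec.seed + t)
    return out


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortParams:
    """Randomized per-patient anatomy ranges for cohort simulation."""

    #: Bulky nodal disease typical of the target population: several large
    #: masses, so lesions carry a substantial share of the threshold masks.
    n_lesions: tuple[int, int] = (3, 6)  # inclusive range
    lesion_radius_mm: tuple[float, float] = (15.0, 35.0)
    lesion_adc_mean: tuple[float, float] = (900.0, 60.0)  # normal (mean, sd)
    lesion_adc_sd: tuple[float, float] = (120.0, 180.0)  # uniform range
    #: Extra baseline lesion-volume multiplier for PMR patients: partial
    #: responders present with a higher baseline disease load.
    pmr_baseline_volume_factor: float = 1.6
    scenarios: dict[str, ResponseScenario] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIOS)
    )


def _sample_lesions(
    rng: np.random.Generator,
    spec_extent,
    body_semi,
    params: CohortParams,
    radius_scale: float = 1.0,
) -> list[LesionSpec]:
    ex, ey, ez = spec_extent
    n = int(rng.integers(params.n_lesions[0], params.n_lesions[1] + 1))
    # on desk-scale grids the anatomical radius range is clamped so lesions fit
    r_cap = 0.18 * min(ex, ey, ez)
    lesions = []
    for _ in range(n):
        radii = tuple(
            min(float(r) * radius_scale, r_cap)
            for r in rng.uniform(*params.lesion_radius_mm, size=3)
        )
        # rejection-sample a center keeping the whole lesion inside body and grid
        while True:
            u, v = rng.uniform(-0.75, 0.75, size=2)
            if u * u + v * v > 0.75**2:
                continue
            cx = ex / 2 + u * body_semi[0]
            cy = ey / 2 + v * body_semi[1]
            cz = rng.uniform(0.12 * ez, 0.82 * ez)
            center = (cx, cy, cz)
            if all(c - r > 0 and c + r < e
                   for c, r, e in zip(center, radii, spec_extent)):
                break
        adc_mean = float(rng.normal(*params.lesion_adc_mean))
        adc_sd = float(rng.uniform(*params.lesion_adc_sd))
        lesions.append(LesionSpec(center, radii, adc_mean, adc_sd))
    return lesions


def make_cohort(
    n_cmr: int,
    n_pmr: int,
    out_dir: str | Path,
    seed: int = 0,
    shape: tuple[int, int, int] = (96, 96, 220),
    spacing: tuple[float, float, float] = (2.0, 2.0, 5.0),
    noise_sigma: float = 10.0,
    params: CohortParams | None = None,
) -> tuple[CohortManifest, pd.DataFrame]:
    """Simulate a longitudinal cohort and write it to disk.

    Writes, under ``out_dir``: one NIfTI per patient/timepoint/b-value, a
    ``manifest.yaml``, and ``ground_truth.csv`` with per-patient true lesion
    volumes and ADC parameters per timepoint.  Fully reproducible from
    ``seed``.  Labels at T1 and T2 both carry the patient's scenario class.
    """
    if n_cmr + n_pmr == 0:
        raise EmptyCohortError("cohort must contain at least one patient")
    params = params or CohortParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    entries: list[PatientEntry] = []
    truth_rows: list[dict] = []
    classes = ["CMR"] * n_cmr + ["PMR"] * n_pmr
    for i, cls in enumerate(classes):
        pid = f"sim{i + 1:03d}"
        base = default_torso_spec(shape, spacing, noise_sigma=noise_sigma,
                                  seed=int(rng.integers(2**31)))
        # partial responders present with a higher baseline disease load
        r_scale = (
            params.pmr_baseline_volume_factor ** (1.0 / 3.0) if cls == "PMR" else 1.0
        )
        lesions = _sample_lesions(rng, base.extent_mm, base.body_semi_axes, params,
                                  radius_scale=r_scale)
        spec = replace(base, lesions=tuple(lesions))
        specs = apply_scenario(spec, params.scenarios[cls])

        series_paths: dict[int, dict[int, Path]] = {}
        for t, spec_t in specs.items():
            series, truth = render_phantom(spec_t, patient_id=pid, timepoint=t)
            paths = {}
            for b, vol in series.volumes.items():
                p = out_dir / f"{pid}_t{t}_b{b}.nii.gz"
                write_volume(vol, p)
                paths[b] = p
            series_paths[t] = paths
            truth_rows.append(
                {
                    "patient_id": pid,
                    "label": cls,
                    "timepoint": t,
                    "n_lesions": len(spec_t.lesions),
                    "true_lesion_volume_cm3": truth.total_lesion_volume_cm3,
                    "lesion_adc_mean": float(np.mean([l.adc_mean for l in spec_t.lesions]))
                    if spec_t.lesions else np.nan,
                    "lesion_adc_sd": float(np.mean([l.adc_sd for l in spec_t.lesions]))
                    if spec_t.lesions else np.nan,
                }
            )
        entries.append(PatientEntry(pid, series_paths, label_t1=cls, label_t2=cls))

    manifest = CohortManifest(entries)
    save_manifest(manifest, out_dir / "manifest.yaml")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest, truth
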