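"""Seeded phantom cohorts with the statistical structure the pipeline assumes.

Each phantom patient is five co-registered contrast volumes on a common grid:
background tissue at raw white-matter intensity (so WM normalization brings it
to ~1), spatially smooth Gaussian noise, and one spherical tumor whose
per-contrast offset is the sum of the signatures of its positive outcomes.
Outcome truth is drawn per patient from the cohort prevalences; the pathology
triage step is modeled as informative — only truly negative outcomes are
triaged — so recorded labels are clean but censoring bookkeeping matches the
reference cohort's tested/triaged counts.  Biopsy cores are spheres sampled
inside the tumor, labeled with the patient's recorded outcomes.

Ground truth (labels and tumor masks) is retained for every pipeline stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import features as feat
from .volumes import (
    CONTRAST_NAMES,
    OUTCOMES,
    BiopsySample,
    ContrastVolume,
    PatientVolumeSet,
    SphereROI,
    radius_from_volume,
    read_patient,
    sphere_mask,
    write_map,
    write_patient,
)

#: Raw white-matter means per contrast (arbitrary scanner units; the ADC scale
#: mimics 1e-6 mm^2/s maps).  Normalization must undo these exactly.
RAW_WM_MEANS = {
    "T1w": 600.0,
    "T1w-post": 620.0,
    "T2w": 950.0,
    "T2-FLAIR": 480.0,
    "ADC": 760.0,
}

#: Default per-outcome contrast offsets (fractions of white matter) applied in
#: the expressing sub-region of positive tumors, ordered
#: (T1w, T1w-post, T2w, T2-FLAIR, ADC).  The sign pattern is anchored in
#: observed tumor biology: IDH1-mutant and MGMT-methylated lesions are
#: T1w-hypointense (IDH1 additionally FLAIR-hyperintense, MGMT ADC-dark),
#: necrosis is T1w-hyperintense, and microvascular proliferation enhances
#: post-contrast.  Each outcome's dominant contrast is distinct, so tumors
#: positive for several outcomes remain decodable per outcome.
DEFAULT_SIGNATURES = {
    "idh1": (-0.15, 0.00, 0.00, 0.50, 0.00),
    "mgmt": (-0.15, 0.00, 0.00, 0.00, -0.50),
    "cnec": (0.50, 0.00, 0.12, 0.00, 0.00),
    "mvp": (0.00, 0.50, 0.12, 0.00, 0.00),
}

#: Generic lesion appearance shared by every tumor regardless of outcome
#: status (T2w/FLAIR hyperintense, mildly T1w-hypointense), modulated by a
#: smooth within-tumor heterogeneity field.  This common cloud is what makes
#: a voxel look "tumor-like" without revealing any specific outcome, so the
#: local outcome rates in it approach the cohort background — the weakly
#: informative bulk that real biopsy populations exhibit.
DEFAULT_TUMOR_BASE = (-0.06, 0.03, 0.18, 0.20, -0.06)

#: Per-patient probability that an outcome is truly positive, matched to the
#: reference cohort's recorded-positive patient counts out of 29.
DEFAULT_PREVALENCE = {"idh1": 2 / 29, "mgmt": 1 / 29, "cnec": 9 / 29, "mvp": 8 / 29}

#: Probability that a truly negative outcome is triaged (not tested), matched
#: to the reference cohort's triaged counts among negatives.
DEFAULT_TRIAGE_GIVEN_NEGATIVE = {
    "idh1": 18 / 27,
    "mgmt": 24 / 28,
    "cnec": 11 / 20,
    "mvp": 18 / 21,
}


@dataclass(frozen=True)
class PhantomSpec:
    """All knobs of the phantom generator; a fixed seed fixes the cohort."""

    n_patients: int = 29
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.02  # global scanner/tissue noise (WM-normalized units)
    tumor_variability: float = 0.12  # within-tumor biological variability
    smoothing_fwhm: float = 1.5  # mm, spatial correlation of the scanner noise
    #: spatial scale of biological variability; 0 = finer than the voxel grid
    #: (microscopic heterogeneity), which keeps wKNN neighborhoods mixing
    #: specimens from many patients the way real biopsy populations do
    variability_fwhm: float = 0.0
    brain_radius: float = 28.0  # mm
    tumor_radius_range: tuple[float, float] = (13.0, 17.0)
    tumor_center_max_offset: float = 10.0  # mm from grid center
    signatures: dict = field(default_factory=lambda: dict(DEFAULT_SIGNATURES))
    tumor_base: tuple[float, ...] = DEFAULT_TUMOR_BASE
    base_heterogeneity: float = 0.3  # relative amplitude of within-tumor modulation
    #: tissue volume (mm^3) of the dedicated positive specimen per outcome,
    #: matched to the reference cohort's positive gross volumes per positive
    #: specimen — positive specimens for the molecular outcomes are small,
    #: which keeps their voxel-level background probabilities rare
    positive_specimen_volume: dict = field(
        default_factory=lambda: {"idh1": 265.0, "mgmt": 104.0, "cnec": 2827.0, "mvp": 1271.0}
    )
    #: expressing tissue volume (mm^3) inside that specimen, matched to the
    #: reference cohort's positive voxel counts per positive specimen (capped
    #: at the specimen); the remainder looks like ordinary lesion bulk
    expression_volume_mm3: dict = field(
        default_factory=lambda: {"idh1": 180.0, "mgmt": 93.0, "cnec": 2827.0, "mvp": 390.0}
    )
    prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    triage_given_negative: dict = field(
        default_factory=lambda: dict(DEFAULT_TRIAGE_GIVEN_NEGATIVE)
    )
    cores_per_patient: tuple[float, float] = (3.24, 1.8)  # clipped normal (mean, sd)
    core_volume_mm3: tuple[float, float] = (1271.0, 300.0)  # clipped normal (mean, sd)
    wm_roi_radius: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.tumor_variability < 0:
            raise ValueError("tumor_variability must be >= 0")
        for o in OUTCOMES:
            if not 0.0 <= self.prevalence[o] <= 1.0:
                raise ValueError(f"prevalence[{o}] outside [0, 1]")
            if not 0.0 <= self.triage_given_negative[o] <= 1.0:
                raise ValueError(f"triage rate[{o}] outside [0, 1]")
            if len(self.signatures[o]) != len(CONTRAST_NAMES):
                raise ValueError(f"signature[{o}] must have 5 entries")
        if len(self.tumor_base) != len(CONTRAST_NAMES):
            raise ValueError("tumor_base must have 5 entries")
        for o in OUTCOMES:
            if self.expression_volume_mm3[o] <= 0:
                raise ValueError(f"expression_volume_mm3[{o}] must be > 0")
            if self.positive_specimen_volume[o] <= 0:
                raise ValueError(f"positive_specimen_volume[{o}] must be > 0")
        if self.base_heterogeneity < 0:
            raise ValueError("base_heterogeneity must be >= 0")
        if self.tumor_radius_range[1] + self.tumor_center_max_offset > self.brain_radius:
            raise ValueError("tumor can escape the brain mask")
        # the white-matter ROI must fit clear of the largest centered tumor
        wm_dist = self.brain_radius - self.wm_roi_radius - 2.0
        if wm_dist < self.tumor_radius_range[1] + self.wm_roi_radius + 0.5:
            raise ValueError("no room for a white-matter ROI clear of the tumor")
        if 2 * self.brain_radius >= min(
            s * n for s, n in zip(self.spacing, self.shape)
        ):
            raise ValueError("brain (and tumor) larger than the grid")


def default_spec(seed: int = 0) -> PhantomSpec:
    """The default study-scale phantom: 29 patients on a 64^3 mm-isotropic grid."""
    return PhantomSpec(seed=seed)


def null_spec(seed: int = 0) -> PhantomSpec:
    """Label-free null cohort: all signatures zero, labels carry no image signal.

    Every patient carries a designated positive specimen per outcome but the
    expression adds no contrast offset — the situation the reference cohort's
    cellular-necrosis outcome exemplifies (balanced specimen labels with no
    detectable imaging correlate).  Rare-positive labels would instead make
    isolated chance rejections unavoidable at desk-scale cohort sizes.
    """
    zero = {o: (0.0,) * 5 for o in OUTCOMES}
    ones = {o: 1.0 for o in OUTCOMES}
    return replace(default_spec(seed), signatures=zero, prevalence=ones)


@dataclass
class PhantomPatient:
    pvs: PatientVolumeSet  # raw (un-normalized) volumes
    samples: list[BiopsySample]
    truth: dict[str, bool]  # ground-truth outcome status
    recorded: dict[str, str]  # pos / neg / triaged tokens
    tumor_mask: np.ndarray
    #: per-outcome voxel-wise ground truth: the expressing sub-region of the
    #: tumor for positive outcomes, empty for negative ones
    truth_fields: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class PhantomCohort:
    spec: PhantomSpec
    patients: list[PhantomPatient]

    def as_pipeline_input(self) -> list[tuple[PatientVolumeSet, list[BiopsySample]]]:
        return [(p.pvs, p.samples) for p in self.patients]


def _smooth_noise(rng, shape, spacing, fwhm_mm, sd) -> np.ndarray:
    g = rng.standard_normal(shape)
    if fwhm_mm > 0:
        sigma_vox = [fwhm_mm / np.sqrt(8 * np.log(2)) / s for s in spacing]
        g = ndimage.gaussian_filter(g, sigma_vox, mode="nearest")
    g *= sd / g.std()
    return g


def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def generate_patient(spec: PhantomSpec, patient_id: int, rng: np.random.Generator) -> PhantomPatient:
    shape, spacing = spec.shape, spec.spacing
    center = np.array([(n - 1) * s / 2.0 for n, s in zip(shape, spacing)])

    # --- outcome truth and informative triage -----------------------------
    truth = {o: bool(rng.random() < spec.prevalence[o]) for o in OUTCOMES}
    recorded = {}
    for o in OUTCOMES:
        if truth[o]:
            recorded[o] = "pos"
        elif rng.random() < spec.triage_given_negative[o]:
            recorded[o] = "triaged"
        else:
            recorded[o] = "neg"

    # --- tumor geometry -----------------------------------------------------
    tumor_r = float(rng.uniform(*spec.tumor_radius_range))
    offset = _random_unit(rng) * spec.tumor_center_max_offset * rng.random() ** (1 / 3)
    tumor_c = center + offset
    tumor_roi = SphereROI(tuple(tumor_c), tumor_r)
    tumor_mask = sphere_mask(tumor_roi, shape, spacing)

    brain_mask = sphere_mask(SphereROI(tuple(center), spec.brain_radius), shape, spacing)

    # --- white-matter reference ROI away from the tumor ----------------------
    wm_dist = spec.brain_radius - spec.wm_roi_radius - 2.0
    wm_dir = -offset / np.linalg.norm(offset) if np.linalg.norm(offset) > 1e-9 else np.array([1.0, 0, 0])
    for _ in range(200):
        wm_c = center + wm_dir * wm_dist
        if np.linalg.norm(wm_c - tumor_c) > tumor_r + spec.wm_roi_radius + 0.5:
            break
        wm_dir = _random_unit(rng)
    else:  # pragma: no cover - spec validation guarantees a gap exists
        raise RuntimeError("could not place white-matter ROI clear of the tumor")
    wm_roi = SphereROI(tuple(wm_c), spec.wm_roi_radius)

    # --- biopsy core geometry and expressing sub-regions -----------------------
    # Pathology labels are per specimen: each truly positive outcome gets one
    # dedicated (small) positive core whose central sub-volume expresses the
    # outcome's signature; all other cores are ordinary negative specimens.
    # Every core is then labeled per outcome by whether it actually contains
    # expressing tissue, exactly as a pathologist would call it.
    def _fit_radius(vol: float) -> tuple[float, float]:
        r = radius_from_volume(vol)
        if r > tumor_r - 1.0:  # oversized draws shrink to fit the lesion
            r = tumor_r - 1.0
            vol = 4.0 / 3.0 * np.pi * r**3
        return r, vol

    def _center_inside_tumor(r: float) -> np.ndarray:
        cmax = max(tumor_r - r, 0.25)
        return tumor_c + _random_unit(rng) * cmax * rng.random() ** (1 / 3)

    n_cores = int(np.clip(np.rint(rng.normal(*spec.cores_per_patient)), 1, 8))
    positive_outcomes = [o for o in OUTCOMES if truth[o]]
    n_cores = max(n_cores, len(positive_outcomes) + 1)

    cores: list[tuple[np.ndarray, float, float]] = []  # (center, radius, volume)
    blob_geom: dict[str, tuple[np.ndarray, float]] = {}
    truth_fields: dict[str, np.ndarray] = {
        o: np.zeros(shape, dtype=bool) for o in OUTCOMES
    }
    for o in positive_outcomes:
        # the dedicated positive specimen carries the outcome's expressing
        # focus, which sits toward the lesion margin (infiltrative-edge
        # biology); this also lets the remaining specimens sample genuinely
        # non-expressing regions
        r, vol = _fit_radius(float(max(spec.positive_specimen_volume[o], 100.0)))
        blob_r = min(radius_from_volume(spec.expression_volume_mm3[o]), r - 0.75)
        direction = _random_unit(rng)
        for _ in range(100):
            # foci of different outcomes head for different lesion sectors
            if all(
                float(np.dot(direction, (pbc - tumor_c)))
                < 0.5 * np.linalg.norm(pbc - tumor_c)
                for pbc, _ in blob_geom.values()
                if np.linalg.norm(pbc - tumor_c) > 1e-9
            ):
                break
            direction = _random_unit(rng)
        bc = tumor_c + direction * max(tumor_r - blob_r - 0.5, 0.0)
        c = tumor_c + direction * (tumor_r - r)  # pulled inward, focus inside
        cores.append((c, r, vol))
        blob_geom[o] = (bc, blob_r)
        truth_fields[o] = sphere_mask(SphereROI(tuple(bc), blob_r), shape, spacing)
    while len(cores) < n_cores:
        vol = float(np.clip(rng.normal(*spec.core_volume_mm3), 150.0, None))
        r, vol = _fit_radius(vol)
        # ordinary specimens sample away from the expressing foci when the
        # lesion geometry allows it (most of the lesion does not express)
        c = _center_inside_tumor(r)
        for _ in range(100):
            if all(
                np.linalg.norm(c - bc) > r + br + 0.1 for bc, br in blob_geom.values()
            ):
                break
            c = _center_inside_tumor(r)
        else:
            # cramped lesion: full tissue avoidance impossible; at least keep
            # the focus center outside the core (else the specimen would
            # sample most of the focus and test positive)
            for _ in range(100):
                if all(
                    np.linalg.norm(c - bc) > r + 0.2 for bc, _ in blob_geom.values()
                ):
                    break
                c = _center_inside_tumor(r)
        cores.append((c, r, vol))

    # --- contrast volumes -----------------------------------------------------
    # generic lesion appearance with smooth within-tumor heterogeneity
    modulation = 1.0 + spec.base_heterogeneity * np.clip(
        _smooth_noise(rng, shape, spacing, spec.variability_fwhm, 1.0), -2.0, 2.0
    ) if spec.base_heterogeneity > 0 else np.ones(shape)
    contrasts = {}
    base = np.asarray(spec.tumor_base, dtype=float)
    expressing_any = np.zeros(shape, dtype=bool)
    for o in positive_outcomes:
        if any(v != 0 for v in spec.signatures[o]):  # zero signature = no
            expressing_any |= truth_fields[o]  # distinct expressing tissue
    for ci, name in enumerate(CONTRAST_NAMES):
        rel = 1.0 + base[ci] * modulation * tumor_mask + _smooth_noise(
            rng, shape, spacing, spec.smoothing_fwhm, spec.noise_sd
        )
        if spec.tumor_variability > 0:
            # biological heterogeneity confined to the lesion; bounded (soft
            # saturation) — tissue composition varies within physiologic
            # limits, not with Gaussian tails — and damped inside expressing
            # foci, which are comparatively homogeneous tissue compartments
            tv = spec.tumor_variability
            v = _smooth_noise(rng, shape, spacing, spec.variability_fwhm, tv)
            v = 2.0 * tv * np.tanh(v / (2.0 * tv))
            v[expressing_any] /= 3.0
            rel += tumor_mask * v
        for o in OUTCOMES:
            if truth[o]:
                rel += spec.signatures[o][ci] * truth_fields[o]
        data = RAW_WM_MEANS[name] * rel
        data[~brain_mask] = 0.0
        contrasts[name] = ContrastVolume(name, data, spacing)
    pvs = PatientVolumeSet(patient_id, contrasts, brain_mask, wm_roi)

    # --- specimen labels from expressing-tissue overlap ------------------------
    _, prov = feat.apply_triage_rule(recorded)
    samples = []
    for c, core_r, vol in cores:
        flags = {}
        for o in OUTCOMES:
            if truth[o]:
                # a specimen tests positive when it samples the bulk of the
                # expressing focus (focus center inside the core); grazing
                # contact is below what representative sectioning detects
                bc, _ = blob_geom[o]
                flags[o] = int(np.linalg.norm(c - bc) <= core_r + 1e-9)
            else:
                flags[o] = 0
        samples.append(
            BiopsySample(patient_id, SphereROI(tuple(c), core_r), vol, flags, dict(prov))
        )
    return PhantomPatient(pvs, samples, truth, recorded, tumor_mask, truth_fields)


def generate_cohort(spec: PhantomSpec) -> PhantomCohort:
    """Generate the full seeded cohort; identical seeds yield identical cohorts."""
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
    patients = [
        generate_patient(spec, pid + 1, np.random.default_rng(children[pid]))
        for pid in range(spec.n_patients)
    ]
    return PhantomCohort(spec, patients)


# ---------------------------------------------------------------------------
# On-disk round trip (the exact formats the I/O layer reads)
# ---------------------------------------------------------------------------

def write_cohort(cohort: PhantomCohort, out_dir: Path | str) -> Path:
    """Write NIfTI volumes, the biopsy TSV sidecar, truth fields and a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cohort.spec.seed, "n_patients": cohort.spec.n_patients, "patients": []}
    all_samples: list[BiopsySample] = []
    for p in cohort.patients:
        sub = out_dir / f"sub-{p.pvs.patient_id:02d}"
        paths = write_patient(p.pvs, sub)
        write_map(p.tumor_mask.astype(np.float32), p.pvs, sub / "truth_tumor_mask.nii.gz")
        for o in OUTCOMES:
            write_map(
                p.truth_fields[o].astype(np.float32), p.pvs, sub / f"truth_{o}.nii.gz"
            )
        manifest["patients"].append(
            {
                "patient_id": p.pvs.patient_id,
                "dir": sub.name,
                "files": {k: str(v.relative_to(out_dir)) for k, v in paths.items()},
                "wm_roi": {"center": list(p.pvs.wm_roi.center), "radius": p.pvs.wm_roi.radius},
                "truth": {o: bool(p.truth[o]) for o in OUTCOMES},
                "recorded": p.recorded,
            }
        )
        all_samples.extend(p.samples)
    feat.write_biopsy_table(all_samples, out_dir / "biopsies.tsv")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def read_cohort(cohort_dir: Path | str) -> list[tuple[PatientVolumeSet, list[BiopsySample]]]:
    """Load a written cohort through the public I/O layer."""
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    samples = feat.read_biopsy_table(cohort_dir / "biopsies.tsv")
    out = []
    for entry in manifest["patients"]:
        wm = SphereROI(tuple(entry["wm_roi"]["center"]), entry["wm_roi"]["radius"])
        paths = {k: cohort_dir / v for k, v in entry["files"].items()}
        pvs = read_patient(paths, entry["patient_id"], wm)
        out.append((pvs, [s for s in samples if s.patient_id == entry["patient_id"]]))
    return out
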