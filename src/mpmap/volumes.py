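"""Data model and NIfTI I/O for co-registered multiparametric MR volumes.

The five contrasts (T1w, T1w-post, T2w, T2-FLAIR, ADC) of one patient live on a
single axis-aligned grid. World coordinates are in millimetres with the
center-of-voxel convention::

    x_world = origin + index * spacing

Voxel indices are 0-based.  Sphere membership uses the closed ball
(distance <= radius) so the test is deterministic and the discretized sphere
volume converges to the analytic volume as spacing shrinks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

#: Canonical contrast names, in feature-column order.
CONTRAST_NAMES = ("T1w", "T1w-post", "T2w", "T2-FLAIR", "ADC")
#: Lower-case column names used in feature tables, aligned with CONTRAST_NAMES.
CONTRAST_COLUMNS = ("t1w", "t1wpost", "t2w", "flair", "adc")
#: The four binary microscopic outcomes (IDH1-R132H mutation, MGMT promoter
#: methylation, cellular necrosis, microvascular proliferation).
OUTCOMES = ("idh1", "mgmt", "cnec", "mvp")


class GridMismatchError(ValueError):
    """Raised when volumes of one patient do not share a common grid."""


@dataclass(frozen=True)
class SphereROI:
    """A spherical region of interest in world coordinates (mm)."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise ValueError(f"sphere radius must be > 0, got {self.radius}")
        if len(self.center) != 3 or not np.all(np.isfinite(self.center)):
            raise ValueError(f"sphere center must be a finite 3-vector, got {self.center}")


@dataclass
class ContrastVolume:
    """One scalar MR volume with its grid geometry."""

    name: str
    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.name not in CONTRAST_NAMES:
            raise ValueError(f"unknown contrast name {self.name!r}; expected one of {CONTRAST_NAMES}")
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"contrast {self.name}: data must be 3-D, got shape {self.data.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"contrast {self.name}: spacing must be strictly positive, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (axis aligned)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class PatientVolumeSet:
    """Five co-registered contrasts, a brain mask and a white-matter reference ROI."""

    patient_id: int
    contrasts: dict[str, ContrastVolume]
    brain_mask: np.ndarray
    wm_roi: SphereROI

    def __post_init__(self) -> None:
        missing = [n for n in CONTRAST_NAMES if n not in self.contrasts]
        if missing:
            raise ValueError(f"missing contrast {missing[0]}")
        extra = set(self.contrasts) - set(CONTRAST_NAMES)
        if extra:
            raise ValueError(f"unknown contrasts {sorted(extra)}")
        ref = self.contrasts[CONTRAST_NAMES[0]]
        for name in CONTRAST_NAMES[1:]:
            c = self.contrasts[name]
            if c.shape != ref.shape or c.spacing != ref.spacing or c.origin != ref.origin:
                raise GridMismatchError(
                    f"patient {self.patient_id}: contrast {name} grid {c.shape}/{c.spacing} "
                    f"does not match {ref.name} grid {ref.shape}/{ref.spacing}"
                )
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.brain_mask.shape != ref.shape:
            raise GridMismatchError(
                f"patient {self.patient_id}: brain mask shape {self.brain_mask.shape} "
                f"does not match contrast grid {ref.shape}"
            )

    # -- grid accessors -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.contrasts[CONTRAST_NAMES[0]].shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.contrasts[CONTRAST_NAMES[0]].spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.contrasts[CONTRAST_NAMES[0]].origin

    def contrast_stack(self) -> np.ndarray:
        """(nx, ny, nz, 5) array of the five contrasts in canonical order."""
        return np.stack([self.contrasts[n].data for n in CONTRAST_NAMES], axis=-1)


@dataclass
class BiopsySample:
    """Sphere geometry of one biopsy core plus its four outcome labels.

    ``outcomes`` maps each outcome to the binary flag after the triage rule
    (1 positive, 0 negative); ``provenance`` records whether the outcome was
    actually tested or triaged to negative by the pathologist.
    """

    patient_id: int
    sphere: SphereROI
    core_volume: float
    outcomes: dict[str, int]
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        if self.core_volume <= 0:
            raise ValueError(f"core volume must be > 0, got {self.core_volume}")
        expected_r = radius_from_volume(self.core_volume)
        if not np.isclose(self.sphere.radius, expected_r, rtol=1e-6):
            raise ValueError(
                f"sphere radius {self.sphere.radius:.6g} inconsistent with core volume "
                f"{self.core_volume:.6g} mm^3 (expected r={expected_r:.6g})"
            )
        for o in OUTCOMES:
            if o not in self.outcomes or o not in self.provenance:
                raise ValueError(f"missing outcome {o}")
            if self.outcomes[o] not in (0, 1):
                raise ValueError(f"outcome flag must be 0/1, got {self.outcomes[o]!r}")
            if self.provenance[o] not in ("tested", "triaged"):
                raise ValueError(f"provenance must be tested/triaged, got {self.provenance[o]!r}")
            if self.provenance[o] == "triaged" and self.outcomes[o] != 0:
                raise ValueError(f"triaged outcome {o} must be negative")


def radius_from_volume(core_volume: float) -> float:
    """Radius (mm) of the sphere with the given volume (mm^3): (3V / 4pi)^(1/3)."""
    if not np.isfinite(core_volume) or core_volume <= 0:
        raise ValueError(f"core volume must be > 0, got {core_volume}")
    return float((3.0 * core_volume / (4.0 * np.pi)) ** (1.0 / 3.0))


def voxel_center_grids(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Open (broadcastable) grids of voxel-center world coordinates per axis."""
    ax = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    return ax[0][:, None, None], ax[1][None, :, None], ax[2][None, None, :]


def sphere_mask(
    roi: SphereROI,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Binary mask of voxels whose centers lie within (<=) ``roi.radius`` of its center.

    Warns (does not fail) when no voxel center falls inside the sphere: very
    small cores can legitimately produce empty masks on coarse grids.
    """
    lo = [origin[a] - 0.5 * spacing[a] for a in range(3)]
    hi = [origin[a] + (shape[a] - 0.5) * spacing[a] for a in range(3)]
    if any(roi.center[a] < lo[a] or roi.center[a] > hi[a] for a in range(3)):
        raise ValueError(f"sphere center {roi.center} lies outside the grid extent")
    gx, gy, gz = voxel_center_grids(shape, spacing, origin)
    d2 = (gx - roi.center[0]) ** 2 + (gy - roi.center[1]) ** 2 + (gz - roi.center[2]) ** 2
    mask = d2 <= roi.radius**2
    if not mask.any():
        warnings.warn(
            f"sphere at {roi.center} (r={roi.radius:.3g} mm) contains no voxel centers",
            stacklevel=2,
        )
    return mask


def normalize_to_wm(pvs: PatientVolumeSet) -> PatientVolumeSet:
    """Divide each contrast by its own mean inside the white-matter reference ROI.

    After normalization the mean of every contrast inside ``wm_roi`` is exactly
    1.0, so the operation is idempotent and invariant to positive rescaling of
    any raw contrast.
    """
    wm = sphere_mask(pvs.wm_roi, pvs.shape, pvs.spacing, pvs.origin)
    if not wm.any():
        raise ValueError(f"patient {pvs.patient_id}: white-matter ROI mask is empty")
    new_contrasts = {}
    for name in CONTRAST_NAMES:
        vol = pvs.contrasts[name]
        m = float(vol.data[wm].mean())
        if not np.isfinite(m) or m <= 0:
            raise ValueError(
                f"patient {pvs.patient_id}: white-matter mean of contrast {name} "
                f"is {m!r}; cannot normalize"
            )
        new_contrasts[name] = ContrastVolume(name, vol.data / m, vol.spacing, vol.origin)
    return PatientVolumeSet(pvs.patient_id, new_contrasts, pvs.brain_mask.copy(), pvs.wm_roi)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

#: File stem used for each contrast on disk.
CONTRAST_FILENAMES = {
    "T1w": "t1w",
    "T1w-post": "t1w_post",
    "T2w": "t2w",
    "T2-FLAIR": "t2_flair",
    "ADC": "adc",
}


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return data, spacing, origin


def read_patient(
    paths: Mapping[str, Path | str],
    patient_id: int,
    wm_roi: SphereROI,
) -> PatientVolumeSet:
    """Load one patient's five contrasts and brain mask from NIfTI files.

    ``paths`` maps each contrast name (plus ``"brain_mask"``) to a file path.
    All volumes must share grid dimensions and spacing; a mismatch raises
    :class:`GridMismatchError` naming both shapes.
    """
    for name in CONTRAST_NAMES:
        if name not in paths:
            raise ValueError(f"missing contrast {name}")
        if not Path(paths[name]).exists():
            raise FileNotFoundError(f"missing contrast {name}: {paths[name]}")
    if "brain_mask" not in paths:
        raise ValueError("missing brain_mask path")

    contrasts = {}
    for name in CONTRAST_NAMES:
        data, spacing, origin = _load_nifti(Path(paths[name]))
        contrasts[name] = ContrastVolume(name, data, spacing, origin)
    mask, mspacing, morigin = _load_nifti(Path(paths["brain_mask"]))
    pvs = PatientVolumeSet(patient_id, contrasts, mask > 0.5, wm_roi)
    if mspacing != pvs.spacing:
        raise GridMismatchError(
            f"brain mask spacing {mspacing} does not match contrast spacing {pvs.spacing}"
        )
    if not np.isfinite(pvs.contrast_stack()[pvs.brain_mask]).all():
        raise ValueError(f"patient {patient_id}: non-finite values inside brain mask")
    return pvs


def write_patient(pvs: PatientVolumeSet, out_dir: Path | str) -> dict[str, Path]:
    """Write one patient's volumes as NIfTI-1 files; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in CONTRAST_NAMES:
        vol = pvs.contrasts[name]
        img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine())
        p = out_dir / f"{CONTRAST_FILENAMES[name]}.nii.gz"
        nib.save(img, str(p))
        paths[name] = p
    aff = pvs.contrasts[CONTRAST_NAMES[0]].affine()
    img = nib.Nifti1Image(pvs.brain_mask.astype(np.uint8), aff)
    p = out_dir / "brain_mask.nii.gz"
    nib.save(img, str(p))
    paths["brain_mask"] = p
    return paths


def write_map(values: np.ndarray, like: PatientVolumeSet, path: Path | str) -> Path:
    """Write a scalar map aligned to a patient's grid as float32 NIfTI."""
    aff = like.contrasts[CONTRAST_NAMES[0]].affine()
    if values.shape != like.shape:
        raise GridMismatchError(f"map shape {values.shape} does not match grid {like.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(values.astype(np.float32), aff), str(path))
    return path
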