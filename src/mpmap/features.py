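"""Feature-matrix construction from biopsy spheres.

Every in-sphere voxel of every core becomes one row mapping the five
white-matter-normalized contrast values to the core's four binary outcome
flags.  Voxels covered by two overlapping cores appear once per core, so the
specimen-to-voxel mapping the classifier trains on is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .volumes import (
    CONTRAST_COLUMNS,
    CONTRAST_NAMES,
    OUTCOMES,
    BiopsySample,
    PatientVolumeSet,
    SphereROI,
    radius_from_volume,
    sphere_mask,
)

#: Canonical column order of the serialized feature matrix.
FEATURE_COLUMNS = (
    list(CONTRAST_COLUMNS)
    + ["patient_id"]
    + list(OUTCOMES)
    + [f"prov_{o}" for o in OUTCOMES]
)

_TOKEN_MAP = {
    "pos": (1, "tested"),
    "positive": (1, "tested"),
    "neg": (0, "tested"),
    "negative": (0, "tested"),
    "triaged": (0, "triaged"),
}


def apply_triage_rule(raw: Mapping[str, str]) -> tuple[dict[str, int], dict[str, str]]:
    """Convert raw pathology tokens to binary flags and provenance.

    ``pos`` -> 1/tested, ``neg`` -> 0/tested, ``triaged`` -> 0/triaged: an
    outcome the pathologist elected not to measure is recorded as negative by
    study convention.
    """
    flags: dict[str, int] = {}
    prov: dict[str, str] = {}
    for o in OUTCOMES:
        if o not in raw:
            raise ValueError(f"missing outcome {o}")
        token = str(raw[o]).strip().lower()
        if token not in _TOKEN_MAP:
            raise ValueError(f"unknown pathology token {raw[o]!r} for outcome {o}")
        flags[o], prov[o] = _TOKEN_MAP[token]
    return flags, prov


def read_biopsy_table(path: Path | str) -> list[BiopsySample]:
    """Read the biopsy sidecar TSV.

    Expected columns: patient_id, x_mm, y_mm, z_mm, core_volume_mm3 and one
    column per outcome (idh1, mgmt, cnec, mvp) valued pos/neg/triaged.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "x_mm", "y_mm", "z_mm", "core_volume_mm3", *OUTCOMES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"biopsy table missing columns {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        flags, prov = apply_triage_rule({o: row[o] for o in OUTCOMES})
        vol = float(row["core_volume_mm3"])
        sphere = SphereROI(
            (float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])),
            radius_from_volume(vol),
        )
        samples.append(BiopsySample(int(row["patient_id"]), sphere, vol, flags, prov))
    return samples


def write_biopsy_table(samples: Sequence[BiopsySample], path: Path | str) -> None:
    rows = []
    for s in samples:
        tokens = {
            o: ("pos" if s.outcomes[o] else ("triaged" if s.provenance[o] == "triaged" else "neg"))
            for o in OUTCOMES
        }
        rows.append(
            {
                "patient_id": s.patient_id,
                "x_mm": s.sphere.center[0],
                "y_mm": s.sphere.center[1],
                "z_mm": s.sphere.center[2],
                "core_volume_mm3": s.core_volume,
                **tokens,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def extract_biopsy_voxels(
    pvs: PatientVolumeSet, samples: Iterable[BiopsySample]
) -> pd.DataFrame:
    """One feature row per in-sphere voxel per core of one (normalized) patient.

    Rows carry the voxel index triple and the core index, so every row is
    traceable back to its source voxel.
    """
    stack = pvs.contrast_stack()
    frames = []
    for core_idx, s in enumerate(samples):
        if s.patient_id != pvs.patient_id:
            raise ValueError(
                f"biopsy sample for patient {s.patient_id} applied to patient {pvs.patient_id}"
            )
        mask = sphere_mask(s.sphere, pvs.shape, pvs.spacing, pvs.origin)
        idx = np.argwhere(mask)
        if idx.shape[0] == 0:
            warnings.warn(
                f"patient {pvs.patient_id}: biopsy core {core_idx} sphere contains no voxels",
                stacklevel=2,
            )
            continue
        vals = stack[mask]  # (n, 5)
        df = pd.DataFrame(vals, columns=list(CONTRAST_COLUMNS))
        df["patient_id"] = pvs.patient_id
        df["core"] = core_idx
        df["i"], df["j"], df["k"] = idx[:, 0], idx[:, 1], idx[:, 2]
        for o in OUTCOMES:
            df[o] = s.outcomes[o]
            df[f"prov_{o}"] = s.provenance[o]
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=list(CONTRAST_COLUMNS) + ["patient_id", "core", "i", "j", "k"]
            + list(OUTCOMES) + [f"prov_{o}" for o in OUTCOMES]
        )
    out = pd.concat(frames, ignore_index=True)
    if not np.isfinite(out[list(CONTRAST_COLUMNS)].to_numpy()).all():
        raise ValueError(f"patient {pvs.patient_id}: non-finite contrast values in biopsy voxels")
    return out


def build_feature_matrix(
    patients: Iterable[tuple[PatientVolumeSet, Sequence[BiopsySample]]]
) -> pd.DataFrame:
    """Pool per-patient biopsy-voxel records into the cohort feature matrix."""
    frames = [extract_biopsy_voxels(pvs, samples) for pvs, samples in patients]
    frames = [f for f in frames if len(f)]
    if not frames:
        raise ValueError("no biopsy voxels in cohort")
    return pd.concat(frames, ignore_index=True)


def loo_split(fm: pd.DataFrame, holdout: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-patient-out split: test rows are exactly the holdout's rows."""
    ids = fm["patient_id"].to_numpy()
    if holdout not in set(ids.tolist()):
        raise KeyError(f"patient {holdout} not present in feature matrix")
    is_test = ids == holdout
    return fm.loc[~is_test], fm.loc[is_test]


@dataclass(frozen=True)
class BackgroundDistribution:
    """Cohort-wide voxel-level class probabilities for one outcome.

    These serve as the expected distribution in the Pearson chi-square
    transform of predicted class probabilities.
    """

    outcome: str
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0 or self.n_pos + self.n_neg == 0:
            raise ValueError(f"invalid counts ({self.n_pos}, {self.n_neg})")

    @property
    def n_total(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def p_pos(self) -> float:
        return self.n_pos / self.n_total

    @property
    def p_neg(self) -> float:
        return self.n_neg / self.n_total

    @classmethod
    def from_counts(cls, outcome: str, n_pos: int, n_neg: int) -> "BackgroundDistribution":
        return cls(outcome, int(n_pos), int(n_neg))


def compute_background_distribution(fm: pd.DataFrame, outcome: str) -> BackgroundDistribution:
    """Positive/negative voxel counts over the pooled cohort (tested + triaged rows)."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    if len(fm) == 0:
        raise ValueError("empty feature matrix")
    flags = fm[outcome].to_numpy()
    n_pos = int((flags == 1).sum())
    return BackgroundDistribution(outcome, n_pos, len(fm) - n_pos)


def write_feature_matrix(fm: pd.DataFrame, path: Path | str) -> None:
    """Serialize with the documented header (extra traceability columns kept last)."""
    extras = [c for c in fm.columns if c not in FEATURE_COLUMNS]
    fm[list(FEATURE_COLUMNS) + extras].to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: Path | str) -> pd.DataFrame:
    fm = pd.read_csv(path, sep="\t")
    missing = set(FEATURE_COLUMNS) - set(fm.columns)
    if missing:
        raise ValueError(f"feature matrix missing columns {sorted(missing)}")
    return fm
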