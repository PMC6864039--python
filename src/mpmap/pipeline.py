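"""End-to-end orchestration of the three experiments.

* sub-hypothesis 1: inclusion-weighted logits of each outcome on the five
  contrasts (joint Wald test, McFadden pseudo R^2, robust SEs);
* sub-hypothesis 2: leave-one-patient-out wKNN -> Pearson chi-square ->
  per-patient Benjamini-Hochberg, swept over the neighbor count k, with
  k_opt = argmax SENS(k) s.t. ACC(k) >= 0.95;
* sub-hypothesis 3: whole-brain chi-square maps at k_opt for held-out
  patients, Gaussianized and cluster-corrected with random field theory.

All functions operate on in-memory cohorts (lists of (PatientVolumeSet,
[BiopsySample])); the CLI layers disk I/O on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import features as feat
from . import inference, logit, rft
from .features import BackgroundDistribution
from .volumes import OUTCOMES, BiopsySample, PatientVolumeSet, normalize_to_wm, sphere_mask

log = logging.getLogger("mpmap")

DEFAULT_K_GRID = tuple(range(100, 3001, 100))


@dataclass(frozen=True)
class RunConfig:
    outcomes: tuple[str, ...] = OUTCOMES
    ks: tuple[int, ...] = DEFAULT_K_GRID
    alpha: float = 0.05
    acc_floor: float = 0.95
    z_cluster_forming: float = 4.0
    connectivity: int = 26
    seed: int = 0
    #: patients to map in sub-hypothesis 3 (None = all with a defined k_opt)
    subhyp3_patients: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.acc_floor <= 1.0:
            raise ValueError("accuracy floor must lie in (0, 1]")
        if len(self.ks) == 0:
            raise ValueError("k grid must be non-empty")


@dataclass
class PreparedCohort:
    patients: list[tuple[PatientVolumeSet, list[BiopsySample]]]  # WM-normalized
    feature_matrix: pd.DataFrame
    backgrounds: dict[str, BackgroundDistribution]


def prepare_cohort(
    patients: Sequence[tuple[PatientVolumeSet, Sequence[BiopsySample]]],
    outcomes: Sequence[str] = OUTCOMES,
) -> PreparedCohort:
    """Normalize every patient to white matter, pool features, fix backgrounds.

    Background distributions are computed once on the full cohort (not per LOO
    fold), matching the study design; this is a mild, documented information
    leak inherent to using cohort-wide expected distributions.
    """
    normalized = [(normalize_to_wm(pvs), list(samples)) for pvs, samples in patients]
    fm = feat.build_feature_matrix(normalized)
    backgrounds = {o: feat.compute_background_distribution(fm, o) for o in outcomes}
    return PreparedCohort(normalized, fm, backgrounds)


# ---------------------------------------------------------------------------
# Sub-hypothesis 1
# ---------------------------------------------------------------------------

def run_subhyp1(prep: PreparedCohort, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-outcome weighted-logit screen; returns (summary, coefficient table)."""
    log.info("sub-hyp 1: weighted logits on %d rows", len(prep.feature_matrix))
    return logit.screen_outcomes(prep.feature_matrix, config.outcomes)


# ---------------------------------------------------------------------------
# Sub-hypothesis 2
# ---------------------------------------------------------------------------

@dataclass
class Subhyp2Result:
    trace: pd.DataFrame  # outcome, k, acc, sens, sens_pooled, n_significant
    detail: pd.DataFrame  # patient_id, outcome, k, n_biopsy, n_significant, n_correct
    k_opt: dict[str, int | None]

    def summary(self) -> pd.DataFrame:
        """Per-outcome optimized results: k_opt, ACC, #significant, SENS."""
        rows = []
        for o, k in self.k_opt.items():
            if k is None:
                rows.append(
                    {"outcome": o, "k_opt": None, "acc": np.nan, "n_significant": 0, "sens": 0.0, "sens_pooled": 0.0}
                )
                continue
            r = self.trace[(self.trace["outcome"] == o) & (self.trace["k"] == k)].iloc[0]
            rows.append(
                {
                    "outcome": o,
                    "k_opt": k,
                    "acc": float(r["acc"]),
                    "n_significant": int(r["n_significant"]),
                    "sens": float(r["sens"]),
                    "sens_pooled": float(r["sens_pooled"]),
                }
            )
        return pd.DataFrame(rows)


def run_subhyp2(prep: PreparedCohort, config: RunConfig) -> Subhyp2Result:
    """Full LOO x k sweep with per-patient BH correction and k optimization."""
    log.info(
        "sub-hyp 2: LOO sweep over %d k values, %d outcomes, %d rows",
        len(config.ks), len(config.outcomes), len(prep.feature_matrix),
    )
    n_train_min = min(
        len(prep.feature_matrix) - n
        for n in prep.feature_matrix.groupby("patient_id").size()
    )
    ks = tuple(k for k in config.ks if k <= n_train_min)
    if not ks:
        raise ValueError("every k in the grid exceeds the smallest training fold")
    trace, detail = inference.loo_k_sweep(
        prep.feature_matrix, prep.backgrounds, ks, config.outcomes, config.alpha
    )
    k_opt = {}
    for o in config.outcomes:
        k_opt[o] = inference.optimize_k(trace[trace["outcome"] == o], config.acc_floor)
    return Subhyp2Result(trace, detail, k_opt)


# ---------------------------------------------------------------------------
# Sub-hypothesis 3
# ---------------------------------------------------------------------------

@dataclass
class PatientMaps:
    patient_id: int
    outcome: str
    k: int
    chi2_map: np.ndarray  # full-brain statistic
    z_map: np.ndarray
    p_pos: np.ndarray
    smoothness: rft.SmoothnessEstimate | None  # None for degenerate maps
    clusters: rft.ClusterTable

    @property
    def corrected_chi2(self) -> np.ndarray:
        """Chi-square map retaining only surviving clusters."""
        return np.where(self.clusters.surviving_mask, self.chi2_map, 0.0)


@dataclass
class Subhyp3Result:
    maps: list[PatientMaps]
    metrics: pd.DataFrame  # per patient x outcome biopsy-voxel metrics


def _biopsy_indices(pvs: PatientVolumeSet, samples: Sequence[BiopsySample]) -> np.ndarray:
    """(n, 3) voxel indices covered by the patient's biopsy spheres (per core)."""
    chunks = []
    for s in samples:
        m = sphere_mask(s.sphere, pvs.shape, pvs.spacing, pvs.origin)
        chunks.append(np.argwhere(m))
    return np.concatenate(chunks, axis=0) if chunks else np.zeros((0, 3), dtype=int)


def run_subhyp3(
    prep: PreparedCohort,
    k_opt: Mapping[str, int | None],
    config: RunConfig,
    keep_maps: bool = True,
) -> Subhyp3Result:
    """Whole-brain chi-square maps with RFT cluster correction at FWER alpha.

    Outcomes without a defined k_opt are skipped with a logged warning.  For
    each evaluated patient the biopsy voxels provide RFT-based accuracy and
    sensitivity comparable to the BH results of sub-hypothesis 2.
    """
    usable = {o: int(k) for o, k in k_opt.items() if k is not None}
    skipped = [o for o, k in k_opt.items() if k is None]
    for o in skipped:
        log.warning("sub-hyp 3: outcome %s has no k_opt (ACC floor unmet); skipped", o)
    if not usable:
        return Subhyp3Result([], pd.DataFrame(
            columns=["patient_id", "outcome", "k", "n_biopsy", "n_significant", "n_correct", "sens", "acc"]
        ))
    ids = [pvs.patient_id for pvs, _ in prep.patients]
    wanted = list(config.subhyp3_patients) if config.subhyp3_patients is not None else ids
    unknown = set(wanted) - set(ids)
    if unknown:
        raise KeyError(f"unknown patients {sorted(unknown)} requested for mapping")

    maps: list[PatientMaps] = []
    rows = []
    for pvs, samples in prep.patients:
        if pvs.patient_id not in wanted:
            continue
        log.info("sub-hyp 3: mapping patient %d", pvs.patient_id)
        fm_train = prep.feature_matrix[prep.feature_matrix["patient_id"] != pvs.patient_id]
        per_outcome = inference.whole_brain_chi2_multi(
            fm_train, pvs, usable, prep.backgrounds
        )
        bidx = _biopsy_indices(pvs, samples)
        for o, (cmap, pvol) in per_outcome.items():
            z = rft.chi2_field_to_z(cmap.values, df=cmap.df)
            try:
                smooth = rft.estimate_smoothness(z, pvs.brain_mask, pvs.spacing)
                clusters = rft.cluster_inference(
                    z,
                    pvs.brain_mask,
                    smooth,
                    z_threshold=config.z_cluster_forming,
                    alpha=config.alpha,
                    connectivity=config.connectivity,
                    spacing=pvs.spacing,
                )
            except ValueError as exc:
                # e.g. a constant map (no informative training labels in this
                # fold): smoothness undefined, nothing can be declared
                log.warning(
                    "patient %d outcome %s: %s; no surviving clusters",
                    pvs.patient_id, o, exc,
                )
                smooth = None
                clusters = rft.empty_cluster_table(pvs.shape, config.alpha)
            pm = PatientMaps(pvs.patient_id, o, usable[o], cmap.values, z, pvol, smooth, clusters)
            if keep_maps:
                maps.append(pm)
            # biopsy-voxel metrics under the RFT correction
            truth_flag = int(samples[0].outcomes[o]) if samples else 0
            if len(bidx):
                sig = clusters.surviving_mask[bidx[:, 0], bidx[:, 1], bidx[:, 2]]
                ppos = pvol[bidx[:, 0], bidx[:, 1], bidx[:, 2]]
                pred = (ppos >= 0.5).astype(int)
                n_sig = int(sig.sum())
                n_correct = int((pred[sig] == truth_flag).sum())
                sens = 100.0 * n_sig / len(bidx)
                acc = n_correct / n_sig if n_sig else np.nan
            else:
                n_sig, n_correct, sens, acc = 0, 0, 0.0, np.nan
            rows.append(
                {
                    "patient_id": pvs.patient_id,
                    "outcome": o,
                    "k": usable[o],
                    "n_biopsy": int(len(bidx)),
                    "n_significant": n_sig,
                    "n_correct": n_correct,
                    "sens": sens,
                    "acc": acc,
                }
            )
    return Subhyp3Result(maps, pd.DataFrame(rows))


def rft_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-outcome cohort summary of the RFT-corrected biopsy-voxel metrics."""
    rows = []
    for o, d in metrics.groupby("outcome"):
        acc = inference.accuracy_over_patients(list(zip(d["n_correct"], d["n_significant"])))
        sens_pp, sens_pool = inference.sensitivity(list(zip(d["n_significant"], d["n_biopsy"])))
        rows.append(
            {
                "outcome": o,
                "k_opt": int(d["k"].iloc[0]),
                "acc": acc,
                "n_significant": int(d["n_significant"].sum()),
                "sens": sens_pp,
                "sens_pooled": sens_pool,
            }
        )
    return pd.DataFrame(rows)
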