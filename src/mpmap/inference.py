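"""Chi-square transformation of class probabilities and per-patient inference.

A voxel's predicted class vector (p_pos, p_neg) from the wKNN is compared with
the cohort background distribution (q_pos, q_neg) by Pearson's statistic on
pseudo-counts scaled by the k neighbors entering the estimate::

    chi2 = k * [ (p_pos - q_pos)^2 / q_pos + (p_neg - q_neg)^2 / q_neg ],  df = 1

Upper-tail p-values are corrected per patient (the voxel family of one
patient's biopsy volume) with the Benjamini-Hochberg step-up rule.  Accuracy
ACC(k) is the mean of per-patient accuracies of the argmax class over
significant voxels, sensitivity SENS(k) the percent of biopsy voxels passing
the threshold; the tuning parameter k_opt maximizes SENS(k) subject to
ACC(k) >= 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import BackgroundDistribution, loo_split
from .volumes import CONTRAST_COLUMNS, OUTCOMES, PatientVolumeSet
from .wknn import wknn_probability


# ---------------------------------------------------------------------------
# Pearson transform
# ---------------------------------------------------------------------------

def pearson_chi2(
    p_pos: np.ndarray | float, background: BackgroundDistribution, k: int
) -> np.ndarray | float:
    """Pearson chi-square of predicted vs background class probabilities (df=1)."""
    q = background.p_pos
    if not 0.0 < q < 1.0:
        raise ValueError(f"degenerate background distribution (p_pos={q})")
    if k < 1:
        raise ValueError("k must be >= 1")
    p = np.asarray(p_pos, dtype=np.float64)
    chi2 = k * ((p - q) ** 2 / q + ((1.0 - p) - (1.0 - q)) ** 2 / (1.0 - q))
    return float(chi2) if np.isscalar(p_pos) else chi2


def chi2_to_p(chi2: np.ndarray | float, df: int = 1) -> np.ndarray | float:
    """Upper-tail probability of the chi-square distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if np.any(np.asarray(chi2) < 0):
        raise ValueError("chi-square values must be non-negative")
    return stats.chi2.sf(chi2, df)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

@dataclass
class SignificanceResult:
    p: np.ndarray
    reject: np.ndarray
    threshold: float
    correction: str = "BH"


def bh_reject(p_values: np.ndarray, alpha: float = 0.05) -> SignificanceResult:
    """Benjamini-Hochberg step-up rule at level ``alpha``.

    ``threshold`` is the effective p-value cutoff actually applied: the largest
    rejected p-value, or alpha/m when nothing is rejected (any p at or below it
    would have been rejected).
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return SignificanceResult(p, np.zeros(0, dtype=bool), float(alpha))
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    reject = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    threshold = float(p[reject].max()) if reject.any() else float(alpha / p.size)
    return SignificanceResult(p, reject, threshold)


# ---------------------------------------------------------------------------
# Accuracy / sensitivity
# ---------------------------------------------------------------------------

def confusion_matrix_binary(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """2x2 confusion matrix [[TN, FP], [FN, TP]] over the given voxels."""
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must be aligned")
    m = np.zeros((2, 2), dtype=int)
    for t in (0, 1):
        for g in (0, 1):
            m[t, g] = int(np.sum((truth == t) & (pred == g)))
    return m


def accuracy_over_patients(per_patient: Sequence[tuple[int, int]]) -> float:
    """Mean of per-patient accuracies over patients contributing >= 1 significant voxel.

    ``per_patient`` holds (n_correct, n_significant) pairs.  Returns NaN when no
    patient has a significant voxel (accuracy undefined, reported as no-result).
    """
    accs = [c / n for c, n in per_patient if n > 0]
    return float(np.mean(accs)) if accs else float("nan")


def sensitivity(per_patient: Sequence[tuple[int, int]]) -> tuple[float, float]:
    """SENS as percent of biopsy voxels passing the threshold.

    ``per_patient`` holds (n_significant, n_biopsy) pairs.  Returns the primary
    per-patient mean and, side by side, the pooled variant
    (total significant / total biopsy voxels).
    """
    fracs = [s / b for s, b in per_patient if b > 0]
    if not fracs:
        return 0.0, 0.0
    pooled_num = sum(s for s, b in per_patient)
    pooled_den = sum(b for s, b in per_patient)
    return 100.0 * float(np.mean(fracs)), 100.0 * pooled_num / pooled_den


def cohort_mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Mean and population (ddof=0) standard deviation of per-outcome summaries."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("no values")
    return float(v.mean()), float(v.std(ddof=0))


# ---------------------------------------------------------------------------
# k optimization
# ---------------------------------------------------------------------------

@dataclass
class KOptimizationTrace:
    outcome: str
    table: pd.DataFrame  # columns: k, acc, sens, sens_pooled, n_significant
    k_opt: int | None


def optimize_k(table: pd.DataFrame, acc_floor: float = 0.95) -> int | None:
    """k maximizing SENS(k) among {k : ACC(k) >= acc_floor}; ties -> smaller k.

    Returns None when no k qualifies (undefined ACC never qualifies).
    """
    ok = table[table["acc"].to_numpy() >= acc_floor]
    if len(ok) == 0:
        return None
    ok = ok.sort_values("k", kind="stable")
    best = ok.loc[ok["sens"].idxmax()]  # idxmax returns the first maximum
    return int(best["k"])


# ---------------------------------------------------------------------------
# LOO x k sweep (sub-hypothesis 2 engine)
# ---------------------------------------------------------------------------

@dataclass
class ChiSquareMap:
    """Voxel-wise chi-square statistic field (biopsy volume or whole brain)."""

    outcome: str
    values: np.ndarray
    df: int
    background: BackgroundDistribution
    k: int

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if np.any(self.values < 0):
            raise ValueError("chi-square values must be non-negative")


def patient_fold_detail(
    fm: pd.DataFrame,
    backgrounds: Mapping[str, BackgroundDistribution],
    ks: Sequence[int],
    pid: int,
    outcomes: Sequence[str] = OUTCOMES,
    alpha: float = 0.05,
) -> list[dict]:
    """One leave-one-out fold: wKNN -> chi-square -> BH counts for patient ``pid``."""
    ks = sorted(int(k) for k in ks)
    train, test = loo_split(fm, pid)
    probs = wknn_probability(
        train[list(CONTRAST_COLUMNS)].to_numpy(),
        {o: train[o].to_numpy() for o in outcomes},
        test[list(CONTRAST_COLUMNS)].to_numpy(),
        ks,
    )
    rows = []
    for o in outcomes:
        truth = test[o].to_numpy()
        q = backgrounds[o]
        for col, k in enumerate(ks):
            p_pos = probs[o][:, col]
            chi2 = pearson_chi2(p_pos, q, k)
            res = bh_reject(chi2_to_p(chi2, df=1), alpha)
            sig = res.reject
            pred = (p_pos >= 0.5).astype(int)
            rows.append(
                {
                    "patient_id": pid,
                    "outcome": o,
                    "k": k,
                    "n_biopsy": len(truth),
                    "n_significant": int(sig.sum()),
                    "n_correct": int((pred[sig] == truth[sig]).sum()),
                }
            )
    return rows


def loo_k_sweep(
    fm: pd.DataFrame,
    backgrounds: Mapping[str, BackgroundDistribution],
    ks: Sequence[int],
    outcomes: Sequence[str] = OUTCOMES,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-patient-out wKNN -> chi-square -> per-patient BH, for every k.

    Returns ``(trace, detail)``: the per-(outcome, k) trace with ACC/SENS
    columns, and the per-(patient, outcome, k) detail with raw counts from
    which the trace is a pure aggregation.
    """
    ks = sorted(int(k) for k in ks)
    patients = sorted(fm["patient_id"].unique().tolist())
    if len(patients) < 2:
        raise ValueError("leave-one-out needs at least two patients")
    detail_rows = []
    for pid in patients:
        detail_rows.extend(
            patient_fold_detail(fm, backgrounds, ks, pid, outcomes, alpha)
        )
    detail = pd.DataFrame(detail_rows)
    return trace_from_detail(detail, ks, outcomes), detail


def trace_from_detail(
    detail: pd.DataFrame, ks: Sequence[int], outcomes: Sequence[str] = OUTCOMES
) -> pd.DataFrame:
    """Aggregate per-(patient, outcome, k) counts into the ACC/SENS trace."""
    trace_rows = []
    for o in outcomes:
        for k in sorted(int(k) for k in ks):
            d = detail[(detail["outcome"] == o) & (detail["k"] == k)]
            acc = accuracy_over_patients(list(zip(d["n_correct"], d["n_significant"])))
            sens_pp, sens_pool = sensitivity(list(zip(d["n_significant"], d["n_biopsy"])))
            trace_rows.append(
                {
                    "outcome": o,
                    "k": k,
                    "acc": acc,
                    "sens": sens_pp,
                    "sens_pooled": sens_pool,
                    "n_significant": int(d["n_significant"].sum()),
                }
            )
    return pd.DataFrame(trace_rows)


# ---------------------------------------------------------------------------
# Whole-brain maps (sub-hypothesis 3 engine)
# ---------------------------------------------------------------------------

def whole_brain_chi2(
    fm_train: pd.DataFrame,
    pvs: PatientVolumeSet,
    outcome: str,
    k: int,
    background: BackgroundDistribution,
) -> tuple[ChiSquareMap, np.ndarray]:
    """Chi-square statistic at every brain-mask voxel of a held-out patient.

    The model is trained on all other patients' biopsy voxels; returns the 3-D
    chi-square map (zero outside the mask) and the matching p_pos volume.
    """
    if (fm_train["patient_id"] == pvs.patient_id).any():
        raise ValueError(f"training matrix contains held-out patient {pvs.patient_id}")
    maps = whole_brain_chi2_multi(fm_train, pvs, {outcome: k}, {outcome: background})
    return maps[outcome]


def whole_brain_chi2_multi(
    fm_train: pd.DataFrame,
    pvs: PatientVolumeSet,
    k_by_outcome: Mapping[str, int],
    backgrounds: Mapping[str, BackgroundDistribution],
) -> dict[str, tuple[ChiSquareMap, np.ndarray]]:
    """Whole-brain chi-square maps for several outcomes with one neighbor search.

    Each outcome may use its own optimized k; the (expensive) distance
    retrieval is shared at max(k).
    """
    if (fm_train["patient_id"] == pvs.patient_id).any():
        raise ValueError(f"training matrix contains held-out patient {pvs.patient_id}")
    outcomes = list(k_by_outcome)
    ks = sorted({int(k) for k in k_by_outcome.values()})
    mask = pvs.brain_mask
    queries = pvs.contrast_stack()[mask]
    train = fm_train[list(CONTRAST_COLUMNS)].to_numpy()
    labels = {o: fm_train[o].to_numpy() for o in outcomes}
    # block the query set: neighbor lists for a whole brain at the largest k
    # would not fit in memory in one piece
    block = 8192
    probs = {o: np.empty((len(queries), len(ks))) for o in outcomes}
    for start in range(0, len(queries), block):
        part = wknn_probability(train, labels, queries[start : start + block], ks)
        for o in outcomes:
            probs[o][start : start + block] = part[o]
    out: dict[str, tuple[ChiSquareMap, np.ndarray]] = {}
    for o in outcomes:
        k = int(k_by_outcome[o])
        p_pos = probs[o][:, ks.index(k)]
        chi2_vals = pearson_chi2(p_pos, backgrounds[o], k)
        vol = np.zeros(pvs.shape)
        vol[mask] = chi2_vals
        pvol = np.full(pvs.shape, np.nan)
        pvol[mask] = p_pos
        out[o] = (ChiSquareMap(o, vol, 1, backgrounds[o], k), pvol)
    return out
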