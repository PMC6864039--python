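"""Weighted k-nearest-neighbor class-membership probabilities.

For a query voxel the k nearest training voxels in the 5-D normalized-contrast
space are weighted by inverse Euclidean distance; the class probability is the
normalized class-wise weight sum.  Two edge rules make the estimate
deterministic and order-independent:

* distance ties at the k-th neighbor expand the neighbor set to include every
  point tied with the k-th distance (overlapping biopsy cores duplicate voxels,
  so exact ties are common in real feature matrices);
* zero-distance neighbors receive the limit of inverse-distance weighting:
  probability mass 1 split uniformly over the zero-distance points' labels.

The heavy path retrieves neighbors once per query set and evaluates all
requested k values (and all outcomes, which share distances) from cumulative
weight sums, so a full k-sweep costs one search.  Large searches pre-select
candidates in float32 with a safety margin and refine them in float64, which
keeps results exact while roughly halving the dominant selection cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .volumes import CONTRAST_COLUMNS

#: relative tolerance used to declare two neighbor distances tied
_TIE_RTOL = 1e-9
#: squared-distance floor below which a neighbor counts as zero-distance
_ZERO_ATOL2 = 1e-18
#: retrieval slack past max(k): absorbs boundary ties without a rescan
_KPAD = 16
#: training sizes above which the float32 candidate pre-selection kicks in
_F32_THRESHOLD = 20_000


def _sq_dists_chunk(
    q: np.ndarray, train_t: np.ndarray, tn: np.ndarray, out: np.ndarray | None = None
) -> np.ndarray:
    """|q - t|^2 for one query chunk, computed in-place around one GEMM.

    ``out`` lets callers reuse a buffer across chunks: the distance matrix is
    large (chunk x n_train) and repeated fresh allocation costs more than the
    arithmetic."""
    if out is not None:
        d2 = np.matmul(q, train_t, out=out[: len(q)])
    else:
        d2 = q @ train_t
    d2 *= -2.0
    d2 += np.einsum("ij,ij->i", q, q)[:, None]
    d2 += tn[None, :]
    np.maximum(d2, 0.0, out=d2)
    return d2


def _select_candidates(d2: np.ndarray, kcand: int) -> np.ndarray:
    """(nq, kcand) indices of the smallest squared distances per row.

    A sampled-quantile threshold prunes each row to a few-times-kcand subset
    before the exact partition, avoiding a full O(n) selection per row; rows
    whose prune undershoots fall back to the exact full partition.
    """
    nq, n = d2.shape
    stride = max(1, n // 4096)
    sub = d2[:, ::stride]
    m = min(int(kcand / n * sub.shape[1] * 1.7) + 8, sub.shape[1] - 1)
    thresh = np.partition(sub, m, axis=1)[:, m]
    mask = d2 <= thresh[:, None]
    counts = mask.sum(axis=1)
    out = np.empty((nq, kcand), dtype=np.int64)
    for r in range(nq):
        if counts[r] < kcand:  # prune undershot; exact selection on the row
            out[r] = np.argpartition(d2[r], kcand - 1)[:kcand]
            continue
        cols = np.flatnonzero(mask[r])
        if len(cols) > kcand:
            cols = cols[np.argpartition(d2[r, cols], kcand - 1)[:kcand]]
        out[r] = cols
    return out


def _query_chunked(
    train: np.ndarray, queries: np.ndarray, kret: int, chunk: int = 1024
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted distances and indices of the ``kret`` nearest training points.

    Brute force via |q-t|^2 = |q|^2 - 2 q.t + |t|^2; exact in float64.  For
    large training sets candidates are first selected on a float32 copy with a
    margin of ``_KPAD`` extra neighbors and then re-ranked in float64; float32
    rounding would have to displace a true neighbor past the margin to change
    the result, which the margin makes negligible.
    """
    n = train.shape[0]
    nq = queries.shape[0]
    use_f32 = n > _F32_THRESHOLD
    train_t = np.ascontiguousarray(train.T)
    tn = np.einsum("ij,ij->i", train, train)
    if use_f32:
        train32 = train.astype(np.float32)
        train32_t = np.ascontiguousarray(train32.T)
        tn32 = np.einsum("ij,ij->i", train32, train32)
    dist = np.empty((nq, kret))
    idx = np.empty((nq, kret), dtype=np.int64)
    kcand = min(kret + _KPAD, n)
    buf32 = np.empty((min(chunk, nq), n), dtype=np.float32) if use_f32 else None
    for start in range(0, nq, chunk):
        q = queries[start : start + chunk]
        if use_f32:
            d2c = _sq_dists_chunk(q.astype(np.float32), train32_t, tn32, out=buf32)
            if kcand < n:
                cand = _select_candidates(d2c, kcand)
            else:
                cand = np.broadcast_to(np.arange(n), (len(q), n))
            # exact float64 distances on the candidate set only
            diff = train[cand] - q[:, None, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            part_local = np.argpartition(d2, kret - 1, axis=1)[:, :kret] if kret < kcand else \
                np.broadcast_to(np.arange(d2.shape[1]), d2.shape)
            dsel = np.take_along_axis(d2, part_local, axis=1)
            isel = np.take_along_axis(cand, part_local, axis=1)
        else:
            d2 = _sq_dists_chunk(q, train_t, tn)
            if kret < n:
                part = np.argpartition(d2, kret - 1, axis=1)[:, :kret]
            else:
                part = np.broadcast_to(np.arange(n), (len(q), n))
            dsel = np.take_along_axis(d2, part, axis=1)
            isel = part
        order = np.argsort(dsel, axis=1, kind="stable")
        idx[start : start + len(q)] = np.take_along_axis(isel, order, axis=1)
        dist[start : start + len(q)] = np.take_along_axis(dsel, order, axis=1)
    np.sqrt(dist, out=dist)
    return dist, idx


def _predict_single(
    train: np.ndarray, labels: np.ndarray, query: np.ndarray, k: int
) -> float:
    """Exact single-query probability with full sort, tie expansion and zero rule."""
    diff = train - query[None, :]
    d2 = np.einsum("ij,ij->i", diff, diff)
    zero = d2 <= _ZERO_ATOL2
    if zero.any():
        return float(labels[zero].mean())
    order = np.argsort(d2, kind="stable")
    kth = d2[order[k - 1]]
    take = d2 <= kth * (1.0 + 2.0 * _TIE_RTOL)
    w = 1.0 / np.sqrt(d2[take])
    return float(w[labels[take] == 1].sum() / w.sum())


def wknn_probability(
    train: np.ndarray,
    labels: Mapping[str, np.ndarray],
    queries: np.ndarray,
    ks: Sequence[int],
) -> dict[str, np.ndarray]:
    """Positive-class probability for every query, outcome and k.

    Returns ``{outcome: array (n_queries, len(ks))}`` of p_pos; p_neg is its
    complement.  All outcomes share one neighbor search since they differ only
    in training labels.
    """
    train = np.ascontiguousarray(np.asarray(train, dtype=np.float64))
    queries = np.ascontiguousarray(np.atleast_2d(np.asarray(queries, dtype=np.float64)))
    if train.ndim != 2 or queries.shape[1] != train.shape[1]:
        raise ValueError("train and queries must be 2-D with matching feature dimension")
    if not np.isfinite(queries).all() or not np.isfinite(train).all():
        raise ValueError("non-finite values in train or query points")
    n = train.shape[0]
    ks = [int(k) for k in ks]
    if len(ks) == 0 or min(ks) < 1:
        raise ValueError("ks must be non-empty positive integers")
    if max(ks) > n:
        raise ValueError(f"k={max(ks)} exceeds the {n} training points")
    lab = {name: np.asarray(v, dtype=np.float64) for name, v in labels.items()}
    for name, v in lab.items():
        if v.shape != (n,):
            raise ValueError(f"labels[{name!r}] not aligned with training points")

    kret = min(max(ks) + _KPAD, n)
    dist, idx = _query_chunked(train, queries, kret)

    with np.errstate(divide="ignore"):
        w = 1.0 / dist
    # relative floor: GEMM rounding leaves |q-t|^2 ~ 1e-15 for identical points,
    # so candidate zero-distance rows are re-resolved with exact differences
    qnorm = np.linalg.norm(queries, axis=1)
    zero_rows = dist[:, 0] <= 1e-7 * (1.0 + qnorm)
    w[zero_rows] = 0.0  # recomputed exactly below

    cw = np.cumsum(w, axis=1)
    out: dict[str, np.ndarray] = {}
    kcols = np.array(ks) - 1
    cwl = {}
    with np.errstate(invalid="ignore"):  # zero-distance rows are recomputed below
        for name, y in lab.items():
            cwl[name] = np.cumsum(w * y[idx], axis=1)
            out[name] = cwl[name][:, kcols] / cw[:, kcols]

    # boundary ties: expand the neighbor set to the end of the tie group
    for c, k in enumerate(ks):
        if k >= kret:
            continue  # k == n: all points already included
        kth = dist[:, k - 1]
        tied = np.flatnonzero(~zero_rows & (dist[:, k] <= kth * (1.0 + _TIE_RTOL)))
        if tied.size == 0:
            continue
        beyond = dist[tied, k:] > kth[tied, None] * (1.0 + 2.0 * _TIE_RTOL)
        resolved = beyond.any(axis=1)
        m_abs = k + np.argmax(beyond, axis=1)  # index of first non-tied neighbor
        rr = tied[resolved]
        mm = m_abs[resolved]
        for name in lab:
            out[name][rr, c] = cwl[name][rr, mm - 1] / cw[rr, mm - 1]
        for r in tied[~resolved]:  # tie group may run past the window: rescan
            for name, y in lab.items():
                out[name][r, c] = _predict_single(train, y, queries[r], k)

    if zero_rows.any():
        for r in np.flatnonzero(zero_rows):
            for name, y in lab.items():
                for c, k in enumerate(ks):
                    out[name][r, c] = _predict_single(train, y, queries[r], k)
    return out


@dataclass
class TrainedWKNN:
    """A fitted wKNN model: training points, binary labels and neighbor count."""

    train_points: np.ndarray
    train_labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.train_points = np.asarray(self.train_points, dtype=np.float64)
        self.train_labels = np.asarray(self.train_labels)
        n = self.train_points.shape[0]
        if self.train_labels.shape != (n,):
            raise ValueError("labels not aligned with training points")
        if not 1 <= self.k <= n:
            raise ValueError(f"k must satisfy 1 <= k <= {n}, got {self.k}")

    def predict_proba(self, queries: np.ndarray) -> np.ndarray:
        """(n_queries, 2) array of [p_neg, p_pos]; rows sum to 1."""
        queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
        p_pos = wknn_probability(
            self.train_points, {"y": self.train_labels}, queries, [self.k]
        )["y"][:, 0]
        return np.column_stack([1.0 - p_pos, p_pos])


def predict_patient(
    fm_train: pd.DataFrame,
    fm_test: pd.DataFrame,
    outcome: str,
    k: int,
) -> np.ndarray:
    """Leave-one-patient-out prediction: (n_test, 2) probabilities [p_neg, p_pos].

    Hard guard: the training matrix must not contain any row from a test
    patient, so train/test leakage is impossible by construction.
    """
    train_ids = set(fm_train["patient_id"].unique().tolist())
    test_ids = set(fm_test["patient_id"].unique().tolist())
    overlap = train_ids & test_ids
    if overlap:
        raise ValueError(f"patients {sorted(overlap)} present in both train and test")
    model = TrainedWKNN(
        fm_train[list(CONTRAST_COLUMNS)].to_numpy(),
        fm_train[outcome].to_numpy(),
        k,
    )
    return model.predict_proba(fm_test[list(CONTRAST_COLUMNS)].to_numpy())
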