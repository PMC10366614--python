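"""Sliding-window tvFC construction, normalization, labeling, and k-NN machinery.

Conventions: windows are half-open, 0-based intervals ``[start, start + w)``;
connections are the unique ROI pairs (i, j), i < j, in row-major upper-triangle
order; windowed correlations are Fisher-z transformed (arctanh) after clipping
|r| at 1 - 1e-7 so degenerate windows cannot produce infinities.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import (
    INSTRUCTION_LABEL,
    MIXED_LABEL,
    DissimilarityMatrix,
    RoiTimeseries,
    TaskSchedule,
    TvfcMatrix,
    WindowSpec,
    connection_pairs,
)

R_CLIP = 1.0 - 1e-7


def count_connections(n_rois: int) -> int:
    """Number of unique pairwise connections among ``n_rois`` regions: N(N-1)/2."""
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    return n_rois * (n_rois - 1) // 2


def count_windows(n_acq: int, spec: WindowSpec) -> int:
    """Number of full sliding windows: floor((N_acq - (W_dur - W_step)) / W_step)."""
    spec.validate_for(n_acq)
    return (n_acq - (spec.w_duration - spec.w_step)) // spec.w_step


def window_start_indices(n_acq: int, spec: WindowSpec) -> np.ndarray:
    n_wins = count_windows(n_acq, spec)
    return np.arange(n_wins) * spec.w_step


def compute_tvfc(
    ts: RoiTimeseries,
    spec: WindowSpec,
    schedule: TaskSchedule | None = None,
) -> TvfcMatrix:
    """Sliding-window Fisher-z Pearson correlation matrix (connections x windows).

    For every window, the Pearson correlation of each unique ROI pair over the
    windowed samples is computed, Fisher-z transformed, and stacked as one
    column. If a ``schedule`` is given, windows are labeled with their task
    (or "mixed") via :func:`label_windows`.
    """
    spec.validate_for(ts.n_acq)
    starts = window_start_indices(ts.n_acq, spec)
    n_rois = ts.n_rois
    iu, ju = np.triu_indices(n_rois, k=1)

    cols = np.empty((len(iu), len(starts)))
    for w, s in enumerate(starts):
        seg = ts.data[:, s : s + spec.w_duration]
        sd = seg.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"zero-variance ROI {ts.roi_names[bad[0]]!r} in window starting at "
                f"acquisition {s}"
            )
        r = np.corrcoef(seg)[iu, ju]
        cols[:, w] = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))

    if schedule is not None:
        labels = label_windows(schedule, ts.n_acq, spec)
    else:
        labels = [MIXED_LABEL] * len(starts)

    return TvfcMatrix(
        values=cols,
        connection_index=connection_pairs(n_rois),
        window_starts=starts,
        spec=spec,
        window_labels=labels,
        normalized=False,
        subject_id=ts.subject_id,
        meta={"tr": ts.tr, "n_rois": n_rois},
    )


def zscore_rows(tvfc: TvfcMatrix) -> TvfcMatrix:
    """Standardize every connection trace to mean 0, std 1 (population std)."""
    mu = tvfc.values.mean(axis=1, keepdims=True)
    sd = tvfc.values.std(axis=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        i, j = tvfc.connection_index[bad[0]]
        raise ValueError(f"constant connection trace for ROI pair ({i}, {j})")
    return TvfcMatrix(
        values=(tvfc.values - mu) / sd,
        connection_index=tvfc.connection_index,
        window_starts=tvfc.window_starts,
        spec=tvfc.spec,
        window_labels=list(tvfc.window_labels),
        normalized=True,
        subject_id=tvfc.subject_id,
        meta=dict(tvfc.meta),
    )


def label_windows(schedule: TaskSchedule, n_acq: int, spec: WindowSpec) -> list[str]:
    """Label each window with its task if task-homogeneous, else "mixed".

    A window is task-homogeneous iff all its acquisitions carry the same single
    task label and none fall in an instruction period.
    """
    if schedule.n_acq < n_acq:
        raise ValueError(
            f"schedule covers only {schedule.n_acq} of {n_acq} acquisitions"
        )
    acq_labels = schedule.acquisition_labels()
    labels = []
    for s in window_start_indices(n_acq, spec):
        seg = acq_labels[s : s + spec.w_duration]
        uniq = set(seg.tolist())
        if len(uniq) == 1 and INSTRUCTION_LABEL not in uniq:
            labels.append(next(iter(uniq)))
        else:
            labels.append(MIXED_LABEL)
    return labels


def pairwise_dissimilarity(samples: np.ndarray, metric: str) -> DissimilarityMatrix:
    """Pairwise dissimilarity between row samples.

    euclidean: L2 distance; correlation: 1 - Pearson r; cosine: 1 - cosine
    similarity.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if metric == "correlation":
        sd = samples.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"zero-variance sample {bad[0]} invalid for correlation distance")
    elif metric == "cosine":
        nrm = np.linalg.norm(samples, axis=1)
        bad = np.flatnonzero(nrm == 0)
        if bad.size:
            raise ValueError(f"zero-norm sample {bad[0]} invalid for cosine distance")
    elif metric != "euclidean":
        raise ValueError(f"unknown metric {metric!r}")
    d = squareform(pdist(samples, metric=metric))
    return DissimilarityMatrix(values=d, metric=metric)


def tvfc_dissimilarity(tvfc: TvfcMatrix, metric: str) -> DissimilarityMatrix:
    """Dissimilarity between tvFC windows (columns are the samples)."""
    return pairwise_dissimilarity(tvfc.values.T, metric)


def knn_sets(ds: DissimilarityMatrix, k: int) -> np.ndarray:
    """Indices of each sample's k nearest neighbors, ascending by dissimilarity.

    Self is excluded; ties are broken by ascending sample index for
    determinism. Returns an (n, k) integer array.
    """
    n = ds.n
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}]")
    d = ds.values.copy()
    np.fill_diagonal(d, np.inf)
    idx = np.arange(n)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        # lexsort: primary key distance, secondary key index (stable tie-break)
        order = np.lexsort((idx, d[i]))
        out[i] = order[:k]
    return out
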