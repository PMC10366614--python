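"""Core data containers shared across the pipeline.

The central object is the :class:`TvfcMatrix`: a connections x windows matrix
of Fisher-z transformed sliding-window Pearson correlations, with each column
("window") treated as one sample of whole-brain functional connectivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MIXED_LABEL = "mixed"
INSTRUCTION_LABEL = "instruction"

VALID_METRICS = ("euclidean", "correlation", "cosine")


@dataclass
class RoiTimeseries:
    """ROI x acquisition signal matrix with sampling interval and subject tag."""

    data: np.ndarray  # shape (n_rois, n_acq)
    tr: float
    roi_names: list[str] = field(default_factory=list)
    subject_id: str = "sub-01"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("timeseries data must be 2-D (ROIs x acquisitions)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 ROIs")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 acquisitions")
        if not np.isfinite(self.data).all():
            raise ValueError("timeseries contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not self.roi_names:
            self.roi_names = [f"ROI{i:03d}" for i in range(self.data.shape[0])]
        if len(self.roi_names) != self.data.shape[0]:
            raise ValueError("roi_names length does not match data")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_acq(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        """Write as delimited text: rows = acquisitions, columns = ROIs."""
        df = pd.DataFrame(self.data.T, columns=self.roi_names)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, tr: float, subject_id: str = "sub-01") -> "RoiTimeseries":
        df = pd.read_csv(path, sep="\t")
        return cls(data=df.to_numpy().T, tr=tr, roi_names=list(df.columns), subject_id=subject_id)


@dataclass
class TaskSchedule:
    """Non-overlapping, sorted events covering the scan.

    Each event is ``(onset_acq, duration_acq, label)`` with 0-based onsets in
    acquisition units; instruction periods use the label ``"instruction"``.
    """

    events: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        self.events = sorted((int(o), int(d), str(lab)) for o, d, lab in self.events)
        prev_end = None
        for onset, dur, _ in self.events:
            if dur <= 0:
                raise ValueError("event durations must be positive")
            if prev_end is not None and onset != prev_end:
                raise ValueError("schedule events must be contiguous and non-overlapping")
            prev_end = onset + dur

    @property
    def n_acq(self) -> int:
        onset, dur, _ = self.events[-1]
        return onset + dur

    def acquisition_labels(self) -> np.ndarray:
        """Per-acquisition label vector."""
        labels = np.empty(self.n_acq, dtype=object)
        for onset, dur, lab in self.events:
            labels[onset : onset + dur] = lab
        return labels

    def task_names(self) -> list[str]:
        seen: list[str] = []
        for _, _, lab in self.events:
            if lab != INSTRUCTION_LABEL and lab not in seen:
                seen.append(lab)
        return seen

    def to_events_tsv(self, path: str | Path, tr: float) -> None:
        """Write a BIDS-style events table (onset/duration in seconds)."""
        rows = [
            {"onset": onset * tr, "duration": dur * tr, "trial_type": lab}
            for onset, dur, lab in self.events
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_events_tsv(cls, path: str | Path, tr: float) -> "TaskSchedule":
        df = pd.read_csv(path, sep="\t")
        events = [
            (int(round(r.onset / tr)), int(round(r.duration / tr)), str(r.trial_type))
            for r in df.itertuples()
        ]
        return cls(events=events)


@dataclass
class WindowSpec:
    """Rectangular sliding-window parameters, in acquisition units."""

    w_duration: int = 30
    w_step: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.w_step <= self.w_duration):
            raise ValueError("require 1 <= w_step <= w_duration")

    def validate_for(self, n_acq: int) -> None:
        if self.w_duration > n_acq:
            raise ValueError(
                f"window duration {self.w_duration} exceeds scan length {n_acq}"
            )


def connection_pairs(n_rois: int) -> list[tuple[int, int]]:
    """Ordered unique ROI pairs (i, j), i < j, row-major over the upper triangle."""
    iu, ju = np.triu_indices(n_rois, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


@dataclass
class TvfcMatrix:
    """Connections x windows Fisher-z sliding-window correlation matrix."""

    values: np.ndarray  # (n_cons, n_wins)
    connection_index: list[tuple[int, int]]
    window_starts: np.ndarray
    spec: WindowSpec
    window_labels: list[str]
    normalized: bool = False
    subject_id: str = "sub-01"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_starts = np.asarray(self.window_starts, dtype=int)
        if self.values.shape != (len(self.connection_index), len(self.window_starts)):
            raise ValueError("values shape inconsistent with connection/window indices")
        if len(self.window_labels) != self.values.shape[1]:
            raise ValueError("window_labels length does not match window count")

    @property
    def n_cons(self) -> int:
        return self.values.shape[0]

    @property
    def n_wins(self) -> int:
        return self.values.shape[1]

    def task_homogeneous_mask(self) -> np.ndarray:
        return np.array([lab != MIXED_LABEL for lab in self.window_labels])

    def window_subset(self, labels: Sequence[str]) -> "TvfcMatrix":
        """Restrict to windows whose label is in ``labels``."""
        keep = np.array([lab in set(labels) for lab in self.window_labels])
        if not keep.any():
            raise ValueError(f"no windows with labels {labels!r}")
        return TvfcMatrix(
            values=self.values[:, keep],
            connection_index=self.connection_index,
            window_starts=self.window_starts[keep],
            spec=self.spec,
            window_labels=[l for l, k in zip(self.window_labels, keep) if k],
            normalized=self.normalized,
            subject_id=self.subject_id,
            meta=dict(self.meta),
        )

    # -- container I/O: binary matrix + JSON sidecar --------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.values)
        sidecar = {
            "connection_index": [list(p) for p in self.connection_index],
            "window_starts": self.window_starts.tolist(),
            "w_duration": self.spec.w_duration,
            "w_step": self.spec.w_step,
            "window_labels": self.window_labels,
            "normalized": self.normalized,
            "subject_id": self.subject_id,
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "TvfcMatrix":
        path = Path(path)
        values = np.load(path.with_suffix(".npy"))
        sc = json.loads(path.with_suffix(".json").read_text())
        return cls(
            values=values,
            connection_index=[tuple(p) for p in sc["connection_index"]],
            window_starts=np.asarray(sc["window_starts"]),
            spec=WindowSpec(sc["w_duration"], sc["w_step"]),
            window_labels=list(sc["window_labels"]),
            normalized=bool(sc["normalized"]),
            subject_id=sc.get("subject_id", "sub-01"),
            meta=sc.get("meta", {}),
        )

    def to_tsv(self, path: str | Path) -> None:
        """Human-readable TSV dump (connections as rows, windows as columns)."""
        cols = [f"w{int(s)}_{lab}" for s, lab in zip(self.window_starts, self.window_labels)]
        idx = [f"{i}-{j}" for i, j in self.connection_index]
        pd.DataFrame(self.values, index=idx, columns=cols).to_csv(path, sep="\t")


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative pairwise dissimilarities with zero diagonal."""

    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.metric not in VALID_METRICS:
            raise ValueError(f"metric must be one of {VALID_METRICS}")
        n, m = self.values.shape
        if n != m:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        np.fill_diagonal(self.values, 0.0)
        if (self.values < -1e-12).any():
            raise ValueError("dissimilarities must be nonnegative")
        self.values = np.maximum(self.values, 0.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Embedding:
    """Windows x m coordinate matrix with method tag and carried metadata."""

    coords: np.ndarray
    method: str  # {"LE", "TSNE", "UMAP"}
    hyperparams: dict = field(default_factory=dict)
    window_labels: list[str] = field(default_factory=list)
    window_starts: np.ndarray | None = None
    subject_id: str = "sub-01"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D (samples x dimensions)")
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding coordinates must be finite")
        if self.window_labels and len(self.window_labels) != self.coords.shape[0]:
            raise ValueError("window_labels length does not match sample count")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def m(self) -> int:
        return self.coords.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.coords, columns=[f"dim_{i + 1}" for i in range(self.m)]
        )
        if self.window_starts is not None:
            df.insert(0, "window_start", self.window_starts)
        if self.window_labels:
            df.insert(0, "label", self.window_labels)
        df.to_csv(path, sep="\t", index=False)
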