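"""Embedding evaluation: silhouette scoring, group-level aggregation
("Concatenate + Embed" and "Embed + Procrustes"), the predictive framework,
and the stability study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, silhouette_score

from .containers import MIXED_LABEL, DissimilarityMatrix, Embedding, TvfcMatrix
from .tvfc import tvfc_dissimilarity, zscore_rows
from .le import le_affinity, le_embed
from .tsne import TsneParams, tsne_embed
from .fuzzy_umap import UmapParams, fuzzy_graph, umap_embed


@dataclass
class GroupEmbedding:
    coords: np.ndarray
    scan_ids: list[str]
    subject_ids: list[str]
    window_labels: list[str]
    strategy: str  # {"concat_embed", "embed_procrustes"}
    align_dims: int | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def m(self) -> int:
        return self.coords.shape[1]


@dataclass
class SilhouetteReport:
    label_type: str  # {"task", "subject"}
    value: float
    n_used: int
    excluded: int


@dataclass
class ClassificationReport:
    scheme: str  # {"split_half", "leave_one_subject_out"}
    f1_per_class: dict[str, float]
    f1_average: float
    m_used: int
    folds: int
    coefficients: np.ndarray | None = None  # per-dimension mean |coef|


def _labels_of(emb: Embedding | GroupEmbedding, label_type: str) -> list[str]:
    if label_type == "task":
        return list(emb.window_labels)
    if label_type == "subject":
        if isinstance(emb, GroupEmbedding):
            return list(emb.subject_ids)
        return [emb.subject_id] * emb.n
    raise ValueError("label_type must be 'task' or 'subject'")


def silhouette_index(
    emb: Embedding | GroupEmbedding | TvfcMatrix,
    label_type: str = "task",
) -> SilhouetteReport:
    """Silhouette over Euclidean distance in embedding (or ambient) space.

    Windows labeled "mixed" are excluded when scoring by task. A
    :class:`TvfcMatrix` may be passed directly, in which case the score is
    computed on the raw window columns (ambient-space silhouette).
    """
    if isinstance(emb, TvfcMatrix):
        coords = emb.values.T
        labels = list(emb.window_labels) if label_type == "task" else [emb.subject_id] * emb.n_wins
    else:
        coords = emb.coords
        labels = _labels_of(emb, label_type)
    labels = np.asarray(labels, dtype=object)
    if label_type == "task":
        keep = labels != MIXED_LABEL
    else:
        keep = np.ones(len(labels), dtype=bool)
    excluded = int((~keep).sum())
    x, y = coords[keep], labels[keep]
    if len(set(y.tolist())) < 2:
        raise ValueError("silhouette undefined with fewer than 2 distinct labels")
    value = float(silhouette_score(x, y, metric="euclidean"))
    return SilhouetteReport(label_type=label_type, value=value, n_used=int(keep.sum()), excluded=excluded)


def scan_embed(
    tvfc: TvfcMatrix,
    method: str,
    params: dict | TsneParams | UmapParams,
    metric: str = "euclidean",
) -> Embedding:
    """Embed one scan's tvFC windows with LE, T-SNE, or UMAP."""
    ds = tvfc_dissimilarity(tvfc, metric)
    meta = dict(
        window_labels=list(tvfc.window_labels),
        window_starts=tvfc.window_starts,
        subject_id=tvfc.subject_id,
    )
    method = method.upper()
    if method == "LE":
        p = dict(params) if isinstance(params, dict) else params
        graph = le_affinity(ds, p.get("k", 75), weighted=p.get("weighted", True))
        return le_embed(graph, p.get("m", 3), **meta)
    if method == "TSNE":
        p = params if isinstance(params, TsneParams) else TsneParams(**params)
        return tsne_embed(ds, p, **meta)
    if method == "UMAP":
        p = params if isinstance(params, UmapParams) else UmapParams(**params)
        graph = fuzzy_graph(ds, p.k)
        return umap_embed(graph, p, **meta)
    raise ValueError(f"unknown method {method!r}")


def _ds_of(samples: np.ndarray, metric: str) -> DissimilarityMatrix:
    from .tvfc import pairwise_dissimilarity

    return pairwise_dissimilarity(samples, metric)


def concat_embed(
    tvfcs: Sequence[TvfcMatrix],
    method: str,
    params: dict | TsneParams | UmapParams,
    metric: str = "euclidean",
    normalize: bool = False,
) -> GroupEmbedding:
    """"Concatenate + Embed": stack all scans' windows into one matrix
    (optionally row z-scoring each scan first) and run a single embedding."""
    ref = tvfcs[0].connection_index
    for t in tvfcs[1:]:
        if t.connection_index != ref:
            raise ValueError("scans have mismatched connection indices")
    mats = [zscore_rows(t) if normalize and not t.normalized else t for t in tvfcs]
    values = np.concatenate([t.values for t in mats], axis=1)
    labels = sum((list(t.window_labels) for t in mats), [])
    subjects = sum(([t.subject_id] * t.n_wins for t in mats), [])
    merged = TvfcMatrix(
        values=values,
        connection_index=ref,
        window_starts=np.concatenate([t.window_starts for t in mats]),
        spec=mats[0].spec,
        window_labels=labels,
        normalized=normalize,
        subject_id="group",
    )
    emb = scan_embed(merged, method, params, metric=metric)
    return GroupEmbedding(
        coords=emb.coords,
        scan_ids=subjects,
        subject_ids=subjects,
        window_labels=labels,
        strategy="concat_embed",
        diagnostics={"method": method, "normalized": normalize, **emb.diagnostics},
    )


@dataclass
class ProcrustesTransform:
    """Similarity transform y ~ scale * x @ rotation + translation."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(x, dtype=float) @ self.rotation + self.translation


def procrustes_fit(
    source: np.ndarray, target: np.ndarray
) -> tuple[ProcrustesTransform, float]:
    """Least-squares similarity (translation + rotation/reflection + uniform
    scale) mapping ``source`` onto ``target``.

    Returns the transform and the disparity: residual sum of squares of the
    aligned source, normalized by the centered target's sum of squares.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError("source and target must have equal shapes")
    n, m = source.shape
    if n < m + 1:
        raise ValueError("need at least m + 1 points")
    mu_s, mu_t = source.mean(axis=0), target.mean(axis=0)
    xs, xt = source - mu_s, target - mu_t
    norm_s, norm_t = np.linalg.norm(xs), np.linalg.norm(xt)
    if norm_s == 0 or norm_t == 0:
        raise ValueError("degenerate (zero-variance) configuration")
    u, s, vt = np.linalg.svd(xs.T @ xt)
    rotation = u @ vt
    scale = s.sum() / norm_s**2
    translation = mu_t - scale * mu_s @ rotation
    aligned = scale * xs @ rotation
    disparity = float(np.sum((aligned - xt) ** 2) / norm_t**2)
    return ProcrustesTransform(rotation, float(scale), translation), disparity


def embed_procrustes(
    embeddings: Sequence[Embedding],
    align_dims: int,
    reference: int = 0,
    generalized: bool = False,
    n_passes: int = 5,
) -> GroupEmbedding:
    """"Embed + Procrustes": align each scan-level embedding to a reference
    using its first ``align_dims`` dimensions, then stack all scans.

    With ``generalized=True``, alignment iterates against the evolving mean
    configuration for ``n_passes`` passes instead of a fixed reference scan.
    """
    n_wins = embeddings[0].n
    for e in embeddings[1:]:
        if e.n != n_wins:
            raise ValueError("scans have mismatched window counts; no correspondence")
    if any(e.m < align_dims for e in embeddings):
        raise ValueError("all embeddings need at least align_dims dimensions")
    blocks = [e.coords[:, :align_dims] for e in embeddings]

    if generalized:
        aligned = [b.copy() for b in blocks]
        for _ in range(n_passes):
            mean_cfg = np.mean(aligned, axis=0)
            aligned = [procrustes_fit(b, mean_cfg)[0].apply(b) for b in blocks]
    else:
        ref = blocks[reference]
        aligned = [procrustes_fit(b, ref)[0].apply(b) for b in blocks]

    coords = np.concatenate(aligned, axis=0)
    labels = sum((list(e.window_labels) for e in embeddings), [])
    subjects = sum(([e.subject_id] * e.n for e in embeddings), [])
    return GroupEmbedding(
        coords=coords,
        scan_ids=subjects,
        subject_ids=subjects,
        window_labels=labels,
        strategy="embed_procrustes",
        align_dims=align_dims,
        diagnostics={"generalized": generalized},
    )


def classify_windows(
    group: GroupEmbedding,
    m_used: int,
    scheme: str = "split_half",
    C: float = 1.0,
) -> ClassificationReport:
    """Task classification from group-embedding coordinates.

    A multiclass logistic regression with L1 penalty is trained on
    task-homogeneous windows. split_half: train on the first half of every
    scan's windows, test on the second, swap, and average; LOSO: one fold per
    held-out subject. Returns per-class and macro-averaged F1; per-dimension
    mean absolute coefficients are kept for feature inspection.
    """
    labels = np.asarray(group.window_labels, dtype=object)
    subjects = np.asarray(group.subject_ids, dtype=object)
    keep = labels != MIXED_LABEL
    x = group.coords[keep, :m_used]
    y = labels[keep].astype(str)
    subj = subjects[keep].astype(str)
    if m_used > group.m:
        raise ValueError("m_used exceeds embedding dimensions")

    def fit_fold(train: np.ndarray, test: np.ndarray) -> tuple[dict[str, float], float, np.ndarray]:
        if set(y[test]) - set(y[train]):
            raise ValueError("class absent from a training fold")
        clf = LogisticRegression(l1_ratio=1.0, C=C, solver="saga", max_iter=5000)
        clf.fit(x[train], y[train])
        pred = clf.predict(x[test])
        classes = sorted(set(y.tolist()))
        per = dict(
            zip(classes, f1_score(y[test], pred, labels=classes, average=None, zero_division=0))
        )
        return per, float(f1_score(y[test], pred, average="macro", zero_division=0)), np.abs(clf.coef_).mean(axis=0)

    folds: list[tuple[np.ndarray, np.ndarray]] = []
    if scheme == "split_half":
        first_half = np.zeros(len(y), dtype=bool)
        for s in np.unique(subj):
            idx = np.flatnonzero(subj == s)
            first_half[idx[: len(idx) // 2]] = True
        folds = [
            (np.flatnonzero(first_half), np.flatnonzero(~first_half)),
            (np.flatnonzero(~first_half), np.flatnonzero(first_half)),
        ]
    elif scheme == "leave_one_subject_out":
        for s in np.unique(subj):
            folds.append((np.flatnonzero(subj != s), np.flatnonzero(subj == s)))
    else:
        raise ValueError("scheme must be 'split_half' or 'leave_one_subject_out'")

    per_class_acc: dict[str, list[float]] = {}
    macros, coefs = [], []
    for train, test in folds:
        per, macro, coef = fit_fold(train, test)
        for c, v in per.items():
            per_class_acc.setdefault(c, []).append(v)
        macros.append(macro)
        coefs.append(coef)
    return ClassificationReport(
        scheme=scheme,
        f1_per_class={c: float(np.mean(v)) for c, v in per_class_acc.items()},
        f1_average=float(np.mean(macros)),
        m_used=m_used,
        folds=len(folds),
        coefficients=np.mean(coefs, axis=0),
    )


def stability_study(
    tvfc: TvfcMatrix,
    method: str,
    params: dict,
    n_reps: int = 20,
    seed: int = 0,
    metric: str = "euclidean",
) -> dict:
    """Re-embed one scan ``n_reps`` times with distinct seeds and collect the
    distribution of task silhouettes.

    Returns all SI_task values with median, interquartile range, and the count
    of 1.5*IQR outliers; failed repetitions are recorded, not fatal.
    """
    method = method.upper()
    if method not in ("TSNE", "UMAP", "LE"):
        raise ValueError("method must be 'TSNE', 'UMAP', or 'LE'")
    if n_reps < 2:
        raise ValueError("need at least 2 repetitions")
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    values, errors = [], []
    for rep_seed in seeds:
        p = dict(params)
        if method != "LE":
            p["seed"] = int(rep_seed)
        if method == "TSNE":
            # run-to-run variability for T-SNE comes from the initial layout
            p.setdefault("init", "random")
        try:
            emb = scan_embed(tvfc, method, p, metric=metric)
            values.append(silhouette_index(emb, "task").value)
        except Exception as exc:  # a failed repetition is recorded, not fatal
            errors.append(str(exc))
    values_arr = np.asarray(values)
    q1, med, q3 = np.percentile(values_arr, [25, 50, 75]) if len(values_arr) else (np.nan,) * 3
    iqr = q3 - q1
    outliers = int(
        ((values_arr < q1 - 1.5 * iqr) | (values_arr > q3 + 1.5 * iqr)).sum()
    ) if len(values_arr) else 0
    return {
        "si_task": values,
        "median": float(med),
        "iqr": float(iqr),
        "outliers": outliers,
        "errors": errors,
        "method": method,
        "n_reps": n_reps,
    }
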