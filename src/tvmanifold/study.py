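"""Canonical study experiments on the synthetic multi-task dataset.

Each function runs one self-contained experiment at the package's default
study conditions (30-ROI scans, four tasks x two 180-s blocks, TR 1.5 s) and
returns a flat dict of named quantities. The scan-level hyper-parameter
contrasts run at full window resolution (w_step = 1, 995 windows) because the
low-neighborhood failure mode is driven by the window-overlap autocorrelation
chain; the stability and group aggregation studies subsample windows
(w_step = 3 and 10) to keep repeated embeddings affordable.
"""

from __future__ import annotations

import numpy as np

from .containers import TvfcMatrix, WindowSpec
from .dimension import estimate_id, lpca_id, twonn_id
from .evaluation import (
    concat_embed,
    embed_procrustes,
    procrustes_fit,
    scan_embed,
    silhouette_index,
    stability_study,
)
from .fuzzy_umap import fuzzy_graph, rho_sigma
from .le import le_affinity, le_embed
from .nulls import phase_randomize, randomize_connectivity
from .pipeline import DEFAULT_GRIDS
from .synthetic import (
    SyntheticConfig,
    fingerprint_config,
    generate_dataset,
    generate_manifold_sample,
    id_contrast_config,
)
from .tsne import calibrate_sigmas, joint_p, low_dim_q
from .tvfc import (
    compute_tvfc,
    count_connections,
    count_windows,
    label_windows,
    pairwise_dissimilarity,
    tvfc_dissimilarity,
)


def _default_scan(seed: int, w_step: int = 1) -> TvfcMatrix:
    cfg = SyntheticConfig(n_subjects=1, n_rois=30, seed=seed)
    ts, schedule, _ = generate_dataset(cfg)[0]
    return compute_tvfc(ts, WindowSpec(30, w_step), schedule)


def structural_identities() -> dict:
    """Counting identities of the sliding-window construction at the study's
    published sizes (157 ROIs, 1,017 acquisitions, 45-s windows, 1-TR step)."""
    from .containers import TaskSchedule

    spec = WindowSpec(30, 1)
    schedule = TaskSchedule([(0, 8, "instruction"), (8, 120, "solo")])
    labels = label_windows(schedule, 128, spec)
    per_block = sum(1 for lab in labels if lab == "solo")
    return {
        "n_connections_157_rois": count_connections(157),
        "n_windows_1017_acq": count_windows(1017, spec),
        "task_windows_per_block": per_block,
        "task_windows_per_scan": 2 * per_block,
        "knn_grid_size": len(DEFAULT_GRIDS["le_knn"]),
    }


def algorithm_core_checks(seed: int) -> dict:
    """Oracle identities of the three embedding cores and Procrustes."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((100, 8))
    ds = pairwise_dissimilarity(x, "euclidean")

    # Laplacian Eigenmaps: lambda_0 ~ 0, constant f_0, truncation consistency
    graph = le_affinity(ds, 10)
    emb5 = le_embed(graph, m=5)
    emb2 = le_embed(graph, m=2)
    lambda0 = abs(emb5.diagnostics["eigenvalues"][0])
    trunc = float(np.abs(np.abs(emb5.coords[:, :2]) - np.abs(emb2.coords)).max())
    W = graph.weights
    D = np.diag(W.sum(axis=1))
    L = D - W
    resid = max(
        float(np.linalg.norm(L @ f - lam * np.diag(D) * f) / np.linalg.norm(f))
        for lam, f in zip(emb5.diagnostics["eigenvalues"][1:], emb5.coords.T)
    )

    # T-SNE: perplexity calibration accuracy; P and Q are distributions
    pp = 30.0
    sigmas = calibrate_sigmas(ds, pp)
    d2 = ds.values**2
    errs = []
    for i in range(ds.n):
        logits = -d2[i] / (2 * sigmas[i] ** 2)
        logits[i] = -np.inf
        w = np.exp(logits - logits.max())
        w[i] = 0
        p = w / w.sum()
        h = -(p[p > 0] * np.log2(p[p > 0])).sum()
        errs.append(abs(2**h - pp))
    perp_err = float(max(errs))
    P = joint_p(ds, pp)
    Q, _ = low_dim_q(rng.standard_normal((ds.n, 2)))
    p_sum, q_sum = float(P.sum()), float(Q.sum())

    # UMAP: sigma equation residual, unit nearest-neighbor weight, fuzzy union
    k = 15
    rho, sigma = rho_sigma(ds, k)
    g = fuzzy_graph(ds, k)
    from .tvfc import knn_sets

    nbrs = knn_sets(ds, k)
    target = np.log2(k)
    sig_resid = float(
        max(
            abs(np.exp(-np.maximum(0, ds.values[i, nbrs[i]] - rho[i]) / sigma[i]).sum() - target)
            for i in range(ds.n)
        )
    )
    nn_weight = float(g.B.max(axis=1).min())
    b_ij, b_ji = 0.4, 0.5
    union_check = float(b_ij + b_ji - b_ij * b_ji)

    # Procrustes: exact recovery of a known similarity transform
    src = rng.standard_normal((50, 3))
    theta = 0.8
    R = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    tgt = 1.7 * src @ R + np.array([2.0, -1.0, 0.5])
    _, disparity = procrustes_fit(src, tgt)

    return {
        "le_lambda0": float(lambda0),
        "le_truncation_max_abs_diff": trunc,
        "le_eigenpair_residual": resid,
        "tsne_perplexity_max_error": perp_err,
        "tsne_p_sum": p_sum,
        "tsne_q_sum": q_sum,
        "umap_sigma_equation_residual": sig_resid,
        "umap_nearest_neighbor_weight": nn_weight,
        "umap_fuzzy_union_0.4_0.5": union_check,
        "procrustes_recovery_disparity": float(disparity),
    }


def null_model_checks(seed: int) -> dict:
    """Invariants of the two surrogate-data models."""
    cfg = SyntheticConfig(n_subjects=1, n_rois=20, seed=seed)
    ts, schedule, _ = generate_dataset(cfg)[0]
    sur = phase_randomize(ts, seed=seed + 1)
    a0 = np.abs(np.fft.rfft(ts.data, axis=1))
    a1 = np.abs(np.fft.rfft(sur.data, axis=1))
    spec_err = float(np.abs(a0 - a1).max())
    var_err = float(np.abs(ts.data.var(axis=1) - sur.data.var(axis=1)).max())

    mat = compute_tvfc(ts, WindowSpec(30, 5), schedule)
    rnd = randomize_connectivity(mat, seed=seed + 2)
    multiset_err = float(
        np.abs(np.sort(mat.values, axis=0) - np.sort(rnd.values, axis=0)).max()
    )
    colsum_err = float(np.abs(mat.values.sum(axis=0) - rnd.values.sum(axis=0)).max())
    return {
        "phase_rand_amplitude_spectrum_error": spec_err,
        "phase_rand_variance_error": var_err,
        "conn_rand_column_multiset_error": multiset_err,
        "conn_rand_column_sum_error": colsum_err,
    }


def id_recovery(seed: int) -> dict:
    """Intrinsic-dimension recovery on known manifolds and the rest-vs-task
    contrast on the dedicated parameter-recovery condition."""
    out = {}
    for d, kind in ((1, "linear-subspace"), (2, "gaussian"), (5, "uniform-cube")):
        x = generate_manifold_sample(d, 50, 2000, kind, seed=seed + d)
        out[f"twonn_estimate_d{d}"] = float(twonn_id(x))
    x5 = generate_manifold_sample(5, 50, 2000, "linear-subspace", seed=seed)
    out["lpca_estimate_d5"] = float(lpca_id(x5, "global").value)

    cfg = id_contrast_config(seed=seed, n_subjects=3)
    per_task = {t: [] for t in cfg.task_names}
    for ts, schedule, _ in generate_dataset(cfg):
        mat = compute_tvfc(ts, WindowSpec(30, 1), schedule)
        for t in cfg.task_names:
            per_task[t].append(
                estimate_id(mat, "twonn", "global", window_subset=[t]).value
            )
    rest = float(np.mean(per_task["rest"]))
    tasks = float(np.mean([np.mean(per_task[t]) for t in cfg.task_names if t != "rest"]))
    out["twonn_id_rest"] = rest
    out["twonn_id_task_mean"] = tasks
    out["twonn_id_rest_minus_task"] = rest - tasks
    return out


def scan_pattern_suite(seed: int) -> dict:
    """Scan-level hyper-parameter and null-model silhouette patterns at full
    window resolution."""
    cfg = SyntheticConfig(n_subjects=1, n_rois=30, seed=seed)
    ts, schedule, _ = generate_dataset(cfg)[0]
    spec = WindowSpec(30, 1)
    mat = compute_tvfc(ts, spec, schedule)

    out = {"ambient_si_task": silhouette_index(mat, "task").value}
    for k in (25, 75):
        emb = scan_embed(mat, "LE", {"k": k, "m": 3}, metric="correlation")
        out[f"si_task_le_corr_k{k}"] = silhouette_index(emb, "task").value
    for lr in (0.01, 1.0):
        emb = scan_embed(
            mat, "UMAP", {"k": 70, "m": 3, "learning_rate": lr, "seed": seed},
            metric="euclidean",
        )
        out[f"si_task_umap_lr{lr:g}"] = silhouette_index(emb, "task").value
    for pp in (5, 75):
        emb = scan_embed(
            mat, "TSNE", {"perplexity": pp, "m": 2, "learning_rate": 10, "seed": seed},
            metric="correlation",
        )
        out[f"si_task_tsne_pp{pp}"] = silhouette_index(emb, "task").value

    conn = randomize_connectivity(mat, seed=seed + 1)
    emb = scan_embed(conn, "LE", {"k": 75, "m": 3}, metric="correlation")
    out["si_task_connectivity_randomized"] = silhouette_index(emb, "task").value
    phs = compute_tvfc(phase_randomize(ts, seed=seed + 2), spec, schedule)
    emb = scan_embed(phs, "LE", {"k": 75, "m": 3}, metric="correlation")
    out["si_task_phase_randomized"] = silhouette_index(emb, "task").value
    return out


def group_pattern_suite(seed: int) -> dict:
    """Group-level aggregation patterns on the fingerprinted 4-subject dataset."""
    cfg = fingerprint_config(seed=seed, n_subjects=4)
    data = generate_dataset(cfg)

    # Embed + Procrustes at full resolution
    mats = [compute_tvfc(ts, WindowSpec(30, 1), sch) for ts, sch, _ in data]
    embs = [scan_embed(t, "LE", {"k": 75, "m": 20}, metric="correlation") for t in mats]
    out = {}
    for ad in (2, 20):
        grp = embed_procrustes(embs, align_dims=ad)
        out[f"si_task_procrustes_dims{ad}"] = silhouette_index(grp, "task").value
    out["si_subject_procrustes_dims20"] = silhouette_index(
        embed_procrustes(embs, align_dims=20), "subject"
    ).value

    # Concatenate + Embed with and without row normalization (subsampled)
    mats10 = [compute_tvfc(ts, WindowSpec(30, 10), sch) for ts, sch, _ in data]
    raw = concat_embed(mats10, "LE", {"k": 50, "m": 3}, metric="euclidean", normalize=False)
    nrm = concat_embed(mats10, "LE", {"k": 50, "m": 3}, metric="euclidean", normalize=True)
    out["si_subject_concat_raw"] = silhouette_index(raw, "subject").value
    out["si_subject_concat_normalized"] = silhouette_index(nrm, "subject").value
    return out


def stability_suite(seed: int, n_reps: int = 20) -> dict:
    """Repeat-embedding stability of T-SNE vs UMAP at their task-optimal
    hyper-parameters (windows subsampled at w_step = 3)."""
    mat = _default_scan(seed, w_step=3)
    tsne = stability_study(
        mat, "TSNE", {"perplexity": 65, "m": 2, "learning_rate": 10},
        n_reps=n_reps, seed=seed, metric="correlation",
    )
    umap = stability_study(
        mat, "UMAP", {"k": 70, "m": 3, "learning_rate": 0.01},
        n_reps=n_reps, seed=seed, metric="euclidean",
    )
    return {
        "tsne_si_task_median": tsne["median"],
        "tsne_si_task_iqr": tsne["iqr"],
        "umap_si_task_median": umap["median"],
        "umap_si_task_iqr": umap["iqr"],
    }
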