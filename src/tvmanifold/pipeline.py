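"""Reproducible pipeline driver: simulate -> tvfc -> null -> id -> embed ->
group -> evaluate, with hyper-parameter grids, seed bookkeeping, and JSON
provenance sidecars for every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .containers import TvfcMatrix, WindowSpec
from .dimension import estimate_id
from .evaluation import concat_embed, embed_procrustes, scan_embed, silhouette_index
from .nulls import phase_randomize, randomize_connectivity
from .synthetic import SyntheticConfig, generate_dataset, write_dataset
from .tvfc import compute_tvfc, zscore_rows

log = logging.getLogger("tvmanifold")

#: Hyper-parameter exploration grids (per-method defaults).
DEFAULT_GRIDS = {
    "metrics": ["euclidean", "correlation", "cosine"],
    "le_knn": list(range(5, 201, 5)),  # 40 values
    "umap_knn": list(range(5, 201, 5)),
    "tsne_perplexity": list(range(5, 101, 5)) + [150, 175, 200],
    "le_dims": [2, 3, 5, 10, 15, 20, 25, 30],
    "umap_dims": [2, 3, 5, 10, 15, 20, 25, 30],
    "tsne_dims": [2, 3, 10, 15],
    "tsne_learning_rate": [10, 50, 75, 100, 200, 500, 1000],
    "umap_learning_rate": [0.01, 0.1, 1.0],
    "umap_min_dist": 0.8,
}


@dataclass
class PipelineConfig:
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "tvfc", "id", "embed", "evaluate"]
    )
    synthetic: dict = field(default_factory=dict)
    window: dict = field(default_factory=lambda: {"w_duration": 30, "w_step": 1})
    grids: dict = field(default_factory=lambda: dict(DEFAULT_GRIDS))
    embed_method: str = "LE"
    embed_params: dict = field(default_factory=lambda: {"k": 75, "m": 3})
    embed_metric: str = "correlation"
    normalize: bool = True
    null_model: str | None = None  # {"connectivity", "phase", None}
    group_strategy: str | None = None  # {"concat", "procrustes", None}
    align_dims: int = 3
    seed: int = 0
    outdir: str = "tvmanifold_out"

    def __post_init__(self) -> None:
        for key, val in DEFAULT_GRIDS.items():
            self.grids.setdefault(key, val)
        if any(isinstance(v, list) and not v for v in self.grids.values()):
            raise ValueError("hyper-parameter grids must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def stage_seed(self, stage: str) -> int:
        """Named per-stage substream derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31)

    def planned_le_combinations(self) -> int:
        """Grid-sweep size for LE per scan: |metrics| x |k grid| x |dims|."""
        return (
            len(self.grids["metrics"])
            * len(self.grids["le_knn"])
            * len(self.grids["le_dims"])
        )


def _write_artifact(outdir: Path, name: str, payload: dict, provenance: dict) -> Path:
    path = outdir / f"{name}.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    import tvmanifold
    prov = {"code_version": tvmanifold.__version__, "written": time.strftime("%Y-%m-%dT%H:%M:%S"), **provenance}
    (outdir / f"{name}.provenance.json").write_text(json.dumps(prov, indent=2, default=str))
    return path


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute the configured stages in dependency order.

    Returns a manifest mapping stage names to produced artifact paths. With
    ``dry_run=True`` only the plan (stages and grid-sweep sizes) is returned.
    """
    manifest: dict = {
        "stages": list(config.stages),
        "seed": config.seed,
        "planned_le_combinations": config.planned_le_combinations(),
        "artifacts": {},
    }
    if dry_run:
        return manifest

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = WindowSpec(**config.window)

    dataset = None
    tvfcs: list[TvfcMatrix] = []
    embeddings = []

    for stage in config.stages:
        t0 = time.time()
        try:
            if stage == "simulate":
                syn = SyntheticConfig(**{"seed": config.stage_seed("simulate"), **config.synthetic})
                dataset = generate_dataset(syn)
                paths = write_dataset(dataset, outdir / "simulate", syn.tr)
                manifest["artifacts"]["simulate"] = [str(p) for p in paths]

            elif stage == "tvfc":
                if dataset is None:
                    raise RuntimeError("tvfc stage requires simulate stage output")
                tvfcs = []
                for ts, schedule, _ in dataset:
                    if config.null_model == "phase":
                        ts = phase_randomize(ts, config.stage_seed(f"phase:{ts.subject_id}"))
                    t = compute_tvfc(ts, spec, schedule)
                    if config.null_model == "connectivity":
                        t = randomize_connectivity(t, config.stage_seed(f"conn:{ts.subject_id}"))
                    if config.normalize:
                        t = zscore_rows(t)
                    t.save(outdir / f"tvfc_{ts.subject_id}")
                    tvfcs.append(t)
                manifest["artifacts"]["tvfc"] = [
                    str(outdir / f"tvfc_{t.subject_id}.npy") for t in tvfcs
                ]

            elif stage == "id":
                reports = {}
                for t in tvfcs:
                    est = estimate_id(t, "twonn", "global")
                    reports[t.subject_id] = {"estimator": "twoNN", "scope": "global", "value": est.value}
                _write_artifact(outdir, "id_estimates", reports, {"stage": "id", "window": config.window})
                manifest["artifacts"]["id"] = str(outdir / "id_estimates.json")

            elif stage == "embed":
                embeddings = []
                for t in tvfcs:
                    params = dict(config.embed_params)
                    if config.embed_method.upper() != "LE":
                        params.setdefault("seed", config.stage_seed(f"embed:{t.subject_id}"))
                    emb = scan_embed(t, config.embed_method, params, metric=config.embed_metric)
                    emb.to_tsv(outdir / f"embedding_{t.subject_id}.tsv")
                    embeddings.append(emb)
                manifest["artifacts"]["embed"] = [
                    str(outdir / f"embedding_{e.subject_id}.tsv") for e in embeddings
                ]

            elif stage == "group":
                if config.group_strategy == "concat":
                    group = concat_embed(
                        tvfcs, config.embed_method, config.embed_params,
                        metric=config.embed_metric, normalize=config.normalize,
                    )
                elif config.group_strategy == "procrustes":
                    group = embed_procrustes(embeddings, align_dims=config.align_dims)
                else:
                    raise RuntimeError("group stage requires group_strategy 'concat' or 'procrustes'")
                np.savetxt(outdir / "group_coords.tsv", group.coords, delimiter="\t")
                manifest["artifacts"]["group"] = str(outdir / "group_coords.tsv")
                manifest["group"] = group
                embeddings_for_eval = [group]

            elif stage == "evaluate":
                target = manifest.get("group") or embeddings
                reports = []
                items = [target] if not isinstance(target, list) else target
                for e in items:
                    rep = silhouette_index(e, "task")
                    reports.append({"label_type": "task", "value": rep.value, "n_used": rep.n_used})
                _write_artifact(outdir, "evaluation", {"silhouette": reports}, {"stage": "evaluate"})
                manifest["artifacts"]["evaluate"] = str(outdir / "evaluation.json")

            else:
                raise RuntimeError(f"unknown stage {stage!r}")
        except Exception:
            log.exception("stage %s failed; partial results preserved in %s", stage, outdir)
            manifest["failed_stage"] = stage
            raise
        log.info("stage %s finished in %.1fs", stage, time.time() - t0)

    manifest.pop("group", None)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
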