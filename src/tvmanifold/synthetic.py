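"""Synthetic multi-subject multi-task ROI timeseries generator.

Emulates the statistical structure a sliding-window tvFC analysis assumes of a
continuous multi-task fMRI scan: four tasks, each occupying two temporally
separated 180-s blocks preceded by 12-s instruction periods; task-specific
covariance states produced by latent-factor mixing; strong AR(1) temporal
autocorrelation; and per-subject connectome "fingerprints".

Fingerprints are produced by two mechanisms that demonstrably shift
connection-level FC statistics (a per-ROI affine transform would not, because
Pearson correlation is affine-invariant): a subject-specific background latent
factor, whose rank-1 loading outer product adds a per-connection mean offset,
and per-ROI signal gains applied before additive noise, which modulate each
connection's signal-to-noise ratio and hence its FC mean and volatility.

Also provides known-dimension manifold samples for validating intrinsic
dimension estimators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import INSTRUCTION_LABEL, RoiTimeseries, TaskSchedule

DEFAULT_TASKS = ["rest", "memory", "math", "attention"]


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate the multi-task study design."""

    n_subjects: int = 1
    n_rois: int = 30
    tr: float = 1.5
    task_names: list[str] = field(default_factory=lambda: list(DEFAULT_TASKS))
    block_length: float = 180.0  # seconds per task block
    instruction_length: float = 12.0  # seconds preceding each block
    blocks_per_task: int = 2
    # latent factors per task; rest mixes more factors (less constrained state)
    n_latent_factors: dict[str, int] | int = field(
        default_factory=lambda: {"rest": 8, "memory": 4, "math": 4, "attention": 4}
    )
    # connectivity backbone shared by all states: most FC structure is stable
    # across tasks, with task demands modulating a limited set of connections
    n_shared_factors: int = 6
    # fraction of signal std carried by the task-specific factors; calibrated so
    # ambient-space task silhouettes are positive but small, as on real tvFC
    task_modulation: float = 0.5
    noise_sd: float = 0.5
    autocorr_strength: float = 0.6  # AR(1) coefficient in [0, 1)
    # slow lognormal modulation of each latent factor's amplitude (network
    # engagement drifting over tens of seconds): makes window covariances move
    # on a manifold whose dimension tracks the number of active factors
    amplitude_mod: float = 0.5
    amplitude_timescale: float = 45.0  # seconds (AR(1) time constant)
    # per-block loading perturbation (slow non-stationarity): the two blocks of
    # a task share most but not all of their covariance, so embeddings can
    # distinguish the blocks while still clustering them by task
    block_jitter: float = 0.35
    # per-subject perturbation of each task's loading matrix: inter-subject
    # variability in FC network topology, so scan-level embedding geometries
    # agree only up to a higher-dimensional similarity transform
    subject_loading_jitter: float = 0.3
    subject_offset_sd: float = 0.0  # background-factor loading scale
    subject_gain_sd: float = 0.0  # per-ROI signal-gain spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_rois < 2:
            raise ValueError("need n_subjects >= 1 and n_rois >= 2")
        if not (0 <= self.autocorr_strength < 1):
            raise ValueError("autocorr_strength must be in [0, 1)")
        if self.blocks_per_task < 1:
            raise ValueError("blocks_per_task must be >= 1")
        if len(set(self.task_names)) != len(self.task_names) or not self.task_names:
            raise ValueError("task_names must be non-empty and unique")

    def factors_for(self, task: str) -> int:
        if isinstance(self.n_latent_factors, int):
            return self.n_latent_factors
        return self.n_latent_factors.get(task, 4)

    @property
    def block_acq(self) -> int:
        return int(round(self.block_length / self.tr))

    @property
    def instruction_acq(self) -> int:
        return int(round(self.instruction_length / self.tr))

    @property
    def n_tasks(self) -> int:
        return len(self.task_names)

    def total_acq(self) -> int:
        per_block = self.block_acq + self.instruction_acq
        return self.blocks_per_task * self.n_tasks * per_block


@dataclass
class GroundTruth:
    """Generator-side truth recorded alongside each synthetic scan."""

    task_covariances: dict[str, np.ndarray]
    subject_offsets: np.ndarray  # implied per-connection FC mean shift (vectorized)
    subject_gains: np.ndarray  # per-ROI signal gains
    schedule: TaskSchedule
    seed: int = 0


class ScheduleError(ValueError):
    """Raised when no block ordering without immediate task repetition exists."""


def make_schedule(config: SyntheticConfig, rng: np.random.Generator) -> TaskSchedule:
    """Interleave task blocks so no task repeats back-to-back.

    Each block is preceded by an instruction period. Ordering is drawn by
    seeded rejection sampling over permutations of the block multiset.
    """
    if config.n_tasks == 1 and config.blocks_per_task > 1:
        raise ScheduleError("cannot avoid immediate repetition with a single task")
    blocks = [t for t in config.task_names for _ in range(config.blocks_per_task)]
    order = None
    for _ in range(10_000):
        cand = list(rng.permutation(blocks))
        if all(a != b for a, b in zip(cand, cand[1:])):
            order = cand
            break
    if order is None:
        raise ScheduleError("could not find a schedule without immediate task repetition")

    events: list[tuple[int, int, str]] = []
    t = 0
    for task in order:
        events.append((t, config.instruction_acq, INSTRUCTION_LABEL))
        t += config.instruction_acq
        events.append((t, config.block_acq, task))
        t += config.block_acq
    return TaskSchedule(events=events)


def _random_loadings(n_rois: int, n_factors: int, rng: np.random.Generator) -> np.ndarray:
    L = rng.standard_normal((n_rois, n_factors))
    # unit-variance signal per ROI so noise_sd is interpretable as a noise/signal ratio
    L /= np.linalg.norm(L, axis=1, keepdims=True)
    return L


def _ar1_filter(x: np.ndarray, phi: float) -> np.ndarray:
    """Apply y[t] = phi*y[t-1] + sqrt(1-phi^2)*x[t] along the last axis."""
    if phi == 0:
        return x
    y = np.empty_like(x)
    y[..., 0] = x[..., 0]
    c = np.sqrt(1.0 - phi**2)
    for t in range(1, x.shape[-1]):
        y[..., t] = phi * y[..., t - 1] + c * x[..., t]
    return y


def _connection_vector(mat: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(mat.shape[0], k=1)
    return mat[iu, ju]


def generate_dataset(
    config: SyntheticConfig,
) -> list[tuple[RoiTimeseries, TaskSchedule, GroundTruth]]:
    """Generate one scan per subject with shared task structure.

    Task loading matrices (hence task covariance states) are drawn once per
    dataset seed and shared across subjects; the schedule is likewise shared so
    window correspondences hold across scans. Subject fingerprints (background
    factor + per-ROI signal gains) are drawn per subject.
    """
    rng = np.random.default_rng(config.seed)
    schedule = make_schedule(config, rng)
    n_acq = schedule.n_acq

    all_states = config.task_names + [INSTRUCTION_LABEL]
    shared_loading = _random_loadings(config.n_rois, config.n_shared_factors, rng)
    loadings = {
        task: _random_loadings(config.n_rois, config.factors_for(task), rng)
        for task in all_states
    }
    w = config.task_modulation
    w_shared = np.sqrt(max(0.0, 1.0 - w**2))

    out = []
    for s in range(config.n_subjects):
        sub_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1 + s]))
        gains = 1.0 + config.subject_gain_sd * sub_rng.standard_normal(config.n_rois)
        bg_loading = config.subject_offset_sd * sub_rng.standard_normal(config.n_rois)

        subj_loadings = {}
        for state in all_states:
            L = loadings[state]
            if config.subject_loading_jitter > 0 and state != INSTRUCTION_LABEL:
                pert = _random_loadings(config.n_rois, L.shape[1], sub_rng)
                L = L + config.subject_loading_jitter * pert
                L = L / np.linalg.norm(L, axis=1, keepdims=True)
            subj_loadings[state] = L

        phi_amp = np.exp(-config.tr / config.amplitude_timescale)

        def _factors(n_f: int, n_t: int, modulated: bool) -> np.ndarray:
            f = sub_rng.standard_normal((n_f, n_t))
            if modulated and config.amplitude_mod > 0:
                env = _ar1_filter(sub_rng.standard_normal((n_f, n_t)), phi_amp)
                f = f * np.exp(config.amplitude_mod * env - config.amplitude_mod**2 / 2)
            return f

        # the shared backbone runs continuously and keeps a stable amplitude;
        # engagement drift affects only the state-specific factors
        signal = w_shared * (shared_loading @ _factors(config.n_shared_factors, n_acq, False))
        for onset, dur, state in schedule.events:
            L = subj_loadings[state]
            if config.block_jitter > 0 and state != INSTRUCTION_LABEL:
                pert = _random_loadings(config.n_rois, L.shape[1], sub_rng)
                L = L + config.block_jitter * pert
                L /= np.linalg.norm(L, axis=1, keepdims=True)
            signal[:, onset : onset + dur] += w * (L @ _factors(L.shape[1], dur, True))
        signal *= gains[:, None]
        # subject background factor: adds a rank-1 component across the whole scan
        signal += bg_loading[:, None] * sub_rng.standard_normal(n_acq)[None, :]
        signal = _ar1_filter(signal, config.autocorr_strength)
        noise = config.noise_sd * sub_rng.standard_normal(signal.shape)
        data = signal + noise

        ts = RoiTimeseries(data=data, tr=config.tr, subject_id=f"sub-{s + 1:02d}")
        def _cov(L_task: np.ndarray) -> np.ndarray:
            L_full = np.hstack([w_shared * shared_loading, w * L_task]) * gains[:, None]
            return L_full @ L_full.T + np.outer(bg_loading, bg_loading)

        task_covs = {t: _cov(subj_loadings[t]) for t in config.task_names}
        gt = GroundTruth(
            task_covariances=task_covs,
            subject_offsets=_connection_vector(np.outer(bg_loading, bg_loading)),
            subject_gains=gains,
            schedule=schedule,
            seed=config.seed,
        )
        out.append((ts, schedule, gt))
    return out


def write_dataset(
    dataset: list[tuple[RoiTimeseries, TaskSchedule, GroundTruth]],
    outdir: str | Path,
    tr: float,
) -> list[Path]:
    """Write ROI timeseries TSVs, one events table, and a ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ts, schedule, gt in dataset:
        p = outdir / f"{ts.subject_id}_roi_timeseries.tsv"
        ts.to_tsv(p)
        paths.append(p)
    schedule = dataset[0][1]
    schedule.to_events_tsv(outdir / "events.tsv", tr)
    sidecar = {
        "seed": dataset[0][2].seed,
        "subjects": [ts.subject_id for ts, _, _ in dataset],
        "task_cov_hashes": {
            t: int(abs(hash(c.tobytes())) % 10**12)
            for t, c in dataset[0][2].task_covariances.items()
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
    return paths


def fingerprint_config(seed: int = 0, n_subjects: int = 4, **kw) -> SyntheticConfig:
    """Multi-subject condition with connectome fingerprints enabled.

    The subject background factor is given the same scale as the unit task
    signal and per-ROI gains a 40% spread, reflecting the large inter-subject
    FC variability that makes fingerprinting effective on real data.
    """
    return SyntheticConfig(
        n_subjects=n_subjects, seed=seed,
        subject_offset_sd=1.0, subject_gain_sd=0.4, **kw,
    )


def id_contrast_config(seed: int = 0, n_subjects: int = 3, **kw) -> SyntheticConfig:
    """Parameter-recovery condition for the rest-vs-task intrinsic-dimension
    contrast.

    State drift must dominate window-level correlation sampling noise for the
    factor count (8 for rest vs 4 per task) to be recoverable from ~180
    windows per task, so the task-specific signal fraction is raised, the
    additive noise and block non-stationarity lowered, and the shared backbone
    kept small.
    """
    return SyntheticConfig(
        n_subjects=n_subjects, seed=seed,
        task_modulation=0.9, noise_sd=0.2, block_jitter=0.0, n_shared_factors=2,
        **kw,
    )


def generate_manifold_sample(
    intrinsic_dim: int,
    ambient_dim: int,
    n_points: int,
    kind: str = "uniform-cube",
    seed: int = 0,
) -> np.ndarray:
    """Sample points with known intrinsic dimension, embedded by a random
    orthonormal map into ``ambient_dim`` coordinates.

    kinds: "uniform-cube" (uniform on [0,1]^d), "gaussian" (standard normal in
    d dims), "linear-subspace" (gaussian on a d-dim linear subspace — exactly
    rank d).
    """
    if intrinsic_dim > ambient_dim:
        raise ValueError("intrinsic_dim must not exceed ambient_dim")
    if n_points < 10:
        raise ValueError("need at least 10 points")
    rng = np.random.default_rng(seed)
    if kind == "uniform-cube":
        latent = rng.uniform(size=(n_points, intrinsic_dim))
    elif kind in ("gaussian", "linear-subspace"):
        latent = rng.standard_normal((n_points, intrinsic_dim))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    # random orthonormal columns via QR of a gaussian matrix
    q, _ = np.linalg.qr(rng.standard_normal((ambient_dim, intrinsic_dim)))
    return latent @ q.T
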