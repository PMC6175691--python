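"""Synthetic cohorts with known ground truth.

The generator emulates the design of a resting-state skill-learning study:
each subject contributes a regional time-series matrix whose correlation
structure contains an implanted edge set covarying across subjects with a
standardized latent skill score, a six-parameter motion trace with
occasional large spikes, WM/CSF-like nuisance series, and a covariate table.
Paired retest sessions with a target intraclass correlation and paired
placebo/drug sessions with a dose-scaled connectivity decrement on the
implanted edges support the reliability and pharmacological-challenge
analyses.

Per-subject target correlation matrices are assembled from a modular
background (shared across subjects) plus the implanted effect, projected to
the nearest valid correlation matrix by eigenvalue clipping, and sampled as
zero-mean correlated Gaussian noise. With a fixed seed every output is
bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BehavioralRecord, BlockSummary, error_rate_from_gates

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "SyntheticBehavior",
    "generate_cohort",
    "generate_behavior",
    "generate_retest_pair",
    "generate_drug_pair",
    "nearest_correlation",
]

_CLIP = 0.95  # keeps Fisher z finite with headroom


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the emulated study: 60 subjects, 264 nodes, a resting
    run of 240 frames at TR = 2 s, and an implanted effect of
    ``effect_beta`` correlation units per SD of the latent skill score on
    the ``implanted_edges``.
    """

    n_subjects: int = 60
    n_nodes: int = 264
    n_frames: int = 240
    repetition_time: float = 2.0
    base_correlation: float = 0.3
    implanted_edges: tuple[tuple[int, int], ...] = ()
    effect_beta: float = 0.1
    edge_noise_sd: float = 0.02
    motion_spike_rate: float = 0.01
    seed: int = 0
    # background structure (shared across subjects, independent of the skill score)
    n_modules: int = 4
    within_module_r: float = 0.25
    background_noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if abs(self.base_correlation) >= 1:
            raise ValueError("base_correlation must lie in (-1, 1)")
        if abs(self.base_correlation + self.effect_beta * 3.0) >= 1:
            raise ValueError(
                "base_correlation + 3*effect_beta leaves no clipping headroom "
                f"({self.base_correlation} + 3*{self.effect_beta})"
            )
        for i, j in self.implanted_edges:
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"implanted edge ({i}, {j}) is not an upper-triangle pair")
        object.__setattr__(self, "implanted_edges", tuple((int(i), int(j)) for i, j in self.implanted_edges))


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort with its ground truth."""

    config: CohortConfig
    timeseries: np.ndarray  # (subjects, frames, nodes)
    motion: np.ndarray  # (subjects, frames, 6)
    nuisance: np.ndarray  # (subjects, frames, 2) WM-like / CSF-like
    records: pd.DataFrame  # id, age, sex, mean_fd, skill_learning, ...
    latent_skill: np.ndarray  # standardized latent score per subject
    target_matrices: np.ndarray  # (subjects, nodes, nodes) pre-sampling targets
    implanted_edges: tuple[tuple[int, int], ...]
    effect_beta: float
    clip_warnings: int = 0


def nearest_correlation(matrix: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the result re-normalized to
    a unit diagonal. Raises if the repair cannot produce entries in (-1, 1).
    """
    m = np.asarray(matrix, dtype=float)
    m = (m + m.T) / 2.0
    vals, vecs = np.linalg.eigh(m)
    vals = np.maximum(vals, eig_floor)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    if np.any(d <= 0):
        raise ValueError("target matrix is not PSD-repairable (non-positive diagonal)")
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    off = repaired[~np.eye(repaired.shape[0], dtype=bool)]
    if off.size and np.max(np.abs(off)) >= 1.0:
        raise ValueError("target matrix is not PSD-repairable (|r| >= 1 after projection)")
    return repaired


def _module_background(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_nodes
    modules = np.arange(n) * config.n_modules // n
    same = modules[:, None] == modules[None, :]
    bg = np.where(same, config.within_module_r, 0.0)
    noise = rng.normal(0.0, config.background_noise_sd, size=(n, n))
    bg = bg + (noise + noise.T) / 2.0
    np.fill_diagonal(bg, 1.0)
    return bg


def _motion_trace(n_frames: int, spike_rate: float, rng: np.random.Generator) -> np.ndarray:
    trans = np.cumsum(rng.normal(0.0, 0.01, size=(n_frames, 3)), axis=0)
    rots = np.cumsum(rng.normal(0.0, 2e-4, size=(n_frames, 3)), axis=0)
    spikes = rng.random(n_frames) < spike_rate
    spikes[0] = False
    # translation jump of 0.6-1.2 mm at spike frames -> FD > 0.5 mm there
    jump = np.where(spikes, rng.uniform(0.6, 1.2, size=n_frames), 0.0)
    trans[:, 0] += jump
    return np.column_stack([trans, rots])


def _smooth_series(n_frames: int, rng: np.random.Generator, window: int = 10) -> np.ndarray:
    raw = rng.normal(size=n_frames + window)
    kernel = np.ones(window) / window
    out = np.convolve(raw, kernel, mode="valid")[:n_frames]
    return (out - out.mean()) / (out.std() or 1.0)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort (time series, motion, nuisance, covariates).

    For subject s with latent score g_s, each implanted edge e targets
    clip(base_correlation + effect_beta * g_s + eps_e, +/-0.95) with
    eps_e ~ N(0, edge_noise_sd); non-implanted edges carry the shared
    modular background. Each subject's target matrix is PSD-projected
    before frames are sampled as zero-mean correlated Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    n_sub, n, frames = config.n_subjects, config.n_nodes, config.n_frames

    g = rng.normal(size=n_sub)
    g = (g - g.mean()) / g.std()

    background = _module_background(config, rng)
    impl = config.implanted_edges
    clip_count = 0

    targets = np.empty((n_sub, n, n))
    series = np.empty((n_sub, frames, n))
    motion = np.empty((n_sub, frames, 6))
    nuisance = np.empty((n_sub, frames, 2))
    mean_fds = np.empty(n_sub)

    for s in range(n_sub):
        target = background.copy()
        if impl:
            eps = rng.normal(0.0, config.edge_noise_sd, size=len(impl))
            raw = config.base_correlation + config.effect_beta * g[s] + eps
            clip_count += int(np.sum(np.abs(raw) >= 1.0))
            vals = np.clip(raw, -_CLIP, _CLIP)
            for (i, j), v in zip(impl, vals):
                target[i, j] = target[j, i] = v
        repaired = nearest_correlation(target)
        targets[s] = repaired
        chol = np.linalg.cholesky(repaired + 1e-10 * np.eye(n))
        series[s] = rng.normal(size=(frames, n)) @ chol.T
        motion[s] = _motion_trace(frames, config.motion_spike_rate, rng)
        nuisance[s] = np.column_stack(
            [_smooth_series(frames, rng), _smooth_series(frames, rng)]
        )
        diffs = np.abs(np.diff(motion[s], axis=0))
        fd = diffs[:, :3].sum(axis=1) + 50.0 * diffs[:, 3:].sum(axis=1)
        mean_fds[s] = np.concatenate([[0.0], fd]).mean()

    if clip_count:
        warnings.warn(
            f"{clip_count} implanted-edge target(s) exceeded |r| >= 1 before clipping",
            stacklevel=2,
        )

    records = pd.DataFrame(
        {
            "id": [f"s{k:03d}" for k in range(n_sub)],
            "age": np.clip(rng.normal(26.6, 7.5, size=n_sub), 18, 60).round(1),
            "sex": rng.binomial(1, 33 / 60, size=n_sub),
            "mean_fd": mean_fds,
            "skill_learning": g,
        }
    )
    return SyntheticCohort(
        config=config,
        timeseries=series,
        motion=motion,
        nuisance=nuisance,
        records=records,
        latent_skill=g,
        target_matrices=targets,
        implanted_edges=impl,
        effect_beta=config.effect_beta,
        clip_warnings=clip_count,
    )


@dataclass(frozen=True)
class SyntheticBehavior:
    """Behavioral record plus the trial- and gate-level tables it came from."""

    record: BehavioralRecord
    trials: pd.DataFrame  # block, trial, duration_s
    gates: pd.DataFrame  # block, gate_index, miss


def generate_behavior(
    n_blocks: int = 4,
    n_trials: int = 35,
    n_gates: int = 5,
    start_duration: float = 20.0,
    learning_rate: float = 0.1,
    start_error: float = 0.25,
    seed: int = 0,
) -> SyntheticBehavior:
    """Block-structured behavioral improvement.

    Block b (0-based) draws trial durations around a geometrically
    decreasing mean start_duration * (1 - learning_rate)^b and per-gate
    misses as Bernoulli with probability start_error * (1 - learning_rate)^b.
    """
    if start_duration <= 1.0:
        raise ValueError("start_duration must exceed 1 s")
    if not 0.0 < start_error < 1.0:
        raise ValueError("start_error must lie in (0, 1)")
    if not 0.0 <= learning_rate < 1.0:
        raise ValueError("learning_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    blocks: list[BlockSummary] = []
    trial_rows, gate_rows = [], []
    for b in range(n_blocks):
        decay = (1.0 - learning_rate) ** b
        mean_dur = start_duration * decay
        durations = np.maximum(rng.normal(mean_dur, 0.05 * mean_dur, size=n_trials), 1.01)
        miss_p = min(start_error * decay, 1.0)
        misses = rng.binomial(1, miss_p, size=n_trials * n_gates)
        for t, d in enumerate(durations):
            trial_rows.append({"block": b + 1, "trial": t + 1, "duration_s": float(d)})
        for gidx, miss in enumerate(misses):
            gate_rows.append({"block": b + 1, "gate_index": gidx + 1, "miss": int(miss)})
        blocks.append(
            BlockSummary(
                mean_duration=float(durations.mean()),
                error_rate=error_rate_from_gates(misses),
                n_trials=n_trials,
                n_gates_per_trial=n_gates,
            )
        )
    return SyntheticBehavior(
        record=BehavioralRecord(blocks=tuple(blocks)),
        trials=pd.DataFrame(trial_rows),
        gates=pd.DataFrame(gate_rows),
    )


def generate_retest_pair(
    n_subjects: int,
    icc_target: float,
    edge_set=None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two session-level mean-connectivity vectors with a target ICC.

    Each subject's value is latent + session noise with the between/total
    variance ratio set to ``icc_target``; values are placed on a plausible
    mean-connectivity scale (0.3 +/- 0.1). ``edge_set`` is carried for
    provenance only; it does not change the construction.
    """
    if not 0.0 <= icc_target < 1.0:
        raise ValueError("icc_target must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    latent = rng.normal(0.0, np.sqrt(icc_target), size=n_subjects)
    noise_sd = np.sqrt(1.0 - icc_target)
    s1 = 0.3 + 0.1 * (latent + rng.normal(0.0, noise_sd, size=n_subjects))
    s2 = 0.3 + 0.1 * (latent + rng.normal(0.0, noise_sd, size=n_subjects))
    return s1, s2


def generate_drug_pair(
    cohort: SyntheticCohort,
    decrement_per_unit: float,
    dose_levels: np.ndarray,
    seed: int = 0,
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Paired placebo/drug session cohorts.

    The drug session's implanted-edge target correlations are reduced by
    ``decrement_per_unit * dose_s``; both sessions are regenerated with
    independent sampling noise. Records gain condition, order, and dose
    columns. A zero-variance dose vector is flagged with a warning since the
    dose-connectivity correlation is then undefined.
    """
    dose = np.asarray(dose_levels, dtype=float)
    if dose.shape != (cohort.config.n_subjects,):
        raise ValueError("dose_levels must have one entry per subject")
    if dose.std() == 0:
        warnings.warn("dose_levels has zero variance; dose-connectivity correlation undefined", stacklevel=2)
    cfg = cohort.config
    rng = np.random.default_rng(seed)
    order = rng.binomial(1, 0.5, size=cfg.n_subjects)

    def _session(decrements: np.ndarray, session_seed: int, condition: str) -> SyntheticCohort:
        srng = np.random.default_rng(session_seed)
        n, frames = cfg.n_nodes, cfg.n_frames
        series = np.empty((cfg.n_subjects, frames, n))
        targets = np.empty((cfg.n_subjects, n, n))
        clip_count = 0
        for s in range(cfg.n_subjects):
            target = cohort.target_matrices[s].copy()
            if decrements[s]:
                for i, j in cohort.implanted_edges:
                    raw = target[i, j] - decrements[s]
                    clip_count += int(abs(raw) >= 1.0)
                    target[i, j] = target[j, i] = np.clip(raw, -_CLIP, _CLIP)
                target = nearest_correlation(target)
            targets[s] = target
            chol = np.linalg.cholesky(target + 1e-10 * np.eye(n))
            series[s] = srng.normal(size=(frames, n)) @ chol.T
        records = cohort.records.copy()
        records["condition"] = condition
        records["order"] = order
        records["dose"] = dose if condition == "drug" else 0.0
        return SyntheticCohort(
            config=cfg,
            timeseries=series,
            motion=cohort.motion,
            nuisance=cohort.nuisance,
            records=records,
            latent_skill=cohort.latent_skill,
            target_matrices=targets,
            implanted_edges=cohort.implanted_edges,
            effect_beta=cfg.effect_beta,
            clip_warnings=clip_count,
        )

    placebo = _session(np.zeros(cfg.n_subjects), int(rng.integers(0, 2**31 - 1)), "placebo")
    drug = _session(decrement_per_unit * dose, int(rng.integers(0, 2**31 - 1)), "drug")
    return placebo, drug
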