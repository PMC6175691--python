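"""Configuration, file I/O, and orchestration of the three experiments:
skill-learning association, test-retest reliability, and the drug-challenge
contrast.

A cohort on disk is a directory with ``subjects.tsv``, a ``timeseries/``,
``motion/`` and ``nuisance/`` folder holding one delimited-text file per
subject, and a ``ground_truth.json`` sidecar when the cohort is synthetic.
Every run echoes its effective configuration (with a content hash and the
seed) to a JSON sidecar so any stage can be reproduced bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import connectome, nbs, preprocess, stats
from .synthetic import SyntheticCohort

__all__ = [
    "PipelineConfig",
    "AssociationResult",
    "stage_seed",
    "write_cohort",
    "read_cohort",
    "subject_matrices",
    "association_analysis",
    "run_association",
    "run_reliability",
    "run_drug_contrast",
]

log = logging.getLogger("connlearn")

ASSOCIATION_METRICS = (
    "transitivity",
    "char_path_length",
    "global_efficiency",
    "small_worldness",
    "modularity_q",
    "assortativity",
    "mean_connectivity",
)


class PreprocessSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    band_low: float = 0.01
    band_high: float = 0.1
    fd_radius: float = 50.0
    scrub_threshold: float = 0.5
    exclusion_fraction: float = 0.10
    scrub: bool = False

    def to_config(self) -> preprocess.PreprocessConfig:
        return preprocess.PreprocessConfig(
            band_low=self.band_low,
            band_high=self.band_high,
            fd_radius=self.fd_radius,
            scrub_threshold=self.scrub_threshold,
            exclusion_fraction=self.exclusion_fraction,
        )


class NBSSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_threshold: float = 5e-4
    t_threshold: float | None = None
    tail: str = "positive"
    n_permutations: int = 5000
    edge_transform: str = "fisher-z"

    def to_config(self, seed: int | None) -> nbs.NBSConfig:
        return nbs.NBSConfig(
            p_threshold=self.p_threshold,
            t_threshold=self.t_threshold,
            tail=self.tail,
            n_permutations=self.n_permutations,
            seed=seed,
            edge_transform=self.edge_transform,
        )


class PipelineConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    input_dir: str = "."
    output_dir: str = "results"
    repetition_time: float = 2.0
    covariates: list[str] = Field(default_factory=lambda: ["age", "sex", "mean_fd"])
    densities: list[float] | None = None  # None -> the 1%..40% grid
    n_random_refs: int = 20
    n_modularity_restarts: int = 4
    preprocessing: PreprocessSettings = Field(default_factory=PreprocessSettings)
    network_stats: NBSSettings = Field(default_factory=NBSSettings)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def content_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def density_grid(self) -> np.ndarray:
        if self.densities is None:
            return connectome.default_density_grid()
        return np.asarray(self.densities, dtype=float)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31 - 1)


def _write_sidecar(out_dir: Path, config: PipelineConfig, stage: str) -> None:
    payload = {"stage": stage, "config_hash": config.content_hash(), "seed": config.seed,
               "config": config.model_dump()}
    (out_dir / f"{stage}_config.json").write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Cohort file I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> Path:
    """Write a cohort as delimited text plus a ground-truth JSON sidecar."""
    root = Path(directory)
    for sub in ("timeseries", "motion", "nuisance"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    labels = [f"n{k:03d}" for k in range(cohort.config.n_nodes)]
    for s, sid in enumerate(cohort.records["id"]):
        pd.DataFrame(cohort.timeseries[s], columns=labels).to_csv(
            root / "timeseries" / f"{sid}.tsv", sep="\t", index=False, float_format="%.6f"
        )
        pd.DataFrame(
            cohort.motion[s], columns=["tx", "ty", "tz", "rx", "ry", "rz"]
        ).to_csv(root / "motion" / f"{sid}.tsv", sep="\t", index=False, float_format="%.6f")
        pd.DataFrame(cohort.nuisance[s], columns=["wm", "csf"]).to_csv(
            root / "nuisance" / f"{sid}.tsv", sep="\t", index=False, float_format="%.6f"
        )
    cohort.records.to_csv(root / "subjects.tsv", sep="\t", index=False)
    (root / "ground_truth.json").write_text(
        json.dumps(
            {
                "implanted_edges": [list(e) for e in cohort.implanted_edges],
                "effect_beta": cohort.effect_beta,
                "seed": cohort.config.seed,
            },
            indent=2,
        )
    )
    return root


@dataclass
class CohortFiles:
    records: pd.DataFrame
    timeseries: np.ndarray
    motion: np.ndarray
    nuisance: np.ndarray
    ground_truth: dict | None


def read_cohort(directory: str | Path) -> CohortFiles:
    root = Path(directory)
    records = pd.read_csv(root / "subjects.tsv", sep="\t")
    ts, mo, nu = [], [], []
    for sid in records["id"]:
        ts.append(pd.read_csv(root / "timeseries" / f"{sid}.tsv", sep="\t").to_numpy())
        mo.append(pd.read_csv(root / "motion" / f"{sid}.tsv", sep="\t").to_numpy())
        nu.append(pd.read_csv(root / "nuisance" / f"{sid}.tsv", sep="\t").to_numpy())
    gt_path = root / "ground_truth.json"
    gt = json.loads(gt_path.read_text()) if gt_path.exists() else None
    return CohortFiles(
        records=records,
        timeseries=np.stack(ts),
        motion=np.stack(mo),
        nuisance=np.stack(nu),
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# Analysis cores (in-memory)
# ---------------------------------------------------------------------------

def subject_matrices(
    timeseries: np.ndarray,
    motion: np.ndarray,
    nuisance: np.ndarray | None,
    tr: float,
    settings: PreprocessSettings | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess every subject and return (matrix stack, mean FD vector).

    Nuisance regression (motion + WM/CSF-like series) then band-pass, then
    Pearson correlation; with ``settings.scrub`` enabled, high-motion frames
    are deleted before the correlation step instead of FD entering as a
    covariate downstream.
    """
    settings = settings or PreprocessSettings()
    cfg = settings.to_config()
    n_sub = timeseries.shape[0]
    mats, fds = [], []
    for s in range(n_sub):
        nuis = None if nuisance is None else nuisance[s]
        filtered, mean_fd = preprocess.preprocess_timeseries(
            timeseries[s], motion[s], nuis, tr, cfg
        )
        if settings.scrub:
            fd, _ = preprocess.framewise_displacement(motion[s], cfg.fd_radius)
            filtered, _, excluded = preprocess.scrub(
                filtered, fd, cfg.scrub_threshold, cfg.exclusion_fraction
            )
            if excluded:
                log.warning("subject %d exceeds the spike-fraction rule", s)
        mats.append(connectome.correlation_matrix(filtered).values)
        fds.append(mean_fd)
    return np.stack(mats), np.asarray(fds)


@dataclass
class AssociationResult:
    metrics: pd.DataFrame  # one row per subject, one column per diagnostic
    association: pd.DataFrame  # metric, beta, t, df, r, p_raw, p_hochberg
    nbs_result: nbs.NBSResult


def association_analysis(
    matrices: np.ndarray,
    records: pd.DataFrame,
    covariates: list[str],
    densities: np.ndarray,
    nbs_config: nbs.NBSConfig,
    n_random_refs: int = 20,
    n_modularity_restarts: int = 4,
    seed: int = 0,
) -> AssociationResult:
    """Graph-diagnostic association plus the network-based statistic.

    Each subject's density-averaged diagnostics are regressed on the
    skill-learning score with the covariates of non-interest; the family of
    raw p-values is Hochberg-adjusted. The NBS runs on the same matrices and
    design.
    """
    rows = []
    for s in range(matrices.shape[0]):
        cm = connectome.ConnectivityMatrix(values=matrices[s])
        ms = connectome.metrics_over_densities(
            cm,
            densities=densities,
            n_random=n_random_refs,
            n_restarts=n_modularity_restarts,
            seed=stage_seed(seed, f"metrics:{s}"),
        )
        row = {k: ms.averaged[k] for k in ms.averaged}
        row["mean_connectivity"] = ms.mean_connectivity
        rows.append(row)
    metrics = pd.DataFrame(rows)

    assoc_rows = []
    for metric in ASSOCIATION_METRICS:
        fit = stats.fit_linear_model(
            metrics[metric].to_numpy(), records, "skill_learning", covariates
        )
        assoc_rows.append(
            {
                "metric": metric,
                "beta": float(fit.coefficients["skill_learning"]),
                "t": fit.t,
                "df": fit.df,
                "r": fit.partial_r,
                "p_raw": fit.p,
            }
        )
    association = pd.DataFrame(assoc_rows)
    association["p_hochberg"] = stats.hochberg_adjust(association["p_raw"].to_numpy())

    result = nbs.nbs_test(
        matrices, records, "skill_learning", covariates, nbs_config
    )
    return AssociationResult(metrics=metrics, association=association, nbs_result=result)


# ---------------------------------------------------------------------------
# File-level experiment runners
# ---------------------------------------------------------------------------

def run_association(config: PipelineConfig) -> AssociationResult:
    """End-to-end association experiment from a cohort directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(config.input_dir)
    matrices, mean_fd = subject_matrices(
        cohort.timeseries, cohort.motion, cohort.nuisance,
        config.repetition_time, config.preprocessing,
    )
    records = cohort.records.copy()
    records["mean_fd"] = mean_fd
    covariates = list(config.covariates)
    if config.preprocessing.scrub and "mean_fd" in covariates:
        covariates.remove("mean_fd")  # scrubbing replaces FD-as-covariate
    result = association_analysis(
        matrices,
        records,
        covariates,
        config.density_grid(),
        config.network_stats.to_config(stage_seed(config.seed, "nbs")),
        n_random_refs=config.n_random_refs,
        n_modularity_restarts=config.n_modularity_restarts,
        seed=config.seed,
    )
    result.metrics.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.8f")
    result.association.to_csv(out / "association.tsv", sep="\t", index=False, float_format="%.8f")
    _write_nbs(result.nbs_result, out)
    _write_sidecar(out, config, "association")
    log.info(
        "association: %d subjects, %d suprathreshold components",
        matrices.shape[0], len(result.nbs_result.components),
    )
    return result


def _write_nbs(result: nbs.NBSResult, out: Path) -> None:
    comp_rows = []
    for ci, comp in enumerate(result.components):
        for i, j in comp.edges:
            comp_rows.append(
                {"component": ci, "node_i": i, "node_j": j, "t": result.t_matrix[i, j]}
            )
    pd.DataFrame(comp_rows, columns=["component", "node_i", "node_j", "t"]).to_csv(
        out / "nbs_components.tsv", sep="\t", index=False, float_format="%.6f"
    )
    summary = {
        "t_threshold": result.t_threshold,
        "df": result.df,
        "n_permutations": result.n_permutations,
        "seed": result.seed,
        "components": [
            {"size": c.size, "n_nodes": len(c.nodes), "fwe_p": c.fwe_p}
            for c in result.components
        ],
    }
    (out / "nbs_summary.json").write_text(json.dumps(summary, indent=2))


def _session_subnetwork_means(directory: str | Path, edges, config: PipelineConfig) -> tuple[pd.DataFrame, np.ndarray]:
    cohort = read_cohort(directory)
    matrices, _ = subject_matrices(
        cohort.timeseries, cohort.motion, cohort.nuisance,
        config.repetition_time, config.preprocessing,
    )
    means = np.array(
        [nbs.subnetwork_mean(connectome.ConnectivityMatrix(values=m), edges) for m in matrices]
    )
    return cohort.records, means


def run_reliability(
    config: PipelineConfig,
    session_dirs: tuple[str | Path, str | Path],
    edges,
) -> stats.ICCResult:
    """Test-retest reliability of the subnetwork mean connectivity."""
    rec1, means1 = _session_subnetwork_means(session_dirs[0], edges, config)
    rec2, means2 = _session_subnetwork_means(session_dirs[1], edges, config)
    if not rec1["id"].equals(rec2["id"]):
        raise ValueError("subject alignment differs across sessions")
    result = stats.icc(np.column_stack([means1, means2]))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "reliability.json").write_text(
        json.dumps(
            {
                "icc_2_1": result.icc_2_1,
                "icc_3_1": result.icc_3_1,
                "label": result.label,
                "n_subjects": len(means1),
                "n_edges": len(list(edges)),
            },
            indent=2,
        )
    )
    _write_sidecar(out, config, "reliability")
    return result


def run_drug_contrast(
    config: PipelineConfig,
    session_dirs: tuple[str | Path, str | Path],
    edges,
    contrast_covariates: list[str] = ("age", "sex", "order"),
    dose_covariates: list[str] = ("age", "sex", "mean_fd"),
) -> dict:
    """Placebo/drug condition contrast on the subnetwork mean connectivity,
    plus the dose (norketamine) partial correlation in the drug session."""
    rec_a, means_a = _session_subnetwork_means(session_dirs[0], edges, config)
    rec_b, means_b = _session_subnetwork_means(session_dirs[1], edges, config)
    if not rec_a["id"].equals(rec_b["id"]):
        raise ValueError("subject pairing differs across conditions")
    contrast = stats.paired_condition_contrast(
        means_a, means_b, rec_b[list(contrast_covariates)].astype(float)
    )
    dose = rec_b["dose"].to_numpy(dtype=float)
    if dose.std() > 0:
        r, t, p, df = stats.partial_correlation(
            dose, means_b, rec_b[list(dose_covariates)].astype(float)
        )
        dose_part = {"r": r, "t": t, "p": p, "df": df}
    else:
        dose_part = None
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "contrast": {
            "F": contrast.f,
            "p": contrast.p,
            "df": contrast.df,
            "mean_difference": contrast.mean_difference,
            "degenerate": contrast.degenerate,
        },
        "dose_partial_correlation": dose_part,
    }
    (out / "drug_contrast.json").write_text(json.dumps(payload, indent=2))
    _write_sidecar(out, config, "drug_contrast")
    return payload
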