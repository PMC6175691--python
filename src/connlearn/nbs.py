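"""Network-based statistics: edge-wise GLM, suprathreshold component
extraction, and permutation-based family-wise error control.

For every node pair, the (Fisher-z transformed) connectivity value is
regressed on an intercept, the variable of interest, and covariates of
non-interest; links whose t statistic exceeds a primary threshold (by
default the one-sided Student-t quantile at p = 5e-4) are kept, and the
connected components of the surviving links form the candidate subnetworks.
Their family-wise error corrected p-values come from the permutation null
distribution of the maximum component size (edge count), built with
Freedman-Lane residual permutation under the reduced model so that the
covariates are respected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectome import ConnectivityMatrix

__all__ = [
    "NBSConfig",
    "NBSComponent",
    "NBSResult",
    "edge_statistics",
    "critical_t",
    "suprathreshold_components",
    "nbs_test",
    "subnetwork_mean",
]

_FISHER_CLIP = 0.999999


@dataclass(frozen=True)
class NBSConfig:
    """Settings of the network-based statistic.

    p_threshold : one-sided tail probability of the primary edge threshold.
    t_threshold : explicit threshold overriding ``p_threshold`` when set.
    tail : "positive" (default), "negative", or "two-sided".
    n_permutations : size of the permutation null (M).
    edge_transform : "fisher-z" (default) or "raw-r".
    """

    p_threshold: float = 5e-4
    t_threshold: float | None = None
    tail: str = "positive"
    n_permutations: int = 5000
    seed: int | None = None
    edge_transform: str = "fisher-z"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 0.5:
            raise ValueError("p_threshold must lie in (0, 0.5)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.tail not in ("positive", "negative", "two-sided"):
            raise ValueError(f"unknown tail {self.tail!r}")
        if self.edge_transform not in ("fisher-z", "raw-r"):
            raise ValueError(f"unknown edge_transform {self.edge_transform!r}")


@dataclass(frozen=True)
class NBSComponent:
    edges: tuple[tuple[int, int], ...]
    nodes: tuple[int, ...]
    size: int  # edge count (extent)
    fwe_p: float | None = None


@dataclass(frozen=True)
class NBSResult:
    t_matrix: np.ndarray
    t_threshold: float
    components: tuple[NBSComponent, ...]
    null_max_size: np.ndarray
    seed: int | None
    n_permutations: int
    df: int
    perfect_fit_edges: int = 0


def critical_t(p_threshold: float, df: int, tail: str = "positive") -> float:
    """Student-t quantile of the primary threshold (upper tail; halved per
    side when two-sided)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    p = p_threshold / 2.0 if tail == "two-sided" else p_threshold
    return float(sps.t.isf(p, df))


def _stack_to_edge_matrix(matrices: np.ndarray, transform: str) -> tuple[np.ndarray, int]:
    """(subjects, nodes, nodes) stack -> (subjects, n_edges) upper-triangle
    values, Fisher-z transformed if requested. Returns the clip count."""
    stack = np.asarray(matrices, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("matrices must be a (subjects, nodes, nodes) stack")
    n = stack.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    Y = stack[:, iu, ju]
    clipped = 0
    if transform == "fisher-z":
        over = np.abs(Y) >= 1.0
        clipped = int(over.sum())
        Y = np.arctanh(np.clip(Y, -_FISHER_CLIP, _FISHER_CLIP))
    return Y, clipped


def _design(records: pd.DataFrame, interest: str, covariates) -> np.ndarray:
    cols = [interest, *covariates]
    if records[cols].isna().any().any():
        raise ValueError("missing values in design variables")
    X = np.column_stack([np.ones(len(records)), records[cols].to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    return X


def _edge_t(X: np.ndarray, Y: np.ndarray, j: int) -> np.ndarray:
    """t statistic of coefficient ``j`` for every column of Y (vectorized OLS)."""
    n, p = X.shape
    df = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    beta = pinv @ Y
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df * xtx_inv[j, j])
        t = beta[j] / se
    t[np.isnan(t)] = 0.0
    scale = np.maximum(np.einsum("ij,ij->j", Y, Y), 1.0)
    perfect = rss <= 1e-12 * scale
    if perfect.any():
        b = beta[j][perfect]
        t[perfect] = np.where(b > 0, np.inf, np.where(b < 0, -np.inf, 0.0))
    return t

def edge_statistics(
    matrices: np.ndarray,
    records: pd.DataFrame,
    interest: str,
    covariates: tuple[str, ...] | list[str] = (),
    transform: str = "fisher-z",
) -> np.ndarray:
    """Symmetric matrix of edge-wise t statistics for the interest variable.

    One OLS per upper-triangle node pair (n(n-1)/2 regressions), diagonal
    zero. Edge values at |r| = 1 are clipped before the Fisher transform.
    """
    Y, _ = _stack_to_edge_matrix(matrices, transform)
    X = _design(records, interest, covariates)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("subject count mismatch between matrices and records")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("too few subjects for the design")
    t = _edge_t(X, Y, j=1)
    n = matrices.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    tm = np.zeros((n, n))
    tm[iu, ju] = t
    tm[ju, iu] = t
    return tm


def _component_list(mask_upper: np.ndarray, n: int, iu: np.ndarray, ju: np.ndarray) -> list[tuple[tuple, tuple, int]]:
    sel = np.flatnonzero(mask_upper)
    if sel.size == 0:
        return []
    ei, ej = iu[sel], ju[sel]
    adj = csr_matrix((np.ones(sel.size), (ei, ej)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    comps: dict[int, list[tuple[int, int]]] = {}
    for i, j in zip(ei, ej):
        comps.setdefault(labels[i], []).append((int(i), int(j)))
    out = []
    for edges in comps.values():
        edges = sorted(edges)
        nodes = tuple(sorted({u for e in edges for u in e}))
        out.append((tuple(edges), nodes, len(edges)))
    out.sort(key=lambda c: (-c[2], c[1][0]))
    return out


def suprathreshold_components(
    t_matrix: np.ndarray, t_threshold: float, tail: str = "positive"
) -> list[NBSComponent]:
    """Connected components of the graph of suprathreshold links, sorted by
    descending edge count (ties by smallest member node index)."""
    t_matrix = np.asarray(t_matrix, dtype=float)
    n = t_matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = t_matrix[iu, ju]
    if tail == "positive":
        mask = vals > t_threshold
    elif tail == "negative":
        mask = vals < -t_threshold
    else:
        mask = np.abs(vals) > t_threshold
    return [
        NBSComponent(edges=e, nodes=nd, size=s)
        for e, nd, s in _component_list(mask, n, iu, ju)
    ]


def _max_component_size(t_vals: np.ndarray, thr: float, tail: str, n: int, iu, ju) -> int:
    if tail == "positive":
        mask = t_vals > thr
    elif tail == "negative":
        mask = t_vals < -thr
    else:
        mask = np.abs(t_vals) > thr
    comps = _component_list(mask, n, iu, ju)
    return comps[0][2] if comps else 0


def nbs_test(
    matrices: np.ndarray,
    records: pd.DataFrame,
    interest: str,
    covariates: tuple[str, ...] | list[str] = (),
    config: NBSConfig | None = None,
) -> NBSResult:
    """Full network-based statistic with Freedman-Lane permutation FWE.

    The null distribution of the maximum component size is built by fitting
    the reduced model (intercept + covariates), permuting its residuals,
    adding back the reduced fit, and recomputing all edge statistics and the
    largest surviving component for each of M permutations. Each observed
    component's FWE p-value is (1 + #{null max >= size}) / (1 + M).
    """
    config = config or NBSConfig()
    Y, clipped = _stack_to_edge_matrix(matrices, config.edge_transform)
    X = _design(records, interest, covariates)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("subject count mismatch between matrices and records")
    n_sub, p = X.shape
    df = n_sub - p
    if df < 2:
        raise ValueError("not enough residual degrees of freedom")
    thr = config.t_threshold if config.t_threshold is not None else critical_t(
        config.p_threshold, df, config.tail
    )

    n = matrices.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    t_obs = _edge_t(X, Y, j=1)
    observed = [
        NBSComponent(edges=e, nodes=nd, size=s)
        for e, nd, s in _component_list(_tail_mask(t_obs, thr, config.tail), n, iu, ju)
    ]

    # Freedman-Lane: reduced model = everything but the interest column
    Z = np.delete(X, 1, axis=1)
    beta_z, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    fitted = Z @ beta_z
    resid = Y - fitted
    rng = np.random.default_rng(config.seed)
    null_max = np.empty(config.n_permutations, dtype=int)
    for m in range(config.n_permutations):
        perm = rng.permutation(n_sub)
        t_perm = _edge_t(X, fitted + resid[perm], j=1)
        null_max[m] = _max_component_size(t_perm, thr, config.tail, n, iu, ju)

    M = config.n_permutations
    components = tuple(
        NBSComponent(
            edges=c.edges,
            nodes=c.nodes,
            size=c.size,
            fwe_p=float((1 + int((null_max >= c.size).sum())) / (1 + M)),
        )
        for c in observed
    )
    tm = np.zeros((n, n))
    tm[iu, ju] = t_obs
    tm[ju, iu] = t_obs
    return NBSResult(
        t_matrix=tm,
        t_threshold=float(thr),
        components=components,
        null_max_size=null_max,
        seed=config.seed,
        n_permutations=M,
        df=df,
        perfect_fit_edges=int(np.isinf(t_obs).sum()),
    )


def _tail_mask(t_vals: np.ndarray, thr: float, tail: str) -> np.ndarray:
    if tail == "positive":
        return t_vals > thr
    if tail == "negative":
        return t_vals < -thr
    return np.abs(t_vals) > thr


def subnetwork_mean(cm: ConnectivityMatrix, edges) -> float:
    """Arithmetic mean of raw r over the listed edges."""
    edges = list(edges)
    if not edges:
        raise ValueError("empty edge list")
    n = cm.n_nodes
    vals = []
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise ValueError(f"edge ({i}, {j}) out of range for {n} nodes")
        vals.append(cm.values[i, j])
    return float(np.mean(vals))
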