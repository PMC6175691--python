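"""Connectivity matrices, density-thresholded binary graphs, and the seven
global graph diagnostics.

A subject's connectome is the node-by-node matrix of Pearson correlations
between preprocessed regional time series (diagonal excluded). Binary graphs
are built by proportional thresholding: at density d, the k = round(d * E)
largest *positive* correlations become edges, E = n(n-1)/2. Graph metrics are
computed per density over a 1%-40% grid and averaged; mean connectivity is
taken once from the unthresholded matrix.

Metric conventions: transitivity is the global triangle/triple ratio;
characteristic path length averages shortest paths over reachable pairs only;
global efficiency averages inverse distances with 1/inf = 0; small-worldness
sigma = gamma / lambda against degree-preserving rewired references, where
gamma uses the mean local clustering coefficient; modularity Q is Newman's
quality of the best partition found by a seeded Louvain-style optimizer with
local-move refinement; assortativity is the Pearson correlation of endpoint
degrees over edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "ConnectivityMatrix",
    "BinaryGraphEnsemble",
    "GraphMetricSet",
    "DegenerateGraphError",
    "DensityShortfallError",
    "default_density_grid",
    "n_candidate_edges",
    "edge_count_at_density",
    "correlation_matrix",
    "binarize_at_density",
    "build_ensemble",
    "transitivity",
    "characteristic_path_length",
    "global_efficiency",
    "small_worldness",
    "modularity_q",
    "assortativity",
    "mean_connectivity",
    "metrics_over_densities",
]

METRIC_NAMES = (
    "transitivity",
    "char_path_length",
    "global_efficiency",
    "small_worldness",
    "gamma",
    "lambda",
    "modularity_q",
    "assortativity",
)


class DegenerateGraphError(ValueError):
    """A metric is undefined on this graph (e.g. assortativity on a regular
    graph, where endpoint degrees have zero variance)."""


class DensityShortfallError(ValueError):
    """Fewer positive correlations than edges requested at a density."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with a zeroed diagonal."""

    values: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"expected a square matrix, got shape {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix is not symmetric to 1e-12")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (np.nanmax(np.abs(off)) > 1.0 + 1e-12):
            raise ValueError("correlation values must lie in [-1, 1]")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", v)
        if self.labels is not None:
            if len(self.labels) != v.shape[0]:
                raise ValueError("label count does not match node count")
            object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def default_density_grid() -> np.ndarray:
    """Densities 1%..40% in 1% steps."""
    return np.arange(1, 41) / 100.0


def n_candidate_edges(n_nodes: int) -> int:
    """Number of node pairs n(n-1)/2 — the candidate links of a connectome."""
    return n_nodes * (n_nodes - 1) // 2


def edge_count_at_density(density: float, n_nodes: int) -> int:
    """k = round(density * E_total), rounding half away from zero."""
    return int(math.floor(density * n_candidate_edges(n_nodes) + 0.5))


def correlation_matrix(ts: np.ndarray, labels: tuple[str, ...] | None = None) -> ConnectivityMatrix:
    """Pairwise Pearson correlations between node time series (frames x nodes)."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be 2-D (frames x nodes)")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 frames for a correlation matrix")
    variances = ts.var(axis=0)
    dead = np.flatnonzero(variances == 0)
    if dead.size:
        names = [labels[i] for i in dead] if labels else dead.tolist()
        raise ValueError(f"zero-variance node(s): {names}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(values=r, labels=labels)


def _ranked_positive_edges(cm: ConnectivityMatrix) -> list[tuple[float, int, int]]:
    iu, ju = np.triu_indices(cm.n_nodes, k=1)
    r = cm.values[iu, ju]
    pos = r > 0
    order = sorted(zip(-r[pos], iu[pos], ju[pos]))  # descending r, ties by (i, j)
    return [(-nr, int(i), int(j)) for nr, i, j in order]


def binarize_at_density(cm: ConnectivityMatrix, density: float) -> nx.Graph:
    """Binary graph keeping the k strongest positive correlations.

    Deterministic: ties in r are broken by ascending node-index pair.
    Negative correlations never become edges.
    """
    if not 0.0 < density <= 0.40:
        raise ValueError(f"density must lie in (0, 0.40], got {density}")
    k = edge_count_at_density(density, cm.n_nodes)
    ranked = _ranked_positive_edges(cm)
    if len(ranked) < k:
        raise DensityShortfallError(
            f"density {density:.2%} needs {k} edges but only {len(ranked)} positive correlations exist"
        )
    g = nx.Graph()
    g.add_nodes_from(range(cm.n_nodes))
    for r, i, j in ranked[:k]:
        g.add_edge(i, j, weight=float(r))
    return g


@dataclass(frozen=True)
class BinaryGraphEnsemble:
    """Density-indexed binary graphs, nested by construction."""

    densities: tuple[float, ...]
    graphs: tuple[nx.Graph, ...]

    def __post_init__(self) -> None:
        if len(self.densities) != len(self.graphs):
            raise ValueError("densities and graphs length mismatch")


def build_ensemble(cm: ConnectivityMatrix, densities: np.ndarray | None = None) -> BinaryGraphEnsemble:
    densities = default_density_grid() if densities is None else np.asarray(densities, dtype=float)
    graphs = tuple(binarize_at_density(cm, d) for d in densities)
    return BinaryGraphEnsemble(densities=tuple(float(d) for d in densities), graphs=graphs)


# ---------------------------------------------------------------------------
# Global metrics
# ---------------------------------------------------------------------------

def transitivity(g: nx.Graph) -> float:
    """Global triangle ratio: 3 * triangles / connected triples (0 if none)."""
    return float(nx.transitivity(g))


def _distance_matrix(g: nx.Graph) -> np.ndarray:
    n = g.number_of_nodes()
    if g.number_of_edges() == 0:
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    adj = nx.to_scipy_sparse_array(g, nodelist=sorted(g.nodes()), format="csr")
    return shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)


def characteristic_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length over reachable ordered pairs."""
    if g.number_of_edges() == 0:
        raise ValueError("characteristic path length is undefined on an edgeless graph")
    d = _distance_matrix(g)
    mask = np.isfinite(d) & ~np.eye(d.shape[0], dtype=bool)
    return float(d[mask].mean())


def global_efficiency(g: nx.Graph) -> float:
    """Mean inverse shortest-path length over all ordered pairs (1/inf = 0)."""
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    d = _distance_matrix(g)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def _rewire(g: nx.Graph, rng: np.random.Generator, n_attempts: int) -> nx.Graph:
    """Degree-preserving double edge swaps; ``n_attempts`` swaps are attempted,
    unswappable proposals (self-loops / existing edges) are skipped."""
    h = g.copy()
    edges = list(h.edges())
    m = len(edges)
    if m < 2:
        raise ValueError("graph too sparse to rewire")
    for _ in range(n_attempts):
        a_idx, b_idx = rng.integers(0, m, size=2)
        if a_idx == b_idx:
            continue
        (u, v), (x, y) = edges[a_idx], edges[b_idx]
        if rng.random() < 0.5:
            x, y = y, x
        # propose u-x, v-y
        if u == x or v == y:
            continue
        if h.has_edge(u, x) or h.has_edge(v, y):
            continue
        h.remove_edge(u, v)
        h.remove_edge(x, y)
        h.add_edge(u, x)
        h.add_edge(v, y)
        edges[a_idx] = (u, x)
        edges[b_idx] = (v, y)
    return h


def small_worldness(
    g: nx.Graph, n_random: int = 20, seed: int | None = None
) -> tuple[float, float, float]:
    """(sigma, gamma, lambda) against degree-preserving rewired references.

    gamma = C(g) / mean C(rand) with C the mean local clustering coefficient;
    lambda = L(g) / mean L(rand); sigma = gamma / lambda. Each reference graph
    results from 10 * |E| attempted edge swaps.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    comp_sizes = [len(c) for c in nx.connected_components(g)]
    if not comp_sizes or max(comp_sizes) < 4:
        raise ValueError("largest connected component must have >= 4 nodes")
    rng = np.random.default_rng(seed)
    c_obs = nx.average_clustering(g)
    l_obs = characteristic_path_length(g)
    n_attempts = 10 * g.number_of_edges()
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    for i in range(n_random):
        h = _rewire(g, rng, n_attempts)
        c_rand[i] = nx.average_clustering(h)
        l_rand[i] = characteristic_path_length(h)
    if c_rand.mean() == 0:
        raise ValueError(
            "reference graphs have zero clustering; small-worldness undefined at this sparsity"
        )
    gamma = c_obs / c_rand.mean()
    lam = l_obs / l_rand.mean()
    sigma = gamma / lam
    return float(sigma), float(gamma), float(lam)


def _refine_partition(g: nx.Graph, labels: dict, m: int) -> tuple[float, dict]:
    """Local search: single-node moves (including splitting off into a new
    singleton community) and pairwise community merges, iterated to a fixed
    point of the modularity."""
    labels = dict(labels)
    degrees = dict(g.degree())
    nodes = sorted(g.nodes())
    changed = True
    while changed:
        changed = False
        comm_deg: dict[int, float] = {}
        for node, c in labels.items():
            comm_deg[c] = comm_deg.get(c, 0) + degrees[node]
        fresh = max(comm_deg) + 1  # label for a brand-new singleton community
        # --- node moves ---
        moved = True
        while moved:
            moved = False
            for node in nodes:
                c_old = labels[node]
                k_i = degrees[node]
                links: dict[int, int] = {}
                for nbr in g.neighbors(node):
                    if nbr != node:
                        links[labels[nbr]] = links.get(labels[nbr], 0) + 1
                comm_deg[c_old] -= k_i
                base_gain = links.get(c_old, 0) / m - k_i * comm_deg[c_old] / (2 * m * m)
                best_c, best_gain = c_old, base_gain
                if 0.0 > best_gain + 1e-12:  # splitting off alone
                    best_c, best_gain = fresh, 0.0
                for c_new, l_new in links.items():
                    if c_new == c_old:
                        continue
                    gain = l_new / m - k_i * comm_deg.get(c_new, 0) / (2 * m * m)
                    if gain > best_gain + 1e-12:
                        best_c, best_gain = c_new, gain
                comm_deg[best_c] = comm_deg.get(best_c, 0) + k_i
                if best_c != c_old:
                    labels[node] = best_c
                    if best_c == fresh:
                        fresh += 1
                    moved = changed = True
        # --- pairwise community merges ---
        # inter-community link counts
        between: dict[tuple[int, int], int] = {}
        for u, v in g.edges():
            cu, cv = labels[u], labels[v]
            if cu != cv:
                key = (min(cu, cv), max(cu, cv))
                between[key] = between.get(key, 0) + 1
        comm_deg = {}
        for node, c in labels.items():
            comm_deg[c] = comm_deg.get(c, 0) + degrees[node]
        best_pair, best_gain = None, 1e-12
        for (ca, cb), l_ab in between.items():
            gain = l_ab / m - comm_deg[ca] * comm_deg[cb] / (2 * m * m)
            if gain > best_gain:
                best_pair, best_gain = (ca, cb), gain
        if best_pair is not None:
            ca, cb = best_pair
            for node in nodes:
                if labels[node] == cb:
                    labels[node] = ca
            changed = True
    comms_sets: dict[int, set] = {}
    for node, c in labels.items():
        comms_sets.setdefault(c, set()).add(node)
    q = nx.community.modularity(g, list(comms_sets.values()))
    return q, labels


def _canonical_assignment(labels: dict, nodes: list) -> tuple[int, ...]:
    remap: dict[int, int] = {}
    out = []
    for node in nodes:
        c = labels[node]
        if c not in remap:
            remap[c] = len(remap)
        out.append(remap[c])
    return tuple(out)


def _exhaustive_modularity(g: nx.Graph, nodes: list) -> tuple[float, tuple[int, ...]]:
    """Exact maximum over all set partitions (restricted-growth enumeration);
    only viable for very small graphs."""
    m = g.number_of_edges()
    degrees = dict(g.degree())
    edges = list(g.edges())
    n = len(nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    best_q, best_assign = -math.inf, None

    def recurse(i: int, assign: list[int], n_comms: int):
        nonlocal best_q, best_assign
        if i == n:
            within = [0.0] * n_comms
            deg_sum = [0.0] * n_comms
            for node, d in degrees.items():
                deg_sum[assign[idx[node]]] += d
            for u, v in edges:
                if assign[idx[u]] == assign[idx[v]]:
                    within[assign[idx[u]]] += 1
            q = sum(w / m - (ds / (2 * m)) ** 2 for w, ds in zip(within, deg_sum))
            assign_t = tuple(assign)
            if q > best_q + 1e-12 or (abs(q - best_q) <= 1e-12 and (best_assign is None or assign_t < best_assign)):
                best_q, best_assign = q, assign_t
            return
        for c in range(n_comms + 1):
            assign.append(c)
            recurse(i + 1, assign, max(n_comms, c + 1))
            assign.pop()

    recurse(0, [], 0)
    return float(best_q), best_assign


#: Node count at or below which the modularity optimizer enumerates all
#: partitions exactly instead of running the heuristic.
EXACT_MODULARITY_LIMIT = 8


def modularity_q(g: nx.Graph, n_restarts: int = 4, seed: int | None = None) -> tuple[float, tuple[int, ...]]:
    """Newman modularity Q of the best partition found.

    For graphs of at most :data:`EXACT_MODULARITY_LIMIT` nodes the maximum is
    exact (exhaustive partition search). Larger graphs use seeded Louvain
    restarts plus a greedy-modularity start, each refined by single-node
    moves and community merges; ties in Q resolve toward the
    lexicographically smallest canonical community assignment. Returns
    (Q, assignment) with the assignment indexed by sorted node order.
    """
    if g.number_of_edges() == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    nodes = sorted(g.nodes())
    if len(nodes) <= EXACT_MODULARITY_LIMIT:
        return _exhaustive_modularity(g, nodes)
    m = g.number_of_edges()
    candidates: list[dict] = []
    rng = np.random.default_rng(seed)
    for _ in range(max(1, n_restarts)):
        comms = nx.community.louvain_communities(g, seed=int(rng.integers(0, 2**31 - 1)))
        candidates.append({node: ci for ci, cs in enumerate(comms) for node in cs})
    greedy = nx.community.greedy_modularity_communities(g)
    candidates.append({node: ci for ci, cs in enumerate(greedy) for node in cs})
    candidates.append({node: 0 for node in nodes})  # single community
    best_q, best_assign = -math.inf, None
    for labels in candidates:
        q, refined = _refine_partition(g, labels, m)
        assign = _canonical_assignment(refined, nodes)
        if q > best_q + 1e-12 or (abs(q - best_q) <= 1e-12 and (best_assign is None or assign < best_assign)):
            best_q, best_assign = q, assign
    return float(best_q), best_assign


def assortativity(g: nx.Graph) -> float:
    """Degree assortativity: Pearson correlation of endpoint degrees over
    edges (both orientations). Raises on graphs where it is undefined."""
    if g.number_of_edges() < 2:
        raise DegenerateGraphError("assortativity needs at least 2 edges")
    deg = dict(g.degree())
    xs, ys = [], []
    for u, v in g.edges():
        xs.extend((deg[u], deg[v]))
        ys.extend((deg[v], deg[u]))
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        raise DegenerateGraphError("endpoint degrees have zero variance (regular graph)")
    return float(np.corrcoef(xs, ys)[0, 1])


def mean_connectivity(cm: ConnectivityMatrix) -> float:
    """Mean off-diagonal Pearson r of the unthresholded matrix."""
    iu, ju = np.triu_indices(cm.n_nodes, k=1)
    return float(cm.values[iu, ju].mean())


@dataclass(frozen=True)
class GraphMetricSet:
    """Density-resolved and density-averaged global diagnostics."""

    per_density: pd.DataFrame  # index: density, columns: METRIC_NAMES
    averaged: dict[str, float]
    mean_connectivity: float
    skipped: dict[str, int] = field(default_factory=dict)


def metrics_over_densities(
    cm: ConnectivityMatrix,
    densities: np.ndarray | None = None,
    n_random: int = 20,
    n_restarts: int = 4,
    seed: int | None = None,
) -> GraphMetricSet:
    """Compute each diagnostic at each density and average across densities.

    Densities where a metric is undefined (disconnected-to-edgeless graphs,
    regular graphs for assortativity) are skipped for that metric, with a
    count recorded in ``skipped``.
    """
    densities = default_density_grid() if densities is None else np.asarray(densities, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    skipped: dict[str, int] = {name: 0 for name in METRIC_NAMES}
    for d in densities:
        g = binarize_at_density(cm, float(d))
        row: dict[str, float] = {"density": float(d)}
        row["transitivity"] = transitivity(g)
        try:
            row["char_path_length"] = characteristic_path_length(g)
        except ValueError:
            row["char_path_length"] = np.nan
            skipped["char_path_length"] += 1
        row["global_efficiency"] = global_efficiency(g)
        try:
            sigma, gamma, lam = small_worldness(
                g, n_random=n_random, seed=int(rng.integers(0, 2**31 - 1))
            )
            row["small_worldness"], row["gamma"], row["lambda"] = sigma, gamma, lam
        except ValueError:
            row["small_worldness"] = row["gamma"] = row["lambda"] = np.nan
            skipped["small_worldness"] += 1
        try:
            q, _ = modularity_q(g, n_restarts=n_restarts, seed=int(rng.integers(0, 2**31 - 1)))
            row["modularity_q"] = q
        except ValueError:
            row["modularity_q"] = np.nan
            skipped["modularity_q"] += 1
        try:
            row["assortativity"] = assortativity(g)
        except DegenerateGraphError:
            row["assortativity"] = np.nan
            skipped["assortativity"] += 1
        rows.append(row)
    per_density = pd.DataFrame(rows).set_index("density")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        averaged = {name: float(np.nanmean(per_density[name].to_numpy())) for name in METRIC_NAMES}
    return GraphMetricSet(
        per_density=per_density,
        averaged=averaged,
        mean_connectivity=mean_connectivity(cm),
        skipped={k: v for k, v in skipped.items() if v},
    )
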