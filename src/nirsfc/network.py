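"""Graph-theoretical analysis of whole-brain connectivity matrices.

A correlation matrix is thresholded — keeping either the strongest positive
fraction of connections (sparsity mode) or entries above an r cutoff — into a
binary or weighted adjacency matrix with a zero diagonal.  From it the module
computes the standard global metrics (clustering coefficient Cp,
characteristic path length Lp, global/local efficiency, modularity Q,
hierarchy exponent beta) and nodal metrics (degree, efficiency, betweenness),
plus small-world indices gamma = Cp/Cp_rand, lambda = Lp/Lp_rand and
sigma = gamma/lambda against degree-preserving rewired null networks
(Maslov-Sneppen edge swaps).

Disconnected node pairs contribute path length only through the connected
fraction (reported) and efficiency through 1/inf = 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "AdjacencyMatrix",
    "GraphMetrics",
    "threshold_matrix",
    "clustering_coefficient",
    "characteristic_path_length",
    "efficiencies",
    "betweenness",
    "modularity",
    "hierarchy",
    "hierarchy_fit",
    "random_rewire",
    "small_world",
    "compute_metrics",
    "sparsity_sweep",
]


@dataclass
class AdjacencyMatrix:
    """A thresholded connectivity graph: symmetric, nonnegative, zero diagonal."""

    weights: np.ndarray
    mode: str = "binary"  # binary | weighted
    threshold_spec: str = ""
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(w < 0):
            raise ValueError("adjacency weights must be nonnegative")
        np.fill_diagonal(w, 0.0)
        if self.mode == "binary":
            vals = np.unique(w)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("binary adjacency must contain only 0/1")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    @property
    def binary(self) -> np.ndarray:
        return (self.weights > 0).astype(float)

    def degrees(self) -> np.ndarray:
        return self.binary.sum(axis=1)

    def edge_list(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.n_nodes, 1)
        mask = self.weights[iu] > 0
        return list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.weights)
        if self.mode == "weighted":
            for _, _, d in g.edges(data=True):
                d["length"] = 1.0 / d["weight"]
        return g


def threshold_matrix(fc: np.ndarray, sparsity: float | None = None,
                     cutoff: float | None = None, mode: str = "binary",
                     use_abs: bool = False,
                     node_labels: list[str] | None = None) -> AdjacencyMatrix:
    """Threshold a correlation matrix into a graph.

    In sparsity mode the ``ceil(s * N(N-1)/2)`` strongest positive entries
    are kept (negative correlations are excluded by default; ``use_abs``
    ranks by magnitude instead).  In cutoff mode entries strictly above the
    cutoff survive.  The diagonal is always forced to zero.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if (sparsity is None) == (cutoff is None):
        raise ValueError("pass exactly one of sparsity or cutoff")
    n = fc.shape[0]
    vals = np.abs(fc) if use_abs else fc.copy()
    np.fill_diagonal(vals, -np.inf)
    iu = np.triu_indices(n, 1)
    upper = vals[iu]
    keep = np.zeros(upper.size, dtype=bool)
    if sparsity is not None:
        if not 0 < sparsity < 1:
            raise ValueError("sparsity must be in (0, 1)")
        k = math.ceil(sparsity * n * (n - 1) / 2)
        positive = np.flatnonzero(np.nan_to_num(upper, nan=-np.inf) > 0)
        if positive.size < k:
            warnings.warn(
                f"only {positive.size} positive connections available for "
                f"requested {k}; actual sparsity "
                f"{positive.size / (n * (n - 1) / 2):.3f}")
            keep[positive] = True
        else:
            order = positive[np.argsort(upper[positive], kind="stable")[::-1]]
            keep[order[:k]] = True
        spec = f"sparsity={sparsity}"
    else:
        keep = np.nan_to_num(upper, nan=-np.inf) > cutoff
        spec = f"cutoff={cutoff}"
    w = np.zeros((n, n))
    w[iu[0][keep], iu[1][keep]] = np.abs(fc[iu[0][keep], iu[1][keep]]) if use_abs \
        else fc[iu[0][keep], iu[1][keep]]
    w = w + w.T
    if mode == "binary":
        w = (w > 0).astype(float)
    elif mode != "weighted":
        raise ValueError("mode must be binary or weighted")
    return AdjacencyMatrix(weights=w, mode=mode, threshold_spec=spec,
                           node_labels=node_labels)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def clustering_coefficient(adj: AdjacencyMatrix) -> tuple[float, np.ndarray]:
    """Mean and per-node clustering coefficient.

    Binary: c_i = 2 triangles(i) / (k_i (k_i - 1)), zero when k_i < 2.
    Weighted: the geometric-mean triangle (Onnela) formulation on weights
    normalized by their maximum.
    """
    a = adj.binary
    k = a.sum(axis=1)
    if adj.mode == "binary":
        tri = np.diag(a @ a @ a) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(k >= 2, 2.0 * tri / (k * (k - 1)), 0.0)
    else:
        wmax = adj.weights.max()
        if wmax == 0:
            return 0.0, np.zeros(adj.n_nodes)
        w13 = np.cbrt(adj.weights / wmax)
        tri = np.diag(w13 @ w13 @ w13) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(k >= 2, 2.0 * tri / (k * (k - 1)), 0.0)
    return float(c.mean()), c


def _distance_matrix(adj: AdjacencyMatrix) -> np.ndarray:
    if adj.mode == "binary":
        return shortest_path(adj.binary, method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        lengths = np.where(adj.weights > 0, 1.0 / adj.weights, 0.0)
    return shortest_path(lengths, method="D", directed=False)


def characteristic_path_length(adj: AdjacencyMatrix) -> tuple[float, float]:
    """Mean shortest-path length over connected ordered pairs.

    Returns ``(lp, disconnected_fraction)``; lp is NaN for an edgeless graph.
    Weighted graphs use inverse-weight edge lengths.
    """
    d = _distance_matrix(adj)
    n = adj.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_pairs = n * (n - 1)
    disconnected = 1.0 - finite.sum() / n_pairs if n_pairs else 0.0
    if not finite.any():
        return np.nan, 1.0
    return float(d[finite].mean()), float(disconnected)


def efficiencies(adj: AdjacencyMatrix) -> tuple[float, float, np.ndarray]:
    """Global, local and nodal efficiency.

    ``eglob`` is the mean inverse shortest-path length over ordered pairs
    (disconnected pairs contribute 0); ``nodal_efficiency[i]`` the mean over
    partners of node i; ``eloc`` the mean over nodes of the global efficiency
    of each node's neighborhood subgraph.
    """
    n = adj.n_nodes
    d = _distance_matrix(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    nodal = inv.sum(axis=1) / max(n - 1, 1)
    eglob = float(inv.sum() / max(n * (n - 1), 1))
    a = adj.binary
    eloc_vals = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = AdjacencyMatrix(weights=adj.weights[np.ix_(nbrs, nbrs)],
                              mode=adj.mode)
        e_sub, _, _ = _sub_eglob_cache(sub)
        eloc_vals[i] = e_sub
    return eglob, float(eloc_vals.mean()), nodal


def _sub_eglob_cache(sub: AdjacencyMatrix) -> tuple[float, float, np.ndarray]:
    m = sub.n_nodes
    d = _distance_matrix(sub)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / max(m * (m - 1), 1)), 0.0, inv


def betweenness(adj: AdjacencyMatrix) -> np.ndarray:
    """Unnormalized shortest-path betweenness with fractional counting."""
    g = adj.to_networkx()
    weight = "length" if adj.mode == "weighted" else None
    bc = nx.betweenness_centrality(g, normalized=False, weight=weight)
    return np.array([bc[i] for i in range(adj.n_nodes)])


# -- modularity --------------------------------------------------------------

def _modularity_q(w: np.ndarray, labels: np.ndarray) -> float:
    """Newman's Q for a (possibly weighted) undirected graph."""
    two_m = w.sum()
    if two_m == 0:
        return np.nan
    k = w.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((w - np.outer(k, k) / two_m) * same).sum() / two_m)


def _set_partitions(n: int) -> Iterator[np.ndarray]:
    """All partitions of n items as label vectors (restricted growth strings)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, max_label: int) -> Iterator[np.ndarray]:
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0)


def _greedy_modularity(w: np.ndarray, rng: np.random.Generator,
                       max_refine_passes: int = 5) -> np.ndarray:
    """Greedy agglomeration (Clauset-Newman-Moore) followed by single-node
    move refinement; node visit order in the refinement is seeded."""
    g = nx.from_numpy_array(w)
    comms = nx.community.greedy_modularity_communities(g, weight="weight")
    n = w.shape[0]
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(comms):
        labels[list(members)] = lab
    for _ in range(max_refine_passes):
        moved = False
        order = rng.permutation(n)
        for i in order:
            best_q, best_lab = _modularity_q(w, labels), labels[i]
            for lab in np.unique(labels):
                if lab == labels[i]:
                    continue
                trial = labels.copy()
                trial[i] = lab
                q = _modularity_q(w, trial)
                if q > best_q + 1e-12:
                    best_q, best_lab = q, lab
            if best_lab != labels[i]:
                labels[i] = best_lab
                moved = True
        if not moved:
            break
    return labels


def modularity(adj: AdjacencyMatrix, seed: int = 0,
               exact_max_nodes: int = 10) -> tuple[float, np.ndarray]:
    """Best-partition Newman modularity Q and the community labels.

    Graphs with up to ``exact_max_nodes`` nodes are solved exactly by
    enumerating all set partitions; larger graphs use greedy agglomeration
    with seeded tie-breaking plus single-node refinement.
    """
    w = adj.weights if adj.mode == "weighted" else adj.binary
    if w.sum() == 0:
        return np.nan, np.arange(adj.n_nodes)
    n = adj.n_nodes
    if n <= exact_max_nodes:
        best_q, best = -np.inf, None
        for labels in _set_partitions(n):
            q = _modularity_q(w, labels)
            if q > best_q:
                best_q, best = q, labels
        return best_q, best
    rng = np.random.default_rng(seed)
    labels = _greedy_modularity(w, rng)
    return _modularity_q(w, labels), labels


def hierarchy_fit(degrees: np.ndarray, clustering: np.ndarray,
                  ) -> tuple[float, int]:
    """Fit log c_i = const - beta * log k_i over eligible nodes.

    Eligible nodes have degree >= 2 and positive clustering; at least three
    eligible nodes spanning >= 2 distinct degrees are required, otherwise
    beta is NaN.  Returns ``(beta, n_eligible)``.
    """
    k = np.asarray(degrees, dtype=float)
    c = np.asarray(clustering, dtype=float)
    mask = (k >= 2) & (c > 0)
    n_eligible = int(mask.sum())
    if n_eligible < 3 or np.unique(k[mask]).size < 2:
        return np.nan, n_eligible
    slope = np.polyfit(np.log(k[mask]), np.log(c[mask]), 1)[0]
    return float(-slope), n_eligible


def hierarchy(adj: AdjacencyMatrix) -> tuple[float, int]:
    """Hierarchy exponent beta of the power-law degree-clustering relation."""
    _, c = clustering_coefficient(adj)
    return hierarchy_fit(adj.degrees(), c)


# -- null models and small-worldness ----------------------------------------

def random_rewire(adj: AdjacencyMatrix, n_swap_per_edge: int = 10,
                  seed: int = 0) -> AdjacencyMatrix:
    """Degree-preserving edge-swap (Maslov-Sneppen) randomization.

    Attempts ``n_swap_per_edge * n_edges`` swaps of edge pairs (a,b),(c,d)
    -> (a,d),(c,b), rejecting self-loops and duplicate edges.  The sorted
    degree sequence is exactly preserved; the result is reproducible for a
    given seed.
    """
    if adj.mode != "binary":
        raise ValueError("rewiring operates on binary graphs")
    edges = adj.edge_list()
    m = len(edges)
    if m < 2:
        warnings.warn("fewer than 2 edges: no swap possible, returning input")
        return AdjacencyMatrix(weights=adj.weights.copy(), mode="binary",
                               threshold_spec=adj.threshold_spec)
    rng = np.random.default_rng(seed)
    a = adj.binary.astype(bool)
    edges = [list(e) for e in edges]
    attempts = n_swap_per_edge * m
    swaps = 0
    for _ in range(attempts):
        i, j = rng.integers(m), rng.integers(m)
        if i == j:
            continue
        a1, b1 = edges[i]
        c1, d1 = edges[j]
        if rng.integers(2):
            c1, d1 = d1, c1
        # propose (a1,d1), (c1,b1)
        if len({a1, b1, c1, d1}) < 4:
            continue
        if a[a1, d1] or a[c1, b1]:
            continue
        a[a1, b1] = a[b1, a1] = False
        a[c1, d1] = a[d1, c1] = False
        a[a1, d1] = a[d1, a1] = True
        a[c1, b1] = a[b1, c1] = True
        edges[i] = [a1, d1]
        edges[j] = [c1, b1]
        swaps += 1
    if swaps == 0:
        warnings.warn("no valid swap found; returning input unchanged")
    return AdjacencyMatrix(weights=a.astype(float), mode="binary",
                           threshold_spec=adj.threshold_spec + "|rewired")


def small_world(adj: AdjacencyMatrix, n_random: int = 100, seed: int = 0,
                n_swap_per_edge: int = 10) -> tuple[float, float, float]:
    """Small-world indices against degree-preserving null networks.

    gamma = Cp / mean(Cp_random), lambda = Lp / mean(Lp_random),
    sigma = gamma / lambda; null metrics come from ``n_random`` rewired
    graphs with seeds derived from ``seed``.
    """
    cp, _ = clustering_coefficient(adj)
    lp, _ = characteristic_path_length(adj)
    child = np.random.SeedSequence(seed).spawn(n_random)
    cps, lps = [], []
    for ss in child:
        null = random_rewire(adj, n_swap_per_edge=n_swap_per_edge,
                             seed=ss.generate_state(1)[0] % (2**31))
        c, _ = clustering_coefficient(null)
        l, _ = characteristic_path_length(null)
        cps.append(c)
        lps.append(l)
    cp_rand = float(np.mean(cps))
    lp_rand = float(np.nanmean(lps))
    gamma = cp / cp_rand if cp_rand > 0 else np.nan
    lam = lp / lp_rand if lp_rand > 0 else np.nan
    sigma = gamma / lam if lam and np.isfinite(lam) and lam != 0 else np.nan
    return gamma, lam, sigma


@dataclass
class GraphMetrics:
    """Global and nodal graph metrics at one threshold."""

    cp: float
    lp: float
    disconnected_fraction: float
    gamma: float
    lam: float
    sigma: float
    eglob: float
    eloc: float
    q: float
    beta: float
    nodal_degree: np.ndarray
    nodal_efficiency: np.ndarray
    nodal_betweenness: np.ndarray
    nodal_clustering: np.ndarray
    n_random: int = 0
    seed: int = 0

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in
                ("cp", "lp", "disconnected_fraction", "gamma", "lam", "sigma",
                 "eglob", "eloc", "q", "beta")}


def compute_metrics(adj: AdjacencyMatrix, n_random: int = 100, seed: int = 0,
                    with_null: bool = True) -> GraphMetrics:
    """All global and nodal metrics for one adjacency matrix."""
    cp, c_nodes = clustering_coefficient(adj)
    lp, frac = characteristic_path_length(adj)
    eglob, eloc, nodal_eff = efficiencies(adj)
    q, _ = modularity(adj, seed=seed)
    beta, _ = hierarchy(adj)
    bet = betweenness(adj)
    if with_null and adj.n_edges >= 2:
        gamma, lam, sigma = small_world(adj, n_random=n_random, seed=seed)
    else:
        gamma = lam = sigma = np.nan
    return GraphMetrics(cp=cp, lp=lp, disconnected_fraction=frac, gamma=gamma,
                        lam=lam, sigma=sigma, eglob=eglob, eloc=eloc, q=q,
                        beta=beta, nodal_degree=adj.degrees(),
                        nodal_efficiency=nodal_eff, nodal_betweenness=bet,
                        nodal_clustering=c_nodes, n_random=n_random, seed=seed)


def _sweep_one(subject: str, fc: np.ndarray, s: float, mode: str,
               n_random: int, seed: int, with_null: bool) -> dict:
    adj = threshold_matrix(fc, sparsity=s, mode=mode)
    # derive a per-task seed from (seed, sparsity) so results do not depend
    # on scheduling order
    task_seed = (seed * 10007 + int(round(s * 1000))) % (2**31)
    metrics = compute_metrics(adj, n_random=n_random, seed=task_seed,
                              with_null=with_null)
    row = {"subject": subject, "sparsity": s, "n_edges": adj.n_edges}
    row.update(metrics.to_row())
    return row


def sparsity_sweep(fc_matrices: dict[str, np.ndarray],
                   s_values: Sequence[float], mode: str = "binary",
                   n_random: int = 100, seed: int = 0, n_jobs: int = 1,
                   with_null: bool = True) -> pd.DataFrame:
    """Metrics per subject per sparsity threshold.

    The result is identical for any ``n_jobs`` because every task derives
    its own seed from the subject-independent base seed and threshold.
    Per-task failures are recorded in the ``error`` column and do not abort
    the sweep.
    """
    tasks = [(name, fc, float(s)) for name, fc in fc_matrices.items()
             for s in s_values]

    def safe(name: str, fc: np.ndarray, s: float) -> dict:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row = _sweep_one(name, fc, s, mode, n_random, seed, with_null)
            row["error"] = ""
            return row
        except Exception as exc:
            return {"subject": name, "sparsity": s,
                    "error": f"{type(exc).__name__}: {exc}"}

    rows = Parallel(n_jobs=n_jobs)(delayed(safe)(*t) for t in tasks)
    return pd.DataFrame(rows).sort_values(["subject", "sparsity"]).reset_index(drop=True)
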