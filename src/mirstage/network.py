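"""Co-expression network modules: resolution-parameterized modularity,
consensus (representative) partitions, z-Rand partition similarity,
recursive submodules, gamma sweeps and cross-dataset comparison.

Nodes are miRNAs; edge weights are the positive part of the Pearson
correlation of row-standardized log2-cpm profiles across all samples.
Communities maximize the Newman-Girvan modularity with the
Reichardt-Bornholdt structural resolution parameter gamma,

    Q(gamma) = (1/2m) * sum_ij [A_ij - gamma * k_i k_j / (2m)] * delta(c_i, c_j),

optimized by seeded multi-level greedy moves (Leiden refinement of the
Louvain scheme, via leidenalg) with random restarts. Because any single
greedy run is stochastic, a partition ensemble is summarized by its
*representative* member: the run with the highest mean pairwise z-Rand
similarity to all other runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd

__all__ = [
    "CorrelationNetwork",
    "Partition",
    "ConsensusResult",
    "correlation_network",
    "modularity",
    "detect_communities",
    "zrand",
    "consensus_partition",
    "submodules",
    "gamma_sweep",
    "compare_datasets",
]


@dataclass
class CorrelationNetwork:
    nodes: list[str]
    corr: np.ndarray        # symmetric, unit diagonal
    adj: np.ndarray         # non-negative weights, zero diagonal

    @property
    def total_weight(self) -> float:
        """2m = sum over all ordered pairs of adj."""
        return float(self.adj.sum())


@dataclass
class Partition:
    assignment: pd.Series   # node -> community id (contiguous from 1)
    gamma: float
    Q: float

    @property
    def n_communities(self) -> int:
        return int(self.assignment.nunique())


@dataclass
class ConsensusResult:
    representative: Partition
    runs: list[Partition]
    pairwise_z: np.ndarray
    mean_z: np.ndarray = field(default=None)  # type: ignore[assignment]


def correlation_network(expr: pd.DataFrame, method: str = "pearson",
                        weighting: str = "positive_part") -> CorrelationNetwork:
    """Build the weighted co-expression network from an expression matrix.

    ``expr`` is miRNAs x samples (log2 cpm, typically row-standardized
    upstream — Pearson correlation is invariant to that). Anti-correlated
    pairs get zero weight under positive-part weighting.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    sd = expr.std(axis=1, ddof=1)
    const = sd.index[(sd == 0) | sd.isna()]
    if len(const):
        warnings.warn(f"dropping {len(const)} constant row(s) from network",
                      stacklevel=2)
        expr = expr.drop(index=const)
    if method != "pearson":
        corr = expr.T.corr(method=method).to_numpy()
    else:
        corr = np.atleast_2d(np.corrcoef(expr.to_numpy(dtype=float)))
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    if weighting != "positive_part":
        raise ValueError(f"unknown weighting {weighting!r}")
    adj = np.maximum(corr, 0.0)
    np.fill_diagonal(adj, 0.0)
    return CorrelationNetwork(nodes=list(expr.index), corr=corr, adj=adj)


def modularity(adj: np.ndarray, assignment, gamma: float = 1.0) -> float:
    """Exact Q(gamma) for a weighted undirected graph with zero self-weights."""
    A = np.asarray(adj, dtype=float)
    labels = np.asarray(assignment)
    if labels.shape[0] != A.shape[0]:
        raise ValueError("assignment must cover all nodes")
    two_m = A.sum()
    if two_m <= 0:
        return 0.0
    k = A.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(np.sum((A - gamma * np.outer(k, k) / two_m) * same) / two_m)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Contiguous community ids from 1, in order of first appearance."""
    seen: dict = {}
    out = np.empty(len(labels), dtype=int)
    for i, c in enumerate(labels):
        out[i] = seen.setdefault(c, len(seen) + 1)
    return out


def _graph_from_adj(adj: np.ndarray) -> ig.Graph:
    n = adj.shape[0]
    iu = np.triu_indices(n, k=1)
    w = adj[iu]
    nz = w > 0
    edges = list(zip(iu[0][nz].tolist(), iu[1][nz].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = w[nz].tolist()
    return g


def detect_communities(net: CorrelationNetwork | np.ndarray, gamma: float = 1.0,
                       n_restarts: int = 20, seed: int = 0) -> Partition:
    """Greedy multi-level maximization of Q(gamma), best of ``n_restarts`` runs.

    Deterministic given ``seed``; isolated nodes become singletons.
    """
    if isinstance(net, CorrelationNetwork):
        adj, nodes = net.adj, net.nodes
    else:
        adj = np.asarray(net, dtype=float)
        nodes = list(range(adj.shape[0]))
    if adj.size == 0:
        raise ValueError("empty graph")
    g = _graph_from_adj(adj)
    best_labels, best_q = None, -np.inf
    rng = np.random.default_rng(seed)
    for _ in range(max(1, n_restarts)):
        s = int(rng.integers(0, 2**31 - 1))
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition, weights="weight",
            resolution_parameter=gamma, seed=s, n_iterations=-1)
        labels = np.asarray(part.membership)
        q = modularity(adj, labels, gamma)
        if q > best_q + 1e-15:
            best_q, best_labels = q, labels
    assignment = pd.Series(_relabel(best_labels), index=pd.Index(nodes), name="community")
    return Partition(assignment=assignment, gamma=gamma, Q=best_q)


def zrand(p1: Partition | pd.Series, p2: Partition | pd.Series) -> float:
    """Standardized pair-counting Rand similarity of two partitions.

    z = (w - E[w]) / sigma_w, where w counts node pairs co-classified in
    both partitions and the moments are taken under the permutation null
    with both partitions' group sizes fixed (hypergeometric model).
    """
    a = p1.assignment if isinstance(p1, Partition) else p1
    b = p2.assignment if isinstance(p2, Partition) else p2
    if set(a.index) != set(b.index):
        raise ValueError("partitions are over different node sets")
    b = b.loc[a.index]
    n = len(a)
    ct = pd.crosstab(a.to_numpy(), b.to_numpy()).to_numpy().astype(float)
    M = n * (n - 1) / 2.0
    arow = ct.sum(axis=1)
    acol = ct.sum(axis=0)
    M1 = float((arow * (arow - 1) / 2.0).sum())
    M2 = float((acol * (acol - 1) / 2.0).sum())
    w = float((ct * (ct - 1) / 2.0).sum())
    mu = M1 * M2 / M
    c1 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * M1 + 4 * float((arow**3).sum())
    c2 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * M2 + 4 * float((acol**3).sum())
    var = (M / 16.0
           - (4 * M1 - 2 * M) ** 2 * (4 * M2 - 2 * M) ** 2 / (256.0 * M**2)
           + c1 * c2 / (16.0 * n * (n - 1) * (n - 2))
           + ((4 * M1 - 2 * M) ** 2 - 4 * c1 - 4 * M)
           * ((4 * M2 - 2 * M) ** 2 - 4 * c2 - 4 * M)
           / (64.0 * n * (n - 1) * (n - 2) * (n - 3)))
    if var <= 0:
        return float("nan")
    return float((w - mu) / np.sqrt(var))


def consensus_partition(net: CorrelationNetwork | np.ndarray, gamma: float = 1.0,
                        n_runs: int = 100, seed: int = 0,
                        n_restarts: int = 1) -> ConsensusResult:
    """Ensemble of seeded detection runs summarized by its representative.

    The representative is the run with maximal mean z-Rand similarity to all
    other runs; ties break by higher Q, then lower run index.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    runs = [detect_communities(net, gamma=gamma, n_restarts=n_restarts,
                               seed=seed + 7919 * r) for r in range(n_runs)]
    z = np.zeros((n_runs, n_runs))
    for i in range(n_runs):
        for j in range(i + 1, n_runs):
            zij = zrand(runs[i], runs[j])
            z[i, j] = z[j, i] = 0.0 if np.isnan(zij) else zij
    mean_z = z.sum(axis=1) / (n_runs - 1)
    qs = np.array([r.Q for r in runs])
    order = np.lexsort((np.arange(n_runs), -qs, -np.round(mean_z, 12)))
    rep = runs[int(order[0])]
    return ConsensusResult(representative=rep, runs=runs, pairwise_z=z, mean_z=mean_z)


def _submodule_order_key(expr: pd.DataFrame, members: pd.Index) -> int:
    """Stage index of peak mean expression; earlier peaks order first."""
    return int(np.argmax(expr.loc[members].mean(axis=0).to_numpy()))


def submodules(expr: pd.DataFrame, module_nodes, gamma: float = 1.0,
               n_runs: int = 20, seed: int = 0, parent_label: str = "1"):
    """Independent community detection within one module's miRNAs.

    Recomputes the correlation network on the subset only, then takes the
    representative partition. Returns (ConsensusResult, labels) where labels
    maps node -> submodule id like "1A", "1B", ... lettered in order of the
    earliest peak of mean expression across samples.
    """
    module_nodes = list(module_nodes)
    sub = expr.loc[module_nodes]
    if len(module_nodes) < 3:
        warnings.warn("module too small to subdivide; returning one submodule",
                      stacklevel=2)
        labels = pd.Series(f"{parent_label}A", index=sub.index, name="submodule")
        assignment = pd.Series(1, index=sub.index, name="community")
        part = Partition(assignment=assignment, gamma=gamma, Q=0.0)
        return ConsensusResult(part, [part], np.zeros((1, 1)), np.zeros(1)), labels
    net = correlation_network(sub)
    cons = consensus_partition(net, gamma=gamma, n_runs=n_runs, seed=seed)
    assign = cons.representative.assignment
    keys = {c: _submodule_order_key(sub, assign.index[assign == c])
            for c in sorted(assign.unique())}
    ordered = sorted(keys, key=lambda c: (keys[c], c))
    letter = {c: chr(ord("A") + i) for i, c in enumerate(ordered)}
    labels = pd.Series([f"{parent_label}{letter[c]}" for c in assign],
                       index=assign.index, name="submodule")
    return cons, labels


def gamma_sweep(net: CorrelationNetwork, gammas=(1.0, 2.5), n_runs: int = 20,
                seed: int = 0):
    """Consensus partitions along a resolution sweep, with a split report.

    For each consecutive pair of gamma values, each low-gamma module is
    mapped to the high-gamma modules its members land in (maximal overlap):
    'persists' if one high-gamma module holds >50% of its nodes and it is
    that module's main parent, 'splits' if its members spread over several
    high-gamma modules, 'dissolves' otherwise.
    """
    results = {g: consensus_partition(net, gamma=g, n_runs=n_runs, seed=seed)
               for g in gammas}
    report = []
    gl = list(gammas)
    for g_lo, g_hi in zip(gl[:-1], gl[1:]):
        lo = results[g_lo].representative.assignment
        hi = results[g_hi].representative.assignment.loc[lo.index]
        for c in sorted(lo.unique()):
            members = lo.index[lo == c]
            counts = hi.loc[members].value_counts()
            top_frac = counts.iloc[0] / len(members)
            n_major = int((counts / len(members) > 0.1).sum())
            if n_major > 1:
                fate = "splits"
            elif top_frac > 0.5:
                fate = "persists"
            else:
                fate = "dissolves"
            report.append({
                "gamma_low": g_lo, "gamma_high": g_hi, "module": int(c),
                "n_nodes": int(len(members)), "fate": fate,
                "children": counts.index.tolist(),
            })
    return [results[g] for g in gl], pd.DataFrame(report)


def compare_datasets(partitions: dict[str, Partition | pd.Series]):
    """Cross-tabulate partitions of overlapping node sets (KR/FDR1/FDR5-style).

    For each dataset pair the partitions are restricted to shared nodes;
    returns a DataFrame of pairwise z-Rand scores and shared-node counts,
    plus the contingency tables. Nodes absent from one dataset are flagged
    in the tables' attrs.
    """
    names = list(partitions)
    assigns = {k: (v.assignment if isinstance(v, Partition) else v)
               for k, v in partitions.items()}
    rows, tables = [], {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = assigns[a].index.intersection(assigns[b].index)
            if len(shared) < 2:
                raise ValueError(f"datasets {a!r} and {b!r} share fewer than 2 nodes")
            pa, pb = assigns[a].loc[shared], assigns[b].loc[shared]
            ct = pd.crosstab(pa, pb)
            ct.attrs["absent_from_" + b] = assigns[a].index.difference(shared).tolist()
            ct.attrs["absent_from_" + a] = assigns[b].index.difference(shared).tolist()
            tables[(a, b)] = ct
            rows.append({"dataset_a": a, "dataset_b": b,
                         "n_shared": int(len(shared)),
                         "zrand": zrand(pa, pb)})
    return pd.DataFrame(rows), tables
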