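"""Network-inference benchmark harness.

Scores how well an undirected network inferred from a count table recovers
the ground-truth interaction network. Includes:

* a zero-aware centred log-ratio transform (``clrm``) that normalises the
  nonzero part of a composition by its geometric mean and passes zeros
  through untouched;
* a naive baseline inference method — Pearson correlation on transformed
  counts with an empirical permutation test and multiple-testing
  correction;
* edge-recovery scoring with the Matthews correlation coefficient over
  unordered taxon pairs;
* topological descriptors (diameter, radius, mean distance, mean
  clustering, degree histogram, betweenness) with explicit "undefined"
  markers for disconnected graphs: the diameter is the maximum over
  connected components, the radius the minimum over components but
  undefined when an isolated node exists, and the mean distance is
  undefined unless the graph is connected.

Externally inferred networks (e.g. from partial-correlation methods) can
be scored by passing any symmetric binary adjacency to :func:`mcc` and
:func:`topology_metrics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._rng import coerce_rng
from .netgen import InteractionNetwork

__all__ = [
    "InferredNetwork",
    "TopologyReport",
    "clrm_transform",
    "infer_pearson_network",
    "to_undirected_truth",
    "mcc",
    "mcc_from_confusion",
    "topology_metrics",
    "write_inferred_edges_tsv",
    "write_topology_report",
]


def clrm_transform(Yk, log: bool = False) -> np.ndarray:
    """Zero-aware centred log-ratio transform of one sample.

    Nonzero entries are divided by the geometric mean of the nonzero
    entries (so their product becomes one); zeros pass through unchanged.
    With ``log=True`` the transformed nonzero entries are logged (zeros
    stay zero), which is the form fed to Pearson correlation.
    """
    y = np.asarray(Yk, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    nz = y != 0
    if not nz.any():
        raise ValueError("cannot transform an all-zero composition")
    gmean = math.exp(np.mean(np.log(y[nz])))
    out = np.zeros_like(y)
    out[nz] = y[nz] / gmean
    if log:
        out[nz] = np.log(out[nz])
    return out


@dataclass
class InferredNetwork:
    """Symmetric binary adjacency with per-pair statistics."""

    adjacency: np.ndarray
    r: np.ndarray
    p: np.ndarray
    q: np.ndarray
    meta: dict = field(default_factory=dict)


def _pairwise_pearson(Z: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations; zero-variance rows give r = 0."""
    sd = Z.std(axis=1)
    ok = sd > 0
    r = np.zeros((Z.shape[0], Z.shape[0]))
    if ok.sum() >= 2:
        sub = np.corrcoef(Z[ok])
        r[np.ix_(ok, ok)] = np.nan_to_num(sub, nan=0.0)
    np.fill_diagonal(r, 0.0)
    return r


def infer_pearson_network(
    Y: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
    seed=None,
    log: bool = True,
) -> InferredNetwork:
    """Pearson-with-permutation baseline inference.

    Each sample column is clrm-transformed, pairwise Pearson correlations
    are computed across samples, and a two-sided empirical null is built by
    shuffling each taxon's samples independently ``n_perm`` times:
    ``p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm)``. Edges passing the
    multiple-testing correction at level ``alpha`` are kept. Constant
    (zero-variance) taxa never gain edges.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1 for a non-degenerate null")
    Y = np.asarray(Y)
    S, B = Y.shape
    if B < 3:
        raise ValueError("at least 3 samples are required")
    rng = coerce_rng(seed)
    Z = np.column_stack([clrm_transform(Y[:, k], log=log) for k in range(B)])
    r_obs = _pairwise_pearson(Z)
    exceed = np.zeros((S, S), dtype=np.int64)
    abs_obs = np.abs(r_obs)
    for _ in range(n_perm):
        # independent within-taxon sample shuffles break the pairing
        perm = np.argsort(rng.random((S, B)), axis=1)
        Zp = np.take_along_axis(Z, perm, axis=1)
        r_perm = _pairwise_pearson(Zp)
        exceed += np.abs(r_perm) >= abs_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    constant = Z.std(axis=1) == 0
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(p, 1.0)
    iu = np.triu_indices(S, k=1)
    reject, q_flat, _, _ = multipletests(p[iu], alpha=alpha, method=correction)
    q = np.ones((S, S))
    q[iu] = q_flat
    q = np.minimum(q, q.T)
    adj = np.zeros((S, S), dtype=bool)
    adj[iu] = reject
    adj |= adj.T
    meta = {
        "method": "pearson+permutation",
        "n_perm": n_perm,
        "alpha": alpha,
        "correction": correction,
        "null": "independent within-taxon sample shuffles, two-sided",
        "clr_mode": "log" if log else "ratio",
    }
    return InferredNetwork(adjacency=adj, r=r_obs, p=p, q=q, meta=meta)


def to_undirected_truth(net: InteractionNetwork) -> np.ndarray:
    """Collapse the directed signed truth to a symmetric binary adjacency
    over taxa (ENV stripped, signs and orientation discarded)."""
    A = net.taxa_only().A
    return ((A != 0) | (A.T != 0)).astype(np.int8)


def mcc_from_confusion(tp: float, tn: float, fp: float, fn: float) -> float:
    """MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero
    denominator yields 0 by convention (random-classifier score)."""
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def mcc(inferred: np.ndarray, truth: np.ndarray) -> float:
    """Matthews correlation coefficient of edge recovery, counted over
    unordered taxon pairs (ENV must already be stripped)."""
    inferred = np.asarray(inferred)
    truth = np.asarray(truth)
    if inferred.shape != truth.shape or inferred.shape[0] != inferred.shape[1]:
        raise ValueError("inferred and truth adjacencies must share the node set")
    iu = np.triu_indices(truth.shape[0], k=1)
    pred = inferred[iu] != 0
    true = truth[iu] != 0
    tp = float(np.sum(pred & true))
    tn = float(np.sum(~pred & ~true))
    fp = float(np.sum(pred & ~true))
    fn = float(np.sum(~pred & true))
    return mcc_from_confusion(tp, tn, fp, fn)


@dataclass
class TopologyReport:
    """Structural descriptors; ``None`` marks an undefined metric."""

    diameter: float | None
    radius: float | None
    mean_distance: float | None
    mean_clustering: float | None
    degree_histogram: list[int]
    betweenness: np.ndarray
    n_components: int

    def as_dict(self) -> dict:
        return {
            "diameter": self.diameter,
            "radius": self.radius,
            "mean_distance": self.mean_distance,
            "mean_clustering": self.mean_clustering,
            "n_components": self.n_components,
        }


def topology_metrics(adjacency: np.ndarray) -> TopologyReport:
    """Topology descriptors with disconnected-graph conventions.

    Diameter: max component diameter. Radius: min component radius,
    undefined when an isolated node exists. Mean distance: ordered-pair
    average, undefined unless the graph is connected with >= 2 nodes. Mean
    clustering: sum of node clustering coefficients over all S nodes
    (degree < 2 contributes 0). Betweenness: unnormalised, per unordered
    pair excluding the focal node.
    """
    adjacency = np.asarray(adjacency)
    n = adjacency.shape[0]
    if n == 0:
        return TopologyReport(None, None, None, None, [], np.array([]), 0)
    G = nx.from_numpy_array((adjacency != 0).astype(int))
    comps = [G.subgraph(c) for c in nx.connected_components(G)]
    diameter = float(max(nx.diameter(c) for c in comps))
    if any(len(c) == 1 for c in comps):
        radius = None
    else:
        radius = float(min(nx.radius(c) for c in comps))
    if len(comps) == 1 and n >= 2:
        total = sum(
            d for _, lengths in nx.all_pairs_shortest_path_length(G)
            for d in lengths.values()
        )
        mean_distance = total / (n * (n - 1))
    else:
        mean_distance = None
    mean_clustering = float(nx.average_clustering(G)) if n else None
    betweenness = np.array(
        [nx.betweenness_centrality(G, normalized=False)[i] for i in range(n)]
    )
    return TopologyReport(
        diameter=diameter,
        radius=radius,
        mean_distance=mean_distance,
        mean_clustering=mean_clustering,
        degree_histogram=nx.degree_histogram(G),
        betweenness=betweenness,
        n_components=len(comps),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_inferred_edges_tsv(inet: InferredNetwork, taxa: list[str], path) -> None:
    iu = np.triu_indices(inet.adjacency.shape[0], k=1)
    keep = inet.adjacency[iu]
    pd.DataFrame(
        {
            "source": [taxa[i] for i in iu[0][keep]],
            "target": [taxa[j] for j in iu[1][keep]],
            "r": inet.r[iu][keep],
            "p": inet.p[iu][keep],
            "q": inet.q[iu][keep],
        }
    ).to_csv(path, sep="\t", index=False)


def write_topology_report(report: TopologyReport, path, prefix: str = "") -> None:
    with open(path, "a") as fh:
        for key, val in report.as_dict().items():
            fh.write(f"{prefix}{key}\t{'undefined' if val is None else val}\n")
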