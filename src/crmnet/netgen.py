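"""Directed, signed microbial interaction networks.

A community of ``S`` taxa is described by a square adjacency matrix ``A``
with entries in ``{-1, 0, +1}``: ``A[i, j] = +1`` means taxon ``i`` feeds
taxon ``j`` (``i`` produces a metabolite that ``j`` consumes), while a
mutual ``-1`` pair marks competition for a shared metabolite. Two
generators are provided — Erdős–Rényi digraphs and a directed variant of
Barabási–Albert preferential attachment — together with the transforms
that make a network interpretable as a consumer-resource system:

* :func:`assign_competitions` converts a fraction of connected pairs into
  mutual competition;
* :func:`disambiguate_competitor_outputs` forces competitors to share
  positive out-neighbours, which makes the network-to-(C, D) map
  invertible;
* :func:`augment_environment` appends the environment (ENV) node that
  supplies source taxa and absorbs waste, closing the energy balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import coerce_rng

__all__ = [
    "InteractionNetwork",
    "NetworkGenParams",
    "generate_er",
    "generate_ba",
    "generate_network",
    "assign_competitions",
    "disambiguate_competitor_outputs",
    "augment_environment",
    "read_adjacency_csv",
    "write_adjacency_csv",
    "write_edgelist_tsv",
]

ENV_LABEL = "ENV"


@dataclass
class InteractionNetwork:
    """Directed signed interaction network.

    Attributes
    ----------
    A : ndarray of int8, shape (n, n)
        Signed adjacency, entries in {-1, 0, +1}; zero diagonal. When
        ``has_env`` the ENV node occupies the last index.
    labels : list of str
        Node labels; the last one is ``"ENV"`` when ``has_env``.
    has_env : bool
        Whether the environment node has been appended.
    topology_meta : dict
        Generator name and parameters for provenance.
    """

    A: np.ndarray
    labels: list[str] = field(default_factory=list)
    has_env: bool = False
    topology_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.int8)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not self.labels:
            n_tax = self.A.shape[0] - (1 if self.has_env else 0)
            self.labels = [f"t{i + 1}" for i in range(n_tax)]
            if self.has_env:
                self.labels.append(ENV_LABEL)
        if len(self.labels) != self.A.shape[0]:
            raise ValueError("label count does not match adjacency size")
        self.validate()

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def S(self) -> int:
        """Number of taxa (ENV excluded)."""
        return self.n_nodes - (1 if self.has_env else 0)

    @property
    def env_index(self) -> int:
        if not self.has_env:
            raise ValueError("network has no ENV node")
        return self.n_nodes - 1

    def validate(self) -> None:
        A = self.A
        if np.any(np.diag(A) != 0):
            raise ValueError("self-interactions are not allowed (nonzero diagonal)")
        if not np.isin(A, (-1, 0, 1)).all():
            raise ValueError("adjacency entries must be in {-1, 0, +1}")
        neg = A == -1
        if not np.array_equal(neg, neg.T):
            raise ValueError("negative edges must be mutual: A[i,j]=-1 requires A[j,i]=-1")
        if self.has_env:
            env = self.env_index
            if np.any(A[env, :] == -1) or np.any(A[:, env] == -1):
                raise ValueError("ENV cannot take part in competition")

    def copy(self) -> "InteractionNetwork":
        return replace(
            self,
            A=self.A.copy(),
            labels=list(self.labels),
            topology_meta=dict(self.topology_meta),
        )

    def taxa_only(self) -> "InteractionNetwork":
        """Return the network restricted to taxa (ENV row/column dropped)."""
        if not self.has_env:
            return self.copy()
        s = self.S
        return InteractionNetwork(
            A=self.A[:s, :s].copy(),
            labels=list(self.labels[:s]),
            has_env=False,
            topology_meta=dict(self.topology_meta),
        )


@dataclass
class NetworkGenParams:
    """Parameters of the topology generators.

    ``p`` is the ER connection probability for each ordered pair; ``k`` is
    the number of seed nodes (and attachments per new node) of the directed
    BA model; ``nneg`` is the fraction of connected unordered pairs turned
    into mutual competition.
    """

    topology: str = "er"
    S: int = 50
    p: float | None = None
    k: int | None = None
    nneg: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.topology not in ("er", "ba"):
            raise ValueError(f"unknown topology {self.topology!r} (expected 'er' or 'ba')")
        if self.S < 2:
            raise ValueError("S must be at least 2")
        if not 0.0 <= self.nneg <= 1.0:
            raise ValueError("nneg must lie in [0, 1]")
        if self.topology == "er":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise ValueError("ER topology requires p in [0, 1]")
        if self.topology == "ba":
            if self.k is None or self.k < 1:
                raise ValueError("BA topology requires k >= 1")
            if self.k >= self.S:
                raise ValueError("BA topology requires k < S")


def generate_er(params: NetworkGenParams) -> InteractionNetwork:
    """Erdős–Rényi digraph: each ordered pair (i, j), i != j, carries a +1
    edge independently with probability ``p``."""
    if params.topology != "er":
        raise ValueError("params.topology must be 'er'")
    rng = coerce_rng(params.seed)
    S = params.S
    A = (rng.random((S, S)) < params.p).astype(np.int8)
    np.fill_diagonal(A, 0)
    meta = {"generator": "er", "S": S, "p": params.p, "seed": params.seed}
    return InteractionNetwork(A=A, has_env=False, topology_meta=meta)


def generate_ba(params: NetworkGenParams) -> InteractionNetwork:
    """Directed Barabási–Albert scale-free network.

    Growth starts from ``k`` unconnected seed nodes; every new node makes
    ``k`` attachments to distinct existing nodes chosen proportionally to
    total degree (uniformly while all degrees are zero). Each attachment is
    oriented away from the new node, towards it, or both, with probability
    1/3 each.
    """
    if params.topology != "ba":
        raise ValueError("params.topology must be 'ba'")
    rng = coerce_rng(params.seed)
    S, k = params.S, params.k
    A = np.zeros((S, S), dtype=np.int8)
    deg = np.zeros(S, dtype=np.int64)
    for new in range(k, S):
        weights = deg[:new].astype(float).copy()
        targets: list[int] = []
        for _ in range(k):
            if weights.sum() <= 0:
                probs = np.ones(new)
                probs[targets] = 0.0
                probs /= probs.sum()
            else:
                probs = weights / weights.sum()
            t = int(rng.choice(new, p=probs))
            targets.append(t)
            weights[t] = 0.0  # sample targets without replacement
        for t in targets:
            orient = rng.integers(3)
            if orient == 0:  # outgoing from the new node
                A[new, t] = 1
                deg[new] += 1
                deg[t] += 1
            elif orient == 1:  # ingoing to the new node
                A[t, new] = 1
                deg[new] += 1
                deg[t] += 1
            else:  # bidirectional
                A[new, t] = 1
                A[t, new] = 1
                deg[new] += 2
                deg[t] += 2
    meta = {"generator": "ba", "S": S, "k": k, "seed": params.seed}
    return InteractionNetwork(A=A, has_env=False, topology_meta=meta)


def generate_network(params: NetworkGenParams) -> InteractionNetwork:
    """Dispatch on ``params.topology``."""
    return generate_er(params) if params.topology == "er" else generate_ba(params)


def _connected_pairs(A: np.ndarray) -> list[tuple[int, int]]:
    conn = (A != 0) | (A.T != 0)
    iu = np.triu_indices(A.shape[0], k=1)
    mask = conn[iu]
    return list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))


def assign_competitions(
    net: InteractionNetwork, nneg: float, seed=None
) -> InteractionNetwork:
    """Convert a fraction ``nneg`` of connected node pairs into mutual
    competition (both directions set to -1)."""
    if net.has_env:
        raise ValueError("assign_competitions must run before ENV augmentation")
    if not 0.0 <= nneg <= 1.0:
        raise ValueError("nneg must lie in [0, 1]")
    rng = coerce_rng(seed)
    out = net.copy()
    pairs = _connected_pairs(out.A)
    n_comp = int(np.rint(nneg * len(pairs)))
    if n_comp > 0:
        chosen = rng.choice(len(pairs), size=n_comp, replace=False)
        for idx in chosen:
            i, j = pairs[idx]
            out.A[i, j] = -1
            out.A[j, i] = -1
    out.topology_meta["nneg"] = nneg
    out.validate()
    return out


def disambiguate_competitor_outputs(net: InteractionNetwork) -> InteractionNetwork:
    """Make competitors share positive out-neighbours.

    In a consumer-resource model every consumer of a metabolite acquires
    the same by-product rules, so two competing taxa are indistinguishable
    as producers. To keep the network-to-(C, D) map one-to-one, the
    positive out-neighbour sets of each mutual-negative pair are replaced
    by their union (never adding an edge towards the pair itself, and never
    overwriting an existing negative edge), iterated to a fixed point.
    """
    if net.has_env:
        raise ValueError("disambiguation must run before ENV augmentation")
    out = net.copy()
    A = out.A
    iu = np.triu_indices(A.shape[0], k=1)
    changed = True
    while changed:
        changed = False
        neg_i, neg_j = iu[0][A[iu] == -1], iu[1][A[iu] == -1]
        for i, j in zip(neg_i.tolist(), neg_j.tolist()):
            union = np.where((A[i, :] == 1) | (A[j, :] == 1))[0]
            for t in union:
                if t in (i, j):
                    continue
                for src in (i, j):
                    if A[src, t] == 0:
                        A[src, t] = 1
                        changed = True
    out.validate()
    return out


def augment_environment(net: InteractionNetwork) -> InteractionNetwork:
    """Append the ENV node and close the production/consumption balance.

    Every taxon must both consume and produce something. A taxon with no
    positive out-edge produces nothing and is wired to ENV (it will secrete
    waste); a taxon with no in-edge of any sign and no negative edge
    consumes nothing and receives an edge from ENV (it will feed on a
    supplied nutrient). Negative edges count as consumption but not
    production.
    """
    if net.has_env:
        raise ValueError("network already has an ENV node")
    S = net.A.shape[0]
    A = np.zeros((S + 1, S + 1), dtype=np.int8)
    A[:S, :S] = net.A
    env = S
    for i in range(S):
        produces = np.any(net.A[i, :] == 1)
        if not produces:
            A[i, env] = 1
        consumes = np.any(net.A[:, i] != 0)  # any in-edge, or mutual -1
        if not consumes:
            A[env, i] = 1
    labels = list(net.labels) + [ENV_LABEL]
    return InteractionNetwork(
        A=A, labels=labels, has_env=True, topology_meta=dict(net.topology_meta)
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_adjacency_csv(net: InteractionNetwork, path) -> None:
    """Dense CSV with taxon labels as header row and index column."""
    df = pd.DataFrame(net.A, index=net.labels, columns=net.labels)
    df.to_csv(path)


def read_adjacency_csv(path) -> InteractionNetwork:
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    if list(df.index.astype(str)) != labels:
        raise ValueError("adjacency CSV row and column labels disagree")
    has_env = bool(labels) and labels[-1] == ENV_LABEL
    return InteractionNetwork(
        A=df.to_numpy(dtype=np.int8), labels=labels, has_env=has_env
    )


def write_edgelist_tsv(net: InteractionNetwork, path) -> None:
    """TSV edge list with columns source, target, sign."""
    src, tgt = np.nonzero(net.A)
    rows = {
        "source": [net.labels[i] for i in src],
        "target": [net.labels[j] for j in tgt],
        "sign": net.A[src, tgt].astype(int),
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
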