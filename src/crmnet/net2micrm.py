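"""Translate an interaction network into consumer-resource parameters.

The translation runs in three deterministic passes over the ENV-augmented
adjacency matrix ``A``:

1. metabolite–edge association: every nonempty set of positive in-edges of
   a taxon shares one fresh metabolite; every mutual-negative pair gets a
   private metabolite; all edges into ENV carry the waste metabolite ``w``
   (always allocated last, consumed by no taxon);
2. metabolite–node association: for a positive edge the source produces
   and the target consumes the edge metabolite; for a negative edge both
   endpoints consume it;
3. matrix assembly: the consumer-preference matrix ``C`` (taxa x
   metabolites) is the consumption slice, and the metabolic matrix ``D``
   (produced x consumed) couples every metabolite a taxon consumes to every
   metabolite it produces, columns normalised to sum one.

Metabolites are numbered 1..M in the edge map (0 = no metabolite); column
``m - 1`` of ``C``/``D`` corresponds to metabolite ``m``. The inverse map
:func:`reconstruct_network` recovers ``A`` from ``(C, D)`` and is the
correctness oracle for the uniqueness of the translation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import coerce_rng
from .netgen import InteractionNetwork

__all__ = [
    "CONSUMPTION",
    "PRODUCTION",
    "MetaboliteEdgeMap",
    "WeightSamplingSpec",
    "MicrmSystem",
    "assign_metabolites_to_edges",
    "assign_metabolites_to_nodes",
    "build_consumer_and_metabolic_matrices",
    "interpret_network",
    "reconstruct_network",
    "metabolite_labels",
    "write_matrix_csv",
    "read_matrix_csv",
]

CONSUMPTION = 0
PRODUCTION = 1


@dataclass
class MetaboliteEdgeMap:
    """Metabolite id per edge (0 = none, ids 1..M; waste id = M)."""

    Me: np.ndarray
    M: int

    @property
    def w_index(self) -> int:
        """1-based id of the waste metabolite (always the last one)."""
        return self.M


@dataclass
class WeightSamplingSpec:
    """How to turn the binary C/D entries into quantitative weights.

    ``target`` is ``"C_rows"`` or ``"D_columns"``; ``distribution`` one of
    ``binary`` (leave as is), ``normal`` (loc/scale, truncated positive by
    resampling), ``gamma`` (shape/scale) or ``dirichlet`` (concentration
    ``alpha`` over the nonzero support of each row/column). Zeros are never
    touched, so the sparsity pattern — and hence the encoded network — is
    preserved.
    """

    target: str = "D_columns"
    distribution: str = "binary"
    loc: float = 1.0
    scale: float = 0.25
    shape: float = 2.0
    alpha: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.target not in ("C_rows", "D_columns"):
            raise ValueError("target must be 'C_rows' or 'D_columns'")
        if self.distribution not in ("binary", "normal", "gamma", "dirichlet"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "normal" and self.scale <= 0:
            raise ValueError("normal sampling requires scale > 0")
        if self.distribution == "gamma" and (self.shape <= 0 or self.scale <= 0):
            raise ValueError("gamma sampling requires shape > 0 and scale > 0")
        if self.distribution == "dirichlet" and self.alpha <= 0:
            raise ValueError("dirichlet sampling requires alpha > 0")


@dataclass
class MicrmSystem:
    """Bundle of everything the translation produces."""

    C: np.ndarray  # S x M consumer preferences (taxa only)
    D: np.ndarray  # M x M metabolic rules, columns sum to 1 on support
    Me: np.ndarray  # (S+1) x (S+1) metabolite-edge map
    Ms: np.ndarray  # M x (S+1) x 2 metabolite-node map
    M: int
    w_index: int  # 1-based waste id
    taxa: list[str]

    @property
    def waste_col(self) -> int:
        """0-based column of the waste metabolite in C and D."""
        return self.w_index - 1


def assign_metabolites_to_edges(net: InteractionNetwork) -> MetaboliteEdgeMap:
    """Metabolite–edge association pass (see module docstring).

    Scans taxa in index order, so metabolite ids are bit-reproducible.
    """
    if not net.has_env:
        raise ValueError("network must be ENV-augmented first")
    A = net.A
    n = A.shape[0]
    env = n - 1
    Me = np.zeros((n, n), dtype=np.int64)
    m = 0
    for j in range(env):  # taxa only; ENV handled by the waste pass
        pos_in = np.where(A[:, j] > 0)[0]
        if pos_in.size:
            m += 1
            Me[pos_in, j] = m
        neg_in = np.where(A[:, j] < 0)[0]
        for i in neg_in:
            if i > j:  # each unordered pair allocated once
                m += 1
                Me[i, j] = m
                Me[j, i] = m
    env_pos_in = np.where(A[:, env] > 0)[0]
    M = w = m + 1  # waste is allocated even when no taxon secretes it
    if env_pos_in.size:
        Me[env_pos_in, env] = w
    return MetaboliteEdgeMap(Me=Me, M=M)


def assign_metabolites_to_nodes(
    net: InteractionNetwork, me: MetaboliteEdgeMap
) -> np.ndarray:
    """Metabolite–node association: returns Ms of shape (M, S+1, 2).

    ``Ms[m, i, CONSUMPTION] = 1`` when node ``i`` consumes metabolite
    ``m + 1``; the PRODUCTION slice marks producers. Positive edge: source
    produces, target consumes. Negative edge: both endpoints consume.
    """
    A = net.A
    if (me.Me != 0).astype(bool).tolist() != (A != 0).astype(bool).tolist():
        raise ValueError("metabolite-edge map does not match the adjacency support")
    n = A.shape[0]
    Ms = np.zeros((me.M, n, 2), dtype=np.int8)
    src, tgt = np.nonzero(A)
    for i, j in zip(src.tolist(), tgt.tolist()):
        m = me.Me[i, j] - 1
        if A[i, j] > 0:
            Ms[m, i, PRODUCTION] = 1
            Ms[m, j, CONSUMPTION] = 1
        else:
            Ms[m, i, CONSUMPTION] = 1
            Ms[m, j, CONSUMPTION] = 1
    return Ms


def _sample_positive(rng, distribution: str, spec: WeightSamplingSpec, size: int):
    if distribution == "normal":
        vals = rng.normal(spec.loc, spec.scale, size)
        while np.any(vals <= 0):  # truncate at zero by resampling
            bad = vals <= 0
            vals[bad] = rng.normal(spec.loc, spec.scale, bad.sum())
        return vals
    if distribution == "gamma":
        return rng.gamma(spec.shape, spec.scale, size)
    raise AssertionError(distribution)


def _apply_sampling(C: np.ndarray, D: np.ndarray, spec: WeightSamplingSpec) -> None:
    if spec.distribution == "binary":
        return
    rng = coerce_rng(spec.seed)
    if spec.target == "C_rows":
        for i in range(C.shape[0]):
            nz = np.nonzero(C[i])[0]
            if nz.size == 0:
                continue
            if spec.distribution == "dirichlet":
                C[i, nz] = rng.dirichlet(np.full(nz.size, spec.alpha))
            else:
                C[i, nz] = _sample_positive(rng, spec.distribution, spec, nz.size)
    else:
        for a in range(D.shape[1]):
            nz = np.nonzero(D[:, a])[0]
            if nz.size == 0:
                continue
            if spec.distribution == "dirichlet":
                D[nz, a] = rng.dirichlet(np.full(nz.size, spec.alpha))
            else:
                D[nz, a] = _sample_positive(rng, spec.distribution, spec, nz.size)


def build_consumer_and_metabolic_matrices(
    Ms: np.ndarray, sampling: WeightSamplingSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble C (taxa x M) and D (M x M) from the metabolite-node map.

    ENV is excluded from the metabolic loop: its inputs are modelled by the
    external supply term, and recycling waste back into nutrients would
    violate the waste definition. Nonzero columns of D are normalised to
    sum one.
    """
    M, n, _ = Ms.shape
    C = Ms[:, :, CONSUMPTION].T[: n - 1].astype(float)  # drop the ENV row
    D = np.zeros((M, M), dtype=float)
    for i in range(n - 1):  # taxa only
        cons = np.nonzero(Ms[:, i, CONSUMPTION])[0]
        prod = np.nonzero(Ms[:, i, PRODUCTION])[0]
        if cons.size and prod.size:
            D[np.ix_(prod, cons)] = 1.0
    if sampling is not None:
        _apply_sampling(C, D, sampling)
    colsum = D.sum(axis=0)
    nz = colsum > 0
    D[:, nz] /= colsum[nz]
    return C, D


def interpret_network(
    net: InteractionNetwork, sampling: WeightSamplingSpec | None = None
) -> MicrmSystem:
    """Run all three translation passes on an augmented network."""
    me = assign_metabolites_to_edges(net)
    Ms = assign_metabolites_to_nodes(net, me)
    C, D = build_consumer_and_metabolic_matrices(Ms, sampling)
    return MicrmSystem(
        C=C,
        D=D,
        Me=me.Me,
        Ms=Ms,
        M=me.M,
        w_index=me.w_index,
        taxa=list(net.labels[: net.S]),
    )


def reconstruct_network(C: np.ndarray, D: np.ndarray) -> InteractionNetwork:
    """Inverse map: rebuild the augmented adjacency matrix from (C, D).

    Only the sparsity patterns matter, so sampled weights do not affect the
    result. Shared consumption of a metabolite means mutual competition
    (which takes precedence over any positive evidence the coupled D rules
    may suggest); a metabolite with a single consumer is that taxon's feed,
    and whoever produces it per D points a positive edge at the consumer.
    Metabolites without taxon producers are supplied by ENV; metabolites
    without taxon consumers are waste, and their producers feed ENV.
    """
    C = np.asarray(C)
    D = np.asarray(D)
    S, M = C.shape
    env = S
    A = np.zeros((S + 1, S + 1), dtype=np.int8)
    cons = [set(np.nonzero(C[i])[0].tolist()) for i in range(S)]
    consumers_of = [set() for _ in range(M)]
    for i in range(S):
        for m in cons[i]:
            consumers_of[m].add(i)
    produced_rows = D.sum(axis=1) > 0  # metabolite has >=1 taxon producer
    products = []
    for i in range(S):
        prods: set[int] = set()
        for a in cons[i]:
            prods.update(np.nonzero(D[:, a])[0].tolist())
        products.append(prods)
    # competition first: it wins over coupled positive evidence
    for i in range(S):
        for j in range(i + 1, S):
            if cons[i] & cons[j]:
                A[i, j] = -1
                A[j, i] = -1
    single = [
        {m for m in cons[j] if len(consumers_of[m]) == 1} for j in range(S)
    ]
    for i in range(S):
        for j in range(S):
            if i == j or A[i, j] != 0:
                continue
            if products[i] & single[j]:
                A[i, j] = 1
    for i in range(S):
        if any(len(consumers_of[m]) == 0 for m in products[i]):
            A[i, env] = 1  # produces waste
        if any(not produced_rows[m] for m in single[i]):
            A[env, i] = 1  # feeds on an ENV-supplied metabolite
    return InteractionNetwork(A=A, has_env=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def metabolite_labels(M: int) -> list[str]:
    """m1..m(M-1) plus the waste metabolite labelled 'w'."""
    return [f"m{i + 1}" for i in range(M - 1)] + ["w"]


def write_matrix_csv(mat: np.ndarray, path, index: list[str], columns: list[str]) -> None:
    pd.DataFrame(mat, index=index, columns=columns).to_csv(path)


def read_matrix_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
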