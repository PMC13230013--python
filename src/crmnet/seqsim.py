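"""Synthetic 16S rDNA-seq count tables.

Sequencing reads a library of ``l_k`` molecules per sample without
replacement from the finite pool of cells present, which a multivariate
hypergeometric distribution models exactly:

    Y_k ~ MultivariateHypergeometric(n = l_k, m = X_k)

where ``X_k`` is the (quantised) vector of absolute abundances of sample
``k``. Sampling without replacement preserves compositionality (column
sums equal the library sizes exactly), the dependence between taxa, and
sparsity — a taxon absent from the community can never receive reads, and
rare taxa may drop out, adding technical zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import coerce_rng

__all__ = [
    "CountTable",
    "LibrarySizeSpec",
    "quantize_abundances",
    "mvhyper_sample",
    "draw_library_sizes",
    "simulate_counts",
    "write_count_table_tsv",
    "read_count_table_tsv",
]


@dataclass
class LibrarySizeSpec:
    """Library sizes per sample.

    ``constant`` uses ``value`` for every sample; ``user_list`` takes
    ``values`` verbatim; ``lognormal`` draws from
    LogNormal(meanlog, sdlog), rounded to integers >= 1. The default
    emulates typical 16S sequencing depths around 5e4 reads.
    """

    mode: str = "lognormal"
    value: int = 50_000
    values: list[int] = field(default_factory=list)
    meanlog: float = math.log(5e4)
    sdlog: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "user_list", "lognormal"):
            raise ValueError(f"unknown library-size mode {self.mode!r}")
        if self.mode == "constant" and self.value < 1:
            raise ValueError("library sizes must be >= 1")
        if self.mode == "user_list" and any(v < 1 for v in self.values):
            raise ValueError("library sizes must be >= 1")


@dataclass
class CountTable:
    Y: np.ndarray  # S x B integer counts
    library_sizes: np.ndarray
    taxa: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if not self.taxa:
            self.taxa = [f"t{i + 1}" for i in range(self.Y.shape[0])]
        if not self.samples:
            self.samples = [f"s{k + 1}" for k in range(self.Y.shape[1])]


def quantize_abundances(X: np.ndarray, pool_scale: float = 1.0) -> np.ndarray:
    """Scale each abundance by ``pool_scale`` and round half-to-even.

    The hypergeometric pool must be integer; zeros are preserved for any
    scale, so structural absences survive quantisation.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("abundances must be nonnegative")
    if pool_scale <= 0:
        raise ValueError("pool_scale must be positive")
    return np.rint(X * pool_scale).astype(np.int64)


def mvhyper_sample(m, l_k: int, seed=None) -> np.ndarray:
    """One multivariate hypergeometric draw of ``l_k`` reads from pool ``m``.

    Delegates to numpy's sequential conditional sampler, which draws each
    category from the exact univariate hypergeometric conditional.
    """
    m = np.asarray(m, dtype=np.int64)
    if np.any(m < 0):
        raise ValueError("pool counts must be nonnegative")
    if m.sum() < l_k:
        raise ValueError(
            f"library size {l_k} exceeds pool total {int(m.sum())}; "
            "increase pool_scale"
        )
    rng = coerce_rng(seed)
    return rng.multivariate_hypergeometric(m, int(l_k), method="marginals")


def draw_library_sizes(spec: LibrarySizeSpec, B: int, seed=None) -> np.ndarray:
    if spec.mode == "constant":
        return np.full(B, spec.value, dtype=np.int64)
    if spec.mode == "user_list":
        if len(spec.values) != B:
            raise ValueError(f"expected {B} library sizes, got {len(spec.values)}")
        return np.asarray(spec.values, dtype=np.int64)
    rng = coerce_rng(seed)
    draws = np.rint(rng.lognormal(spec.meanlog, spec.sdlog, B)).astype(np.int64)
    return np.maximum(draws, 1)


def simulate_counts(
    X: np.ndarray,
    libspec: LibrarySizeSpec | None = None,
    pool_scale: float | str = 1.0,
    seed=None,
    taxa: list[str] | None = None,
) -> CountTable:
    """Quantise abundances and sequence every sample column independently.

    ``pool_scale="auto"`` rescales the pool so that the smallest column
    total is at least 100x the largest library size, approximating the
    large-pool (multinomial) regime when absolute abundances are small.
    """
    libspec = libspec or LibrarySizeSpec()
    rng = coerce_rng(seed)
    X = np.asarray(X, dtype=float)
    B = X.shape[1]
    lib = draw_library_sizes(libspec, B, rng)
    if pool_scale == "auto":
        min_total = X.sum(axis=0).min()
        if min_total <= 0:
            raise ValueError("a sample column is entirely zero; cannot sequence")
        pool_scale = max(1.0, 100.0 * lib.max() / min_total)
    pools = quantize_abundances(X, pool_scale)
    deficits = pools.sum(axis=0) - lib
    if np.any(deficits < 0):
        k = int(np.argmin(deficits))
        raise ValueError(
            f"sample {k}: pool total {int(pools[:, k].sum())} < library size "
            f"{int(lib[k])}; increase pool_scale"
        )
    Y = np.empty_like(pools)
    for k in range(B):
        Y[:, k] = rng.multivariate_hypergeometric(
            pools[:, k], int(lib[k]), method="marginals"
        )
    return CountTable(Y=Y, library_sizes=lib, taxa=taxa or [])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_count_table_tsv(table: CountTable, path, meta_path=None) -> None:
    pd.DataFrame(table.Y, index=table.taxa, columns=table.samples).to_csv(
        path, sep="\t"
    )
    if meta_path is not None:
        pd.DataFrame(
            {"sample": table.samples, "library_size": table.library_sizes}
        ).to_csv(meta_path, sep="\t", index=False)


def read_count_table_tsv(path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    Y = df.to_numpy(dtype=np.int64)
    return CountTable(
        Y=Y,
        library_sizes=Y.sum(axis=0),
        taxa=[str(i) for i in df.index],
        samples=[str(c) for c in df.columns],
    )
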