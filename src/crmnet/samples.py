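"""Biological-sample generation by environmental perturbation.

Starting from a converged community, each biological sample is produced by
perturbing the environment — scaling the supply rates (constant-supply
mode) or the steady-state concentrations (bolus mode) of a random subset
of resources up or down by a factor ``ps`` — and re-integrating to a new
steady state. All samples share the same consumer preferences and
metabolic rules, so they are realisations of the same underlying
interaction network under different conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import coerce_rng
from .micrm import (
    CommunityState,
    MiCRMParams,
    SteadyState,
    Supply,
    integrate_to_steady_state,
)

__all__ = [
    "PerturbationDesign",
    "SampleAbundances",
    "design_perturbations",
    "apply_perturbation",
    "generate_samples",
    "write_abundance_tsv",
    "write_sample_metadata_tsv",
]


@dataclass
class PerturbationDesign:
    """Per-sample perturbation parameters.

    ``fp[k]`` is the fraction of perturbable resources targeted in sample
    ``k``, ``ps[k] >= 1`` the scale factor, ``direction[k]`` +1 for up- and
    -1 for down-scaling, ``targets[k]`` the chosen metabolite indices.
    """

    B: int
    mode: str
    fp: np.ndarray
    ps: np.ndarray
    direction: np.ndarray
    targets: list = field(default_factory=list)
    perturbable: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if np.any((self.fp < 0) | (self.fp > 1)):
            raise ValueError("fp values must lie in [0, 1]")
        if np.any(self.ps < 1):
            raise ValueError("ps values must be >= 1")


def _draw(dist, rng, size):
    """A distribution spec is a fixed float or a (low, high) uniform range."""
    if np.isscalar(dist):
        return np.full(size, float(dist))
    low, high = dist
    return rng.uniform(low, high, size)


def design_perturbations(
    perturbable,
    B: int,
    seed=None,
    fp_dist=(0.0, 1.0),
    ps_dist=(2.0, 10.0),
    mode: str = "constant",
) -> PerturbationDesign:
    """Draw B independent perturbations.

    For each sample: ``fp ~ U(0,1)`` and ``ps ~ U(2,10)`` by default;
    ``round(fp * |perturbable|)`` target resources are picked uniformly
    without replacement and the direction (up/down) is a fair coin.
    """
    perturbable = np.asarray(perturbable, dtype=int)
    if perturbable.size == 0:
        raise ValueError("the perturbable resource set is empty")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = coerce_rng(seed)
    fp = _draw(fp_dist, rng, B)
    ps = _draw(ps_dist, rng, B)
    direction = np.where(rng.random(B) < 0.5, 1, -1)
    targets = []
    for k in range(B):
        n_t = int(np.rint(fp[k] * perturbable.size))
        targets.append(np.sort(rng.choice(perturbable, size=n_t, replace=False)))
    return PerturbationDesign(
        B=B, mode=mode, fp=fp, ps=ps, direction=direction,
        targets=targets, perturbable=perturbable,
    )


def apply_perturbation(
    ss: SteadyState,
    design: PerturbationDesign,
    k: int,
    supply: Supply,
    params: MiCRMParams,
) -> tuple[CommunityState, Supply]:
    """Perturbed initial condition and supply for sample ``k``.

    Constant mode scales the supply rates of the targets by ``ps`` (up) or
    ``1/ps`` (down), starting from the unperturbed steady state. Bolus mode
    scales the nonzero steady-state concentrations directly and turns the
    supply off.
    """
    if (design.mode == "bolus") != (supply.mode == "bolus"):
        raise ValueError(
            f"design mode {design.mode!r} does not match supply mode {supply.mode!r}"
        )
    tgt = np.asarray(design.targets[k], dtype=int)
    factor = design.ps[k] if design.direction[k] > 0 else 1.0 / design.ps[k]
    if design.mode == "constant":
        kappa = supply.kappa0.copy()
        kappa[tgt] *= factor
        new_supply = Supply(
            mode=supply.mode, kappa0=kappa, supplied_set=supply.supplied_set,
            R0=supply.R0, tau=supply.tau,
        )
        state0 = CommunityState(N=ss.Nss.copy(), R=ss.Rss.copy(), t=0.0)
    else:  # bolus: alter nonzero steady-state concentrations directly
        R = ss.Rss.copy()
        nz = tgt[R[tgt] > 0]
        R[nz] *= factor
        new_supply = Supply(
            mode="bolus", kappa0=np.zeros_like(supply.kappa0),
            supplied_set=supply.supplied_set, R0=supply.R0, tau=supply.tau,
        )
        state0 = CommunityState(N=ss.Nss.copy(), R=R, t=0.0)
    return state0, new_supply


@dataclass
class SampleAbundances:
    """Absolute abundances X (taxa x samples) with provenance."""

    X: np.ndarray
    converged: np.ndarray
    design: PerturbationDesign


def generate_samples(
    ss: SteadyState,
    design: PerturbationDesign,
    C: np.ndarray,
    D: np.ndarray,
    params: MiCRMParams,
    supply: Supply,
) -> SampleAbundances:
    """Re-integrate one perturbed run per sample; non-convergence is
    recorded per sample and does not abort the batch."""
    if not ss.converged:
        raise ValueError("base steady state did not converge")
    S = C.shape[0]
    X = np.zeros((S, design.B))
    flags = np.zeros(design.B, dtype=bool)
    for k in range(design.B):
        state0, supply_k = apply_perturbation(ss, design, k, supply, params)
        ss_k = integrate_to_steady_state(state0, C, D, params, supply_k)
        X[:, k] = ss_k.Nss
        flags[k] = ss_k.converged
    return SampleAbundances(X=X, converged=flags, design=design)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_abundance_tsv(samples: SampleAbundances, taxa: list[str], path) -> None:
    cols = [f"s{k + 1}" for k in range(samples.X.shape[1])]
    pd.DataFrame(samples.X, index=taxa, columns=cols).to_csv(path, sep="\t")


def write_sample_metadata_tsv(samples: SampleAbundances, path) -> None:
    d = samples.design
    pd.DataFrame(
        {
            "sample": [f"s{k + 1}" for k in range(d.B)],
            "fp": d.fp,
            "ps": d.ps,
            "direction": np.where(d.direction > 0, "up", "down"),
            "targets": [";".join(map(str, t)) for t in d.targets],
            "converged": samples.converged.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)
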