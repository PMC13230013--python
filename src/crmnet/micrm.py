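"""Microbial consumer-resource model (MiCRM) dynamics.

State: taxon abundances ``N`` (length S) and metabolite concentrations
``R`` (length M). Each taxon grows in proportion to its energy surplus —
the retained fraction of the energy taken up from its resources minus a
maintenance cost — while resources change through external supply,
consumer uptake and leaked by-product secretion routed by the metabolic
matrix ``D``:

    dN_i/dt = g * N_i * ( (1 - l) * w_e * sum_a C[i,a] * sigma(R_a) - m_c )
    dR_a/dt = kappa_a(R) - sum_i N_i * C[i,a] * sigma(R_a)
              + sum_i sum_b D[a,b] * l * N_i * C[i,b] * sigma(R_b)

with a uniform energy content ``w_e`` per unit resource, so the energy
ratio of secreted to consumed metabolites is one. The uptake response
``sigma`` is linear (``sigma(R) = R``) or a Hill (type III) saturating
function. Integration proceeds in chunks until the community reaches a
steady state; taxa falling below an extinction threshold are clamped to
zero at chunk boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._rng import coerce_rng

__all__ = [
    "MiCRMParams",
    "CommunityState",
    "SteadyState",
    "uptake_response",
    "community_derivatives",
    "Supply",
    "make_supply",
    "choose_supplied_set",
    "init_community",
    "integrate_to_steady_state",
    "write_steady_state_tsv",
    "write_resources_tsv",
]


@dataclass
class MiCRMParams:
    """MiCRM parameters.

    Defaults follow the canonical parameterisation of the model: unit
    conversion factor ``g`` (1/energy), unit maintenance cost ``m_c``
    (energy/time), leakage fraction ``l`` = 0.8, unit energy content
    ``w_e`` (energy/mass), intrinsic equilibrium resource abundance ``R0``
    = 1000 (mass/volume) and supply timescale ``tau`` = 1 (time), with a
    linear uptake response. ``fr`` is the fraction of non-waste metabolites
    that receive external supply.
    """

    g: float = 1.0
    m_c: float = 1.0
    l: float = 0.8
    w_e: float = 1.0
    R0: float = 1000.0
    tau: float = 1.0
    response: str = "linear"  # "linear" | "hill"
    sigma_max: float = 5.0
    n_hill: float = 2.0
    K_half: float = 20.0  # not fixed by the model definition; exposed
    supply_mode: str = "constant"  # "constant" | "bolus" | "logistic"
    fr: float = 1.0
    extinction_threshold: float = 1e-6
    ss_tol: float = 1e-6
    t_chunk: float = 100.0
    t_max: float = 1e5
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if not 0.0 <= self.l <= 1.0:
            raise ValueError("leakage l must lie in [0, 1]")
        if not 0.0 <= self.fr <= 1.0:
            raise ValueError("fr must lie in [0, 1]")
        for name in ("g", "m_c", "w_e", "R0", "tau", "sigma_max", "K_half"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.response not in ("linear", "hill"):
            raise ValueError("response must be 'linear' or 'hill'")
        if self.supply_mode not in ("constant", "bolus", "logistic"):
            raise ValueError("supply_mode must be 'constant', 'bolus' or 'logistic'")


@dataclass
class CommunityState:
    N: np.ndarray
    R: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if np.any(self.N < 0) or np.any(self.R < 0):
            raise ValueError("abundances and concentrations must be nonnegative")


@dataclass
class SteadyState:
    Nss: np.ndarray
    Rss: np.ndarray
    converged: bool
    survivors: np.ndarray  # indices of taxa above the extinction threshold
    t_elapsed: float = 0.0


def uptake_response(R_alpha, params: MiCRMParams):
    """Per-unit-affinity uptake rate sigma(R); monotone, sigma(0) = 0."""
    R_alpha = np.asarray(R_alpha, dtype=float)
    if np.any(R_alpha < 0):
        raise ValueError("resource concentrations must be nonnegative")
    if params.response == "linear":
        return R_alpha.copy() if R_alpha.ndim else float(R_alpha)
    Rn = R_alpha ** params.n_hill
    out = params.sigma_max * Rn / (params.K_half ** params.n_hill + Rn)
    return out if R_alpha.ndim else float(out)


@dataclass
class Supply:
    """External resource supply.

    ``constant``: a fixed influx ``R0/tau`` on the supplied set;
    ``logistic``: intrinsic replenishment ``(R0 - R)/tau`` towards the
    equilibrium abundance; ``bolus``: no influx — the supplied resources
    are provided once through the initial condition.
    """

    mode: str
    kappa0: np.ndarray  # constant-mode rates (zero for bolus)
    supplied_set: np.ndarray
    R0: float = 1000.0
    tau: float = 1.0

    def rate(self, R: np.ndarray) -> np.ndarray:
        if self.mode == "constant":
            return self.kappa0
        if self.mode == "logistic":
            out = np.zeros_like(self.kappa0)
            s = self.supplied_set
            out[s] = (self.R0 - R[s]) / self.tau
            return out
        return np.zeros_like(self.kappa0)


def choose_supplied_set(
    M: int, w_index: int, fr: float, seed=None
) -> np.ndarray:
    """Pick round(fr * (M - 1)) non-waste metabolites uniformly at random.

    ``w_index`` is the 1-based waste id (column ``w_index - 1``).
    """
    rng = coerce_rng(seed)
    candidates = np.array([m for m in range(M) if m != w_index - 1])
    n = int(np.rint(fr * candidates.size))
    chosen = rng.choice(candidates, size=n, replace=False)
    return np.sort(chosen)


def make_supply(
    params: MiCRMParams, supplied_set, M: int, w_index: int
) -> Supply:
    """Build the supply term for the chosen metabolite set."""
    supplied_set = np.asarray(supplied_set, dtype=int)
    if np.any(supplied_set == w_index - 1):
        raise ValueError("waste metabolite cannot be supplied")
    if supplied_set.size and (supplied_set.min() < 0 or supplied_set.max() >= M):
        raise ValueError("supplied metabolite index out of range")
    kappa0 = np.zeros(M)
    if params.supply_mode == "constant":
        kappa0[supplied_set] = params.R0 / params.tau
    return Supply(
        mode=params.supply_mode,
        kappa0=kappa0,
        supplied_set=supplied_set,
        R0=params.R0,
        tau=params.tau,
    )


def init_community(
    C: np.ndarray,
    params: MiCRMParams,
    supply: Supply,
    init_spec="lognormal",
    seed=None,
    meanlog: float = 0.0,
    sdlog: float = 2.0,
) -> CommunityState:
    """Initial condition: abundances from a heavy-tailed sampler (default
    log-normal, emulating the skewness of real 16S count tables), a
    constant, or a user-provided vector; resources set to R0 on the
    supplied set (the environment is equilibrated before taxa are
    introduced) and zero elsewhere."""
    S, M = C.shape
    rng = coerce_rng(seed)
    if isinstance(init_spec, str):
        if init_spec != "lognormal":
            raise ValueError(f"unknown init spec {init_spec!r}")
        N0 = rng.lognormal(meanlog, sdlog, S)
    elif np.isscalar(init_spec):
        N0 = np.full(S, float(init_spec))
    else:
        N0 = np.asarray(init_spec, dtype=float)
        if N0.shape != (S,):
            raise ValueError(f"initial abundance vector must have length {S}")
    if np.any(N0 <= 0):
        raise ValueError("initial abundances must be strictly positive")
    R0vec = np.zeros(M)
    R0vec[supply.supplied_set] = params.R0
    return CommunityState(N=N0, R=R0vec, t=0.0)


def _response_derivative(R: np.ndarray, params: MiCRMParams) -> np.ndarray:
    """d sigma / dR, used by the analytic Jacobian."""
    if params.response == "linear":
        return np.ones_like(R)
    Kn = params.K_half ** params.n_hill
    Rn = R ** params.n_hill
    with np.errstate(divide="ignore", invalid="ignore"):
        d = params.sigma_max * params.n_hill * Kn * Rn / (
            np.where(R > 0, R, 1.0) * (Kn + Rn) ** 2
        )
    return np.where(R > 0, d, 0.0)


def _rhs_factory(C: np.ndarray, D: np.ndarray, params: MiCRMParams, supply: Supply):
    g, mc, l, we = params.g, params.m_c, params.l, params.w_e
    retained = (1.0 - l) * we
    S, M = C.shape

    def rhs(t, y):
        N = np.maximum(y[:S], 0.0)
        R = np.maximum(y[S:], 0.0)
        sig = uptake_response(R, params)
        energy = retained * (C @ sig) - mc
        dN = g * N * energy
        flux = (N @ C) * sig  # total uptake flux per metabolite
        dR = supply.rate(R) - flux + D @ (l * flux)
        return np.concatenate([dN, dR])

    def jac(t, y):
        N = np.maximum(y[:S], 0.0)
        R = np.maximum(y[S:], 0.0)
        sig = uptake_response(R, params)
        sigp = _response_derivative(R, params)
        energy = retained * (C @ sig) - mc
        T = N @ C  # total affinity-weighted abundance per metabolite
        J = np.zeros((S + M, S + M))
        J[:S, :S] = np.diag(g * energy)
        J[:S, S:] = g * retained * N[:, None] * C * sigp[None, :]
        U = C.T * sig[:, None]  # M x S uptake per unit N
        J[S:, :S] = -U + l * (D @ U)
        J[S:, S:] = -np.diag(sigp * T) + l * D * (sigp * T)[None, :]
        if supply.mode == "logistic":
            s = supply.supplied_set
            J[S + s, S + s] -= 1.0 / supply.tau
        return J

    return rhs, jac


def community_derivatives(
    state: CommunityState,
    C: np.ndarray,
    D: np.ndarray,
    params: MiCRMParams,
    supply: Supply,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dN, dR) of the MiCRM at the given state."""
    if np.any(~np.isfinite(state.N)) or np.any(~np.isfinite(state.R)):
        raise ValueError("state contains non-finite values")
    if np.any(state.N < 0) or np.any(state.R < 0):
        raise ValueError("state must be nonnegative")
    rhs, _ = _rhs_factory(C, D, params, supply)
    dy = rhs(state.t, np.concatenate([state.N, state.R]))
    S = C.shape[0]
    return dy[:S], dy[S:]


class IntegrationError(RuntimeError):
    pass


def integrate_to_steady_state(
    state0: CommunityState,
    C: np.ndarray,
    D: np.ndarray,
    params: MiCRMParams,
    supply: Supply,
) -> SteadyState:
    """Integrate the MiCRM until the community settles.

    The ODE is integrated with LSODA in chunks of ``t_chunk``; after every
    chunk negative round-off is clipped and taxa below the extinction
    threshold are set to zero. Convergence requires the maximum relative
    derivative ``|dx/dt| / (|x| + eps)`` to fall below ``ss_tol`` over all
    taxa and over all resources that still have a surviving consumer;
    resources without consumers (the waste sink and any supplied-but-unused
    nutrient) accumulate linearly by construction and are excluded, as they
    no longer feed back on the community. Failing to converge by ``t_max``
    is reported through the ``converged`` flag rather than raised.
    """
    S, M = C.shape
    rhs, jac = _rhs_factory(C, D, params, supply)
    y = np.concatenate([state0.N, state0.R])
    t = float(state0.t)
    t_end = t + params.t_max
    eps = 1e-8
    converged = False
    while t < t_end:
        sol = solve_ivp(
            rhs,
            (t, min(t + params.t_chunk, t_end)),
            y,
            method="LSODA",
            jac=jac,
            rtol=params.rtol,
            atol=params.atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE solver failed at t={t:.1f}: {sol.message}"
            )
        y = sol.y[:, -1]
        t = float(sol.t[-1])
        y = np.maximum(y, 0.0)
        y[:S][y[:S] < params.extinction_threshold] = 0.0
        dy = rhs(t, y)
        alive = y[:S] > 0
        consumed = (C[alive].sum(axis=0) > 0) if alive.any() else np.zeros(M, bool)
        rel_N = np.abs(dy[:S]) / (y[:S] + eps)
        rel_R = np.abs(dy[S:][consumed]) / (y[S:][consumed] + eps)
        worst = max(rel_N.max() if S else 0.0, rel_R.max() if consumed.any() else 0.0)
        if worst < params.ss_tol:
            converged = True
            break
    N, R = y[:S], y[S:]
    survivors = np.where(N > params.extinction_threshold)[0]
    return SteadyState(
        Nss=N, Rss=R, converged=converged, survivors=survivors,
        t_elapsed=t - float(state0.t),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_steady_state_tsv(ss: SteadyState, taxa: list[str], path) -> None:
    surv = np.zeros(len(taxa), dtype=bool)
    surv[ss.survivors] = True
    pd.DataFrame(
        {"taxon": taxa, "Nss": ss.Nss, "survivor": surv.astype(int)}
    ).to_csv(path, sep="\t", index=False)


def write_resources_tsv(ss: SteadyState, metabolites: list[str], path) -> None:
    pd.DataFrame({"metabolite": metabolites, "Rss": ss.Rss}).to_csv(
        path, sep="\t", index=False
    )
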