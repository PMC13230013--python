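import numpy as np
import pytest

from crmnet import micrm, net2micrm, netgen


@pytest.fixture
def w1_network():
    """Three-taxon fixture: 1 feeds 2; 2 and 3 compete."""
    A = np.zeros((3, 3), dtype=int)
    A[0, 1] = 1
    A[1, 2] = A[2, 1] = -1
    return netgen.InteractionNetwork(A=A)


@pytest.fixture
def w1_augmented(w1_network):
    return netgen.augment_environment(w1_network)


@pytest.fixture
def single_consumer():
    """One taxon eating metabolite 1 and secreting waste (metabolite 2)."""
    C = np.array([[1.0, 0.0]])
    D = np.zeros((2, 2))
    D[1, 0] = 1.0
    return C, D


def random_interpreted(topology, S, seed, nneg=0.1, p=0.1, k=3):
    """Random network taken through signing, disambiguation, augmentation
    and translation. Shared helper for round-trip and pipeline tests."""
    params = netgen.NetworkGenParams(
        topology=topology, S=S, p=p if topology == "er" else None,
        k=k if topology == "ba" else None, nneg=nneg, seed=seed,
    )
    net = netgen.generate_network(params)
    net = netgen.assign_competitions(net, nneg, seed=seed + 10_000)
    net = netgen.disambiguate_competitor_outputs(net)
    aug = netgen.augment_environment(net)
    system = net2micrm.interpret_network(aug)
    return net, aug, system


def steady_community(topology="er", S=20, seed=0, fr=1.0, nneg=0.1, p=0.15, k=3,
                     **param_overrides):
    """Small community integrated to steady state; returns everything the
    sampling/sequencing layers need."""
    net, aug, system = random_interpreted(topology, S, seed, nneg=nneg, p=p, k=k)
    params = micrm.MiCRMParams(fr=fr, **param_overrides)
    supplied = micrm.choose_supplied_set(system.M, system.w_index, fr, seed + 20_000)
    supply = micrm.make_supply(params, supplied, system.M, system.w_index)
    state0 = micrm.init_community(system.C, params, supply, seed=seed + 30_000)
    ss = micrm.integrate_to_steady_state(state0, system.C, system.D, params, supply)
    return net, system, params, supply, ss
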