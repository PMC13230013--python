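import numpy as np
import pytest

from crmnet import micrm
from crmnet.micrm import (
    CommunityState,
    MiCRMParams,
    choose_supplied_set,
    community_derivatives,
    init_community,
    integrate_to_steady_state,
    make_supply,
    uptake_response,
)
from conftest import steady_community


class TestUptakeResponse:
    def test_linear_is_identity(self):
        p = MiCRMParams(response="linear")
        assert uptake_response(1000.0, p) == 1000.0

    def test_hill_half_saturation(self):
        p = MiCRMParams(response="hill", sigma_max=5, n_hill=2, K_half=20)
        assert uptake_response(20.0, p) == pytest.approx(2.5)

    def test_hill_saturates(self):
        p = MiCRMParams(response="hill", sigma_max=5, n_hill=2, K_half=20)
        assert uptake_response(1e6, p) == pytest.approx(5.0, abs=1e-6)
        assert uptake_response(0.0, p) == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            uptake_response(-1.0, MiCRMParams())


class TestDerivatives:
    def test_single_consumer_hand_evaluation(self, single_consumer):
        # N=1, R=(1000, 0), no supply: dN = 0.2*1000 - 1 = 199,
        # dR = (-1000, 0.8*1000)
        C, D = single_consumer
        p = MiCRMParams()
        supply = make_supply(p, [], 2, 2)  # empty supplied set -> kappa = 0
        state = CommunityState(N=np.array([1.0]), R=np.array([1000.0, 0.0]))
        dN, dR = community_derivatives(state, C, D, p, supply)
        assert dN[0] == pytest.approx(199.0)
        assert dR[0] == pytest.approx(-1000.0)
        assert dR[1] == pytest.approx(800.0)

    def test_empty_community_leaves_only_supply(self, single_consumer):
        C, D = single_consumer
        p = MiCRMParams()
        supply = make_supply(p, [0], 2, 2)
        state = CommunityState(N=np.array([0.0]), R=np.array([10.0, 0.0]))
        dN, dR = community_derivatives(state, C, D, p, supply)
        assert dN[0] == 0.0
        assert np.allclose(dR, supply.kappa0)

    def test_full_leakage_means_pure_maintenance_decay(self, single_consumer):
        C, D = single_consumer
        p = MiCRMParams(l=1.0)
        supply = make_supply(p, [], 2, 2)
        state = CommunityState(N=np.array([3.0]), R=np.array([500.0, 0.0]))
        dN, _ = community_derivatives(state, C, D, p, supply)
        assert dN[0] == pytest.approx(-p.g * 3.0 * p.m_c)

    def test_zero_leakage_secretes_nothing(self, single_consumer):
        C, D = single_consumer
        p = MiCRMParams(l=0.0)
        supply = make_supply(p, [], 2, 2)
        state = CommunityState(N=np.array([2.0]), R=np.array([100.0, 0.0]))
        _, dR = community_derivatives(state, C, D, p, supply)
        assert dR[1] == 0.0  # no by-product flux at all

    def test_invalid_state_rejected(self, single_consumer):
        C, D = single_consumer
        p = MiCRMParams()
        supply = make_supply(p, [0], 2, 2)
        with pytest.raises(ValueError):
            CommunityState(N=np.array([-1.0]), R=np.array([0.0, 0.0]))
        state = CommunityState(N=np.array([1.0]), R=np.array([1.0, 0.0]))
        state.N = np.array([np.nan])
        with pytest.raises(ValueError):
            community_derivatives(state, C, D, p, supply)


class TestSupply:
    def test_constant_supply_vector(self):
        p = MiCRMParams(fr=1.0)
        supply = make_supply(p, [0, 1, 2, 3], 5, 5)
        assert np.allclose(supply.kappa0, [1000, 1000, 1000, 1000, 0])
        assert np.allclose(supply.rate(np.ones(5)), supply.kappa0)

    def test_bolus_rate_is_zero(self):
        p = MiCRMParams(supply_mode="bolus")
        supply = make_supply(p, [0, 1], 4, 4)
        assert not np.any(supply.rate(np.full(4, 123.0)))

    def test_logistic_replenishment_toward_R0(self):
        p = MiCRMParams(supply_mode="logistic")
        supply = make_supply(p, [0], 2, 2)
        rate = supply.rate(np.array([400.0, 0.0]))
        assert rate[0] == pytest.approx((1000 - 400) / 1.0)
        assert rate[1] == 0.0

    def test_waste_cannot_be_supplied(self):
        with pytest.raises(ValueError):
            make_supply(MiCRMParams(), [4], 5, 5)

    def test_supplied_set_size_and_reproducibility(self):
        a = choose_supplied_set(5, 5, 0.5, seed=3)
        b = choose_supplied_set(5, 5, 0.5, seed=3)
        assert len(a) == 2  # round(0.5 * 4)
        assert np.array_equal(a, b)
        assert 4 not in a  # waste column excluded


class TestInitCommunity:
    def test_constant_init(self, single_consumer):
        C, _ = single_consumer
        p = MiCRMParams()
        supply = make_supply(p, [0], 2, 2)
        state = init_community(C, p, supply, init_spec=3.5)
        assert np.allclose(state.N, 3.5)
        assert state.R[0] == 1000.0 and state.R[1] == 0.0

    def test_lognormal_init_is_right_skewed(self):
        from scipy import stats

        C = np.zeros((250, 3))
        p = MiCRMParams()
        supply = make_supply(p, [0], 3, 3)
        for seed in range(50):
            state = init_community(C, p, supply, seed=seed)
            assert stats.skew(state.N) > 0
            assert np.all(state.N > 0)

    def test_user_vector_passthrough(self, single_consumer):
        C, _ = single_consumer
        p = MiCRMParams()
        supply = make_supply(p, [0], 2, 2)
        state = init_community(C, p, supply, init_spec=np.array([42.0]))
        assert state.N[0] == 42.0

    def test_wrong_length_rejected(self, single_consumer):
        C, _ = single_consumer
        p = MiCRMParams()
        supply = make_supply(p, [0], 2, 2)
        with pytest.raises(ValueError):
            init_community(C, p, supply, init_spec=np.ones(5))


class TestSteadyState:
    def test_single_consumer_analytic_limit(self, single_consumer):
        # constant kappa = 1000 on the feed: R* = m_c/((1-l) w_e) = 5,
        # N* = kappa / R* = 200
        C, D = single_consumer
        p = MiCRMParams()
        supply = make_supply(p, [0], 2, 2)
        state0 = CommunityState(N=np.array([1.0]), R=np.array([1000.0, 0.0]))
        ss = integrate_to_steady_state(state0, C, D, p, supply)
        assert ss.converged
        assert ss.Rss[0] == pytest.approx(5.0, rel=0.01)
        assert ss.Nss[0] == pytest.approx(200.0, rel=0.01)
        assert list(ss.survivors) == [0]

    def test_doubling_supply_doubles_abundance(self, single_consumer):
        C, D = single_consumer
        base = None
        for R0 in (1000.0, 2000.0):
            p = MiCRMParams(R0=R0)
            supply = make_supply(p, [0], 2, 2)
            state0 = CommunityState(N=np.array([1.0]), R=np.array([R0, 0.0]))
            ss = integrate_to_steady_state(state0, C, D, p, supply)
            if base is None:
                base = ss.Nss[0]
            else:
                assert ss.Nss[0] == pytest.approx(2 * base, rel=0.01)

    def test_zero_growth_condition_for_survivors(self):
        _, system, params, supply, ss = steady_community(seed=1)
        assert ss.converged
        sig = uptake_response(ss.Rss, params)
        surplus = (1 - params.l) * params.w_e * (system.C @ sig) - params.m_c
        assert np.all(np.abs(surplus[ss.survivors]) < 10 * params.ss_tol)

    def test_no_taxa_with_logistic_supply_restores_R0(self, single_consumer):
        C, D = single_consumer
        p = MiCRMParams(supply_mode="logistic")
        supply = make_supply(p, [0], 2, 2)
        state0 = CommunityState(N=np.array([0.0]), R=np.array([100.0, 0.0]))
        ss = integrate_to_steady_state(state0, C, D, p, supply)
        assert ss.Rss[0] == pytest.approx(1000.0, rel=1e-3)
        assert ss.survivors.size == 0

    def test_nonnegativity_and_extinction_clamping(self):
        _, system, params, supply, ss = steady_community(seed=4, fr=0.05, S=25)
        assert np.all(ss.Nss >= 0) and np.all(ss.Rss >= 0)
        dead = np.setdiff1d(np.arange(system.C.shape[0]), ss.survivors)
        assert np.all(ss.Nss[dead] == 0.0)

    def test_nonconvergence_reported_not_raised(self, single_consumer):
        C, D = single_consumer
        p = MiCRMParams(t_max=5.0, t_chunk=5.0, ss_tol=1e-14)
        supply = make_supply(p, [0], 2, 2)
        state0 = CommunityState(N=np.array([1.0]), R=np.array([1000.0, 0.0]))
        ss = integrate_to_steady_state(state0, C, D, p, supply)
        assert not ss.converged


def test_steady_state_writers(tmp_path, single_consumer):
    import pandas as pd

    C, D = single_consumer
    p = MiCRMParams()
    supply = make_supply(p, [0], 2, 2)
    state0 = CommunityState(N=np.array([1.0]), R=np.array([1000.0, 0.0]))
    ss = integrate_to_steady_state(state0, C, D, p, supply)
    micrm.write_steady_state_tsv(ss, ["t1"], tmp_path / "ss.tsv")
    micrm.write_resources_tsv(ss, ["m1", "w"], tmp_path / "r.tsv")
    df = pd.read_csv(tmp_path / "ss.tsv", sep="\t")
    assert df.loc[0, "survivor"] == 1
    assert df.loc[0, "Nss"] == pytest.approx(200.0, rel=0.01)
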