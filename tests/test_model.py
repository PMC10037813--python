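import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import caredyn as cd


class TestTreatmentRates:
    def test_throughput_at_upper_fold_capacity(self, table1):
        # With no severe patients the whole capacity treats mild/moderate
        # cases: C/k people per year, c. 344 thousand at the critical capacity.
        res = cd.treatment_rates(10_000.0, 0.0, 688_619.0, table1)
        assert res.patients_treated == pytest.approx(688_619.0 / 2.0)
        assert res.patients_treated == pytest.approx(344_309.5)

    def test_empty_system_is_regularised_to_zero(self, table1):
        assert cd.treatment_rates(0.0, 0.0, 5e5, table1) == (0.0, 0.0, 0.0)

    def test_mixed_caseload_arithmetic(self, table1):
        # independent arithmetic: demand = kM + theta k S, treated = C(M+S)/demand
        M, S, C = 50_000.0, 60_000.0, 200_000.0
        demand = table1.k * M + table1.theta * table1.k * S
        res = cd.treatment_rates(M, S, C, table1)
        assert demand == 1_300_000.0
        assert res.demand == demand
        assert res.patients_treated == pytest.approx(C * (M + S) / demand)
        assert res.patients_treated == pytest.approx(16_923.0769, abs=1e-3)
        assert res.percap_rate == pytest.approx(table1.r * C / demand)
        assert res.percap_rate == pytest.approx(0.068615, abs=1e-6)

    def test_negative_inputs_rejected(self, table1):
        with pytest.raises(cd.DomainError):
            cd.treatment_rates(-1.0, 0.0, 1e5, table1)

    @given(
        M=st.floats(0.1, 4e5),
        S=st.floats(0.0, 4e5, allow_subnormal=False),
        C=st.floats(0.0, 1e6, allow_subnormal=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_throughput_bounds_and_mix(self, M, S, C, table1):
        # C/(theta k) <= treated <= C/k, and the treated mix equals the
        # engaged mix M/(M+S).
        res = cd.treatment_rates(M, S, C, table1)
        lo = C / (table1.theta * table1.k)
        hi = C / table1.k
        assert lo * (1 - 1e-12) <= res.patients_treated <= hi * (1 + 1e-12)
        if res.patients_treated > 0:
            mild_treated = C * M / res.demand
            assert mild_treated / res.patients_treated == pytest.approx(M / (M + S))


class TestDerivatives:
    def test_empty_system_inflow(self, table1, P):
        state = cd.SystemState(t=0, M=0, S=0, P=P, C=2e5)
        d = cd.derivatives(state, table1)
        assert d.dM == pytest.approx((1 - table1.gamma) * table1.i * P)
        assert d.dM == pytest.approx(54_960.0)
        assert d.dS == 0.0

    def test_frozen_system(self):
        frozen = cd.ModelParameters(
            i=0, gamma=0, v=0, u=0, r=0, k=1, theta=1, mu=0, eta=1, g=0, h=0
        )
        d = cd.derivatives(cd.SystemState(t=0, M=100, S=50, P=1000, C=10), frozen)
        assert (d.dM, d.dS, d.dP, d.dC) == (0.0, 0.0, 0.0, 0.0)

    def test_flow_by_flow_against_printed_expressions(self, table1, P):
        # independent oracle: sum each flow term exactly as printed
        M, S, C = 50_000.0, 60_000.0, 200_000.0
        p = table1
        rho = p.r * C / (p.k * M + p.theta * p.k * S)
        dM_expect = (1 - p.gamma) * p.i * (P - S - M) - p.v * M - p.u * M - rho * M - p.mu * M
        dS_expect = p.gamma * p.i * (P - S - M) + p.v * M - p.u * S - rho * S - p.eta * p.mu * S
        d = cd.derivatives(cd.SystemState(t=0, M=M, S=S, P=P, C=C), table1)
        assert d.dM == pytest.approx(dM_expect, rel=1e-12)
        assert d.dS == pytest.approx(dS_expect, rel=1e-12)
        assert d.dM == pytest.approx(1.55e2, rel=0.01)
        assert d.dS == pytest.approx(5.98e3, rel=0.01)

    @given(
        M=st.floats(0, 3e5, allow_subnormal=False),
        S=st.floats(0, 3e5, allow_subnormal=False),
        C=st.floats(0, 1e6, allow_subnormal=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_flows_nonnegative_and_inflow_split(self, M, S, C, table1, P):
        d = cd.derivatives(cd.SystemState(t=0, M=M, S=S, P=P, C=C), table1)
        f = d.flows
        for name in (
            "inflow_M", "inflow_S", "progression", "spont_recovery_M",
            "spont_recovery_S", "treat_recovery_M", "treat_recovery_S",
            "mortality_M", "mortality_S", "demand", "patients_treated",
        ):
            assert getattr(f, name) >= 0.0
        assert f.inflow_M + f.inflow_S == pytest.approx(table1.i * (P - S - M))


class TestSimulate:
    def test_frozen_parameters_give_constant_trajectory(self):
        frozen = cd.ModelParameters(
            i=0, gamma=0, v=0, u=0, r=0, k=1, theta=1, mu=0, eta=1
        )
        st0 = cd.SystemState(t=0, M=1000, S=500, P=10_000, C=100)
        traj = cd.simulate(st0, frozen, horizon=50)
        assert np.allclose(traj["M"], 1000) and np.allclose(traj["S"], 500)
        assert np.allclose(traj["P"], 10_000) and np.allclose(traj["C"], 100)

    def test_relaxation_back_to_stable_equilibrium(self, table1, P):
        eq = cd.find_equilibria(table1, P, 200_000.0)[0]
        st0 = cd.SystemState(
            t=0, M=1.001 * eq.M_star, S=1.001 * eq.S_star, P=P, C=200_000.0
        )
        traj = cd.simulate(st0, table1, horizon=200)
        last = traj.iloc[-1]
        assert abs(last["M"] - eq.M_star) / eq.M_star < 1e-3
        assert abs(last["S"] - eq.S_star) / eq.S_star < 1e-3

    def test_bistable_divergence_by_initial_severe_share(self, table1, P):
        # same total engaged, different severe share -> different stable states
        C = 600_000.0
        total = 30_000.0
        low = cd.simulate(
            cd.SystemState(t=0, M=total, S=0.0, P=P, C=C), table1, horizon=300
        )
        high = cd.simulate(
            cd.SystemState(t=0, M=0.5 * total, S=0.5 * total, P=P, C=C),
            table1,
            horizon=300,
        )
        assert low.iloc[-1][["M", "S"]].sum() < 1e-3 * P
        assert high.iloc[-1][["M", "S"]].sum() > 5e-2 * P

    def test_conserved_population_and_capacity(self, table1, P):
        st0 = cd.SystemState(t=0, M=5e4, S=5e4, P=P, C=3e5)
        traj = cd.simulate(st0, table1, horizon=100)
        assert np.allclose(traj["P"], P)
        assert np.allclose(traj["C"], 3e5)
        growing = cd.simulate(st0, table1.replace(g=1000.0, h=50.0), horizon=100)
        assert growing.iloc[-1]["P"] == pytest.approx(P + 1000.0 * 100, rel=1e-9)
        assert growing.iloc[-1]["C"] == pytest.approx(3e5 + 50.0 * 100, rel=1e-9)

    def test_output_nonnegative_even_through_collapse(self, table1, P):
        traj = cd.simulate(
            cd.SystemState(t=0, M=5000, S=500, P=P, C=600_000.0),
            table1,
            horizon=50,
        )
        assert (traj["M"] >= 0).all() and (traj["S"] >= 0).all()

    def test_tolerance_refinement_changes_little(self, table1, P):
        st0 = cd.SystemState(t=0, M=5e4, S=5e4, P=P, C=3e5)
        times = np.linspace(0, 50, 51)
        a = cd.simulate(st0, table1, 50, output_times=times, rtol=1e-8, atol=1e-6)
        b = cd.simulate(st0, table1, 50, output_times=times, rtol=5e-9, atol=5e-7)
        rel = np.max(np.abs(a[["M", "S"]].values - b[["M", "S"]].values)) / P
        assert rel < 1e-6

    def test_bad_horizon_and_times_rejected(self, table1, P):
        st0 = cd.SystemState(t=0, M=1e4, S=1e4, P=P, C=3e5)
        with pytest.raises(cd.DomainError):
            cd.simulate(st0, table1, horizon=0)
        with pytest.raises(cd.DomainError):
            cd.simulate(st0, table1, horizon=10, output_times=[0, 20])
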