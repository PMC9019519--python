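"""Closed-form steady states, stability condition, monotone structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from sigseq import (ReducedPhosSeq, ResourceParams, check_assumptions,
                    corner_convergence, local_stability_condition,
                    monotone_structure_check, nominal_params, perturb_params,
                    resource_ode_rhs, resource_steady_state,
                    rr_star_vs_beta_sr, rrp_star_dephos, rrp_star_phos_seq)


class TestClosedForms:
    def test_sequestration_free_limit_coincides(self, nominal):
        """With no sequestration protein the two motifs' formulas agree
        (their 'duality')."""
        p = nominal.replace(beta_SR=0.0, beta_PH=0.0)
        for I in (0.2, 1.0, 5.0):
            assert rrp_star_phos_seq(p, I) == pytest.approx(
                rrp_star_dephos(p, I), rel=1e-12)

    def test_strictly_decreasing_in_sequestration(self, nominal):
        v = [rrp_star_phos_seq(nominal.replace(beta_SR=b), 2.0)
             for b in (0.0, 0.1, 0.3)]
        assert v[0] > v[1] > v[2]
        w = [rrp_star_dephos(nominal.replace(beta_PH=b), 2.0)
             for b in (0.0, 0.1, 0.3)]
        assert w[0] > w[1] > w[2]

    def test_kp_zero_is_undefined(self, nominal):
        with pytest.raises(ZeroDivisionError):
            rrp_star_phos_seq(nominal.replace(kp=0.0), 1.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000), I=st.floats(0.01, 50))
    def test_bounded_by_kap_over_kp(self, seed, I):
        from sigseq.network import autophosphorylation_rate
        p = perturb_params(nominal_params(), 0.5, seed).replace(beta_SR=0.05)
        bound = autophosphorylation_rate(I, p) / p.kp
        assert rrp_star_phos_seq(p, I) <= bound * (1 + 1e-12)
        assert rrp_star_dephos(p, I) <= bound * (1 + 1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_duality_identity(self, seed):
        """The formulas coincide exactly when ktc SR_tot = kpc PH_tot
        (kt RR_tot + delta)/(kp HK_tot + delta)."""
        p = perturb_params(nominal_params(), 0.5, seed)
        p = p.replace(beta_PH=0.1)
        sr_tot = (p.kpc * p.PH_tot * (p.kt * p.RR_tot + p.delta)
                  / (p.kp * p.HK_tot + p.delta)) / p.ktc
        p_seq = p.replace(beta_SR=sr_tot * p.delta, beta_PH=0.0)
        p_deph = p.replace(beta_SR=0.0)
        assert rrp_star_phos_seq(p_seq, 2.0) == pytest.approx(
            rrp_star_dephos(p_deph, 2.0), rel=1e-10)


class TestAssumptions:
    def test_nominal_valid_with_small_error(self, nominal):
        rep = check_assumptions(nominal, 2.0, "phos_seq")
        assert rep.valid
        assert rep.relative_error < 0.05
        assert set(rep.assumption_ratios) >= {"timescale", "RR_sum/RRp"}

    def test_delta_dominant_regime_invalid(self, nominal):
        slow = nominal.replace(kap_max=0.05, kt=1e-6, kp=1e-6, ktc=1e-6,
                               kpc=1e-6)
        rep = check_assumptions(slow, 2.0, "phos_seq")
        assert not rep.valid
        assert rep.assumption_ratios["timescale"] < 10

    def test_error_shrinks_with_margin(self, nominal):
        errs = [check_assumptions(nominal.replace(kap_max=k), 1000.0,
                                  "phos_seq").relative_error
                for k in (0.046, 0.015, 0.005)]
        assert errs[0] > errs[1] > errs[2]

    def test_unknown_motif(self, nominal):
        with pytest.raises(ValueError, match="motif"):
            check_assumptions(nominal, 1.0, "resource")


class TestResourceCompetition:
    def test_abundant_resources_limit(self):
        rp = ResourceParams(T_Y=1.0, T_S=1.0, beta_Y=2.0, beta_S=3.0,
                            J_Y=0.0, J_S=0.0, delta=0.02)
        assert resource_steady_state(rp) == pytest.approx(rp.K_Y * rp.beta_Y)

    def test_decreasing_in_competitor(self):
        vals = [resource_steady_state(
            ResourceParams(1.0, 1.0, 2.0, bs, 0.1, 0.2, 0.02))
            for bs in (0.0, 1.0, 5.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_matches_ode_long_time_limit(self):
        rp = ResourceParams(T_Y=1.0, T_S=0.8, beta_Y=2.0, beta_S=1.5,
                            J_Y=0.3, J_S=0.4, delta=0.02)
        sol = solve_ivp(lambda t, y: resource_ode_rhs(rp, y), (0, 5000),
                        [0.0, 0.0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(resource_steady_state(rp),
                                             abs=1e-8)


class TestStabilityCondition:
    def test_unphosphorylated_state_trivially_stable(self, nominal):
        rep = local_stability_condition(
            [nominal.HK_tot, nominal.RR_tot], nominal, 0.0)
        assert rep.stable and rep.simplified and rep.margin > 0

    def test_inconsistent_state_rejected(self, nominal):
        with pytest.raises(ValueError, match="outside"):
            local_stability_condition([2 * nominal.HK_tot, 1.0], nominal, 1.0)

    def test_matches_eigenvalue_oracle(self, nominal):
        """Condition true <=> negative spectrum of the reduced Jacobian,
        checked on random parameter sets."""
        for s in range(60):
            p = perturb_params(nominal, 0.5, seed=s)
            m = ReducedPhosSeq(p, 2.0)
            ss = m.steady_state()
            rep = local_stability_condition(ss[:2], p, 2.0)
            eig_stable = np.max(np.linalg.eigvals(m.jac(ss)[:2, :2]).real) < 0
            assert rep.stable == eig_stable
            if rep.simplified:
                assert rep.stable  # sufficient condition implies the full one


class TestMonotoneStructure:
    def test_reduced_model_is_cooperative(self, nominal):
        m = ReducedPhosSeq(nominal.replace(beta_SR=0.1), 2.0)
        ok, witness = monotone_structure_check(m, n_samples=1000, seed=3)
        assert ok and witness is None

    def test_sign_broken_model_detected(self, nominal):
        m = ReducedPhosSeq(nominal.replace(beta_SR=0.1), 2.0)

        class Broken:
            box = m.box

            def jac(self, x):
                J = m.jac(x)
                J[0, 1] = -abs(J[0, 1]) - 1e-3  # negate a coupling
                return J

        ok, witness = monotone_structure_check(Broken(), n_samples=100, seed=3)
        assert not ok and witness is not None

    def test_ordered_initial_conditions_stay_ordered(self, nominal, rng):
        m = ReducedPhosSeq(nominal.replace(beta_SR=0.1), 2.0)
        lo_b, hi_b = m.box()
        t = np.linspace(0, 3000, 30)
        for _ in range(5):
            a = lo_b + (hi_b - lo_b) * rng.random(3) * 0.5
            b = a + (hi_b - a) * rng.random(3) * 0.5  # componentwise above
            _, xa = m.simulate(a, 3000, t_eval=t)
            _, xb = m.simulate(b, 3000, t_eval=t)
            assert np.all(xb - xa >= -1e-7)


def test_corner_trajectories_converge(nominal):
    conv, x_star, gap = corner_convergence(nominal.replace(beta_SR=0.1), 2.0)
    assert conv and gap < 1e-6
    lo, hi = ReducedPhosSeq(nominal.replace(beta_SR=0.1), 2.0).box()
    assert np.all(x_star >= lo - 1e-9) and np.all(x_star <= hi + 1e-9)


def test_rr_star_monotone_in_beta_sr(nominal):
    grid = np.linspace(0.0, 0.5, 8)
    rr = rr_star_vs_beta_sr(nominal, 2.0, grid)
    assert np.all(np.diff(rr) >= -1e-9)
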