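"""Reaction networks: rate laws, stoichiometry, and architecture algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sigseq import (autophosphorylation_rate, build_network, nominal_params,
                    output_initiation_rate, simulate)
from sigseq.params import ARCHITECTURES


class TestRateLaws:
    def test_autophosphorylation_landmarks(self, nominal):
        assert autophosphorylation_rate(0.0, nominal) == 0.0
        assert autophosphorylation_rate(nominal.Kda, nominal) == \
            pytest.approx(nominal.kap_max / 2)
        assert autophosphorylation_rate(99 * nominal.Kda, nominal) == \
            pytest.approx(nominal.kap_max, rel=0.011)
        with pytest.raises(ValueError):
            autophosphorylation_rate(-1.0, nominal)

    def test_output_initiation_landmarks(self, nominal):
        assert output_initiation_rate(0.0, nominal) == 0.0
        assert output_initiation_rate(nominal.Kdr, nominal) == \
            pytest.approx(nominal.kout_max / 2)
        # half-max at Kdr is independent of cooperativity
        assert output_initiation_rate(nominal.Kdr, nominal.replace(n=4)) == \
            pytest.approx(nominal.kout_max / 2)
        # below Kdr, higher cooperativity lowers the output
        low = nominal.Kdr / 2
        assert output_initiation_rate(low, nominal.replace(n=4)) < \
            output_initiation_rate(low, nominal)
        with pytest.raises(ValueError):
            output_initiation_rate(-0.1, nominal)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(x=st.floats(0, 1e4), y=st.floats(0, 1e4))
    def test_rate_laws_monotone_bounded(self, x, y):
        p = nominal_params()
        lo, hi = sorted([x, y])
        assert autophosphorylation_rate(lo, p) <= autophosphorylation_rate(hi, p)
        assert output_initiation_rate(hi, p) <= p.kout_max


class TestBuildNetwork:
    def test_unknown_architecture(self, nominal):
        with pytest.raises(ValueError, match="unknown architecture"):
            build_network("ring_oscillator", nominal, 1.0)

    def test_zero_feedback_matches_wild_type(self, nominal, rng):
        """P = 0 closed loops have the wild-type vector field on shared species."""
        wt = build_network("wild_type", nominal, 2.0)
        for arch in ("closed_loop_phos_seq", "closed_loop_dephos",
                     "molecular_seq_feedback", "transcriptional_feedback"):
            net = build_network(arch, nominal.replace(P=0.0), 2.0)
            for _ in range(20):
                x_wt = rng.random(wt.n_species) * 50
                x = np.zeros(net.n_species)
                for i, sp in enumerate(wt.species):
                    x[net.index(sp)] = x_wt[i]
                f = net.rhs(x)
                f_wt = wt.rhs(x_wt)
                for i, sp in enumerate(wt.species):
                    assert f[net.index(sp)] == pytest.approx(f_wt[i], abs=1e-12)

    def test_architecture_reduction_collapses(self, nominal, rng):
        """beta_SR = beta_PH = 0, P = 0 collapses every architecture to WT."""
        wt = build_network("wild_type", nominal, 1.0)
        p0 = nominal.replace(beta_SR=0.0, beta_PH=0.0, P=0.0)
        for arch in ARCHITECTURES:
            net = build_network(arch, p0, 1.0)
            x = np.zeros(net.n_species)
            x_wt = rng.random(wt.n_species) * 30
            for i, sp in enumerate(wt.species):
                x[net.index(sp)] = x_wt[i]
            f = net.rhs(x)
            for i, sp in enumerate(wt.species):
                assert f[net.index(sp)] == pytest.approx(wt.rhs(x_wt)[i],
                                                         abs=1e-12)

    def test_kinase_total_conservation_structure(self, nominal, rng):
        """Transfer reactions conserve HK+HKp: its net rate is
        beta_HK - delta*([HK]+[HKp]) at any state."""
        net = build_network("closed_loop_phos_seq",
                            nominal.replace(P=0.7), 3.0)
        for _ in range(20):
            x = rng.random(net.n_species) * 80
            f = net.rhs(x)
            lhs = f[net.index("HK")] + f[net.index("HKp")]
            rhs = nominal.beta_HK - nominal.delta * (
                x[net.index("HK")] + x[net.index("HKp")])
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_crosstalk_with_empty_kinase_pool_is_inert(self, nominal):
        p = nominal.replace(kap_X=0.08)
        net_x = build_network("wild_type", p, 2.0, X_tot=0.0)
        net = build_network("wild_type", nominal, 2.0)
        t = np.linspace(0, 2000, 50)
        tr_x = simulate(net_x, net_x.default_x0(), 2000, t_eval=t)
        tr = simulate(net, net.default_x0(), 2000, t_eval=t)
        for sp in net.species:
            np.testing.assert_allclose(tr_x.series(sp), tr.series(sp),
                                       rtol=1e-6, atol=1e-8)


class TestOdeRhs:
    def test_zero_state_production_only(self, nominal):
        net = build_network("wild_type", nominal, 5.0)
        f = net.rhs(np.zeros(net.n_species))
        assert f[net.index("HK")] == pytest.approx(nominal.beta_HK)
        assert f[net.index("RR")] == pytest.approx(nominal.beta_RR)
        for sp in ("HKp", "RRp", "Output"):
            assert f[net.index(sp)] == 0.0

    def test_dimension_and_negative_state_rejected(self, nominal):
        net = build_network("wild_type", nominal, 1.0)
        with pytest.raises(ValueError, match="dimension"):
            net.rhs(np.zeros(3))
        with pytest.raises(ValueError, match="negative"):
            net.rhs(np.full(net.n_species, -1.0))
        # micro-undershoot is clamped, not fatal
        x = np.zeros(net.n_species)
        x[0] = -1e-12
        assert np.all(np.isfinite(net.rhs(x)))

    def test_steady_state_residual(self, nominal):
        from sigseq import steady_state
        net = build_network("closed_loop_phos_seq",
                            nominal.replace(P=1.0), 2.0)
        ss = steady_state(net)
        assert np.linalg.norm(net.rhs(ss)) < 1e-8

    def test_rhs_consistent_with_trajectory(self, nominal):
        """Finite differences of a simulated path reproduce the vector field."""
        net = build_network("wild_type", nominal, 2.0)
        t = np.linspace(0, 400, 4001)
        tr = simulate(net, net.default_x0(), 400, t_eval=t)
        k = 2000
        fd = (tr.x[k + 1] - tr.x[k - 1]) / (t[k + 1] - t[k - 1])
        f = net.rhs(tr.x[k])
        np.testing.assert_allclose(fd, f, rtol=1e-3, atol=1e-9)

    def test_propensities_nonnegative_and_jacobian(self, nominal, rng):
        net = build_network("transcriptional_feedback",
                            nominal.replace(P=0.9, kap_X=0.08), 1.0)
        for _ in range(20):
            x = rng.random(net.n_species) * 100
            a = net.propensities(x)
            assert np.all(a >= 0)
            # analytic propensity Jacobian vs finite differences
            dA = net.propensity_jacobian(x)
            eps = 1e-6
            for i in rng.choice(net.n_species, 3, replace=False):
                xp = x.copy(); xp[i] += eps
                np.testing.assert_allclose(
                    (net.propensities(xp) - a) / eps, dA[:, i],
                    rtol=1e-4, atol=1e-7)

    def test_trajectories_stay_nonnegative(self, nominal):
        from sigseq import perturb_params
        for s in range(5):
            p = perturb_params(nominal, 0.3, seed=s).replace(P=0.8)
            net = build_network("closed_loop_dephos", p, 5.0)
            tr = simulate(net, net.default_x0(), 5e4)
            assert tr.x.min() > -1e-8


def test_structured_text_export(nominal):
    net = build_network("closed_loop_phos_seq", nominal.replace(P=1.0), 2.0)
    text = net.to_text()
    assert "species:" in text and "prod_SR" in text and "Output" in text
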