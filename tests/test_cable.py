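import io

import numpy as np
import pytest
from scipy import sparse

from t4circuit import cable
from t4circuit.cable import (CableParams, ClampConfig, Morphology, SWCError,
                             Synapse)

TOY_SWC = """\
# toy: root with two children
1 1 0 0 0 0.5 -1
2 3 10 0 0 0.25 1
3 3 0 10 0 0.25 1
"""


def cylinder():
    """100 um x 1 um single-compartment cylinder."""
    m = Morphology(parent=[-1], length_um=[100.0], diameter_um=[1.0])
    return cable.assemble(m, CableParams())


def chain(n=20, length=5.0, diam=0.5):
    m = Morphology(parent=[-1] + list(range(n - 1)),
                   length_um=[length] * n, diameter_um=[diam] * n)
    return cable.assemble(m, CableParams())


def random_tree(rng, n):
    parent = [-1] + [int(rng.integers(0, i)) for i in range(1, n)]
    return Morphology(parent=parent,
                      length_um=rng.uniform(1.0, 10.0, n),
                      diameter_um=rng.uniform(0.2, 2.0, n))


class TestReadSWC:
    def test_toy_tree(self):
        m = cable.read_swc(io.StringIO(TOY_SWC))
        assert m.n_compartments == 3
        assert int(np.sum(m.parent >= 0)) == 2  # edges exclude the root
        np.testing.assert_allclose(sorted(m.length_um), [0.0, 10.0, 10.0])
        np.testing.assert_allclose(m.diameter_um, [1.0, 0.5, 0.5])

    def test_unknown_parent_names_line(self):
        bad = TOY_SWC.replace("0.25 1\n3", "0.25 9\n3", 1)
        with pytest.raises(SWCError, match="line 3.*parent id 9"):
            cable.read_swc(io.StringIO(bad))

    def test_nonpositive_radius_rejected(self):
        bad = TOY_SWC.replace("10 0 0 0.25", "10 0 0 0.0")
        with pytest.raises(SWCError, match="radius"):
            cable.read_swc(io.StringIO(bad))

    def test_cycle_detected(self):
        cyc = "1 1 0 0 0 0.5 -1\n2 3 1 0 0 0.2 3\n3 3 2 0 0 0.2 2\n"
        with pytest.raises(SWCError, match="cycle"):
            cable.read_swc(io.StringIO(cyc))


class TestAssemble:
    def test_cylinder_input_resistance_closed_form(self):
        system = cylinder()
        v = cable.solve_steady(system, injections_pa={0: 1.0})
        rin_gohm = v[0] - (-65.0)  # 1 pA injection: mV change == GOhm
        area_cm2 = np.pi * 1e-4 * 100e-4  # pi * d * L in cm^2
        expected = 28e3 / area_cm2 * 1e-9
        assert rin_gohm == pytest.approx(expected, rel=1e-9)
        assert rin_gohm == pytest.approx(8.91, abs=0.01)

    def test_doubling_ra_halves_axial_only(self):
        rng = np.random.default_rng(5)
        m = random_tree(rng, 12)
        s1 = cable.assemble(m, CableParams(r_a_ohm_cm=150.0))
        s2 = cable.assemble(m, CableParams(r_a_ohm_cm=300.0))
        off1 = s1.m_steady - sparse.diags(s1.m_steady.diagonal())
        off2 = s2.m_steady - sparse.diags(s2.m_steady.diagonal())
        np.testing.assert_allclose(off2.toarray(), off1.toarray() / 2.0)
        np.testing.assert_allclose(s1.g_leak, s2.g_leak)

    def test_kirchhoff_row_sums(self):
        rng = np.random.default_rng(6)
        system = cable.assemble(random_tree(rng, 30), CableParams())
        resid = np.asarray(system.m_steady.sum(axis=1)).ravel() - system.g_leak
        np.testing.assert_allclose(resid, 0.0, atol=1e-20)


class TestSolveSteady:
    def test_rest_is_e_leak_everywhere(self):
        system = chain()
        np.testing.assert_allclose(cable.solve_steady(system), -65.0)

    def test_two_compartment_closed_form(self):
        m = Morphology(parent=[-1, 0], length_um=[50.0, 50.0],
                       diameter_um=[1.0, 1.0])
        system = cable.assemble(m, CableParams())
        i_a = 2.0  # pA at compartment 0
        v = cable.solve_steady(system, injections_pa={0: i_a})
        # hand-solved 2x2: (gm+ga)dVa - ga dVb = I ; -ga dVa + (gm+ga)dVb = 0
        gm = system.g_leak[0]
        ga = -system.m_steady[0, 1]
        det = (gm + ga) ** 2 - ga**2
        dva = (gm + ga) * i_a * 1e-12 / det
        dvb = ga * i_a * 1e-12 / det
        np.testing.assert_allclose(v, [-65.0 + dva * 1e3, -65.0 + dvb * 1e3],
                                   rtol=1e-12)

    def test_synapse_at_leak_reversal_is_silent(self):
        system = chain()
        v = cable.solve_steady(system, synapses=[Synapse(5, 1.0, -65.0)])
        np.testing.assert_allclose(v, -65.0, atol=1e-9)


class TestStepDynamic:
    def test_rest_is_exact_fixed_point(self):
        system = chain()
        v = cable.step_dynamic(system, system.rest_v() * 1e3)
        np.testing.assert_allclose(v, -65.0, atol=1e-12)

    def test_converges_to_steady_state(self):
        system = chain(10)
        target = cable.solve_steady(system, injections_pa={9: 1.0})
        v = system.rest_v() * 1e3
        n = int(10 * system.params.tau_m_s / 1e-4)
        for _ in range(n):
            v = cable.step_dynamic(system, v, injections_pa={9: 1.0})
        assert np.max(np.abs(v - target)) < 0.01

    def test_single_compartment_relaxation_time_constant(self):
        system = cylinder()
        v = system.rest_v() * 1e3
        vs = []
        for _ in range(1000):
            v = cable.step_dynamic(system, v, injections_pa={0: 1.0})
            vs.append(v[0])
        vs = np.asarray(vs)
        vinf = cable.solve_steady(system, injections_pa={0: 1.0})[0]
        frac = (vs + 65.0) / (vinf + 65.0)
        tau_ms = 0.1 * (1 + np.argmax(frac >= 1 - np.exp(-1)))
        assert tau_ms == pytest.approx(28.0, abs=1.0)

    def test_rejects_nonpositive_dt(self):
        system = cylinder()
        with pytest.raises(ValueError):
            cable.step_dynamic(system, system.rest_v() * 1e3, dt_ms=0.0)


class TestDenseOracle:
    """Sparse solves agree with dense brute force on random trees."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_steady_and_dynamic_match_dense(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        system = cable.assemble(random_tree(rng, n), CableParams())
        inj = {int(rng.integers(0, n)): 2.0}
        syns = [Synapse(int(rng.integers(0, n)), 0.05, -21.0)]

        b = system.params.e_leak_mv * 1e-3 * system.g_leak.copy()
        m = system.m_steady.toarray()
        for site, ipa in inj.items():
            b[site] += ipa * 1e-12
        for s in syns:
            m[s.site, s.site] += s.g_ns * 1e-9
            b[s.site] += s.g_ns * 1e-9 * s.e_mv * 1e-3
        v_dense = np.linalg.solve(m, b) * 1e3
        v_sparse = cable.solve_steady(system, inj, syns)
        np.testing.assert_allclose(v_sparse, v_dense, rtol=1e-9)

        v_prev = v_dense + rng.normal(0, 1, n)
        dt = 1e-4
        m_dyn = m + np.diag(system.c_m / dt)
        b_dyn = b + system.c_m / dt * v_prev * 1e-3
        v_dense_dyn = np.linalg.solve(m_dyn, b_dyn) * 1e3
        v_sparse_dyn = cable.step_dynamic(system, v_prev, inj, syns)
        np.testing.assert_allclose(v_sparse_dyn, v_dense_dyn, rtol=1e-9)


class TestVoltageClamp:
    def test_no_driving_force_no_current(self):
        system = chain()
        cfg = ClampConfig(site=0, v_cmd_mv=-65.0)
        i, _ = cable.run_voltage_clamp(system, cfg, n_steps=1000)
        assert abs(i[-1]) < 1e-6

    def test_ohmic_step_on_single_compartment(self):
        system = cylinder()
        cfg = ClampConfig(site=0, v_cmd_mv=-55.0)
        i, v = cable.run_voltage_clamp(system, cfg, n_steps=2000)
        expected_pa = 10e-3 * system.g_leak[0] * 1e12
        assert i[-1] == pytest.approx(expected_pa, rel=1e-6)
        assert abs(v[-1, 0] - (-55.0)) < 0.1

    def test_synapse_at_command_reversal_evokes_nothing(self):
        system = chain(10)
        cfg = ClampConfig(site=0, v_cmd_mv=-55.0)
        sched = lambda s: [Synapse(0, 0.05, -55.0)] if s >= 1000 else []
        i, _ = cable.run_voltage_clamp(system, cfg, sched, n_steps=1600)
        evoked = i[1599] - np.mean(i[900:1000])
        assert abs(evoked) < 1e-4


class TestIVReversal:
    def test_space_clamped_single_compartment_exact(self):
        system = cylinder()
        res = cable.iv_reversal(system, 0, [-80, -65, -50, -35, -20, -5],
                                0, 0.05, -21.0, settle_steps=1200,
                                event_steps=600)
        assert res["e_rev_mv"] == pytest.approx(-21.0, abs=1e-6)
        assert res["bracketed"]

    def test_soma_synapse_recovered_within_1mv(self):
        system = chain(25)
        res = cable.iv_reversal(system, 0, [-80, -65, -50, -35, -20, -5],
                                0, 0.05, -21.0, settle_steps=1200,
                                event_steps=600)
        assert res["e_rev_mv"] == pytest.approx(-21.0, abs=1.0)

    def test_distal_synapse_inflates_apparent_driving_force(self):
        """Space clamp: the zero crossing of the evoked somatic current
        occurs where the attenuated dendritic potential reaches E_syn,
        i.e. at E_leak + (E_syn - E_leak)/A with attenuation A < 1 — the
        estimate moves beyond E_syn, away from E_leak."""
        system = chain(25)
        distal = cable.iv_reversal(system, 0, [-80, -65, -50, -35, -20, -5],
                                   24, 0.05, -21.0, settle_steps=1200,
                                   event_steps=600)
        e_leak = -65.0
        att = cable.transfer_attenuation(system, 0, 24)
        expected = e_leak + (-21.0 - e_leak) / att
        assert abs(distal["e_rev_mv"] - e_leak) > abs(-21.0 - e_leak)
        assert distal["e_rev_mv"] == pytest.approx(expected, abs=0.5)

    def test_requires_three_sweeps(self):
        with pytest.raises(ValueError):
            cable.iv_reversal(cylinder(), 0, [-80, -20], 0, 0.05, -21.0)


class TestTransferAttenuation:
    def test_identity_at_source(self):
        system = chain()
        assert cable.transfer_attenuation(system, 3, 3) == pytest.approx(1.0)

    def test_monotone_decay_along_chain(self):
        system = chain(15)
        ratios = [cable.transfer_attenuation(system, 0, k) for k in range(15)]
        assert all(0 < r <= 1 + 1e-12 for r in ratios)
        assert all(b <= a + 1e-12 for a, b in zip(ratios, ratios[1:]))

    def test_two_compartment_voltage_divider(self):
        m = Morphology(parent=[-1, 0], length_um=[50.0, 80.0],
                       diameter_um=[1.0, 0.6])
        system = cable.assemble(m, CableParams())
        ga = -system.m_steady[0, 1]
        gm_t = system.g_leak[1]
        assert cable.transfer_attenuation(system, 0, 1) == pytest.approx(
            ga / (ga + gm_t), rel=1e-9)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_reciprocity_of_transfer_resistance(self, seed):
        rng = np.random.default_rng(seed)
        system = cable.assemble(random_tree(rng, 20), CableParams())
        a, b = 2, 17
        v0 = cable.solve_steady(system)
        dv_b = cable.solve_steady(system, {a: 1.0})[b] - v0[b]
        dv_a = cable.solve_steady(system, {b: 1.0})[a] - v0[a]
        assert dv_b == pytest.approx(dv_a, rel=1e-9)

    def test_attenuation_robust_to_membrane_parameters(self):
        """Sweeping R_a over [50, 400] and R_m over [7, 112] changes the
        dendrite-to-soma attenuation only by a bounded factor."""
        m = Morphology(parent=[-1] + list(range(19)),
                       length_um=[5.0] * 20, diameter_um=[0.5] * 20)
        vals = []
        for ra in (50.0, 150.0, 400.0):
            for rm in (7.0, 28.0, 112.0):
                s = cable.assemble(m, CableParams(r_a_ohm_cm=ra,
                                                  r_m_kohm_cm2=rm))
                vals.append(cable.transfer_attenuation(s, 19, 0))
        vals = np.asarray(vals)
        assert np.all((vals > 0) & (vals <= 1))
        assert vals.max() / vals.min() < 10.0
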