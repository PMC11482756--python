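"""Initializer geometry, move primitives, Boltzmann sampling, bookkeeping."""

import math

import numpy as np
import pytest
from scipy import stats

import ringtwist as rt
from ringtwist import topology
from ringtwist.engine import (
    EngineState,
    TopologyAuditError,
    apply_crankshaft,
    apply_twist_rotation,
    initialize_configuration,
)

TWOPI = 2 * math.pi


class TestInitializer:
    def test_relaxed_circle_topology(self):
        p = rt.SimulationParameters(N=100)
        cfg = initialize_configuration("circular_fixed_lk", 100, p, delta_lk=0)
        ok, rec = topology.verify_topology(cfg, 0.0)
        assert ok and rec.twist == pytest.approx(0, abs=1e-9)

    def test_underwound_ring_at_physiological_density(self):
        # a 2130 nm circle at σ=-0.06: Lk0 = L/3.55 = 600, ΔLk = -36
        p = rt.SimulationParameters(N=213)
        assert p.lk0 == pytest.approx(600, rel=1e-12)
        cfg = initialize_configuration("circular_fixed_lk", 213, p, delta_lk=-36)
        ok, rec = topology.verify_topology(cfg, -36)
        assert ok
        assert rec.twist == pytest.approx(-36, abs=1e-8)
        assert rec.writhe == pytest.approx(0, abs=1e-9)

    @pytest.mark.parametrize("N", [90, 108, 144])
    def test_linear_extension_exact(self, N):
        p = rt.SimulationParameters(N=N)
        ext = N * p.l0 / 9
        cfg = initialize_configuration("linear_fixed_extension", N, p,
                                       delta_lk=-10, extension=ext)
        assert np.linalg.norm(cfg.positions[-1] - cfg.positions[0]) == \
            pytest.approx(ext, abs=1e-9)
        cfg.validate()
        # end tangents along the stretching axis
        e = cfg.ehat()
        assert e[0] == pytest.approx([1, 0, 0], abs=1e-12)
        assert e[-1] == pytest.approx([1, 0, 0], abs=1e-12)
        assert topology.total_twist(cfg) == pytest.approx(-10, abs=1e-9)

    def test_infeasible_extension_raises(self):
        p = rt.SimulationParameters(N=50)
        with pytest.raises(ValueError):
            initialize_configuration("linear_fixed_extension", 50, p,
                                     extension=501.0)


class TestMovePrimitives:
    def test_crankshaft_zero_angle_is_identity(self):
        cfg = initialize_configuration(
            "circular_fixed_lk", 60, rt.SimulationParameters(N=60), delta_lk=-4)
        moved = apply_crankshaft(cfg, 10, 15, 0.0)
        np.testing.assert_allclose(moved.positions, cfg.positions, atol=1e-14)
        np.testing.assert_allclose(moved.fhat, cfg.fhat, atol=1e-14)

    @pytest.mark.parametrize("start,length,angle", [
        (0, 10, 0.7), (50, 25, -1.3), (55, 20, 2.0),  # last one wraps
    ])
    def test_crankshaft_preserves_linking(self, start, length, angle):
        cfg = initialize_configuration(
            "circular_fixed_lk", 60, rt.SimulationParameters(N=60), delta_lk=-4)
        moved = apply_crankshaft(cfg, start, length, angle)
        moved.validate()
        lk0 = topology.total_twist(cfg) + topology.total_writhe(cfg)
        lk1 = topology.total_twist(moved) + topology.total_writhe(moved)
        assert lk1 == pytest.approx(lk0, abs=1e-8)

    def test_twist_rotation_conserves_total_twist(self):
        cfg = initialize_configuration(
            "circular_fixed_lk", 40, rt.SimulationParameters(N=40), delta_lk=3)
        moved = apply_twist_rotation(cfg, 7, 0.45)
        tw0 = topology.total_twist(cfg)
        tw1 = topology.total_twist(moved)
        assert tw1 == pytest.approx(tw0, abs=1e-12)
        # only the two flanking junctions change
        dphi = (topology.junction_twist_angles(moved)
                - topology.junction_twist_angles(cfg))
        assert dphi[7] == pytest.approx(0.45, abs=1e-10)
        assert dphi[8] == pytest.approx(-0.45, abs=1e-10)
        assert np.max(np.abs(np.delete(dphi, [7, 8]))) < 1e-12


class TestSampling:
    def test_seeded_rerun_is_bit_reproducible(self):
        p = rt.SimulationParameters(N=50)

        def one():
            cfg = initialize_configuration("circular_fixed_lk", 50, p,
                                           delta_lk=-8)
            eng = EngineState(cfg, p, seed=99, max_arc=12)
            eng.equilibrate(20_000)
            return eng.sample(20_000, 50)

        a, b = one(), one()
        np.testing.assert_array_equal(a.phi, b.phi)
        np.testing.assert_array_equal(a.writhe, b.writhe)
        np.testing.assert_array_equal(a.seg_len, b.seg_len)

    def test_linking_number_held_every_sample(self):
        p = rt.SimulationParameters(N=60)
        cfg = initialize_configuration("circular_fixed_lk", 60, p, delta_lk=-9)
        eng = EngineState(cfg, p, seed=5, max_arc=15)
        eng.equilibrate(40_000)
        ss = eng.sample(60_000, 100)
        assert np.max(np.abs(ss.twist + ss.writhe - (-9))) < 1e-3

    def test_boltzmann_twist_marginal_on_frozen_backbone(self):
        # backbone frozen (twist moves only): junction angles are Gaussian
        # with variance (l0/C)(1-1/N) under the fixed total-twist constraint
        N, C = 8, 110.0
        p = rt.SimulationParameters(N=N, C=C)
        cfg = initialize_configuration("circular_fixed_lk", N, p, delta_lk=1)
        eng = EngineState(cfg, p, seed=13, move_mix=(0.0, 0.0, 1.0))
        eng.equilibrate(30_000)
        ss = eng.sample(400_000, 20)
        phi = ss.phi.ravel()
        mean_th = TWOPI * 1 / N
        var_th = (p.l0 / C) * (1 - 1 / N)
        n_eff = ss.phi.shape[0]  # junction angles refresh every few moves
        assert phi.mean() == pytest.approx(mean_th, abs=4 * math.sqrt(var_th / n_eff))
        assert phi.var() == pytest.approx(var_th, rel=0.05)
        # chi-square goodness of fit against the predicted Gaussian
        z = (phi - mean_th) / math.sqrt(var_th)
        edges = np.array([-np.inf, -2, -1.5, -1, -0.5, 0, 0.5, 1, 1.5, 2, np.inf])
        obs = np.histogram(z[::8], bins=edges)[0]  # thin to ~independent
        prob = np.diff(stats.norm.cdf(edges))
        chi2 = ((obs - prob * obs.sum()) ** 2 / (prob * obs.sum())).sum()
        assert stats.chi2.sf(chi2, df=len(obs) - 1) > 1e-4

    def test_empty_production_gives_empty_series(self):
        p = rt.SimulationParameters(N=40)
        cfg = initialize_configuration("circular_fixed_lk", 40, p, delta_lk=0)
        eng = EngineState(cfg, p, seed=1)
        ss = eng.run(0, 0, 100)
        assert ss.n_samples == 0

    def test_audit_catches_corrupted_state(self):
        p = rt.SimulationParameters(N=60)
        cfg = initialize_configuration("circular_fixed_lk", 60, p, delta_lk=-6)
        eng = EngineState(cfg, p, seed=3)
        eng.equilibrate(10_000)
        # reflect an arc through the centre of mass: a bundle of strand
        # passages, so Tw+Wr no longer matches ΔLk
        com = eng.pos.mean(axis=0)
        eng.pos[5:15] = 2 * com - eng.pos[5:15]
        eng._refresh_derived()
        with pytest.raises(TopologyAuditError):
            eng.audit()

    def test_linear_mode_respects_clamps(self):
        N = 90
        p = rt.SimulationParameters(N=N)
        ext = N * p.l0 / 9
        cfg = initialize_configuration("linear_fixed_extension", N, p,
                                       delta_lk=-8, extension=ext)
        ends = (cfg.positions[0].copy(), cfg.positions[1].copy(),
                cfg.positions[-2].copy(), cfg.positions[-1].copy())
        f_ends = (cfg.fhat[0].copy(), cfg.fhat[-1].copy())
        eng = EngineState(cfg, p, seed=17, max_arc=20)
        eng.equilibrate(60_000)
        out = eng.to_configuration()
        out.validate()
        np.testing.assert_allclose(out.positions[0], ends[0], atol=1e-12)
        np.testing.assert_allclose(out.positions[1], ends[1], atol=1e-12)
        np.testing.assert_allclose(out.positions[-2], ends[2], atol=1e-12)
        np.testing.assert_allclose(out.positions[-1], ends[3], atol=1e-12)
        np.testing.assert_allclose(out.fhat[0], f_ends[0], atol=1e-12)
        np.testing.assert_allclose(out.fhat[-1], f_ends[1], atol=1e-12)
        assert np.linalg.norm(out.positions[-1] - out.positions[0]) == \
            pytest.approx(ext, abs=1e-9)
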