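"""Energy terms on analytically known configurations."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import ringtwist as rt
from ringtwist import energy
from ringtwist.chain import GeometryError
from ringtwist.fixtures import planar_circle, straight_clamped, twisted_ring


def rigid_motion(cfg, seed=0):
    rot = Rotation.random(random_state=seed).as_matrix()
    shift = np.array([13.0, -40.0, 7.5])
    out = cfg.copy()
    out.positions = cfg.positions @ rot.T + shift
    out.fhat = cfg.fhat @ rot.T
    return out


class TestBending:
    def test_regular_polygon_closed_form(self):
        # N equal bends of 2π/N: Σ (A/2l0)θ² = (43/20)·100·(2π/100)²
        cfg = planar_circle(n=100, l0=10)
        p = rt.SimulationParameters(N=100, A=43.0)
        assert energy.bending_energy(cfg, p) == pytest.approx(
            43 / 20 * 100 * (2 * math.pi / 100) ** 2, rel=1e-12)

    def test_straight_chain_is_zero(self):
        cfg = straight_clamped(n=50)
        p = rt.SimulationParameters(N=50)
        assert energy.bending_energy(cfg, p) == 0.0

    def test_linear_in_stiffness(self):
        cfg = planar_circle(n=64)
        p1 = rt.SimulationParameters(N=64, A=43.0)
        p2 = rt.SimulationParameters(N=64, A=86.0)
        assert energy.bending_energy(cfg, p2) == pytest.approx(
            2 * energy.bending_energy(cfg, p1), rel=1e-12)


class TestTwist:
    def test_relaxed_ring_is_zero(self):
        cfg = planar_circle(n=80)
        p = rt.SimulationParameters(N=80)
        assert energy.twist_energy(cfg, p) == pytest.approx(0.0, abs=1e-18)

    def test_uniformly_twisted_ring_closed_form(self):
        # φ = 2π·10/100 at each of 100 junctions, C=110, l0=10
        cfg = twisted_ring(n=100, k=10)
        p = rt.SimulationParameters(N=100, C=110.0)
        expect = 110 / 20 * 100 * (2 * math.pi * 0.1) ** 2
        assert energy.twist_energy(cfg, p) == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(217.1, abs=0.1)

    def test_invariant_under_twist_permutation(self):
        # redistributing the same multiset of junction angles along the
        # ring leaves the (uniform-C) twist energy unchanged
        from ringtwist.runio import config_from_snapshot
        rng = np.random.default_rng(5)
        base = planar_circle(n=40)
        phi = np.concatenate([[0.0], rng.normal(0, 0.3, 39)])
        p = rt.SimulationParameters(N=40)
        e_ref = None
        for perm_seed in (1, 2):
            shuffled = phi.copy()
            rng2 = np.random.default_rng(perm_seed)
            shuffled[1:] = rng2.permutation(phi[1:])
            cfg = config_from_snapshot(base.positions, shuffled,
                                       "circular_fixed_lk")
            e = energy.twist_energy(cfg, p)
            if e_ref is None:
                e_ref = e
            else:
                assert e == pytest.approx(e_ref, rel=1e-9)


class TestElectrostatics:
    def test_single_pair_closed_form(self):
        # U-shaped 3-segment chain: only the two parallel arms interact,
        # at rod-rod distance 3·λ_D exactly
        from ringtwist.chain import ChainConfiguration, transported_fhat
        lam, l0 = 0.8, 10.0
        r = 3 * lam
        pos = np.array([
            [0, 0, 0], [l0, 0, 0], [l0, 0, r], [0, 0, r],
        ], dtype=float)
        bonds = pos[1:] - pos[:-1]
        ehat = bonds / np.linalg.norm(bonds, axis=1)[:, None]
        cfg = ChainConfiguration(pos, transported_fhat(ehat),
                                 "linear_fixed_extension", extension=r)
        p = rt.SimulationParameters(N=3, debye_length=lam, el_cutoff=7 * lam)
        expect = p.el_prefactor * l0**2 * math.exp(-3.0) / (r * p.kBT)
        assert energy.electrostatic_energy(cfg, p) == pytest.approx(expect, rel=1e-12)

    @staticmethod
    def _oracle(cfg, p):
        """Independent O(N²) double loop over rod-rod distances, no cutoff
        shortcuts beyond the configured radius."""
        n = cfg.n_segments
        pos = cfg.positions
        scale = p.el_prefactor * p.l0**2 / p.kBT
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i >= j:
                    continue
                sep = min(abs(i - j), n - abs(i - j)) if cfg.closed else abs(i - j)
                if sep <= p.el_exclude:
                    continue
                r = _min_seg_dist(pos[i], pos[(i + 1) % len(pos)],
                                  pos[j], pos[(j + 1) % len(pos)])
                if r < p.el_cutoff:
                    total += scale * math.exp(-r / p.debye_length) / r
        return total

    def test_far_apart_segments_zero(self):
        cfg = planar_circle(n=60, l0=10)  # radius ~95 nm, gaps >> cutoff
        p = rt.SimulationParameters(N=60)
        assert energy.electrostatic_energy(cfg, p) == 0.0

    def test_matches_bruteforce_on_compact_fixture(self):
        from ringtwist.fixtures import solenoid
        cfg = solenoid(n=80, n_coils=5, major_radius=60, minor_radius=18)
        p = rt.SimulationParameters(N=80, debye_length=2.0, el_cutoff=40.0)
        got = energy.electrostatic_energy(cfg, p)
        assert got > 0
        assert got == pytest.approx(self._oracle(cfg, p), rel=1e-10)

    def test_hard_overlap_signals(self):
        cfg = planar_circle(n=40, l0=10)
        squeezed = cfg.copy()
        squeezed.positions *= 0.02  # everything inside the hard core
        p = rt.SimulationParameters(N=40, el_cutoff=100.0)
        with pytest.raises(GeometryError):
            energy.electrostatic_energy(squeezed, p)


def _min_seg_dist(p1, q1, p2, q2):
    """Brute-force minimum distance between two segments by dense sampling
    refinement (independent of the analytic closest-point routine)."""
    ts = np.linspace(0, 1, 41)
    a = p1[None, :] + ts[:, None] * (q1 - p1)[None, :]
    b = p2[None, :] + ts[:, None] * (q2 - p2)[None, :]
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    lo_i, hi_i = max(ts[i] - 0.05, 0), min(ts[i] + 0.05, 1)
    lo_j, hi_j = max(ts[j] - 0.05, 0), min(ts[j] + 0.05, 1)
    for _ in range(12):
        ti = np.linspace(lo_i, hi_i, 9)
        tj = np.linspace(lo_j, hi_j, 9)
        a = p1[None, :] + ti[:, None] * (q1 - p1)[None, :]
        b = p2[None, :] + tj[:, None] * (q2 - p2)[None, :]
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        span_i, span_j = (hi_i - lo_i) / 4, (hi_j - lo_j) / 4
        lo_i, hi_i = max(ti[i] - span_i, 0), min(ti[i] + span_i, 1)
        lo_j, hi_j = max(tj[j] - span_j, 0), min(tj[j] + span_j, 1)
    return d[i, j]


class TestStretch:
    def test_rest_length_zero(self):
        cfg = planar_circle(n=50)
        p = rt.SimulationParameters(N=50)
        assert energy.stretch_energy(cfg, p) == pytest.approx(0.0, abs=1e-20)

    def test_single_stretched_segment(self):
        cfg = straight_clamped(n=10)
        cfg.positions[10, 0] += 0.1  # stretch the last segment by 0.1 nm
        cfg.extension = float(np.linalg.norm(cfg.positions[-1] - cfg.positions[0]))
        p = rt.SimulationParameters(N=10, k_spring=200.0, kBT=4.11)
        assert energy.stretch_energy(cfg, p) == pytest.approx(
            200 * 0.01 / (2 * 4.11), rel=1e-9)

    def test_rigid_motion_invariance(self):
        cfg = twisted_ring(n=30, k=2)
        cfg.positions[4] += 0.3  # break the perfect lengths
        p = rt.SimulationParameters(N=30)
        assert energy.stretch_energy(rigid_motion(cfg), p) == pytest.approx(
            energy.stretch_energy(cfg, p), rel=1e-9)


class TestBreakdownAndInvariances:
    def test_total_is_sum_of_terms(self):
        from ringtwist.fixtures import solenoid
        cfg = solenoid(n=60, n_coils=4, major_radius=70, minor_radius=20)
        p = rt.SimulationParameters(N=60, debye_length=2.0, el_cutoff=30.0)
        eb = energy.energy_breakdown(cfg, p)
        assert eb.total == pytest.approx(
            eb.bend + eb.twist + eb.electrostatic + eb.stretch, rel=1e-10)
        # independent re-evaluation of each term
        assert eb.bend == energy.bending_energy(cfg, p)
        assert eb.electrostatic == energy.electrostatic_energy(cfg, p)

    def test_rigid_motion_invariance_all_terms(self):
        from ringtwist.fixtures import solenoid
        cfg = solenoid(n=48, n_coils=3, major_radius=60, minor_radius=20)
        p = rt.SimulationParameters(N=48, debye_length=2.0, el_cutoff=30.0)
        a = energy.energy_breakdown(cfg, p)
        b = energy.energy_breakdown(rigid_motion(cfg, seed=3), p)
        for name in ("bend", "twist", "electrostatic", "stretch"):
            assert getattr(b, name) == pytest.approx(
                getattr(a, name), rel=1e-9, abs=1e-12)

    def test_per_segment_arrays_match_scalar_path(self):
        cfg = twisted_ring(n=40, k=-3)
        ps = rt.SimulationParameters(N=40, A=43.0, C=110.0)
        pa = rt.SimulationParameters(N=40, A=np.full(40, 43.0), C=np.full(40, 110.0))
        assert energy.bending_energy(cfg, pa) == energy.bending_energy(cfg, ps)
        assert energy.twist_energy(cfg, pa) == energy.twist_energy(cfg, ps)

    def test_zero_prefactor_removes_electrostatics(self):
        from ringtwist.fixtures import solenoid
        cfg = solenoid(n=48, n_coils=4, major_radius=50, minor_radius=16)
        p0 = rt.SimulationParameters(N=48, el_prefactor=0.0, debye_length=2.0)
        eb = energy.energy_breakdown(cfg, p0)
        assert eb.electrostatic == 0.0
        assert eb.total == eb.bend + eb.twist + eb.stretch

    def test_mismatched_N_raises(self):
        cfg = planar_circle(n=30)
        with pytest.raises(ValueError):
            energy.bending_energy(cfg, rt.SimulationParameters(N=31))
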