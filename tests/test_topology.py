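"""Twist extraction, writhe, and the Călugăreanu identity Lk = Tw + Wr."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import ringtwist as rt
from ringtwist import topology
from ringtwist.chain import ChainConfiguration, GeometryError, transported_fhat
from ringtwist.fixtures import planar_circle, solenoid, straight_clamped, twisted_ring


# ----------------------------------------------------------------------
# oracles
# ----------------------------------------------------------------------
def swing_twist_oracle(e0, f0, e1, f1):
    """Twist angle via quaternion swing–twist decomposition (scipy)."""
    g0, g1 = np.cross(e0, f0), np.cross(e1, f1)
    R0 = np.column_stack([e0, f0, g0])
    R1 = np.column_stack([e1, f1, g1])
    rel = Rotation.from_matrix(R1 @ R0.T)
    q = rel.as_quat()  # (x, y, z, w)
    # project the rotation onto the twist axis e1 (swing-twist split)
    proj = np.dot(q[:3], e1)
    twist = Rotation.from_quat([*(proj * e1), q[3]])
    ang = 2.0 * math.atan2(proj, q[3])
    # map into (-pi, pi]
    while ang <= -math.pi:
        ang += 2 * math.pi
    while ang > math.pi:
        ang -= 2 * math.pi
    return ang


def writhe_bruteforce(positions):
    """Pure-numpy O(N²) Gauss sum over the closed polygon (Levitt-style
    discrete double integral via exact pair solid angles)."""
    nv = len(positions)
    total = 0.0
    for i in range(nv):
        for j in range(i + 2, nv):
            if i == 0 and j == nv - 1:
                continue
            total += _pair_solid_angle(
                positions[i], positions[(i + 1) % nv],
                positions[j], positions[(j + 1) % nv])
    return total


def _pair_solid_angle(p1, p2, p3, p4):
    # signed area of the Gauss-map quadrilateral, fanned into two
    # spherical triangles (numpy implementation, independent of the kernel)
    vecs = [p3 - p1, p4 - p1, p4 - p2, p3 - p2]
    norms = [np.linalg.norm(v) for v in vecs]
    if min(norms) < 1e-10:
        return 0.0
    a, b, c, d = [v / s for v, s in zip(vecs, norms)]

    def tri(u, v, w):
        num = float(np.dot(u, np.cross(v, w)))
        if num == 0.0:
            return 0.0
        den = 1.0 + np.dot(u, v) + np.dot(v, w) + np.dot(w, u)
        return 2.0 * math.atan2(num, den)

    return -(tri(a, b, c) + tri(a, c, d)) / (2 * math.pi)


# ----------------------------------------------------------------------
# junction twist
# ----------------------------------------------------------------------
class TestJunctionTwist:
    def test_identical_frames_zero(self):
        e = np.array([1.0, 0, 0]); f = np.array([0, 1.0, 0])
        frame = np.stack([e, f, np.cross(e, f)])
        assert topology.junction_twist_angle(frame, frame) == 0.0

    def test_pure_twist_about_shared_tangent(self):
        e = np.array([0, 0, 1.0]); f = np.array([1.0, 0, 0])
        rot = Rotation.from_rotvec(0.3 * e)
        f2 = rot.apply(f)
        fr1 = np.stack([e, f, np.cross(e, f)])
        fr2 = np.stack([e, f2, np.cross(e, f2)])
        assert topology.junction_twist_angle(fr1, fr2) == pytest.approx(0.3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_quaternion_swing_twist_oracle(self, seed):
        rng = np.random.default_rng(seed)
        R0 = Rotation.random(random_state=seed).as_matrix()
        R1 = Rotation.random(random_state=seed + 100).as_matrix()
        e0, f0 = R0[:, 0], R0[:, 1]
        e1, f1 = R1[:, 0], R1[:, 1]
        if np.dot(e0, e1) < -0.999:
            pytest.skip("near-antipodal tangents excluded")
        got = topology.junction_twist_angle(np.stack([e0, f0, np.cross(e0, f0)]),
                                            np.stack([e1, f1, np.cross(e1, f1)]))
        assert got == pytest.approx(swing_twist_oracle(e0, f0, e1, f1), abs=1e-10)

    def test_antipodal_tangent_raises(self):
        e = np.array([1.0, 0, 0]); f = np.array([0, 1.0, 0])
        fr1 = np.stack([e, f, np.cross(e, f)])
        fr2 = np.stack([-e, f, np.cross(-e, f)])
        with pytest.raises(GeometryError):
            topology.junction_twist_angle(fr1, fr2)


class TestTotalTwist:
    def test_untwisted_circle_zero(self):
        assert topology.total_twist(planar_circle(n=60)) == pytest.approx(0, abs=1e-12)

    @pytest.mark.parametrize("k", [1, -5, 17])
    def test_uniformly_twisted_ring_exact(self, k):
        assert topology.total_twist(twisted_ring(n=100, k=k)) == pytest.approx(
            k, abs=1e-9)

    def test_rigid_rotation_invariance(self):
        cfg = twisted_ring(n=50, k=-4)
        R = Rotation.random(random_state=7).as_matrix()
        rotated = ChainConfiguration(cfg.positions @ R.T, cfg.fhat @ R.T,
                                     cfg.mode, cfg.delta_lk)
        assert topology.total_twist(rotated) == pytest.approx(
            topology.total_twist(cfg), abs=1e-9)

    def test_additive_over_contiguous_partitions(self):
        cfg = solenoid(n=90, n_coils=3)
        phi = topology.junction_twist_angles(cfg)
        total = topology.total_twist(cfg)
        parts = [phi[:30].sum(), phi[30:71].sum(), phi[71:].sum()]
        assert sum(parts) / (2 * math.pi) == pytest.approx(total, abs=1e-12)


class TestWrithe:
    def test_planar_circle_zero(self):
        assert topology.total_writhe(planar_circle(n=80)) == pytest.approx(0, abs=1e-9)

    def test_mirror_negates(self):
        cfg = solenoid(n=120, n_coils=4)
        mirrored = cfg.copy()
        mirrored.positions[:, 2] *= -1
        w = topology.total_writhe(cfg)
        assert abs(w) > 0.5
        assert topology.total_writhe(mirrored) == pytest.approx(-w, abs=1e-10)

    def test_matches_bruteforce_double_loop(self):
        cfg = solenoid(n=70, n_coils=5, major_radius=80, minor_radius=25)
        assert topology.total_writhe(cfg) == pytest.approx(
            writhe_bruteforce(cfg.positions), abs=1e-10)

    def test_solenoid_matches_quadrature_oracle(self):
        # dense midpoint quadrature of the Gauss double integral over the
        # smooth curve; the polygon value converges to it as n grows
        R, a, q = 100.0, 30.0, 4
        M = 700
        t = 2 * np.pi * (np.arange(M) + 0.5) / M
        r = R + a * np.cos(q * t)
        P = np.column_stack([r * np.cos(t), r * np.sin(t), a * np.sin(q * t)])
        dr = -a * q * np.sin(q * t)
        D = np.column_stack([dr * np.cos(t) - r * np.sin(t),
                             dr * np.sin(t) + r * np.cos(t),
                             a * q * np.cos(q * t)])
        diff = P[None, :, :] - P[:, None, :]
        n3 = np.einsum("ijk,ijk->ij", diff, diff) ** 1.5
        np.fill_diagonal(n3, np.inf)
        num = np.einsum("ijk,ijk->ij", np.cross(D[None, :, :], D[:, None, :]), diff)
        wr_oracle = (num / n3).sum() * (2 * np.pi / M) ** 2 / (4 * np.pi)
        cfg = solenoid(n=800, n_coils=q, major_radius=R, minor_radius=a)
        assert topology.total_writhe(cfg) == pytest.approx(wr_oracle, abs=1e-3)

    def test_closed_ribbon_linking_is_integer(self):
        # transported frames on any closed curve give integer Tw + Wr
        cfg = solenoid(n=150, n_coils=5)
        lk = topology.total_twist(cfg) + topology.total_writhe(cfg)
        assert lk == pytest.approx(round(lk), abs=1e-8)


class TestVerifyTopology:
    def test_fresh_twisted_ring_passes(self):
        ok, rec = topology.verify_topology(twisted_ring(n=100, k=-36), -36)
        assert ok
        assert rec.twist == pytest.approx(-36, abs=1e-9)
        assert rec.writhe == pytest.approx(0, abs=1e-9)

    def test_strand_passage_changes_linking_by_two(self):
        # swapping over/under at a crossing is a strand passage; the mirror
        # image of a ribbon with Lk = −1 realizes exactly that swap
        cfg = solenoid(n=100, n_coils=4, major_radius=100, minor_radius=30)
        lk0 = topology.total_twist(cfg) + topology.total_writhe(cfg)
        assert lk0 == pytest.approx(-1, abs=1e-6)
        passed = cfg.copy()
        passed.positions[:, 2] *= -1
        passed.fhat[:, 2] *= -1
        lk1 = topology.total_twist(passed) + topology.total_writhe(passed)
        assert lk1 - lk0 == pytest.approx(2, abs=1e-6)
        ok, rec = topology.verify_topology(passed, lk0, tol=0.5)
        assert not ok
        assert abs(rec.linking - lk0) == pytest.approx(2, abs=1e-6)

    def test_infinite_tolerance_always_passes(self):
        ok, _ = topology.verify_topology(twisted_ring(n=40, k=3), 999.0,
                                         tol=math.inf)
        assert ok


class TestLinearClosure:
    def test_straight_clamped_topology(self):
        cfg = straight_clamped(n=40, turns=-3)
        assert topology.total_twist(cfg) == pytest.approx(-3, abs=1e-9)
        assert topology.total_writhe(cfg) == pytest.approx(0, abs=1e-9)

    def test_closure_is_far_from_chain(self):
        cfg = straight_clamped(n=30)
        virt = topology.closure_path(cfg)
        d = np.linalg.norm(virt[:, None, :] - cfg.positions[None, :, :], axis=-1)
        assert d.min() > cfg.n_segments * 10  # at least one contour away
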