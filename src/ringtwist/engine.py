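"""Metropolis Monte Carlo over chain configurations in three boundary modes.

The sampler mixes three reversible, symmetric proposals:

* **crankshaft** — rigid rotation of a contiguous sub-arc (vertices and
  frames) about the chord through its end pivots,
* **vertex** — Gaussian displacement of a single vertex, with the material
  frames of the two flanking segments re-aimed by the minimal rotation
  between old and new tangents (this move samples the spring lengths and
  thus feeds the tension readout),
* **twist** — rotation of one segment's frame about its own tangent, which
  exchanges twist between the two flanking junctions and conserves total
  twist exactly.

In the fixed-ΔLk modes every accepted backbone move passes a strand-passage
guard: legitimate moves leave Tw + Wr unchanged (the identity Lk = Tw + Wr
holds exactly for the discrete ribbon), while a passage jumps it by ±2
turns, so any change above 0.45 turns forces rejection.  The nicked mode
runs the same machinery with zero twist stiffness as ghost bookkeeping to
keep the backbone unknotted; its twist fluctuations are attached
analytically (they are Gaussian with variance L/4π²C and decouple from the
backbone).

Proposal amplitudes are auto-tuned toward ~40% acceptance during
equilibration and frozen for production, preserving detailed balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .chain import ChainConfiguration, GeometryError, transported_fhat
from .fixtures import twisted_ring
from .parameters import SimulationParameters
from .topology import circuit_vertices

__all__ = [
    "SampleSet",
    "MoveProposal",
    "EngineState",
    "TopologyAuditError",
    "initialize_configuration",
    "interwound_start",
    "apply_crankshaft",
    "apply_twist_rotation",
]

TWOPI = 2.0 * math.pi


class TopologyAuditError(RuntimeError):
    """Raised when the running topology bookkeeping disagrees with a
    from-scratch recomputation (strand passage or frame corruption)."""


# ----------------------------------------------------------------------
# initial configurations
# ----------------------------------------------------------------------
def _serpentine_positions(n_seg: int, l0: float, extension: float) -> np.ndarray:
    """Planar serpentine from (0,0,0) to (extension,0,0), both end tangents
    along +x̂, with n_seg segments of length ≈ l0 (horizontal runs are
    uniformly scaled by <2% to land the clamp exactly)."""
    if extension >= n_seg * l0:
        raise ValueError("extension must be smaller than the contour length")
    n_h = max(int(round(extension / l0)), 6)
    if (n_seg - n_h) % 2:  # columns come in up/down pairs of equal height
        n_h += 1
    n_v = n_seg - n_h
    if n_v < 6:
        raise ValueError("extension too close to the contour length")
    # vertical segments split into an even number of paired columns whose
    # height is comparable to the extension
    col_h = max(3, int(round(extension / l0)))
    n_col = max(2, int(math.ceil(n_v / col_h)))
    if n_col % 2:
        n_col += 1
    while n_col - 1 > n_h - 4:  # keep at least 2 lead segments per end
        n_col -= 2
        if n_col < 2:
            raise ValueError("cannot build serpentine: extension too short")
    base = n_v // n_col
    extra = n_v - base * n_col  # even by construction; spread pairwise
    heights = [base] * n_col
    for p in range(extra // 2):
        heights[(2 * p) % n_col] += 1
        heights[(2 * p + 1) % n_col] += 1
    lh = extension / n_h  # uniform horizontal step
    m_lead = (n_h - (n_col - 1)) // 2
    m_tail = n_h - (n_col - 1) - m_lead

    pts = [np.zeros(3)]
    x = y = 0.0
    for _ in range(m_lead):
        x += lh
        pts.append(np.array([x, y, 0.0]))
    for c in range(n_col):
        direction = 1.0 if c % 2 == 0 else -1.0
        for _ in range(heights[c]):
            y += direction * l0
            pts.append(np.array([x, y, 0.0]))
        if c < n_col - 1:
            x += lh
            pts.append(np.array([x, y, 0.0]))
    for _ in range(m_tail):
        x += lh
        pts.append(np.array([x, y, 0.0]))
    pos = np.array(pts)
    if abs(y) > 1e-9 or abs(x - extension) > 1e-6:
        raise RuntimeError("serpentine construction failed to close")
    return pos


def initialize_configuration(
    mode: str,
    N: int,
    params: SimulationParameters,
    delta_lk: float = 0.0,
    extension: float | None = None,
) -> ChainConfiguration:
    """Build the starting configuration for a run.

    Circular modes: planar regular N-gon with uniform junction twist
    2π·ΔLk/N (so ΔTw = ΔLk, ΔWr = 0).  Linear mode: planar serpentine
    between clamps ``extension`` apart with uniform imposed twist; the end
    tangents lie along the stretching axis.
    """
    if N != params.N:
        raise ValueError(f"N={N} does not match params.N={params.N}")
    if mode in ("circular_fixed_lk", "nicked_circular"):
        dlk = 0.0 if mode == "nicked_circular" else delta_lk
        return twisted_ring(N, dlk, params.l0, mode=mode)
    if mode == "linear_fixed_extension":
        if extension is None:
            raise ValueError("linear mode requires an extension")
        if not 0 < extension < N * params.l0:
            raise ValueError("extension must lie in (0, contour length)")
        pos = _serpentine_positions(N, params.l0, extension)
        bonds = pos[1:] - pos[:-1]
        ehat = bonds / np.linalg.norm(bonds, axis=1)[:, None]
        fhat = transported_fhat(ehat)
        # add uniform twist over the N-1 junctions
        alpha = TWOPI * delta_lk / (N - 1)
        for i in range(N):
            a = alpha * i
            c, s = math.cos(a), math.sin(a)
            e = ehat[i]
            f = fhat[i]
            fhat[i] = f * c + np.cross(e, f) * s
        cfg = ChainConfiguration(pos, fhat, mode, delta_lk=delta_lk,
                                 extension=extension)
        cfg.validate()
        return cfg
    raise ValueError(f"unknown mode {mode!r}")


def interwound_start(N: int, params: SimulationParameters, delta_lk: float,
                     superhelix_radius: float = 10.0) -> ChainConfiguration:
    """Pre-writhed starting configuration for supercoiled circular runs.

    Builds a closed two-strand interwound loop (two antiparallel helical
    strands around a common axis, closed by end loops) whose writhe carries
    most of the imposed ΔLk, with the remainder placed as uniform twist.
    Equilibrating from this shape only requires local relaxation, whereas
    the planar twisted ring must first nucleate and grow a plectoneme —
    a much slower coarsening process.  The shape is an unknot and respects
    the hard core, so it is a valid member of the fixed-ΔLk ensemble.
    """
    if abs(delta_lk) < 3:
        return twisted_ring(N, delta_lk, params.l0)
    l0 = params.l0
    L = N * l0
    r_s = superhelix_radius
    cap_len = math.pi * r_s
    strand_len = (L - 2 * cap_len) / 2
    m = min(max(2, int(0.39 * abs(delta_lk))),
            max(2, int(strand_len / (1.2 * 2 * math.pi * r_s))))
    lam = strand_len / m                     # strand length per superhelical turn
    height = m * math.sqrt(max(lam**2 - (2 * math.pi * r_s) ** 2, 1.0))
    s = 1.0 if delta_lk < 0 else -1.0        # superhelix chirality

    def point(arc: float) -> np.ndarray:
        """Position at contour coordinate ``arc`` along the closed curve."""
        if arc < strand_len:                 # strand A, ascending
            t = arc / strand_len
            th = s * 2 * math.pi * m * t
            return np.array([r_s * math.cos(th), r_s * math.sin(th),
                             t * height])
        arc -= strand_len
        th1 = s * 2 * math.pi * m
        d = np.array([math.cos(th1), math.sin(th1), 0.0])
        if arc < cap_len:                    # top cap
            u = math.pi * arc / cap_len
            return (r_s * math.cos(u) * d
                    + np.array([0.0, 0.0, height + r_s * math.sin(u)]))
        arc -= cap_len
        if arc < strand_len:                 # strand B, descending
            t = arc / strand_len
            th = th1 + math.pi - s * 2 * math.pi * m * t
            return np.array([r_s * math.cos(th), r_s * math.sin(th),
                             (1 - t) * height])
        arc -= strand_len                    # bottom cap
        u = math.pi * arc / cap_len
        return (-r_s * math.cos(u) * np.array([1.0, 0.0, 0.0])
                + np.array([0.0, 0.0, -r_s * math.sin(u)]))

    pos = np.array([point(L * i / N) for i in range(N)])
    # chords are slightly shorter than arcs on curved sections: rescale so
    # the mean segment length is the rest length (springs absorb the rest)
    bonds = np.roll(pos, -1, axis=0) - pos
    pos *= l0 / np.linalg.norm(bonds, axis=1).mean()
    bonds = np.roll(pos, -1, axis=0) - pos
    ehat = bonds / np.linalg.norm(bonds, axis=1)[:, None]
    fhat = transported_fhat(ehat)
    cfg = ChainConfiguration(pos, fhat, "circular_fixed_lk", delta_lk=delta_lk)
    # place the remainder of ΔLk into uniform twist on top of the transport
    # frames; the closure junction wraps mod 2π, so correct iteratively
    from .topology import total_twist, total_writhe
    base = fhat.copy()
    lk_now = total_twist(cfg) + total_writhe(cfg)
    dphi = TWOPI * (delta_lk - lk_now) / N
    for _ in range(4):
        if abs(dphi) > 2.5:
            raise GeometryError(
                f"interwound start cannot place ΔLk={delta_lk}: residual "
                f"junction twist {dphi:.2f} rad")
        for i in range(N):
            a = dphi * i
            c, sn = math.cos(a), math.sin(a)
            f = base[i]
            e = ehat[i]
            fhat[i] = f * c + np.cross(e, f) * sn
        cfg = ChainConfiguration(pos, fhat, "circular_fixed_lk",
                                 delta_lk=delta_lk)
        miss = delta_lk - (total_twist(cfg) + total_writhe(cfg))
        if abs(miss) < 1e-9:
            break
        dphi += TWOPI * miss / N
    cfg.validate()
    return cfg


# ----------------------------------------------------------------------
# reference move operations (pure, configuration-level; the production
# kernel implements the same updates in place)
# ----------------------------------------------------------------------
@dataclass
class MoveProposal:
    """One proposed elementary move."""

    kind: str  # crankshaft | vertex | twist_exchange
    start: int
    length: int
    angle: float = 0.0
    displacement: np.ndarray | None = None


def apply_crankshaft(config: ChainConfiguration, start: int, length: int,
                     angle: float) -> ChainConfiguration:
    """Rigidly rotate the sub-arc of ``length`` segments beginning at
    segment ``start`` about the chord through its end pivots."""
    new = config.copy()
    ncv = new.positions.shape[0]
    a, b = start, (start + length) % ncv
    axis = new.positions[b] - new.positions[a]
    nrm = np.linalg.norm(axis)
    if nrm < 1e-9:
        raise GeometryError("degenerate crankshaft chord")
    k = axis / nrm
    c, s = math.cos(angle), math.sin(angle)

    def rot(v):
        return v * c + np.cross(k, v) * s + k * np.dot(k, v) * (1.0 - c)

    for t in range(1, length):
        v = (a + t) % ncv
        new.positions[v] = new.positions[a] + rot(new.positions[v] - new.positions[a])
    nseg = new.n_segments
    for t in range(length):
        sseg = (a + t) % ncv
        if sseg < nseg:
            new.fhat[sseg] = rot(new.fhat[sseg])
    return new


def apply_twist_rotation(config: ChainConfiguration, segment: int,
                         beta: float) -> ChainConfiguration:
    """Rotate one segment's frame about its tangent by ``beta`` (rad);
    exchanges twist between the two flanking junctions."""
    new = config.copy()
    e = new.ehat()[segment]
    f = new.fhat[segment]
    c, s = math.cos(beta), math.sin(beta)
    new.fhat[segment] = f * c + np.cross(e, f) * s + e * np.dot(e, f) * (1.0 - c)
    return new


# ----------------------------------------------------------------------
# sample container
# ----------------------------------------------------------------------
@dataclass
class SampleSet:
    """Raw production samples from one run.

    ``phi``/``seg_len`` are (n_samples, N) arrays of per-junction twist
    angles (rad) and per-segment lengths (nm); ``twist``/``writhe`` are in
    turns; ``energies`` holds (bend, twist, electrostatic, stretch) in kBT.
    ``positions`` stores every ``pos_stride``-th sampled conformation.
    """

    phi: np.ndarray
    seg_len: np.ndarray
    twist: np.ndarray
    writhe: np.ndarray
    energies: np.ndarray
    positions: np.ndarray
    mode: str
    delta_lk: float
    sample_every: int
    pos_stride: int
    params: SimulationParameters
    extension: float | None = None
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.phi.shape[0]


# ----------------------------------------------------------------------
# the engine
# ----------------------------------------------------------------------
@dataclass
class _Amplitudes:
    crank: float = 0.8
    vertex: float = 0.25
    twist: float = 0.8


class EngineState:
    """Monte Carlo engine state: configuration, cached derived arrays,
    running topology/energy bookkeeping, RNG stream and counters.

    Parameters
    ----------
    config : ChainConfiguration
        Starting configuration (see :func:`initialize_configuration`).
    params : SimulationParameters
    seed : int
        Seeds the whole run; bursts draw child seeds from a private
        generator, so reruns are bit-reproducible.
    move_mix : (float, float, float)
        Proposal probabilities (crankshaft, vertex, twist).  The nicked
        mode forces the twist share to zero.
    max_arc : int, optional
        Largest crankshaft arc length in segments (default N//4, capped
        at 60).
    audit_every : int
        Moves between bookkeeping audits (from-scratch recomputation of
        energies, twist and writhe).
    """

    def __init__(self, config: ChainConfiguration, params: SimulationParameters,
                 seed: int, move_mix: tuple[float, float, float] = (0.4, 0.3, 0.3),
                 max_arc: int | None = None, audit_every: int = 5000):
        config.validate()
        if config.n_segments != params.N:
            raise ValueError("config/params segment count mismatch")
        self.params = params
        self.mode = config.mode
        self.delta_lk = config.delta_lk
        self.extension = config.extension
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self.audit_every = int(audit_every)
        self.step_count = 0
        self.attempts = np.zeros(3, dtype=np.int64)
        self.accepts = np.zeros(3, dtype=np.int64)
        self.guard_rejections = 0
        self.amplitudes = _Amplitudes()
        self._frozen = False

        N = params.N
        self.nseg = N
        self.closed = config.closed
        self.pos = np.ascontiguousarray(circuit_vertices(config))
        self.ncv = self.pos.shape[0]
        self.fh = config.fhat.copy()
        self._refresh_derived()

        self.A = params.A_array()
        C = params.C_array()
        self.nicked = self.mode == "nicked_circular"
        self.C_eff = np.zeros(N) if self.nicked else C
        pc, pv, pt = move_mix
        if self.nicked:
            pt = 0.0
        tot = pc + pv + pt
        self.p_crank, self.p_vertex, self.p_twist = pc / tot, pv / tot, pt / tot
        cap = max(4, min(N // 4, 60))
        self.max_arc = min(max_arc or cap, N - 2 if self.closed else N - 3)

        _, phi = _kernels.all_junction_angles(self.eh, self.fh, self.closed)
        self.phi = phi
        self.running = np.array([phi.sum(), _kernels.polygon_writhe(self.pos)])
        self.lk_book = self.running[0] / TWOPI + self.running[1]
        if self.mode == "circular_fixed_lk":
            if abs(self.lk_book - self.delta_lk) > 1e-6:
                raise TopologyAuditError(
                    f"initial Tw+Wr={self.lk_book:.6f} != delta_lk={self.delta_lk}")
        self.energies = np.array(self._energies_scratch())

        if self.closed:
            self._ranges = dict(vlo=0, vhi=N, clo=0, chi=N, tlo=0, thi=N)
        else:
            self._ranges = dict(vlo=2, vhi=N - 1, clo=1, chi=N - 1,
                                tlo=1, thi=N - 1)

    # -- derived-state helpers ------------------------------------------
    def _refresh_derived(self) -> None:
        p = self.pos
        n = self.nseg
        if self.closed:
            nxt = np.roll(p, -1, axis=0)
            bonds = nxt - p
        else:
            bonds = p[1:n + 1] - p[:n]
        self.slen = np.linalg.norm(bonds, axis=1)
        self.eh = np.ascontiguousarray(bonds / self.slen[:, None])

    def _energies_scratch(self):
        return self._energies_scratch_with(self.phi)

    @property
    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.attempts > 0, self.accepts / self.attempts, np.nan)

    def to_configuration(self) -> ChainConfiguration:
        nv = self.nseg if self.closed else self.nseg + 1
        return ChainConfiguration(self.pos[:nv].copy(), self.fh.copy(),
                                  self.mode, self.delta_lk, self.extension)

    # -- bookkeeping audit ----------------------------------------------
    def audit(self, tol_energy: float = 1e-6, tol_topology: float = 1e-3) -> dict:
        """Recompute energies, twist and writhe from scratch and reconcile.

        Raises :class:`TopologyAuditError` if Tw + Wr has drifted from the
        imposed linking number (strand passage or frame corruption).
        """
        # re-orthonormalize frames against floating-point drift
        self._refresh_derived()
        f = self.fh
        f -= np.einsum("ij,ij->i", f, self.eh)[:, None] * self.eh
        f /= np.linalg.norm(f, axis=1)[:, None]
        if self.nicked:
            # re-zero the ghost twist so junction angles stay small
            self.fh = transported_fhat(self.eh, f0=self.fh[0])
            _, phi = _kernels.all_junction_angles(self.eh, self.fh, self.closed)
            dphi = 0.0
        else:
            _, phi = _kernels.all_junction_angles(self.eh, self.fh, self.closed)
            # stored angles are continuous (unwrapped); atan2 reports them
            # modulo 2π, so compare and reassign on the stored branch
            phi += TWOPI * np.floor((self.phi - phi) / TWOPI + 0.5)
            dphi = float(np.max(np.abs(phi - self.phi)))
        wr = _kernels.polygon_writhe(self.pos)
        d_wr = abs(wr - self.running[1])
        e_new = np.array(self._energies_scratch_with(phi))
        e_drift = float(np.max(np.abs(e_new - self.energies)))
        self.phi = phi
        self.running[0] = phi.sum()
        self.running[1] = wr
        self.energies = e_new
        lk_now = self.running[0] / TWOPI + self.running[1]
        if self.nicked:
            self.lk_book = lk_now
        report = dict(step=self.step_count, phi_drift=float(dphi),
                      writhe_drift=float(d_wr), energy_drift=e_drift,
                      lk=float(lk_now))
        if not self.nicked and abs(lk_now - self.lk_book) > tol_topology:
            raise TopologyAuditError(
                f"Tw+Wr={lk_now:.6f} deviates from ΔLk={self.lk_book:.6f} "
                f"at step {self.step_count}: {report}")
        if e_drift > max(tol_energy, 1e-8 * abs(e_new.sum())) * 100:
            raise TopologyAuditError(f"energy bookkeeping drift: {report}")
        return report

    def _energies_scratch_with(self, phi):
        pr = self.params
        return _kernels.total_energies(
            self.pos, self.eh, self.fh, self.slen, phi,
            self.nseg, self.ncv, self.closed, self.A, self.C_eff, pr.l0,
            pr.k_spring / (2.0 * pr.kBT),
            pr.el_prefactor * pr.l0**2 / pr.kBT,
            1.0 / pr.debye_length, pr.el_cutoff, pr.hard_core, pr.el_exclude)

    # -- running the kernel ---------------------------------------------
    def _burst(self, n_steps: int, sample_every: int, bufs, samp_start: int,
               pos_stride: int) -> int:
        pr = self.params
        r = self._ranges
        a = self.amplitudes
        seed = int(self._rng.integers(0, 2**31 - 1))
        g_rej = np.zeros(1, dtype=np.int64)
        out = _kernels.mc_kernel(
            self.pos, self.fh, self.eh, self.slen, self.phi,
            self.nseg, self.ncv, self.closed,
            self.A, self.C_eff, pr.l0,
            pr.k_spring / (2.0 * pr.kBT),
            pr.el_prefactor * pr.l0**2 / pr.kBT,
            1.0 / pr.debye_length, pr.el_cutoff, pr.hard_core, pr.el_exclude,
            True, self.lk_book,
            self.running, self.energies,
            self.p_crank, self.p_vertex, self.max_arc,
            a.crank, a.vertex, a.twist,
            r["vlo"], r["vhi"], r["clo"], r["chi"], r["tlo"], r["thi"],
            n_steps, sample_every,
            bufs["phi"], bufs["len"], bufs["wr"], bufs["tw"], bufs["e"],
            pos_stride, bufs["pos"], samp_start,
            seed, self.attempts, self.accepts, g_rej)
        self.guard_rejections += int(g_rej[0])
        self.step_count += n_steps
        return out

    @staticmethod
    def _empty_bufs(n_samples: int, nseg: int, nv: int, pos_stride: int):
        npos = 0 if pos_stride <= 0 else (n_samples + pos_stride - 1) // pos_stride
        return dict(
            phi=np.empty((n_samples, nseg)),
            len=np.empty((n_samples, nseg)),
            wr=np.empty(n_samples),
            tw=np.empty(n_samples),
            e=np.empty((n_samples, 4)),
            pos=np.empty((npos, nv, 3)),
        )

    def equilibrate(self, n_steps: int, tune: bool = True,
                    target: float = 0.4) -> dict:
        """Relax the chain for ``n_steps`` moves, tuning proposal
        amplitudes toward the target acceptance, then freeze them."""
        burst = max(2000, min(self.audit_every, n_steps // 10 or n_steps))
        done = 0
        bufs = self._empty_bufs(0, self.nseg, 1, 0)
        while done < n_steps:
            n = min(burst, n_steps - done)
            a0, c0 = self.attempts.copy(), self.accepts.copy()
            self._burst(n, 0, bufs, 0, 0)
            done += n
            self.audit()
            if tune and not self._frozen:
                att = self.attempts - a0
                acc = self.accepts - c0
                rates = np.where(att > 0, acc / np.maximum(att, 1), target)
                amp = self.amplitudes
                for name, rate, hi in (("crank", rates[0], math.pi),
                                       ("vertex", rates[1], 3.0),
                                       ("twist", rates[2], math.pi)):
                    f = math.sqrt(max(rate, 0.02) / target)
                    f = min(max(f, 0.5), 2.0)
                    setattr(amp, name, min(max(getattr(amp, name) * f, 1e-3), hi))
        self._frozen = True
        return dict(amplitudes=self.amplitudes,
                    acceptance=self.acceptance_rates.tolist())

    def sample(self, n_steps: int, sample_every: int,
               pos_stride: int = 0) -> SampleSet:
        """Production sampling: record every ``sample_every`` moves."""
        if sample_every <= 0:
            raise ValueError("sample_every must be positive")
        n_samples = n_steps // sample_every
        nv = self.nseg if self.closed else self.nseg + 1
        bufs = self._empty_bufs(n_samples, self.nseg, nv, pos_stride)
        done = 0
        written = 0
        while done < n_steps:
            n = min(self.audit_every, n_steps - done)
            # keep bursts aligned with the sampling stride
            n = max(sample_every, (n // sample_every) * sample_every)
            n = min(n, n_steps - done)
            written = self._burst(n, sample_every, bufs, written,
                                  pos_stride)
            done += n
            self.audit()
        return SampleSet(
            phi=bufs["phi"][:written], seg_len=bufs["len"][:written],
            twist=bufs["tw"][:written], writhe=bufs["wr"][:written],
            energies=bufs["e"][:written], positions=bufs["pos"],
            mode=self.mode, delta_lk=self.delta_lk,
            sample_every=sample_every, pos_stride=pos_stride,
            params=self.params, extension=self.extension, seed=self.seed)

    def run(self, n_equil: int, n_prod: int, sample_every: int,
            pos_stride: int = 0) -> SampleSet:
        """Equilibrate then sample; the standard entry point."""
        if n_equil > 0:
            self.equilibrate(n_equil)
        if n_prod <= 0:
            return SampleSet(
                phi=np.empty((0, self.nseg)), seg_len=np.empty((0, self.nseg)),
                twist=np.empty(0), writhe=np.empty(0),
                energies=np.empty((0, 4)), positions=np.empty((0, 0, 3)),
                mode=self.mode, delta_lk=self.delta_lk,
                sample_every=sample_every, pos_stride=pos_stride,
                params=self.params, extension=self.extension, seed=self.seed)
        return self.sample(n_prod, sample_every, pos_stride)
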