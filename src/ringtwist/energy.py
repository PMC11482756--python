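"""Energy terms of the discrete twistable worm-like chain, in kBT units.

Four contributions: harmonic bending at each junction, harmonic twisting at
each junction, screened Debye–Hückel repulsion between segment midpoints,
and the Hookean stretching of each segment used as the tension readout.
The bending discretization is harmonic in the bend angle, (A/2l0)·θ², which
agrees with the (A/l0)(1−cos θ) form to O(θ⁴) at the ~10 nm segment sizes
used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .chain import ChainConfiguration, GeometryError
from .parameters import SimulationParameters
from .topology import junction_twist_angles

__all__ = [
    "EnergyBreakdown",
    "bending_energy",
    "twist_energy",
    "electrostatic_energy",
    "stretch_energy",
    "energy_breakdown",
]


@dataclass
class EnergyBreakdown:
    """Per-term energies of one configuration (kBT)."""

    bend: float
    twist: float
    electrostatic: float
    stretch: float

    @property
    def total(self) -> float:
        return self.bend + self.twist + self.electrostatic + self.stretch


def _check(config: ChainConfiguration, params: SimulationParameters) -> None:
    if config.n_segments != params.N:
        raise ValueError(
            f"configuration has {config.n_segments} segments, parameters say N={params.N}"
        )


def bend_angles(config: ChainConfiguration) -> np.ndarray:
    """Bend angle θ_j between consecutive tangents at each junction (rad)."""
    e = config.ehat()
    if config.closed:
        e_prev = np.roll(e, 1, axis=0)
        pairs = (e_prev, e)
    else:
        pairs = (e[:-1], e[1:])
    dots = np.einsum("ij,ij->i", *pairs)
    crosses = np.linalg.norm(np.cross(*pairs), axis=1)
    theta = np.arctan2(crosses, dots)
    if not config.closed:
        theta = np.concatenate([[0.0], theta])
    return theta


def bending_energy(config: ChainConfiguration, params: SimulationParameters) -> float:
    """Σ_j (A_j / 2l0) θ_j² over junctions; A_j is the segment-j stiffness."""
    _check(config, params)
    theta = bend_angles(config)
    return float(np.sum(params.A_array() * theta**2) / (2.0 * params.l0))


def twist_energy(config: ChainConfiguration, params: SimulationParameters) -> float:
    """Σ_j (C_j / 2l0) φ_j² with φ_j the excess junction twist angle."""
    _check(config, params)
    phi = junction_twist_angles(config)
    return float(np.sum(params.C_array() * phi**2) / (2.0 * params.l0))


def pairwise_segment_distances(config: ChainConfiguration) -> np.ndarray:
    """Matrix of minimum rod–rod distances between all segment pairs."""
    n = config.n_segments
    p = config.positions
    out = np.full((n, n), np.inf)
    for i in range(n):
        ip = (i + 1) % p.shape[0]
        for j in range(i + 1, n):
            jp = (j + 1) % p.shape[0]
            d = _kernels.seg_distance(
                p[i, 0], p[i, 1], p[i, 2], p[ip, 0], p[ip, 1], p[ip, 2],
                p[j, 0], p[j, 1], p[j, 2], p[jp, 0], p[jp, 1], p[jp, 2])
            out[i, j] = out[j, i] = d
    return out


def electrostatic_energy(config: ChainConfiguration, params: SimulationParameters) -> float:
    """Screened Debye–Hückel repulsion between segments.

    The chain is a uniformly charged rod: each segment pair interacts
    through the screened-Coulomb kernel evaluated at the minimum rod–rod
    distance, ``el_prefactor·l0²·exp(−r/λ_D)/r`` (kBT after division by
    kBT).  Pairs closer than ``el_exclude`` in contour index (circularly
    for closed chains) or beyond ``el_cutoff`` in space are skipped; a pair
    inside the hard-core diameter signals infinite energy (the Monte Carlo
    proposal must be rejected).
    """
    _check(config, params)
    n = params.N
    r = pairwise_segment_distances(config)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    if config.closed:
        sep = np.minimum(sep, n - sep)
    iu = np.triu_indices(n, k=1)
    keep = (sep[iu] > params.el_exclude) & (r[iu] < params.el_cutoff)
    rr = r[iu][keep]
    if np.any(rr < params.hard_core):
        raise GeometryError("segments inside the hard core: infinite energy")
    scale = params.el_prefactor * params.l0**2 / params.kBT
    return float(np.sum(scale * np.exp(-rr / params.debye_length) / rr))


def stretch_energy(config: ChainConfiguration, params: SimulationParameters) -> float:
    """Σ_i (k_spring / 2kBT) (ℓ_i − l0)² over segments."""
    _check(config, params)
    d = config.segment_lengths() - params.l0
    return float(params.k_spring / (2.0 * params.kBT) * np.sum(d**2))


def energy_breakdown(config: ChainConfiguration, params: SimulationParameters) -> EnergyBreakdown:
    """All four terms evaluated from scratch on one configuration."""
    return EnergyBreakdown(
        bend=bending_energy(config, params),
        twist=twist_energy(config, params),
        electrostatic=electrostatic_energy(config, params),
        stretch=stretch_energy(config, params),
    )
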