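"""Twist, writhe and linking-number bookkeeping (Călugăreanu: Lk = Tw + Wr).

Twist is extracted per junction by the minimal-rotation (parallel transport)
decomposition; writhe is the exact pairwise Gauss-integral sum over segment
pairs.  For the end-clamped linear mode the open chain is closed through a
fixed far-away rectangular return path aligned with the stretching axis, and
``ΔTw + ΔWr`` of that circuit is the conserved verification quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .chain import ChainConfiguration, GeometryError

__all__ = [
    "TopologyRecord",
    "junction_twist_angle",
    "junction_twist_angles",
    "total_twist",
    "total_writhe",
    "closure_path",
    "circuit_vertices",
    "verify_topology",
]


@dataclass
class TopologyRecord:
    """Twist, writhe and linking number of one configuration, in turns."""

    twist: float
    writhe: float
    linking: float
    mode: str

    def __post_init__(self) -> None:
        if abs(self.linking - (self.twist + self.writhe)) > 1e-6:
            raise ValueError("linking must equal twist + writhe")


def junction_twist_angle(frame_i: np.ndarray, frame_j: np.ndarray) -> float:
    """Twist angle (rad) between two triads sharing a junction.

    ``frame_i`` and ``frame_j`` are (3, 3) arrays with rows (ê, f̂, ĝ).  The
    bend is removed by the minimal rotation mapping ê_i onto ê_j; the
    returned angle is the residual rotation of f̂ about ê_j, in (−π, π].
    """
    e0, f0 = np.asarray(frame_i[0], float), np.asarray(frame_i[1], float)
    e1, f1 = np.asarray(frame_j[0], float), np.asarray(frame_j[1], float)
    _, phi = _kernels.junction_angles(
        e0[0], e0[1], e0[2], f0[0], f0[1], f0[2],
        e1[0], e1[1], e1[2], f1[0], f1[1], f1[2],
    )
    if math.isnan(phi):
        raise GeometryError("180° bend: parallel transport undefined")
    return phi


def junction_twist_angles(config: ChainConfiguration) -> np.ndarray:
    """Per-junction twist angles (rad).

    Length-``N`` array for closed chains (entry ``j`` is the junction between
    segments ``j-1`` and ``j``); for the linear mode entry 0 is 0 (no
    junction at the free/clamped end).
    """
    eh = config.ehat()
    _, phi = _kernels.all_junction_angles(eh, config.fhat, config.closed)
    if np.any(np.isnan(phi)):
        raise GeometryError("180° bend: parallel transport undefined")
    return phi


def total_twist(config: ChainConfiguration) -> float:
    """Total twist in turns: (1/2π) Σ_j φ_j over all junctions."""
    return float(junction_twist_angles(config).sum() / (2.0 * math.pi))


def closure_path(config: ChainConfiguration, offset_factor: float = 3.0) -> np.ndarray:
    """Virtual return-path vertices closing an end-clamped linear chain.

    The path leaves the last vertex along the stretching axis, loops around
    the chain at a distance ``offset_factor`` × contour length, and re-enters
    the first vertex from behind, so both closure tangents match the clamped
    end tangents.
    """
    p0 = config.positions[0]
    p1 = config.positions[-1]
    axis = p1 - p0
    ext = np.linalg.norm(axis)
    if ext < 1e-9:
        raise GeometryError("degenerate end-to-end vector")
    u = axis / ext
    # any unit vector perpendicular to the axis
    trial = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(trial, u)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, trial)
    v /= np.linalg.norm(v)
    L = config.n_segments * float(np.mean(config.segment_lengths()))
    d = offset_factor * max(L, ext)
    return np.array([
        p1 + d * u,
        p1 + d * u + d * v,
        p0 - d * u + d * v,
        p0 - d * u,
    ])


def circuit_vertices(config: ChainConfiguration) -> np.ndarray:
    """Vertices of the closed circuit used for writhe (chain + closure)."""
    if config.closed:
        return config.positions
    return np.vstack([config.positions, closure_path(config)])


def total_writhe(config: ChainConfiguration) -> float:
    """Writhe from the exact pairwise Gauss-integral sum.

    Closed modes use the chain polygon itself; the linear mode uses the
    virtually closed circuit (see :func:`closure_path`).
    """
    return float(_kernels.polygon_writhe(np.ascontiguousarray(circuit_vertices(config))))


def verify_topology(
    config: ChainConfiguration,
    target_delta_lk: float,
    tol: float = 1e-3,
) -> tuple[bool, TopologyRecord]:
    """Check ΔTw + ΔWr against the imposed ΔLk.

    A failure indicates a strand passage (jump of ±2 turns) or corrupted
    frame bookkeeping; in the Monte Carlo context the offending move must be
    rejected.
    """
    tw = total_twist(config)
    wr = total_writhe(config)
    ok = abs(tw + wr - target_delta_lk) <= tol
    return ok, TopologyRecord(twist=tw, writhe=wr, linking=tw + wr, mode=config.mode)
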