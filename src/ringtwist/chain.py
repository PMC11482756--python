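"""Chain state: vertex positions plus material frames of each segment.

A configuration is a polygon of ``N`` straight segments.  Segment ``i`` runs
from vertex ``i`` to vertex ``i+1`` (indices wrap in the circular modes, so a
closed chain stores ``N`` vertices; the end-clamped linear mode stores
``N+1``).  Each segment carries a right-handed orthonormal triad
``(ê, f̂, ĝ)`` with ``ê`` along the segment; ``f̂`` tracks the material twist
and is the quantity the torque readout differentiates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MODES", "ChainConfiguration", "GeometryError", "transported_fhat"]

MODES = ("circular_fixed_lk", "nicked_circular", "linear_fixed_extension")

_ORTHO_TOL = 1e-9


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent chain geometry."""


@dataclass
class ChainConfiguration:
    """Positions and material frames of a discrete twistable worm-like chain.

    Parameters
    ----------
    positions : (N, 3) or (N+1, 3) ndarray
        Vertex coordinates in nm.  ``N`` vertices for the circular modes
        (vertex ``N`` is vertex ``0``), ``N+1`` for the linear mode.
    fhat : (N, 3) ndarray
        The f̂ vector of each segment triad; ê is derived from the bond
        vector and ĝ = ê × f̂.
    mode : str
        One of ``circular_fixed_lk``, ``nicked_circular``,
        ``linear_fixed_extension``.
    delta_lk : float
        Imposed linking-number change in turns (bookkeeping value in the
        nicked mode; imposed turns in the linear mode).
    extension : float, optional
        Fixed end-to-end distance in nm (linear mode only).
    """

    positions: np.ndarray
    fhat: np.ndarray
    mode: str
    delta_lk: float = 0.0
    extension: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.fhat = np.ascontiguousarray(self.fhat, dtype=float)
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")

    # -- basic geometry --------------------------------------------------
    @property
    def closed(self) -> bool:
        return self.mode != "linear_fixed_extension"

    @property
    def n_segments(self) -> int:
        return self.fhat.shape[0]

    @property
    def n_junctions(self) -> int:
        return self.n_segments if self.closed else self.n_segments - 1

    def bond_vectors(self) -> np.ndarray:
        p = self.positions
        if self.closed:
            return np.roll(p, -1, axis=0) - p
        return p[1:] - p[:-1]

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.bond_vectors(), axis=1)

    def ehat(self) -> np.ndarray:
        b = self.bond_vectors()
        return b / np.linalg.norm(b, axis=1)[:, None]

    def ghat(self) -> np.ndarray:
        return np.cross(self.ehat(), self.fhat)

    def midpoints(self) -> np.ndarray:
        p = self.positions
        if self.closed:
            return 0.5 * (p + np.roll(p, -1, axis=0))
        return 0.5 * (p[:-1] + p[1:])

    def copy(self) -> "ChainConfiguration":
        return ChainConfiguration(
            self.positions.copy(), self.fhat.copy(), self.mode,
            self.delta_lk, self.extension,
        )

    # -- validation ------------------------------------------------------
    def validate(self, tol: float = _ORTHO_TOL) -> None:
        """Check triad orthonormality, ê/bond alignment and boundary shape."""
        nseg = self.n_segments
        nvert = self.positions.shape[0]
        expected = nseg if self.closed else nseg + 1
        if nvert != expected:
            raise GeometryError(
                f"{self.mode} with {nseg} segments needs {expected} vertices, got {nvert}"
            )
        e = self.ehat()
        f = self.fhat
        if np.any(np.abs(np.einsum("ij,ij->i", f, f) - 1.0) > 10 * tol):
            raise GeometryError("f̂ vectors are not unit length")
        if np.any(np.abs(np.einsum("ij,ij->i", e, f)) > 10 * tol):
            raise GeometryError("f̂ not orthogonal to segment tangent ê")
        lengths = self.segment_lengths()
        if np.any(lengths <= 0):
            raise GeometryError("zero-length segment")
        if self.mode == "linear_fixed_extension":
            if self.extension is None:
                raise GeometryError("linear mode requires an extension")
            ee = np.linalg.norm(self.positions[-1] - self.positions[0])
            if abs(ee - self.extension) > 1e-6 * max(1.0, self.extension):
                raise GeometryError(
                    f"end-to-end distance {ee:.6f} != extension {self.extension:.6f}"
                )

    def frames(self) -> np.ndarray:
        """Return the (N, 3, 3) array of triads, rows (ê, f̂, ĝ)."""
        return np.stack([self.ehat(), self.fhat, self.ghat()], axis=1)


def _rodrigues(v: np.ndarray, k: np.ndarray, c: float, s: float) -> np.ndarray:
    return v * c + np.cross(k, v) * s + k * np.dot(k, v) * (1.0 - c)


def transported_fhat(ehat: np.ndarray, f0: np.ndarray | None = None) -> np.ndarray:
    """Twist-free (parallel-transported) f̂ field along the tangent sequence.

    Starting from ``f0`` (any unit vector perpendicular to ``ehat[0]``;
    chosen automatically if omitted), each subsequent f̂ is the previous one
    rotated by the minimal rotation between consecutive tangents, so every
    interior junction has zero twist.  For a closed chain the junction
    between the last and first segment absorbs the transport holonomy.
    """
    e = np.asarray(ehat, dtype=float)
    n = e.shape[0]
    if f0 is None:
        trial = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(trial, e[0])) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        f0 = np.cross(e[0], np.cross(trial, e[0]))
        f0 = trial - np.dot(trial, e[0]) * e[0]
        f0 /= np.linalg.norm(f0)
    f = np.empty_like(e)
    f[0] = f0
    for i in range(1, n):
        ax = np.cross(e[i - 1], e[i])
        s = np.linalg.norm(ax)
        c = float(np.dot(e[i - 1], e[i]))
        if s < 1e-14:
            if c < 0:
                raise GeometryError("180° bend: parallel transport undefined")
            f[i] = f[i - 1]
        else:
            f[i] = _rodrigues(f[i - 1], ax / s, c, s)
        # re-orthonormalize against drift
        f[i] -= np.dot(f[i], e[i]) * e[i]
        f[i] /= np.linalg.norm(f[i])
    return f
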