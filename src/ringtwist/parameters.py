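"""Elastic, electrostatic and discretization parameters of the twistable worm-like chain.

All lengths are in nanometres, energies in pN·nm (kBT = 4.11 pN·nm at 298 K),
forces in pN.  The chain is a closed (or end-clamped) polygon of ``N`` segments
of rest length ``l0``; bending stiffness ``A`` and twist stiffness ``C`` are
persistence lengths and may be scalars or per-segment arrays for
sequence-heterogeneous DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "KBT_298",
    "OMEGA0",
    "BJERRUM_NM",
    "SimulationParameters",
]

#: thermal energy at 298 K, pN·nm
KBT_298 = 4.11
#: intrinsic helical density conversion, rad per nm of contour (one helical
#: turn per 3.55 nm; Lk0 = L/3.55 for relaxed B-DNA)
OMEGA0 = 2.0 * math.pi / 3.55
#: Bjerrum length of water at room temperature, nm
BJERRUM_NM = 0.714

# Stigter-style effective linear charge density of B-DNA in ~0.15 M
# monovalent salt, e/nm.  Enters the Debye–Hückel prefactor as
# kBT * lB * nu^2 (pN·nm^2).
_NU_EFF = 2.43


def _default_el_prefactor() -> float:
    return KBT_298 * BJERRUM_NM * _NU_EFF**2


@dataclass
class SimulationParameters:
    """Parameter set for the discrete twistable worm-like chain.

    Parameters
    ----------
    A, C : float or ndarray
        Bending / twist persistence lengths (nm).  Arrays of length ``N``
        give per-segment (sequence-specific) stiffness; junction ``i``
        (between segments ``i-1`` and ``i``) uses the segment-``i`` value.
    l0 : float
        Segment rest length (nm).  Default 10 nm (~29 bp).
    N : int
        Number of segments (>= 3).
    kBT : float
        Thermal energy (pN·nm).
    omega0 : float
        Helical conversion factor (rad/nm); 2π/3.55 by default.
    k_spring : float
        Hookean spring constant of each segment (pN/nm), used as the
        tension readout.
    debye_length : float
        Debye screening length (nm); 0.8 nm ≈ 150 mM monovalent salt.
    el_prefactor : float
        Debye–Hückel coupling, energy×distance (pN·nm²).  The pair energy of
        segment midpoints at distance r is
        ``el_prefactor * l0² * exp(-r/debye_length) / r``.
    el_cutoff : float
        Pair interactions beyond this distance (nm) are dropped.
    el_exclude : int
        Number of nearest neighbours (in contour index, circularly) excluded
        from the electrostatic sum; 1 skips adjacent segments (which share a
        vertex and must be excluded for the rod-rod distance to make sense).
    hard_core : float
        Excluded-volume diameter of the DNA rod (nm); segment pairs closer
        than this are rejected outright.  2 nm is the bare B-DNA diameter.
    """

    N: int
    A: float | np.ndarray = 43.0
    C: float | np.ndarray = 110.0
    l0: float = 10.0
    kBT: float = KBT_298
    omega0: float = OMEGA0
    k_spring: float = 100.0
    debye_length: float = 0.8
    el_prefactor: float = field(default_factory=_default_el_prefactor)
    el_cutoff: float | None = None
    el_exclude: int = 1
    hard_core: float = 2.0

    def __post_init__(self) -> None:
        if self.el_cutoff is None:
            self.el_cutoff = 7.0 * self.debye_length
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.N < 3:
            raise ValueError(f"need at least 3 segments, got N={self.N}")
        for name in ("l0", "kBT", "k_spring", "debye_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("A", "C"):
            val = np.asarray(getattr(self, name), dtype=float)
            if val.ndim not in (0, 1):
                raise ValueError(f"{name} must be a scalar or 1-D array")
            if val.ndim == 1 and val.shape[0] != self.N:
                raise ValueError(
                    f"per-segment {name} has length {val.shape[0]}, expected N={self.N}"
                )
            if np.any(val <= 0):
                raise ValueError(f"{name} must be positive")
        if self.el_exclude < 1:
            raise ValueError(
                "el_exclude must be >= 1: adjacent segments share a vertex, "
                "so their rod-rod distance is always zero")
        if self.hard_core < 0:
            raise ValueError("hard_core must be non-negative")

    # -- derived quantities ---------------------------------------------
    @property
    def contour_length(self) -> float:
        """Total contour length L = N * l0 (nm)."""
        return self.N * self.l0

    @property
    def lk0(self) -> float:
        """Linking number of the relaxed chain, Lk0 = L*omega0/(2π) = L/3.55."""
        return self.contour_length * self.omega0 / (2.0 * math.pi)

    def sigma_to_delta_lk(self, sigma: float) -> float:
        """Superhelical density -> linking-number change (turns, unrounded)."""
        return sigma * self.lk0

    def A_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.A, dtype=float), (self.N,)).copy()

    def C_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.C, dtype=float), (self.N,)).copy()

    def free_segment_length(self) -> float:
        """Mean segment length of an unloaded spring segment.

        Vertex positions are sampled in Cartesian measure, so the segment
        vector carries an ℓ² Jacobian: p(ℓ) ∝ ℓ² exp(-k(ℓ-l0)²/2kBT).  The
        resulting zero-tension mean is l0·(1+3s)/(1+s) with s = kBT/(k·l0²),
        and is the baseline the force readout subtracts.
        """
        s = self.kBT / (self.k_spring * self.l0**2)
        return self.l0 * (1.0 + 3.0 * s) / (1.0 + s)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParameters":
        known = {f.name for f in fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        for key in ("A", "C"):
            if isinstance(kwargs.get(key), list):
                kwargs[key] = np.asarray(kwargs[key], dtype=float)
        return cls(**kwargs)

    def replace(self, **kwargs) -> "SimulationParameters":
        return replace(self, **kwargs)
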