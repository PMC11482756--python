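"""Analytically characterized conformations for oracle tests.

Each fixture is an exactly constructed :class:`ChainConfiguration` whose
twist and writhe are known in closed form (or, for the solenoid, computable
by dense quadrature of the Gauss double integral over the smooth curve).
"""

from __future__ import annotations

import math

import numpy as np

from .chain import ChainConfiguration, transported_fhat

__all__ = [
    "planar_circle",
    "twisted_ring",
    "solenoid",
    "straight_clamped",
    "generate_fixture",
]


def _ring_positions(n: int, l0: float) -> np.ndarray:
    # regular n-gon in the xy-plane with side length l0
    radius = l0 / (2.0 * math.sin(math.pi / n))
    t = 2.0 * math.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), np.zeros(n)])


def planar_circle(n: int = 100, l0: float = 10.0,
                  mode: str = "circular_fixed_lk") -> ChainConfiguration:
    """Planar regular n-gon with twist-free frames: Tw = Wr = 0."""
    return twisted_ring(n, 0, l0, mode=mode)


def twisted_ring(n: int = 100, k: float = 0.0, l0: float = 10.0,
                 mode: str = "circular_fixed_lk") -> ChainConfiguration:
    """Planar regular n-gon with uniform junction twist 2πk/n: Tw = k, Wr = 0.

    For a planar polygon the parallel transport of ẑ is ẑ itself, so the
    twisted frame field is simply ẑ rotated about each tangent by an angle
    growing linearly along the chain.
    """
    pos = _ring_positions(n, l0)
    bonds = np.roll(pos, -1, axis=0) - pos
    ehat = bonds / np.linalg.norm(bonds, axis=1)[:, None]
    alpha = 2.0 * math.pi * k / n
    fhat = np.empty_like(ehat)
    z = np.array([0.0, 0.0, 1.0])
    for i in range(n):
        a = alpha * i
        e = ehat[i]
        # Rodrigues rotation of ẑ about ê_i by a (ẑ ⟂ ê for a planar ring)
        fhat[i] = z * math.cos(a) + np.cross(e, z) * math.sin(a)
    cfg = ChainConfiguration(pos, fhat, mode, delta_lk=float(k))
    cfg.validate()
    return cfg


def solenoid(n: int = 200, n_coils: int = 4, major_radius: float = 100.0,
             minor_radius: float = 30.0) -> ChainConfiguration:
    """Closed solenoidal curve winding ``n_coils`` times around a torus.

    The centreline is r(t) = ((R + a·cos qt)·cos t, (R + a·cos qt)·sin t,
    a·sin qt); its writhe is not available in closed form and is fixed by
    the quadrature oracle in the test-suite.  Frames are twist-free
    (parallel transported), so the closure junction carries the transport
    holonomy as its only twist.
    """
    t = 2.0 * math.pi * np.arange(n) / n
    q = n_coils
    r = major_radius + minor_radius * np.cos(q * t)
    pos = np.column_stack([
        r * np.cos(t), r * np.sin(t), minor_radius * np.sin(q * t)
    ])
    bonds = np.roll(pos, -1, axis=0) - pos
    ehat = bonds / np.linalg.norm(bonds, axis=1)[:, None]
    fhat = transported_fhat(ehat)
    cfg = ChainConfiguration(pos, fhat, "nicked_circular")
    cfg.validate()
    return cfg


def straight_clamped(n: int = 50, l0: float = 10.0,
                     turns: float = 0.0) -> ChainConfiguration:
    """Straight end-clamped chain along x̂ with uniform imposed twist."""
    pos = np.column_stack([
        l0 * np.arange(n + 1), np.zeros(n + 1), np.zeros(n + 1)
    ])
    alpha = 2.0 * math.pi * turns / (n - 1) if n > 1 else 0.0
    fhat = np.empty((n, 3))
    for i in range(n):
        a = alpha * i
        fhat[i] = (0.0, -math.sin(a), math.cos(a))
    cfg = ChainConfiguration(pos, fhat, "linear_fixed_extension",
                             delta_lk=float(turns), extension=n * l0)
    cfg.validate()
    return cfg


_KINDS = {
    "planar_circle": planar_circle,
    "twisted_ring": twisted_ring,
    "solenoid": solenoid,
    "straight_clamped": straight_clamped,
}


def generate_fixture(kind: str, **parameters) -> ChainConfiguration:
    """Dispatcher over the fixture constructors above."""
    try:
        builder = _KINDS[kind]
    except KeyError:
        raise ValueError(
            f"unknown fixture kind {kind!r}; expected one of {sorted(_KINDS)}"
        ) from None
    return builder(**parameters)
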