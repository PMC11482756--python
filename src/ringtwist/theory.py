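"""Quasi-analytical fluctuation theory of circular DNA torsion.

For a nicked circular DNA of contour length L the twist and writhe
fluctuate independently:

* twist variance   s²_Tw = L / (4π² C)                        (turns²)
* writhe variance  s²_Wr = f(A, L), the Shimada–Yamakawa empirical
  closure formula in t = λL with λ = 1/(2A)

and the linking-number variance is their sum, s²_Lk = s²_Tw + s²_Wr, which
also defines the plectonemic twist persistence length through
s²_Lk = L / (4π² P), giving the closed form

    P(A, C, L) = L C / (L + 4π² C f(A, L)).

Fixing ΔLk couples the two channels; each then fluctuates with the harmonic
combination s'² = s²_Tw s²_Wr / (s²_Tw + s²_Wr), and propagating the twist
fluctuations through τ = 2π kBT C Tw / L yields the torque fluctuation

    s'_τ = kBT √((C − P)/L),

independent of the imposed superhelical density.  The mean torque itself is
τ = P kBT ω0 σ.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .parameters import KBT_298, OMEGA0

__all__ = [
    "TheoryInputs",
    "twist_variance",
    "writhe_variance",
    "linking_variance",
    "plectonemic_P",
    "coupled_variance",
    "torque_std",
    "expected_torque",
]

FOUR_PI2 = 4.0 * math.pi**2


@dataclass
class TheoryInputs:
    """(A, C, L) triple plus thermal constants feeding the closed forms."""

    A: float
    C: float
    L: float
    kBT: float = KBT_298
    omega0: float = OMEGA0

    def __post_init__(self) -> None:
        for name in ("A", "C", "L", "kBT", "omega0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def twist_variance(C: float, L: float) -> float:
    """Twist variance of a nicked circle, L/(4π²C), in turns²."""
    return L / (FOUR_PI2 * C)


def writhe_variance(A: float, L: float) -> float:
    """Writhe variance of a nicked circle (turns²), Shimada–Yamakawa form.

    f(t) = 0.095 t³ e^{−6.8 t^{−2.5}} / (19.47 + t²)
         + 0.00385 t² (1 + 1.092 t + 0.76 t² + 0.2788 t³) e^{−t},

    with t = λL and λ = 1/(2A).  Vanishes for stiff rings (t → 0) and grows
    as 0.095 t for long chains.  The empirical fit was built for rings up to
    a few hundred Kuhn lengths; a warning is issued outside t ∈ [0.5, 1000].
    """
    t = L / (2.0 * A)
    if not 0.5 <= t <= 1000.0:
        warnings.warn(
            f"lambda*L = {t:.3g} outside the fitted range of the "
            "writhe-variance formula", stacklevel=2)
    f1 = 0.095 * t**3 * math.exp(-6.8 * t**-2.5) / (19.47 + t * t)
    f2 = (0.00385 * t * t * (1.0 + 1.092 * t + 0.76 * t * t + 0.2788 * t**3)
          * math.exp(-t))
    return f1 + f2


def linking_variance(A: float, C: float, L: float) -> float:
    """s²_Lk = s²_Tw + s²_Wr of a nicked circle (turns²)."""
    return twist_variance(C, L) + writhe_variance(A, L)


def plectonemic_P(A: float, C: float, L: float) -> float:
    """Plectonemic twist persistence length P = LC/(L + 4π²C f(A,L)), nm.

    Always below C, approaching C as the writhe channel closes (f → 0).
    """
    return L * C / (L + FOUR_PI2 * C * writhe_variance(A, L))


def coupled_variance(A: float, C: float, L: float) -> float:
    """Twist (= writhe) variance of a ΔLk-constrained circle (turns²).

    Harmonic combination of the free twist and writhe variances; bounded by
    the smaller of the two.
    """
    st2 = twist_variance(C, L)
    sw2 = writhe_variance(A, L)
    return st2 * sw2 / (st2 + sw2)


def torque_std(A: float, C: float, L: float, kBT: float = KBT_298) -> float:
    """Thermal torque fluctuation of a ΔLk-constrained circle (pN·nm)."""
    P = plectonemic_P(A, C, L)
    return kBT * math.sqrt((C - P) / L)


def expected_torque(P: float, sigma: float, kBT: float = KBT_298,
                    omega0: float = OMEGA0) -> float:
    """Mean torque τ = P kBT ω0 σ (pN·nm); odd in σ."""
    if P <= 0:
        raise ValueError("P must be positive")
    return P * kBT * omega0 * sigma


def summary(A: float, C: float, L: float, sigma: float | None = None,
            kBT: float = KBT_298, omega0: float = OMEGA0) -> dict:
    """All closed-form quantities for one (A, C, L) triple as a dict."""
    P = plectonemic_P(A, C, L)
    out = {
        "A_nm": A,
        "C_nm": C,
        "L_nm": L,
        "twist_variance_turns2": twist_variance(C, L),
        "writhe_variance_turns2": writhe_variance(A, L),
        "linking_variance_turns2": linking_variance(A, C, L),
        "coupled_variance_turns2": coupled_variance(A, C, L),
        "P_nm": P,
        "torque_std_pNnm": torque_std(A, C, L, kBT),
    }
    if sigma is not None:
        out["sigma"] = sigma
        out["expected_torque_pNnm"] = expected_torque(P, sigma, kBT, omega0)
    return out
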