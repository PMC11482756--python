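"""Shared fixtures: parameter sets and a session-scoped simulation cache.

The physics checks (fluctuation variances, torque/force levels, fits) all
consume equilibrium Monte Carlo runs; the cache keys runs by their physical
conditions so several tests can share one trajectory.  Slowly-mixing
observables (tension, writhe variance of plectonemic rings) can request
independent replicas, which are equilibrated separately and concatenated.
Chains are kept at desk scale (50–200 segments of 10 nm).
"""

from __future__ import annotations

import sys
import zlib

import numpy as np
import pytest

import ringtwist as rt
from ringtwist.engine import (EngineState, SampleSet, initialize_configuration,
                              interwound_start)

DESK_N = 100


def make_params(N=DESK_N, A=43.0, C=110.0, **kw):
    return rt.SimulationParameters(N=N, A=A, C=C, **kw)


def _concat(sets: list[SampleSet]) -> SampleSet:
    first = sets[0]
    return SampleSet(
        phi=np.concatenate([s.phi for s in sets]),
        seg_len=np.concatenate([s.seg_len for s in sets]),
        twist=np.concatenate([s.twist for s in sets]),
        writhe=np.concatenate([s.writhe for s in sets]),
        energies=np.concatenate([s.energies for s in sets]),
        positions=np.concatenate([s.positions for s in sets]),
        mode=first.mode, delta_lk=first.delta_lk,
        sample_every=first.sample_every, pos_stride=first.pos_stride,
        params=first.params, extension=first.extension, seed=first.seed)


@pytest.fixture(scope="session")
def sim():
    """Factory returning cached equilibrium runs keyed by their conditions.

    ``phantom=True`` switches off electrostatics and the hard core (the
    ideal twistable worm-like chain); topology guarding stays on either
    way, so chains remain unknotted.
    """
    cache: dict = {}

    def run(mode="circular_fixed_lk", sigma=0.0, N=DESK_N, A=43.0, C=110.0,
            n_equil=150_000, n_prod=400_000, sample_every=100,
            pos_stride=0, extension=None, heterogeneous=False,
            phantom=False, max_arc=None, replicas=1):
        key = (mode, round(sigma, 5), N, A, C, extension, pos_stride,
               n_prod, heterogeneous, phantom, replicas)
        if key not in cache:
            extra = dict(el_prefactor=0.0, hard_core=0.0) if phantom else {}
            if heterogeneous:
                # two-block sequence heterogeneity around the given means
                A_arr = np.where(np.arange(N) < N // 2, A * 0.8, A * 1.2)
                C_arr = np.where(np.arange(N) < N // 2, C * 1.2, C * 0.8)
                p = rt.SimulationParameters(N=N, A=A_arr, C=C_arr, **extra)
            else:
                p = rt.SimulationParameters(N=N, A=A, C=C, **extra)
            if mode == "circular_fixed_lk":
                dlk = float(round(p.sigma_to_delta_lk(sigma)))
            elif mode == "linear_fixed_extension":
                dlk = p.sigma_to_delta_lk(sigma)
            else:
                dlk = 0.0
            sets = []
            for rep in range(replicas):
                if mode == "circular_fixed_lk":
                    cfg = interwound_start(N, p, dlk)
                else:
                    cfg = initialize_configuration(mode, N, p, delta_lk=dlk,
                                                   extension=extension)
                seed = zlib.crc32(repr((key, rep)).encode()) % (2**31)
                eng = EngineState(cfg, p, seed=seed,
                                  move_mix=(0.25, 0.5, 0.25),
                                  max_arc=max_arc or min(30, N // 4))
                eng.equilibrate(n_equil)
                sets.append(eng.sample(n_prod, sample_every, pos_stride))
            ss = sets[0] if replicas == 1 else _concat(sets)
            tau = (ss.phi * (p.kBT / p.l0) * p.C_array()[None, :]).mean()
            print(f"[sim] {mode} sigma={sigma:+.3f} N={N} A={A} C={C} "
                  f"reps={replicas}: tau={tau:+.2f} Tw={ss.twist.mean():+.2f} "
                  f"Wr_var={ss.writhe.var():.3f}", file=sys.stderr, flush=True)
            cache[key] = (ss, eng)
        return cache[key]

    return run


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)
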