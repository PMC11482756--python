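"""Run configuration, trajectory and table I/O.

A run is fully described by a flat key-value YAML file (all
:class:`SimulationParameters` fields plus the run keys below); every
simulation writes a manifest (config + seed + code version) sufficient to
reproduce its outputs bit-for-bit.  Trajectories go to XYZ text frames
(comment line carries step index, ΔTw, ΔWr) with a sidecar CSV of
per-junction twist angles; an optional HDF5 bundle holds the same content.
Coordinates are written as decimal text with 9 significant digits.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .chain import ChainConfiguration, transported_fhat
from .engine import SampleSet
from .parameters import SimulationParameters

__all__ = [
    "RunConfig",
    "write_trajectory",
    "read_trajectory",
    "config_from_snapshot",
    "write_hdf5",
    "read_hdf5",
    "sweep_table",
    "profile_table",
]

_RUN_KEYS = (
    "mode", "sigma", "delta_lk", "turns", "extension",
    "n_equil", "n_prod", "sample_every", "pos_stride",
    "seed", "max_arc", "mix_crank", "mix_vertex", "mix_twist",
)


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run.

    Exactly one of ``sigma``, ``delta_lk`` or ``turns`` must be given
    (``turns`` is the linear-mode spelling of ``delta_lk``).  For circular
    fixed-ΔLk runs a ``sigma`` is converted through ΔLk = σ·Lk0 = σ·L/3.55
    and rounded to the nearest integer number of turns; a warning is stored
    when the rounding exceeds 0.25 turns.
    """

    params: SimulationParameters
    mode: str = "circular_fixed_lk"
    sigma: float | None = None
    delta_lk: float | None = None
    turns: float | None = None
    extension: float | None = None
    n_equil: int = 0
    n_prod: int = 0
    sample_every: int = 100
    pos_stride: int = 10
    seed: int = 0
    max_arc: int | None = None
    mix_crank: float = 0.3
    mix_vertex: float = 0.4
    mix_twist: float = 0.3

    def __post_init__(self) -> None:
        given = [k for k in ("sigma", "delta_lk", "turns")
                 if getattr(self, k) is not None]
        if len(given) != 1:
            raise ValueError(
                f"exactly one of sigma/delta_lk/turns required, got {given or 'none'}")

    def resolved_delta_lk(self) -> tuple[float, str | None]:
        """Imposed linking-number change in turns, plus a rounding warning."""
        if self.turns is not None:
            return float(self.turns), None
        if self.delta_lk is not None:
            return float(self.delta_lk), None
        raw = self.params.sigma_to_delta_lk(self.sigma)
        if self.mode == "circular_fixed_lk":
            dlk = float(round(raw))
            warn = None
            if abs(dlk - raw) > 0.25:
                warn = (f"sigma={self.sigma} maps to delta_lk={raw:.3f}; "
                        f"rounded to {dlk:.0f} turns")
            return dlk, warn
        return float(raw), None

    def actual_sigma(self) -> float:
        dlk, _ = self.resolved_delta_lk()
        return dlk / self.params.lk0

    # -- flat-key serialization -----------------------------------------
    def to_dict(self) -> dict:
        out = self.params.to_dict()
        for k in _RUN_KEYS:
            out[k] = getattr(self, k)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        params = SimulationParameters.from_dict(d)
        kwargs = {k: d[k] for k in _RUN_KEYS if k in d}
        return cls(params=params, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed config file {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a flat mapping")
        return cls.from_dict(data)

    def manifest(self) -> dict:
        dlk, warn = self.resolved_delta_lk()
        m = dict(self.to_dict(), resolved_delta_lk=dlk,
                 actual_sigma=self.actual_sigma() if self.mode != "nicked_circular" else 0.0,
                 code_version=_pkg_version)
        if warn:
            m["rounding_warning"] = warn
        return m


def simulate_run(rc: RunConfig, verbose: bool = False):
    """Run one simulation described by a :class:`RunConfig`.

    Returns ``(samples, engine)``.  ``n_equil``/``n_prod`` of 0 choose
    defaults proportional to chain size (1500·N and 3000·N moves).
    """
    from .engine import EngineState, initialize_configuration

    p = rc.params
    dlk, warn = rc.resolved_delta_lk()
    cfg = initialize_configuration(rc.mode, p.N, p, delta_lk=dlk,
                                   extension=rc.extension)
    eng = EngineState(cfg, p, seed=rc.seed,
                      move_mix=(rc.mix_crank, rc.mix_vertex, rc.mix_twist),
                      max_arc=rc.max_arc)
    n_equil = rc.n_equil or 1500 * p.N
    n_prod = rc.n_prod or 3000 * p.N
    info = eng.equilibrate(n_equil)
    if verbose:
        print(f"equilibrated {n_equil} moves; acceptance "
              f"{np.round(eng.acceptance_rates, 3).tolist()}"
              + (f"; {warn}" if warn else ""))
    samples = eng.sample(n_prod, rc.sample_every, rc.pos_stride)
    return samples, eng


# ----------------------------------------------------------------------
# XYZ + CSV trajectories
# ----------------------------------------------------------------------
def write_trajectory(samples: SampleSet, out_dir: str | Path,
                     prefix: str = "traj") -> dict:
    """Write stored conformations as XYZ frames plus a twist-angle CSV.

    Returns the paths written.  Only samples with stored positions become
    XYZ frames; the CSV holds the matching per-junction twist angles (rad).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    xyz = out / f"{prefix}.xyz"
    stride = max(samples.pos_stride, 1)
    rows = []
    with xyz.open("w") as fh:
        for r in range(samples.positions.shape[0]):
            s = r * stride
            if s >= samples.n_samples:
                break
            pos = samples.positions[r]
            fh.write(f"{pos.shape[0]}\n")
            fh.write(
                f"step={(s + 1) * samples.sample_every} "
                f"tw={samples.twist[s]:.9g} wr={samples.writhe[s]:.9g} "
                f"mode={samples.mode} delta_lk={samples.delta_lk:.9g}\n")
            for v in pos:
                fh.write(f"C {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            rows.append(samples.phi[s])
    csv = out / f"{prefix}_twist.csv"
    pd.DataFrame(np.array(rows)).to_csv(csv, index=False)
    return dict(xyz=str(xyz), twist_csv=str(csv))


def read_trajectory(xyz_path: str | Path,
                    twist_csv: str | Path | None = None):
    """Read XYZ frames (and optional twist CSV) back.

    Returns ``(frames, meta, phi)``: a list of (n_vertices, 3) arrays, a
    list of comment-line dicts, and the twist-angle array (or None).
    """
    frames, meta = [], []
    lines = Path(xyz_path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nv = int(lines[i])
        except ValueError as exc:
            raise ValueError(f"{xyz_path}:{i + 1}: expected a vertex count") from exc
        info = {}
        for tok in lines[i + 1].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                try:
                    info[k] = float(v)
                except ValueError:
                    info[k] = v
        block = lines[i + 2:i + 2 + nv]
        if len(block) < nv:
            raise ValueError(f"{xyz_path}:{i + 1}: truncated frame")
        coords = np.array([[float(x) for x in ln.split()[1:4]] for ln in block])
        frames.append(coords)
        meta.append(info)
        i += 2 + nv
    phi = None
    if twist_csv is not None:
        phi = pd.read_csv(twist_csv).to_numpy()
    return frames, meta, phi


def config_from_snapshot(positions: np.ndarray, phi: np.ndarray, mode: str,
                         delta_lk: float = 0.0,
                         extension: float | None = None) -> ChainConfiguration:
    """Rebuild a configuration from vertices plus junction twist angles.

    Frames are reconstructed by parallel transport with the stored twist
    angle applied at each junction, so the rebuilt chain reproduces the
    original twist and writhe (the f̂ field itself is recovered up to a
    global rotation about the local tangents).
    """
    closed = mode != "linear_fixed_extension"
    bonds = (np.roll(positions, -1, axis=0) - positions) if closed \
        else positions[1:] - positions[:-1]
    ehat = bonds / np.linalg.norm(bonds, axis=1)[:, None]
    f = transported_fhat(ehat)
    n = ehat.shape[0]
    acc = 0.0
    for i in range(1, n):
        acc += phi[i]
        c, s = math.cos(acc), math.sin(acc)
        e = ehat[i]
        f[i] = f[i] * c + np.cross(e, f[i]) * s
    if extension is None and not closed:
        extension = float(np.linalg.norm(positions[-1] - positions[0]))
    cfg = ChainConfiguration(positions.copy(), f, mode, delta_lk, extension)
    cfg.validate()
    return cfg


# ----------------------------------------------------------------------
# HDF5 bundle
# ----------------------------------------------------------------------
def write_hdf5(samples: SampleSet, path: str | Path) -> None:
    """Bundle a full sample set (including XYZ/CSV content) into HDF5."""
    import h5py

    with h5py.File(path, "w") as h5:
        for name in ("phi", "seg_len", "twist", "writhe", "energies", "positions"):
            h5.create_dataset(name, data=getattr(samples, name))
        h5.attrs["mode"] = samples.mode
        h5.attrs["delta_lk"] = samples.delta_lk
        h5.attrs["sample_every"] = samples.sample_every
        h5.attrs["pos_stride"] = samples.pos_stride
        h5.attrs["extension"] = -1.0 if samples.extension is None else samples.extension
        h5.attrs["seed"] = -1 if samples.seed is None else samples.seed
        h5.attrs["params_json"] = json.dumps(samples.params.to_dict())


def read_hdf5(path: str | Path) -> SampleSet:
    import h5py

    with h5py.File(path, "r") as h5:
        params = SimulationParameters.from_dict(json.loads(h5.attrs["params_json"]))
        ext = float(h5.attrs["extension"])
        seed = int(h5.attrs["seed"])
        return SampleSet(
            phi=h5["phi"][...], seg_len=h5["seg_len"][...],
            twist=h5["twist"][...], writhe=h5["writhe"][...],
            energies=h5["energies"][...], positions=h5["positions"][...],
            mode=str(h5.attrs["mode"]), delta_lk=float(h5.attrs["delta_lk"]),
            sample_every=int(h5.attrs["sample_every"]),
            pos_stride=int(h5.attrs["pos_stride"]),
            params=params,
            extension=None if ext < 0 else ext,
            seed=None if seed < 0 else seed)


# ----------------------------------------------------------------------
# observable tables
# ----------------------------------------------------------------------
def sweep_table(rows: list[dict]) -> pd.DataFrame:
    """τ/F versus σ table with the canonical column order."""
    cols = ["sigma", "mean_torque", "se_torque", "mean_force", "se_force",
            "n_samples"]
    return pd.DataFrame(rows)[cols]


def profile_table(torque, torque_se, force, force_se) -> pd.DataFrame:
    return pd.DataFrame(dict(
        segment_index=np.arange(len(torque)),
        mean_torque=torque, se_torque=torque_se,
        mean_force=force, se_force=force_se))
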