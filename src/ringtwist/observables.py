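"""Measurables derived from sampled configurations.

Torque is read locally at each junction from the excess twist angle,
τ_j = kBT·C_j·φ_j / l0 (negative when underwound).  Tension is read from
the Hookean springs, F_i = k_spring·(⟨ℓ_i⟩ − ℓ_free), where ℓ_free is the
closed-form zero-tension mean segment length (the Cartesian sampling
measure biases ⟨ℓ⟩ above the rest length by ≈ 2kBT/(k·l0) even with no
load; see :meth:`SimulationParameters.free_segment_length`).  Scalar
uncertainties come from block averaging over at least 10 blocks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .engine import SampleSet
from .parameters import SimulationParameters

__all__ = [
    "ObservableSeries",
    "FitResult",
    "StatisticsError",
    "block_stats",
    "torque_samples",
    "force_profile",
    "segment_torque",
    "segment_force",
    "observable_series",
    "apex_align_profile",
    "classify_segments_linear",
    "plectonemic_sigma",
    "fit_P",
    "fit_alpha",
    "torque_distribution",
    "autocorrelation_time",
]


class StatisticsError(RuntimeError):
    """Raised when there are too few samples for a reliable estimate."""


# ----------------------------------------------------------------------
# statistics helpers
# ----------------------------------------------------------------------
def block_stats(x: np.ndarray, n_blocks: int = 10) -> tuple[float, float]:
    """Mean and block-averaged standard error of a 1-D sample series."""
    x = np.asarray(x, float)
    if x.size < n_blocks:
        raise StatisticsError(
            f"need at least {n_blocks} samples for {n_blocks} blocks, got {x.size}")
    usable = (x.size // n_blocks) * n_blocks
    blocks = x[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(x.mean()), float(blocks.std(ddof=1) / math.sqrt(n_blocks))


def autocorrelation_time(x: np.ndarray, c: float = 6.0) -> float:
    """Integrated autocorrelation time (in sample strides) with a
    self-consistent window cutoff at ``c``·τ."""
    x = np.asarray(x, float)
    n = x.size
    if n < 8:
        return 1.0
    y = x - x.mean()
    var = np.dot(y, y) / n
    if var <= 0:
        return 1.0
    acf = np.correlate(y, y, mode="full")[n - 1:] / (n * var)
    tau = 1.0
    for k in range(1, n // 2):
        tau += 2.0 * acf[k]
        if k >= c * tau:
            break
    return max(tau, 1.0)


# ----------------------------------------------------------------------
# per-segment readouts
# ----------------------------------------------------------------------
def _junction_mask(samples: SampleSet) -> np.ndarray:
    """Valid-junction mask (the open chain has no junction 0)."""
    mask = np.ones(samples.phi.shape[1], dtype=bool)
    if samples.mode == "linear_fixed_extension":
        mask[0] = False
    return mask


def torque_samples(samples: SampleSet) -> np.ndarray:
    """(n_samples, n_junctions) instantaneous junction torques in pN·nm."""
    p = samples.params
    C = p.C_array()
    tau = samples.phi * (p.kBT / p.l0) * C[None, :]
    return tau[:, _junction_mask(samples)]


def segment_torque(samples: SampleSet, i: int) -> tuple[float, float]:
    """Mean and block SE of the torque at junction ``i`` (pN·nm)."""
    tau = torque_samples(samples)
    return block_stats(tau[:, i])


def force_profile(samples: SampleSet, n_blocks: int = 10,
                  baseline: str = "free") -> tuple[np.ndarray, np.ndarray]:
    """Per-segment mean tension and block SE (pN) from the spring readout.

    ``baseline="free"`` (default) subtracts the thermal zero-tension mean
    segment length, so a relaxed chain reads zero force; ``baseline="rest"``
    subtracts the bare rest length l0 (the raw spring extension).
    """
    p = samples.params
    if samples.n_samples < n_blocks:
        raise StatisticsError("too few samples for a force readout")
    l_free = p.free_segment_length() if baseline == "free" else p.l0
    k = p.k_spring
    n = samples.seg_len.shape[1]
    means = np.empty(n)
    ses = np.empty(n)
    for i in range(n):
        m, s = block_stats(samples.seg_len[:, i], n_blocks)
        means[i] = k * (m - l_free)
        ses[i] = k * s
    return means, ses


def segment_force(samples: SampleSet, i: int,
                  baseline: str = "free") -> tuple[float, float]:
    """Mean and block SE of the spring tension of segment ``i`` (pN)."""
    means, ses = force_profile(samples, baseline=baseline)
    return float(means[i]), float(ses[i])


@dataclass
class ObservableSeries:
    """Summary of a run: profiles and scalar torque/force with block SEs."""

    torque_mean: float
    torque_se: float
    force_mean: float
    force_se: float
    torque_profile: np.ndarray
    torque_profile_se: np.ndarray
    force_profile: np.ndarray
    force_profile_se: np.ndarray
    n_samples: int
    n_blocks: int
    sigma: float | None = None

    def pooled_torque_se(self) -> float:
        return float(np.mean(self.torque_profile_se))

    def pooled_force_se(self) -> float:
        return float(np.mean(self.force_profile_se))


def run_sigma(samples: SampleSet) -> float:
    """Superhelical density of a run, ΔLk / Lk0."""
    return samples.delta_lk / samples.params.lk0


def observable_series(samples: SampleSet, n_blocks: int = 10) -> ObservableSeries:
    """Block-averaged torque/force summaries of one production run."""
    tau = torque_samples(samples)
    chain_tau = tau.mean(axis=1)  # instantaneous chain-averaged torque
    t_mean, t_se = block_stats(chain_tau, n_blocks)
    f_prof, f_prof_se = force_profile(samples, n_blocks)
    # chain-averaged force: average the spring lengths first
    p = samples.params
    chain_len = samples.seg_len.mean(axis=1)
    lm, ls = block_stats(chain_len, n_blocks)
    f_mean = p.k_spring * (lm - p.free_segment_length())
    f_se = p.k_spring * ls
    nt = tau.shape[1]
    t_prof = np.empty(nt)
    t_prof_se = np.empty(nt)
    for j in range(nt):
        t_prof[j], t_prof_se[j] = block_stats(tau[:, j], n_blocks)
    return ObservableSeries(
        torque_mean=t_mean, torque_se=t_se,
        force_mean=float(f_mean), force_se=float(f_se),
        torque_profile=t_prof, torque_profile_se=t_prof_se,
        force_profile=f_prof, force_profile_se=f_prof_se,
        n_samples=samples.n_samples, n_blocks=n_blocks,
        sigma=run_sigma(samples))


# ----------------------------------------------------------------------
# apex alignment and extended/plectonemic classification
# ----------------------------------------------------------------------
def _apex_index(pos: np.ndarray) -> tuple[int, bool]:
    """Apex vertex of one circular conformation.

    The apex is the vertex farthest from the centre of mass; a conformation
    whose radial spread is small (no plectoneme) is flagged as apex-less.
    """
    com = pos.mean(axis=0)
    d = np.linalg.norm(pos - com, axis=1)
    spread = (d.max() - d.min()) / max(d.mean(), 1e-9)
    return int(np.argmax(d)), spread > 0.25


def apex_align_profile(samples: SampleSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-segment mean torque and force profiles with index 0 at the
    plectoneme apex of each stored conformation.

    Returns ``(torque, torque_se, force, force_se)`` arrays of length N.
    Falls back to unshifted averaging (with a warning) when no apex is
    detectable.
    """
    if samples.positions.shape[0] == 0:
        raise ValueError("run was sampled without stored positions")
    if samples.mode == "linear_fixed_extension":
        raise ValueError("apex alignment applies to circular trajectories")
    p = samples.params
    C = p.C_array()
    stride = samples.pos_stride
    n = samples.phi.shape[1]
    acc_tau = []
    acc_len = []
    n_missing = 0
    for r in range(samples.positions.shape[0]):
        s = r * stride
        if s >= samples.n_samples:
            break
        apex, ok = _apex_index(samples.positions[r])
        if not ok:
            n_missing += 1
            apex = 0
        acc_tau.append(np.roll(samples.phi[s] * (p.kBT / p.l0) * C, -apex))
        acc_len.append(np.roll(samples.seg_len[s], -apex))
    if n_missing:
        warnings.warn(
            f"{n_missing}/{len(acc_tau)} conformations had no detectable "
            "plectoneme apex; averaged unshifted", stacklevel=2)
    acc_tau = np.array(acc_tau)
    acc_len = np.array(acc_len)
    nb = min(10, max(2, acc_tau.shape[0] // 4))
    t_prof = np.empty(n); t_se = np.empty(n)
    f_prof = np.empty(n); f_se = np.empty(n)
    l_free = p.free_segment_length()
    for j in range(n):
        t_prof[j], t_se[j] = block_stats(acc_tau[:, j], nb)
        m, s = block_stats(acc_len[:, j], nb)
        f_prof[j] = p.k_spring * (m - l_free)
        f_se[j] = p.k_spring * s
    return t_prof, t_se, f_prof, f_se


def classify_segments_linear(positions: np.ndarray, cutoff: float = 10.0,
                             min_separation: int = 4,
                             closing_window: int = 3) -> np.ndarray:
    """Label each segment of one linear conformation extended/plectonemic.

    A segment is plectonemic when some non-neighbouring segment
    (contour separation > ``min_separation``) approaches within ``cutoff``
    nm of it — about twice the superhelix radius, measured as the rod–rod
    minimum distance, the same metric the electrostatics uses.  A
    morphological closing over ``closing_window`` segments removes label
    speckle.  Returns a boolean array, True = plectonemic.
    """
    from ._kernels import seg_distance

    n = positions.shape[0] - 1
    mid = 0.5 * (positions[:-1] + positions[1:])
    d2 = np.sum((mid[:, None, :] - mid[None, :, :]) ** 2, axis=-1)
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    # midpoint prefilter, then the exact rod-rod distance
    reach = cutoff + 1.5 * np.median(np.linalg.norm(
        positions[1:] - positions[:-1], axis=1))
    cand = (d2 < reach**2) & (sep > min_separation)
    close = np.zeros((n, n), dtype=bool)
    for i, j in zip(*np.nonzero(np.triu(cand))):
        r = seg_distance(*positions[i], *positions[i + 1],
                         *positions[j], *positions[j + 1])
        if r < cutoff:
            close[i, j] = close[j, i] = True
    label = close.any(axis=1)
    if closing_window > 1:  # close gaps, then remove isolated marks
        kern = np.ones(closing_window)
        grow = np.convolve(label.astype(float), kern, mode="same") > 0
        label = np.convolve(grow.astype(float), kern, mode="same") >= closing_window
    return label


def plectonemic_sigma(samples: SampleSet,
                      with_error: bool = False) -> float | tuple[float, float]:
    """Superhelical density attributed to the plectonemic phase of a
    stretched linear chain.

    The writhe lives in the plectoneme; the extended phase holds only its
    (uniform-density) share of the twist, so
    σ_p = ΔTw/Lk0 + ΔWr/(Lk0·x_p) with x_p the plectonemic contour
    fraction.  Because σ_p is sensitive to x_p, two estimators bracket it:
    the strand-proximity classification (which misses loose plectoneme
    regions and end loops) and its complement restricted to segments
    aligned with the stretching axis (everything not both isolated and
    axis-aligned counts as plectonemic).  ``with_error=True`` also returns
    half their spread as a systematic uncertainty.
    """
    if samples.mode != "linear_fixed_extension":
        raise ValueError("plectonemic_sigma applies to linear-mode runs")
    if samples.positions.shape[0] == 0:
        raise ValueError("run was sampled without stored positions")
    x_prox, x_align = [], []
    for r in range(samples.positions.shape[0]):
        pos = samples.positions[r]
        lab = classify_segments_linear(pos)
        x_prox.append(lab.mean())
        bonds = pos[1:] - pos[:-1]
        e = bonds / np.linalg.norm(bonds, axis=1)[:, None]
        axis = pos[-1] - pos[0]
        axis /= np.linalg.norm(axis)
        extended = (~lab) & (np.abs(e @ axis) > 0.7)
        x_align.append(1.0 - extended.mean())
    tw = samples.twist.mean()
    wr = samples.writhe.mean()
    lk0 = samples.params.lk0
    sig = []
    for x in (float(np.mean(x_prox)), float(np.mean(x_align))):
        x = max(x, 1e-6)
        sig.append(tw / lk0 + wr / (lk0 * x))
    centre = 0.5 * (sig[0] + sig[1])
    if with_error:
        return float(centre), float(abs(sig[0] - sig[1]) / 2)
    return float(centre)


# ----------------------------------------------------------------------
# fits
# ----------------------------------------------------------------------
@dataclass
class FitResult:
    """Weighted least-squares through the origin."""

    value: float
    stderr: float
    residuals: np.ndarray
    inputs: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predicted(self, x: np.ndarray) -> np.ndarray:
        return self.value * np.asarray(x, float)


def _fit_through_origin(x: np.ndarray, y: np.ndarray,
                        se: np.ndarray | None) -> FitResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or np.allclose(x, 0):
        raise ValueError("degenerate input for a through-origin fit")
    w = np.ones_like(x) if se is None else 1.0 / np.asarray(se, float) ** 2
    sxx = np.sum(w * x * x)
    slope = np.sum(w * x * y) / sxx
    resid = y - slope * x
    dof = max(x.size - 1, 1)
    chi2 = np.sum(w * resid**2) / dof
    stderr = math.sqrt(max(chi2, 1e-300) / sxx)
    return FitResult(value=float(slope), stderr=float(stderr),
                     residuals=resid, inputs=x)


def fit_P(sigmas, mean_torques, params: SimulationParameters,
          torque_ses=None) -> FitResult:
    """Plectonemic twist persistence length from τ = P·kBT·ω0·σ (nm).

    Least squares through the origin of torque against kBT·ω0·σ, weighted
    by 1/SE² when torque uncertainties are given.
    """
    sig = np.asarray(sigmas, float)
    if sig.size < 3:
        raise ValueError("need at least 3 sigma points in the linear regime")
    x = params.kBT * params.omega0 * sig
    return _fit_through_origin(x, mean_torques, torque_ses)


def fit_alpha(sigmas, mean_forces, force_ses=None) -> FitResult:
    """Quadratic force coefficient from F = α·σ² (pN)."""
    sig = np.asarray(sigmas, float)
    if sig.size < 3:
        raise ValueError("need at least 3 sigma points")
    return _fit_through_origin(sig**2, mean_forces, force_ses)


# ----------------------------------------------------------------------
# torque fluctuations
# ----------------------------------------------------------------------
def torque_distribution(samples: SampleSet, n_boot: int = 200,
                        rng: np.random.Generator | None = None) -> dict:
    """Distribution of the instantaneous chain-averaged torque.

    Samples are thinned by the measured integrated autocorrelation time
    before the standard deviation is estimated; its uncertainty comes from
    a bootstrap over the decorrelated samples.
    """
    tau = torque_samples(samples).mean(axis=1)
    t_int = autocorrelation_time(tau)
    step = max(1, int(math.ceil(t_int)))
    if step > 1:
        thin = tau[::step]
    else:
        thin = tau
    if thin.size < 10:
        raise StatisticsError("too few decorrelated samples")
    if t_int > 5.0:
        warnings.warn(
            f"torque autocorrelation time {t_int:.1f} sample strides; "
            "consider sampling less often", stacklevel=2)
    rng = rng or np.random.default_rng(0)
    boots = np.array([
        rng.choice(thin, thin.size, replace=True).std(ddof=1)
        for _ in range(n_boot)
    ])
    hist, edges = np.histogram(thin, bins="auto", density=True)
    return dict(
        mean=float(thin.mean()),
        std=float(thin.std(ddof=1)),
        std_err=float(boots.std(ddof=1)),
        n_independent=int(thin.size),
        autocorr_time=float(t_int),
        hist=hist, bin_edges=edges,
    )
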