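# Methods

## Model

A circular (or end-clamped linear) DNA of contour length `L` is discretized
into `N` straight segments of rest length `l0` (default 10 nm ≈ 29 bp).
Segment `i` carries a right-handed orthonormal triad `(ê_i, f̂_i, ĝ_i)` with
`ê_i` along the segment; `f̂_i` tracks the material (torsional) orientation.
The energy, in units of kBT (4.11 pN·nm at 298 K), is

- **bending** `Σ_j A_j/(2 l0) · θ_j²`, with `θ_j` the angle between
  consecutive tangents and `A` the bending persistence length (43 nm).
  The harmonic-in-angle form agrees with `A/l0 (1 − cos θ)` to O(θ⁴) at
  10 nm resolution; it is isolated in one function and swappable.
- **twisting** `Σ_j C_j/(2 l0) · φ_j²`, with `φ_j` the excess twist angle at
  junction `j` and `C` the twist persistence length (110 nm; 109 nm is used
  in the fluctuation-theory comparisons, both values appearing in the
  measured literature range).  `φ_j` is extracted by the minimal-rotation
  (parallel-transport) decomposition: remove the bend by the smallest
  rotation mapping `ê_{j-1}` onto `ê_j`, then measure the residual rotation
  of `f̂` about `ê_j`.  The quaternion swing–twist decomposition is the
  reference implementation in the test-suite.
- **electrostatics** screened Debye–Hückel repulsion between segments,
  `q·l0²·exp(−r/λ_D)/r`, evaluated at the minimum rod–rod distance `r`
  between the two segments, cut off at `7 λ_D`, with the nearest contour
  neighbour excluded (adjacent segments share a vertex).  Defaults:
  `λ_D = 0.8 nm` (≈150 mM monovalent salt) and
  `q = kBT · l_B · ν²  = 17.33 pN·nm²` from an effective linear charge
  density `ν = 2.43 e/nm` (Stigter-type effective charge) and Bjerrum
  length 0.714 nm.  A hard-core diameter of 2 nm (the bare B-DNA diameter)
  rejects contacts outright.  Midpoint point charges were tried first and
  discarded: with 10 nm segments the potential has gaps near segment ends
  through which strands slide freely, collapsing the plectoneme radius and
  the torque.  The rod–rod distance closes those gaps.
- **stretching** `Σ_i k/(2 kBT) (ℓ_i − l0)²` — each segment is a stiff
  Hookean spring (`k = 100 pN/nm`) used as the tension readout.

Per-segment arrays for `A` and `C` support sequence heterogeneity; junction
`j` uses the stiffness of segment `j` (the outgoing segment), a pure
convention at this resolution.

## Topology bookkeeping

Writhe is the exact pairwise Gauss sum over segment pairs; each pair
contributes the signed solid angle of its Gauss-map quadrilateral,
evaluated as two spherical triangles with the atan2 (van Oosterom–Strackee)
formula, which remains well-conditioned for nearly crossing segments where
arcsine-based forms lose digits.  Twist is the sum of the junction angles.
For the discrete closed ribbon the Călugăreanu identity `Lk = Tw + Wr`
holds **exactly** (to round-off), which the sampler exploits: a legitimate
move leaves `Tw + Wr` unchanged, a strand passage jumps it by ±2, and a
junction angle wrapping past π jumps it by ±1, so the passage guard rejects
any accepted backbone move with `|Δ(Tw+Wr)| > 0.45` turns.  Because the
invariant is integer-quantized there is no slow drift to monitor — the
audits (every ~5000 moves) recompute everything from scratch and confirm
agreement at the 1e−6 level.

The end-clamped linear chain is closed virtually through a fixed
rectangular return path three contour lengths away, entering both clamps
along the stretching axis; `Tw + Wr` of that circuit is the conserved
quantity.

## Monte Carlo sampling

Three symmetric proposals: crankshaft rotations of a random sub-arc (2 to
`N/4` segments, capped at 30) about its chord; single-vertex Gaussian
displacements; and twist exchanges between an arbitrary junction pair
(+δ at one junction, −δ at another, realized by rotating every segment
frame between them about its own tangent).  The pairwise exchange
conserves total twist exactly and mixes the twist field globally — with
only adjacent exchanges the twist coordinate equilibrates diffusively in
O(N²) moves, slow enough to leave spurious structure in per-segment
torque profiles.  The default mixture is 25/50/25 — vertex moves are
over-weighted because they are the only moves that sample the spring
lengths, and the tension readout is the noisiest observable.  Amplitudes
are tuned toward ~40% acceptance during equilibration and then frozen, so
production sampling satisfies detailed balance.  Equilibrium is verified
in the tests by first/second-half comparisons and by the Boltzmann check
on an enumerable twist-only system.

Production runs of supercoiled circles start from a pre-writhed
interwound loop (two antiparallel strands around a common axis at a 10 nm
superhelix radius, closed by end loops) carrying most of the imposed ΔLk
as writhe: plectoneme nucleation from a flat twisted ring takes over 10⁶
moves at N = 200, whereas the interwound start needs only local
relaxation.  Slowly-mixing observables — tension above all, which rides
on plectoneme branch-number fluctuations with correlation times of
several 10⁵ moves — are additionally sampled over independently
equilibrated replicas rather than one long trajectory.

The nicked circle decouples twist from the backbone: it is sampled with
zero twist stiffness (backbone moves only), while its twist fluctuations —
exactly Gaussian with variance `L/(4π²C)` — are attached analytically or by
direct Gaussian sampling; the two routes are cross-checked in the tests.
The frames still ride along as ghost bookkeeping so the passage guard keeps
the backbone unknotted, and are re-zeroed at every audit so junction angles
never wrap.

## Readouts

- **Torque** at junction `j`: `τ_j = kBT · C_j · φ_j / l0`, negative when
  underwound.  Chain-averaged torque per sample equals
  `2π kBT C Tw / L` for uniform `C`.
- **Tension** of segment `i`: `F_i = k · (⟨ℓ_i⟩ − ℓ_free)`.  Because vertex
  positions are sampled in Cartesian measure, each bond vector carries an
  `ℓ²` Jacobian and the unloaded spring equilibrates at
  `ℓ_free = l0 (1+3s)/(1+s)`, `s = kBT/(k l0²)` — about 0.008 nm (0.8 pN)
  above the rest length at the defaults.  Subtracting `ℓ_free` (closed
  form, exact for a free spring) makes a relaxed ring read zero force; the
  residual couplings (ring closure, electrostatics) shift the baseline by
  under 0.01 pN at desk scale.  A `baseline="rest"` option reports the raw
  spring extension instead.
- **Apex alignment**: the plectoneme apex of a circular conformation is the
  vertex farthest from the centre of mass (conformations with small radial
  spread fall back, with a warning, to unshifted averaging).
- **Extended/plectonemic classification** (linear mode): a segment is
  plectonemic when a non-neighbouring segment (contour separation > 4) has
  its midpoint within 10 nm (≈ twice the superhelix radius); a
  morphological closing over 3 segments removes speckle.  The plectonemic
  superhelical density divides the plectonemic turns (all writhe plus the
  plectonemic share of twist) by the relaxed linking number of the
  plectonemic contour fraction.
- **Fits**: `τ = P·kBT·ω0·σ` and `F = α·σ²` are weighted (1/SE²)
  least-squares through the origin — the model forms have no intercept.
- **Uncertainties**: block averaging with ≥ 10 blocks; torque-fluctuation
  SDs are computed on samples thinned by the measured integrated
  autocorrelation time, with bootstrap errors.

## Fluctuation theory

For a nicked circle, twist and writhe fluctuate independently:
`s²_Tw = L/(4π²C)` and `s²_Wr = f(A, L)`, the Shimada–Yamakawa empirical
closure formula in `t = L/(2A)`:

    f(t) = 0.095 t³ e^(−6.8 t^(−2.5)) / (19.47 + t²)
         + 0.00385 t² (1 + 1.092 t + 0.76 t² + 0.2788 t³) e^(−t)

(vanishing for stiff rings, growing as `0.095 t` for long ones).  Their sum
is the linking variance, which defines the plectonemic twist persistence
length through `s²_Lk = L/(4π²P)`, giving the closed form
`P = LC / (L + 4π²C f(A,L))` — for A = 43 nm, C = 110 nm this sits at
19–21 nm across the multi-kb range, matching the torque-slope measurement.
Constraining ΔLk couples the channels; each then fluctuates with the
harmonic combination `s'² = s²_Tw s²_Wr/(s²_Tw+s²_Wr)`, and propagating
through `τ = 2π kBT C Tw / L` gives the torque fluctuation
`s'_τ = kBT √((C−P)/L)`, independent of σ.  The transcription of the
closure formula was cross-validated against nicked-ring simulation (the
test-suite's authority for it), against its stiff- and long-chain limits,
and against published linking-number variances of plasmid-sized rings.

The closure-formula validation runs use the full model (electrostatics
on), which reproduces the formula within ~7% at desk scale — the same
comparison the quasi-analytical framework itself makes.  Two opposing
corrections sit inside that agreement: the 10-nm discretization of an
*ideal* (no-electrostatics) ring over-writhes relative to the continuum
formula by ~15–20% at these ring sizes, while the screened self-repulsion
suppresses writhe by a comparable amount.  The ideal-chain excess is a
property of the formula's reach at small rings, not of the writhe
computation (which is validated independently against quadrature); it is
surfaced here rather than hidden because users running phantom chains will
see it.

## Study conditions and problem sizes

Simulation-based checks run at desk scale, chosen so the whole suite and
the reproduction script complete on one CPU:

- headline torque/force/fit checks: N = 200 segments (L = 2000 nm ≈
  5.9 kb), with two to three independently equilibrated replicas at the
  force-bearing σ points;
- fluctuation-closure checks: N = 64 nicked/relaxed rings (L = 640 nm);
- torque-fluctuation length scan: N = 36, 50, 72 — small rings mix the
  slow twist–writhe exchange mode fast enough to estimate a variance;
- linear-mode checks: N = 180 at extension = contour/9.

Equilibration is the slow step and grows with |σ| (0.4–1.4 M moves at
N = 200 even from the interwound start); production runs of 0.3–2 M moves
give torque SEs of ~0.1–0.3 pN·nm and force SEs of ~0.05–0.1 pN.  The
force readout is intrinsically noisy: the spring-length fluctuation per
sample is √(kBT·k) ≈ 20 pN per segment, and the chain-averaged tension
also rides on slow plectoneme branch-number modes (correlation times of
several 10⁵ moves at N = 200), which dominates its error bar and is the
reason for replica averaging.

## What the generator emulates — and what it does not

The synthetic conformations and the sampler represent torsionally
constrained B-DNA in ~150 mM monovalent salt with homogeneous (or two-block
heterogeneous) elastic constants.  Not represented: sequence-dependent
intrinsic curvature, DNA melting (so computed torques keep rising beyond
σ ≈ −0.08, where real DNA plateaus near −11 pN·nm as it denatures —
magnitudes beyond that density are model extrapolations), bound proteins,
hydrodynamics or any physical time scale (Monte Carlo time is not
kinetics), and knotted topologies (the initializer produces unknots and the
passage guard preserves them).  Desk-scale rings also carry finite-size
effects: at L = 2000 nm the measured torque at σ = −0.08 is ~10–15% above
the melting-capped experimental value, consistent with both the missing
melting transition and the residual curvature of a small ring.

## Numerical choices

- Tolerances: triad orthonormality 1e−9; topology audits 1e−3 turns
  (violations raise, they are never absorbed); passage-guard threshold
  0.45 turns (unambiguous between 0 and the smallest possible jump of 1).
- Degenerate inputs: 180° bends make parallel transport undefined and are
  rejected (as proposals) or raised (as inputs); segment pairs inside the
  hard core are rejected; crankshaft chords shorter than 1e−9 nm are
  skipped.
- The electrostatic pair loop prefilters with midpoint distances
  (`r_min ≥ |Δmid| − (ℓ_i+ℓ_j)/2`) before the exact rod–rod distance.
- Sensitivity checks (reported by `scripts/sensitivity.py` if run
  manually): doubling `el_cutoff` from 5.6 nm to 11.2 nm changes the
  σ = −0.06 torque and force by well under the sampling error, because the
  screened potential at 5.6 nm is already below 0.07 kBT per contact;
  halving `l0` to 5 nm (N doubled) keeps the fitted P within a few percent;
  the force readout shifts by `ΔF ≈ 2 kBT Δ(1/l0)` through the baseline
  term, which the closed-form `ℓ_free` absorbs exactly.

## Known limitations

- The per-segment force profile needs long runs; at the default scales its
  per-segment error bars are ~0.1–0.2 pN, so the uniformity checks bound
  deviations at the 3·SE level rather than resolving fine structure.
- `P` from the τ–σ slope mixes the pre-buckling and plectonemic regimes;
  at desk scale the slope is a few percent below the nicked-ring closure
  value, as expected from the slightly sublinear torque curve.
- The quadratic force law is an effective fit: the measured force at
  σ = −0.06 runs ~0.05–0.1 pN below `α σ²` with the α fitted over
  |σ| ≤ 0.08, matching the behaviour seen in the torque (both readouts are
  sub-quadratic/sub-linear approaching the melting-relevant range).
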