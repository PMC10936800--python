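# Methods

`kinnet` simulates a point cargo pulled by a team of two kinesins over a 2-D
network of static microtubules (MTs). This note records the model, its
parameters, the numerical scheme, the design choices that were genuinely
open, and the limitations a user should know about before trusting any
number the package prints.

## Motor model

Each kinesin occupies a discrete lattice site `r_i = i * 8 nm` on one MT and
is described by four load-dependent laws (load `F` in pN, positive when the
cargo-motor spring pulls the motor toward the minus end, i.e. resists
plus-end stepping; assisting loads are negative):

* dwell time: `tau_D(F) = a1 + a2 * (1 + tanh(a3 * (F - a4)))`, with
  `a1 = 0.0098 s`, `a2 = 0.07 s`, `a3 = 0.06 /pN`, `a4 = 6 pN` (a high-ATP
  Kif5B parameterization);
* forward/backward ratio: `R(F) = A * exp(-F ln A / F0)` with `A = 1000`
  and stall force `F0 = 6 pN`. The logarithm is natural: only then does
  `R(F0) = 1`, i.e. forward and backward stepping balance exactly at stall,
  which is what "stall force" means;
* step rates: `P_f = [R/(1+R)] / tau_D`, `P_b = [1/(1+R)] / tau_D`, so
  `P_f + P_b = 1/tau_D` identically and `P_f/P_b = R`;
* unbinding rate: `P_det(F) = exp(-F/Fd) / (Ad * tau_D(F))` with
  `Fd = 3.18 pN` and detachment coefficient `Ad = 1` by default. The law is
  catch-bond-like: resisting load slows unbinding, assisting load
  accelerates it (the experimentally observed detachment asymmetry). `Ad`
  rescales the whole curve as `1/Ad`.

A detached motor is carried along at the cargo position and rebinds with
rate `Pi = 5 /s` to a uniformly chosen MT whose distance to the cargo is at
most the maximum tether stretch `r0`, at the lattice site nearest the
cargo's projection (the attempt fails if the other motor occupies it).

Per time step `dt` each attached motor draws at most one event from the
disjoint probabilities `P_det dt`, `P_f dt`, `P_b dt` (first-order kinetic
Monte Carlo; `dt = 1e-5 s` keeps their sum far below 1 at moderate loads).
Two motors never share a lattice site: a step into an occupied or
nonexistent site resolves to a hold. A motor standing on a crossing site
that attempts a step first chooses uniformly among its current MT and every
MT registered at that crossing, then steps one site in the chosen direction
on the chosen track; this is the minimal track-switching rule consistent
with "remain or switch at a junction" and introduces no extra parameters.

During the initial transient, motors placed on distant MTs can experience
spring loads of O(100) pN, for which `P_det dt` exceeds 1. Inside the
engine such probabilities are capped at 1 (the event fires with certainty —
physically, the tether rips the motor off instantly) instead of aborting;
the public `sample_motor_event` keeps the strict contract and raises, since
a user calling it directly with such a `dt` is making an error.

## Cargo model

The cargo is a point particle obeying the overdamped Langevin equation
`gamma dr_c/dt = xi(t) + sum_i f_i` in 2-D, integrated with explicit
Euler-Maruyama at fixed `dt`, with isotropic thermal noise applied
independently per axis (`<xi xi'> = 2 gamma kBT delta(t-t')`,
`kBT = 4.1 pN nm`, room temperature). Each motor pulls through a dead-zone
spring: zero force while the separation `Delta_i` is below the critical
tether length `r0 = 110 nm`, and an attractive Hookean force
`k (Delta_i - r0)` with `k = 0.32 pN/nm` beyond it. (A third, 1-D notation
branch `k (Delta + r0)` for `Delta <= -r0` is unreachable in 2-D, where
`Delta` is a norm, and is not implemented.) The load entering the motor
rate laws is the exact Newton's-third-law reaction of the spring force on
the cargo, projected on the MT axis.

The drag is the Stokes value for a 0.5 um bead in cytoplasm-like medium
(100x the viscosity of water): `gamma = 6 pi eta r = 9.42e-4 pN s/nm`.
Written with the exponent dropped this constant is sometimes quoted as
"9.42 pN s/nm"; that reading is dimensionally untenable here — it would
give a free-diffusion coefficient of 0.4 nm^2/s and cap the two-motor
cargo speed at ~1 nm/s, freezing the system — while the consistent value
reproduces the unloaded single-motor transport speed to within 1% and a
realistic cargo diffusivity `kBT/gamma = 4.4e-3 um^2/s`. The spring
relaxation time `gamma/k ~ 3 ms` is 300x the time step, so the explicit
scheme is comfortably stable.

## Networks

MTs are straight 12000-nm segments (1500 sites) with uniform polarity:
minus end left, plus end right, inside a 12100 x 7000 nm region. Pairwise
segment intersections are computed exactly and mapped to the nearest
lattice site on each MT (mapping error <= 4 nm + tolerance; equidistant
ties round down for determinism; collinear overlaps, a measure-zero event
under continuous sampling, register no crossing and log a warning).

Two layout families are provided. The exact sampling laws are a design
choice constrained by the intended crossing structure:

* **NRS** (non-radial): orientation `theta ~ U(-15deg, +15deg)`, minus-end
  `x ~ U[0, L - 12000 cos(theta)]`, `y ~ U[0, W]`, rejecting draws that
  leave the region. Crossings spread over the whole region.
* **QRS** (quasi-radial): minus ends uniform in a 300-nm disc centered at
  `(150 nm, W/2)`, `theta ~ U(-16deg, +16deg)` (chosen so plus ends span
  the region width), with rejection on region exit. Crossings concentrate
  in the core and the line density decays roughly as 1/r outward.

Both samplers are bit-reproducible per seed and abort after 1000 rejected
draws (impossible geometry). By default every replicate draws a fresh
network, so ensemble averages marginalize over geometry; `fixed_network`
reuses one realization.

## Update loop and the all-detached fast path

Per `dt`: (1) spring forces and signed loads from start-of-step positions;
(2) motor events in random motor order; (3) reattachment trials for
detached motors; (4) the cargo Euler-Maruyama update; (5) time advance,
first-passage detection (at `dt` resolution), and recording every 10 ms.

While *all* motors are detached the system is exactly a freely diffusing
cargo plus independent Bernoulli(`Pi dt`) rebinding trials. The compiled
loop therefore leaps over such stretches: the number of steps to the next
trial is geometric (memoryless, so truncating at recording boundaries and
resampling is exact), and the accumulated displacement over `n` steps is
`N(0, n * 2 kBT dt / gamma)` per axis. This is a pure speed optimization —
it changes no statistic — and it is what makes censoring-dominated
first-passage ensembles affordable; its noise scaling and rebinding
statistics are covered by the free-diffusion and ensemble tests. The one
approximation it introduces is that during an all-detached stretch first
passage is checked at segment ends (<= one recording stride apart) rather
than every `dt`; a free cargo would have to diffuse ~10 um inside a 0.1 s
segment for this to matter, which has negligible probability.

Initialization places each motor independently on a uniformly chosen MT at
a site uniform over the first 10 lattice sites of its minus end (resampling
site collisions), and the cargo at the centroid of the motor positions.
Replicate seeds are spawned from the master seed with `SeedSequence`, so
ensembles are reproducible and order-independent.

## Observables

All ensemble curves are replicate averages on the recording grid:

* `vc`: trailing-window (0.1 s) displacement along the transport axis
  divided by the window. The axial component is used, not speed magnitude,
  because the passage target and MT polarity are axial; the window length
  is a smoothing choice.
* `mc_same` / `mc_diff`: indicator that both motors are bound to the same /
  to different MTs; any unbound motor contributes 0 to both, so the curves
  are deliberately non-complementary.
* `ma`: fraction of motor-replicate pairs with `f_i > 0` (taut spring),
  normalized by `2 x n_replicates`.
* `mid`: Euclidean intermotor distance; detached motors sit at the cargo,
  so two detached motors give 0 with no special-casing.
* First passage: earliest time the cargo's axial displacement from its
  start reaches the target (default 10000 nm). Runs that never arrive
  within their horizon are censored, excluded from the summary statistics
  and counted as slow in the fast-fraction (threshold 18.8 s). First-
  passage ensembles run with `stop_at_target` under an extended 200 s
  horizon, since sparse networks produce passages far beyond a 25 s
  observation window.
* Distribution summaries: arithmetic mean; mode as the center of the
  fullest 0.5-s histogram bin anchored at 0 (half-second resolution
  matches how such modes are conventionally quoted; first bin wins ties);
  standard deviation (sample `ddof=1` in `distribution_stats`, population
  `ddof=0` in the first-passage summary — both exposed as arguments); and
  Fisher skewness `g1 = m3 / m2^{3/2}` on central moments without
  small-sample bias correction.

## Problem sizes used by `scripts/acceptance.py`

The script reports ensemble statistics at sizes chosen as a deliberate
compromise between sampling error and single-CPU runtime: 200 replicates
for each first-passage ensemble (NRS-80 and QRS-80 with a 60 s horizon,
2.4x the 25 s observation window; NRS-20 with the full 200 s extended
horizon) and 100 replicates per point of the 7-value detachment sweep on
both structures (15.2 s runs, steady window 5-15 s). When a first-passage
ensemble is fully censored at its horizon — which is the case at the
default `Ad = 1`, see below — the script reports the mean of
`min(FPT, cap)`, a computed lower bound on the true mean, rather than an
undefined value, and says so on stdout.

## Known limitations and the detachment-scale sensitivity

The central caveat of this parameter set: at zero load the stepping and
unbinding rates nearly coincide (`P_f(0) = 17.96 /s`,
`P_det(0) = 17.97 /s` at `Ad = 1`), so the mean attachment lasts a single
8-nm step and the mean zero-load run length is `Ad x 8 nm`. The tether
transmits no force until it is stretched past `r0 = 110 nm`, so a motor
must string together ~14 surviving steps before the cargo feels anything.
At `Ad = 1` that has probability ~`0.5^14 ~ 6e-5` per attachment:
directed transport is essentially switched off (measured steady `vc` of a
two-motor NRS-80 ensemble is O(1-10) nm/s, and no replicate reaches 10 um
within 200 s). Sustained transport requires run lengths past the dead
zone, i.e. `Ad` of order 15 or more (`examples/05_detachment_sweep.py`
makes this visible: `vc` rises monotonically with `Ad` through the whole
0.002-5.0 range and approaches the 143.7 nm/s single-motor ceiling only
around `Ad ~ 100`). Published two-kinesin first-passage statistics of
order 15 s to 10 um (i.e. ~650 nm/s) are unreachable under these laws for
*any* `Ad` — they exceed even the unloaded single-motor speed — so the
acceptance ensembles report censoring-dominated bounds instead; the
discrepancy is a property of the printed constants, not of the sampler,
and the package deliberately does not retune them.

Scope limitations by construction: MTs are volume-less rigid lines with a
single protofilament and no dynamic instability; the two motors bind a
single point on the cargo (no rotational degrees of freedom or finite
cargo radius); teams larger than 2 are accepted by the data model but
untested against any reference; minus-end-directed motors (dynein) and
mixed-polarity networks are out of scope. The synthetic networks emulate
only the crossing *statistics* of the two architectures — real
cytoskeletal meshes have curvature, bundling and 3-D structure that these
samplers do not represent — so conclusions transfer to real geometries
only at the level of orderings (e.g. core-concentrated vs spread-out
crossing maps), not absolute numbers.
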