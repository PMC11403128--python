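# Methods

## Model and procedure

The measurement model is `B = G Q + N`: an M×T MEG sensor matrix generated by
a 2P×T source matrix through the M×2P gain (lead-field) matrix `G`, plus
noise. Each of the P grid nodes carries an equivalent current dipole with two
orientations. In the single-sphere conductor model these are the two
tangential directions (a radial dipole in a spherically symmetric conductor
is magnetically silent); for imported lead fields computed with a realistic
head model they are the two dominant right-singular vectors of the per-node
M×3 lead field. `sphere_leadfield` evaluates the closed-form field of a
current dipole in a homogeneous conducting sphere at point magnetometers
(field projected on the coil normal).

The imaging chain, per frequency band and per EMG channel:

1. **Condition** the EMG (per-channel linear detrend; zero-phase IIR notches
   at the powerline frequency and harmonics, Q = 30; no rectification — the
   method uses the full EMG waveform, not its envelope) and band-pass both
   MEG and EMG into the analysis band with a zero-phase 4th-order Butterworth
   (delta 1–4, theta 4–7, alpha 8–12, beta 15–30, gamma 30–90, upper-gamma
   60–90 Hz). Filtering the EMG to the analysis band (default, configurable)
   confines the measured coupling to the band under test.
2. **Delay matrix.** D rows of the EMG, advanced by 0…100 ms in 1-ms steps
   (delays −100…0 ms, D = 101), truncated to the common support, each row
   zero-meaned and unit-L2-normalized. A brain signal leading the muscle by
   |d| ms correlates maximally with the row at delay d.
3. **Projection.** `F = B Eᵀ` (M×D). Projection is a temporal matched filter:
   the expected contribution of activity uncorrelated with the EMG is zero,
   so F concentrates the EMG-locked brain signal.
4. **Whitening and spatial modes.** A symmetric whitener from the band-passed
   empty-room covariance (diagonal loading 1e-3 × mean diagonal guarantees
   invertibility) is applied to the sensor dimension of F; the SVD of the
   whitened F gives spatial modes. The retained count κ is the number of
   singular values above `mode_factor` (default 3) × the noise floor, where
   the floor is the leading singular value the identical chain produces on
   empty-room data; κ is clipped to [1, 10], with a warning when nothing
   clears the floor.
5. **Inverse solve.** For each retained mode i the constraint is the
   consistent reduction of the projected-data system by the truncated gain
   SVD: `S_G V_Gᵀ h_i = U_Gᵀ u_i s_i`, relaxed to a second-order cone of
   radius ε_i. The objective is the depth-weighted group-L1 norm
   `Σ_j ω_j √(Σ_i h²_ijθ + h²_ijφ)`; grouping the orientation pair makes the
   solution invariant to rotations of the dipole in its tangent plane, and
   grouping across modes makes all mode maps share one sparse support.
   Depth weights use the leverage `w = diag(V_G V_Gᵀ)` of the retained gain
   subspace, combined per node as `ω_j = √(w_{2j−1} + w_{2j})` (sum is the
   default; max is available). Zero-leverage nodes receive the maximum
   weight so no current is placed where the sensors cannot see.
6. **Maps, combination, thresholding.** Per-node magnitude
   `A_j = √(Σ h²)` over the node's orientation pair and all modes (the
   per-node aggregation of diag(H Hᵀ)); delay-resolved maps
   `Q_d = H V_Fᵀ` (retained modes) give a per-node max-across-delays map and
   a winning delay. EMG channels are combined by Euclidean norm at the map
   stage. The identical chain applied to the empty-room recording (against
   the task EMG delay matrices, time-aligned and equal length) sets the
   display threshold at 1.5× its maximum node magnitude (saturation 3.0×);
   a localization counts as a success when the suprathreshold peak lies
   within 10 mm of the target (two nodes at the desk grid's 10-mm spacing).

## The GSOCP solver

The cone program is solved by ADMM with exact per-iteration projections:

* the projection onto `{h : ‖S V_Gᵀ h − b_i‖ ≤ ε_i}` keeps the component of
  the iterate orthogonal to range(V_G) and moves the reduced coordinates
  onto the ellipsoidal ball by solving the scalar secular equation
  `Σ_l r_l²/(1+μ S_l²)² = ε_i²` for the multiplier μ (safeguarded Newton,
  warm-started across iterations; ε_i = 0 reduces to the exact solve
  `c = S⁻¹ b_i`);
* the proximal step of the weighted group norm is a block soft-threshold
  over each node's 2×κ coefficient block.

The problem is internally rescaled by the leading gain singular value and
the largest right-hand-side norm, with residual-balancing adaptation of the
ADMM penalty. Iterations are deterministic (no randomized initialization);
stopping uses standard primal/dual residual tolerances (defaults: relative
1e-8, absolute 1e-10, 200 000 iterations for the bare solver; the pipeline
uses relative 1e-6 and 30 000 iterations, logged in provenance). The
returned iterate is the exact projection onto the constraint set, hence
always feasible; hitting the iteration cap returns status `max_iter` with a
warning (or raises, configurable) rather than an infeasible point. The
correctness reference is an independently solved smoothed epigraph
reformulation (SLSQP), which the test suite checks to 1e-5 relative on
random small instances.

### Cone radii (regularization)

The bare solver defaults to ε_i = δ‖b_i‖ with δ = 1e-3 (δ = 0 requests
equality). The pipeline instead derives ε_i from the data: the trailing
singular values (beyond κ) of each chain's own whitened projection measure
its non-EMG-locked content — sensor noise *and* ongoing background brain
activity, which an empty-room recording cannot estimate (background 1/f
activity is strong in the delta band). Their expected leakage into a
retained mode is `ε = √(Σ_{j>κ} s_j² / D_eff)`, where D_eff is the
participation ratio `(Σλ)²/Σλ²` of the delay-matrix Gram spectrum: delayed
copies of a narrow-band EMG are highly correlated, so projected noise
concentrates into far fewer than D dimensions. Radii are capped at 0.8 s_i
so the leading mode is never discarded outright. With the fixed small δ
instead, the solver is forced to fit background leakage and delta-band maps
mislocalize; the data-derived radius is the package's discrepancy-principle
choice and applies identically to task and empty-room chains, keeping their
map magnitudes comparable for the 1.5× threshold.

## Synthetic data

`simulate_emg` draws movement bursts at jittered intervals (rate 1 Hz,
interval CV 0.15 by default; irregular mode draws intervals uniformly from
0.35–2.2 s, destroying the spectral peak). Each burst is a 150-ms
Hann-windowed 20–150 Hz noise carrier plus a movement-locked slow deflection
(Gaussian, 50-ms sigma, 0.8× burst amplitude) — the low-frequency component
that places the movement rate and its harmonics at the top of the raw EMG
spectrum, as real movement EMG shows. Two channels (flexor, extensor) have
time-offset envelopes and independent carriers; 2% measurement noise.

`simulate_sources` builds the target-node course per coupled band as the
agonist (flexor) EMG band-filtered to the coupling band, advanced by the
true lag, RMS-normalized and scaled by the coupling gain, with a fixed
orientation mix in the tangent plane, plus an uncoupled narrow-band
intrinsic oscillation (0.3 gain). Coupling to a single channel keeps the lag
well defined in each per-channel delay chain; the flexor/extensor envelopes
are offset in time, so a summed reference would smear the effective lag.
Coupled components are confined well inside their nominal band — the
multiband preset's beta coupling uses 15–24 Hz — because finite-order
analysis filters pass shared-edge content into the neighboring band's chain,
which would blur the generator's "no gamma coupling" condition. Background
sources (15 by default) sit at random nodes at least 15 mm from the target
with 1/f spectra (exponent 1) and an 8–12 Hz alpha bump, scaled to the
sensor-noise RMS. Sensor noise is i.i.d. Gaussian (2e-13 T RMS), and the
empty-room recording is an equal-duration draw from the same noise process.

**Reference SNR.** The coupled-source sensor-level RMS is scaled to
`REFERENCE_SNR = 1.0` × the sensor-noise RMS. This operating point — and the
multiband per-band coupling gains (delta 2.5, theta 1.0, beta 0.7) — was
calibrated once with `scripts/calibrate_snr.py` so the healthy presets
localize in essentially every run while the no-coupling control stays at the
false-positive floor, then frozen. Delta carries the largest gain because
band-limited background activity is strongest at low frequencies.

**What the generator does not emulate:** volume-conducted EMG crosstalk,
motor-unit physiology, head movement, correlated (environmental) sensor
noise, gradiometer arrays, and realistic (BEM) head geometry. Passing tests
therefore demonstrate the method's behavior under its stated statistical
assumptions — band-limited brain–EMG dependence at a negative lag against
uncorrelated background — not performance on any particular real recording.

## Desk-scale problem sizes

The default geometry is a 102-magnetometer spherical cap (radius 0.102 m)
and a 15–55-mm shell grid at 10-mm spacing (~700 nodes); recordings are 60 s
at 1 kHz. The detection-rate analyses use 26 datasets (13 seeds ×
left/right hemisphere mirror). These sizes keep a full three-band cohort run
in minutes on one CPU while preserving the regime the method targets
(2P ≫ M, D ≪ T).

## Numerical choices and edge cases

* Deterministic sign conventions for all singular vectors; lexicographic
  (z, y, x) grid ordering; peak ties resolve to the smallest node index.
* Gain SVD truncation keeps `s_i/s_1 > 1e-6` by default (energy- and
  rank-based rules available); the rule is recorded with the factorization.
* Grids are built on a cubic lattice anchored at multiples of the spacing;
  the simulator's shell mask excludes a 15-mm core because a node at the
  conductor center has no tangential frame (and cortex is not at the head
  center).
* A recording shorter than the delay window plus 1 s warns (poorly averaged
  delay rows) but only a support of fewer than 2 samples is an error.
* All-zero projected data yields κ = 0 and a skipped solve with explicit
  status; an exactly zero empty-room map substitutes a solver-floor
  threshold with a warning.
* Empty-room and task data are truncated to their common duration for the
  map chains; the noise covariance always uses the full empty-room
  recording (minimum 10 s).

## Known limitations

* The empty-room threshold compares map maxima, not calibrated statistics;
  uncoupled bands with strong in-band background (alpha) can exceed it away
  from the target, as in real data.
* ADMM at pipeline tolerances yields maps accurate to the localization and
  thresholding task, not to machine precision; tighten `solver_rel_tol` for
  magnitude-critical work.
* The analytic forward model is a single sphere; realistic-geometry studies
  should import BEM lead fields via the HDF5 container.
* MNI reporting applies a user-supplied affine only; no registration is
  performed.
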