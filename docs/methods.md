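# Methods

`patternlab` simulates and analyses two reaction–diffusion pattern-forming
systems on periodic (toroidal) grids — the Brusselator chemical model and a
mean-field model of the cerebral cortex with gap-junction diffusion — and
provides the supporting theory: linear stability analysis (LSA) with
instability classification and critical-parameter bisection, Turing-mode
amplitude equations for the Brusselator, and spectral pattern
characterisation.  The van der Pol oscillator is included as the integrator
verification problem.  This note records the models, the numerical choices,
and what the shipped tests do and do not demonstrate.

## Spatial discretisation

Space is a uniform 1-D ring or 2-D torus with spacing `h` (cm).  The
Laplacian is the second-difference stencil `[1, -2, 1]/h²` (1-D) or the
five-point cross (2-D), applied as a circular convolution so edges wrap.
`periodic_convolve` implements wrap-pad followed by a "valid" convolution;
`laplacian` uses an equivalent cyclic-shift path (identical to machine
precision, asserted in the tests) because it is several times faster inside
the integrator loop.  On grid plane waves the operator acts with the exact
circulant eigenvalue `-(2 - 2cos qh)/h²` per axis; the suite checks this
identity, linearity, discrete conservation (zero column sums) and
translation equivariance.  Axis 0 is x, axis 1 is y; all shipped
configurations use square grids.

## Time stepping

Fixed-step explicit Euler and classical RK4 are provided, plus an adaptive
embedded RK4(5) wrapper over `scipy.integrate.solve_ivp`.  Stochastic
forcing is injected only by the fixed-step driver in the Euler–Maruyama
convention — per step each driven component receives
`amplitude · √dt · scale · N(0,1)`, independent across grid nodes and steps
(delta-correlated noise) — so RHS callables stay deterministic.  Adaptive
stepping with noise is refused: step-size control under white noise is
ill-defined.  A "kick" mode applies the same perturbation on the first step
only and nothing afterwards.  Non-finite states abort immediately with the
offending component named, since an explicit scheme that exceeds its
stability limit diverges quickly and silently otherwise.

Two independent RK4 implementations (the generic driver and a hand-written
reference loop in the tests) agree to ≤ 1e-10 on the van der Pol problem
over 20 s, and fixed-step RK4 agrees with the adaptive integrator to 1e-8
— the package's solver cross-validation.

## Brusselator

Kinetics `dX/dt = A − (B+1)X + X²Y`, `dY/dt = BX − X²Y`, with diffusion
`D_X, D_Y`; homogeneous state `(A, B/A)`.  Closed-form thresholds (used as
test oracles against the numeric bisection): Hopf at `B = 1 + A²`, Turing
at `B = (1 + A√(D_X/D_Y))²` with critical wavenumber `q_c² = A/√(D_X D_Y)`.
Negative concentrations are not clipped.

## Mean-field cortical model

Two neural populations (excitatory e, inhibitory i) interact through
chemical synapses and gap junctions on a 2-D cortical sheet.  Long-range
excitatory flux obeys a damped wave equation with axonal speed
`v = 140 cm/s` and inverse length scale `Λ = 4 cm⁻¹`; dendrites filter
input flux with the alpha response `H(t) = γ² t e^(−γt)` (peak `1/γ`,
implemented as the critically damped second-order ODE); soma voltages relax
with time constant `τ = 0.04 s` toward rest plus reversal-weighted synaptic
input plus gap-junction voltage diffusion (`D₁ = D₂/100` between e pairs,
`D₂` between i pairs).  Firing rates follow the sigmoid
`Q = Q_max / (1 + exp(−C(V−θ)/σ))`; synaptic weights are the linear
reversal-potential factors `ψ_ab = (V_a^rev − V_b)/(V_a^rev − V_b^rest)`,
normalised to 1 at rest.  The full state is 14 fields (2 wave fluxes and
their rates, 4 dendritic fluxes and their rates, 2 voltages).

The subcortical drive is a uniform excitatory tone `s·⟨φ^sc⟩` entering the
e→b dendrite equations, with optional Gaussian white-noise fluctuations
scaled by `√(s⟨φ^sc⟩)` (a linear-scaling variant is available by
configuration; fluctuation statistics only shift the effective noise
amplitude, which is a free small parameter).

Three model choices are left open by the published parameter table and are
exposed as configuration switches:

* sigmoid slope constant `C`: `π/√3` (default, the model lineage's value)
  or `π/3`;
* whether the resting-level offset `ΔV^rest` (1.5 mV for e, 0 for i)
  enters the soma relaxation target, the ψ normalisation, or both;
* the subcortical scale factor `s` (no published value; 1 by default).

### Reference configuration

The published working point of the mixed Turing–Hopf ("beating") regime is
characterised by three critical values: Hopf-critical `γ_i ≈ 30.94 s⁻¹`,
Hopf frequency `≈ 0.95 Hz` at `γ_i = 29.45 s⁻¹`, and Turing-critical
`D₂ ≈ 0.9066 cm²` at the same `γ_i`.  `patternlab.reference` sweeps the
open switches, the steady-state branch and `s`, scores each combination by
the summed relative error against those three values, and requires
consistency with the published regime (an excited q=0 oscillation at
`γ_i = 29.45` and a Turing onset below `D₂ = 1 cm²`).  The sweep is
recomputed at run time.

Its outcome: `C = π/√3`, offset applied to the soma rest level, ψ
normalised at the plain rest level, high-firing branch (`V_e* ≈ −57.7 mV`),
`s ≈ 1.09`.  At that point the Hopf frequency comes out `0.948 Hz`
(within 0.3 %) and the Turing-critical `D₂` at `0.867 cm²` (within ~4 %).
No swept combination reproduces `30.94 s⁻¹` as the `α(0) = 0` crossing —
the model built from the published equations places that crossing near
`62 s⁻¹` on the matching branch, and between 23 and 65 s⁻¹ elsewhere —
which the sweep records as an open mismatch rather than hiding; the
corresponding acceptance check is expected to fail and says so.  A
plausible cause is an unpublished detail of the original implementation
(the printed critical values were produced by the authors' own code base,
which this package does not have access to); the two quantities that are
reproduced are exactly those that pin the beating regime used by the
simulations.

### Numerical stability of cortical runs

The published fixed Euler step of `0.8 × 10⁻³ s` is outside the explicit
Euler stability region for the shortest resolved wave modes on the shipped
grids (`|1 + λ dt| > 1` for `λ = −vΛ ± i v q` at `q` near `π/h`); the
published 2-D runs were integrated with an adaptive solver.  The
package therefore keeps the 0.8 ms step but uses RK4 (whose stability
region covers those eigenvalues) for fixed-step cortical simulations;
explicit Euler remains available and stable at `dt ≲ 0.4 ms` on the
60×60 / 20-cm grid.

## Linear stability analysis

Homogeneous steady states: Brusselator closed-form; cortical by
multi-start Newton iteration of the two reduced soma equations over a
voltage lattice (`[−90, −40] mV`, 8×8 starts), deduplicated at 1e-6 and
polished to residuals ≤ 1e-10 (scaled by component magnitude + 1).  The
model family is multistable; all branches are returned and analyses are
reported per branch (the CLI defaults to the branch nearest −64 mV).

Linearisation replaces the Laplacian by `−q²` (continuous convention,
matching the theory; the discrete circulant symbol is available for
reconciling coarse-grid simulations).  The dominant eigenvalue is the one
with the largest real part, ties broken toward larger |ω|; conjugate pairs
are collapsed to ω ≥ 0.  Instability classes over a dispersion curve:
Hopf (excited oscillation at q = 0), Turing (excited stationary mode at
finite q, stable q = 0), Turing–Hopf (both), wave (oscillatory growth
peaking at finite q), else stable; thresholds `tol_ω = 1e-6 rad/s`,
`tol_α = 1e-8 s⁻¹`.  "Stationary" modes for the Turing maximum are
eigenvalues with |ω| < 1e-2 rad/s — well below every oscillatory branch of
either model but tolerant of numerical imaginary dust.

Critical parameters are found by Brentq bisection of the monitored growth
rate (`α(0)` for Hopf, the stationary finite-q maximum for Turing) with
the steady state re-solved at each trial; the finite-q maximum is refined
continuously around the best grid point, which makes the Brusselator
bisection agree with the closed forms to 1e-6 relative.

## Amplitude equations (Brusselator Turing mode)

Near the Turing onset the pattern is carried by three wavevector triads at
120°; their complex amplitudes obey
`dZ₁/dt = μZ₁ + v Z̄₂Z̄₃ − g|Z₁|²Z₁ − h(|Z₂|²+|Z₃|²)Z₁` (cyclic), with
`μ = (B−B_c)/B_c`.  Conventions adopted here, validated behaviourally:
`η = √(D_X/D_Y)` — this (not the bare ratio) makes `B_c = (1+Aη)²` agree
with the LSA threshold, which the code asserts at 1e-6 relative — and,
writing `e = Aη`,

```
v(μ) = 2(1−e)/(A(1+e)) + 2μ/A
g    = [38e + 5e² − 8 − 8e³] / [9A³η(1+e)]
h    = [ 5e + 7e² − 3 − 3e³] / [ A³η(1+e)]
```

The μ-dependence of the quadratic coefficient is essential: `v` changes
sign at `μ_p = (e−1)/(e+1)`, which is what makes the hexagon class
reentrant (total phase π below `μ_p`, honeycombs `H_π`; total phase 0
above, `H_0`).  Stationary solutions are stripes `(√(μ/g), 0, 0)` and
equal-amplitude hexagons `(±r, r, r)` with `(g+2h)r² ∓ vr − μ = 0`; each
is verified to zero the amplitude flow to 1e-12.  Stability is decided
numerically — central finite differences (step 1e-7) of the
6-real-dimensional flow, excluding the neutral phase modes by count (one
for stripes, two for hexagons), stable iff all remaining real parts are
below 1e-8 — rather than by literature closed-form boundaries, which makes
the result robust to any residual coefficient-transcription risk.  At
`A = 5, D_X = 5, D_Y = 40` this reproduces the published five-point mode
map (μ = 0.0495 → H_π only; 0.1100 → stripes + H_π; 0.3994 → stripes
only; 0.7000 → stripes + H_0; 1.4802 → H_0 only) and the boundary
ordering `μ_s⁻ < μ_h⁻ < μ_p < μ_h⁺ < μ_s⁺`.

## Spectral pattern analysis

* Spatial spectra: mean-subtracted periodogram over torus wavenumbers,
  radially binned at the fundamental `2π/(Nh)`; total binned power equals
  the spatial variance.
* Angular fold scores: annulus power around the dominant wavenumber
  resolved in orientation (mod π).  Both scores are baseline-corrected
  against the isotropic expectation of their 20°-half-width windows, so
  featureless textures score ≈ 0: `two_fold` is the excess concentration
  of one orientation window (≈1 for a plane wave), `six_fold` is three
  times the smallest fraction of the best 60°-spaced window triple (≈1
  for three balanced waves at 120°).  The window width and the correction
  were calibrated on synthetic plane-wave/hexagon fields and isotropic
  noise; simulated patterns score lower than ideal fields because domains
  and defects spread the annulus power (a perfect hexagonal lattice is
  also incommensurate with a square torus).
* Temporal spectra: Hann-windowed periodogram (boxcar available, for which
  total power equals variance exactly); peaks are local maxima with
  prominence ≥ 5 % of the maximum.
* Beat frequency: both the difference of the two strongest carrier peaks
  and the dominant spectral peak of the analytic-signal (Hilbert)
  envelope are reported with the record's bin resolution; the two should
  agree within a bin for a clean beat.  The envelope search is restricted
  below half the lower carrier frequency — an anharmonic carrier leaks its
  own frequency into the Hilbert envelope otherwise — a choice validated
  on synthetic two-tone and amplitude-modulated signals.
* The leading 20 % of every simulated record is discarded as transient
  before spectral analysis.

## Synthetic-data / simulation conditions

There is no external data; all inputs are parameter sets printed in the
sources plus seeded perturbations.  Shipped study conditions: Brusselator
1-D regimes on 60 points at 1 cm (oscillatory: A=2.5, B=9, D_X=7, D_Y=10;
stationary: A=2, B=4.8, D_X=2, D_Y=10; 30 s); 2-D mode-map runs at
A=5, D_X=5, D_Y=40 with `B = B_c(1+μ)`; the cortical Turing labyrinth
(D₂ = 1 cm², γ_i = 50 s⁻¹, low-firing branch) and the scaled beating run
(60×60 nodes over 20 cm, 150 s at dt = 0.8 ms, γ_i = 29.45 s⁻¹,
D₂ = 1 cm², one-off seeded kick, single-pixel probe at (1, 30)).  The
2-D mode-map tests run on 40×40 at 1 cm for a few hundred seconds —
large enough for several pattern wavelengths (λ ≈ 10.6 cm), small enough
that one orientation domain dominates within the simulated time;
multi-domain labyrinths on larger grids depress the fold scores without
changing the mode physics.  These scaled conditions demonstrate mode
selection and beating qualitatively and quantitatively at the recorded
working point; they do not reproduce the original 100×100 / 400-s runs,
and the beat-frequency comparison inherits the ~0.007 Hz resolution of a
150-s record.

### Beating-regime outcome

Because the reconstructed model's own Hopf crossing sits far above the
prescribed `γ_i = 29.45 s⁻¹`, the q=0 oscillation at the beating working
point is deeply supercritical (`α(0) ≈ +13 s⁻¹`) rather than weakly
excited.  The scaled 150-s beating simulation consequently settles into a
strongly anharmonic quasi-periodic state — a carrier cluster near
1.3–1.4 Hz with a dominant second harmonic near 2.7 Hz and slow
modulation components below 0.2 Hz — instead of a clean two-tone beat at
the published 0.80/0.95 Hz with a 0.15 Hz envelope.  The beat-frequency
acceptance checks report the computed values and fail at the published
numbers; this mismatch is inherited from the Hopf-critical-γ_i
discrepancy above, not from the estimators (which are validated on
synthetic signals).

## Known limitations

* The cortical Hopf-critical γ_i mismatch described above, and the
  beating-regime consequence just described.
* Explicit schemes only; no implicit/stiff or operator-splitting paths.
* LSA uses the torus plane-wave basis; no finite-size eigenmode analysis,
  no noise-driven spectra, no amplitude equations for the cortical model
  or for coupled Turing–Hopf interactions.
* Boundaries are periodic only.
* Stripe-order measurements on finite tori are seed-dependent when several
  orientation domains nucleate; the shipped conditions use a fixed seed
  and a domain size chosen for single-domain selection.
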