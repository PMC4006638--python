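# patternlab

Simulation and bifurcation analysis of reaction–diffusion pattern
formation on periodic grids, for two systems:

* the **Brusselator**, the minimal activator–inhibitor chemical model
  (`dX/dt = A − (B+1)X + X²Y + D_X∇²X`,
  `dY/dt = BX − X²Y + D_Y∇²Y`), and
* a **mean-field cortical model** in which excitatory and inhibitory
  neural populations interact through chemical synapses (damped-wave
  axonal flux, alpha-function dendrites, sigmoidal firing rates) and
  through electrical gap junctions modelled as voltage diffusion, whose
  inhibitory strength `D₂` drives a Turing instability and whose
  inhibitory dendritic rate constant `γ_i` controls a slow Hopf
  oscillation.

The package is aimed at pattern-dynamics researchers who want, in one
place: toroidal finite-difference Laplacians, fixed-step (Euler/RK4) and
adaptive RK45 integration with seeded stochastic forcing, homogeneous
steady states and Fourier-space linear stability analysis
(`σ_q = α(q) + iω(q)`, with Turing / Hopf / Turing–Hopf / wave
classification and critical-parameter bisection), the Turing-mode
amplitude equations of the Brusselator
(`∂t Z₁ = μZ₁ + v Z̄₂Z̄₃ − g|Z₁|²Z₁ − h(|Z₂|²+|Z₃|²)Z₁`, with stripe and
hexagon branch stability), and spectral pattern characterisation (radial
and angular spatial spectra, temporal periodograms, beat and envelope
frequencies).  The scientific background and every numerical convention
are documented in [docs/methods.md](docs/methods.md).

## Worked example

Classify the 1-D Brusselator at `A=2, B=4.8, D_X=2, D_Y=10`:

```sh
patternlab lsa --config src/patternlab/configs/brusselator_turing_1d.toml
```

```json
{
  "model": "brusselator",
  "steady_state": {"X": 2.0, "Y": 2.4},
  "residual": 0.0,
  "label": "Turing",
  "q_critical_rad_per_cm": 0.70283294797522,
  "frequency_hz": 0.0
}
```

The steady state `(A, B/A) = (2, 2.4)` loses stability to a stationary
mode at wavenumber `q* ≈ 0.70 rad/cm` (wavelength ≈ 8.9 cm) with zero
frequency — a Turing instability; `patternlab run` on the same
configuration freezes into a stationary stripe profile with that
wavelength.  The same library calls are available in Python
(`patternlab.linstab.dispersion`, `classify`, `critical_value`).

Mode selection for the 2-D Brusselator at `A=5, D_X=5, D_Y=40`:

```sh
patternlab amplitude --config src/patternlab/configs/brusselator_stripes_2d.toml \
    --mu 0.0495 --mu 0.3994 --mu 1.4802
```

reports `g = 0.0278`, `h = 0.0911`, `B_c = 7.6605`, and the stable mode
at each distance-to-threshold `μ = (B−B_c)/B_c`: honeycomb hexagons
(`H_π`) only at μ = 0.0495, stripes only at μ = 0.3994, and reentrant
hexagons (`H_0`) only at μ = 1.4802 — the hexagon → stripe → reentrant
hexagon sequence.  Two-dimensional simulations
(`patternlab run --config .../brusselator_hexagons_2d.toml`) develop the
corresponding six-fold or two-fold angular spectra.

Other entry points: `patternlab run` (simulate + analyse, HDF5 + JSON
output bundle) and `patternlab analyze` (re-analyse a saved trajectory).
Example configurations for every shipped experiment are packaged under
`src/patternlab/configs/`.

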