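# Methods

## The constitutive model

The vessel wall is modeled as an incompressible hyperelastic cylindrical
membrane under a constant axial stretch λz, loaded by a quasi-static
luminal pressure. The stored energy is the four-fiber-family (4FF) form
widely used for arterial tissue: an isotropic neo-Hookean matrix term of
modulus `c` (kPa) representing elastin and amorphous constituents, plus
four exponential fiber families — axial (0°), circumferential (90°) and a
symmetric diagonal pair at ±α₀ — each with a modulus `c1` (kPa) and a
dimensionless stiffening exponent `c2`. The diagonal pair shares one
(c1, c2), leaving seven material constants plus the angle. A family with
`c2 = 0` degenerates continuously to the quadratic energy `(c1/4)(λₖ²−1)²`;
the stress expression is continuous there without special-casing.

Kinematics are exact incompressible cylinder kinematics referenced to the
mid-wall: the circumferential stretch is λθ = r_m/R_m with
R_m = A + H/2, and the deformed inner/outer radii follow from conservation
of wall cross-section, `(b² − a²) λz = B² − A²` (held to 1e−9 relative in
tests). Equilibrium uses the thin-wall (Laplace) closure `P = σθ h/a`,
with σθ = λθ ∂Ŵ/∂λθ evaluated analytically from the reduced
(incompressibility-eliminated) energy. A single equilibrium operation
isolates this closure so a thick-wall variant could be swapped in. The
choice of a membrane treatment matches the analysis target: one
circumferential stress/stretch pair per loaded state.

Units: pressures are mmHg at every public interface, stresses and moduli
kPa internally, with the conversion fixed at 0.133322 kPa/mmHg. The
pressure–diameter map inverts the equilibrium curve by bracketed
root-finding on λθ ∈ [~kinematic minimum, 2.5], tolerance 1e−10 on λθ,
giving round-trip residuals below 1e−6 mmHg.

Not modeled: residual stress/opening angle, active smooth-muscle tone,
viscoelasticity, axial force balance, damage accumulation before rupture.
λz defaults to 1.0 and is configurable; no specific in-situ value is
assumed.

## Pressure protocols

Two drives mirror what a myography rig applies:

* **Pulsatile** — smoothed rectangular pulses on a diastolic baseline
  (default 80/120 mmHg): within each cycle of period 60/beat_rate the
  systolic window occupies the final `systolic_fraction` (default 0.35, a
  typical arterial systole fraction; the rig's occlusion duty cycle is not
  otherwise constrained) and is shaped as a Tukey window —
  raised-cosine rise/fall over `rise_fraction` (default 0.5) of the window
  with a flat top. Cycles start at t = 0 on the baseline. Placing the
  systolic window at the *end* of the cycle makes the number of complete
  pulses in a record of length T exactly `floor(T × beat_rate/60)`: a
  trailing partial cycle contributes baseline only, never a truncated
  pulse counted as complete. Setpoints are taken literally; real hardware
  overshoot/undershoot is not modeled.
* **Stepwise** — a click-quantized staircase: constant holds of
  `hold_time` (default 20 s) at `start + k·increment`, ending at the first
  level ≥ `max_pressure`. The default increment, 64.37 mmHg, is the
  per-click pressure step of a 3 mL syringe ratchet; 7.62 mmHg corresponds
  to a 1 mL syringe.

## Synthetic recordings and their limits

`simulate_recording` maps the drive through the equilibrium model sample
by sample (quasi-static: the wall is assumed to equilibrate within one
sample) and adds independent, homoscedastic Gaussian noise to the
recorded OD, ID and pressure channels. There is no temporal
autocorrelation, no vasomotion, no drift, no frame-rate jitter — passing
tests on this twin demonstrates the analyzers' correctness on their
stated assumptions, not robustness to every artifact of real video
myography. Inner diameter is derived from the outer through the
incompressible kinematics, never simulated independently.

Burst experiments apply the staircase until the noiseless wall stress
first reaches the failure stress σ_fail; rupture is instantaneous and
manifests at the following sample (the triggering level is momentarily
recorded, then pressure collapses to 0 and diameters become absent). The
burst pressure recovered by the analysis is therefore the pressure of the
level that caused failure, matching the convention "maximum recorded
pressure before rupture".

Dose–response series follow a Hill curve in concentration with a signed
maximal effect (`emax_fraction` of baseline diameter), the standard
pharmacological response model; the generator exists to exercise the
min–max normalization, not to model receptor kinetics.

Rendered frames are a horizontal two-band vessel (dark walls, bright
lumen and background) with additive Gaussian pixel noise — sufficient for
validating scanline tracking geometry and noise robustness, but with none
of the focus gradients, illumination drift or wall texture of real
microscopy.

## Shipped presets

Two parameter presets bracket the phenotypes the analysis is meant to
separate, on a carotid-like unloaded geometry (A = 200 μm, H = 30 μm,
λz = 1):

| preset | c | c1 (ax/circ/diag) | c2 | behaviour |
|---|---|---|---|---|
| `compliant` | 30 | 20/20/14 | 0.8 | elastin-dominated toe, P–D sweep plateaus ≈ 198 mmHg |
| `stiff` | 30 | 60/60/42 | 16 | early collagen engagement, plateaus ≈ 125 mmHg |

These values are package calibration choices (selected once, by grid
search against the plateau targets ~200 vs ~125 mmHg at slope fraction
0.1), not measurements of any tissue. Under the 80/120 mmHg drive they
give per-pulse ΔOD ≈ 31 vs 7 μm and dynamic compliance ordered
compliant > stiff, the qualitative normotensive-vs-hypertensive signature.

## Analyzer choices

* **Peak detection.** Peaks are prominence-filtered local maxima with a
  minimum separation (default 0.3 s, supporting rates to 200/min). The
  default prominence is 3 × 1.4826 × MAD of the median-subtracted trace,
  floored at 10% and capped at 50% of the peak-to-peak range: the floor
  handles clean pulse trains (near-zero MAD), the cap handles
  sinusoid-like traces whose MAD-based threshold would exceed the peak
  prominence itself. A pulse is *complete* only if the trace descends at
  least half the prominence on both sides of the peak within the record,
  so edge-truncated pulses are not counted. The baseline D_min is a single
  global value — the median of inter-peak minima — rather than a per-pulse
  trough; per-pulse ΔD and Dc use it.
* **Pulse frequency.** Amplitude spectrum of the mean-subtracted signal;
  among spectral local maxima within 6 dB of the global maximum the lowest
  frequency wins. This fundamental rule prevents harmonic capture for
  square-ish pulses, whose second harmonic can rival the fundamental.
  Resolution is one FFT bin (1/duration Hz).
* **Compliance pairing.** (Pmax, Pmin) come from running the same peak
  detector on the pressure channel and taking the median peak pressure
  and the pressure baseline — one pulse-pressure pair per recording, since
  Dc depends only on the difference.
* **Plateau pressure.** Central-difference slope dOD/dP; the plateau is
  the lowest pressure from which the slope stays below `slope_fraction`
  (default 0.1) of its maximum for all higher pressures; `None` when the
  curve never flattens.
* **Tracking.** Per scanline: box smoothing (default window 5 px), first
  differences, the two strongest negative and two strongest positive
  gradient extrema with greedy non-maximum suppression (minimum separation
  one smoothing window) and an enforced −/+/−/+ top-to-bottom sign
  pattern; sub-pixel refinement by parabolic fit, with plateau centering
  for the exactly flat gradient runs a box filter produces on ideal
  steps. Frame diameters are medians across scanlines after MAD-based
  outlier rejection (factor 3.5); a frame fails if more than half its
  scanlines do. Each frame is tracked independently — no temporal
  smoothing. Calibration (μm/px) is a required user input.
* **Fitting.** Least squares on outer-diameter residuals (OD is the
  measured quantity at prescribed pressure), in log10 parameter space with
  bounds c, c1 ∈ [1e−3, 1e3] kPa and c2 ∈ [1e−3, 50]; the diagonal pair
  shares parameters and the fiber angle is fixed (default 45°) to curb
  non-identifiability on single-protocol data. Multistart (default 8)
  perturbs the initial guess log-uniformly within ±0.5 decades, seeded.
  Pressures a trial parameter set cannot reach within the stretch bracket
  map to the bracket-edge diameter, a finite smooth penalty. 4FF
  parameters are *not* identifiable from one inflation curve: the
  meaningful fit outputs are the reproduced curve and the stiffness
  evaluated on it, which the tests check to 0.5 μm and 5% respectively —
  raw parameter equality is deliberately not asserted.
* **Linearized stiffness.** dσθ/dλθ at the loaded equilibrium state with
  λz fixed, evaluated analytically (verified against central differences
  at relative step 1e−5); defaults to 20, 90 and 120 mmHg. The
  small-on-large stiffness tensor component is a documented alternative
  that could sit behind the same interface; the simple incremental
  modulus is used here.

## Problem sizes

The test suite and acceptance script run at desk scale by design:
one-minute recordings at 100 Hz (6 000 samples), 12-point fitting sweeps
with 2-start multistart in tests (8 is the library default), and
100-frame Monte-Carlo batches for tracking noise. These sizes were chosen
to make every statistical check stable at fixed seeds while keeping the
whole suite under half a minute of compute, and are stated here so larger
reruns can scale them up deliberately.

## Known limitations

* Membrane (thin-wall) equilibrium: no transmural stress distribution.
* Quasi-static response: inertia and viscoelastic lag are absent, so very
  fast drives are reproduced without the amplitude attenuation a real rig
  shows.
* The tracker is validated on synthetic frames only and assumes a roughly
  horizontal vessel spanning the frame.
* Rupture is a sharp stress threshold; real burst involves damage
  accumulation and flaw statistics.
* The noise model is white and Gaussian; correlated drift (temperature,
  focus) must be handled upstream.
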