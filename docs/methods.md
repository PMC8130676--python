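# Methods

This note documents the physical models, numerical choices and synthetic
study conditions behind `afsrheo`, and what the test suite does and does not
demonstrate about real instrument data.

## Medium properties

The suspension medium is parameterized as water. Air-saturated density and
isothermal compressibility are fourth-order polynomials in temperature
(valid 5–40 °C; the 0 °C endpoint is admitted with a warning because the
polynomial constant is the 0 °C value, which is useful in tests). Dynamic
viscosity follows a modified Andrade form, η[mPa·s] = exp(A + B/(C + T))
with A = −3.63148, B = 542.05 °C, C = 129.0 °C: this reproduces
≈1.006 mPa·s at 20 °C and 0.707 mPa·s at 36 °C, and through the
rectangular-channel relation τ_w = 6μQ/(h²w) it gives wall shear stresses
of 5.9 mPa at 1.66 μl·min⁻¹ and 106.1 mPa at 30 μl·min⁻¹ for the default
100 μm × 2 mm chamber at the 36 °C set point. Serum-containing culture
media raise viscosity by only a few percent, handled by a multiplicative
`viscosity_factor` (default 1.0). Speed of sound uses Newton–Laplace,
c = 1/√(κρ). Compressibility-corrected density is
ρ_AS(T)·[1 + κ(T)(P − 101.325 kPa)] with pressure in kPa.

## Wall drag

A sphere of radius R at center distance L = z + R from a plane wall feels
drag 6πRvηλ. For perpendicular motion (the AFS geometry) λ is Brenner's
exact bipolar-coordinate series with cosh α = L/R, truncated at 100 terms
by default (truncating at 100 vs 1000 terms changes λ by < 10⁻⁶ for
L/R ≥ 1.1). The series is evaluated in an exponentially rescaled form that
is stable at any L/R; the free-space limit λ → 1 and the lubrication
asymptote λ ≈ R/gap are both test-pinned. Faxén's fifth-order parallel-wall
polynomial is provided for comparison only — it is the optical-tweezers
correction and under-corrects perpendicular motion, which is exactly what
the fall-validation test demonstrates. λ diverges at contact, so the motion
integrator imposes a minimum surface clearance z_min = 10 nm (configurable)
below which the bead is "landed" and held.

## Bead dynamics and calibration

The bead is overdamped (Reynolds and Stokes numbers are vanishingly small
at these scales), so inertia is dropped:
dz/dt = (F_ac(z) − F_grav)/(6πRη λ(z)), with the acoustic profile
F_ac(z) = f₀k_p sin(2(k_p z + φ_p)) and buoyancy-corrected weight
(ρ_p − ρ_m)(4/3)πR³g. Integration uses an adaptive Runge–Kutta scheme
(rtol 10⁻⁸) with dense output at the 59 Hz camera rate; the wall-drag
factor, the cost center of the right-hand side, is tabulated on a log-z
grid (512 points, cached per drag specification) and interpolated, which
is accurate to ~10⁻⁶ relative and keeps a single calibration fit in the
seconds range. A fixed-step RK4 reference in the test suite confirms
sub-nanometer agreement.

The calibration fit minimizes Σ(z_num − z_meas)² over (f₀, k_p, φ_p) with
a trust-region least-squares solver, multi-started over
φ_p ∈ {0.2, 0.8, 1.4} rad to escape the sine's periodic local minima. Two
numerical points matter here:

- the release height enters the stiff near-wall dynamics strongly while the
  first tracked sample carries noise, so z₀ is fitted as a bounded nuisance
  parameter instead of being read off the trace — without this, 20 nm of
  tracking noise propagates into tens of percent of f₀ error;
- finite-difference steps are set to 10⁻⁴ relative so the Jacobian is
  evaluated above the adaptive integrator's noise floor.

Identifiability: the pull trace must sample a nontrivial portion of the
force profile; traces spanning less than roughly a third of the distance
to the node leave (f₀, k_p, φ_p) nearly degenerate (only the product near
the surface is constrained). Quality control rejects beads with total
displacement < 0.5 μm ("stuck"), start height > 1 μm (pre-detached) or
pull-fit R² < 0.95; thresholds are configurable and intentionally
conservative.

The fall after drive-off is predicted with zero free parameters from the
known effective gravity; its R² is the model-selection statistic. A control
analysis refits the bead density from the fall and should return the
literature polystyrene value (1050 kg·m⁻³) when the drag model is right.

## Conversion factor and spatial map

Force is quadratic in drive amplitude, F = cV². c is obtained by a
one-parameter least squares through the origin on forces evaluated at the
z = 1 μm reference height (configurable) from at least two amplitudes.
Maps merge QC-passing beads within 5 μm (one bead radius; greedy in input
order) by averaging position and c, and are queried by linear interpolation
on a Delaunay triangulation with nearest-neighbor fallback (and a warning)
outside the hull. The merge radius and interpolation mode are free choices;
the data do not pin them.

## mOsc estimation

The drive is F(t) = F_offset + ΣᵢAᵢ sin(2πfᵢt) with defaults 0.1/0.5/1.5 Hz.
Per-component amplitudes of 50 pN on a 200 pN offset keep the force
strictly positive and sit in the middle of the instrument's pN–nN range;
they give window-level displacement SNR of roughly 20–60 per bead at 20 nm
RMS tracking noise. Windows of 500 s shifted by 100 s hold exactly
50/250/750 cycles of the three components, so the discrete regressors are
mutually orthogonal.

Demodulation is harmonic regression: each window's force and position are
projected onto [1, t, cos ωᵢt, sin ωᵢt] by least squares, sharing one
precomputed pseudo-inverse across windows and beads (all windows share the
same relative time grid). On integer-cycle windows this is identical to
single-bin Fourier projection after perfect detrending, is exact to
floating point for noiseless drive-bin signals, and absorbs offset and
linear drift without leaking them into the drive bins — a plain
detrend-then-FFT slightly biases the lowest bin through the trend's
spectral tail, which is why regression was chosen.

The modulus follows from G\*(ω) = F̃(ω)/(6πR f(θ) z̃(ω)). The immersion
factor is f(θ) = 1 − cos θ, the normalized immersion depth of the contact
cap: smooth, strictly increasing, below 1 for partial immersion on
(10°, 90°), and exactly 1 at θ = 90° so the estimate reduces to the
generalized Stokes–Einstein relation for a fully immersed bead. This
specific functional form is a package design choice satisfying those
constraints; since the synthetic generator and the estimator share it, all
round-trip results are independent of the choice, but *absolute* moduli
from real data scale with it, and users with their own immersion model can
swap the function. The default θ = 28.73° is the measured population mean
for 10 μm beads on an endothelial monolayer (θ = arcsin(d/2R) from the
contact-circle diameter d).

Points with negative G′ or G″ (non-passive, i.e. noise-dominated) are
flagged invalid rather than dropped; aggregation across beads takes the
mean and SEM of G′ and G″ per (window, frequency) over valid points, with
|G| and the phase δ derived from the aggregated components and their errors
by first-order propagation.

## Viscoelastic models

The springpot (SFE) is G\* = G̃(iωt₀)^a with t₀ = 1 s fixed; it is fitted
separately to G′(f) and G″(f) on linear scale (log-log seeded), and fits
are conventionally retained at R² > 0.9. The generalized Kelvin–Voigt model
is two springpots in parallel,

    G*(ω) = G₀[(iωt₀)^α + (iωt₀)^β],  t₀ = 1 s,  0 ≤ β ≤ α ≤ 1,

fitted jointly to the concatenated (G′, G″) vector by bounded least squares
with three starts; the two springpots are exchange-symmetric, so results
are reported with α ≥ β. Residuals are unweighted on linear scale by
default (log-scale residuals are a config option; nothing in the data fixes
the residual convention). R² is computed over the concatenated vector and
fits below 0.7 are flagged, not dropped. The storage/loss crossover has the
closed form

    ω_x = [(cos(πβ/2) − sin(πβ/2)) / (sin(πα/2) − cos(πα/2))]^(1/(α−β)),

defined exactly when α > 1/2 > β; it is verified against a bisection
root-finder to 10⁻⁹ relative over an (α, β) grid. At the mean monolayer
exponents (α = 0.850, β = 0.058) it gives f_x = ω_x/2π ≈ 0.2055 Hz;
evaluating the closed form at mean parameters differs from averaging
per-window crossovers by ~1% (Jensen gap). For β ≈ 0 the low-frequency
modulus is the steady-state elasticity and E = 2G₀(1 + ν) with ν = 0.5 by
default. Bootstrap confidence intervals resample *beads* with replacement
(n_boot = 100 by default), refit the aggregated spectrum, and report twice
the parameter standard deviation; the RNG seed is mandatory, so reruns are
bit-identical. A generalized-Maxwell entry exists only as a named stub.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of (configuration, seed). The mOsc
generator synthesizes each bead's response per frequency through the linear
transfer function z̃ = F̃/(6πR f(θ) G\*) — the exact inverse of the
estimator — plus a constant baseline, linear drift (0.2 nm/s default),
and Gaussian tracking noise (20 nm RMS default, the typical z-tracking
precision of the camera/LUT method). Per-bead stiffness heterogeneity is
log-normal with 10% CV (bead-to-bead spread on real monolayers is not well
quantified; this value makes SEMs and bootstrap CIs non-degenerate).
Default experiment shape: 15 beads (the typical per-experiment throughput
of the field of view), 3700 s at 59 Hz. Time-varying stiffness (a drug
effect and wash-out) is a piecewise-constant factor on G₀ applied
adiabatically — valid because the schedule changes over hundreds of
seconds while the fastest drive period is 0.67 s.

Deliberately **not** emulated: Brownian motion during calibration pulls
(noise is purely additive measurement noise), lateral acoustic forces,
nonlinear or amplitude-dependent cell response, window-to-window
physiological fluctuations, temperature drift of the resonance, and any
imaging/tracking artifacts. Passing round-trip tests therefore shows the
analysis chain is self-consistent and unbiased under its own model
assumptions at realistic noise; it does not validate the immersion model
or the linear-response assumption against real cells.

## Problem sizes used in checks

The recovery study behind the acceptance script uses 20 seeded replicates
of the default experiment (15 beads × 3700 s, 33 windows each) and reports
the median across replicates of the window-averaged G₀ and α; with the
default noise this recovers the generating values to within a few percent.
The calibration Monte-Carlo uses 50 seeded repetitions of a single 1 s pull
at 20 nm noise, recovering (f₀, k_p, φ_p) with median errors well under 5%.

## Known limitations

- Single-wall drag only; the top chamber wall (~100 μm away) is ignored,
  justified while beads stay within ~20 μm of the bottom surface.
- The force-profile model is the leading-order sinusoidal approximation;
  higher-order acoustic terms are not modeled.
- The immersion correction is a one-parameter geometric factor, not a full
  contact-mechanics solution; absolute moduli inherit its uncertainty.
- Frequencies are limited to below the camera Nyquist rate; the defaults
  assume 59 Hz sampling.
- The GKV fit uses three frequencies for three parameters plus scale; with
  fewer than two valid frequencies in a window the fit is skipped and
  flagged.
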