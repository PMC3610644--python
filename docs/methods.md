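# Methods

This note records the models implemented in `cwesr`, the assumptions they
make, the numerical choices behind the measurements, and the limits of what
the synthetic-data tests demonstrate.

## Spectral model

A CW-ESR spectrum is stored as a strictly increasing, uniformly spaced
field axis in Gauss with first-derivative intensity in arbitrary units
(`Spectrum`).  The sign convention is the standard CW display: the
low-field lobe of each resonance line is positive.  The number of spins is
proportional to the double integral — trapezoidal integration of the
derivative to absorption, then trapezoidal area — which is exact for
piecewise-linear data and needs no tuning.  `normalize_to_unit_spins`
rescales the double integral to 1; all cross-spectrum arithmetic
(comparison, unmixing, subtraction) happens between unit-spin spectra so
amplitudes read as spin fractions.

### Fast-motion triplet

In the motionally narrowed regime a nitroxide gives three lines at
B₀ − m·a_N for the ¹⁴N manifolds m = +1, 0, −1 (m = +1 at low field), each
a first-derivative Lorentzian with peak-to-peak width

    W(m) = W₀ + B·m + C·m².

Lines carry equal integrated intensity (equal manifold populations), so
peak-to-peak height scales as 1/W(m)².  Lorentzian shapes are the default
because the correlation-time analysis below assumes exactly that
height-width relation; a Gaussian option (`lineshape="gaussian"`) exists
for work where negligible far tails matter more (see *Area bookkeeping*).

The quadratic width coefficient C encodes the rotational correlation time:
substituting h₀/h_m = (W(m)/W₀)² into

    τ_C = k · W₀ · (√(h₀/h₊₁) + √(h₀/h₋₁) − 2)

collapses it to τ_C = 2·k·C, independent of W₀ and of the linear
coefficient B.  `c_coef_for_tau` inverts this to build spectra of known
τ_C.  The recovery loop is non-circular at the lineshape level: the
measurement works from detected extrema, heights and zero crossings of the
trace, never from the generative parameters.

### Ordered axial powder pattern

A membrane-embedded probe undergoing fast but orientationally restricted
motion is modelled as an axially averaged hyperfine pattern: absorption

    ∫₀^{π/2} sinθ Σ_m L(B − B₀ + m·A_eff(θ)) dθ,
    A_eff(θ) = √(A∥² cos²θ + A⊥² sin²θ),

differentiated in field, with L a Lorentzian of the intrinsic width.  The
orientation integral is evaluated by Gauss–Legendre quadrature on
u = cosθ (800 nodes by default; the integrand is smooth in u, so
convergence is spectral, and the m = 0 manifold is orientation-independent
and added as a single line).  g-anisotropy is neglected (one centre
field): at X-band the nitrogen hyperfine term dominates the outer
splitting the order-parameter analysis uses.  In the limit A∥ = A⊥ the
pattern collapses onto the isotropic triplet to machine precision, which
the suite checks for several parameter draws.

## Measurements and their numerics

**Line detection.**  Local extrema are found by prominence-filtered peak
picking.  For triplets the floor is 10% of the full intensity range: the
weakest physical line in the conditions studied stays above ~18%, while
Gaussian noise at SNR 50 stays near 1%.  For ordered spectra the floor is
0.5% because the outer wings are only ~1% of the dominant,
orientation-independent central line; noisy ordered spectra are instead
guarded by requiring the outer-wing amplitude to exceed 3× the noise sigma
estimated from the sweep edges.  Extremum positions and values are refined
by a least-squares parabola over ±2 samples.  Line centres are taken from
the linear-interpolated zero crossing between each maximum/minimum pair —
the zero crossing of a derivative Lorentzian is its resonance field
exactly, unlike the midpoint of the extrema.

**No smoothing by default.**  Smoothing biases peak-to-peak widths, so it
is opt-in: a quadratic Savitzky–Golay filter behind `smooth_window`
(5–11 points) for noisy traces.  At SNR 50 the ±2-sample parabola has
heavy-tailed single-draw errors (widths occasionally off by ~10%); with the
smoothing flag the mean width error over seeded draws stays under 5%, and
that ensemble statement is what the noisy-recovery tests assert.  Splitting
measurements (zero crossings) are far more robust: a_N errors stay below
1% per draw.

**Line-overlap bias (known, physical).**  Lorentzian tails of the m = ±1
lines overlap the central line.  Two consequences, both reproduced by a
brute-force fine-grid oracle and documented rather than corrected:
(1) the peak-to-peak width of the *composite* central line is narrower than
the isolated-line parameter — by 2.5% for 4 G lines separated by 14 G —
so width recovery is asserted against the composite (oracle) width at 1%
and against the generative parameter only at 3%; (2) the measured central
height is slightly depressed, driving the τ_C bracket to small negative
values (down to −0.016) on spectra with τ_C = 0.  The bracket therefore
clamps to zero above −0.05 and only raises below it, where the height
pattern genuinely contradicts the fast-motion regime.

**Hyperfine extrema.**  2A∥ is the distance from the outermost significant
low-field maximum to the outermost high-field minimum; 2A⊥ the distance
between the innermost significant extrema flanking the central line (the
derivative lobes of the perpendicular edges of the m = ±1 manifolds).
With a 0.4 G intrinsic width the outer extrema sit at ±A∥ to well under
0.1 G while the inner extrema are pulled inward by a fraction of the
linewidth; the net effect is a small positive S bias (~+0.004 under the
default conditions), within the ±0.03 recovery band.  No empirical
correction is applied to the raw inner splitting — published analyses
sometimes add a fixed offset to A⊥, and any such correction belongs in the
caller's hands, not silently in the measurement.  A
`min_anisotropy_G = 4 G` floor rejects quasi-isotropic spectra whose
"inner" and "outer" extrema are the same line a linewidth apart.

**Derived parameters.**  S = (A∥ − A⊥)/(Azz − (Axx+Ayy)/2) with the
rigid-limit tensor (6.0, 6.0, 32.0) G by default; the optional polarity
correction multiplies by the tensor-to-measured isotropic-coupling ratio
and defaults to off, with both forms logged at DEBUG on every call.
Values marginally outside [0, 1] are returned with a warning, never
clipped.  τ_C uses k = 6.5×10⁻¹⁰ s/G, configurable.  Percent changes are
reported as nearest-integer values (half away from zero) for narration,
with the exact value retained in machine-readable output.

## Alignment and unmixing

Cross-spectrum arithmetic first puts both spectra on one uniform grid over
their overlap (required to cover ≥80% of each sweep) and removes a field
offset by integer-step cross-correlation with parabolic refinement.  The
search window is ±5 G: free-vs-bound nitroxide centre shifts are
sub-Gauss, and a larger requirement indicates a data problem.  A
displacement beyond the window raises when the correlation peak hits the
window edge; a displacement far beyond it can alias onto a spurious
interior peak (triplet structure is quasi-periodic), which is a known
limitation of correlation alignment.

Two-component unmixing is non-negative least squares (`scipy.optimize.nnls`)
of the composite on unit-spin-normalized bases; fractions are the fitted
amplitudes renormalized to sum to 1, and a design condition number above
1e6 raises (collinear bases).  A per-component field shift (±2 G) is
optimized coordinate-wise by bounded scalar minimization of the NNLS
residual; the reported shift is the total (coarse pre-alignment + fine
search).  Exactly two components are supported — the spectra this targets
show at most two populations.  Subtraction of a known fraction f of a
unit-spin basis from a unit-spin composite leaves a double integral of
1 − f identically (linearity of the integral); the implementation verifies
this to 1e-6 and then renormalizes.

## Area bookkeeping and Lorentzian tails

On a finite sweep a truncated Lorentzian loses O(Γ/πL) of its area off
each end (Γ the half-width, L the distance to the sweep edge) — of order
1% on realistic spans.  Consequences: strict (1e-6) double-integral
conservation under linewidth changes holds only for the Gaussian option;
the Lorentzian default conserves area at the percent level on standard
spans and to ~1e-4 on wide (±100 G) sweeps, which is how the conservation
properties are tested.  Unit-spin normalization is unaffected (it
renormalizes whatever area is in the sweep).

## Synthetic-data conditions

The generator defaults emulate the X-band conditions of the motivating
study system: centre field 3350 G, a_N between 14.5 and 15.3 G,
W₀ = 1.4–1.5 G for mobile probes, 0.4–2 G intrinsic widths for ordered
ones, acquisition metadata 1.0 G modulation at 100 kHz over a 160 G sweep,
grids of 0.02 G step.  Recovery runs use τ_C targets {0.96, 1.12, 1.48} ns
and order-parameter targets {0.45, 0.51, 0.58, 0.60}; effective powder
splittings for an S target preserve the tensor's isotropic coupling
((A∥ + 2A⊥)/3 = 14.67 G), the appropriate constraint when probe polarity
matches the rigid-limit reference.  Noise is i.i.d. Gaussian per point
with SNR defined as max |signal| / σ; 100-kHz modulation-filter noise
correlation is not emulated.  Mixture compositions use a mobile triplet
plus a broad immobilized pattern (A∥ = 30 G, A⊥ = 8 G, width 2 G).

What passing tests do *not* show about real data: baseline drifts beyond
cubic, field-modulation distortion of lineshapes at large modulation
amplitude, slow-motion lineshapes between the two regimes (no
stochastic-Liouville solver here), g-anisotropy, or instrument phase
errors.  The recovery bands quoted above are for the emulated conditions.

## Problem sizes

Test and acceptance runs use spectra of 3–6 thousand points, 800-node
orientation quadrature, 20-draw unmixing ensembles and 5-draw noise
averages for reported recoveries — sizes at which every quoted tolerance
is comfortably resolved.
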