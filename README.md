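# cwesr

Empirical analysis of continuous-wave ESR (electron spin resonance) spectra
of nitroxide spin labels, with a lineshape simulator that provides exact
ground truth for every measurement routine.

## Who this is for

Membrane biophysics and site-directed spin labeling (SDSL) studies read
protein–membrane interactions off first-derivative nitroxide spectra: a
doxyl-stearic-acid probe (n-SASL) embedded in a micelle or bilayer reports
acyl-chain order and dynamics at depth *n*; an MTSSL-labelled cysteine (the
R1 side chain) reports backbone mobility and local polarity.  The raw data
are two-column traces (magnetic field in Gauss vs. derivative intensity),
and everything of scientific interest is a handful of empirical features:
line positions, peak-to-peak widths and heights, hyperfine extrema.  This
package measures those features and turns them into the standard derived
quantities, with a simulator in place of the (rarely deposited) instrument
traces.

## What it computes

For an **ordered** probe (e.g. 5-SASL), the order parameter from the outer
(2A∥) and inner (2A⊥) hyperfine splittings and the rigid-limit tensor
(Axx, Ayy, Azz) = (6.0, 6.0, 32.0) G:

    S = (A∥ − A⊥) / (Azz − (Axx + Ayy)/2)

with an optional polarity correction that multiplies by
[(Axx+Ayy+Azz)/3] / [(A∥ + 2A⊥)/3] (off by default; both forms logged).

For a **fast-tumbling** probe (e.g. 16-SASL), the pseudoisotropic rotational
correlation time from motional narrowing of the three ¹⁴N manifolds:

    τ_C = k · W₀ · ( √(h₀/h₊₁) + √(h₀/h₋₁) − 2 ),    k = 6.5×10⁻¹⁰ s/G

where W₀ is the central peak-to-peak width and h₊₁, h₀, h₋₁ the low-field,
central and high-field line heights.  The empirical mobility δ⁻¹ = 1/W₀ and
polarity a_N (the isotropic hyperfine splitting) come from the same
features; a CD helper converts raw ellipticity to mean residue ellipticity.

Two-population spectra (mobile + immobilized "boundary" probe, or bound
label + residual free label) are decomposed by non-negative least squares on
unit-spin-normalized bases, so fitted amplitudes are spin-count fractions;
the free-label share can then be subtracted exactly.

The simulator generates the two regimes from first principles — derivative
Lorentzian triplets with m-dependent widths W(m) = W₀ + B·m + C·m², and
axially symmetric hyperfine powder patterns by Gauss–Legendre orientation
averaging — plus seeded noisy mixtures with known fractions.

## Worked example

Simulate a 5-SASL-like control/protein pair with ground-truth order
parameters 0.45 → 0.58 and run the comparison pipeline:

```python
import cwesr as cw
from cwesr.report import AnalysisConfig, analyze_pair, rows_to_frame

control = cw.simulate_axial_powder(
    cw.powder_params_for_order(0.45), cw.field_axis(3350.0, 30.0, 0.02))
treated = cw.simulate_axial_powder(
    cw.powder_params_for_order(0.58), cw.field_axis(3350.0, 32.0, 0.02))
report = analyze_pair(control, treated, AnalysisConfig(probe="5-SASL", lipid="LPG"))
print(rows_to_frame(report.rows).to_string(index=False))
```

```
 probe lipid parameter  control_value  treated_value  percent_change  percent_change_rounded
5-SASL   LPG         S       0.454291       0.584303       28.618547                      29
```

The measured S values sit within 0.005 of the generative truth (the small
positive bias is the finite-linewidth shift of the inner extrema, see
`docs/methods.md`), and the reported change rounds to 29%.  The features
behind each number are in `report.features`, e.g. the control spectrum's
splittings `2A_par = 44.93 G, 2A_perp = 21.31 G`.

Unmixing a noisy 0.7/0.3 mobile/immobilized composite:

```python
model = cw.TwoComponentModel(composite, [basis_mobile, basis_immobilized])
print(model.fit().summary())
```

```
Two-component spectral decomposition
====================================
 component    amplitude   fraction  shift (G)
         0      0.70003     0.6999      0.000
         1      0.30009     0.3001     -0.000
residual rms: 2.001e-05
```

A thin CLI wraps the same calls:

```
cwesr simulate --kind powder --a-par 25.07 --a-perp 9.47 --width 0.4 --out control.txt
cwesr measure --in control.txt --mode extrema
cwesr compare --control c.txt --treated t.txt --probe 16-SASL --lipid LPG --out report.csv
```

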