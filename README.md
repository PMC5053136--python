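# iecsaxs

Background correction and structural analysis for small-angle X-ray
scattering (SAXS) collected **online during ion-exchange chromatography
(IEC)**.

In chromatography-coupled BioSAXS the detector records one 1D curve per
second while the protein elutes.  With an ion-exchange column the mobile
phase changes during elution — a linear or stepwise NaCl gradient — so the
buffer background is *time-dependent*: its high-angle level rises with the
salt concentration, and the matching background in a blank run is offset
from the sample run by an unknown number of frames.  Plain "average some
buffer frames and subtract" fails.  This package implements the three
correction strategies appropriate to the three regimes, the downstream
Guinier/Porod analysis, and a synthetic-run generator with full ground
truth so that every stage can be validated at desk scale.

## Methods at a glance

**Linear gradients — shift scan** (`ShiftScan`, `scan_shifts`).  The blank
gradient run reproduces the sample run's background up to a clock offset
*s*.  For each trial shift (5-frame grid), sample frame *N* minus buffer
frame *N − s*, then score the per-frame ratio of low-q (0.11–0.5 nm⁻¹) to
mid-q (1.5–2.5 nm⁻¹) scattering across the elution peak: one species with a
correct background gives a *parallel line*; under-subtraction bends it
concave, over-subtraction convex.  The chosen shift minimizes the
(uncertainty-weighted) RMS deviation from a straight line.

**Stepwise gradients — exponential buffer transition** (`StepTransition`,
`fit_transition`).  A salt step arrives at the capillary delayed and
smeared (dispersion, co-eluting ions).  With averaged buffers I (before)
and II (after the peak), the high-q level (q > 4.5 nm⁻¹) follows

    y(N) = II − (II − I) · exp[−(N − N0)/N′],   N ≥ N0,

fitted for the onset `N0` and decay constant `N′` (half-life `N′·ln 2`).
The whole-curve buffer for any frame interpolates pointwise between I and
II with the same weight, enabling frame-by-frame subtraction through the
peak, with buffer II / mean(I, II) subtractions as over/under bounds.

**Irregular backgrounds — averaged-curve matching** (`match_buffer`).  When
the background changes irregularly (e.g. a transient high-q overshoot from
co-eluting small ions), average the peak frames and pick the buffer from a
pre-recorded salt series whose mean scattering in 4.25–4.75 nm⁻¹ matches;
neighbouring salt steps bracket the systematic error.

**Analysis** (`iecsaxs.analysis`): Guinier fit (ln I = ln I₀ − (qRg)²/3,
automatic window with qRg ≤ 1.3), Porod volume Vp = 2π²I₀/Q with fitted
flat-background removal, protein mass Vp/1.7 nm³ kDa⁻¹, mass from the
volume of correlation Vc = I₀/∫qI dq (Rambo–Tainer), concentration from
calibrated forward scattering (I₀ = c·M; 1 a.u. = 8.03×10⁻⁴ cm⁻¹), the
exact CorMap longest-run similarity test with Bonferroni adjustment, and
stable-region selection for averaging.

## Worked example

Simulate a BSA-like run on a linear gradient (66.5 kDa sphere with
Rg 2.74 nm eluting at 1.75 mg/ml; buffers 25 mM → 1 M NaCl; true clock
offset 130 frames; Poisson-like noise) and run the full pipeline:

```python
from iecsaxs import (scan_shifts, stable_region, auto_guinier,
                     porod_volume, mass_from_porod)
from iecsaxs.simulate import bsa_linear_config, simulate_run

run = simulate_run(bsa_linear_config(seed=1))
result = scan_shifts(run.sample, run.buffer)
print(result.summary())

region = stable_region(result.subtracted)
avg = result.subtracted.average(region.start, region.stop)
g = auto_guinier(avg)
print(region.summary()); print(g.summary())
p = porod_volume(avg, g)
print(p.summary()); print(f"mass from Vp: {mass_from_porod(p.Vp):.1f} kDa")
```

prints

```
Shift scan (linear-gradient background correction)
  shifts tested : -100..300 (81 values)
  ROI (frames)  : [694, 908)
  best shift    : 135 +/- 5 frames
  min flatness  : 0.2873
  classification: under
  ...
stable region: frames [685, 922) (237 frames) around reference 801
Guinier fit: Rg = 2.787 +/- 0.0023 nm, I0 = 60.57 +/- 0.022 a.u., points 0-89, qRg 0.089-1.298
Porod: Vp = 158.4 +/- 14 nm^3, Q = 7.549, B = 0.014, extrapolated fractions 0.000 (low) / 0.135 (high)
mass from Vp: 93.2 kDa
```

The scan recovers the 130-frame offset to within the ten-frame precision
the method can claim (best shift 135 on this noise realization, exact 130
without noise).  The Guinier radius lands within 2 % of the generator's
2.74 nm and the forward scattering of every frame equals concentration ×
molar mass by construction.  The Porod volume is the least robust output on
noisy runs — the subtracted signal above ~3.5 nm⁻¹ sits below the noise
floor, so residual background leaks into the q⁻⁴ tail term (here Vp is
~15 % low against the generating sphere's 185 nm³) — which is why the
stepwise workflow brackets every result with deliberate over- and
under-subtractions.

The same stages are available from the shell:

```bash
iecsaxs simulate --config sim.toml --out run/
iecsaxs subtract --method linear-shift \
    --sample run/sample/manifest.csv --buffer run/buffer/manifest.csv --out sub/
iecsaxs analyze --subtracted sub/subtracted/manifest.csv --mass-kda 66.5 --out ana/
```

All curves are plain three-column text (q [nm⁻¹], I, σ; Å⁻¹ accepted via a
`# units:` header), series are directories with a CSV manifest, and
configs are TOML.

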