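# synchrofluor

First-derivative synchronous spectrofluorimetry for resolving binary
mixtures of spectrally overlapping fluorophores, with the bambuterol (BAM) /
terbutaline (TEB) pair as the built-in application.  The package is aimed at
analytical chemists who want a tested, scriptable implementation of the
zero-crossing derivative technique together with the ICH-style validation
statistics used to report such methods (calibration diagnostics, LOD/LOQ,
recovery, precision, t/F method comparison), plus a seedable
excitation–emission matrix (EEM) simulator standing in for the instrument.

## The method

A synchronous fluorescence spectrum is recorded by scanning excitation and
emission monochromators together at a constant offset Δλ (here 20 nm):

&nbsp;&nbsp;&nbsp;&nbsp;S(λ) = I(λ_ex = λ, λ_em = λ + Δλ)

Synchronous scanning narrows bands, but for strongly overlapping pairs the
raw synchronous spectra still interfere.  The assay therefore works on the
smoothed first derivative ¹D(λ) = dS/dλ (15-point quadratic Savitzky–Golay
filter) and reads it at each analyte's **zero-crossing wavelength of the
other component**: a wavelength where the interferent's derivative is zero
at *every* concentration, so the measured amplitude depends only on the
analyte.  For the BAM/TEB pair at Δλ = 20 nm, BAM is quantified at 260 nm
(TEB's zero crossing) and TEB at 290 nm (BAM's zero crossing).  Calibration
is ordinary least squares, ¹D = a + b·C over 0.2–6.0 µg/ml (BAM) and
0.2–4.0 µg/ml (TEB), with

- S_y/x = √(ΣΔ²/(n−2)), S_b = S_y/x/√S_xx, S_a = S_y/x·√(Σx²/(n·S_xx)),
- LOD = 3.3·S_a/b, LOQ = 10·S_a/b (ICH, σ = s.d. of the intercept),
- pooled-variance Student's t and variance-ratio F against a reference
  method at p = 0.05.

The simulator models each fluorophore as unit-peak Gaussian excitation and
emission bands with a linear concentration response and additive +
proportional noise; mixtures are superpositions.  The default band models
place the mutual zero crossings at 260/290 nm and make Δλ = 20 nm the
sensitivity-optimal offset.

## Worked example

Simulate a noisy study, calibrate, and assay the standard mixture panel:

```
$ synchrofluor simulate --out demo --seed 7
$ synchrofluor calibrate --config demo/config.json \
      --manifest demo/calibration_manifest.csv --out demo/cal
analytical performance of the derivative synchronous assay

parameter                            BAM         TEB
wavelength (nm)                      260         290
n                                      6           6
intercept a                         0.08       -0.04
slope b                            13.65       28.78
correlation r                     0.9999      1.0000
s.d. of residuals Sy/x             0.369       0.303
s.d. of intercept Sa               0.249       0.192
s.d. of slope Sb                   0.075       0.086
LOD (ug/ml)                        0.060       0.022
LOQ (ug/ml)                        0.183       0.067
```

The slopes are the assay sensitivities in a.u. per µg/ml at the 260/290 nm
readouts; r ≈ 0.9999 and the sub-0.1 µg/ml detection limits reflect the
linear, low-noise regime of the simulated instrument.

```
$ synchrofluor assay --config demo/config.json \
      --manifest demo/mixture_manifest.csv \
      --curves demo/cal/curves.json --out demo/assay
$ head -4 demo/assay/results.csv
sample_id,analyte,d1_amplitude,concentration_ug_ml,flags,true_ug_ml,recovery_pct
mix_000,BAM,27.1006724,1.9791586,,2,98.95793
mix_000,TEB,5.89816364,0.206283706,,0.2,103.141853
mix_001,BAM,54.8085821,4.008651,,4,100.216275
```

Each mixture (ratios from 1:1 up to 10:1) is quantified on both channels;
recoveries scatter around 100% with the spread set by the noise model.
Comparing a recovery set against a reference method:

```
$ synchrofluor compare proposed.csv reference.csv
t = 1.05 (crit 2.45), F = 5.69 (crit 19.25): no significant difference
```

Library use mirrors the CLI:

```python
import synchrofluor as sf
from synchrofluor import synth_spectra as ss, quantitation as qt

bam, teb = ss.default_bam_teb_models()
assay_bam, assay_teb = qt.default_assays()
sample = ss.simulate_eem((bam, teb), {"BAM": 2.0, "TEB": 1.0}, noise=None)
amp = qt.measure(sample.eem, assay_bam)   # signed 1D amplitude at 260 nm
```

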