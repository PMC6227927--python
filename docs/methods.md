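# Methods

## Signal model and processing chain

The measured object is an excitation–emission matrix (EEM) I(λ_ex, λ_em) in
arbitrary units on uniform 1 nm grids (excitation 200–400 nm, emission
220–420 nm by default).  The synchronous spectrum at constant offset Δλ is
the diagonal slice S(λ) = I(λ, λ + Δλ), indexed by excitation wavelength
(the axis convention is a configuration flag; the instrument literature is
ambiguous on which axis is plotted).  Off-node slices are bilinearly
interpolated; node-aligned slices reproduce stored matrix values bitwise,
which keeps the extraction testable against a direct index-pair oracle.

Smoothing and differentiation are a single quadratic Savitzky–Golay pass.
The default window is 15 points (15 nm at the 1 nm step), mapping the
common vendor "smoothing factor = 15" setting onto the standard open
definition of a local-polynomial filter; vendor semantics are proprietary,
so the window is exposed in configuration.  Edge samples are produced by
evaluating the edge window's fitted polynomial rather than padding, and any
readout within half a window of the axis edge raises a warning.  Every
operator in the chain (slice, blank subtraction, smoothing, derivative,
linear interpolation) is linear in the intensity, which is what makes the
zero-crossing argument exact: the derivative of a mixture is the sum of the
components' derivatives.

Negative intensities (after blank subtraction or from noise) are retained;
the derivative signal is signed by construction.  Each assay carries a
polarity (+1/−1), the sign of the analyte's derivative flank at its readout
wavelength, so calibrations always run on positive signal scales — the TEB
readout at 290 nm sits on the falling flank of its synchronous band and
would otherwise calibrate with a negative slope.

## Zero-crossing quantitation

A zero-crossing wavelength of component X is a wavelength where ¹D_X
vanishes at every concentration; for a single-band synchronous spectrum this
is its band maximum, since amplitudes scale linearly with concentration and
zeros are fixed.  `find_zero_crossing` takes derivative spectra of the
interferent at ≥ 3 concentrations spanning its range and minimizes the
worst-case normalized amplitude max_i |¹D_i(λ)|/max|¹D_i|, refined to a
tenth of the grid step by linear interpolation; if the minimum exceeds the
tolerance (default 2%) there is no usable crossing and an error is raised —
the situation in which raw synchronous spectra cannot resolve the pair.

Readout wavelengths are fixed assay constants (260 nm for BAM, 290 nm for
TEB at Δλ = 20 nm), validated once against `find_zero_crossing` rather than
re-detected per sample; per-sample re-detection drifts with noise.
Quantitation inverts the calibration, C = (¹D − a)/b; results outside the
calibrated range are returned unclipped with an extrapolation warning.

The offset sweep (`optimize_delta_lambda`) scores each candidate Δλ by
whether both mutual crossings exist and by the partner's per-unit
concentration response at each crossing, marking the feasible candidate
that maximizes the smaller of the two responses.  The crossing search is
confined to the interferent's own band region (synchronous intensity ≥ 10%
of peak): outside the bands the normalized derivative is trivially near
zero everywhere and any wavelength would spuriously qualify.

## Simulator

Each fluorophore is a set of Gaussian excitation and emission bands
(weight-summed, normalized to unit peak) with a linear response coefficient
(a.u. per µg/ml at the joint band maximum).  Mixtures are exact
superpositions; noise adds `additive_sd·z₁ + proportional_sd·I·z₂` per EEM
point with independent standard-normal draws from one explicit integer seed
(no global state).

Default band models: BAM excitation 290 nm / emission 310 nm (σ = 24 nm),
TEB excitation 260 nm / emission 280 nm (σ = 20 nm), responses 625 and
1750 a.u. per µg/ml, linear ranges 0.2–6.0 and 0.2–4.0 µg/ml.  These were
chosen once to satisfy the assay's defining geometry: with 20 nm Stokes
shifts the Δλ = 20 synchronous bands peak exactly at 260 nm (TEB) and
290 nm (BAM), putting each component's zero crossing at the partner's
readout, and Δλ = 20 nm is simultaneously the sensitivity-optimal offset
(synchronous intensity peaks when the offset matches the Stokes shift).
The responses give noiseless calibration slopes of 13.7 and 28.7 a.u. per
µg/ml — the magnitude a bench instrument reports for this assay.  True
band maxima of the real drugs are not numerically published; the defaults
are calibrated to the assay geometry, not to the drugs' photophysics.

Default noise: proportional_sd = 0.5% of the local signal and an additive
floor of 0.05% of the largest top-of-calibration EEM intensity (4 a.u. for
the default pair).  Propagated through the derivative filter this yields
recovery RSDs of roughly 0.3–4% across the working ranges — a few tenths of
a percent at mid/high levels, dominated by the additive floor at the lowest
levels and by the interferent's proportional noise for the minor component
of lopsided mixtures (at 10:1 the strong component's band sits directly on
the weak component's readout, so its proportional noise leaks into that
channel even though its mean contribution is nulled).  That leakage is a
real limitation of zero-crossing methods, not a simulator artifact.

Standard study conditions: calibration levels {0.2, 0.8, 1.6, 3.2, 4.0,
6.0} µg/ml for BAM and {0.2, 0.4, 0.8, 1.6, 3.2, 4.0} µg/ml for TEB (six
levels each), and a five-mixture (BAM, TEB) panel (2+0.2, 4+0.4, 2+1, 2+2,
5+1 µg/ml) spanning ratios 1:1 to 10:1.

What the simulator does **not** model: Rayleigh/Raman scatter ridges,
inner-filter effects, photobleaching, pH/solvent/surfactant band shifts,
slit-width or detector-voltage response.  Passing tests therefore
demonstrate the correctness of the signal processing, the zero-crossing
logic and the statistics under the stated noise structure — not robustness
to the chemistry-dependent effects a real validation must probe.

## Statistics

Calibration is unweighted OLS with the textbook diagnostics (see README);
the fit is checked against a normal-equations oracle to 1e-10.  With
exactly two points the fit is saturated and the residual diagnostics are
reported as zero with a warning.  Sensitivity limits use σ = S_a (s.d. of
the intercept): LOD = 3.3·S_a/b, LOQ = 10·S_a/b, so LOQ/LOD = 10/3.3
exactly.  Recovery summaries use the n−1 sample standard deviation,
%RSD = 100·sd/mean and %error = %RSD/√n (the relative standard error of
the mean).  Method comparison uses the pooled-variance two-sample t
(reported as |t|, df = n₁+n₂−2) and the variance-ratio F with the larger
variance in the numerator; critical values are scipy's t and F quantiles
at p = 0.05 (two-sided t, upper-tail F).  Precision studies emit one cell
per (day, concentration) replicate set (intra-day) and one pooled cell per
concentration across days (inter-day); each cell needs ≥ 2 replicates.

Degenerate inputs: identical calibration concentrations raise a
singular-design error; a zero slope makes quantitation undefined and
raises; two groups with zero variance report F = 1.

## Bundled reference data

`synchrofluor.datasets` carries the published validation tables of the
BAM/TEB assay (calibration performance constants, pure-form and mixture
recovery panels, pharmacopoeial-reference recoveries, precision summaries,
formulation assays) as plain Python constants; they are inputs to the
statistics layer, never outputs of this package.  The summary statistics of
those panels derive from the published rounded recovery columns, which are
therefore stored alongside the raw taken/found pairs (recomputing
recoveries from the pairs shifts some 2 d.p. summary values by 0.01).  One
transcription repair: a formulation-table reference row prints a found
amount inconsistent with its own printed recovery (19.84 at 60 µg/ml,
99.22%); it is stored as 59.53 = 60 × 0.9922 to keep the printed
recovery/mean/sd self-consistent.

## Problem sizes and determinism

Simulated EEMs are 201 × 201 points; a full simulated study (two six-level
calibration series plus the five-mixture panel) runs in well under a
second, so the Monte-Carlo checks use 200 calibration sets and 100 mixture
panels with seeds spawned from one parent seed.  All generation is
deterministic per seed and bit-reproducible; pipeline outputs are
byte-identical given identical inputs and configuration, and reports store
full-precision values in JSON alongside the rounded display tables.
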