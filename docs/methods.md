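# Methods

## Model overview

The simulator decomposes a manual OCT calliper reading of a full-thickness
macular hole (FTMH) into a ground-truth geometry, an acquisition, and an
observer act, each with explicit parameters.

**Hole geometry.** A hole is described by its true minimum linear diameter
(MLD), basal diameter (BD), nasal and temporal heights, and a lateral offset
of its centre from the raster origin (all µm). The MLD and BD apertures are
modelled as concentric circles in their horizontal planes. This is the
assumption under which the chord mathematics below is exact; irregular or
elliptical holes, and tilted b-scans through staphylomatous eyes, are out of
scope.

**Chord sampling.** A b-scan at perpendicular offset `o` from the centre of
a circular aperture of diameter `D` records the chord
`2·sqrt((D/2)² − o²)` (0 if it misses). For a raster with spacing `s`, the
phase of the grid relative to the hole centre is a nuisance parameter,
taken uniform on `[0, s)` per acquisition: fixation relative to the grid is
arbitrary. The widest chord over slices, minimised over phase, has the
closed form `sqrt(D² − s²)` for `s < D`: the worst phase places the two
nearest slices symmetrically at ±s/2, and the chord there is
`2·sqrt((D/2)² − (s/2)²) = sqrt(D² − s²)`. When `s ≥ D` the function
returns 0 rather than raising — a phase exists at which no slice meets the
aperture, the hole-missed limit. Both BD and MLD receive the chord
treatment (geometrically forced for concentric circular apertures); hole
height is held independent of slice offset, since height error is driven by
display scaling rather than slice choice — a deliberate simplification.

**Acquisition.** A protocol (`ScanProtocol`) carries b-scan spacing, scan
count, lateral and axial resolution, and the default vertical display
scaling. Two presets ship with the package: a 125 µm / 49-scan /
5.7 µm-lateral / 1:3.775 configuration ("spectralis-like") and a 50 µm /
149-scan / 20 µm-lateral / 1:2 configuration ("triton-like"). Each
eye × protocol acquisition draws one raster phase and one Gaussian fixation
decentration (default SD 50 µm, emulating poor vision or eccentric
fixation); both observers measure the same acquired volume.

**Observer.** Three error mechanisms, each with its own knob:

| parameter | meaning | default | why |
|---|---|---|---|
| `jitter_coeff` | per-endpoint Gaussian SD = coeff × lateral resolution | 0.5 | border ambiguity scales with pixel size; magnitude is a calibration knob, not identifiable from available data |
| `bias_coeff` | systematic offset = coeff × lateral resolution | −0.75 (observer 1), 0 (observer 2) | one grader consistently choosing a nearer reference point on low-resolution scans; vanishes on high-resolution scans by construction |
| `slice_error_prob` | probability of measuring an adjacent slice instead of the widest | 0 | opt-in: a non-negligible rate injects chord-gap variance (tens of µm on a sparse raster) that would dominate and confound the resolution-driven interobserver comparison the default configuration is designed to isolate |
| `oblique_tol_deg` | maximum on-screen deviation from vertical of a height calliper | 3° | small, plausible visual tolerance; uniform drift within the cone is the maximum-entropy choice |

A horizontal reading is `max(0, w + bias + ε_L + ε_R)` with two independent
endpoint errors; its SD is therefore `sqrt(2)·jitter_coeff·L` and the
paired interobserver difference SD is `2·jitter_coeff·L`, linear in lateral
resolution `L`. A height reading draws a horizontal drift uniform on
`[−w, +w]` with `w = vscale·h·tan(tol)` and reports `sqrt(Δx² + h²)`:
heights can only be inflated, the inflation (≈ `h·(vscale·tan tol)²/6` in
expectation) grows with vscale, and it vanishes at `tol = 0`.

**Agreement analysis.** Bland-Altman bias and limits of agreement use the
plain 1.96 multiplier with the sample (n−1) SD — no small-sample t
correction, matching standard practice. The ICC is the single-measurement
two-way absolute-agreement form ICC(A,1), computed directly from the ANOVA
mean squares

    ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))

with 95% CI via McGraw & Wong's F-procedure (Satterthwaite df) and the
ICC=0 test from `F = MS_R/MS_E` on `(n−1, (n−1)(k−1))` df. Single measures
were chosen over average measures because individual readings, not rater
means, are being compared; absolute agreement (rather than consistency) is
required because a constant between-rater offset is exactly the kind of
disagreement the simulator produces. Stratified reports pair observers per
(eye, machine, parameter); machine comparisons first average the two
observers per (eye, machine, parameter) and then pair machines per
(eye, parameter). Pairing order follows first appearance in the record
list, so the sign of the bias tracks the caller's protocol/observer order.
No multiple-testing correction is applied.

## Synthetic cohort

The generator's defaults describe a plausible surgical FTMH case mix, since
per-eye geometry distributions are not available from real data: MLD
lognormal with median 350 µm and log-SD 0.45, BD uniform at 1.5–2.5× the
MLD, heights Gaussian 420 ± 60 µm truncated at >0, fixation SD 50 µm. The
default study is 8 eyes × 2 protocols × 2 observers × 4 parameters = 128
records; phenomenon-level checks use 200 eyes, large enough that the
directional effects (a few µm) clear their Monte-Carlo standard errors by a
comfortable margin while the whole run stays under a second.

What the generator does **not** emulate: irregular hole shapes, repeat
acquisitions, media opacity or signal-strength effects, segmentation
differences between vendors, and axial-resolution effects on height
endpoints. Passing tests therefore demonstrate the *mechanisms* — chord
under-sampling, resolution-scaled endpoint error, scaling-induced oblique
inflation — not the magnitudes any particular clinic would observe.

## Numerical and reproducibility choices

* One master seed; child generators are keyed per eye, per (eye, protocol)
  and per (eye, protocol, observer) through `numpy` `SeedSequence`, so
  subsetting the cohort or protocol list leaves the remaining draws
  unchanged, and every stochastic operation is bit-reproducible.
* Widest-slice ties break to the smaller |offset|, then the lower slice
  index; `select_slice` consumes its random draws unconditionally so the
  stream does not depend on the error knobs.
* Degenerate (constant) rating matrices yield a flagged report with NaN ICC
  rather than NaN propagation or a crash; a perfect-agreement matrix
  returns ICC exactly 1 with a collapsed CI.
* Horizontal readings are clipped at 0 (a calliper cannot report a negative
  length); measurement CSVs are written with round-trip float precision and
  re-read with `float_precision="round_trip"`, so write → read is
  bit-exact.
* The ICC parameter-recovery check averages estimates over replicate
  500×2 matrices: with two raters the single rater-difference draw is
  χ²₁-distributed and moves any individual matrix's estimate by more than
  the ±0.02 band the mean satisfies.

## Known limitations

* Circular apertures make the chord model exact but understate variability
  for irregular holes, where the widest-slice rule itself becomes
  ambiguous.
* Observer coefficients (jitter, bias, oblique tolerance) are calibration
  knobs: a single published disagreement instance cannot identify them, so
  the defaults are chosen for mechanism isolation, not fitted.
* Radial raster patterns and vendor file formats are not modelled; the
  agreement stage accepts any measurement CSV with the documented columns,
  so real reader-study tables can be analysed, but the simulator only
  produces horizontal rasters.
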