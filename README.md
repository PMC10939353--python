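# f2f — fluorophore-to-fluorophore distance measurement

`f2f` measures the separation between two fluorescent labels — far below the
diffraction limit — from repeated two-colour wide-field imaging of
diffraction-limited spots. It is built for PICT-style experiments in budding
yeast, where a protein complex is recruited to engineered membrane anchor
platforms (anchor–RFP, channel 1) and one of its subunits carries a GFP tag
(prey, channel 2): imaging many cells yields hundreds of anchor/prey spot
pairs whose centroid distances carry the label separation. The same pipeline
applies to any two-channel dataset of paired point emitters.

## The model

A measured 2D centroid distance `d` between two labels at true separation μ,
each localized with isotropic Gaussian noise of scale σ, follows the Rice
distribution

    p(d | μ, σ) = (d/σ²) · exp(−(μ² + d²)/(2σ²)) · I₀(dμ/σ²),   d ≥ 0,

with `I₀` the modified Bessel function of order zero. Because the law is
skewed, the raw sample mean overestimates μ; `f2f` estimates (μ, σ) by
maximum likelihood after a bootstrap-scored rejection of upper-tail outliers
(mislinked or contaminated pairs).

Getting from images to clean distances takes four stages, each available as
a library function and as a CLI subcommand:

1. **Registration** (`f2f register`) — channels are chromatically shifted
   against each other; an affine map is calibrated from fields of
   multicolour beads, fit on half the fields and validated on the other
   half. The target registration error (TRE) on held-out beads should be
   below 1 nm before measuring distances.
2. **Pre-processing** (`f2f preprocess`) — rolling-ball background
   subtraction (radius ~ cell size) followed by subtraction of the
   median-filtered image (window ≈ twice the diffraction limit) removes
   extracellular and cytoplasmic background.
3. **Detection, linking, correction** (`f2f detect`) — Crocker–Grier-style
   sub-pixel centroiding with shape features, mutual nearest-neighbour
   linking of the two channels within 2–3 px, then affine correction of
   channel-1 coordinates.
4. **Selection and estimation** (`f2f select`, `f2f estimate`) — a quality
   cascade (isolation → cell-contour proximity → feature-space density →
   2D-Gaussian fit quality) keeps only reliable pairs; the Rician MLE with
   bootstrap outlier rejection turns their distances into μ̂ ± SE.

A synthetic-scene generator (`f2f.simulate`, `f2f simulate beads|cells`)
renders bead calibrations with a known affine distortion and yeast-like cell
fields with membrane-anchored pairs at a known separation, so the whole
pipeline is testable without any experimental data.

## Worked example

`examples/04_full_distance_measurement.py` simulates a bead calibration and
four cell fields with a 20 nm true separation and 7 nm per-channel
localization noise, then runs everything:

```
registration TRE: 0.658 nm (gate: < 1 nm)
80 linked pairs, 40 pass all filters
estimated separation: mu = 18.86 +/- 2.07 nm (truth 20 nm)
localization noise:   sigma = 8.84 nm
outlier rejection trimmed 5.0% (2 of 40 distances)
```

The TRE passes the 1 nm gate; the selection cascade halves the pair set
(the density filter keeps the denser half of feature space by design); the
estimate recovers the 20 nm truth within its standard error, and σ̂ ≈ 9 nm
matches the simulated per-channel jitter (√2·7 ≈ 9.9 nm). The other
examples cover Rician sampling and robust fitting, bead registration alone,
detection plus selection on a single field, and the cross-dataset anchor QC
(`f2f qc`), which flags experiments whose anchor brightness/second-momentum
relation falls off the trend of their peers.

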