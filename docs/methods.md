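# Methods

## Model

Preclassification treats the reference water spectrum Z_w as a one-column
regressor. For each measured spectrum Z on the same wavenumber axis,

    Z(ν̃) = a + b·Z_w(ν̃) + ε(ν̃)

is fitted by ordinary least squares over a fit region R: with the
reference mean-centred for conditioning, b = cov(Z_w, Z)/var(Z_w) and
a = mean(Z) − b·mean(Z_w), all moments over R. This is the exact
closed-form solution of the 2×2 normal equations; no iterative solver is
involved. The residual RMSE, √(Σ εᵢ²/n) with n = |R|, gauges dissimilarity
to water, and the label rule is

    water      if RMSE ≤ θ   (boundary inclusive on the water side)
    cartilage  if RMSE > θ.

The model deliberately stops at the additive + multiplicative terms.
The extended variant with polynomial wavenumber terms (EMSC) is out of
scope here: on a seven-channel sparse axis the additional degrees of
freedom would consume most of the residual and erase the very signal the
RMSE is meant to detect.

Assumptions worth stating explicitly:

* The water matrix enters a measured spectrum (approximately) affinely —
  baseline offset plus path-length/contact scaling. Analyte absorption
  is not an affine function of the water spectrum over the fit region,
  so it must appear in ε.
* The reference is non-constant over the fit region (otherwise the
  design is rank deficient; this is raised as an error).
* Spectrum and reference share one axis. Resampling (linear
  interpolation, no extrapolation) is the caller's step, exposed as
  `resample_to_axis`; the CLI does it automatically.

## Parameters that matter

| parameter | units | default | notes |
|---|---|---|---|
| fit region | cm⁻¹ | 800–1900 (CLI, broadband); full axis (sparse) | The region entering the least squares is an explicit parameter everywhere in the library: the choice is material (n enters the RMSE) and must stay visible and reproducible. 800–1900 cm⁻¹ is the fingerprint window where both water bands and all cartilage marker bands live. |
| θ | absorbance (RMSE units) | none — required | Dataset dependent by construction: the water-cluster RMSE sits at the instrument noise floor and the cartilage cluster's position depends on analyte strength, so no absolute value transfers between datasets, instruments, or axis sizes. The CLI refuses to run without it. |
| sparse targets | cm⁻¹ | 850, 1080, 1210, 1560, 1620, 1745, 1800 | Water libration, carbohydrate C–O, amide III, amide II, amide I, lipid C=O, plus a baseline point at 1800 where tissue and water are nearly transparent. |
| matching tolerance | cm⁻¹ | one axis spacing | Nearest-channel matching (QCL hardware emits fixed lines); ties break toward the lower wavenumber for determinism. Interpolated picking is available behind `mode="interpolate"`. |
| SNR regions | cm⁻¹ | signal 920–1200, noise 2000–2100 | Peak-to-peak of the first derivative in each region; endpoints inclusive. Regions are parameters; the polysaccharide association of 920–1200 is documentation, not logic. |
| PCA components k | — | 2 | Score plots are two-dimensional; k is capped at min(n_spectra − 1, n_channels). |

## Numerical choices

* **Derivative estimator.** Plain finite differences with respect to
  wavenumber: central in the interior, one-sided at the ends. On axes
  whose channel spacing is uniform to within 1e-9 relative, the scalar
  spacing is used, so a constant spectrum differentiates to exactly
  zero (the coordinate-array formula leaves ~1e-16 rounding residue that
  would break the flat-spectrum contract). Non-uniform axes use the
  three-point coordinate formula. No Savitzky–Golay smoothing: the
  statistic is defined on the raw derivative, and the estimator is
  isolated behind `first_derivative` so a smoothing variant can be
  swapped in.
* **PCA.** Singular value decomposition of the mean-centred raw matrix
  (scikit-learn, full solver). "Raw" means no derivative, normalisation,
  or scaling; mean-centring is intrinsic to PCA and the centring vector
  is returned so the choice is auditable. Signs are fixed
  deterministically (largest-magnitude loading positive). Explained
  variance fractions are clipped to [0, 1] to absorb ulp-level
  overshoot; a dataset with zero total variance reports zero fractions.
* **Otsu suggester.** `suggest_threshold` maximises the between-class
  variance over every split of the sorted RMSE values (exact, no
  histogram binning) and places the threshold midway between the two
  straddling values. Histogram-binned Otsu tie-breaks the flat
  between-class-variance plateau of a well-separated bimodal sample at
  the gap's left edge, which is a poor advisory value; the exact split
  lands mid-gap. The suggestion is advisory only and says so.
* **Threshold between clusters.** `separation_midpoint` defaults to the
  midpoint of the separation gap, (max water RMSE + min analyte RMSE)/2,
  which guarantees zero misclassifications whenever the two RMSE
  distributions are disjoint. The midpoint of the cluster means is
  available (`method="means"`) but is not a safe default: with analyte
  fractions spread over a range, the analyte cluster is wide and its
  minimum can fall below the means midpoint.
* **Axis canonicalisation.** The internal axis order is strictly
  ascending everywhere; descending files (the conventional IR display
  order) are reversed on ingestion. This removes sign ambiguities from
  derivative and interpolation code. Duplicated wavenumbers, non-finite
  values, and NaN/Inf absorbances are rejected at the door rather than
  propagated.
* **Degenerate inputs.** Constant reference over the fit region → rank
  deficiency error; fit region with < 3 channels → region error; zero
  noise peak-to-peak → SNR ratio reported as undefined (NaN), not an
  exception; all-identical RMSE values → no-split warning from the
  suggester.

## Synthetic data: what it emulates, and what it does not

The generator builds water rows as `a + b·W + noise` and cartilage rows
as `a + b·W + c·C + noise`, with W a two-band Gaussian water model
(1630 cm⁻¹, σ 60, amplitude 1.0; 800 cm⁻¹, σ 120, amplitude 0.6 — flat
elsewhere in the fingerprint region) and C a six-band cartilage
signature (850, 1080, 1210, 1560, 1620, 1745 cm⁻¹; amide I at 1620
dominant). Defaults: a ∈ [−0.05, 0.05], b ∈ [0.8, 1.2], c ∈ [0.3, 1.0],
i.i.d. Gaussian channel noise σ = 0.005, axis 400–4000 cm⁻¹ at
1.0292 cm⁻¹ spacing (a realistic ATR-FTIR digital grid, ~3500
channels). The ranges are chosen to produce the two-cluster RMSE
structure the method targets: a water cluster at the noise floor and an
analyte cluster well above it, with the weakest analyte fraction (0.3)
still clearly resolvable at that noise level. All randomness flows
through one seeded generator; the truth record regenerates the matrix
bitwise.

Deliberately not modelled: Lorentzian/Voigt band shapes (Gaussian is
sufficient to exercise an affine-fit-plus-residual method, and the band
model is swappable), correlated noise, water-vapour and CO₂ artifacts,
ATR penetration-depth dispersion, scatter fringes, and detector
nonlinearity. Consequently, passing tests demonstrate the method's
algebra, determinism and self-consistency — not its performance on real
clinical spectra, where θ selection against real artifact structure is
the hard part and remains a per-dataset, human-supervised decision.

## Design choices where the design was open

* The fit region is a required explicit parameter rather than a
  hard-coded range: nothing forces 800–1900 cm⁻¹, and hiding it would
  make RMSE values irreproducible across tools.
* Absolute θ values are never built in, for the same reason; published
  thresholds from any one instrument/dataset do not transfer (n and the
  noise floor both change).
* Sparse selection defaults to nearest-channel rather than
  interpolation because fixed-wavelength lasers sample the axis at
  their emission lines; the interpolated variant exists behind a flag
  for broadband-emulation studies.
* Scatter-corrected spectra (Z − a)/b are intentionally not produced:
  MSC serves here as a similarity gauge, and emitting "corrected"
  spectra would invite using the preclassifier as a preprocessing step,
  which it is not.
* JCAMP-DX support covers the uncompressed AFFN subset
  (`XYDATA=(X++(Y..Y))`, `XYPOINTS`); SQZ/DIF/DUP compressed tables and
  vendor binary formats are rejected with explicit errors — users
  convert upstream.

## Problem sizes

The test suite and the acceptance script run on a 650–2200 cm⁻¹ axis
(~1500 channels) for per-spectrum checks and on the full default axis
(~3500 channels, 400 spectra) for the separation and concordance runs;
Monte-Carlo checks use 20 seeds at 200–250 spectra each. These sizes
give stable statistics (recovery biases ~1e-5, disjoint RMSE clusters)
while keeping a full run in the seconds range.

## Known limitations

* θ selection is out of scope by design; the Otsu suggester can cut
  into a wide analyte cluster (unequal cluster variances are a known
  Otsu failure mode) and must be reviewed before use.
* No quality test in the vendor sense: low-signal, fringe, or
  atmospheric-artifact screening is a separate concern from the
  water/analyte split implemented here.
* Linear interpolation is the only resampling scheme; band-limited
  resampling is unnecessary for the smooth spectra targeted but would
  matter for very sparse source axes.
* The cartilage-as-reference variant is supported mechanically (any
  reference spectrum can be supplied) but is known to separate poorly —
  analyte spectra vary far more among themselves than water spectra do —
  and is not tuned or recommended.
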