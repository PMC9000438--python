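# irpreclass

Preclassification of infrared absorbance spectra by multiplicative signal
correction (MSC) against a water reference — for broadband ATR-FTIR data
and for sparse, discrete-wavenumber (fixed-wavelength QCL) data.

## The problem

In ATR infrared spectroscopy of tissue (e.g. articular cartilage probed
during arthroscopy), poor probe contact yields spectra dominated by the
surrounding water/synovial-fluid matrix instead of the analyte. Such
analyte-poor spectra carry no diagnostic value and must be removed before
any modelling. On a broadband axis a human can spot them by eye; on a
sparse axis of a handful of laser wavelengths, visual inspection is
impossible — an automated preclassification is required, and it must work
identically on both kinds of axes.

## The method

Each measured spectrum Z(ν̃) is modelled around a reference water spectrum
Z_w(ν̃) with an additive baseline term and a multiplicative scaling term
(the MSC model):

    Z(ν̃) = a + b·Z_w(ν̃) + ε(ν̃)

(a, b) are fitted by ordinary least squares over a chosen wavenumber
region. The residual summarises how unlike water the spectrum is:

    RMSE(ε) = √( (1/n) Σᵢ εᵢ² ),   n = channels in the fit region

and a user-chosen, dataset-dependent threshold θ assigns the label:

    RMSE(ε) ≤ θ  →  water (analyte-poor)
    RMSE(ε) > θ  →  cartilage (analyte-rich)

A water spectrum fits the water reference almost perfectly (RMSE near the
noise floor); any genuine analyte contribution is not expressible as
`a + b·Z_w` and inflates the RMSE. Because the rule only needs the
channels present, it applies unchanged to a seven-wavenumber sparse
subset (850, 1080, 1210, 1560, 1620, 1745, 1800 cm⁻¹ — the cartilage
marker bands plus a 1800 cm⁻¹ baseline point), with its own θ since n
changes.

Two auxiliary annotation tools support the choice of θ: a
first-derivative peak-to-peak Signal (920–1200 cm⁻¹) over Noise
(2000–2100 cm⁻¹) ratio, and PCA score plots of the raw spectra. A
synthetic generator produces ground-truthed water-like and
cartilage-like spectra (Gaussian band models, additive baseline,
multiplicative scaling, white noise) so the entire pipeline is testable
end to end.

## Worked example

```python
import numpy as np
from irpreclass import (default_axis, simulate_dataset, make_water_reference,
                        preclassify_dataset, separation_midpoint, WATER)

axis = default_axis()                       # 400-4000 cm-1, 1.0292 cm-1 spacing
dataset, truth = simulate_dataset(axis, n_water=200, n_cartilage=200, seed=1)
reference = make_water_reference(axis)

fits = preclassify_dataset(dataset, reference, threshold=1.0, region=(800, 1900))
rmse = np.array([r.fit.rmse for r in fits])
is_water = (truth.table["label"] == WATER).to_numpy()
theta = separation_midpoint(rmse[is_water], rmse[~is_water])
print(f"water RMSE:     {rmse[is_water].min():.5f} .. {rmse[is_water].max():.5f}")
print(f"cartilage RMSE: {rmse[~is_water].min():.5f} .. {rmse[~is_water].max():.5f}")
print(f"gap-midpoint theta = {theta:.5f}")

results = preclassify_dataset(dataset, reference, theta, region=(800, 1900))
labels = np.array([r.label for r in results])
print(f"labelled water: {(labels == WATER).sum()} / {len(labels)}")
print(f"misclassified:  {(labels != truth.table['label']).sum()}")
```

prints

```
water RMSE:     0.00474 .. 0.00523
cartilage RMSE: 0.05996 .. 0.19165
gap-midpoint theta = 0.03260
labelled water: 200 / 400
misclassified:  0
```

The water cluster sits at the noise floor (σ = 0.005 per channel), the
cartilage cluster far above it, and any θ in the gap separates the two
classes without error. On real data θ is chosen by inspecting the RMSE
distribution (see `suggest_threshold` for an advisory Otsu split and the
`pca`/`snr` commands for annotation support); it does not transfer
between datasets or between broadband and sparse axes.

The same analysis from the shell:

```sh
irpreclass pipeline --simulate --n-water 200 --n-cartilage 200 --seed 1 \
    --threshold auto --out-dir demo/
```

```
n spectra: 400
broadband theta: 0.0716992169182  water=214 cartilage=186
sparse theta: 0.0787591565292  water=214 cartilage=186
broadband vs sparse label agreement: 398/400
broadband labels vs SNR-ranking partition agreement: 354/400
```

(`--threshold auto` uses the advisory Otsu split, which here cuts
slightly into the broad cartilage cluster — 14 low-analyte cartilage
spectra fall below it; with an in-gap θ as above the separation is
perfect. The broadband and sparse label vectors agree almost everywhere
even under the advisory threshold, and exactly when θ lies in the gap.)

Other subcommands: `simulate`, `preclassify`, `subset`, `snr`, `pca`
(`irpreclass COMMAND --help` for options). Every command writes a JSON
copy of its resolved configuration next to its outputs and is
byte-identical on rerun.

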