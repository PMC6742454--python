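# hemcyto

Quantitative imaging cytometry at very low magnification ("cell
astronomy"). At ≈3 µm per pixel a fluorescently labeled cell occupies
only 3–7 pixels, which makes high-throughput slide imaging cheap but
turns quantification into an astronomy-style photometry problem with
severe partial-volume effects, low SNR, and unresolved cell clusters.
`hemcyto` is for people building or evaluating such low-magnification
cytometers who need per-cell fluorescence *and* physical diameter —
the pair of biomarkers that separates, e.g., lymphocytes, monocytes and
granulocytes in CD45-labeled blood, where fluorescence alone cannot.

## What it does

1. **Detection** — a sliding-window linear discriminant (LDA, shared
   pooled covariance, min–max normalized 15×15 windows) scores every
   pixel; the threshold is cross-validated to hold a ≥99% true-positive
   rate; 8-connected supra-threshold blobs become events.
2. **Heterogeneous-mixture EM photometry** — each event patch is fit by
   N bivariate Gaussians (cells) plus one uniform component
   (background) with an intensity-weighted EM: responsibilities

       z_c(x) = π_c f_c(x) / Σ_n π_n f_n(x)

   are computed once per pixel and every M-step sum weights pixel x by
   its photon count I(x). Per cell, fluorescence is
   F_c = Σ_x z_c(x) I(x) and diameter is
   pixel_size · 2√(2 ln 2) · |Σ_c|^¼ (the FWHM of the fitted Gaussian).
3. **QC and cluster splitting** — implausible fits are rejected from the
   covariance alone (too small / too large / degenerate); clustered
   events are resolved by deterministic recursive splitting along the
   leading covariance eigenvector (offset √λ_max), with a
   residual-guided reseed for strong brightness contrasts, accepted only
   when the BIC k·ln(Σ I) − 2L improves by more than a threshold.

A seeded simulator (`hemcyto.simgen`) renders bead fields, cell fields
and small clusters with exact ground truth in the same imaging regime,
so the whole pipeline is testable without any dataset. See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
from hemcyto import detector as det_mod, pipeline as pipe_mod, simgen

model = det_mod.train_calibrated_detector(seed=42)      # simulated labels
image, truth = simgen.scatter_field(12, snr=20.0, seed=7, image_size=(256, 256))
table = pipe_mod.run_pipeline(image, model, image_id="demo")
valid = table[table.qc_status == "valid"]
print(f"{table.event_id.nunique()} events detected, {len(valid)} valid cells")
print(valid[["row", "col", "fluorescence", "diameter_um"]].head(3).round(2).to_string(index=False))
```

prints

```
12 events detected, 12 valid cells
  row    col  fluorescence  diameter_um
 9.71 204.10        947.72         8.21
59.61  46.49        949.76         7.82
69.18 114.38        882.69         8.00
```

All 12 simulated spots (894 expected photons each, true diameter
7.5 µm) are detected; the mean recovered fluorescence is 872.6
intensity units and the mean recovered diameter 7.73 µm — photometry
within a few percent at SNR 20 even though each "cell" spans barely
4 pixels. `pipe_mod.plot_scatter(table, "scatter.png")` writes the
cytometry-style fluorescence-vs-diameter scatter.

From the shell, the same pipeline is:

```
hem simulate field --seed 7 --n 12 --snr 20 --out sim/
hem train-detector --labels labels.csv --out model.json   # or use the API above
hem run --image sim/field.tif --model model.json --out results/
hem check-table1
```

`hem check-table1` recomputes the bead-calibration linearity worked
example from the built-in constants (three tier-mean fluorescences vs
three reference bead intensities) and prints `R^2 = 0.9998`.

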