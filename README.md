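# duodose

Healthy-liver segmentation and voxel dosimetry for holmium-166 (¹⁶⁶Ho)
microsphere liver radioembolization, built around the ¹⁶⁶Ho–⁹⁹ᵐTc
dual-isotope SPECT protocol.

## The problem

Radioembolization dosimetry needs an accurate healthy-liver volume of
interest (VOI). The clinical standard — manual delineation on a separately
acquired contrast-enhanced CT, followed by manual rigid registration onto
the SPECT/CT — is slow (tens of minutes per patient) and prone to
registration error and inter-observer variability. In the dual-isotope
protocol, [⁹⁹ᵐTc]-stannous–phytate accumulates in Kupffer cells, which
exist only in healthy liver parenchyma (and the spleen). A ⁹⁹ᵐTc SPECT
acquired simultaneously with the therapeutic ¹⁶⁶Ho SPECT is therefore a
physiological map of healthy tissue, *intrinsically registered* to the
dose-bearing image — so the healthy liver can be segmented automatically,
with no registration step at all.

This package implements that workflow end to end, for people studying
segmentation/dosimetry methodology rather than treating patients:

* **automatic segmentation** — after removing the (also Tc-avid) spleen,
  the maximum of a Gaussian-smoothed copy of the ⁹⁹ᵐTc image is found and
  the *original* image is thresholded at 40% of that maximum;
* **manual-reference VOI** — liver minus tumors with diameter > 1 cm minus
  necrotic tissue, degraded by a rigid misregistration model in synthetic
  studies;
* **voxel dosimetry** — local-deposition model,
  `Dose [Gy] = 15.87 [mJ/MBq] · C [MBq/ml] / ρ [g/ml]` with ρ = 1.06 g/ml,
  where the ¹⁶⁶Ho counts are scaled to MBq/ml by the administered activity
  within an automatically delineated body mask;
* **DVH metrics** — mean dose, D₇₀ (minimum dose to the hottest 70% of the
  VOI), V₅₀ (percentage of the VOI receiving ≥ 50 Gy);
* **agreement statistics** — Sørensen–Dice coefficient, Hausdorff distance,
  volume difference, Bland–Altman with coefficient of reproducibility
  (1.96 × SD of paired differences), Pearson correlation, two-sided paired
  t test, and per-grade hepatotoxicity summaries with a Spearman
  dose–grade correlation;
* **a synthetic SPECT phantom** (ellipsoidal liver/spleen, spherical
  tumors with necrotic cores, Gaussian PSF blur, Poisson count noise) that
  exercises the whole pipeline with known ground truth.

## Worked example

A single synthetic comparison run — phantom, dual-isotope SPECT simulation,
both segmentation arms, dosimetry, agreement report:

```bash
duodose run --seed 1 --outdir demo
```

prints

```
{"dice": 0.8173032246073785, "hausdorff_cm": 1.662768775266122, "volume_difference_ml": 40.03430400000002}
```

and writes `demo/report.json` containing (abridged):

```json
{
  "automatic": {"volume_ml": 1210.1, "mean_dose_gy": 58.06, "d70_gy": 55.99, "v50_pct": 79.54},
  "manual":    {"volume_ml": 1170.1, "mean_dose_gy": 53.34, "d70_gy": 54.24, "v50_pct": 73.62},
  "comparison": {"dice": 0.817, "hausdorff_cm": 1.66, "volume_difference_ml": 40.03},
  "truth": {"healthy_volume_ml": 1171.5, "true_mean_dose_gy": 61.72,
            "dice_auto_vs_truth": 0.984, "dice_manual_vs_truth": 0.814}
}
```

Reading: the automatic mask recovers the true healthy liver almost exactly
(Dice 0.98 against ground truth), while the "manual" arm — the true VOI
degraded by the default (8, 4, 12) mm + 3° rigid misregistration — overlaps
the automatic mask at Dice 0.82. The automatic arm reports a 4.7 Gy higher
mean healthy-liver dose here, because the misregistered manual VOI leaks
out of the liver into cold surroundings. Masks, the dose map and per-arm
cumulative DVH tables are written alongside the report.

Other subcommands: `duodose phantom` (write truth maps and simulated
counts), `duodose segment`, `duodose dose`, `duodose compare`,
`duodose cohort` (seeded multi-run studies with Bland–Altman/Pearson/t
aggregation). The library API mirrors the CLI (`duodose.make_phantom`,
`automatic_healthy_mask`, `dose_from_concentration`, `run_comparison`, …).

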