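# petbias

Quantifies the bias that contrast-enhanced CT (CE-CT) attenuation correction
introduces into PET SUV measurements, relative to a low-dose attenuation-only
CT (AC-CT), and propagates that bias into rule-based Deauville response
scoring for lymphoma lesions.

Because the underlying clinical data are not publicly available, the package
ships a first-class synthetic generator that reproduces the statistical
structure of the published cohort (21 patients, 18 with lesions, 66 lesions;
organ attenuation and SUV distributions; tissue-specific multiplicative bias
medians) and exercises the full analysis on it.

## What is in the box

| module | purpose |
| --- | --- |
| `petbias.synthetic` | seeded cohort generator (tabular mode), piecewise-constant voxel phantoms (volume mode), optional line-integral physics mode (`lor_bias_field`) |
| `petbias.attenuation` | bilinear HU → μ(511 keV) conversion, per-organ mean attenuation from label masks, missing-slice in-fill from the AC-CT, paired μ-change tables |
| `petbias.voi` | spheroid VOIs, 41 %-of-max isocontour VOIs, cross-reconstruction VOI copying, SUVmax/SUVmean/volume extraction, body-weight SUV scaling |
| `petbias.stats` | percent changes, median/MAD/IQR/whisker summaries, exact + normal-approximation Wilcoxon signed-rank, Pearson/Spearman correlation, histogram + KDE curves |
| `petbias.deauville` | SUV ratios, rule-based Deauville scores (2/3/4), OLS fit of the AC-on-CE ratio relation, Gaussian prediction-interval misclassification probabilities, risk flags and score-change tables |
| `petbias.pipeline` / `petbias.cli` | end-to-end simulate → measure → stats → deauville runs with deterministic, manifest-stamped report bundles |

## CLI

```sh
# full synthetic run: all report tables + manifest into out/
petbias run-all --seed 1 --out out/

# individual stages
petbias simulate --seed 1 --out sim/              # cohort + truth tables (add --volumes for NIfTI phantoms)
petbias stats --measurements sim/measurements.csv --out stats/
petbias deauville --measurements sim/measurements.csv \
    --fit-out fit.json --curves-out curves.csv
petbias report --measurements sim/measurements.csv --out report/
petbias measure --pet-ac ac.nii.gz --pet-ce ce.nii.gz --vois vois.json --out m.csv
```

`run-all` accepts a YAML config mirroring `petbias.pipeline.RunConfig`
(generator calibration constants, phantom geometry, volume mode, SUVR
denominator metric, Wilcoxon alternatives, risk α). Identical config + seed
produces byte-identical CSV outputs; the manifest records the seed and a
SHA-256 of the resolved configuration.

Report bundle contents: `mu_table.csv` (per-organ paired attenuation),
`suv_table.csv` (paired SUV summaries with Wilcoxon p-values),
`suvr_table.csv` and `suvr_records.csv` (lesion-to-reference ratios),
`correlation_table.csv` (Δμ% vs ΔSUVmax%), `risk_curves.csv` + `fits.json`
(misclassification probabilities over observed SUVR), `score_changes.json`,
and the ground-truth tables behind the synthetic cohort.

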