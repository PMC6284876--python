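# radtex

Mask-aware 2D radiomic texture analysis for discriminating brain-tumor
tissue from peritumoral edema on MRI regions of interest.

## The problem

In small prospective imaging studies, two readers contour two regions of
interest (ROIs) — tumor and peritumoral edema — per patient on each MR
pulse sequence (FLAIR, ADC, T1W, T1W+C, T2W), and the question is which of
several hundred quantitative texture features separates the two tissues,
per disease (glioblastoma vs meningioma) and per normalization scenario.
`radtex` implements that pipeline end to end for Python users:

* **extraction** — first-order histogram/gradient statistics, 22
  gray-level co-occurrence (GLCM) statistics at distances d = 1..5 and
  angles θ = 0°, 45°, 90°, 135° (regular + transpose summed, so the matrix
  is symmetric), and 13 gray-level run-length (GLRLM) statistics at the
  four angles — 512 named features per ROI, all computed strictly inside
  an arbitrary binary mask;
* **preprocessing** — per-ROI 1%–99% cumulative-histogram normalization
  and equal-width gray-level quantization;
* **selection** — per-reader L1-penalized logistic regression (binomial
  family, logit link) with λ chosen by cross-validated deviance, and a
  two-reader consensus: only features selected by *both* readers survive;
* **evaluation** — Mann–Whitney AUC with DeLong 95% CIs, single-feature
  perfect-classification thresholds, multivariable refit AUCs, and
  Cohen's κ between readers;
* **synthetic cohort** — a generator that emulates the two-tissue,
  two-reader, five-sequence study design with planted ground truth (a
  first-order intensity shift in one disease arm, a pure
  spatial-correlation texture contrast with exactly matched marginal
  histograms in the other), so the whole pipeline is testable without
  patient data.

At the core, the GLCM at displacement (d, θ) is the symmetric probability
matrix P(i, j | d, θ) over quantized gray-level pairs with both pixels
in-mask, from which the classical second-order statistics (contrast
Σ(i−j)²p, correlation, entropy −Σp log₂p, ...) are computed; the GLRLM
r(i, ℓ) counts maximal in-mask runs of level i and length ℓ, satisfying
Σ ℓ·r(i, ℓ) = number of masked pixels along every direction. AUC is
P(score_tumor > score_edema) + ½P(tie). See `docs/methods.md` for every
convention and its rationale.

## Worked example

`examples/04_select_and_evaluate.py` simulates a reduced cohort (8 + 8
patients, two sequences), extracts all features with and without
normalization, runs the two-reader LASSO consensus, and prints the
study-style report:

```
   disease normalization sequence       status            most_useful   auc                               perfect_rule  kappa
       GBM          none    FLAIR           ok GLCM_Correlation_d1_...   1.0 GLCM_Correlation_d1_a000 > 0.509139 (...)    1.0
meningioma          none    FLAIR           ok      HIST_Percentile99   1.0 HIST_Percentile99 > 783.163 (perfectly...)   1.0
meningioma         p1_99    FLAIR no_agreement                     NA   NaN                                              NaN
...
6/8 scenarios reached reader consensus; 'NA' rows mirror the no-agreement reporting convention.
```

Reading the rows: in the GBM arm the generator planted a texture-only
contrast, and the consensus discriminator is a GLCM correlation feature
with AUC 1.0 and a perfect threshold (`> 0.509`: tumor fields are spatially
correlated, edema is white noise). In the meningioma arm the planted signal
is a brightness shift, so a histogram percentile separates the tissues
perfectly in the `>` (tumor-brighter) direction — and after per-ROI [0, 1]
normalization that shift no longer exists, so the readers cannot agree on
any feature and the row is reported `NA`. κ = 1 means the two readers'
rule-based classifications agree on every ROI.

The other examples cover single-ROI feature extraction
(`01_extract_features.py`), ADC-map computation from a b = 0/1000 s/mm²
pair (`02_adc_map.py`), and cohort generation with ground-truth inspection
(`03_simulate_cohort.py`). A thin CLI wraps the same library calls:
`radtex simulate|extract|select|evaluate|run` (see `radtex --help`).

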