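"""Extract texture features from a single masked ROI.

Builds two synthetic 48x48 elliptical ROIs with identical intensity
histograms but different spatial correlation, extracts the full feature
vector from each, and prints features from all three families. First-order
(HIST) values coincide because the marginals are matched; co-occurrence
(GLCM) and run-length (GLRLM) values separate, because only they see the
spatial arrangement.
"""

import numpy as np

from radtex import ROIMeta, elliptical_mask, extract_features, generate_textured_roi

mask = elliptical_mask((48, 48), (14, 12))
meta = ROIMeta("demo", "FLAIR", "tumor", "A", "GBM")

smooth = generate_textured_roi(mean=600, sd=60, corr_len=2.5, mask=mask,
                               rng=np.random.default_rng(1), meta=meta,
                               marginal="rank_gaussian")
rough = generate_textured_roi(mean=600, sd=60, corr_len=0.0, mask=mask,
                              rng=np.random.default_rng(2), meta=meta,
                              marginal="rank_gaussian")

fv_smooth = extract_features(smooth)
fv_rough = extract_features(rough)

print(f"features per ROI: {len(fv_smooth)}")
print(f"{'feature':34s}{'smooth':>12s}{'white':>12s}")
for name in ("HIST_Mean", "HIST_Percentile90", "HIST_Entropy",
             "GLCM_Correlation_d1_a000", "GLCM_Entropy_d1_a000",
             "GLRLM_SRE_a000", "GLRLM_LRE_a000"):
    print(f"{name:34s}{fv_smooth[name]:12.4f}{fv_rough[name]:12.4f}")

print("\nHIST rows match (matched marginals); GLCM correlation ~0.9 vs ~0")
print("and longer runs (higher LRE) reveal the smooth field's texture.")
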