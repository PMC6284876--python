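"""Full per-ROI feature extraction and feature-table assembly.

One ROI yields one row of the feature table: ~20 first-order statistics,
22 co-occurrence statistics at each of 5 distances × 4 angles (440), and
13 run-length statistics at each of 4 angles (52). Column names encode the
family, statistic and displacement (``GLCM_Correlation_d1_a090``), so the
selection stage can be audited feature-by-feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .glcm import ANGLES, DEFAULT_DISTANCES, glcm_feature_block
from .glrlm import glrlm_feature_block
from .histogram import DEFAULT_N_BINS, histogram_features
from .io import ROIImage
from .preprocess import DEFAULT_N_LEVELS, normalize_1_99, quantize
from .vector import FeatureVector

META_COLUMNS = ("patient_id", "sequence", "tissue", "reader", "disease",
                "normalization")
LABEL_COLUMN = "tissue"  # tumor = 1, edema = 0 downstream


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the extraction stage, with the package defaults."""

    n_levels: int = DEFAULT_N_LEVELS
    n_bins: int = DEFAULT_N_BINS
    distances: tuple[int, ...] = DEFAULT_DISTANCES
    angles: tuple[int, ...] = ANGLES
    normalization: str = "none"  # "none" or "p1_99"

    def __post_init__(self) -> None:
        if self.normalization not in ("none", "p1_99"):
            raise ValueError("normalization must be 'none' or 'p1_99'")


def extract_features(roi: ROIImage,
                     config: ExtractionConfig = ExtractionConfig()) -> FeatureVector:
    """Extract the complete feature vector of one ROI under one configuration."""
    work = normalize_1_99(roi) if config.normalization == "p1_99" else roi
    fv = FeatureVector()
    fv.extend(histogram_features(work, n_bins=config.n_bins))
    qroi = quantize(work, n_levels=config.n_levels,
                    mode="normalized" if config.normalization == "p1_99" else "raw_range")
    fv.extend(glcm_feature_block(qroi, distances=config.distances,
                                 angles=config.angles))
    fv.extend(glrlm_feature_block(qroi, angles=config.angles))
    return fv


def feature_table(rois: list[ROIImage],
                  config: ExtractionConfig = ExtractionConfig()) -> pd.DataFrame:
    """Tabulate one extraction configuration over a list of ROIs.

    Rows carry the ROI metadata columns followed by the feature columns;
    undefined-flagged features appear as NaN cells (the selection stage
    drops any column containing NaN, a documented conservative rule).
    """
    rows = []
    for roi in rois:
        row: dict = dict(roi.meta.to_dict())
        row["normalization"] = config.normalization
        row.update(extract_features(roi, config).as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature (non-metadata) columns of a table."""
    return [c for c in table.columns if c not in META_COLUMNS]
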