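"""Synthetic two-tissue, two-reader, multi-sequence cohort generator.

The generator emulates the statistical structure of a small brain-tumor
radiomics study — two contoured tissue regions (tumor and peritumoral
edema) per patient per MR pulse sequence, segmented independently by two
readers — so that every stage of the pipeline can be exercised without
patient data. Two disease arms carry two qualitatively different planted
signals:

* **meningioma arm** — tumor and edema differ by a *first-order* shift:
  the tumor intensity distribution is offset in mean at equal spatial
  correlation length, so histogram features (percentiles, mean)
  discriminate while texture is matched;
* **GBM arm** — tumor and edema have *matched marginals* (the field is
  standardized to identical mean and SD inside the mask) but different
  spatial correlation lengths, so co-occurrence/texture features
  discriminate while histogram percentiles carry no signal by
  construction.

ROIs are elliptical masks with jittered axes; each texture field is white
Gaussian noise smoothed by an isotropic Gaussian kernel of scale
``corr_len``, and the in-mask values of every contoured ROI are rank-mapped
onto an exact Gaussian quantile grid at the target mean/SD, so the marginal
histogram is controlled exactly regardless of correlation length. Reader
B's masks are derived from reader A's by a random morphological erosion or
dilation of up to one pixel, emulating expert boundary disagreement at high
overlap (Dice ≥ 0.8); both readers contour the same acquired field, each
ROI receiving its own marginal-matched sample. The five "sequences" are
independent contrast re-parameterizations of the same slice geometry,
mirroring a replicate-contour-across-sequences design. A ground-truth
ledger records which feature family discriminates in each arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ROIImage, ROIMeta, SEQUENCES

#: per-sequence plausible intensity scales (arbitrary MR units; base mean, SD)
SEQUENCE_CONTRAST = {
    "FLAIR": (600.0, 60.0),
    "ADC": (1.1e-3, 1.2e-4),
    "T1W": (500.0, 50.0),
    "T1W_C": (700.0, 70.0),
    "T2W": (800.0, 80.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the synthetic cohort (defaults = the
    emulated study: 17 GBM + 8 meningioma patients, two readers, five
    sequences, two slices per patient)."""

    n_gbm: int = 17
    n_meningioma: int = 8
    slices_per_patient: int = 2
    sequences: tuple[str, ...] = SEQUENCES
    raster_shape: tuple[int, int] = (64, 64)
    axis_range: tuple[float, float] = (9.0, 14.0)  # ellipse semi-axes, pixels
    first_order_shift: float = 1.5   # tumor mean offset, units of sequence SD
    corr_len_tumor: float = 2.5      # GBM tumor correlation length, pixels
    corr_len_edema: float = 0.0      # GBM edema: white noise
    corr_len_matched: float = 1.0    # both tissues, meningioma arm
    patient_sd: float = 0.2          # per-patient brightness offset, seq SD units
    reader_perturb_max: int = 1      # reader B erosion/dilation radius, pixels
    seed: int = 20181008

    def __post_init__(self) -> None:
        if min(self.n_gbm, self.n_meningioma, self.slices_per_patient) < 1:
            raise ValueError("cohort counts must be positive")
        if min(self.corr_len_tumor, self.corr_len_edema,
               self.corr_len_matched) < 0:
            raise ValueError("correlation lengths must be nonnegative")


@dataclass
class Cohort:
    rois: list[ROIImage]
    ledger: dict

    def subset(self, **criteria) -> list[ROIImage]:
        out = []
        for roi in self.rois:
            meta = roi.meta.to_dict()
            if all(meta[k] == v for k, v in criteria.items()):
                out.append(roi)
        return out


def elliptical_mask(shape: tuple[int, int], semi_axes: tuple[float, float],
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Centered elliptical mask, optionally with a jittered boundary."""
    h, w = shape
    rows = np.arange(h)[:, None] - (h - 1) / 2.0
    cols = np.arange(w)[None, :] - (w - 1) / 2.0
    a, b = semi_axes
    radius = (rows / a) ** 2 + (cols / b) ** 2
    if rng is not None:
        radius = radius + rng.normal(0.0, 0.02, size=radius.shape)
    return radius <= 1.0


def correlated_field(shape: tuple[int, int], corr_len: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian noise field: white noise smoothed at ``corr_len``."""
    if corr_len < 0:
        raise ValueError("corr_len must be nonnegative")
    if corr_len > 0 and 4 * corr_len > min(shape):
        raise ValueError("smoothing kernel larger than the raster")
    white = rng.standard_normal(shape)
    return ndimage.gaussian_filter(white, corr_len) if corr_len > 0 else white


def _masked_rescale(field: np.ndarray, mask: np.ndarray, mean: float, sd: float,
                    marginal: str) -> np.ndarray:
    """Impose the target marginal on the in-mask values of a field.

    ``marginal="moment"`` standardizes the masked sample to exact mean/SD;
    ``marginal="rank_gaussian"`` replaces the masked values, rank for rank,
    by the Gaussian quantile grid ppf((k+½)/n) scaled to mean/SD — the
    within-ROI histogram is then *identical* across correlation lengths
    (exact marginal matching), while the spatial arrangement, and hence the
    co-occurrence structure, is preserved by the monotone map.
    """
    from scipy.stats import norm

    inside = field[mask]
    n = inside.size
    if marginal == "rank_gaussian":
        order = np.empty(n, dtype=np.int64)
        order[np.argsort(inside, kind="stable")] = np.arange(n)
        grid = norm.ppf((np.arange(n) + 0.5) / n)
        grid = (grid - grid.mean()) / grid.std()
        values = mean + sd * grid[order]
    elif marginal == "moment":
        spread = inside.std()
        if spread == 0:
            spread = 1.0
        values = (inside - inside.mean()) / spread * sd + mean
    else:
        raise ValueError("marginal must be 'moment' or 'rank_gaussian'")
    pixels = np.zeros(field.shape)
    pixels[mask] = values
    return pixels


def generate_textured_roi(mean: float, sd: float, corr_len: float,
                          mask: np.ndarray, rng: np.random.Generator,
                          meta: ROIMeta, marginal: str = "moment") -> ROIImage:
    """Correlated-noise ROI with an exactly controlled masked marginal.

    White noise is smoothed with an isotropic Gaussian kernel of scale
    ``corr_len`` (0 → white noise) and the masked values are rescaled to
    the target mean/SD (``marginal="moment"``) or rank-mapped onto an exact
    Gaussian quantile grid (``marginal="rank_gaussian"``) — the
    marginal-matching device the GBM arm relies on.
    """
    field = correlated_field(mask.shape, corr_len, rng)
    pixels = _masked_rescale(field, mask, mean, sd, marginal)
    return ROIImage(pixels=pixels, mask=mask, meta=meta)


def _perturb_mask(mask: np.ndarray, rng: np.random.Generator,
                  max_radius: int) -> np.ndarray:
    """Reader-B mask: random erosion or dilation of up to ``max_radius``."""
    if max_radius < 1:
        return mask.copy()
    radius = int(rng.integers(0, max_radius + 1))
    if radius == 0:
        return mask.copy()
    op = ndimage.binary_erosion if rng.random() < 0.5 else ndimage.binary_dilation
    structure = ndimage.generate_binary_structure(2, 1)
    return op(mask, structure=structure, iterations=radius)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def generate_cohort(spec: CohortSpec = CohortSpec()) -> Cohort:
    """Generate the full two-reader cohort plus its ground-truth ledger.

    For every patient × slice × sequence, one tumor and one edema ROI per
    reader (same intensity raster, reader-specific mask). The ledger
    records the discriminative feature family per arm and the planted
    parameters.
    """
    rng = np.random.default_rng(spec.seed)
    rois: list[ROIImage] = []
    patients = ([("GBM", f"GBM{i + 1:02d}") for i in range(spec.n_gbm)]
                + [("meningioma", f"MEN{i + 1:02d}")
                   for i in range(spec.n_meningioma)])

    for disease, patient_id in patients:
        brightness = rng.normal(0.0, spec.patient_sd)
        for slice_idx in range(spec.slices_per_patient):
            for tissue in ("tumor", "edema"):
                axes = rng.uniform(*spec.axis_range, size=2)
                mask_a = elliptical_mask(spec.raster_shape, tuple(axes), rng)
                for attempt in range(20):
                    mask_b = _perturb_mask(mask_a, rng, spec.reader_perturb_max)
                    if mask_b.sum() >= 16 and dice(mask_a, mask_b) >= 0.8:
                        break
                else:
                    raise RuntimeError("could not perturb mask within Dice bound")

                for sequence in spec.sequences:
                    base_mean, base_sd = SEQUENCE_CONTRAST[sequence]
                    mean = base_mean + brightness * base_sd
                    if disease == "meningioma":
                        corr = spec.corr_len_matched
                        if tissue == "tumor":
                            mean = mean + spec.first_order_shift * base_sd
                    else:  # GBM: matched marginals, texture contrast
                        corr = (spec.corr_len_tumor if tissue == "tumor"
                                else spec.corr_len_edema)
                    pid = f"{patient_id}s{slice_idx + 1}"
                    # one acquired field per slice; each reader's contour
                    # yields its own exactly marginal-matched ROI sample
                    field = correlated_field(spec.raster_shape, corr, rng)
                    meta_a = ROIMeta(patient_id=pid, sequence=sequence,
                                     tissue=tissue, reader="A", disease=disease)
                    roi_a = ROIImage(
                        pixels=_masked_rescale(field, mask_a, mean, base_sd,
                                               "rank_gaussian"),
                        mask=mask_a, meta=meta_a)
                    meta_b = ROIMeta(patient_id=pid, sequence=sequence,
                                     tissue=tissue, reader="B", disease=disease)
                    roi_b = ROIImage(
                        pixels=_masked_rescale(field, mask_b, mean, base_sd,
                                               "rank_gaussian"),
                        mask=mask_b, meta=meta_b)
                    rois.extend([roi_a, roi_b])

    ledger = {
        "discriminative_family": {"meningioma": "HIST", "GBM": "GLCM"},
        "planted": {
            "meningioma": {"first_order_shift_sd": spec.first_order_shift,
                           "corr_len_both": spec.corr_len_matched},
            "GBM": {"corr_len_tumor": spec.corr_len_tumor,
                    "corr_len_edema": spec.corr_len_edema,
                    "marginals": "matched mean/SD inside mask"},
        },
        "counts": {"patients": len(patients),
                   "rois_per_reader": (len(patients) * spec.slices_per_patient
                                       * 2 * len(spec.sequences))},
        "seed": spec.seed,
    }
    return Cohort(rois=rois, ledger=ledger)
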