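"""Reading, writing and deriving region-of-interest images.

A *ROI* is one contoured tissue region on a single 2D MR slice: a float
intensity raster plus a boolean mask of the pixels inside the contour,
tagged with the acquisition and labelling metadata the downstream analysis
stratifies on (patient, pulse sequence, tissue class, reader, disease).

Three on-disk forms are supported behind one contract:

* a plain-text CSV dialect (one CSV raster for the image, one for the mask,
  a JSON sidecar for metadata) — the native fixture format, fully
  round-trippable;
* single-frame DICOM slices (rescale slope/intercept applied);
* NIfTI-1 volumes with a slice index.

The module also computes apparent-diffusion-coefficient (ADC) maps from a
b=0 / b=b1 pair of diffusion-weighted images, and transfers a mask across
co-registered sequences (the study design replicates one contour onto every
sequence of the same slice).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

SEQUENCES = ("FLAIR", "ADC", "T1W", "T1W_C", "T2W")
TISSUES = ("tumor", "edema")
READERS = ("A", "B")
DISEASES = ("GBM", "meningioma")

#: smallest mask for which texture features are considered defined
MIN_ROI_PIXELS = 16


class FormatError(ValueError):
    """Raised when an input file or raster pair violates the format contract."""


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but analytically unusable."""


class RegistrationError(ValueError):
    """Raised when a mask cannot be transferred between two pixel grids."""


@dataclass(frozen=True)
class ROIMeta:
    patient_id: str
    sequence: str
    tissue: str
    reader: str
    disease: str

    def __post_init__(self) -> None:
        for value, allowed, name in (
            (self.sequence, SEQUENCES, "sequence"),
            (self.tissue, TISSUES, "tissue"),
            (self.reader, READERS, "reader"),
            (self.disease, DISEASES, "disease"),
        ):
            if value not in allowed:
                raise ValueError(f"{name}={value!r} not in {allowed}")

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "sequence": self.sequence,
            "tissue": self.tissue,
            "reader": self.reader,
            "disease": self.disease,
        }


@dataclass
class ROIImage:
    """One tissue region: intensities, mask and labelling metadata."""

    pixels: np.ndarray
    mask: np.ndarray
    meta: ROIMeta
    min_pixels: int = field(default=MIN_ROI_PIXELS, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise FormatError("pixels must be a 2D raster")
        if self.mask.shape != self.pixels.shape:
            raise FormatError(
                f"mask shape {self.mask.shape} != pixel shape {self.pixels.shape}"
            )
        if not np.isfinite(self.pixels[self.mask]).all():
            raise FormatError("non-finite intensities inside the mask")
        n = int(self.mask.sum())
        if n == 0:
            raise DegenerateInputError("empty mask")
        if n < self.min_pixels:
            raise DegenerateInputError(
                f"mask has {n} pixels, below the floor of {self.min_pixels}"
            )

    @property
    def masked_values(self) -> np.ndarray:
        """Intensities inside the mask, as a flat array."""
        return self.pixels[self.mask]

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def with_pixels(self, pixels: np.ndarray) -> "ROIImage":
        return replace(self, pixels=np.asarray(pixels, dtype=float))


@dataclass(frozen=True)
class ADCInputs:
    """Signal rasters of a two-point diffusion acquisition."""

    s0: np.ndarray  # signal at b = 0 s/mm^2
    sb: np.ndarray  # signal at b = b1
    b1: float = 1000.0  # s/mm^2

    def __post_init__(self) -> None:
        object.__setattr__(self, "s0", np.asarray(self.s0, dtype=float))
        object.__setattr__(self, "sb", np.asarray(self.sb, dtype=float))
        if self.s0.shape != self.sb.shape:
            raise FormatError("b=0 and b=b1 rasters differ in shape")
        if self.b1 <= 0:
            raise ValueError("b1 must be positive")


# ---------------------------------------------------------------------------
# CSV fixture dialect
# ---------------------------------------------------------------------------

def _read_csv_raster(path: Path) -> np.ndarray:
    try:
        arr = np.loadtxt(path, delimiter=",", ndmin=2, dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: not a rectangular CSV raster ({exc})") from exc
    return arr


def _write_csv_raster(path: Path, arr: np.ndarray) -> None:
    np.savetxt(path, np.asarray(arr, dtype=float), delimiter=",", fmt="%.17g")


def _read_dicom_slice(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-frame 2D DICOM image")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept


def _read_nifti_slice(path: Path, slice_index: int) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 2:
        return data
    if data.ndim == 3:
        return data[:, :, slice_index]
    raise FormatError(f"{path}: unsupported NIfTI dimensionality {data.ndim}")


def _read_raster(path: str | Path, slice_index: int = 0) -> np.ndarray:
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        return _read_nifti_slice(path, slice_index)
    if suffix.endswith((".dcm", ".dicom")):
        return _read_dicom_slice(path)
    if suffix.endswith(".csv"):
        return _read_csv_raster(path)
    # fall back on content sniffing: DICOM preamble magic
    with open(path, "rb") as fh:
        head = fh.read(132)
    if head[128:132] == b"DICM":
        return _read_dicom_slice(path)
    return _read_csv_raster(path)


def read_roi(
    image_path: str | Path,
    mask_path: str | Path,
    meta: ROIMeta | dict,
    *,
    slice_index: int = 0,
    min_pixels: int = MIN_ROI_PIXELS,
) -> ROIImage:
    """Read an intensity raster and its mask into a validated :class:`ROIImage`.

    The mask raster is interpreted as nonzero = inside the ROI. Formats are
    dispatched on extension (``.csv``, ``.dcm``, ``.nii``/``.nii.gz``) with a
    DICOM magic-number fallback.
    """
    if isinstance(meta, dict):
        meta = ROIMeta(**meta)
    pixels = _read_raster(image_path, slice_index)
    mask_raw = _read_raster(mask_path, slice_index)
    if mask_raw.shape != pixels.shape:
        raise FormatError(
            f"mask raster {mask_raw.shape} does not match image {pixels.shape}"
        )
    return ROIImage(pixels=pixels, mask=mask_raw != 0, meta=meta, min_pixels=min_pixels)


def write_roi(roi: ROIImage, image_path: str | Path, mask_path: str | Path,
              meta_path: str | Path | None = None) -> None:
    """Write a ROI in the CSV fixture dialect (bit-exact round trip)."""
    _write_csv_raster(Path(image_path), roi.pixels)
    _write_csv_raster(Path(mask_path), roi.mask.astype(float))
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(roi.meta.to_dict(), indent=1) + "\n")


def read_roi_fixture(prefix: str | Path) -> ROIImage:
    """Read ``<prefix>.image.csv`` / ``<prefix>.mask.csv`` / ``<prefix>.meta.json``."""
    prefix = Path(prefix)
    meta = json.loads(Path(f"{prefix}.meta.json").read_text())
    return read_roi(f"{prefix}.image.csv", f"{prefix}.mask.csv", meta)


def write_roi_fixture(roi: ROIImage, prefix: str | Path) -> None:
    prefix = Path(prefix)
    write_roi(roi, f"{prefix}.image.csv", f"{prefix}.mask.csv", f"{prefix}.meta.json")


# ---------------------------------------------------------------------------
# Mask transfer and ADC
# ---------------------------------------------------------------------------

def transfer_mask(
    source: ROIImage,
    target_pixels: np.ndarray,
    meta: ROIMeta | None = None,
    *,
    max_size_change: float = 0.20,
) -> ROIImage:
    """Replicate a contoured mask onto a co-registered raster.

    Same-grid targets receive the identical boolean mask. A target on a
    different (but axis-aligned, same field-of-view) grid gets the mask
    resampled by nearest neighbour; the transfer is rejected if the resampled
    mask area deviates from the source area by more than ``max_size_change``
    (fractional, relative to the rescaled expectation).
    """
    target_pixels = np.asarray(target_pixels, dtype=float)
    if target_pixels.ndim != 2:
        raise FormatError("target must be a 2D raster")
    meta = meta if meta is not None else source.meta

    if target_pixels.shape == source.mask.shape:
        return ROIImage(pixels=target_pixels, mask=source.mask.copy(), meta=meta,
                        min_pixels=source.min_pixels)

    src_h, src_w = source.mask.shape
    tgt_h, tgt_w = target_pixels.shape
    # nearest-neighbour resample assuming both grids span the same extent
    rows = np.minimum((np.arange(tgt_h) * src_h) // tgt_h, src_h - 1)
    cols = np.minimum((np.arange(tgt_w) * src_w) // tgt_w, src_w - 1)
    new_mask = source.mask[np.ix_(rows, cols)]
    if not new_mask.any():
        raise RegistrationError("transferred mask is empty: grids do not overlap")

    scale = (tgt_h * tgt_w) / (src_h * src_w)
    expected = source.mask.sum() * scale
    if abs(new_mask.sum() - expected) > max_size_change * expected:
        raise RegistrationError(
            f"transferred mask area {new_mask.sum()} deviates more than "
            f"{max_size_change:.0%} from expectation {expected:.1f}"
        )
    return ROIImage(pixels=target_pixels, mask=new_mask, meta=meta,
                    min_pixels=source.min_pixels)


def compute_adc(inputs: ADCInputs, epsilon: float | None = None) -> np.ndarray:
    """Voxelwise apparent diffusion coefficient from a b=0 / b=b1 signal pair.

    ADC = ln(S0 / Sb) / b1, in mm^2/s, with both signals floored at ``epsilon``
    to keep the logarithm finite where the diffusion-weighted signal vanishes.
    When ``epsilon`` is None it defaults to 1e-6 of the median b=0 signal
    (falling back to 1e-6 absolute on an all-zero raster).
    """
    s0, sb = inputs.s0, inputs.sb
    if (s0 < 0).any() or (sb < 0).any():
        raise DegenerateInputError("negative MR signal values")
    if epsilon is None:
        med = float(np.median(s0))
        epsilon = 1e-6 * med if med > 0 else 1e-6
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return np.log(np.maximum(s0, epsilon) / np.maximum(sb, epsilon)) / inputs.b1
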