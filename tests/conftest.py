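import numpy as np
import pytest

from radtex.io import ROIImage, ROIMeta


@pytest.fixture
def meta():
    return ROIMeta(patient_id="p01", sequence="FLAIR", tissue="tumor",
                   reader="A", disease="GBM")


@pytest.fixture
def make_roi(meta):
    """Factory: ROIImage from a pixel array (full mask unless given)."""

    def _make(pixels, mask=None, **meta_overrides):
        pixels = np.asarray(pixels, dtype=float)
        if mask is None:
            mask = np.ones(pixels.shape, dtype=bool)
        m = meta
        if meta_overrides:
            m = ROIMeta(**{**meta.to_dict(), **meta_overrides})
        return ROIImage(pixels=pixels, mask=np.asarray(mask, dtype=bool),
                        meta=m, min_pixels=1)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20181008)
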