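import numpy as np
import pytest

from pvs_sas.io_formats import BinaryMask2D, Slice2D, VolumeGeometry


@pytest.fixture
def geom_small():
    return VolumeGeometry(n_rows=64, n_cols=64, n_slices=1)


@pytest.fixture
def make_slice(geom_small):
    def _make(pixels, slice_index=0, geom=None):
        pixels = np.asarray(pixels, dtype=float)
        g = geom or VolumeGeometry(
            n_rows=pixels.shape[0], n_cols=pixels.shape[1], n_slices=1
        )
        return Slice2D(pixels, slice_index, g)

    return _make


@pytest.fixture
def make_mask():
    def _make(pixels, slice_index=0, geom=None):
        pixels = np.asarray(pixels).astype(bool)
        g = geom or VolumeGeometry(
            n_rows=pixels.shape[0], n_cols=pixels.shape[1], n_slices=1
        )
        return BinaryMask2D(pixels, slice_index, g)

    return _make


@pytest.fixture(scope="session")
def tiny_phantom():
    """A small, fast phantom shared across tests (2 slices, 8 structures each)."""
    from pvs_sas.synthetic_phantom import PhantomParams, generate_phantom

    params = PhantomParams(
        n_slices=2, image_shape=(256, 256), wm_semi_axes_mm=(20.0, 20.0),
        n_pvs_per_slice=8, seed=42,
    )
    slices, wm_masks, truth = generate_phantom(params)
    return params, slices, wm_masks, truth
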