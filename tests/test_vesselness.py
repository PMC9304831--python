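import numpy as np
import pytest

from _oracles import frangi_oracle
from pvs_sas.io_formats import BinaryMask2D, VolumeGeometry
from pvs_sas.vesselness import (
    HessianEigen,
    VesselnessParams,
    build_scale_list,
    frangi_multiscale,
    hessian_at_scale,
    normalize_intensity,
    vesselness_at_scale,
)


class TestNormalizeIntensity:
    def test_affine_span(self, make_slice, make_mask):
        rng = np.random.default_rng(0)
        img = rng.uniform(100, 600, size=(64, 64))
        mask = np.ones((64, 64), bool)
        out = normalize_intensity(make_slice(img), make_mask(mask))
        assert out.pixels.min() == 0.0
        assert out.pixels.max() == pytest.approx(1.0, abs=0.05)

    def test_lower_clip_no_negatives(self, make_slice, make_mask):
        rng = np.random.default_rng(1)
        img = rng.normal(0, 5, size=(32, 32))
        out = normalize_intensity(make_slice(img), make_mask(np.ones((32, 32), bool)))
        assert out.pixels.min() >= 0.0

    def test_bright_structures_exceed_one(self, make_slice, make_mask):
        """The top is open: rare bright structure pixels map above 1."""
        img = np.full((50, 50), 10.0)
        img += np.random.default_rng(2).normal(0, 0.5, img.shape)
        img[25, :] = np.linspace(40.0, 60.0, 50)  # bright line, 2% of pixels
        out = normalize_intensity(make_slice(img), make_mask(np.ones((50, 50), bool)))
        assert out.pixels[25, 49] > 1.0

    def test_idempotent_up_to_percentile_trim(self, make_slice, make_mask):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, size=(64, 64))
        mask = make_mask(np.ones((64, 64), bool))
        once = normalize_intensity(make_slice(img), mask)
        twice = normalize_intensity(make_slice(once.pixels), mask)
        assert np.abs(twice.pixels - once.pixels).max() < 0.06

    def test_constant_image_rejected(self, make_slice, make_mask):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_intensity(
                make_slice(np.full((16, 16), 7.0)), make_mask(np.ones((16, 16), bool))
            )

    def test_empty_mask_rejected(self, make_slice, make_mask):
        with pytest.raises(ValueError, match="empty"):
            normalize_intensity(
                make_slice(np.zeros((8, 8))), make_mask(np.zeros((8, 8), bool))
            )


class TestHessianAtScale:
    def test_constant_image_zero_curvature(self, make_slice):
        eig = hessian_at_scale(make_slice(np.full((32, 32), 3.0)), 1.4)
        assert np.abs(eig.lambda1).max() < 1e-12
        assert np.abs(eig.lambda2).max() < 1e-12

    def test_magnitude_ordering(self, make_slice):
        rng = np.random.default_rng(4)
        eig = hessian_at_scale(make_slice(rng.normal(size=(48, 48))), 2.0)
        assert (np.abs(eig.lambda1) <= np.abs(eig.lambda2) + 1e-15).all()
        assert (eig.s >= 0).all()

    def test_bright_ridge_crest_eigenvalues(self, make_slice):
        """On the crest of a bright Gaussian ridge: lambda2 < 0, lambda1 ~ 0,
        and lambda2 matches the analytic gamma-normalized second derivative."""
        w, amp, sigma = 3.0, 1.0, 2.0
        rows = np.arange(80, dtype=float)
        profile = amp * np.exp(-((rows - 40.0) ** 2) / (2 * w * w))
        img = np.tile(profile[:, None], (1, 80))
        eig = hessian_at_scale(make_slice(img), sigma)
        crest = eig.lambda2[40, 40]
        # Gaussian ridge convolved with Gaussian: sd -> sqrt(w^2 + sigma^2);
        # second derivative at the crest = -A' / s'^2 with A' the smoothed amplitude
        s_eff = np.sqrt(w * w + sigma * sigma)
        expect = -(sigma**2) * amp * (w / s_eff) / s_eff**2
        assert crest == pytest.approx(expect, rel=5e-3)
        assert abs(eig.lambda1[40, 40]) < 1e-6 * abs(crest)

    def test_eigenvalues_match_per_pixel_eigvalsh(self, make_slice):
        """Closed-form 2x2 eigenvalues equal numpy's symmetric eigensolver."""
        rng = np.random.default_rng(5)
        img = rng.normal(size=(32, 32))
        sigma = 1.4
        eig = hessian_at_scale(make_slice(img), sigma)
        from pvs_sas.vesselness import _derivative_kernels, _sep_filter

        g, g1, g2 = _derivative_kernels(sigma)
        h_rr = _sep_filter(img, g2, g) * sigma**2
        h_cc = _sep_filter(img, g, g2) * sigma**2
        h_rc = _sep_filter(img, g1, g1) * sigma**2
        for i in range(0, 32, 5):
            for j in range(0, 32, 5):
                e = np.linalg.eigvalsh(
                    np.array([[h_rr[i, j], h_rc[i, j]], [h_rc[i, j], h_cc[i, j]]])
                )
                got = sorted([eig.lambda1[i, j], eig.lambda2[i, j]])
                assert got == pytest.approx(sorted(e), abs=1e-10)


class TestVesselnessFormula:
    def _eig(self, l1, l2):
        l1 = np.asarray(l1, float)
        l2 = np.asarray(l2, float)
        s = np.sqrt(l1**2 + l2**2)
        rb = np.where(l2 != 0, l1 / np.where(l2 != 0, l2, 1), 0.0)
        return HessianEigen(l1, l2, rb, s, sigma=1.0)

    def test_zero_fields_zero_response(self):
        v = vesselness_at_scale(self._eig(np.zeros((4, 4)), np.zeros((4, 4))))
        assert (v == 0).all()

    def test_wrong_polarity_suppressed(self):
        v = vesselness_at_scale(self._eig([[0.0]], [[5.0]]), polarity="bright_on_dark")
        assert v[0, 0] == 0.0
        v = vesselness_at_scale(self._eig([[0.0]], [[-5.0]]), polarity="dark_on_bright")
        assert v[0, 0] == 0.0

    def test_isotropic_blob_suppression_factor(self):
        """lambda1 = lambda2 < 0 gives R_B = 1: response is exp(-1/(2*0.95^2))
        times the structureness term, vs ~1x for an ideal ridge of equal S."""
        c = 50.0
        blob = vesselness_at_scale(self._eig([[-c]], [[-c]]))[0, 0]
        ridge_s_matched = vesselness_at_scale(self._eig([[0.0]], [[-c * np.sqrt(2)]]))[0, 0]
        assert blob / ridge_s_matched == pytest.approx(np.exp(-1 / (2 * 0.95**2)), rel=1e-9)

    def test_ideal_ridge_limit(self):
        v = vesselness_at_scale(self._eig([[0.0]], [[-1e4]]))
        assert v[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(6)
        l2 = -rng.exponential(1.0, (20, 20))
        l1 = l2 * rng.uniform(-1, 1, (20, 20))
        swap = np.abs(l1) > np.abs(l2)
        l1b = np.where(swap, l2, l1)
        l2b = np.where(swap, l1, l2)
        v = vesselness_at_scale(self._eig(l1b, l2b))
        assert (v >= 0).all() and (v <= 1).all()


class TestMultiscale:
    def test_default_scale_list(self):
        assert build_scale_list(VesselnessParams()) == [1.4, 3.2]

    def test_single_scale_degenerate(self, make_slice):
        rng = np.random.default_rng(7)
        img = rng.normal(size=(32, 32))
        p = VesselnessParams(scale_min_px=2.0, scale_max_px=2.0)
        assert build_scale_list(p) == [2.0]
        single = vesselness_at_scale(hessian_at_scale(make_slice(img), 2.0))
        multi = frangi_multiscale(make_slice(img), p).values
        np.testing.assert_allclose(multi, single, atol=1e-15)

    def test_max_dominates_each_scale(self, make_slice):
        rng = np.random.default_rng(8)
        img = rng.normal(size=(48, 48))
        s = make_slice(img)
        multi = frangi_multiscale(s, VesselnessParams()).values
        for sigma in (1.4, 3.2):
            single = vesselness_at_scale(hessian_at_scale(s, sigma))
            assert (multi >= single - 1e-15).all()

    def test_offset_invariance(self, make_slice):
        rng = np.random.default_rng(9)
        img = rng.normal(size=(40, 40))
        a = frangi_multiscale(make_slice(img)).values
        b = frangi_multiscale(make_slice(img + 37.5)).values
        assert np.abs(a - b).max() < 1e-8

    def test_rotation_equivariance(self, make_slice):
        rng = np.random.default_rng(10)
        img = rng.normal(size=(40, 40))
        a = frangi_multiscale(make_slice(np.rot90(img).copy())).values
        b = np.rot90(frangi_multiscale(make_slice(img)).values)
        assert np.abs(a - b).max() < 1e-8

    def test_matches_brute_force_oracle(self, make_slice):
        """Full-field equality with the explicit-kernel per-pixel oracle."""
        rng = np.random.default_rng(11)
        img = rng.normal(size=(64, 64))
        got = frangi_multiscale(make_slice(img)).values
        want = frangi_oracle(img, [1.4, 3.2])
        assert np.abs(got - want).max() < 1e-8

    def test_phantom_centerlines_beat_background(self, tiny_phantom):
        """Mean vesselness on truth structures exceeds the 99th percentile
        of vesselness on structure-free white matter."""
        from pvs_sas.mask_prep import prep_mask

        params, slices, wm_masks, truth = tiny_phantom
        s, m = slices[0], wm_masks[0]
        prepped, interior = prep_mask(m)
        norm = normalize_intensity(s, prepped)
        v = frangi_multiscale(norm).values
        on_truth = v[truth.labels[0] > 0]
        off = v[interior.pixels & (truth.labels[0] == 0)]
        assert on_truth.mean() > np.percentile(off, 99)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(scale_min_px=0.0), dict(scale_min_px=3.0, scale_max_px=2.0),
         dict(scale_step_px=0.0), dict(beta1=0.0), dict(polarity="sideways")],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VesselnessParams(**kwargs)
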