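import numpy as np
import pytest

from nanorheo.fvmap import (
    NO_DATA_RGB,
    QUALITY_PREPROCESS_FAILED,
    encode_channels,
    PhantomSpec,
    NanomechMap,
    QUALITY_INFERENCE_FAILED,
    build_fields,
    compositional_map,
    decode_compositional,
    process_force_volume,
    synth_force_volume,
)


class TestPhantom:
    def test_uniform_phantom_identical_pixels(self):
        fv, truth = synth_force_volume(
            PhantomSpec(kind="uniform", nx=5, ny=4), seed=0, n_points=101
        )
        assert np.all(fv.F == fv.F[0, 0])
        assert np.all(fv.I == fv.I[0, 0])
        assert truth["n_clamped"] == 0

    def test_two_region_field_values_exact(self):
        spec = PhantomSpec(kind="two-region", nx=32, ny=32)
        E0, gamma, h = build_fields(spec)
        assert set(np.unique(E0)) == {spec.E0_nucleus, spec.E0_background}
        assert set(np.unique(gamma)) == {spec.gamma_nucleus, spec.gamma_background}
        assert np.all(h == spec.h_peak)
        nucleus = E0 == spec.E0_nucleus
        assert 0 < nucleus.sum() < nucleus.size

    def test_dome_margin_pixels_clamped_at_expected_count(self):
        import math

        spec = PhantomSpec(kind="dome", nx=16, ny=16, I_max=3e-6)
        fv, truth = synth_force_volume(spec, seed=0, n_points=61)
        # direct geometric computation of how many pixels need clamping
        from nanorheo.fvmap import RHO_CLAMP

        expected = int(
            np.sum(truth["height"] < math.tan(spec.theta) * spec.I_max / RHO_CLAMP)
        )
        assert truth["n_clamped"] == expected
        assert expected > 0
        assert np.all(fv.I_max > 0)

    def test_deterministic(self):
        spec = PhantomSpec(kind="dome", nx=6, ny=6)
        a, _ = synth_force_volume(spec, seed=5, n_points=61)
        b, _ = synth_force_volume(spec, seed=5, n_points=61)
        assert np.array_equal(a.F, b.F)


@pytest.fixture(scope="module")
def uniform_volume():
    return synth_force_volume(
        PhantomSpec(kind="uniform", nx=4, ny=4), seed=1, n_points=201
    )


class TestProcessing:
    def test_fit_engine_recovers_uniform_phantom(self, uniform_volume):
        fv, truth = uniform_volume
        nmap = process_force_volume(fv, engine="fit")
        assert nmap.mask.sum() == 0
        assert np.allclose(nmap.E0, truth["E0"], rtol=1e-3)
        assert np.allclose(nmap.gamma, truth["gamma"], atol=1e-3)
        for key in ("loading_s", "preprocessing_s", "parameter_inference_s",
                    "other_s"):
            assert key in nmap.timings

    def test_pixel_order_shuffle_invariance(self, uniform_volume):
        fv, _ = uniform_volume
        a = process_force_volume(fv, engine="fit")
        order = np.random.default_rng(0).permutation(16)
        b = process_force_volume(fv, engine="fit", pixel_order=order)
        assert np.array_equal(a.E0, b.E0)
        assert np.array_equal(a.gamma, b.gamma)
        assert np.array_equal(a.quality, b.quality)

    def test_failures_mask_instead_of_abort(self, uniform_volume):
        fv, _ = uniform_volume
        broken = synth_force_volume(
            PhantomSpec(kind="uniform", nx=4, ny=4), seed=1, n_points=201
        )[0]
        broken.F[2, 3] = np.nan  # corrupt one pixel
        nmap = process_force_volume(broken, engine="fit")
        assert nmap.quality[2, 3] == QUALITY_PREPROCESS_FAILED  # NaN force fails curve validation
        assert np.isnan(nmap.E0[2, 3])
        assert nmap.mask.sum() == 1
        assert np.isfinite(nmap.E0[0, 0])

    def test_engine_validation(self, uniform_volume):
        fv, _ = uniform_volume
        with pytest.raises(ValueError, match="engine"):
            process_force_volume(fv, engine="bogus")
        with pytest.raises(ValueError, match="model"):
            process_force_volume(fv, engine="sml", model=None)


class TestCompositionalMap:
    def _map(self, E0, gamma, height, quality=None):
        if quality is None:
            quality = np.zeros_like(E0)
        return NanomechMap(E0=E0, gamma=gamma, height=height, quality=quality)

    def test_constant_maps_render_constant(self):
        nmap = self._map(
            np.full((5, 5), 2000.0), np.full((5, 5), 0.3), np.full((5, 5), 3e-6)
        )
        img = compositional_map(nmap, e0_range=(1000.0, 4000.0))
        assert img.shape == (5, 5, 3)
        assert len(np.unique(img.reshape(-1, 3), axis=0)) == 1

    def test_single_pixel_modulus_changes_only_that_pixel(self):
        E0 = np.full((6, 6), 2000.0)
        nmap = self._map(E0, np.full((6, 6), 0.3), np.full((6, 6), 3e-6))
        base = compositional_map(nmap, e0_range=(100.0, 100_000.0))
        E0b = E0.copy()
        E0b[2, 4] = 50_000.0
        bumped = compositional_map(
            self._map(E0b, np.full((6, 6), 0.3), np.full((6, 6), 3e-6)),
            e0_range=(100.0, 100_000.0),
        )
        diff = np.any(base != bumped, axis=-1)
        assert diff[2, 4]
        assert diff.sum() == 1

    def test_round_trip_within_quantization(self):
        rng = np.random.default_rng(3)
        E0 = 10 ** rng.uniform(2, 5, size=(8, 8))
        h = rng.uniform(1e-6, 7e-6, size=(8, 8))
        nmap = self._map(E0, np.full((8, 8), 0.3), h)
        channels = encode_channels(nmap, e0_range=(100.0, 100_000.0))
        hue_n, val_n, mask = decode_compositional(channels)
        expected_hue = (np.log10(E0) - 2.0) / 3.0
        expected_val = (h - h.min()) / (h.max() - h.min())
        assert not mask.any()
        assert np.max(np.abs(hue_n - expected_hue)) <= 1.5 / 255.0
        assert np.max(np.abs(val_n - expected_val)) <= 1.5 / 255.0

    def test_masked_pixels_get_no_data_color(self):
        quality = np.zeros((4, 4))
        quality[1, 2] = QUALITY_INFERENCE_FAILED
        nmap = self._map(
            np.full((4, 4), 2000.0), np.full((4, 4), 0.2),
            np.full((4, 4), 2e-6), quality,
        )
        img = compositional_map(nmap, e0_range=(1000.0, 4000.0))
        assert tuple(img[1, 2] / 255.0) == NO_DATA_RGB
        _, _, mask = decode_compositional(encode_channels(nmap))
        assert mask[1, 2] and mask.sum() == 1
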