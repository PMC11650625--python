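import numpy as np
import pytest

from niend import (
    DiffusionParams,
    Volume3D,
    diffusion_filter,
    highpass,
    orthogonal_filter,
)
from niend.highpass import gaussian_blur_2d

from .oracles import blur_n_times, explicit_sum_diffusion


def toy_volume(rng, shape=(6, 16, 16), scale=100.0):
    return Volume3D(scale * rng.random(shape), dtype_bits="float")


class TestDiffusionFilter:
    def test_single_slice_is_identity(self, rng):
        vol = toy_volume(rng, shape=(1, 8, 8))
        out = diffusion_filter(vol, DiffusionParams(speed_s=1.0))
        np.testing.assert_allclose(out.data[0], vol.data[0], rtol=1e-6)

    def test_all_zero_maps_to_all_zero(self):
        vol = Volume3D(np.zeros((5, 8, 8), np.float32), dtype_bits="float")
        out = diffusion_filter(vol, DiffusionParams(speed_s=1.0))
        assert not out.data.any()

    def test_k_zero_is_identity(self, rng):
        vol = toy_volume(rng)
        out = diffusion_filter(vol, DiffusionParams(speed_s=1.0, k=0.0))
        np.testing.assert_allclose(out.data, vol.data, rtol=1e-6)

    def test_recursion_matches_explicit_sum_oracle(self, rng):
        """The two-slice recursion must equal the literal noise sum
        (each contribution blurred once per slice of axial distance)."""
        vol = toy_volume(rng, shape=(8, 12, 12))
        p = DiffusionParams(speed_s=0.8, k=0.9)
        out = diffusion_filter(vol, p)
        expected = explicit_sum_diffusion(vol.data, s=0.8, k=0.9, truncate=p.kernel_truncate)
        np.testing.assert_allclose(out.data, expected, rtol=1e-6, atol=1e-6 * vol.data.max())

    def test_alpha_matches_mean_ratio_on_constant_slices(self):
        """Constant slices survive reflect-padded blurs unchanged, so the
        noise-matching multiplier is exactly k*mean(raw_n)/mean(noise_n):
        slices (5, 10) with k=0.9 give alpha=1.8 and res_2 = 10 - 1.8*5 = 1."""
        data = np.stack([np.full((8, 8), 5.0), np.full((8, 8), 10.0)])
        out = diffusion_filter(Volume3D(data, dtype_bits="float"), DiffusionParams(speed_s=1.0, k=0.9))
        np.testing.assert_allclose(out.data[1], 1.0, rtol=1e-6)

    def test_gaussian_semigroup(self, rng):
        """n successive blurs of std s agree with one blur of std s*sqrt(n)
        up to kernel-truncation error."""
        a = rng.random((32, 32))
        twice = blur_n_times(a, 1.0, 4)
        once = gaussian_blur_2d(a, 2.0)
        assert np.max(np.abs(twice - once)) < 1e-3 * np.max(a)

    def test_no_energy_creation_where_input_zero(self, rng):
        vol = toy_volume(rng)
        data = vol.data.copy()
        data[:, :8, :] = 0.0
        out = diffusion_filter(Volume3D(data, dtype_bits="float"), DiffusionParams(speed_s=1.0))
        assert np.all(out.data >= 0)
        assert np.all(out.data[data == 0] == 0)

    def test_input_unchanged_and_output_float(self, rng):
        vol = toy_volume(rng)
        before = vol.data.copy()
        out = diffusion_filter(vol, DiffusionParams(speed_s=1.0))
        np.testing.assert_array_equal(vol.data, before)
        assert out.dtype_bits == "float"

    def test_z_reverse_equals_flipped_traversal(self, rng):
        vol = toy_volume(rng)
        fwd = diffusion_filter(
            Volume3D(vol.data[::-1].copy(), dtype_bits="float"), DiffusionParams(speed_s=1.0)
        )
        rev = diffusion_filter(vol, DiffusionParams(speed_s=1.0), z_reverse=True)
        np.testing.assert_allclose(rev.data, fwd.data[::-1], rtol=1e-6)

    def test_linear_sigma_mode_differs_but_agrees_on_two_slices(self, rng):
        # with a single contaminating slice both sigma laws coincide
        vol = toy_volume(rng, shape=(2, 16, 16))
        a = diffusion_filter(vol, DiffusionParams(speed_s=1.0), sigma_mode="recursive")
        b = diffusion_filter(vol, DiffusionParams(speed_s=1.0), sigma_mode="linear")
        np.testing.assert_allclose(a.data, b.data, rtol=1e-6)

    def test_invalid_speed_rejected(self):
        with pytest.raises(ValueError, match="speed"):
            DiffusionParams(speed_s=0.0)


class TestOrthogonalFilter:
    def test_separable_field_annihilated(self, rng):
        nz, ny, nx = 5, 12, 10
        f = rng.random((nz, ny))
        g = rng.random((nz, nx))
        vol = Volume3D(f[:, :, None] + g[:, None, :], dtype_bits="float")
        out = orthogonal_filter(vol, clip=False)
        assert np.max(np.abs(out.data)) <= 1e-9

    def test_constant_volume_maps_to_zero(self):
        vol = Volume3D(np.full((4, 6, 6), 3.7), dtype_bits="float")
        out = orthogonal_filter(vol, clip=False)
        assert np.max(np.abs(out.data)) < 1e-12

    def test_residual_profiles_are_zero_mean(self, rng):
        vol = toy_volume(rng)
        out = orthogonal_filter(vol, clip=False).data
        np.testing.assert_allclose(out.mean(axis=2), 0, atol=1e-4)
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-4)

    def test_idempotent_pre_clip(self, rng):
        vol = toy_volume(rng)
        once = orthogonal_filter(vol, clip=False)
        twice = orthogonal_filter(once, clip=False)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-4)

    def test_clip_default_is_nonnegative(self, rng):
        out = orthogonal_filter(toy_volume(rng))
        assert np.all(out.data >= 0)


class TestHighpassComposition:
    def test_both_disabled_is_identity_as_float(self, rng):
        vol = toy_volume(rng)
        out = highpass(vol, diffusion_enabled=False, orthogonal_enabled=False)
        assert out.dtype_bits == "float"
        np.testing.assert_allclose(out.data, vol.data, rtol=1e-6)

    def test_ablation_arms_distinct(self, small_phantom, small_spec):
        from niend import degrade

        clean, _ = small_phantom
        deg = degrade(clean, small_spec)
        arms = [
            highpass(deg, DiffusionParams(speed_s=1.0), diffusion_enabled=d, orthogonal_enabled=o)
            for d in (True, False)
            for o in (True, False)
        ]
        for i in range(len(arms)):
            for j in range(i + 1, len(arms)):
                assert not np.array_equal(arms[i].data, arms[j].data)
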