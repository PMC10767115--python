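import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emalign.fields import (
    DisplacementField,
    blur_field,
    build_mip,
    compose,
    field_distance_map,
    gaussian_kernel_1d,
    invert,
    rescale_field,
    warp,
)


class TestWarp:
    def test_identity_field_preserves_image(self, rng):
        img = rng.random((6, 7)).astype(np.float32)
        out = warp(img, DisplacementField.zeros((6, 7)))
        np.testing.assert_allclose(out, img)

    def test_half_pixel_shift_on_linear_ramp_is_exact(self):
        # bilinear interpolation reproduces a linear signal exactly
        ramp = np.tile(np.arange(8, dtype=np.float32), (8, 1))
        out = warp(ramp, DisplacementField.constant((8, 8), (0, 0.5)))
        np.testing.assert_allclose(out[:, :7], ramp[:, :7] + 0.5, atol=1e-6)

    def test_integer_shift_matches_index_oracle(self, rng):
        img = rng.random((4, 4)).astype(np.float32)
        out = warp(img, DisplacementField.constant((4, 4), (0, 1)))
        expected = np.zeros_like(img)
        expected[:, :3] = img[:, 1:]  # vacated column filled with 0
        np.testing.assert_allclose(out, expected)

    def test_shape_mismatch_reports_both_shapes(self, rng):
        with pytest.raises(ValueError, match=r"\(4, 4\).*\(5, 5\)"):
            warp(rng.random((4, 4)), DisplacementField.zeros((5, 5)))


class TestCompose:
    def test_zero_first_argument_returns_second(self, rng):
        B = DisplacementField(rng.normal(size=(5, 5, 2)).astype(np.float32))
        out = compose(DisplacementField.zeros((5, 5)), B)
        np.testing.assert_allclose(out.u, B.u)

    def test_constants_compose_additively(self):
        a = DisplacementField.constant((5, 5), (1, 0))
        b = DisplacementField.constant((5, 5), (0, 2))
        out = compose(a, b)
        inner = out.u[1:-1, 1:-2]
        np.testing.assert_allclose(inner, np.broadcast_to([1.0, 2.0], inner.shape), atol=1e-6)

    def test_nonconstant_fields_match_manual_bilinear(self, rng, bilinear_oracle):
        a = DisplacementField(rng.uniform(-1, 1, (3, 3, 2)).astype(np.float32))
        b = DisplacementField(rng.uniform(-1, 1, (3, 3, 2)).astype(np.float32))
        out = compose(a, b)
        for r in range(3):
            for c in range(3):
                y = r + b.u[r, c, 0]
                x = c + b.u[r, c, 1]
                exp = b.u[r, c] + np.array(
                    [bilinear_oracle(a.u[..., 0], y, x), bilinear_oracle(a.u[..., 1], y, x)]
                )
                np.testing.assert_allclose(out.u[r, c], exp, atol=1e-5)

    def test_identity_is_left_and_right_neutral(self, rng):
        F = DisplacementField(rng.uniform(-0.5, 0.5, (6, 6, 2)).astype(np.float32))
        I = DisplacementField.zeros((6, 6))
        np.testing.assert_allclose(compose(F, I).u, F.u, atol=1e-6)
        np.testing.assert_allclose(compose(I, F).u, F.u, atol=1e-6)


class TestInvert:
    def test_constant_field_inverts_to_negation(self):
        inv = invert(DisplacementField.constant((8, 8), (3, -1)))
        np.testing.assert_allclose(inv.u, np.broadcast_to([-3, 1], (8, 8, 2)), atol=1e-2)

    def test_zero_field_inverts_to_zero(self):
        inv = invert(DisplacementField.zeros((6, 6)))
        np.testing.assert_allclose(inv.u, 0, atol=1e-8)

    def test_smooth_sinusoid_round_trip(self, windowed_sinusoid_field):
        F = windowed_sinusoid_field(32, 2.0)
        V = invert(F, tol=1e-4, max_iter=1000)
        residual = compose(F, V).magnitude().max()
        assert residual < 1e-3

    def test_non_convergence_raises_with_residual(self):
        # folding field (gradient magnitude > 1): no inverse exists
        rr = np.arange(32, dtype=np.float32)[:, None]
        u = np.zeros((32, 32, 2), dtype=np.float32)
        u[..., 0] = 6.0 * np.sin(2 * np.pi * rr / 16)
        with pytest.raises(RuntimeError, match="residual"):
            invert(DisplacementField(u), tol=1e-3, max_iter=50)


class TestRescale:
    def test_identity_stays_identity(self):
        out = rescale_field(DisplacementField.zeros((8, 8)), 2.0)
        assert out.shape == (16, 16)
        np.testing.assert_allclose(out.u, 0)

    def test_constant_upsample_doubles_displacement(self):
        out = rescale_field(DisplacementField.constant((8, 8), (1, 0)), 2.0)
        np.testing.assert_allclose(out.u[..., 0], 2.0, atol=1e-6)

    def test_linear_gradient_round_trip(self):
        rr, cc = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        F = DisplacementField(np.stack([0.1 * rr, 0.05 * cc], axis=-1).astype(np.float32))
        rt = rescale_field(rescale_field(F, 2.0), 0.5)
        np.testing.assert_allclose(rt.u, F.u, atol=1e-6)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            rescale_field(DisplacementField.zeros((4, 4)), 0.0)


class TestMip:
    def test_constant_field_constant_at_every_level(self):
        pyr = build_mip(DisplacementField.constant((16, 16), (2, -3)), 4)
        for lvl in pyr.levels:
            np.testing.assert_allclose(lvl.u, np.broadcast_to([2, -3], (*lvl.shape, 2)), atol=1e-6)

    def test_single_box_filter_matches_mean_oracle(self):
        F = DisplacementField(np.arange(32, dtype=np.float32).reshape(4, 4, 2))
        pyr = build_mip(F, 2)
        manual = F.u.reshape(2, 2, 2, 2, 2).mean(axis=(1, 3))
        np.testing.assert_allclose(pyr.levels[1].u, manual)

    def test_single_level_pyramid_is_the_field(self, rng):
        F = DisplacementField(rng.normal(size=(8, 8, 2)).astype(np.float32))
        pyr = build_mip(F, 1)
        assert len(pyr.levels) == 1
        np.testing.assert_allclose(pyr.levels[0].u, F.u)

    def test_excessive_levels_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            build_mip(DisplacementField.zeros((8, 8)), 10)


class TestBlur:
    def test_sigma_zero_is_identity(self, rng):
        F = DisplacementField(rng.normal(size=(8, 8, 2)).astype(np.float32))
        np.testing.assert_allclose(blur_field(F, 0.0).u, F.u)

    @pytest.mark.parametrize("method", ["direct", "mip"])
    def test_constant_field_is_fixed_point(self, method):
        F = DisplacementField.constant((32, 32), (2, 3))
        out = blur_field(F, 4.0, method)
        np.testing.assert_allclose(out.u, F.u, atol=1e-4)

    def test_impulse_profile_is_sampled_gaussian(self):
        F = DisplacementField.zeros((21, 21))
        F.u[10, 10, 0] = 1.0
        out = blur_field(F, 2.0, "direct")
        k2 = np.outer(gaussian_kernel_1d(2.0), gaussian_kernel_1d(2.0))
        np.testing.assert_allclose(out.u[4:17, 4:17, 0], k2, atol=1e-7)

    def test_mean_preserved_for_interior_supported_fields(self, rng):
        # normalized kernel: when the support stays clear of the boundary by
        # at least the kernel radius, the total displacement is conserved
        u = np.zeros((64, 64, 2), dtype=np.float32)
        u[20:44, 20:44] = rng.normal(size=(24, 24, 2)).astype(np.float32)
        F = DisplacementField(u)
        out = blur_field(F, 3.0, "direct")
        assert abs(out.u[..., 0].mean() - F.u[..., 0].mean()) < 1e-6
        assert abs(out.u[..., 1].mean() - F.u[..., 1].mean()) < 1e-6

    def test_mip_blur_tracks_direct_on_smooth_fields(self):
        from scipy import ndimage

        g = np.random.default_rng(1)
        comps = [
            ndimage.gaussian_filter(g.normal(size=(512, 512)), 192, mode="nearest")
            for _ in range(2)
        ]
        u = np.stack(comps, axis=-1)
        u *= 20 / np.abs(u).max()
        F = DisplacementField(u.astype(np.float32))
        for sigma in [1, 4, 8, 16, 32]:
            d = blur_field(F, sigma, "direct")
            m = blur_field(F, sigma, "mip")
            rel = np.linalg.norm(m.u - d.u) / np.linalg.norm(d.u)
            assert rel < 0.15, f"sigma={sigma}: rel L2 {rel:.3f}"

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            blur_field(DisplacementField.zeros((8, 8)), -1.0)


class TestDistanceMap:
    def test_equal_fields_give_zero(self, rng):
        F = DisplacementField(rng.normal(size=(5, 5, 2)).astype(np.float32))
        np.testing.assert_allclose(field_distance_map(F, F), 0)

    def test_three_four_five(self):
        A = DisplacementField.constant((4, 4), (3, 4))
        B = DisplacementField.zeros((4, 4))
        np.testing.assert_allclose(field_distance_map(A, B), 5.0)

    def test_random_pair_matches_hypot_oracle(self, rng):
        A = DisplacementField(rng.normal(size=(6, 6, 2)).astype(np.float32))
        B = DisplacementField(rng.normal(size=(6, 6, 2)).astype(np.float32))
        expected = np.hypot(*(A.u.astype(np.float64) - B.u.astype(np.float64)).transpose(2, 0, 1))
        np.testing.assert_allclose(field_distance_map(A, B), expected, atol=1e-6)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    dy=st.floats(-2, 2), dx=st.floats(-2, 2), sy=st.floats(-2, 2), sx=st.floats(-2, 2)
)
def test_constant_fields_compose_commutatively(dy, dx, sy, sx):
    A = DisplacementField.constant((6, 6), (dy, dx))
    B = DisplacementField.constant((6, 6), (sy, sx))
    ab = compose(A, B).u[2:-2, 2:-2]
    ba = compose(B, A).u[2:-2, 2:-2]
    np.testing.assert_allclose(ab, ba, atol=1e-5)
    np.testing.assert_allclose(ab, np.broadcast_to([dy + sy, dx + sx], ab.shape), atol=1e-5)


def test_invert_compose_round_trip_for_gentle_fields(windowed_sinusoid_field):
    # gradient magnitude < 0.5 per the inversion contract
    F = windowed_sinusoid_field(48, 1.5)
    V = invert(F, tol=1e-3, max_iter=500)
    assert compose(F, V).magnitude().max() <= 1e-2
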