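import numpy as np
import pytest

from emalign.abcd import (
    BlockSpec,
    DecayConfig,
    GlobalAlignment,
    StitchField,
    align_block,
    decay,
    globalize,
    kernel_difference_curve,
    partition_blocks,
    select_starters,
    stitch_field,
    verify_pair_preservation,
)
from emalign.fields import DisplacementField, compose, warp
from emalign.preprocess import SectionImage
from emalign.voting import VotingConfig


class TestPartition:
    def test_fifty_sections_size_25_overlap_3(self):
        blocks = partition_blocks(50, 25, 3)
        assert [(b.start, b.stop) for b in blocks] == [(0, 24), (22, 49)]

    def test_short_series_single_block(self):
        blocks = partition_blocks(10, 25, 3)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].stop) == (0, 9)

    def test_default_sizes_match_production_run(self):
        import inspect

        sig = inspect.signature(partition_blocks)
        assert sig.parameters["block_size"].default == 25
        assert sig.parameters["overlap"].default == 3

    def test_explicit_starters_override_partition(self):
        blocks = partition_blocks(30, 10, 3, starters=[0, 12, 21])
        assert [b.start for b in blocks] == [0, 12, 21]
        assert blocks[0].stop == 14  # runs to next starter + overlap - 1

    def test_invalid_starters(self):
        with pytest.raises(ValueError, match="outside"):
            partition_blocks(10, 5, 1, starters=[0, 20])
        with pytest.raises(ValueError, match="closer"):
            partition_blocks(30, 10, 3, starters=[0, 2])


class TestSelectStarters:
    def test_clean_sections_give_stride_grid(self):
        out = select_starters(np.zeros(30), 10)
        assert out == [0, 10, 20]

    def test_defective_nominal_starter_replaced_by_cleanest_neighbor(self):
        fracs = np.zeros(20)
        fracs[10] = 1.0
        fracs[11] = 0.05
        fracs[12:20] = 0.2
        out = select_starters(fracs, 10)
        assert out[1] == 11

    def test_single_section(self):
        assert select_starters(np.array([0.3]), 10) == [0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_starters(np.array([]), 5)


class TestDecay:
    def test_distance_zero_leaves_field_unchanged(self, rng):
        F = DisplacementField(rng.normal(size=(16, 16, 2)).astype(np.float32))
        out = decay(F, 0, DecayConfig(c=0.2, d=200))
        np.testing.assert_allclose(out.u, F.u)

    def test_beyond_decay_distance_gives_identity(self, rng):
        F = DisplacementField(rng.normal(size=(16, 16, 2)).astype(np.float32))
        out = decay(F, 200, DecayConfig(c=0.2, d=200))
        np.testing.assert_allclose(out.u, 0)

    def test_constant_field_halved_at_half_distance(self):
        F = DisplacementField.constant((16, 16), (8, 0))
        out = decay(F, 100, DecayConfig(c=0.2, d=200))
        np.testing.assert_allclose(out.u[..., 0], 4.0, atol=1e-5)

    def test_amplitude_bounded_by_beta(self, rng):
        F = DisplacementField(rng.normal(size=(32, 32, 2)).astype(np.float32) * 5)
        cfg = DecayConfig(c=0.2, d=100)
        for n in [1, 25, 50, 99]:
            beta = 1 - n / 100
            out = decay(F, n, cfg)
            assert out.magnitude().max() <= beta * F.magnitude().max() + 1e-4

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DecayConfig(c=-1)
        with pytest.raises(ValueError):
            DecayConfig(d=0)


class TestGlobalize:
    def test_single_block_unchanged(self, rng):
        fields = {z: DisplacementField(rng.normal(size=(8, 8, 2)).astype(np.float32)) for z in range(5)}
        out = globalize([fields], [], DecayConfig())
        for z in range(5):
            np.testing.assert_allclose(out.fields[z].u, fields[z].u)

    def test_two_blocks_constant_stitch_no_decay(self):
        b0 = {z: DisplacementField.zeros((8, 8)) for z in range(5)}
        b1 = {z: DisplacementField.zeros((8, 8)) for z in range(4, 9)}
        stitch = StitchField(DisplacementField.constant((8, 8), (6, 0)), interface=4)
        out = globalize([b0, b1], [stitch], DecayConfig(c=0.2, d=10**6))
        np.testing.assert_allclose(out.fields[8].u[..., 0], 6.0, atol=1e-4)
        np.testing.assert_allclose(out.fields[0].u, 0)

    def test_linear_beta_at_half_distance(self):
        b0 = {z: DisplacementField.zeros((8, 8)) for z in range(0, 101)}
        b1 = {z: DisplacementField.zeros((8, 8)) for z in range(100, 201)}
        stitch = StitchField(DisplacementField.constant((8, 8), (6, 0)), interface=100)
        out = globalize([b0, b1], [stitch], DecayConfig(c=0.0, d=200))
        np.testing.assert_allclose(out.fields[200].u[..., 0], 3.0, atol=1e-5)

    def test_identity_stitches_are_a_no_op(self, rng):
        b0 = {z: DisplacementField(rng.normal(size=(8, 8, 2)).astype(np.float32)) for z in range(5)}
        b1 = {z: DisplacementField(rng.normal(size=(8, 8, 2)).astype(np.float32)) for z in range(4, 9)}
        stitch = StitchField(DisplacementField.zeros((8, 8)), interface=4)
        out = globalize([b0, b1], [stitch], DecayConfig())
        for z in range(5, 9):
            np.testing.assert_allclose(out.fields[z].u, b1[z].u, atol=1e-6)

    def test_stitch_locality_beyond_decay_distance(self, rng):
        # a stitch more than d sections behind z cannot influence z
        b0 = {z: DisplacementField.zeros((8, 8)) for z in range(0, 6)}
        b1 = {z: DisplacementField.zeros((8, 8)) for z in range(5, 30)}
        cfg = DecayConfig(c=0.0, d=10)
        near = globalize([b0, b1], [StitchField(DisplacementField.constant((8, 8), (5, 5)), 5)], cfg)
        far = globalize([b0, b1], [StitchField(DisplacementField.constant((8, 8), (-9, 3)), 5)], cfg)
        for z in range(16, 30):  # z - interface >= d
            np.testing.assert_allclose(near.fields[z].u, far.fields[z].u)
            np.testing.assert_allclose(near.fields[z].u, 0)

    def test_missing_stitch_rejected(self):
        b0 = {0: DisplacementField.zeros((8, 8))}
        b1 = {1: DisplacementField.zeros((8, 8))}
        with pytest.raises(ValueError, match="stitch"):
            globalize([b0, b1], [], DecayConfig())


class TestKernelDifferenceCurve:
    def test_first_section_difference_negligible(self):
        curve = kernel_difference_curve(0.02, 30)
        assert curve[0, 1] < 5e-3

    def test_peak_near_five_percent_around_22_sections(self):
        curve = kernel_difference_curve(0.02, 60)
        assert curve[21, 1] == pytest.approx(0.05, abs=0.01)
        peak_n = curve[np.argmax(curve[:, 1]), 0]
        assert 15 <= peak_n <= 30

    def test_zero_growth_rate_gives_zero_differences(self):
        curve = kernel_difference_curve(0.0, 20)
        np.testing.assert_allclose(curve[:, 1], 0)


class TestVerifyPairPreservation:
    def test_identity_everything_zero_deviation(self):
        ga = GlobalAlignment(fields={z: DisplacementField.zeros((16, 16)) for z in range(4)})
        pairs = {z: DisplacementField.zeros((16, 16)) for z in range(1, 4)}
        report = verify_pair_preservation(ga, pairs, tol=0.5)
        assert report["passed"]
        assert report["max_deviation"] == pytest.approx(0.0, abs=1e-6)


def _constant_offset_stack(n=8, size=128, seed=0):
    """Identical texture per section; later 'block frame' shifted by (5, 0)."""
    from emalign.synthstack import gen_texture
    from emalign.preprocess import normalize_nonzero

    tex = normalize_nonzero(SectionImage(gen_texture(seed, size))).pixels
    return [SectionImage(tex.copy(), 1.0, z) for z in range(n)]


def _cheap_aligner():
    from emalign.aligners import BlockmatchParams, FinetuneConfig, blockmatch, finetune_field

    def aligner(src, tgt):
        F = blockmatch(src, tgt, BlockmatchParams())
        return finetune_field(
            F, src.pixels[None], tgt.pixels[None], None, FinetuneConfig(max_iters=40)
        )

    return aligner


class TestAlignAndStitch:
    def test_identical_sections_align_to_identity(self):
        stack = _constant_offset_stack(6)
        fields = align_block(stack, BlockSpec(0, 5), _cheap_aligner(), VotingConfig(3, 5.7))
        for z, F in fields.items():
            assert np.abs(F.u).max() < 0.1, f"section {z}"

    def test_blank_starter_rejected(self):
        stack = _constant_offset_stack(4)
        stack[0] = SectionImage(np.zeros((128, 128), dtype=np.float32), 1.0, 0)
        with pytest.raises(ValueError, match="starter"):
            align_block(stack, BlockSpec(0, 3), _cheap_aligner(), VotingConfig())

    def test_constant_frame_offset_recovered_by_stitch(self):
        stack = _constant_offset_stack(6)
        shape = (128, 128)
        prev_fields = {z: DisplacementField.zeros(shape) for z in range(6)}
        next_fields = {z: DisplacementField.constant(shape, (5, 0)) for z in range(6)}
        sf = stitch_field(stack, prev_fields, next_fields, [2, 3, 4], _cheap_aligner(), VotingConfig())
        inner = sf.field.u[24:-24, 24:-24]
        # stitch maps the later frame onto the earlier: warp undoes the (5,0) offset
        assert np.abs(inner[..., 0] - (-5)).max() < 0.25
        assert np.abs(inner[..., 1]).max() < 0.25

    def test_single_overlap_section_degenerates_to_single_field(self):
        stack = _constant_offset_stack(4)
        shape = (128, 128)
        prev_fields = {z: DisplacementField.zeros(shape) for z in range(4)}
        next_fields = {z: DisplacementField.zeros(shape) for z in range(4)}
        sf = stitch_field(stack, prev_fields, next_fields, [2], _cheap_aligner(), VotingConfig())
        assert np.abs(sf.field.u).max() < 0.1
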