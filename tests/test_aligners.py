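import numpy as np
import pytest

from emalign import autograd as ag
from emalign.aligners import (
    BlockmatchParams,
    FinetuneConfig,
    MultiscaleConfig,
    TrainConfig,
    _finetune_loss_and_grad,
    align_pair_multiscale,
    blockmatch,
    encode,
    finetune_field,
    predict_residual,
    train_pair_aligner,
)
from emalign.fields import DisplacementField, warp
from emalign.nets import PairAlignerModel
from emalign.preprocess import SectionImage, build_pyramid


class TestBlockmatch:
    def test_recovers_integer_shift_at_interior_nodes(self, texture128):
        shift = (3, -5)
        tgt = warp(texture128, DisplacementField.constant((128, 128), shift))
        F = blockmatch(texture128, tgt)
        inner = F.u[40:-40, 40:-40]
        assert np.abs(inner - np.array(shift)).max() < 0.1

    def test_identical_images_give_zero_field(self, texture128):
        F = blockmatch(texture128, texture128)
        assert np.abs(F.u).max() < 0.1

    def test_all_zero_source_raises_insufficient_texture(self):
        zeros = np.zeros((128, 128), dtype=np.float32)
        with pytest.raises(RuntimeError, match="texture"):
            blockmatch(zeros, zeros)

    def test_zeroed_patch_node_filled_from_neighbors(self, texture128):
        src = texture128.copy()
        src[40:80, 40:80] = 0.0  # a dead node in the middle
        F = blockmatch(src, texture128)
        assert np.isfinite(F.u).all()
        assert np.abs(F.u).max() < 0.5

    def test_param_validation(self):
        with pytest.raises(ValueError):
            BlockmatchParams(src_patch=48, tgt_patch=48)
        preset = BlockmatchParams.coarse_em_preset()
        assert (preset.src_patch, preset.tgt_patch, preset.grid_step) == (256, 358, 96)


class TestEncode:
    def test_passthrough_returns_the_image(self, texture128):
        enc = encode(texture128, None)
        assert enc.shape == (1, 128, 128)
        np.testing.assert_allclose(enc[0], texture128)

    def test_deterministic_forward(self, texture128):
        model = PairAlignerModel(seed=3, enc_channels=4)
        a = encode(SectionImage(texture128), model)
        b = encode(SectionImage(texture128), model)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (4, 128, 128)

    def test_resolution_mismatch_rejected(self, texture128):
        model = PairAlignerModel(resolution=2.0, enc_channels=4)
        with pytest.raises(ValueError, match="resolution"):
            encode(SectionImage(texture128, resolution=1.0), model)


class TestPredictResidual:
    def test_zero_initialized_final_layer_predicts_zero_field(self, rng):
        model = PairAlignerModel(seed=0, enc_channels=4)
        enc = rng.normal(size=(4, 32, 32))
        F = predict_residual(enc, rng.normal(size=(4, 32, 32)), model)
        np.testing.assert_allclose(F.u, 0)

    def test_shape_mismatch_rejected(self, rng):
        model = PairAlignerModel(seed=0, enc_channels=4)
        with pytest.raises(ValueError, match="mismatch"):
            predict_residual(rng.normal(size=(4, 8, 8)), rng.normal(size=(4, 9, 9)), model)


class TestFinetune:
    def test_aligned_inputs_stay_put(self, texture128):
        F = finetune_field(
            DisplacementField.zeros((128, 128)),
            texture128[None],
            texture128[None],
            cfg=FinetuneConfig(max_iters=30),
        )
        assert np.abs(F.u).max() < 0.05

    def test_recovers_subpixel_translation(self, texture128):
        tgt = warp(texture128, DisplacementField.constant((128, 128), (1.5, 0)))
        F = finetune_field(
            DisplacementField.zeros((128, 128)), texture128[None], tgt[None],
            cfg=FinetuneConfig(max_iters=200),
        )
        inner = F.u[20:-20, 20:-20]
        assert np.abs(inner - np.array([1.5, 0])).max() < 0.1

    def test_never_worse_than_start(self, rng, texture128):
        tgt = np.roll(texture128, 2, axis=0)
        F0 = DisplacementField(rng.normal(size=(128, 128, 2)).astype(np.float32))
        cfg = FinetuneConfig(max_iters=15)
        qs, qt = texture128[None], tgt[None]
        def loss(F):
            u = np.moveaxis(F.u.astype(np.float32), -1, 0)
            val, _ = _finetune_loss_and_grad(
                u, qs.astype(np.float32), qt.astype(np.float32),
                np.any(qt != 0, axis=0), np.zeros((128, 128), bool), cfg.gamma,
            )
            return val
        F1 = finetune_field(F0, qs, qt, cfg=cfg)
        assert loss(F1) <= loss(F0) + 1e-9

    def test_fused_gradient_matches_autograd(self, rng):
        C, H, W = 2, 20, 18
        qs = rng.normal(size=(C, H, W)).astype(np.float32)
        qt = rng.normal(size=(C, H, W)).astype(np.float32)
        u = (rng.normal(size=(2, H, W)) * 0.7).astype(np.float32)
        dd = np.zeros((H, W), bool)
        dd[4:7, 4:7] = True
        loss, grad = _finetune_loss_and_grad(u, qs, qt, np.any(qt != 0, axis=0), dd, 9.0)
        ft = ag.Tensor(u.astype(np.float64), requires_grad=True)
        warped = ag.warp_op(ag.Tensor(qs.astype(np.float64)), ft)
        tst = np.any(warped.data != 0, axis=0) & np.any(qt != 0, axis=0)
        ref = ag.weighted_sum(
            (warped - ag.Tensor(qt.astype(np.float64))).square(),
            np.broadcast_to(tst / tst.sum(), qs.shape),
        )
        vm = np.any(warped.data != 0, axis=0) & ~dd
        ref = ref + 9.0 * ag.elastic_energy(ft, vm / vm.sum())
        ref.backward()
        assert abs(loss - ref.data) < 1e-5
        assert np.abs(grad - ft.grad).max() < 1e-6


class TestMultiscale:
    def test_identical_stacks_give_near_zero_field(self, texture128):
        sec = SectionImage(texture128)
        pyr = build_pyramid(sec, None, 1)
        ms = MultiscaleConfig(levels=[1, 0], aligners={1: "blockmatch"},
                              finetune={})
        F = align_pair_multiscale(pyr, pyr, ms)
        assert np.abs(F.u).max() < 0.1

    def test_recovers_smooth_warp_within_half_pixel(self, texture128, smooth_field64):
        from emalign.fields import invert, rescale_field

        R = rescale_field(smooth_field64, 2.0)  # 4 px warp on the 128 grid
        src = SectionImage(warp(texture128, invert(R, tol=1e-3)))
        tgt = SectionImage(texture128)
        ft = FinetuneConfig(max_iters=100)
        ms = MultiscaleConfig(levels=[1, 0], aligners={1: "blockmatch"},
                              finetune={1: ft, 0: ft})
        F = align_pair_multiscale(build_pyramid(src, None, 1), build_pyramid(tgt, None, 1), ms)
        dev = np.hypot(*(F.u - R.u).transpose(2, 0, 1))[16:-16, 16:-16]
        assert np.sqrt((dev**2).mean()) < 0.5

    def test_single_level_equivalent_to_blockmatch_plus_finetune(self, texture128):
        tgt = warp(texture128, DisplacementField.constant((128, 128), (2, 1)))
        src = SectionImage(texture128)
        ft = FinetuneConfig(max_iters=30)
        ms = MultiscaleConfig(levels=[0], aligners={0: "blockmatch"}, finetune={0: ft})
        F = align_pair_multiscale(build_pyramid(src, None, 0), build_pyramid(SectionImage(tgt), None, 0), ms)
        ref = blockmatch(texture128, tgt)
        ref = finetune_field(ref, texture128[None], tgt[None], None, ft)
        np.testing.assert_allclose(F.u, ref.u, atol=1e-5)

    def test_level_failure_reports_level(self):
        zeros = SectionImage(np.zeros((128, 128), dtype=np.float32))
        pyr = build_pyramid(zeros, None, 1)
        ms = MultiscaleConfig(levels=[1, 0], aligners={1: "blockmatch"}, finetune={})
        with pytest.raises(RuntimeError, match="level 1"):
            align_pair_multiscale(pyr, pyr, ms)


class TestTraining:
    def _tiny_dataset(self, n_pairs=2, size=64):
        from emalign.preprocess import normalize_nonzero
        from emalign.synthstack import gen_smooth_field, gen_texture
        from emalign.fields import invert

        pairs = []
        for s in range(n_pairs):
            tex = gen_texture(s, size)
            R = gen_smooth_field(s + 100, 1.5, 16.0, size)
            src = warp(tex, invert(R, tol=1e-3))
            pairs.append(
                (
                    normalize_nonzero(SectionImage(src)).pixels,
                    normalize_nonzero(SectionImage(tex)).pixels,
                )
            )
        return pairs

    def test_fixed_seed_reproduces_weights_exactly(self):
        pairs = self._tiny_dataset()
        cfg = TrainConfig(stage1_epochs=2, stage2_epochs=1, seed=11)
        m1 = train_pair_aligner(pairs, cfg)
        m2 = train_pair_aligner(pairs, cfg)
        for p1, p2 in zip(m1.params, m2.params):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_pair_aligner([], TrainConfig(stage1_epochs=1, stage2_epochs=0))

    def test_checkpoint_round_trip_bit_exact(self, tmp_path):
        pairs = self._tiny_dataset(1)
        model = train_pair_aligner(pairs, TrainConfig(stage1_epochs=1, stage2_epochs=0, seed=2))
        path = tmp_path / "model.h5"
        model.save(path)
        loaded = PairAlignerModel.load(path)
        for p1, p2 in zip(model.params, loaded.params):
            np.testing.assert_array_equal(p1.data, p2.data)
        assert loaded.stage == model.stage
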