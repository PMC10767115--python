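"""Small convolutional Encoder and Aligner nets built on the numpy autograd.

The Encoder maps a 1-channel section to a C-channel dense feature image of
the same spatial shape (a residual two-block design with a 1x1 skip). The
Aligner maps the concatenated source/target encodings to a residual
displacement field; its final layer is zero-initialized so an untrained
Aligner predicts the zero field. Both are deterministic given their weights,
and weights are reproducible given the seed used at construction.
"""

from __future__ import annotations

import json

import numpy as np

from .autograd import Tensor, concat_channels, conv2d, leaky_relu, tanh


class Conv2dLayer:
    """3x3 (or kxk) conv layer with He-initialized weights."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator, zero_init=False):
        if zero_init:
            w = np.zeros((out_ch, in_ch, k, k))
        else:
            std = np.sqrt(2.0 / (in_ch * k * k))
            w = rng.normal(0.0, std, size=(out_ch, in_ch, k, k))
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class EncoderNet:
    """Residual conv encoder: 1 -> hidden -> hidden -> C, plus a 1x1 skip.

    The output is bounded by tanh; an unbounded encoder would let stage-2
    training inflate the encoding scale to grow the (negative) pre-alignment
    similarity term without limit.
    """

    def __init__(self, channels: int = 8, hidden: int = 8, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.c1 = Conv2dLayer(1, hidden, 3, rng)
        self.c2 = Conv2dLayer(hidden, hidden, 3, rng)
        self.c3 = Conv2dLayer(hidden, channels, 3, rng)
        self.skip = Conv2dLayer(1, channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = leaky_relu(self.c1(x))
        h = leaky_relu(self.c2(h))
        return tanh(self.c3(h) + self.skip(x))

    @property
    def params(self) -> list[Tensor]:
        return self.c1.params + self.c2.params + self.c3.params + self.skip.params


class AlignerNet:
    """Conv net mapping concatenated encodings (2C,H,W) to a field (2,H,W).

    The final layer is zero-initialized: with fresh weights the predicted
    residual field is identically zero.
    """

    def __init__(self, enc_channels: int = 8, hidden: int = 16, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.l1 = Conv2dLayer(2 * enc_channels, hidden, 3, rng)
        self.l2 = Conv2dLayer(hidden, hidden, 3, rng)
        self.l3 = Conv2dLayer(hidden, hidden, 3, rng)
        self.l4 = Conv2dLayer(hidden, 2, 3, rng, zero_init=True)

    def __call__(self, enc_s: Tensor, enc_t: Tensor) -> Tensor:
        h = concat_channels([enc_s, enc_t])
        h = leaky_relu(self.l1(h))
        h = leaky_relu(self.l2(h))
        h = leaky_relu(self.l3(h))
        return self.l4(h)

    @property
    def params(self) -> list[Tensor]:
        return self.l1.params + self.l2.params + self.l3.params + self.l4.params


class PairAlignerModel:
    """Encoder/Aligner pair operating at one fixed resolution.

    With ``encoder is None`` the model is a passthrough: encodings equal the
    input image (1 channel) and the rest of the pipeline runs net-free.
    """

    def __init__(
        self,
        resolution: float = 1.0,
        enc_channels: int = 8,
        hidden: int = 16,
        seed: int = 0,
        passthrough: bool = False,
    ):
        self.resolution = resolution
        self.seed = seed
        self.stage = 0
        self.epoch = 0
        self.loss_history: dict[str, list[float]] = {"stage1": [], "stage2": []}
        if passthrough:
            self.encoder = None
            self.aligner = None
            self.enc_channels = 1
        else:
            rng = np.random.default_rng(seed)
            self.encoder = EncoderNet(enc_channels, rng=rng)
            self.aligner = AlignerNet(enc_channels, hidden, rng=rng)
            self.enc_channels = enc_channels

    @property
    def params(self) -> list[Tensor]:
        if self.encoder is None:
            return []
        return self.encoder.params + self.aligner.params

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            meta = {
                "resolution": self.resolution,
                "seed": self.seed,
                "stage": self.stage,
                "epoch": self.epoch,
                "enc_channels": self.enc_channels,
                "passthrough": self.encoder is None,
            }
            f.attrs["meta"] = json.dumps(meta)
            if self.encoder is not None:
                for i, p in enumerate(self.params):
                    f.create_dataset(f"weights/{i}", data=p.data)

    @classmethod
    def load(cls, path) -> "PairAlignerModel":
        import h5py

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            model = cls(
                resolution=meta["resolution"],
                enc_channels=meta["enc_channels"] if not meta["passthrough"] else 8,
                seed=meta["seed"],
                passthrough=meta["passthrough"],
            )
            model.stage = meta["stage"]
            model.epoch = meta["epoch"]
            if not meta["passthrough"]:
                for i, p in enumerate(model.params):
                    p.data = f[f"weights/{i}"][...].astype(np.float64)
        return model
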