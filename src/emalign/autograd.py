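"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the alignment losses need: same-padding 2D
convolution, leaky ReLU, channel concatenation, elementwise arithmetic,
bilinear warping of a multi-channel image by a displacement field (with
gradients to both the image and the field), fixed-weight sums, and the
elastic spring energy of a field. Tensors are float64 throughout; graphs are
built eagerly and freed after backward.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph.

    parents is a list of (parent, grad_fn) pairs where grad_fn maps the
    upstream gradient to this parent's gradient contribution.
    """

    __slots__ = ("data", "grad", "parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = list(parents)
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p, _ in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.grad is None:
                t.grad = g.copy()
            else:
                t.grad += g
            for p, fn in t.parents:
                if not p.requires_grad:
                    continue
                pg = fn(g)
                if id(p) in grads:
                    grads[id(p)] += pg
                else:
                    grads[id(p)] = pg

    # -- elementwise --
    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data + other.data,
            [(self, lambda g: g), (other, lambda g: g)],
        )

    def __sub__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data - other.data,
            [(self, lambda g: g), (other, lambda g: -g)],
        )

    def __mul__(self, scalar: float):
        s = float(scalar)
        return Tensor(self.data * s, [(self, lambda g: g * s)])

    __rmul__ = __mul__

    def square(self):
        d = self.data
        return Tensor(d * d, [(self, lambda g: 2.0 * d * g)])


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    return Tensor(y, [(x, lambda g: g * (1.0 - y * y))])


def leaky_relu(x: Tensor, alpha: float = 0.1) -> Tensor:
    mask = x.data > 0
    scale = np.where(mask, 1.0, alpha)
    return Tensor(x.data * scale, [(x, lambda g: g * scale)])


def concat_channels(tensors: list[Tensor]) -> Tensor:
    sizes = [t.data.shape[0] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    parents = []
    for t, o, s in zip(tensors, offsets[:-1], sizes):
        parents.append((t, lambda g, o=o, s=s: g[o : o + s]))
    return Tensor(np.concatenate([t.data for t in tensors], axis=0), parents)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding 2D convolution: x (C,H,W), w (O,C,k,k), b (O) -> (O,H,W)."""
    C, H, W = x.data.shape
    O, _, k, _ = w.data.shape
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))  # C,H,W,k,k
    cols = win.transpose(1, 2, 0, 3, 4).reshape(H * W, C * k * k)
    wmat = w.data.reshape(O, C * k * k)
    out = (cols @ wmat.T + b.data).reshape(H, W, O).transpose(2, 0, 1)

    def grad_x(g):
        gmat = g.transpose(1, 2, 0).reshape(H * W, O)
        gcols = (gmat @ wmat).reshape(H, W, C, k, k)
        gxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                gxp[:, di : di + H, dj : dj + W] += gcols[:, :, :, di, dj].transpose(2, 0, 1)
        return gxp[:, pad : pad + H, pad : pad + W] if pad else gxp

    def grad_w(g):
        gmat = g.transpose(1, 2, 0).reshape(H * W, O)
        return (gmat.T @ cols).reshape(O, C, k, k)

    def grad_b(g):
        return g.sum(axis=(1, 2))

    return Tensor(out, [(x, grad_x), (w, grad_w), (b, grad_b)])


def _bilinear_setup(field: np.ndarray, H: int, W: int):
    rr, cc = np.meshgrid(np.arange(H, dtype=np.float64), np.arange(W, dtype=np.float64), indexing="ij")
    y = rr + field[0]
    x = cc + field[1]
    y0 = np.floor(y).astype(np.int64)
    x0 = np.floor(x).astype(np.int64)
    fy = y - y0
    fx = x - x0
    # sample points outside the grid evaluate to 0 with zero gradient
    inside = (y >= 0) & (y <= H - 1) & (x >= 0) & (x <= W - 1)
    corners = []
    for dy, dx, wgt in (
        (0, 0, (1 - fy) * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 0, fy * (1 - fx)),
        (1, 1, fy * fx),
    ):
        yy = y0 + dy
        xx = x0 + dx
        valid = inside & (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
        corners.append((np.clip(yy, 0, H - 1), np.clip(xx, 0, W - 1), wgt * valid, dy, dx, valid))
    return y0, x0, fy, fx, corners


def warp_op(image: Tensor, field: Tensor) -> Tensor:
    """Bilinear warp of image (C,H,W) by field (2,H,W) of (drow, dcol).

    out_c(r) = image_c(r + u(r)); out-of-grid samples are 0. Gradients flow
    to both the image (bilinear scatter) and the field (exact derivative of
    the bilinear interpolant, zero outside the grid).
    """
    C, H, W = image.data.shape
    _, Hf, Wf = field.data.shape
    assert (H, W) == (Hf, Wf), "warp_op: image/field grid mismatch"
    y0, x0, fy, fx, corners = _bilinear_setup(field.data, H, W)
    out = np.zeros((C, H, W))
    for yy, xx, wgt, dy, dx, valid in corners:
        out += image.data[:, yy, xx] * wgt

    def grad_image(g):
        gi = np.zeros_like(image.data)
        for yy, xx, wgt, dy, dx, valid in corners:
            np.add.at(gi, (slice(None), yy, xx), g * wgt)
        return gi

    def grad_field(g):
        # d out / d y = sum over corners of image * d wgt / d fy, etc.
        gy = np.zeros((H, W))
        gx = np.zeros((H, W))
        img = image.data
        for yy, xx, wgt, dy, dx, valid in corners:
            vals = (img[:, yy, xx] * g).sum(axis=0)  # (H, W)
            dw_dfy = (1.0 if dy else -1.0) * (fx if dx else (1 - fx))
            dw_dfx = (1.0 if dx else -1.0) * (fy if dy else (1 - fy))
            gy += vals * dw_dfy * valid
            gx += vals * dw_dfx * valid
        return np.stack([gy, gx])

    return Tensor(out, [(image, grad_image), (field, grad_field)])


def weighted_sum(x: Tensor, weights: np.ndarray) -> Tensor:
    """Scalar sum(x * weights) with fixed (non-differentiated) weights."""
    w = np.asarray(weights, dtype=np.float64)
    val = float((x.data * w).sum())
    return Tensor(val, [(x, lambda g: g * w)])


_ELASTIC_OFFSETS = ((0, 1), (1, 0), (1, 1))


def elastic_energy(field: Tensor, vertex_weights: np.ndarray) -> Tensor:
    """Weighted sum of per-vertex spring energies of a (2,H,W) field tensor.

    vertex_weights is a fixed (H,W) map (typically mask / count, so the value
    equals the masked-average regularizer). Gradient is analytic.
    """
    u = field.data
    _, H, W = u.shape
    vw = np.asarray(vertex_weights, dtype=np.float64)
    total = 0.0
    cache = []
    for dr, dc in _ELASTIC_OFFSETS:
        rest = float(np.hypot(dr, dc))
        dy = u[0, : H - dr or None, : W - dc or None] - u[0, dr:, dc:] - dr
        dx = u[1, : H - dr or None, : W - dc or None] - u[1, dr:, dc:] - dc
        dist = np.hypot(dy, dx)
        wv = vw[: H - dr or None, : W - dc or None]
        total += float((((dist - rest) ** 2) * wv).sum())
        cache.append((dr, dc, rest, dy, dx, dist, wv))

    def grad_field(g):
        gf = np.zeros_like(u)
        for dr, dc, rest, dy, dx, dist, wv in cache:
            safe = np.where(dist > 1e-12, dist, 1.0)
            coef = 2.0 * (dist - rest) / safe * wv * g
            gy = coef * dy
            gx = coef * dx
            gf[0, : H - dr or None, : W - dc or None] += gy
            gf[1, : H - dr or None, : W - dc or None] += gx
            gf[0, dr:, dc:] -= gy
            gf[1, dr:, dc:] -= gx
        return gf

    return Tensor(total, [(field, grad_field)])


class Adam:
    """Adam optimizer over a list of leaf tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
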