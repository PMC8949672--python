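"""ArrhythmiaNet: a small attention-gated CNN over scalogram images.

Architecture (single channel input, side S):

    conv1 3x3 same -> ReLU -> conv2 3x3 same -> ReLU -> maxpool 2x2
    -> [self-attention gate] -> conv3 3x3 same -> ReLU
    -> flatten = spatial feature vector (SFV) -> fully connected head

The self-attention gate maps the pooled feature map x through three learned
1x1 convolutions f, g, h (f(x)=Wx+b and likewise for g, h), forms attention
weights A_ij = softmax_j f(x_i)^T g(x_j) over spatial positions, outputs
o_i = sum_j A_ij h(x_j), and the conv3 input is the elementwise product
x * o (the gate multiplies the pooled map).  With the gate disabled the
pooled map feeds conv3 directly (the ablation path).

At the reference geometry (S=256, channels 32/64/128, one 2x2 pool) the SFV
has (256/2)^2 * 128 = 2,097,152 features and the whole network — conv stack,
attention 1x1 convolutions and the 17-way head — has 35,756,753 trainable
parameters (~36 M, dominated by the head).

The network is implemented directly on NumPy arrays with hand-written
backpropagation (im2col convolutions, cached attention softmax); gradients
are validated against finite differences in the test-suite.  Training is
plain SGD with momentum, cross-entropy loss, and a per-step multiplicative
learning-rate decay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "NetConfig",
    "TrainConfig",
    "AttentionSpaces",
    "Network",
    "build",
    "attention_block",
    "train",
    "extract_sfvs",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class NetConfig:
    input_side: int = 256
    in_channels: int = 1
    conv_channels: tuple[int, int, int] = (32, 64, 128)
    n_classes: int = 17
    attention_enabled: bool = True
    attention_subsample: int | None = None  # None -> 4 at side 256, else 1

    def __post_init__(self) -> None:
        if self.input_side % 2 != 0:
            raise ValueError(f"input_side must be even, got {self.input_side}")
        if any(c <= 0 for c in self.conv_channels):
            raise ValueError("conv_channels must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def pooled_side(self) -> int:
        return self.input_side // 2

    @property
    def flatten_length(self) -> int:
        return self.pooled_side**2 * self.conv_channels[2]

    @property
    def subsample(self) -> int:
        if self.attention_subsample is not None:
            return self.attention_subsample
        return 4 if self.input_side >= 256 else 1


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 32
    lr_decay: float = 1e-7  # multiplicative, per optimisation step
    epochs: int = 5
    seed: int = 0


@dataclass
class AttentionSpaces:
    """Weights of the f, g, h 1x1-convolution feature spaces (c -> c)."""

    W_f: np.ndarray
    W_g: np.ndarray
    W_h: np.ndarray
    b_f: np.ndarray
    b_g: np.ndarray
    b_h: np.ndarray


# ---------------------------------------------------------------------------
# primitive layers

def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B,C,H,W) -> (B, C*9, H*W) patches for a 3x3 same-padding conv."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * 9, H * W)


def _col2im(dcols: np.ndarray, shape) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    B, C, H, W = shape
    d = dcols.reshape(B, C, 3, 3, H, W)
    dxp = np.zeros((B, C, H + 2, W + 2))
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di : di + H, dj : dj + W] += d[:, :, di, dj]
    return dxp[:, :, 1 : H + 1, 1 : W + 1]


def _conv_forward(x, W2d, b):
    B, C, H, Wd = x.shape
    cols = _im2col(x)
    out = np.matmul(W2d, cols) + b[None, :, None]
    return out.reshape(B, W2d.shape[0], H, Wd), cols


def _conv_backward(dout, cols, W2d, x_shape):
    B = dout.shape[0]
    d2 = dout.reshape(B, dout.shape[1], -1)
    dW = np.matmul(d2, cols.transpose(0, 2, 1)).sum(axis=0)
    db = d2.sum(axis=(0, 2))
    dcols = np.matmul(W2d.T, d2)
    return _col2im(dcols, x_shape), dW, db


def _maxpool_forward(x):
    B, C, H, W = x.shape
    r = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(B, C, H // 2, W // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(dout, idx, x_shape):
    B, C, H, W = x_shape
    dr = np.zeros((B, C, H // 2, W // 2, 4))
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    dr = dr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dr.reshape(B, C, H, W)


def _softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _attention_forward(P, spaces: AttentionSpaces, sub_idx):
    """P: (B, C, N) flattened feature map.  Returns (O, cache)."""
    Ps = P[:, :, sub_idx]
    F = np.einsum("dc,bcn->bdn", spaces.W_f, P, optimize=True) + spaces.b_f[None, :, None]
    G = np.einsum("dc,bcm->bdm", spaces.W_g, Ps, optimize=True) + spaces.b_g[None, :, None]
    Hh = np.einsum("dc,bcm->bdm", spaces.W_h, Ps, optimize=True) + spaces.b_h[None, :, None]
    S = np.einsum("bcn,bcm->bnm", F, G, optimize=True)
    A = _softmax(S, axis=2)
    O = np.einsum("bnm,bcm->bcn", A, Hh, optimize=True)
    return O, (P, Ps, F, G, Hh, A)


def _attention_backward(dO, cache, spaces: AttentionSpaces, sub_idx):
    P, Ps, F, G, Hh, A = cache
    dHh = np.einsum("bcn,bnm->bcm", dO, A, optimize=True)
    dA = np.einsum("bcn,bcm->bnm", dO, Hh, optimize=True)
    dS = A * (dA - (dA * A).sum(axis=2, keepdims=True))
    dF = np.einsum("bnm,bcm->bcn", dS, G, optimize=True)
    dG = np.einsum("bnm,bcn->bcm", dS, F, optimize=True)
    grads = {
        "W_f": np.einsum("bdn,bcn->dc", dF, P, optimize=True),
        "b_f": dF.sum(axis=(0, 2)),
        "W_g": np.einsum("bdm,bcm->dc", dG, Ps, optimize=True),
        "b_g": dG.sum(axis=(0, 2)),
        "W_h": np.einsum("bdm,bcm->dc", dHh, Ps, optimize=True),
        "b_h": dHh.sum(axis=(0, 2)),
    }
    dP = np.einsum("dc,bdn->bcn", spaces.W_f, dF, optimize=True)
    dPs = np.einsum("dc,bdm->bcm", spaces.W_g, dG, optimize=True)
    dPs += np.einsum("dc,bdm->bcm", spaces.W_h, dHh, optimize=True)
    dP[:, :, sub_idx] += dPs
    return dP, grads


def attention_block(
    x: np.ndarray, spaces: AttentionSpaces, subsample: int = 1
) -> np.ndarray:
    """Self-attention over the spatial positions of a (C,H,W) or (B,C,H,W) map.

    Keys/values are taken on a grid thinned by ``subsample`` in each spatial
    direction; queries cover every position, so the output keeps the input
    shape.  Every attention row is a probability vector.
    """
    single = x.ndim == 3
    xb = x[None] if single else x
    B, C, H, W = xb.shape
    sub_idx = _subsample_indices(H, W, subsample)
    O, _ = _attention_forward(xb.reshape(B, C, H * W), spaces, sub_idx)
    out = O.reshape(B, C, H, W)
    return out[0] if single else out


def attention_rows(x: np.ndarray, spaces: AttentionSpaces, subsample: int = 1):
    """The attention weight matrix A (N x M) for a single (C,H,W) map."""
    C, H, W = x.shape
    sub_idx = _subsample_indices(H, W, subsample)
    _, cache = _attention_forward(x.reshape(1, C, H * W), spaces, sub_idx)
    return cache[5][0]


def _subsample_indices(H, W, sub):
    if sub < 1:
        raise ValueError("subsample must be >= 1")
    return (np.arange(0, H, sub)[:, None] * W + np.arange(0, W, sub)[None, :]).ravel()


# ---------------------------------------------------------------------------
# the network

class Network:
    """ArrhythmiaNet with explicit parameter dict and hand-written backprop."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        c0 = cfg.in_channels
        c1, c2, c3 = cfg.conv_channels
        p = {}
        p["W1"] = _he_uniform(rng, (c1, c0 * 9), c0 * 9)
        p["b1"] = np.zeros(c1)
        p["W2"] = _he_uniform(rng, (c2, c1 * 9), c1 * 9)
        p["b2"] = np.zeros(c2)
        p["W_f"] = _he_uniform(rng, (c2, c2), c2)
        p["b_f"] = np.zeros(c2)
        p["W_g"] = _he_uniform(rng, (c2, c2), c2)
        p["b_g"] = np.zeros(c2)
        p["W_h"] = _he_uniform(rng, (c2, c2), c2)
        p["b_h"] = np.zeros(c2)
        p["W3"] = _he_uniform(rng, (c3, c2 * 9), c2 * 9)
        p["b3"] = np.zeros(c3)
        p["Wfc"] = _he_uniform(rng, (cfg.n_classes, cfg.flatten_length),
                               cfg.flatten_length)
        p["bfc"] = np.zeros(cfg.n_classes)
        self.params = p

    # -- introspection ------------------------------------------------------
    @property
    def flatten_length(self) -> int:
        return int(self.params["Wfc"].shape[1])

    def parameter_count(self) -> int:
        """Total trainable scalars, attention included (whether enabled or not
        at forward time, the parameters exist)."""
        return int(sum(v.size for v in self.params.values()))

    @property
    def attention_spaces(self) -> AttentionSpaces:
        p = self.params
        return AttentionSpaces(p["W_f"], p["W_g"], p["W_h"],
                               p["b_f"], p["b_g"], p["b_h"])

    # -- forward ------------------------------------------------------------
    def _as_batch(self, images) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.shape[-1] != self.cfg.input_side or x.shape[-2] != self.cfg.input_side:
            raise ValueError(
                f"input side {x.shape[-2:]} does not match config "
                f"{self.cfg.input_side}"
            )
        return x

    def forward(self, images, want_cache: bool = False):
        """Returns (logits, sfv[, cache]) for a batch of scalogram images."""
        cfg = self.cfg
        p = self.params
        x = self._as_batch(images)
        B = x.shape[0]
        z1, cols1 = _conv_forward(x, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        z2, cols2 = _conv_forward(a1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        pool, pool_idx = _maxpool_forward(a2)
        Hp = cfg.pooled_side
        if cfg.attention_enabled:
            sub_idx = _subsample_indices(Hp, Hp, cfg.subsample)
            O, att_cache = _attention_forward(
                pool.reshape(B, cfg.conv_channels[1], Hp * Hp), spacesof(p), sub_idx
            )
            gate = O.reshape(pool.shape)
            z_in = pool * gate
        else:
            sub_idx, att_cache, gate = None, None, None
            z_in = pool
        z3, cols3 = _conv_forward(z_in, p["W3"], p["b3"])
        a3 = np.maximum(z3, 0.0)
        sfv = a3.reshape(B, -1)
        logits = sfv @ p["Wfc"].T + p["bfc"]
        if not want_cache:
            return logits, sfv
        cache = dict(x=x, z1=z1, cols1=cols1, a1=a1, z2=z2, cols2=cols2,
                     a2=a2, pool=pool, pool_idx=pool_idx, gate=gate,
                     att_cache=att_cache, sub_idx=sub_idx, z_in=z_in,
                     z3=z3, cols3=cols3, a3=a3, sfv=sfv)
        return logits, sfv, cache

    def forward_gated(self, scalogram):
        """(logits, SFV) for one scalogram image or a batch."""
        logits, sfv = self.forward(scalogram)
        if np.asarray(scalogram).ndim == 2:
            return logits[0], sfv[0]
        return logits, sfv

    # -- backward -----------------------------------------------------------
    def loss_and_grads(self, images, y: np.ndarray):
        """Mean cross-entropy over the batch and gradients for every
        parameter.  y holds integer class indices."""
        cfg = self.cfg
        p = self.params
        logits, sfv, c = self.forward(images, want_cache=True)
        B = logits.shape[0]
        probs = _softmax(logits, axis=1)
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + 1e-300)))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["Wfc"] = dlogits.T @ sfv
        g["bfc"] = dlogits.sum(axis=0)
        dsfv = dlogits @ p["Wfc"]
        da3 = dsfv.reshape(c["a3"].shape)
        dz3 = da3 * (c["z3"] > 0)
        dz_in, g["W3"], g["b3"] = _conv_backward(dz3, c["cols3"], p["W3"],
                                                 c["z_in"].shape)
        if cfg.attention_enabled:
            pool = c["pool"]
            gate = c["gate"]
            dpool = dz_in * gate
            dO = (dz_in * pool).reshape(B, cfg.conv_channels[1], -1)
            dP, att_g = _attention_backward(dO, c["att_cache"], spacesof(p),
                                            c["sub_idx"])
            for k, v in att_g.items():
                g[k] = v
            dpool = dpool + dP.reshape(pool.shape)
        else:
            dpool = dz_in
        da2 = _maxpool_backward(dpool, c["pool_idx"], c["a2"].shape)
        dz2 = da2 * (c["z2"] > 0)
        da1, g["W2"], g["b2"] = _conv_backward(dz2, c["cols2"], p["W2"],
                                               c["a1"].shape)
        dz1 = da1 * (c["z1"] > 0)
        _, g["W1"], g["b1"] = _conv_backward(dz1, c["cols1"], p["W1"],
                                             c["x"].shape)
        return loss, g


def spacesof(p: dict) -> AttentionSpaces:
    return AttentionSpaces(p["W_f"], p["W_g"], p["W_h"],
                           p["b_f"], p["b_g"], p["b_h"])


def build(cfg: NetConfig, seed: int = 0) -> Network:
    """Construct a seeded, He-uniform-initialised network."""
    return Network(cfg, seed=seed)


# ---------------------------------------------------------------------------
# training

def train(
    network: Network,
    images: np.ndarray,
    labels,
    tc: TrainConfig,
) -> list[float]:
    """SGD with momentum and per-step multiplicative lr decay.

    ``images`` is (n, S, S); ``labels`` is a sequence of class names or
    integer indices.  Returns the per-epoch mean training loss.  Epochs are
    shuffled under ``tc.seed``; identical seeds give identical traces.
    """
    y, classes = _encode_labels(labels, network.cfg.n_classes)
    n = len(y)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes present")
    if tc.batch_size > n:
        raise ValueError(f"batch_size {tc.batch_size} exceeds dataset size {n}")
    rng = np.random.default_rng(tc.seed)
    vel = {k: np.zeros_like(v) for k, v in network.params.items()}
    step = 0
    trace: list[float] = []
    for _ in range(tc.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n - tc.batch_size + 1, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            loss, grads = network.loss_and_grads(images[idx], y[idx])
            lr = tc.learning_rate * (1.0 - tc.lr_decay) ** step
            for k in network.params:
                vel[k] = tc.momentum * vel[k] - lr * grads[k]
                network.params[k] += vel[k]
            losses.append(loss)
            step += 1
        if not losses:  # batch_size == n handled above; guard anyway
            loss, _ = network.loss_and_grads(images, y)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    if not all(np.isfinite(trace)):
        raise FloatingPointError(f"non-finite training loss trace: {trace}")
    return trace


def _encode_labels(labels, n_classes: int):
    labels = list(labels)
    if all(isinstance(l, (int, np.integer)) for l in labels):
        y = np.asarray(labels, dtype=int)
        classes = sorted(set(labels))
    else:
        classes = sorted(set(labels))
        lut = {c: i for i, c in enumerate(classes)}
        y = np.array([lut[l] for l in labels], dtype=int)
    if len(classes) > n_classes:
        raise ValueError(
            f"{len(classes)} classes present but network head has {n_classes}"
        )
    return y, classes


def extract_sfvs(network: Network, images: np.ndarray, batch_size: int = 32):
    """Order-preserving batched SFV extraction; returns an (n, flat) array."""
    images = np.asarray(images, dtype=float)
    out = []
    for start in range(0, len(images), batch_size):
        _, sfv = network.forward(images[start : start + batch_size])
        out.append(sfv)
    return np.concatenate(out, axis=0) if out else np.empty((0, network.flatten_length))


# ---------------------------------------------------------------------------
# persistence

def save_checkpoint(network: Network, path) -> None:
    meta = dict(version=CHECKPOINT_VERSION, seed=network.seed,
                cfg=asdict(network.cfg))
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **network.params)


def load_checkpoint(path) -> Network:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg_d = meta["cfg"]
    cfg_d["conv_channels"] = tuple(cfg_d["conv_channels"])
    net = Network(NetConfig(**cfg_d), seed=meta["seed"])
    for k in net.params:
        net.params[k] = np.array(data[k])
    return net
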