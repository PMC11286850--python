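"""The contact-map predictor: sequence trunk + caRNA features + dilated heads.

Architecture (per ~1 Mb window):

1. one-hot DNA (4 x L) -> ``log2(bin_bp)`` convolution blocks, each
   convolution + batch norm + ReLU + max-pool-by-2, reducing 1-bp resolution
   to one embedding per 2048-bp bin;
2. concatenation of the per-bin feature channels (nascent / trans-group /
   ATAC / RNA-seq, already natural-log scaled);
3. a dilated 1D convolution stack (residual) for long-range dependencies;
4. 1D -> 2D pair averaging, ``P[i,j] = (u_i + u_j) / 2`` (exchange-symmetric
   by construction);
5. a dilated 2D convolution head producing one value per bin pair, explicitly
   symmetrized at the output.

Training maximizes Pearson's correlation between predicted and experimental
maps over the upper triangle (diagonal offset 2).  Each model is trained
``n_replicates`` times with distinct seeds; the replicate with the best mean
rank over (validation MSE ascending, validation Pearson descending) is
selected.

The whole network, backprop and Adam optimizer are implemented on numpy so
the model runs (and trains, at desk scale) on a single CPU with no deep
learning framework.  All randomness flows from explicit seeds; inference is
deterministic (batch-norm statistics frozen, no dropout).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

DTYPE = np.float32


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    window_bp: int = 2**20
    bin_bp: int = 2048
    n_feature_channels: int = 0
    trunk_channels: int = 8
    trunk_kernel_first: int = 15
    trunk_kernel: int = 3
    dilated_1d_channels: int = 16
    dilations_1d: tuple = (1, 2, 4)
    dilations_2d: tuple = (1, 2)
    head_kernel: int = 3
    diag_offset: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.bin_bp & (self.bin_bp - 1):
            raise ValueError("bin_bp must be a power of two")
        if self.window_bp % self.bin_bp:
            raise ValueError("window_bp must be a multiple of bin_bp")

    @property
    def n_conv_blocks(self) -> int:
        # one pool-by-2 per block takes 1-bp resolution to bin_bp resolution
        return int(np.log2(self.bin_bp))

    @property
    def n_bins(self) -> int:
        return self.window_bp // self.bin_bp


@dataclass
class TrainConfig:
    lr: float = 0.01
    epochs: int = 40
    batch_size: int = 4
    n_replicates: int = 5
    seeds: tuple = (0, 1, 2, 3, 4)
    weight_decay: float = 0.0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if len(set(self.seeds[: self.n_replicates])) < self.n_replicates:
            raise ValueError("replicate seeds must be distinct")


# ---------------------------------------------------------------------------
# Sequence encoding
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_sequence(seq: str) -> np.ndarray:
    """One-hot encode ACGT as (L, 4); N (or any other code) -> uniform 0.25."""
    arr = np.full((len(seq), 4), 0.25, dtype=DTYPE)
    idx = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    code = lut[idx]
    known = code >= 0
    arr[known, :] = 0.0
    arr[np.flatnonzero(known), code[known]] = 1.0
    return arr


# ---------------------------------------------------------------------------
# Layers (forward + backward, float32)
# ---------------------------------------------------------------------------

class _Param:
    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


class Conv1d:
    """Same-padded 1D convolution via im2col + one GEMM per direction.

    Channels-last layout: x is (B, L, C)."""

    _CACHE_MAX = 48_000_000  # cols elements above this are recomputed in backward

    def __init__(self, cin, cout, k, dilation=1, rng=None):
        scale = np.sqrt(2.0 / (cin * k))
        self.W = _Param(rng.normal(0, scale, size=(k, cin, cout)))
        self.b = _Param(np.zeros(cout))
        self.k, self.d = k, dilation
        self.pad = (k - 1) // 2 * dilation

    def params(self):
        return [self.W, self.b]

    def _cols(self, xp, L):
        # (B, Lp, C) -> (B, L, k*C)
        span = (self.k - 1) * self.d + 1
        view = np.lib.stride_tricks.sliding_window_view(xp, span, axis=1)
        view = view[:, :L, :, :: self.d]  # (B, L, C, k)
        return view.transpose(0, 1, 3, 2).reshape(xp.shape[0], L, -1)

    def forward(self, x, train=True):
        # x: (B, L, C)
        B, L, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        cols = self._cols(xp, L)
        self._xp, self._L = xp, L
        self._cols_cache = cols if cols.size <= self._CACHE_MAX else None
        Wm = self.W.value.reshape(-1, self.W.value.shape[2])  # (k*C, Cout)
        return cols @ Wm + self.b.value

    def backward(self, dy):
        # dy: (B, L, Cout)
        B, L, cout = dy.shape
        self.b.grad += dy.sum(axis=(0, 1))
        cols = self._cols_cache
        if cols is None:
            cols = self._cols(self._xp, L)
        flat_cols = cols.reshape(-1, cols.shape[2])
        flat_dy = np.ascontiguousarray(dy).reshape(-1, cout)
        self.W.grad += (flat_cols.T @ flat_dy).reshape(self.W.value.shape)
        Wm = self.W.value.reshape(-1, cout)
        dcols = (flat_dy @ Wm.T).reshape(B, L, self.k, -1)  # (B, L, k, C)
        dxp = np.zeros_like(self._xp)
        for j in range(self.k):
            dxp[:, j * self.d: j * self.d + L, :] += dcols[:, :, j, :]
        self._xp = self._cols_cache = None
        return dxp[:, self.pad: self.pad + self._L, :] if self.pad else dxp


class BatchNorm:
    """Batch normalization over all axes but the (last) channel axis."""

    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = _Param(np.ones(c))
        self.beta = _Param(np.zeros(c))
        self.run_mean = np.zeros(c, dtype=DTYPE)
        self.run_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = np.maximum((x * x).mean(axis=axes) - mean * mean, 0.0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps).astype(DTYPE)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value
        if not self._train:
            out = dy * g / self._std
        else:
            dxhat = dy * g
            out = (dxhat - dxhat.mean(axis=axes, keepdims=True)
                   - self._xhat * (dxhat * self._xhat).mean(axis=axes, keepdims=True)
                   ) / self._std
        self._xhat = None
        return out


class ReLU:
    def params(self):
        return []

    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        out = dy * self._mask
        self._mask = None
        return out


class MaxPool1d:
    """Pool-by-2 along the length axis (ties break toward the left element)."""

    def params(self):
        return []

    def forward(self, x, train=True):
        B, L, C = x.shape
        pairs = x.reshape(B, L // 2, 2, C)
        self._left = pairs[:, :, 0, :] >= pairs[:, :, 1, :]
        return np.where(self._left, pairs[:, :, 0, :], pairs[:, :, 1, :])

    def backward(self, dy):
        B, Lh, C = dy.shape
        out = np.zeros((B, Lh, 2, C), dtype=dy.dtype)
        out[:, :, 0, :] = dy * self._left
        out[:, :, 1, :] = dy * ~self._left
        self._left = None
        return out.reshape(B, Lh * 2, C)


class Conv2d:
    """Same-padded 2D convolution via im2col; layout (B, H, W, C)."""

    def __init__(self, cin, cout, k, dilation=1, rng=None):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = _Param(rng.normal(0, scale, size=(k, k, cin, cout)))
        self.b = _Param(np.zeros(cout))
        self.k, self.d = k, dilation
        self.pad = (k - 1) // 2 * dilation

    def params(self):
        return [self.W, self.b]

    def _cols(self, xp, H, Wd):
        span = (self.k - 1) * self.d + 1
        view = np.lib.stride_tricks.sliding_window_view(xp, (span, span), axis=(1, 2))
        view = view[:, :H, :Wd, :, :: self.d, :: self.d]  # (B, H, W, C, k, k)
        return view.transpose(0, 1, 2, 4, 5, 3).reshape(xp.shape[0], H, Wd, -1)

    def forward(self, x, train=True):
        B, H, Wd, C = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp, self._hw = xp, (H, Wd)
        cols = self._cols(xp, H, Wd)
        self._cols_cache = cols
        Wm = self.W.value.reshape(-1, self.W.value.shape[3])
        return cols @ Wm + self.b.value

    def backward(self, dy):
        H, Wd = self._hw
        B = dy.shape[0]
        cout = dy.shape[3]
        self.b.grad += dy.sum(axis=(0, 1, 2))
        cols = self._cols_cache
        flat_cols = cols.reshape(-1, cols.shape[3])
        flat_dy = np.ascontiguousarray(dy).reshape(-1, cout)
        self.W.grad += (flat_cols.T @ flat_dy).reshape(self.W.value.shape)
        Wm = self.W.value.reshape(-1, cout)
        dcols = (flat_dy @ Wm.T).reshape(B, H, Wd, self.k, self.k, -1)
        dxp = np.zeros_like(self._xp)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i * self.d: i * self.d + H, j * self.d: j * self.d + Wd, :] += \
                    dcols[:, :, :, i, j, :]
        self._xp = self._cols_cache = None
        p = self.pad
        return dxp[:, p: p + H, p: p + Wd, :] if p else dxp


class PairAverage:
    """1D -> 2D: ``P[:, i, j, :] = (u_i + u_j) / 2`` (exchange-symmetric)."""

    def params(self):
        return []

    def forward(self, x, train=True):
        # x: (B, n, C) -> (B, n, n, C)
        return 0.5 * (x[:, :, None, :] + x[:, None, :, :])

    def backward(self, dy):
        return 0.5 * (dy.sum(axis=2) + dy.sum(axis=1))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class _Residual1d:
    """x + ReLU(BN(dilated conv(x))), channel-preserving."""

    def __init__(self, c, k, dilation, rng):
        self.conv = Conv1d(c, c, k, dilation, rng)
        self.bn = BatchNorm(c)
        self.act = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train=True):
        return x + self.act.forward(self.bn.forward(self.conv.forward(x, train), train))

    def backward(self, dy):
        return dy + self.conv.backward(self.bn.backward(self.act.backward(dy)))


class _Residual2d:
    def __init__(self, c, k, dilation, rng):
        self.conv = Conv2d(c, c, k, dilation, rng)
        self.bn = BatchNorm(c)
        self.act = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train=True):
        return x + self.act.forward(self.bn.forward(self.conv.forward(x, train), train))

    def backward(self, dy):
        return dy + self.conv.backward(self.bn.backward(self.act.backward(dy)))


class ContactMapModel:
    """Sequence trunk -> feature concat -> dilated 1D -> pair avg -> 2D head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        # affine output calibration (the Pearson objective is scale-free;
        # gain/bias are fitted on training windows after training so MSE and
        # map values live on the target scale)
        self.out_gain = 1.0
        self.out_bias = 0.0
        rng = np.random.default_rng(config.seed)
        c = config.trunk_channels
        self.trunk = []
        cin = 4
        for i in range(config.n_conv_blocks):
            k = config.trunk_kernel_first if i == 0 else config.trunk_kernel
            self.trunk.append((Conv1d(cin, c, k, 1, rng), BatchNorm(c), ReLU(),
                               MaxPool1d()))
            cin = c
        d1 = config.dilated_1d_channels
        self.bottleneck = Conv1d(c + config.n_feature_channels, d1, 1, 1, rng)
        self.dilated1d = [_Residual1d(d1, 3, d, rng) for d in config.dilations_1d]
        self.pair = PairAverage()
        self.dilated2d = [_Residual2d(d1, config.head_kernel, d, rng)
                          for d in config.dilations_2d]
        self.head = Conv2d(d1, 1, 1, 1, rng)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        ps = []
        for conv, bn, act, pool in self.trunk:
            ps += conv.params() + bn.params()
        ps += self.bottleneck.params()
        for blk in self.dilated1d:
            ps += blk.params()
        for blk in self.dilated2d:
            ps += blk.params()
        ps += self.head.params()
        return ps

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- forward / backward -------------------------------------------------
    def forward(self, seqs, features=None, train=False):
        """seqs (B, L, 4); features (B, n_bins, F) or None -> (B, n, n)."""
        cfg = self.config
        if seqs.shape[1] != cfg.window_bp:
            raise ValueError(f"sequence length {seqs.shape[1]} != window {cfg.window_bp}")
        if cfg.n_feature_channels:
            if features is None or features.shape[2] != cfg.n_feature_channels:
                got = None if features is None else features.shape[2]
                raise ValueError(
                    f"expected {cfg.n_feature_channels} feature channels, got {got}")
        x = seqs.astype(DTYPE)
        for conv, bn, act, pool in self.trunk:
            x = pool.forward(act.forward(bn.forward(conv.forward(x, train), train)))
        self._n_trunk_channels = x.shape[2]
        if cfg.n_feature_channels:
            x = np.concatenate([x, features.astype(DTYPE)], axis=2)
        x = self.bottleneck.forward(x, train)
        for blk in self.dilated1d:
            x = blk.forward(x, train)
        x = self.pair.forward(x)
        for blk in self.dilated2d:
            x = blk.forward(x, train)
        m = self.head.forward(x, train)[..., 0]  # (B, n, n)
        return 0.5 * (m + m.transpose(0, 2, 1))

    def backward(self, dmap):
        """Backprop d(loss)/d(map); returns (dseq, dfeatures)."""
        d = 0.5 * (dmap + dmap.transpose(0, 2, 1))
        d = self.head.backward(d[..., None].astype(DTYPE))
        for blk in reversed(self.dilated2d):
            d = blk.backward(d)
        d = self.pair.backward(d)
        for blk in reversed(self.dilated1d):
            d = blk.backward(d)
        d = self.bottleneck.backward(d)
        c = self._n_trunk_channels
        dfeat = d[:, :, c:] if self.config.n_feature_channels else None
        d = d[:, :, :c]
        for conv, bn, act, pool in reversed(self.trunk):
            d = conv.backward(bn.backward(act.backward(pool.backward(d))))
        return d, dfeat

    def predict(self, seqs, features=None):
        return self.out_gain * self.forward(seqs, features, train=False) + self.out_bias

    def calibrate_output(self, seqs, features, targets, offset=None, batch_size=4):
        """Fit the affine output calibration by least squares on given data."""
        offset = self.config.diag_offset if offset is None else offset
        n = targets.shape[-1]
        iu = np.triu_indices(n, k=offset)
        ps, ts = [], []
        for i in range(0, len(seqs), batch_size):
            raw = self.forward(seqs[i:i + batch_size],
                               None if features is None else features[i:i + batch_size],
                               train=False)
            ps.append(np.concatenate([m[iu] for m in raw]))
            ts.append(np.concatenate([t[iu] for t in targets[i:i + batch_size]]))
        p, t = np.concatenate(ps), np.concatenate(ts)
        if p.std() == 0:
            self.out_gain, self.out_bias = 1.0, float(t.mean() - p.mean())
        else:
            g = float(np.cov(p, t)[0, 1] / p.var())
            self.out_gain, self.out_bias = g, float(t.mean() - g * p.mean())
        return self.out_gain, self.out_bias

    def feature_gradient(self, seqs, features, output_weights=None):
        """Gradient of a scalar map summary w.r.t. the feature channels.

        The default summary is the mean predicted contact value of the window
        (the scalar used for attribution); ``output_weights`` (n x n) selects
        any other linear summary.
        """
        pred = self.forward(seqs, features, train=False)
        n = pred.shape[1]
        w = (np.full((n, n), 1.0 / (n * n), dtype=DTYPE)
             if output_weights is None else output_weights.astype(DTYPE))
        dmap = np.broadcast_to(w, pred.shape).copy()
        _, dfeat = self.backward(dmap)
        return pred, dfeat

    # -- checkpointing ------------------------------------------------------
    def save(self, path):
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        bns = [l for l in self._all_layers() if isinstance(l, BatchNorm)]
        for i, bn in enumerate(bns):
            arrays[f"rm{i}"] = bn.run_mean
            arrays[f"rv{i}"] = bn.run_var
        arrays["out_affine"] = np.array([self.out_gain, self.out_bias])
        cfg = json.dumps(asdict(self.config))
        np.savez_compressed(path, _config=np.frombuffer(cfg.encode(), dtype=np.uint8),
                            **arrays)
        return Path(path)

    def _all_layers(self):
        out = []
        for conv, bn, act, pool in self.trunk:
            out += [conv, bn]
        out.append(self.bottleneck)
        for blk in self.dilated1d + self.dilated2d:
            out += [blk.conv, blk.bn]
        out.append(self.head)
        return out

    @classmethod
    def load(cls, path):
        data = np.load(path)
        cfg_dict = json.loads(bytes(data["_config"]).decode())
        cfg_dict["dilations_1d"] = tuple(cfg_dict["dilations_1d"])
        cfg_dict["dilations_2d"] = tuple(cfg_dict["dilations_2d"])
        model = cls(ModelConfig(**cfg_dict))
        for i, p in enumerate(model.parameters()):
            p.value[...] = data[f"p{i}"]
        bns = [l for l in model._all_layers() if isinstance(l, BatchNorm)]
        for i, bn in enumerate(bns):
            bn.run_mean = data[f"rm{i}"]
            bn.run_var = data[f"rv{i}"]
        if "out_affine" in data:
            model.out_gain, model.out_bias = map(float, data["out_affine"])
        return model


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def pearson_loss(pred, target, offset=2, with_grad=False):
    """``1 - r`` averaged over the batch, on upper-triangle (offset) entries.

    Scale/shift invariant in either argument.  A zero-variance target makes
    the correlation undefined; the loss is then 1 with zero gradient (warned).
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    single = pred.ndim == 2
    if single:
        pred, target = pred[None], target[None]
    B, n, _ = pred.shape
    iu = np.triu_indices(n, k=offset)
    losses = []
    grad = np.zeros_like(pred)
    for b in range(B):
        p = pred[b][iu]
        t = target[b][iu]
        u = p - p.mean()
        v = t - t.mean()
        su, sv = np.sqrt((u * u).sum()), np.sqrt((v * v).sum())
        if sv == 0 or su == 0:
            warnings.warn("zero-variance map in pearson_loss; loss set to 1")
            losses.append(1.0)
            continue
        r = (u * v).sum() / (su * sv)
        losses.append(1.0 - r)
        if with_grad:
            dr_du = (v - r * (sv / su) * u) / (su * sv)
            dr_dp = dr_du - dr_du.mean()
            g = np.zeros((n, n))
            g[iu] = -dr_dp / B  # loss reads the upper triangle only; the
            grad[b] = g         # head's symmetrization splits it correctly
    loss = float(np.mean(losses))
    if single:
        grad = grad[0]
    return (loss, grad) if with_grad else loss


def map_mse(pred, target, offset=2):
    iu = np.triu_indices(pred.shape[-1], k=offset)
    if pred.ndim == 2:
        return float(np.mean((pred[iu] - target[iu]) ** 2))
    return float(np.mean([(p[iu] - t[iu]) ** 2 for p, t in zip(pred, target)]))


# ---------------------------------------------------------------------------
# Optimizer + training
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.wd = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad + self.wd * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.value -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(DTYPE)


@dataclass
class TrainResult:
    model: ContactMapModel
    log: list  # (epoch, train_loss, valid_pearson, valid_mse)
    best_valid_pearson: float
    best_valid_mse: float
    seed: int = 0
    failed: bool = False


def _evaluate(model, seqs, feats, targets, offset, batch_size=4):
    rs, mses = [], []
    for i in range(0, len(seqs), batch_size):
        pred = model.predict(seqs[i:i + batch_size],
                             None if feats is None else feats[i:i + batch_size])
        tgt = targets[i:i + batch_size]
        rs.append(1.0 - pearson_loss(pred, tgt, offset))
        mses.append(map_mse(pred, tgt, offset))
    return float(np.mean(rs)), float(np.mean(mses))


def train_model(config: ModelConfig, train_data, valid_data, tc: TrainConfig,
                seed=0, verbose=False) -> TrainResult:
    """Train one replicate; keeps the best-validation-Pearson parameter set.

    ``train_data``/``valid_data`` are ``(seqs, features, targets)`` tuples;
    ``features`` may be None for the sequence-only variant.  A NaN loss aborts
    the replicate (``failed=True``) instead of raising.
    """
    cfg = ModelConfig(**{**asdict(config), "seed": seed})
    cfg.dilations_1d = tuple(cfg.dilations_1d)
    cfg.dilations_2d = tuple(cfg.dilations_2d)
    model = ContactMapModel(cfg)
    seqs, feats, targets = train_data
    vseqs, vfeats, vtargets = valid_data
    opt = Adam(model.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
    rng = np.random.default_rng(seed + 10_000)
    offset = cfg.diag_offset
    log = []
    best = (-np.inf, np.inf, None)  # (pearson, mse, params snapshot)
    n = len(seqs)
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        ep_loss = []
        for i in range(0, n, tc.batch_size):
            idx = order[i:i + tc.batch_size]
            model.zero_grad()
            pred = model.forward(seqs[idx],
                                 None if feats is None else feats[idx], train=True)
            loss, grad = pearson_loss(pred, targets[idx], offset, with_grad=True)
            if not np.isfinite(loss):
                return TrainResult(model, log, -np.inf, np.inf, seed, failed=True)
            model.backward(grad)
            opt.step()
            ep_loss.append(loss)
        vp, vm = _evaluate(model, vseqs, vfeats, vtargets, offset, tc.batch_size)
        log.append((epoch, float(np.mean(ep_loss)), vp, vm))
        if verbose:
            print(f"epoch {epoch}: train_loss={np.mean(ep_loss):.4f} "
                  f"valid_r={vp:.4f} valid_mse={vm:.4f}")
        if vp > best[0]:
            best = (vp, vm, [p.value.copy() for p in model.parameters()],
                    [(bn.run_mean.copy(), bn.run_var.copy())
                     for bn in model._all_layers() if isinstance(bn, BatchNorm)])
    if best[2] is not None:
        for p, v in zip(model.parameters(), best[2]):
            p.value[...] = v
        bns = [l for l in model._all_layers() if isinstance(l, BatchNorm)]
        for bn, (rm, rv) in zip(bns, best[3]):
            bn.run_mean, bn.run_var = rm, rv
    # fit the affine output calibration on the training windows, then report
    # validation MSE on the calibrated scale (Pearson is unaffected)
    model.calibrate_output(seqs, feats, targets, offset, tc.batch_size)
    vp, vm = _evaluate(model, vseqs, vfeats, vtargets, offset, tc.batch_size)
    return TrainResult(model, log, vp, vm, seed)


def train_replicates(config: ModelConfig, train_data, valid_data,
                     tc: TrainConfig, verbose=False):
    """Train ``n_replicates`` seeds; returns (selected, all_results).

    Selection: best mean rank over (validation MSE ascending, validation
    Pearson descending), as the published training protocol prescribes.
    """
    results = []
    for seed in tc.seeds[: tc.n_replicates]:
        results.append(train_model(config, train_data, valid_data, tc, seed,
                                   verbose=verbose))
    ok = [r for r in results if not r.failed]
    if not ok:
        raise RuntimeError("all replicates failed with non-finite loss")
    mse_rank = np.argsort(np.argsort([r.best_valid_mse for r in ok]))
    r_rank = np.argsort(np.argsort([-r.best_valid_pearson for r in ok]))
    mean_rank = (mse_rank + r_rank) / 2.0
    # ties on mean rank go to the higher validation Pearson (the objective)
    order = sorted(range(len(ok)),
                   key=lambda i: (mean_rank[i], -ok[i].best_valid_pearson))
    selected = ok[order[0]]
    return selected, results


def predict_batch(model: ContactMapModel, seqs, features=None, batch_size=4):
    """Order-preserving batched prediction -> (N, n, n) array."""
    out = []
    for i in range(0, len(seqs), batch_size):
        out.append(model.predict(
            seqs[i:i + batch_size],
            None if features is None else features[i:i + batch_size]))
    return np.concatenate(out, axis=0)
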