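"""Patch-based 3D CNN for vessel segmentation, in pure NumPy.

The network maps a 33x33x7 intensity patch to foreground probabilities for
the central 5x5x1 block:

    3 x [conv 3x3x3, 32 ch, ReLU]  (33x33x7 -> 27x27x1, valid)
    max pool 2x2 in-plane          (27 -> 14, ceil)
    2 x [conv 3x3, 64 ch, ReLU]    (14 -> 10)
    max pool 2x2 in-plane          (10 -> 5)
    dense 1024, ReLU, dropout 0.5
    dense -> 5x5x1x2 logits, softmax over the two channels

All convolutions are unpadded ("valid"), which is what shrinks the input
tile to exactly the 5x5x1 output geometry; the first pool uses ceil
semantics (27 -> 14) for the same reason.  Pooling is 2D because the depth
extent is already reduced to a single slice by the third convolution.

Training minimizes a cross-entropy in which true-negative voxels (label 0,
predicted probability below threshold) contribute nothing — this counters
the extreme foreground/background imbalance of angiograms.  Confusion-class
membership is non-differentiable gating: the mask is computed from the
current probabilities and gradients flow only through the cross-entropy of
the masked voxels.  Optimization is Adam; forward, backward and the update
rule are implemented here directly on float32 BLAS matmuls, so a fixed seed
gives bit-reproducible training.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .core import ImageStack, as_binary

log = logging.getLogger(__name__)

INPUT_TILE = (7, 33, 33)  # (z, y, x)
OUTPUT_TILE = (5, 5, 1)  # (y, x, z) as reported to users
_EPS = 1e-7
_COMPUTE_CHUNK = 8  # micro-chunk size keeping conv activations cache-resident


@dataclass
class ModelConfig:
    """Hyperparameters; geometry (tile sizes, kernel shapes) is fixed."""

    conv_channels1: int = 32
    conv_channels2: int = 64
    hidden_nodes: int = 1024
    dropout_rate: float = 0.5
    learning_rate: float = 1e-4
    epochs: int = 100
    minibatch: int = 1000
    seed: int = 0
    loss_threshold: float = 0.5
    early_stop_patience: int | None = None
    early_stop_min_delta: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if min(self.conv_channels1, self.conv_channels2, self.hidden_nodes) < 1:
            raise ValueError("channel and hidden-node counts must be positive")
        if self.epochs < 1 or self.minibatch < 1:
            raise ValueError("epochs and minibatch must be positive")


#: Named presets: paper-scale settings and a CPU desk-scale configuration.
PRESETS: dict[str, ModelConfig] = {
    "exploration": ModelConfig(learning_rate=1e-4, epochs=100, minibatch=1000),
    "finetune": ModelConfig(learning_rate=1e-6, epochs=30000, minibatch=1000),
    "desk": ModelConfig(
        learning_rate=1e-3, epochs=200, minibatch=256,
        early_stop_patience=2, early_stop_min_delta=0.01,
    ),
}


# ---------------------------------------------------------------------------
# layer primitives (channel-last, float32)


def _window_view(x, dz, dy, zo, yo, xo, run):
    """Strided (n, zo, yo, xo, run) view of C-contiguous ``x``, shifted by
    (dz, dy).

    ``run`` spans the contiguous (kx, c) block, which is what lets BLAS see
    a K = kx*c contraction without materializing an im2col matrix.  Strides
    are derived from the shape rather than read off the array: NumPy keeps
    arbitrary (often zero) strides on size-1 axes even for contiguous
    arrays, and a zero run stride would silently read one voxel ``run``
    times.
    """
    n, z, y, xx, c = x.shape
    it = x.itemsize
    strides = (z * y * xx * c * it, y * xx * c * it, xx * c * it, c * it, it)
    return np.lib.stride_tricks.as_strided(
        x[:, dz:, dy:, :, :], shape=(n, zo, yo, xo, run), strides=strides
    )


def _conv_forward(x, w, b):
    kz, ky, kx, cin, cout = w.shape
    if not x.flags["C_CONTIGUOUS"]:
        x = np.ascontiguousarray(x)
    n, z, y, xx, _ = x.shape
    zo, yo, xo = z - kz + 1, y - ky + 1, xx - kx + 1
    wr = w.reshape(kz * ky, kx * cin, cout)
    out = None
    k = 0
    for dz in range(kz):
        for dy in range(ky):
            src = _window_view(x, dz, dy, zo, yo, xo, kx * cin)
            contrib = src @ wr[k]
            out = contrib if out is None else out + contrib
            k += 1
    out += b
    return out


def _conv_backward(dout, x, w, need_dx=True):
    kz, ky, kx, cin, cout = w.shape
    if not x.flags["C_CONTIGUOUS"]:
        x = np.ascontiguousarray(x)
    n, z, y, xx, _ = x.shape
    zo, yo, xo = z - kz + 1, y - ky + 1, xx - kx + 1
    dout = np.ascontiguousarray(dout)
    dwr = np.empty((kz * ky, kx * cin, cout), dtype=w.dtype)
    k = 0
    for dz in range(kz):
        for dy in range(ky):
            src = _window_view(x, dz, dy, zo, yo, xo, kx * cin)
            dwr[k] = np.tensordot(src, dout, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
            k += 1
    db = dout.sum(axis=(0, 1, 2, 3))
    dx = None
    if need_dx:
        # gradient w.r.t. the input is a full correlation with the flipped,
        # transposed kernel; reuse the forward pass on zero-padded dout
        dpad = np.zeros(
            (n, zo + 2 * (kz - 1), yo + 2 * (ky - 1), xo + 2 * (kx - 1), cout), dtype=dout.dtype
        )
        dpad[:, kz - 1 : kz - 1 + zo, ky - 1 : ky - 1 + yo, kx - 1 : kx - 1 + xo, :] = dout
        wt = np.ascontiguousarray(w[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3))
        dx = _conv_forward(dpad, wt, np.zeros(cin, dtype=w.dtype))
    return dx, dwr.reshape(w.shape), db


def _pool_forward(x):
    """2x2 in-plane max pool, stride 2, ceil mode (odd extents padded with -inf)."""
    n, z, y, xx, c = x.shape
    yp, xp = -(-y // 2) * 2, -(-xx // 2) * 2
    if (yp, xp) != (y, xx):
        x = np.pad(x, ((0, 0), (0, 0), (0, yp - y), (0, xp - xx), (0, 0)),
                   constant_values=-np.inf)
    xr = x.reshape(n, z, yp // 2, 2, xp // 2, 2, c)
    xm = xr.transpose(0, 1, 2, 4, 6, 3, 5).reshape(n, z, yp // 2, xp // 2, c, 4)
    idx = xm.argmax(-1)
    out = np.take_along_axis(xm, idx[..., None], -1)[..., 0]
    return out, (idx, (n, z, y, xx, c), (yp, xp))


def _pool_backward(dout, cache):
    idx, (n, z, y, xx, c), (yp, xp) = cache
    dxm = np.zeros((n, z, yp // 2, xp // 2, c, 4), dtype=np.float32)
    np.put_along_axis(dxm, idx[..., None], dout[..., None], -1)
    dxp = (
        dxm.reshape(n, z, yp // 2, xp // 2, c, 2, 2)
        .transpose(0, 1, 2, 5, 3, 6, 4)
        .reshape(n, z, yp, xp, c)
    )
    return dxp[:, :, :y, :xx, :]


# ---------------------------------------------------------------------------
# loss


def masked_cross_entropy(
    y: np.ndarray, p: np.ndarray, threshold: float = 0.5, reduction: str = "sum"
) -> float:
    """Cross-entropy summed over all voxels except true negatives.

    A voxel is a true negative when its label is 0 and its predicted
    foreground probability is below ``threshold``; such voxels contribute
    zero.  Probabilities are epsilon-clipped before the logarithms.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: labels {y.shape} vs probabilities {p.shape}")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    mask = (y == 1) | (p >= threshold)  # TP, FN, FP; excludes TN
    ce = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    total = float((ce * mask).sum())
    if reduction == "mean":
        return total / max(int(mask.sum()), 1)
    return total


def binary_entropy(p: np.ndarray) -> np.ndarray:
    """Shannon entropy in bits of a Bernoulli(p) map; H(0) = H(1) = 0."""
    p = np.asarray(p, dtype=np.float64)
    out = np.zeros_like(p)
    interior = (p > 0) & (p < 1)
    q = p[interior]
    out[interior] = -q * np.log2(q) - (1 - q) * np.log2(1 - q)
    return out


# ---------------------------------------------------------------------------
# the network


class VesselPatchCNN:
    """The fixed-geometry patch CNN; see the module docstring."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        c1, c2, h = cfg.conv_channels1, cfg.conv_channels2, cfg.hidden_nodes
        rng = np.random.default_rng(cfg.seed)

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        self.params: dict[str, np.ndarray] = {
            "w1": he((3, 3, 3, 1, c1), 27),
            "b1": np.zeros(c1, np.float32),
            "w2": he((3, 3, 3, c1, c1), 27 * c1),
            "b2": np.zeros(c1, np.float32),
            "w3": he((3, 3, 3, c1, c1), 27 * c1),
            "b3": np.zeros(c1, np.float32),
            "w4": he((1, 3, 3, c1, c2), 9 * c1),
            "b4": np.zeros(c2, np.float32),
            "w5": he((1, 3, 3, c2, c2), 9 * c2),
            "b5": np.zeros(c2, np.float32),
            "wf1": he((25 * c2, h), 25 * c2),
            "bf1": np.zeros(h, np.float32),
            "wf2": he((h, 50), h),
            "bf2": np.zeros(50, np.float32),
        }

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _forward(self, x, train=False, dropout_rng=None, dropout_rate=None):
        """x: (N, 7, 33, 33) -> logits (N, 25, 2) plus cache for backward."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[..., None]
        if x.shape[1:] != (7, 33, 33, 1):
            raise ValueError(f"expected (N, 7, 33, 33) input tiles, got {x.shape}")
        p = self.params
        cache: dict = {"x0": x}
        a = x
        for i in (1, 2, 3):
            z = _conv_forward(a, p[f"w{i}"], p[f"b{i}"])
            m = z > 0
            a = z * m
            cache[f"x{i}"] = a
            cache[f"m{i}"] = m
        a, cache["pool1"] = _pool_forward(a)
        cache["x3p"] = a
        for i in (4, 5):
            z = _conv_forward(a, p[f"w{i}"], p[f"b{i}"])
            m = z > 0
            a = z * m
            cache[f"x{i}"] = a
            cache[f"m{i}"] = m
        a, cache["pool2"] = _pool_forward(a)
        n = a.shape[0]
        flat = a.reshape(n, -1)
        cache["flat"] = flat
        h = flat @ p["wf1"] + p["bf1"]
        mh = h > 0
        h = h * mh
        cache["mh"] = mh
        rate = self.cfg.dropout_rate if dropout_rate is None else dropout_rate
        if train and rate > 0:
            if dropout_rng is None:
                raise ValueError("dropout requires an RNG in training mode")
            keep = (dropout_rng.random(h.shape) >= rate).astype(np.float32) / (1.0 - rate)
            h = h * keep
            cache["drop"] = keep
        cache["h"] = h
        logits = h @ p["wf2"] + p["bf2"]
        return logits.reshape(n, 25, 2), cache

    def _backward(self, dlogits, cache):
        p = self.params
        n = dlogits.shape[0]
        g: dict[str, np.ndarray] = {}
        d = dlogits.reshape(n, 50).astype(np.float32)
        g["wf2"] = cache["h"].T @ d
        g["bf2"] = d.sum(axis=0)
        dh = d @ p["wf2"].T
        if "drop" in cache:
            dh *= cache["drop"]
        dh *= cache["mh"]
        g["wf1"] = cache["flat"].T @ dh
        g["bf1"] = dh.sum(axis=0)
        dflat = dh @ p["wf1"].T
        da = dflat.reshape(n, 1, 5, 5, self.cfg.conv_channels2)
        da = _pool_backward(da, cache["pool2"])
        for i in (5, 4):
            da = da * cache[f"m{i}"]
            prev = cache["x3p"] if i == 4 else cache[f"x{i - 1}"]
            da, g[f"w{i}"], g[f"b{i}"] = _conv_backward(da, prev, p[f"w{i}"])
        da = _pool_backward(da, cache["pool1"])
        for i in (3, 2, 1):
            da = da * cache[f"m{i}"]
            prev = cache[f"x{i - 1}"]
            da, g[f"w{i}"], g[f"b{i}"] = _conv_backward(da, prev, p[f"w{i}"], need_dx=i > 1)
        return g

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Deterministic forward pass; logits of shape (N, 5, 5, 1, 2)."""
        logits, _ = self._forward(x, train=False)
        return logits.reshape(-1, 5, 5, 1, 2)

    def predict_proba(self, x: np.ndarray, train_dropout=False, dropout_rng=None) -> np.ndarray:
        """Foreground probabilities for the 5x5x1 output tiles, (N, 5, 5)."""
        logits, _ = self._forward(
            x, train=train_dropout, dropout_rng=dropout_rng,
            dropout_rate=self.cfg.dropout_rate if train_dropout else 0.0,
        )
        prob = _softmax(logits)[..., 1]
        return prob.reshape(-1, 5, 5)

    # -- persistence ---------------------------------------------------

    def save(self, weights_path, config_path=None) -> None:
        np.savez(weights_path, **self.params)
        if config_path is not None:
            with open(config_path, "w") as fh:
                json.dump(dataclasses.asdict(self.cfg), fh, indent=2)

    @classmethod
    def load(cls, weights_path, cfg: ModelConfig | None = None, config_path=None) -> "VesselPatchCNN":
        if cfg is None:
            if config_path is None:
                raise ValueError("provide either cfg or config_path")
            with open(config_path) as fh:
                d = json.load(fh)
            cfg = ModelConfig(**d)
        model = cls(cfg)
        with np.load(weights_path) as data:
            for k in model.params:
                model.params[k] = data[k].astype(np.float32)
        return model


def build_model(cfg: ModelConfig) -> VesselPatchCNN:
    """Construct the fixed-architecture patch CNN from a config."""
    return VesselPatchCNN(cfg)


def _softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# patch sampling


@dataclass
class PatchSet:
    """Training tiles: inputs (n, 7, 33, 33), binary targets (n, 5, 5), centers (n, 3)."""

    inputs: np.ndarray
    targets: np.ndarray
    centers: np.ndarray

    def __len__(self) -> int:
        return len(self.inputs)


def sample_patches(
    image: ImageStack | np.ndarray,
    labels: np.ndarray,
    n: int,
    balance: float = 0.5,
    seed: int = 0,
) -> PatchSet:
    """Draw training patch pairs, stratified by target-tile content.

    ``balance`` is the fraction of tiles whose central 5x5x1 target block
    contains at least one foreground voxel.  Border tiles read intensity
    context through reflection padding.  Deterministic for a fixed seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    data = image.data if isinstance(image, ImageStack) else np.asarray(image)
    labels = as_binary(labels)
    if data.shape != labels.shape:
        raise ValueError("image and label volumes must be aligned")
    rng = np.random.default_rng(seed)
    has_fg = ndimage.maximum_filter(labels, size=(1, 5, 5), mode="constant") > 0
    fg_centers = np.argwhere(has_fg)
    bg_centers = np.argwhere(~has_fg)
    n_fg = int(round(n * balance))
    if n_fg > 0 and len(fg_centers) == 0:
        raise ValueError("no foreground voxels available but balance > 0")
    if n - n_fg > 0 and len(bg_centers) == 0:
        n_fg = n
    picks = []
    if n_fg > 0:
        picks.append(fg_centers[rng.choice(len(fg_centers), n_fg, replace=len(fg_centers) < n_fg)])
    if n - n_fg > 0:
        picks.append(bg_centers[rng.choice(len(bg_centers), n - n_fg, replace=len(bg_centers) < n - n_fg)])
    centers = np.concatenate(picks, axis=0)
    order = rng.permutation(len(centers))
    centers = centers[order]

    pad = np.pad(data.astype(np.float32), ((3, 3), (16, 16), (16, 16)), mode="reflect")
    lpad = np.pad(labels, ((0, 0), (2, 2), (2, 2)), mode="constant")
    inputs = np.empty((len(centers), 7, 33, 33), dtype=np.float32)
    targets = np.empty((len(centers), 5, 5), dtype=np.uint8)
    for i, (cz, cy, cx) in enumerate(centers):
        inputs[i] = pad[cz : cz + 7, cy : cy + 33, cx : cx + 33]
        targets[i] = lpad[cz, cy : cy + 5, cx : cx + 5]
    return PatchSet(inputs=inputs, targets=targets, centers=centers)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainResult:
    loss_history: list[float] = field(default_factory=list)
    val_jaccard_history: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_jaccard: float = float("nan")


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, gr in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gr
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gr * gr
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _masked_ce_with_grad(logits, y, threshold, denom=None):
    """Masked cross-entropy and d(loss)/d(logits).

    Normalized by the number of contributing (non-TN) voxels unless an
    explicit ``denom`` is given (used when a minibatch is processed in
    micro-chunks and the caller normalizes across the whole batch).
    """
    m = logits.max(axis=-1, keepdims=True)
    shifted = logits - m
    lse = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    logp = shifted - lse  # (N, 25, 2) log-softmax
    prob = np.exp(logp)
    pf = prob[..., 1]
    yb = y.astype(np.float32)
    mask = (yb == 1) | (pf >= threshold)  # stop-gradient confusion gating
    ce = -(yb * logp[..., 1] + (1 - yb) * logp[..., 0])
    n_masked = int(mask.sum())
    d = max(n_masked, 1) if denom is None else denom
    loss = float((ce * mask).sum() / d)
    onehot = np.stack([1 - yb, yb], axis=-1)
    dlogits = (prob - onehot) * mask[..., None].astype(np.float32) / d
    return loss, dlogits, n_masked


def _patch_jaccard(model, inputs, targets, threshold, batch=32):
    tp = fp = fn = 0
    for i in range(0, len(inputs), batch):
        p = model.predict_proba(inputs[i : i + batch]) >= threshold
        t = targets[i : i + batch].astype(bool)
        tp += int(np.count_nonzero(p & t))
        fp += int(np.count_nonzero(p & ~t))
        fn += int(np.count_nonzero(~p & t))
    return tp / max(tp + fp + fn, 1)


def train(
    model: VesselPatchCNN,
    patches: PatchSet,
    cfg: ModelConfig | None = None,
    validation_fraction: float = 0.1,
    threshold: float = 0.5,
) -> TrainResult:
    """Adam training with per-epoch loss history and best-validation-Jaccard
    checkpointing; optional early stop when validation Jaccard plateaus."""
    cfg = cfg or model.cfg
    n = len(patches)
    if n < 1:
        raise ValueError("need at least one patch")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    n_val = int(n * validation_fraction)
    split = rng.permutation(n)
    val_idx, tr_idx = split[:n_val], split[n_val:]
    xin = patches.inputs.reshape(n, 7, 33, 33)
    yin = patches.targets.reshape(n, 25)
    opt = _Adam(model.params, cfg.learning_rate)
    result = TrainResult()
    best_params = None
    stale = 0
    chunk = _COMPUTE_CHUNK
    for epoch in range(cfg.epochs):
        order = tr_idx[rng.permutation(len(tr_idx))]
        losses = []
        for i in range(0, len(order), cfg.minibatch):
            idx = order[i : i + cfg.minibatch]
            # micro-chunked forward/backward: identical math to one big
            # batch (sum-reduced, then normalized by the joint mask count)
            grads = None
            loss_sum = 0.0
            mask_total = 0
            for j in range(0, len(idx), chunk):
                sub = idx[j : j + chunk]
                logits, cache = model._forward(xin[sub], train=True, dropout_rng=drop_rng)
                ls, dlogits, nm = _masked_ce_with_grad(logits, yin[sub], threshold, denom=1)
                loss_sum += ls
                mask_total += nm
                g = model._backward(dlogits, cache)
                if grads is None:
                    grads = g
                else:
                    for k in grads:
                        grads[k] += g[k]
            denom = max(mask_total, 1)
            loss = loss_sum / denom
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, batch {i // cfg.minibatch}"
                )
            losses.append(loss)
            for k in grads:
                grads[k] /= denom
            opt.step(model.params, grads)
        result.loss_history.append(float(np.mean(losses)) if losses else 0.0)
        if n_val > 0:
            vj = _patch_jaccard(model, xin[val_idx], patches.targets[val_idx], threshold)
            result.val_jaccard_history.append(vj)
            log.info("epoch %d: loss %.4f, val Jaccard %.4f", epoch, result.loss_history[-1], vj)
            prev_best = result.best_val_jaccard
            if not (vj <= prev_best):  # NaN-safe first update
                result.best_val_jaccard = vj
                result.best_epoch = epoch
                best_params = {k: v.copy() for k, v in model.params.items()}
                if np.isnan(prev_best) or vj - prev_best > cfg.early_stop_min_delta:
                    stale = 0
                else:
                    stale += 1  # improved, but below the plateau threshold
            else:
                stale += 1
            if cfg.early_stop_patience is not None and stale >= cfg.early_stop_patience:
                break
    if best_params is not None:
        model.params = best_params
    return result


# ---------------------------------------------------------------------------
# tiled inference


def predict_volume(
    model: VesselPatchCNN,
    image: ImageStack | np.ndarray,
    threshold: float = 0.5,
    batch: int = 32,
    _dropout_rng=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment a whole volume by tiling it into 5x5x1 output blocks.

    The blocks partition the volume exactly (stride 5, 5, 1); context
    outside the borders is supplied by reflection padding, so every voxel
    receives exactly one probability.  Returns ``(probabilities, mask)``.
    """
    data = image.data if isinstance(image, ImageStack) else np.asarray(image)
    nz, ny, nx = data.shape
    if nz < 7:
        raise ValueError("volume has fewer than 7 slices; reflection-pad it in z first")
    yb = -(-ny // 5) * 5
    xb = -(-nx // 5) * 5
    pad = np.pad(
        data.astype(np.float32),
        ((3, 3), (14, 14 + yb - ny), (14, 14 + xb - nx)),
        mode="reflect",
    )
    windows = sliding_window_view(pad, INPUT_TILE)[:, ::5, ::5]
    gz, gy, gx = windows.shape[:3]
    flat = windows.reshape(gz * gy * gx, *INPUT_TILE)
    out_blocks = np.empty((gz * gy * gx, 5, 5), dtype=np.float32)
    for i in range(0, len(flat), batch):
        out_blocks[i : i + batch] = model.predict_proba(
            np.ascontiguousarray(flat[i : i + batch]),
            train_dropout=_dropout_rng is not None,
            dropout_rng=_dropout_rng,
        )
    blocks = out_blocks.reshape(gz, gy, gx, 5, 5)
    prob = blocks.transpose(0, 1, 3, 2, 4).reshape(gz, yb, xb)
    prob = prob[:, :ny, :nx]
    return prob, (prob >= threshold).astype(np.uint8)


def entropy_map(
    model: VesselPatchCNN,
    image: ImageStack | np.ndarray,
    n_samples: int = 20,
    dropout_rate: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel predictive uncertainty from test-time dropout.

    Runs ``n_samples`` stochastic forward passes with dropout active,
    averages the foreground probabilities and returns the Shannon entropy
    map (bits) along with the mean probability volume.
    """
    if n_samples < 2:
        raise ValueError("need at least two stochastic samples")
    old_rate = model.cfg.dropout_rate
    model.cfg.dropout_rate = dropout_rate
    try:
        acc = None
        for k in range(n_samples):
            rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
            p, _ = predict_volume(model, image, _dropout_rng=rng)
            acc = p.astype(np.float64) if acc is None else acc + p
        pbar = acc / n_samples
    finally:
        model.cfg.dropout_rate = old_rate
    return binary_entropy(pbar), pbar
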