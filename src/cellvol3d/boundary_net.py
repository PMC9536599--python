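"""2D boundary-confidence prediction ("spaghetti model").

A small UNet-family convolutional network maps a boundary-marker channel
slice to a per-pixel boundary probability.  The implementation is pure
NumPy with hand-written backprop and an Adam optimizer so it trains on
small synthetic crops with no deep-learning runtime; the architecture
(depth, width) is configurable.  Training crops are normalized by dividing
by 255 and subtracting the per-image mean; the stopping rule is a training
binary-cross-entropy below ``loss_threshold``.

A classical fallback predictor (gradient magnitude + ridge filter,
normalized to [0, 1]) exposes the same interface so the downstream
pipeline can run without training.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import filters

from .stack import ImageStack

__all__ = [
    "TrainingConfig", "UNet", "ClassicalBoundaryPredictor",
    "bce_loss", "prepare_training_set", "train", "predict_boundaries",
    "save_model", "load_model", "boundary_recall",
]

EPS = 1e-7


@dataclass
class TrainingConfig:
    crop_size: int = 448
    crops_per_image: int = 4
    augmentations: tuple = ("rotation", "shift", "shear", "zoom", "flip")
    target_train_size: int = 4960
    val_fraction: float = 0.2
    loss_threshold: float = 0.001
    max_epochs: int = 50
    dropout_rate: float = 0.1
    lr: float = 3e-3
    batch_size: int = 8
    base_channels: int = 8
    depth: int = 2
    rotation_range_deg: float = 20.0
    shift_range_frac: float = 0.1
    shear_range_deg: float = 8.0
    zoom_range: tuple = (0.9, 1.1)
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


def bce_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean binary cross-entropy; probabilities clamped away from 0/1."""
    y = np.asarray(y, dtype=float)
    yhat = np.clip(np.asarray(yhat, dtype=float), EPS, 1.0 - EPS)
    if y.shape != yhat.shape:
        raise ValueError("shape mismatch between targets and predictions")
    return float(-np.mean(y * np.log(yhat) + (1.0 - y) * np.log(1.0 - yhat)))


# ---------------------------------------------------------------------------
# minimal NumPy layers (NCHW)

def _im2col(x, k):
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((n, c, k * k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i * k + j] = xp[:, :, i:i + h, j:j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(cols, x_shape, k):
    n, c, h, w = x_shape
    p = k // 2
    cols = cols.reshape(n, c, k * k, h, w)
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + h, j:j + w] += cols[:, :, i * k + j]
    return xp[:, :, p:p + h, p:p + w]


class _Conv:
    def __init__(self, c_in, c_out, k, rng):
        scale = math.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.k = k
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k)
        n, _, h, w = x.shape
        out = np.einsum("oc,ncp->nop", self.W, self._cols)
        out += self.b[None, :, None]
        return out.reshape(n, -1, h, w)

    def backward(self, dout):
        n, c_out, h, w = dout.shape
        dflat = dout.reshape(n, c_out, h * w)
        self.grads[0][...] = np.einsum("nop,ncp->oc", dflat, self._cols)
        self.grads[1][...] = dflat.sum(axis=(0, 2))
        dcols = np.einsum("oc,nop->ncp", self.W, dflat)
        return _col2im(dcols, self._x_shape, self.k)


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2:
    params: list = []
    grads: list = []

    def forward(self, x):
        n, c, h, w = x.shape
        self._in_shape = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, dout):
        n, c, h, w = self._in_shape
        dr = np.where(self._mask, dout[:, :, :, None, :, None], 0.0)
        return dr.reshape(n, c, h, w)


class _Upsample2:
    params: list = []
    grads: list = []

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _Dropout:
    params: list = []
    grads: list = []

    def __init__(self, rate):
        self.rate = rate
        self.training = False
        self.rng = np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class UNet:
    """Small configurable-depth UNet emitting per-pixel boundary logits."""

    def __init__(self, cfg: TrainingConfig, c_in: int = 1):
        self.cfg = cfg
        self.trained = False
        self.loss_history: list[dict] = []
        rng = np.random.default_rng(cfg.rng_seed)
        B, D = cfg.base_channels, cfg.depth

        def block(ci, co):
            return [_Conv(ci, co, 3, rng), _ReLU(), _Conv(co, co, 3, rng), _ReLU()]

        self.enc, self.pools = [], []
        ci = c_in
        for d in range(D):
            co = B * 2 ** d
            self.enc.append(block(ci, co))
            self.pools.append(_MaxPool2())
            ci = co
        self.bottleneck = block(ci, B * 2 ** D)
        self.drop = _Dropout(cfg.dropout_rate)
        self.ups, self.dec = [], []
        ci = B * 2 ** D
        for d in reversed(range(D)):
            co = B * 2 ** d
            self.ups.append((_Upsample2(), _Conv(ci, co, 3, rng), _ReLU()))
            self.dec.append(block(2 * co, co))
            ci = co
        self.head = _Conv(ci, 1, 1, rng)

        self.layers = []
        for blk in self.enc:
            self.layers += blk
        self.layers += self.pools + self.bottleneck + [self.drop]
        for (up, conv, act), blk in zip(self.ups, self.dec):
            self.layers += [up, conv, act] + blk
        self.layers.append(self.head)
        self.params = [p for l in self.layers for p in l.params]
        self.grads = [g for l in self.layers for g in l.grads]

    def _run_block(self, blk, x):
        for layer in blk:
            x = layer.forward(x)
        return x

    def _back_block(self, blk, d):
        for layer in reversed(blk):
            d = layer.backward(d)
        return d

    def forward(self, x, training=False):
        self.drop.training = training
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = self._run_block(blk, x)
            skips.append(x)
            x = pool.forward(x)
        x = self._run_block(self.bottleneck, x)
        x = self.drop.forward(x)
        self._skip_channels = []
        for (up, conv, act), blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = act.forward(conv.forward(up.forward(x)))
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = self._run_block(blk, x)
        return self.head.forward(x)

    def backward(self, dlogits):
        d = self.head.backward(dlogits)
        dskips = []
        for (up, conv, act), blk, sc in zip(reversed(self.ups), reversed(self.dec),
                                            reversed(self._skip_channels)):
            d = self._back_block(blk, d)
            dskip, d = d[:, :sc], d[:, sc:]
            dskips.append(dskip)
            d = up.backward(conv.backward(act.backward(d)))
        d = self.drop.backward(d)
        d = self._back_block(self.bottleneck, d)
        # dskips were appended shallow-first; encoders unwind deep-first
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            d = pool.backward(d)
            d = d + dskip
            d = self._back_block(blk, d)
        return d

    def predict_proba(self, x):
        logits = self.forward(np.asarray(x, dtype=float), training=False)
        return 1.0 / (1.0 + np.exp(-logits))

    def predict_slice(self, image2d: np.ndarray, tile: int | None = None,
                      overlap: int = 32) -> np.ndarray:
        """Confidence for one slice, tiled with linear seam blending."""
        if not self.trained:
            raise RuntimeError("model is untrained; call train() first")
        img = normalize_image(image2d)
        h, w = img.shape
        tile = tile or min(self.cfg.crop_size, _pow2_floor(min(h, w)))
        tile = min(tile, _pow2_floor(min(h, w)))
        step = tile - overlap if tile < min(h, w) else tile
        out = np.zeros((h, w))
        weight = np.zeros((h, w))
        ramp = _blend_window(tile, overlap)
        for y0 in _tile_starts(h, tile, step):
            for x0 in _tile_starts(w, tile, step):
                patch = img[y0:y0 + tile, x0:x0 + tile]
                conf = self.predict_proba(patch[None, None])[0, 0]
                out[y0:y0 + tile, x0:x0 + tile] += conf * ramp
                weight[y0:y0 + tile, x0:x0 + tile] += ramp
        return out / np.maximum(weight, EPS)


def _pow2_floor(n):
    return 1 << (n.bit_length() - 1) if n & (n - 1) else n


def _tile_starts(extent, tile, step):
    starts = list(range(0, max(extent - tile, 0) + 1, step))
    if starts[-1] + tile < extent:
        starts.append(extent - tile)
    return starts


def _blend_window(tile, overlap):
    ramp = np.ones(tile)
    k = min(overlap, tile // 2)
    if k > 0:
        edge = np.linspace(1.0 / (k + 1), 1.0, k)
        ramp[:k] = edge
        ramp[-k:] = edge[::-1]
    return ramp[:, None] * ramp[None, :]


def normalize_image(image2d: np.ndarray) -> np.ndarray:
    """Divide by 255 and subtract the per-image mean."""
    img = np.asarray(image2d, dtype=float) / 255.0
    return img - img.mean()


# ---------------------------------------------------------------------------
# training-set preparation

def _corner_crops(image, mask, size, n_crops):
    h, w = image.shape
    size = min(size, h, w)
    corners = [(0, 0), (0, w - size), (h - size, 0), (h - size, w - size)]
    out = []
    for y0, x0 in corners[:n_crops]:
        out.append((image[y0:y0 + size, x0:x0 + size],
                    mask[y0:y0 + size, x0:x0 + size]))
    return out


def _augment(image, mask, cfg: TrainingConfig, rng):
    aug = set(cfg.augmentations)
    h, w = image.shape
    angle = rng.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg) \
        if "rotation" in aug else 0.0
    shear = math.radians(rng.uniform(-cfg.shear_range_deg, cfg.shear_range_deg)) \
        if "shear" in aug else 0.0
    zoom = rng.uniform(*cfg.zoom_range) if "zoom" in aug else 1.0
    shift = (rng.uniform(-cfg.shift_range_frac, cfg.shift_range_frac) * h,
             rng.uniform(-cfg.shift_range_frac, cfg.shift_range_frac) * w) \
        if "shift" in aug else (0.0, 0.0)

    theta = math.radians(angle)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    shear_m = np.array([[1.0, shear], [0.0, 1.0]])
    m = rot @ shear_m / zoom
    center = np.array([h / 2.0, w / 2.0])
    offset = center - m @ center + np.asarray(shift)
    img = ndimage.affine_transform(image, m, offset=offset, order=1, mode="reflect")
    msk = ndimage.affine_transform(mask, m, offset=offset, order=0, mode="reflect")
    if "flip" in aug and rng.random() < 0.5:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if "flip" in aug and rng.random() < 0.5:
        img, msk = img[::-1], msk[::-1]
    return img, msk


def prepare_training_set(images, masks, cfg: TrainingConfig):
    """Crop, augment to ``target_train_size``, normalize and split.

    Returns ``(train, val)`` where each is ``(X, Y)`` with shapes
    (n, 1, crop, crop); X is normalized (/255, mean-centered per crop),
    Y is binary.  The split is seed-deterministic.
    """
    if len(images) == 0:
        raise ValueError("need at least one annotated image")
    rng = np.random.default_rng(cfg.rng_seed)
    base = []
    for img, msk in zip(images, masks):
        img = np.asarray(img, dtype=float)
        msk = np.asarray(msk, dtype=float)
        if img.shape != msk.shape:
            raise ValueError(f"image shape {img.shape} != mask shape {msk.shape}")
        base.extend(_corner_crops(img, msk, cfg.crop_size, cfg.crops_per_image))

    items = list(base)
    i = 0
    while len(items) < cfg.target_train_size:
        img, msk = base[i % len(base)]
        items.append(_augment(img, msk, cfg, rng))
        i += 1
    items = items[:cfg.target_train_size]

    X = np.stack([normalize_image(im) for im, _ in items])[:, None]
    Y = np.stack([(mk > 0.5).astype(float) for _, mk in items])[:, None]
    order = rng.permutation(len(items))
    n_val = int(round(cfg.val_fraction * len(items)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    return (X[train_idx], Y[train_idx]), (X[val_idx], Y[val_idx])


# ---------------------------------------------------------------------------
# training

class _Adam:
    def __init__(self, params, grads, lr):
        self.params, self.grads, self.lr = params, grads, lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


def train(cfg: TrainingConfig, train_split, val_split=None) -> UNet:
    """Train a UNet until training BCE < ``loss_threshold`` or max_epochs.

    Deterministic for a fixed config seed.  Raises on divergence (NaN loss)
    with the epoch index.  ``max_epochs == 0`` returns an untrained model
    (``model.trained`` False).
    """
    X, Y = train_split
    model = UNet(cfg, c_in=X.shape[1] if X.ndim == 4 else 1)
    if cfg.max_epochs == 0:
        return model
    rng = np.random.default_rng(cfg.rng_seed + 1)
    model.drop.rng = np.random.default_rng(cfg.rng_seed + 2)
    opt = _Adam(model.params, model.grads, cfg.lr)
    n = len(X)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            logits = model.forward(xb, training=True)
            probs = 1.0 / (1.0 + np.exp(-logits))
            loss = bce_loss(yb, probs)
            if math.isnan(loss):
                raise FloatingPointError(f"training diverged (NaN loss) at "
                                         f"epoch {epoch}")
            dlogits = (probs - yb) / probs.size
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        entry = {"epoch": epoch, "train_loss": train_loss}
        if val_split is not None and len(val_split[0]):
            vp = model.predict_proba(val_split[0])
            entry["val_loss"] = bce_loss(val_split[1], vp)
        model.loss_history.append(entry)
        if train_loss < cfg.loss_threshold:
            break
    model.trained = True
    return model


# ---------------------------------------------------------------------------
# inference over stacks

class ClassicalBoundaryPredictor:
    """Training-free fallback: gradient magnitude + ridge filter in [0, 1]."""

    trained = True

    def __init__(self, ridge_sigma: float = 1.0):
        self.ridge_sigma = ridge_sigma

    def predict_slice(self, image2d: np.ndarray, **_) -> np.ndarray:
        img = np.asarray(image2d, dtype=float)
        if img.max() > img.min():
            img = (img - img.min()) / (img.max() - img.min())
        grad = filters.sobel(img)
        ridge = filters.sato(img, sigmas=[self.ridge_sigma], black_ridges=False)
        conf = grad + ridge
        top = conf.max()
        return conf / top if top > 0 else conf


def predict_boundaries(model, stack: ImageStack, channel: str = "CK7") -> np.ndarray:
    """Slice-wise 2D inference assembled into a 3D confidence volume."""
    if not getattr(model, "trained", False):
        raise RuntimeError("model is untrained")
    img3d = stack.channel(channel)
    return np.stack([model.predict_slice(img3d[z])
                     for z in range(img3d.shape[0])]).astype(np.float32)


def boundary_recall(confidence: np.ndarray, true_mask: np.ndarray,
                    threshold: float = 0.5, tolerance_px: int = 1) -> float:
    """Fraction of true boundary pixels with a super-threshold prediction
    within ``tolerance_px``."""
    pred = confidence >= threshold
    if tolerance_px > 0:
        pred = ndimage.binary_dilation(pred, iterations=tolerance_px)
    truth = np.asarray(true_mask) > 0.5
    if truth.sum() == 0:
        raise ValueError("no true boundary pixels")
    return float((pred & truth).sum() / truth.sum())


# ---------------------------------------------------------------------------
# persistence (JSON config + loss history, npz weights)

def save_model(model: UNet, path) -> None:
    path = Path(path)
    meta = {"config": asdict(model.cfg), "trained": model.trained,
            "loss_history": model.loss_history}
    meta["config"]["augmentations"] = list(model.cfg.augmentations)
    meta["config"]["zoom_range"] = list(model.cfg.zoom_range)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    np.savez(path.with_suffix(".npz"),
             **{f"p{i}": p for i, p in enumerate(model.params)})


def load_model(path) -> UNet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg_d = meta["config"]
    cfg_d["augmentations"] = tuple(cfg_d["augmentations"])
    cfg_d["zoom_range"] = tuple(cfg_d["zoom_range"])
    model = UNet(TrainingConfig(**cfg_d))
    weights = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(model.params):
        p[...] = weights[f"p{i}"]
    model.trained = meta["trained"]
    model.loss_history = meta["loss_history"]
    return model
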