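"""Scaled-down CNN thickness regression with Grad-CAM heat maps.

Implements the deep-learning protocol around the fundus photographs: a
VGG-16-shaped convolutional regressor (five blocks of stride-1
same-padding 3x3 convolutions, each closed by a stride-2 max-pool, then a
flatten and two fully connected layers with a single linear output unit
predicting choroidal thickness in um), six-fold image augmentation
(original, brightness shift, gamma correction, histogram equalisation,
noise addition, left-right inversion), K-fold cross-validation with strict
leakage prevention, and gradient-weighted class-activation heat maps with
positive-gradient back-propagation.

The network is a small self-contained numpy implementation (im2col-free
shifted-slice convolutions, manual backprop, Adam). No GPU framework is
required; the ``vgg_small`` architecture keeps the exact topology pattern
at desk scale (one convolution per block, 8/16/32/32/32 channels). The
full ``vgg16`` shape is constructible for completeness but is not meant to
be trained on one CPU. ImageNet pretraining is unavailable offline: blocks
initialise randomly (He) and a warning is logged when freezing is
requested without pretrained weights.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import exposure
from skimage.transform import resize as _sk_resize

from .exceptions import ParameterError
from .image_io import FundusImage
from .stats import correlation

logger = logging.getLogger(__name__)

_ARCHITECTURES = {
    # name: (convs per block, channels per block, dense hidden units)
    "vgg16": ((2, 2, 3, 3, 3), (64, 128, 256, 512, 512), 512),
    "vgg_small": ((1, 1, 1, 1, 1), (8, 16, 32, 32, 32), 64),
}


@dataclass
class ModelConfig:
    """Hyperparameters of the thickness regressor.

    The source protocol leaves optimiser, learning rate, epochs, input
    resolution and loss unstated; defaults here are standard
    transfer-learning regression settings and are all overridable.
    """

    input_side_px: int = 64
    architecture: str = "vgg_small"
    #: initial blocks whose convolution weights are not trained
    frozen_blocks: int = 0
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    loss: str = "mean_squared_error"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in _ARCHITECTURES:
            raise ParameterError(
                f"architecture must be one of {sorted(_ARCHITECTURES)}, "
                f"got {self.architecture!r}"
            )
        if self.input_side_px % 32 != 0:
            raise ParameterError("input_side_px must be divisible by 32 (five pools)")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.frozen_blocks > 5:
            raise ParameterError("frozen_blocks must be <= 5 (total blocks)")
        if self.loss != "mean_squared_error":
            raise ParameterError("only mean_squared_error loss is supported")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping) -> "ModelConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown model option(s): {sorted(unknown)}")
        return cls(**dict(mapping))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    name = "layer"
    trainable = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        raise NotImplementedError

    def params(self):
        return ()


class Conv2D(_Layer):
    """3x3 convolution, stride 1, same padding, implemented as nine
    shifted-slice matrix products (BLAS-friendly, no im2col buffer)."""

    def __init__(self, cin: int, cout: int, name: str, rng: np.random.Generator,
                 trainable: bool = True):
        self.name = name
        self.trainable = trainable
        scale = np.sqrt(2.0 / (cin * 9))
        self.W = rng.normal(0.0, scale, (cout, cin, 3, 3)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xpad = None

    def forward(self, x):
        n, c, h, w = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xpad = xpad
        out = np.zeros((n, self.W.shape[0], h, w), dtype=np.float32)
        for ki in range(3):
            for kj in range(3):
                out += np.einsum(
                    "oi,nihw->nohw", self.W[:, :, ki, kj],
                    xpad[:, :, ki : ki + h, kj : kj + w], optimize=True,
                )
        return out + self.b[None, :, None, None]

    def backward(self, grad, guided=False):
        xpad = self._xpad
        n, _, hp, wp = xpad.shape
        h, w = hp - 2, wp - 2
        self.db = grad.sum(axis=(0, 2, 3))
        dxpad = np.zeros_like(xpad)
        for ki in range(3):
            for kj in range(3):
                xs = xpad[:, :, ki : ki + h, kj : kj + w]
                self.dW[:, :, ki, kj] = np.einsum(
                    "nohw,nihw->oi", grad, xs, optimize=True
                )
                dxpad[:, :, ki : ki + h, kj : kj + w] += np.einsum(
                    "oi,nohw->nihw", self.W[:, :, ki, kj], grad, optimize=True
                )
        return dxpad[:, :, 1:-1, 1:-1]

    def params(self):
        if not self.trainable:
            return ()
        return ((self, "W"), (self, "b"))


class ReLU(_Layer):
    def __init__(self, name: str):
        self.name = name
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad, guided=False):
        grad = grad * self._mask
        if guided:  # propagate only positive gradients
            grad = np.maximum(grad, 0.0)
        return grad


class MaxPool2(_Layer):
    """2x2 max pooling, stride 2."""

    def __init__(self, name: str):
        self.name = name
        self._idx = None
        self._shape = None

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ParameterError(f"{self.name}: spatial size must be even, got {h}x{w}")
        self._shape = x.shape
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad, guided=False):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(out, self._idx[..., None], grad[..., None], axis=-1)
        return (
            out.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class Flatten(_Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad, guided=False):
        return grad.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, nin: int, nout: int, name: str, rng: np.random.Generator,
                 trainable: bool = True):
        self.name = name
        self.trainable = trainable
        scale = np.sqrt(2.0 / nin)
        self.W = rng.normal(0.0, scale, (nin, nout)).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad, guided=False):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        if not self.trainable:
            return ()
        return ((self, "W"), (self, "b"))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class Network:
    """Sequential CNN regressor with named layers."""

    def __init__(self, layers: list[_Layer], cfg: ModelConfig):
        self.layers = layers
        self.cfg = cfg

    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad, guided=guided)
        return grad

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = [
            self.forward(x[i : i + batch_size])
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out)[:, 0]

    def trainable_params(self):
        return [p for layer in self.layers for p in layer.params()]

    def n_params(self, trainable_only: bool = False) -> int:
        total = 0
        for layer in self.layers:
            if not hasattr(layer, "W"):
                continue
            if trainable_only and not layer.trainable:
                continue
            total += layer.W.size + layer.b.size
        return total

    def preprocess(self, pixels: np.ndarray) -> np.ndarray:
        """(H, W, 3) uint8 -> (3, S, S) float32 in [-0.5, 0.5]."""
        s = self.cfg.input_side_px
        img = pixels.astype(np.float32) / 255.0
        if img.shape[:2] != (s, s):
            img = _sk_resize(img, (s, s, 3), preserve_range=True, anti_aliasing=True)
        return (img - 0.5).transpose(2, 0, 1).astype(np.float32)

    def activation_and_gradient(
        self, x: np.ndarray, target_layer: str, guided: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Activation of ``target_layer`` and the gradient of the scalar
        output w.r.t. it (single image, x of shape (3, S, S))."""
        names = self.layer_names()
        if target_layer not in names:
            raise ParameterError(
                f"layer {target_layer!r} not in network (layers: {names})"
            )
        idx = names.index(target_layer)
        act = x[None].astype(np.float32)
        activations = []
        for layer in self.layers:
            act = layer.forward(act)
            activations.append(act)
        grad = np.ones_like(act)
        for layer in reversed(self.layers[idx + 1 :]):
            grad = layer.backward(grad, guided=guided)
        return activations[idx][0], grad[0]


def build_network(cfg: ModelConfig) -> Network:
    """Build the five-block convolutional regressor described by ``cfg``."""
    convs_per_block, channels, hidden = _ARCHITECTURES[cfg.architecture]
    rng = np.random.default_rng(cfg.seed)
    if cfg.frozen_blocks > 0:
        logger.warning(
            "no pretrained weights available offline: %d frozen block(s) keep "
            "their random initialisation", cfg.frozen_blocks,
        )
    layers: list[_Layer] = []
    cin = 3
    for b, (n_convs, cout) in enumerate(zip(convs_per_block, channels), start=1):
        trainable = b > cfg.frozen_blocks
        for j in range(1, n_convs + 1):
            layers.append(Conv2D(cin, cout, f"block{b}_conv{j}", rng, trainable))
            layers.append(ReLU(f"block{b}_conv{j}_relu"))
            cin = cout
        layers.append(MaxPool2(f"block{b}_pool"))
    side = cfg.input_side_px // 32
    layers.append(Flatten("flatten"))
    layers.append(Dense(side * side * channels[-1], hidden, "fc1", rng))
    layers.append(ReLU("fc1_relu"))
    layers.append(Dense(hidden, 1, "fc2", rng))
    return Network(layers, cfg)


class Adam:
    """Adam optimiser over a network's trainable parameters."""

    def __init__(self, net: Network, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = net.trainable_params()
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(l, n)) for l, n in self.params]
        self.v = [np.zeros_like(getattr(l, n)) for l, n in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (layer, name) in enumerate(self.params):
            g = getattr(layer, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            setattr(
                layer, name,
                getattr(layer, name) - self.lr * mhat / (np.sqrt(vhat) + self.eps),
            )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def adjust_brightness(img: FundusImage, delta: float) -> FundusImage:
    px = np.clip(img.pixels.astype(np.float64) + delta, 0, 255)
    return FundusImage(px.astype(np.uint8), eye_id=img.eye_id)


def gamma_correct(img: FundusImage, gamma: float) -> FundusImage:
    """Power-law intensity mapping; gamma = 1.0 is the identity on pixels."""
    if gamma == 1.0:
        return FundusImage(img.pixels.copy(), eye_id=img.eye_id)
    px = 255.0 * (img.pixels.astype(np.float64) / 255.0) ** gamma
    return FundusImage(np.clip(np.rint(px), 0, 255).astype(np.uint8), eye_id=img.eye_id)


def equalise_histogram(img: FundusImage) -> FundusImage:
    chans = [
        np.rint(exposure.equalize_hist(img.pixels[..., k], nbins=256) * 255)
        for k in range(3)
    ]
    return FundusImage(
        np.clip(np.stack(chans, axis=-1), 0, 255).astype(np.uint8), eye_id=img.eye_id
    )


def add_noise(img: FundusImage, sd: float, rng: np.random.Generator) -> FundusImage:
    px = img.pixels.astype(np.float64) + rng.normal(0.0, sd, img.pixels.shape)
    return FundusImage(np.clip(np.rint(px), 0, 255).astype(np.uint8), eye_id=img.eye_id)


def mirror_lr(img: FundusImage) -> FundusImage:
    """Left-right inversion (an involution)."""
    return FundusImage(img.pixels[:, ::-1].copy(), eye_id=img.eye_id)


def augment(img: FundusImage, seed: int = 0) -> list[FundusImage]:
    """Six-fold augmentation of one image.

    Returns exactly ``[original, brightness-shifted, gamma-corrected,
    histogram-equalised, noise-added, left-right inverted]``; element 0 is
    bit-identical to the input. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    delta = rng.uniform(-30.0, 30.0)
    gamma = rng.uniform(0.7, 1.4)
    noise_sd = rng.uniform(3.0, 8.0)
    return [
        FundusImage(img.pixels.copy(), eye_id=img.eye_id),
        adjust_brightness(img, delta),
        gamma_correct(img, gamma),
        equalise_histogram(img),
        add_noise(img, noise_sd, rng),
        mirror_lr(img),
    ]


# ---------------------------------------------------------------------------
# cross-validated training
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """Assignment of eyes to cross-validation folds."""

    k: int
    assignments: dict[str, int]

    def fold_ids(self, fold: int) -> list[str]:
        return [e for e, f in self.assignments.items() if f == fold]

    def validate(self) -> None:
        folds = np.array(list(self.assignments.values()))
        if set(np.unique(folds)) != set(range(self.k)):
            raise AssertionError("folds must be exhaustive")
        sizes = np.bincount(folds, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise AssertionError("fold sizes must differ by at most 1")


@dataclass
class PredictionSet:
    """Cross-validated out-of-fold predictions, one row per eye."""

    frame: pd.DataFrame  # eye_id, true_thickness_um, predicted_thickness_um, fold
    split: FoldSplit

    def correlation(self, method: str = "pearson") -> tuple[float, float]:
        return correlation(
            self.frame["true_thickness_um"],
            self.frame["predicted_thickness_um"],
            method=method,
        )


def make_folds(eye_ids: list[str], k: int, seed: int = 0) -> FoldSplit:
    if len(eye_ids) < k:
        raise ParameterError(f"need at least {k} eyes for {k}-fold CV, got {len(eye_ids)}")
    order = list(eye_ids)
    np.random.default_rng(seed).shuffle(order)
    split = FoldSplit(k, {eye: i % k for i, eye in enumerate(order)})
    split.validate()
    return split


def _as_items(cohort) -> list[tuple[str, np.ndarray, float]]:
    """Normalise the accepted cohort forms to (eye_id, pixels, thickness)."""
    items = []
    for entry in cohort:
        if hasattr(entry, "image") and hasattr(entry, "thickness_um"):
            items.append((entry.image.eye_id, entry.image.pixels, float(entry.thickness_um)))
        else:
            img, thickness = entry
            items.append((img.eye_id, img.pixels, float(thickness)))
    ids = [i[0] for i in items]
    if len(set(ids)) != len(ids):
        raise ParameterError("eye_id values must be unique")
    return items


def kfold_train_eval(
    cohort,
    cfg: ModelConfig | None = None,
    k: int = 5,
    augment_seed: int | None = None,
) -> PredictionSet:
    """Train/evaluate the regressor with K-fold cross-validation.

    ``cohort`` is a list of SyntheticEye objects or of ``(FundusImage,
    thickness_um)`` pairs. For each fold the model is trained from scratch
    on the six-fold-augmented images of the other folds' eyes (augmentation
    is applied to training eyes only) and predicts the held-out eyes, so
    every eye receives exactly one out-of-fold prediction. Augmented copies
    of an eye never straddle folds — this is asserted on every fold.
    Thickness targets are z-scored on the training folds; predictions are
    mapped back to um.
    """
    cfg = cfg or ModelConfig()
    items = _as_items(cohort)
    split = make_folds([i[0] for i in items], k, seed=cfg.seed)
    aug_seed = cfg.seed if augment_seed is None else augment_seed

    # preprocess once per augmented image, reusing one throw-away net's helper
    proto = Network([], cfg)
    rows = []
    for fold in range(k):
        val_ids = set(split.fold_ids(fold))
        train_items = [it for it in items if it[0] not in val_ids]
        val_items = [it for it in items if it[0] in val_ids]

        x_train, y_train, train_src_ids = [], [], []
        for eye_id, pixels, thickness in train_items:
            # stable across processes (unlike hash())
            per_eye_seed = (aug_seed * 1000003 + zlib.crc32(eye_id.encode())) & 0x7FFFFFFF
            for aug_img in augment(FundusImage(pixels, eye_id=eye_id), per_eye_seed):
                x_train.append(proto.preprocess(aug_img.pixels))
                y_train.append(thickness)
                train_src_ids.append(eye_id)
        if set(train_src_ids) & val_ids:
            raise AssertionError(
                f"fold {fold}: augmented training copies leak into the validation fold"
            )
        x_train = np.stack(x_train)
        y_train = np.asarray(y_train, dtype=np.float32)
        mu, sd = float(y_train.mean()), float(y_train.std() + 1e-9)
        y_z = (y_train - mu) / sd

        net = build_network(cfg)
        opt = Adam(net, cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1000 + fold)
        n = len(x_train)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                pred = net.forward(x_train[idx])[:, 0]
                err = pred - y_z[idx]
                net.backward((2.0 * err / len(idx))[:, None].astype(np.float32))
                opt.step()
        x_val = np.stack([proto.preprocess(px) for _, px, _ in val_items])
        pred_um = net.predict(x_val) * sd + mu
        for (eye_id, _, thickness), p in zip(val_items, pred_um):
            rows.append(
                {
                    "eye_id": eye_id,
                    "true_thickness_um": thickness,
                    "predicted_thickness_um": float(p),
                    "fold": fold,
                }
            )
        logger.info("fold %d/%d done (%d train images)", fold + 1, k, n)

    frame = pd.DataFrame(rows).sort_values("eye_id").reset_index(drop=True)
    if frame["eye_id"].duplicated().any() or len(frame) != len(items):
        raise AssertionError("every eye must be predicted exactly once")
    return PredictionSet(frame, split)


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

@dataclass
class HeatMap:
    """Gradient-weighted activation map in [0, 1] at image resolution."""

    values: np.ndarray
    degenerate: bool = False


def grad_cam(
    model: Network,
    img: FundusImage | np.ndarray,
    target_layer: str = "block3_pool",
) -> HeatMap:
    """Heat map of the regions driving the model's thickness output.

    The scalar output is back-propagated to ``target_layer`` with the
    rectified rule (each ReLU passes only positive gradients); the map is
    the channel sum of gradient x activation, rectified, upsampled to the
    input resolution and max-normalised to [0, 1]. An all-zero map (e.g. a
    zeroed output head) is returned with ``degenerate=True`` and a logged
    warning.
    """
    if isinstance(img, np.ndarray) and img.ndim == 3 and img.shape[0] == 3:
        x = img.astype(np.float32)
    else:
        x = model.preprocess(img.pixels if isinstance(img, FundusImage) else img)
    act, grad = model.activation_and_gradient(x, target_layer, guided=True)
    cam = np.maximum((grad * act).sum(axis=0), 0.0)
    side = x.shape[1]
    cam = ndimage.zoom(cam, (side / cam.shape[0], side / cam.shape[1]), order=1)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak <= 0:
        logger.warning("degenerate Grad-CAM: all-zero map")
        return HeatMap(np.zeros_like(cam), degenerate=True)
    return HeatMap(cam / peak, degenerate=False)


def overlay_heatmap(
    img: FundusImage,
    heatmap: HeatMap | np.ndarray,
    alpha: float = 0.5,
    colormap: str = "jet",
    out_path: str | Path | None = None,
) -> np.ndarray:
    """Alpha-blend a colour-mapped heat map onto the fundus image.

    Blending weight is ``alpha * heat`` per pixel, so a zero map returns
    the image unchanged. Returns (and optionally writes) an (H, W, 3)
    uint8 rendering.
    """
    import matplotlib

    cam = heatmap.values if isinstance(heatmap, HeatMap) else np.asarray(heatmap, float)
    if cam.ndim != 2:
        raise ParameterError("heat map must be a 2-D grid")
    h, w = img.pixels.shape[:2]
    if cam.shape != (h, w):
        if cam.shape[0] > h or cam.shape[1] > w:
            raise ParameterError(
                f"heat map {cam.shape} larger than image {(h, w)}"
            )
        cam = ndimage.zoom(cam, (h / cam.shape[0], w / cam.shape[1]), order=1)
        if cam.shape != (h, w):
            raise ParameterError("heat map cannot be upsampled to the image size")
    cam = np.clip(cam, 0.0, 1.0)
    colours = matplotlib.colormaps[colormap](cam)[..., :3] * 255.0
    weight = (alpha * cam)[..., None]
    blended = img.pixels.astype(np.float64) * (1 - weight) + colours * weight
    out = np.clip(np.rint(blended), 0, 255).astype(np.uint8)
    if out_path is not None:
        iio.imwrite(Path(out_path), out)
    return out
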