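"""Residual-encoder U-Net for binary crown segmentation.

The network follows the classic ResU-Net layout: a stem of one 7x7 stride-2
convolution plus 2x2 max pooling brings a chip to a quarter of its spatial
size at ``base_width`` channels; a cascade of residual stages then halves
the spatial size and doubles the width per stage (at the default
``base_width=64`` and four stages, a 256x256 chip reaches an 8x8 bottleneck
with 2048 channels).  The decoder mirrors the encoder with 2x2 stride-2
transposed convolutions, concatenates the equal-size encoder feature after
each upsampling step, and fuses with a 3x3 convolution + batch
normalization + ReLU; a final 1x1 convolution emits a one-channel per-pixel
crown score.

Training optimizes per-pixel binary cross-entropy with Adam (default
learning rate 0.001, batch size 4, up to 100 epochs) on a seeded hold-out
split, monitors validation mean IoU, stops early when it fails to improve
for ``patience`` consecutive epochs, and returns the best-mIoU checkpoint.

``base_width``, ``encoder_depth`` and ``blocks_per_stage`` scale the model
down for CPU-sized experiments without changing the architecture's shape
contract.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from ._nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Layer,
    MaxPool2d,
    ReLU,
    bce_with_logits,
    sigmoid,
)
from .errors import ConfigurationError, DataError, DimensionError, ParameterError
from .raster_prep import TileSet

__all__ = [
    "ModelConfig",
    "TrainingLog",
    "ResUNet",
    "ResUNetSegmenter",
    "build_resunet",
    "train",
    "predict_mask",
    "miou",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Hyper-parameters of the segmentation model and its training loop.

    ``in_layers`` must equal the layer count of the band combination fed to
    the model (1, 2, 3 or 4).  Defaults reproduce the reference protocol:
    learning rate 0.001, 100 epochs, batch size 4, early-stop patience 10,
    and a 64-channel stem whose four residual stages reach an 8x8x2048
    bottleneck on 256x256 input.
    """

    in_layers: int = 3
    base_width: int = 64
    encoder_depth: int = 4
    blocks_per_stage: int = 1
    learning_rate: float = 0.001
    max_epochs: int = 100
    batch_size: int = 4
    patience: int = 10
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.in_layers <= 4:
            raise ParameterError(f"in_layers must be in 1..4, got {self.in_layers}")
        if self.patience > self.max_epochs:
            raise ParameterError(
                f"patience ({self.patience}) must not exceed max_epochs "
                f"({self.max_epochs})"
            )
        if not 0.0 < self.val_fraction < 1.0:
            raise ParameterError(
                f"val_fraction must be in (0, 1), got {self.val_fraction}"
            )
        for name in ("base_width", "encoder_depth", "blocks_per_stage",
                     "max_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")


@dataclass
class TrainingLog:
    """Per-epoch loss / validation-mIoU trace with the best-epoch marker."""

    records: list[dict] = field(default_factory=list)
    best_epoch: int = 0
    best_miou: float = -1.0
    stopped_early: bool = False

    def append(self, epoch: int, train_loss: float, val_miou: float) -> None:
        self.records.append(
            {"epoch": epoch, "train_loss": train_loss, "val_miou": val_miou}
        )

    @property
    def last_epoch(self) -> int:
        return self.records[-1]["epoch"] if self.records else 0

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.records).to_csv(path, index=False)


class _ResBlock:
    """conv3-BN-ReLU-conv3-BN with projection shortcut, post-add ReLU."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng):
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.short_conv = Conv2d(c_in, c_out, 1, stride=stride, pad=0,
                                     bias=False, rng=rng)
            self.short_bn = BatchNorm2d(c_out)
        else:
            self.short_conv = None
            self.short_bn = None
        self.relu_out = ReLU()

    def layers(self) -> list[Layer]:
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2]
        if self.short_conv is not None:
            out += [self.short_conv, self.short_bn]
        return out + [self.relu_out]

    def forward(self, x, train):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        if self.short_conv is not None:
            s = self.short_bn.forward(self.short_conv.forward(x, train), train)
        else:
            s = x
        return self.relu_out.forward(h + s, train)

    def backward(self, g):
        g = self.relu_out.backward(g)
        gh = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(self.conv2.backward(self.bn2.backward(g)))
            )
        )
        if self.short_conv is not None:
            gs = self.short_conv.backward(self.short_bn.backward(g))
        else:
            gs = g
        return gh + gs


class _DecoderStep:
    """Upsample x2, optionally concat an encoder skip, fuse conv3-BN-ReLU."""

    def __init__(self, c_in: int, c_mid: int, c_out: int, has_skip: bool, rng):
        self.up = ConvTranspose2d(c_in, c_mid, rng=rng)
        self.has_skip = has_skip
        c_cat = c_mid * 2 if has_skip else c_mid
        self.conv = Conv2d(c_cat, c_out, 3, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)
        self.relu = ReLU()
        self._c_mid = c_mid

    def layers(self) -> list[Layer]:
        return [self.up, self.conv, self.bn, self.relu]

    def forward(self, x, skip, train):
        u = self.up.forward(x, train)
        if self.has_skip:
            if skip.shape[2:] != u.shape[2:]:
                raise DimensionError(
                    f"decoder skip {skip.shape[2:]} != upsampled {u.shape[2:]}"
                )
            z = np.concatenate([u, skip], axis=1)
        else:
            z = u
        return self.relu.forward(self.bn.forward(self.conv.forward(z, train), train), train)

    def backward(self, g):
        gz = self.conv.backward(self.bn.backward(self.relu.backward(g)))
        if self.has_skip:
            gu, gskip = gz[:, : self._c_mid], gz[:, self._c_mid :]
        else:
            gu, gskip = gz, None
        return self.up.backward(np.ascontiguousarray(gu)), gskip


class ResUNet:
    """The assembled encoder-decoder network (see module docstring)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        b, depth = config.base_width, config.encoder_depth
        self.stage_channels = [b * 4 * 2**i for i in range(depth)]

        self.stem_conv = Conv2d(config.in_layers, b, 7, stride=2, bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(b)
        self.stem_relu = ReLU()
        self.pool = MaxPool2d()

        self.stages: list[list[_ResBlock]] = []
        c_prev = b
        for i, c_out in enumerate(self.stage_channels):
            stride = 1 if i == 0 else 2
            blocks = [_ResBlock(c_prev, c_out, stride, rng)]
            for _ in range(config.blocks_per_stage - 1):
                blocks.append(_ResBlock(c_out, c_out, 1, rng))
            self.stages.append(blocks)
            c_prev = c_out

        self.decoder: list[_DecoderStep] = []
        for i in range(depth - 1, 0, -1):
            self.decoder.append(
                _DecoderStep(self.stage_channels[i], self.stage_channels[i - 1],
                             self.stage_channels[i - 1], True, rng)
            )
        # back to half resolution, concatenating the pre-pool stem feature
        self.decoder.append(_DecoderStep(self.stage_channels[0], b, b, True, rng))
        # back to full resolution (no encoder feature exists at this scale)
        self.decoder.append(_DecoderStep(b, b, b, False, rng))
        self.final = Conv2d(b, 1, 1, pad=0, rng=rng)

    # ---- bookkeeping ----------------------------------------------------
    @property
    def in_layers(self) -> int:
        return self.config.in_layers

    @property
    def downsample_factor(self) -> int:
        return 4 * 2 ** (self.config.encoder_depth - 1)

    def _all_layers(self) -> list[Layer]:
        out: list[Layer] = [self.stem_conv, self.stem_bn, self.stem_relu, self.pool]
        for blocks in self.stages:
            for blk in blocks:
                out += blk.layers()
        for step in self.decoder:
            out += step.layers()
        out.append(self.final)
        return out

    def params(self):
        return [p for layer in self._all_layers() for p in layer.params()]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def get_state(self) -> list[np.ndarray]:
        state = []
        for layer in self._all_layers():
            state.extend(p.value for p in layer.params())
            if isinstance(layer, BatchNorm2d):
                state += [layer.running_mean, layer.running_var]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for layer in self._all_layers():
            for p in layer.params():
                p.value[...] = next(it)
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)

    def feature_shapes(self, input_hw: tuple[int, int]) -> dict[str, tuple[int, int, int]]:
        """Analytic (rows, cols, channels) of each encoder feature.

        ``"bottleneck"`` aliases the deepest stage; at the default
        configuration on a 256x256 chip it is (8, 8, 2048) and ``"stem"``
        (the post-pool feature) is (64, 64, base_width).
        """
        h, w = input_hw
        self._check_size(h, w)
        shapes = {"stem_pre_pool": (h // 2, w // 2, self.config.base_width),
                  "stem": (h // 4, w // 4, self.config.base_width)}
        sh, sw = h // 4, w // 4
        for i, c in enumerate(self.stage_channels):
            if i > 0:
                sh, sw = sh // 2, sw // 2
            shapes[f"stage_{i + 1}"] = (sh, sw, c)
        shapes["bottleneck"] = shapes[f"stage_{len(self.stage_channels)}"]
        return shapes

    def _check_size(self, h: int, w: int) -> None:
        f = self.downsample_factor
        if h % f or w % f:
            raise DimensionError(
                f"input {h}x{w} not divisible by the total downsampling "
                f"factor {f}"
            )

    # ---- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                record_shapes: dict | None = None) -> np.ndarray:
        """Score a batch ``x`` of shape (N, C, H, W); returns (N, 1, H, W)."""
        if x.shape[1] != self.config.in_layers:
            raise ConfigurationError(
                f"model expects {self.config.in_layers} input layers, "
                f"got {x.shape[1]}"
            )
        self._check_size(x.shape[2], x.shape[3])
        x = np.ascontiguousarray(x, dtype=np.float32)
        pre = self.stem_relu.forward(
            self.stem_bn.forward(self.stem_conv.forward(x, train), train), train
        )
        h = self.pool.forward(pre, train)
        if record_shapes is not None:
            record_shapes["stem_pre_pool"] = pre.shape[1:]
            record_shapes["stem"] = h.shape[1:]
        skips = []
        for i, blocks in enumerate(self.stages):
            for blk in blocks:
                h = blk.forward(h, train)
            skips.append(h)
            if record_shapes is not None:
                record_shapes[f"stage_{i + 1}"] = h.shape[1:]
        if record_shapes is not None:
            record_shapes["bottleneck"] = h.shape[1:]
        # decoder: deepest feature consumes progressively shallower skips
        for j, step in enumerate(self.decoder[:-2]):
            h = step.forward(h, skips[-2 - j], train)
        h = self.decoder[-2].forward(h, pre, train)
        h = self.decoder[-1].forward(h, None, train)
        return self.final.forward(h, train)

    def backward(self, gout: np.ndarray) -> None:
        g = self.final.backward(gout)
        g, _ = self.decoder[-1].backward(g)
        g, g_pre = self.decoder[-2].backward(g)
        skip_grads: list[np.ndarray | None] = [None] * len(self.stages)
        for j in range(len(self.decoder) - 3, -1, -1):
            # decoder step j consumed the skip from encoder stage depth-2-j
            g, gskip = self.decoder[j].backward(g)
            skip_grads[len(self.stages) - 2 - j] = gskip
        # walk encoder stages deepest-first, folding in decoder skip grads
        for i in range(len(self.stages) - 1, -1, -1):
            if i < len(self.stages) - 1 and skip_grads[i] is not None:
                g = g + skip_grads[i]
            for blk in reversed(self.stages[i]):
                g = blk.backward(g)
        g = self.pool.backward(g)
        g = g + g_pre
        self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(g)))


def build_resunet(config: ModelConfig) -> ResUNet:
    """Construct a randomly initialized (seeded) network from ``config``."""
    return ResUNet(config)


# ---------------------------------------------------------------------------
# metrics and data handling
# ---------------------------------------------------------------------------

def miou(pred_mask: np.ndarray, label_mask: np.ndarray) -> float:
    """Mean IoU over the background and crown classes.

    Masks may be {0, 1} or {0, 255}; any positive value is crown.  A class
    absent from both masks is skipped (its IoU is undefined, not 0).
    """
    pred_mask = np.asarray(pred_mask)
    label_mask = np.asarray(label_mask)
    if pred_mask.shape != label_mask.shape:
        raise DimensionError(
            f"mask shapes differ: {pred_mask.shape} vs {label_mask.shape}"
        )
    p = pred_mask > 0
    t = label_mask > 0
    ious = []
    for cls_p, cls_t in ((~p, ~t), (p, t)):
        union = np.count_nonzero(cls_p | cls_t)
        if union == 0:
            continue
        ious.append(np.count_nonzero(cls_p & cls_t) / union)
    return float(np.mean(ious))


def _as_binary_targets(y: np.ndarray) -> np.ndarray:
    """Validate {0,255} (or {0,1}) labels and return float32 {0,1}."""
    vals = np.unique(y)
    if np.isin(vals, (0, 1)).all() or np.isin(vals, (0, 255)).all():
        return (y > 0).astype(np.float32)
    raise DataError(f"labels must be binary 0/255 masks; found values {vals[:10]}")


def _tiles_to_arrays(tiles) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(tiles, TileSet):
        if len(tiles) == 0:
            raise DataError("empty tile set")
        return tiles.arrays()
    X, y = tiles
    return np.asarray(X), np.asarray(y)


def _fit_loop(model: ResUNet, X: np.ndarray, y: np.ndarray,
              config: ModelConfig, verbose: bool = False) -> TrainingLog:
    """Seeded hold-out training with best-mIoU checkpointing and early stop."""
    t = _as_binary_targets(y)
    Xc = np.ascontiguousarray(np.transpose(X, (0, 3, 1, 2)), dtype=np.float32)
    n = Xc.shape[0]
    if n < 2:
        raise DataError(f"need at least 2 tiles to hold out validation, got {n}")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = min(n - 1, max(1, round(config.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    opt = Adam(model.params(), lr=config.learning_rate)
    log = TrainingLog()
    best_state: list[np.ndarray] | None = None

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = Xc[idx]
            tb = t[idx][:, None]
            opt.zero_grad()
            z = model.forward(xb, train=True)
            loss, gz = bce_with_logits(z, tb)
            model.backward(gz)
            opt.step()
            losses.append(loss)
        val_miou = _validate(model, Xc, t, val_idx, config.batch_size)
        log.append(epoch, float(np.mean(losses)), val_miou)
        if verbose:
            print(f"epoch {epoch:3d}  loss {np.mean(losses):.4f}  "
                  f"val mIoU {val_miou:.4f}")
        if val_miou > log.best_miou:
            log.best_miou = val_miou
            log.best_epoch = epoch
            best_state = [a.copy() for a in model.get_state()]
        elif epoch - log.best_epoch >= config.patience:
            log.stopped_early = True
            break
    if best_state is not None:
        model.set_state(best_state)
    return log


def _validate(model: ResUNet, Xc, t, val_idx, batch_size) -> float:
    vals = []
    for start in range(0, len(val_idx), batch_size):
        idx = val_idx[start : start + batch_size]
        z = model.forward(Xc[idx], train=False)
        pred = sigmoid(z[:, 0]) >= 0.5
        vals.extend(miou(pred[i], t[idx[i]]) for i in range(len(idx)))
    return float(np.mean(vals))


def train(model: ResUNet, tiles, config: ModelConfig,
          verbose: bool = False) -> tuple[ResUNet, TrainingLog]:
    """Train ``model`` on a :class:`TileSet` (or an ``(X, y)`` pair)."""
    X, y = _tiles_to_arrays(tiles)
    log = _fit_loop(model, X, y, config, verbose=verbose)
    return model, log


def predict_mask(model: ResUNet, input_grid: np.ndarray,
                 threshold: float = 0.5, tile_size: int = 256,
                 batch_size: int = 4) -> np.ndarray:
    """Segment a raster of any size into a {0, 255} crown mask.

    Rasters larger than one tile are scored in half-tile-overlapping
    windows whose sigmoid scores are averaged before thresholding, which
    suppresses seam artifacts; rasters smaller than a tile are
    reflection-padded up to one tile and cropped back.
    """
    grid = np.asarray(input_grid, dtype=np.float32)
    if grid.ndim == 2:
        grid = grid[:, :, None]
    if grid.shape[2] != model.in_layers:
        raise ConfigurationError(
            f"model expects {model.in_layers} layers, raster has {grid.shape[2]}"
        )
    h, w = grid.shape[:2]
    pad_h, pad_w = max(0, tile_size - h), max(0, tile_size - w)
    if pad_h or pad_w:
        grid = np.pad(grid, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
    hh, ww = grid.shape[:2]
    stride = tile_size // 2
    rows = list(range(0, hh - tile_size + 1, stride))
    cols = list(range(0, ww - tile_size + 1, stride))
    if rows[-1] != hh - tile_size:
        rows.append(hh - tile_size)
    if cols[-1] != ww - tile_size:
        cols.append(ww - tile_size)
    score = np.zeros((hh, ww), dtype=np.float64)
    weight = np.zeros((hh, ww), dtype=np.float64)
    windows = [(r, c) for r in rows for c in cols]
    for start in range(0, len(windows), batch_size):
        batch = windows[start : start + batch_size]
        xb = np.stack(
            [grid[r : r + tile_size, c : c + tile_size] for r, c in batch]
        ).transpose(0, 3, 1, 2)
        z = model.forward(xb, train=False)
        s = sigmoid(z[:, 0])
        for (r, c), sm in zip(batch, s):
            score[r : r + tile_size, c : c + tile_size] += sm
            weight[r : r + tile_size, c : c + tile_size] += 1.0
    mask = (score / weight) >= threshold
    return np.where(mask[:h, :w], 255, 0).astype(np.uint8)


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class ResUNetSegmenter(BaseEstimator):
    """Crown segmenter with the scikit-learn estimator protocol.

    ``fit(X, y)`` takes chips ``X`` of shape (n, H, W, C) (H, W divisible by
    the downsampling factor) and binary {0, 255} masks ``y`` of shape
    (n, H, W); ``predict`` returns {0, 255} masks, ``predict_proba`` the
    per-pixel sigmoid crown scores, and ``score`` the mean two-class mIoU
    against reference masks.  ``in_layers`` may be left ``None`` to be
    inferred from ``X``.

    Examples
    --------
    >>> seg = ResUNetSegmenter(base_width=8, encoder_depth=2, max_epochs=5,
    ...                        random_state=0)
    >>> seg.fit(X_chips, y_masks)            # doctest: +SKIP
    >>> masks = seg.predict(X_chips)         # doctest: +SKIP
    """

    def __init__(self, in_layers: int | None = None, base_width: int = 64,
                 encoder_depth: int = 4, blocks_per_stage: int = 1,
                 learning_rate: float = 0.001, max_epochs: int = 100,
                 batch_size: int = 4, patience: int = 10,
                 val_fraction: float = 0.2, threshold: float = 0.5,
                 tile_size: int = 256, verbose: bool = False,
                 random_state: int = 0):
        self.in_layers = in_layers
        self.base_width = base_width
        self.encoder_depth = encoder_depth
        self.blocks_per_stage = blocks_per_stage
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.val_fraction = val_fraction
        self.threshold = threshold
        self.tile_size = tile_size
        self.verbose = verbose
        self.random_state = random_state

    def _config(self, in_layers: int) -> ModelConfig:
        return ModelConfig(
            in_layers=in_layers, base_width=self.base_width,
            encoder_depth=self.encoder_depth,
            blocks_per_stage=self.blocks_per_stage,
            learning_rate=self.learning_rate, max_epochs=self.max_epochs,
            batch_size=self.batch_size, patience=self.patience,
            val_fraction=self.val_fraction, seed=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim == 3:
            X = X[:, :, :, None]
        if X.ndim != 4 or y.ndim != 3 or X.shape[:3] != y.shape:
            raise DataError(
                f"expected X (n, H, W, C) and matching y (n, H, W); "
                f"got {X.shape} and {y.shape}"
            )
        in_layers = X.shape[3] if self.in_layers is None else self.in_layers
        if in_layers != X.shape[3]:
            raise ConfigurationError(
                f"in_layers={in_layers} but chips have {X.shape[3]} layers"
            )
        config = self._config(in_layers)
        self.model_ = build_resunet(config)
        self.log_ = _fit_loop(self.model_, X, y, config, verbose=self.verbose)
        self.in_layers_ = in_layers
        self.n_features_in_ = in_layers
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("ResUNetSegmenter is not fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel crown probabilities, shape (n, H, W)."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[:, :, :, None]
        out = []
        for start in range(0, X.shape[0], self.batch_size):
            xb = X[start : start + self.batch_size].transpose(0, 3, 1, 2)
            z = self.model_.forward(xb, train=False)
            out.append(sigmoid(z[:, 0]))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        """{0, 255} masks, shape (n, H, W)."""
        proba = self.predict_proba(X)
        return np.where(proba >= self.threshold, 255, 0).astype(np.uint8)

    def predict_raster(self, input_grid: np.ndarray) -> np.ndarray:
        """Segment one raster of arbitrary size (overlap-averaged windows)."""
        self._check_fitted()
        return predict_mask(self.model_, input_grid, threshold=self.threshold,
                            tile_size=self.tile_size,
                            batch_size=self.batch_size)

    def score(self, X, y) -> float:
        """Mean per-chip mIoU against reference masks."""
        pred = self.predict(X)
        y = np.asarray(y)
        return float(np.mean([miou(p, t) for p, t in zip(pred, y)]))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: ResUNet, log: TrainingLog | None = None) -> None:
    """Serialize weights (npz) with a JSON config sidecar."""
    path = Path(path)
    state = {f"a{i:04d}": a for i, a in enumerate(model.get_state())}
    np.savez_compressed(path, **state)
    sidecar = {"config": asdict(model.config)}
    if log is not None:
        sidecar["best_epoch"] = log.best_epoch
        sidecar["best_miou"] = log.best_miou
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path) -> ResUNet:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")  # np.savez appended it
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    model = build_resunet(ModelConfig(**sidecar["config"]))
    with np.load(path) as data:
        model.set_state([data[k] for k in sorted(data.files)])
    return model
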