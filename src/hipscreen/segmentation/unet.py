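"""U-Net-like encoder-decoder segmenter and its training loop.

The network follows the classic U-Net topology at configurable scale:
``depth`` encoder levels of double 3x3 conv + ReLU with 2x2 max pooling
between them, a mirrored decoder with nearest-neighbor upsampling and skip
concatenations, and a 1x1 output head.
The head carries one sigmoid logit map per foreground landmark
class; the background probability is composed as the product of the
complements and the triple normalized to sum to one.  Weights are
Xavier-uniform initialized (output biases to the class log-odds priors of
the training masks); training minimizes a soft DICE loss over the
foreground landmark classes with Adam at a single fixed learning rate, and
the checkpoint with the highest validation DICE is the one returned (ties
resolve to the earliest epoch).  Per-class sigmoid heads rather than one
softmax keep the very thin bone class from being crushed by the much
larger femoral-head class during early training.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize

from ..errors import ValidationError
from ..phantom import LabelMask, PhantomDataset
from . import nn
from .ops import FOREGROUND_CLASSES, dice_per_class, grouped_split, preprocess, resize_mask


@dataclass(frozen=True)
class ModelConfig:
    input_size_px: int = 256
    depth: int = 3
    base_channels: int = 8
    n_classes: int = 3
    init_scheme: str = "xavier-uniform"

    def __post_init__(self) -> None:
        if self.input_size_px < 32:
            raise ValidationError("input_size_px must be >= 32")
        if self.depth < 2:
            raise ValidationError("depth must be >= 2")
        if self.input_size_px % (2 ** (self.depth - 1)) != 0:
            raise ValidationError("input_size_px must be divisible by 2**(depth-1)")
        if self.init_scheme != "xavier-uniform":
            raise ValidationError(f"unsupported init_scheme {self.init_scheme!r}")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 1e-3
    split_fractions: tuple[float, float] = (0.8, 0.2)
    seed: int = 0
    selection_metric: str = "val_dice"

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValidationError("epochs and batch_size must be positive")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValidationError("split_fractions must sum to 1")
        if self.selection_metric != "val_dice":
            raise ValidationError("only validation-DICE model selection is supported")


@dataclass
class TrainReport:
    epochs: list[dict] = field(default_factory=list)  # epoch, train_loss, val_dice
    selected_epoch: int = 0                            # 1-based
    selected_val_dice: float = 0.0
    model_checksum: str = ""
    optimizer: str = "adam"
    learning_rate: float = 0.0
    train_subjects: list = field(default_factory=list)
    val_subjects: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


class _DoubleConv:
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.layers = [nn.Conv3x3(in_ch, out_ch, rng), nn.ReLU(),
                       nn.Conv3x3(out_ch, out_ch, rng), nn.ReLU()]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class _OutConv:
    """1x1 conv head implemented as a 3x3 conv restricted to its center tap."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.W = nn.Param(nn.xavier_uniform(rng, (out_ch, in_ch), in_ch, out_ch))
        self.b = nn.Param(np.zeros(out_ch))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        y = np.tensordot(x, self.W.value, axes=([1], [1])) + self.b.value
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, gy):
        gyt = gy.transpose(0, 2, 3, 1)
        self.b.grad += gyt.sum(axis=(0, 1, 2))
        self.W.grad += np.tensordot(gyt, self._x, axes=([0, 1, 2], [0, 2, 3]))
        gx = np.tensordot(gyt, self.W.value, axes=([3], [0])).transpose(0, 3, 1, 2)
        self._x = None
        return np.ascontiguousarray(gx).astype(nn.DTYPE)


class UNet:
    """U-Net-like fully convolutional segmenter (NumPy, CPU)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.trained = False
        rng = np.random.default_rng(seed)
        ch = [config.base_channels * 2**i for i in range(config.depth)]
        self.enc = [_DoubleConv(1 if i == 0 else ch[i - 1], ch[i], rng)
                    for i in range(config.depth)]
        self.pools = [nn.MaxPool2() for _ in range(config.depth - 1)]
        self.ups = [nn.Upsample2() for _ in range(config.depth - 1)]
        # decoder level i consumes up(deeper) concat skip_i
        self.dec = [_DoubleConv(ch[i + 1] + ch[i], ch[i], rng)
                    for i in reversed(range(config.depth - 1))]
        # one sigmoid head per foreground class; background is derived
        self.head = _OutConv(ch[0], config.n_classes - 1, rng)
        self._skip_channels = ch

    def params(self) -> list[nn.Param]:
        out = []
        for block in (*self.enc, *self.dec):
            out.extend(block.params())
        out.extend(self.head.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        d = self.config.depth
        skips = []
        for i in range(d - 1):
            x = self.enc[i].forward(x)
            skips.append(x)
            x = self.pools[i].forward(x)
        x = self.enc[d - 1].forward(x)
        self._concat_sizes = []
        for j, i in enumerate(reversed(range(d - 1))):
            x = self.ups[j].forward(x)
            skip = skips[i]
            self._concat_sizes.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = self.dec[j].forward(x)
        return self.head.forward(x)

    def backward(self, gy: np.ndarray) -> None:
        d = self.config.depth
        g = self.head.backward(gy)
        skip_grads = {}
        for j in reversed(range(d - 1)):  # unwind decoder blocks deepest-last
            i = d - 2 - j                  # skip level consumed by dec[j]
            g = self.dec[j].backward(g)
            n_up = self._concat_sizes[j]
            g_up, g_skip = g[:, :n_up], g[:, n_up:]
            skip_grads[i] = g_skip
            g = self.ups[j].backward(np.ascontiguousarray(g_up))
        g = self.enc[d - 1].backward(g)
        for i in reversed(range(d - 1)):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc[i].backward(np.ascontiguousarray(g))

    def predict_probs(self, batch: np.ndarray) -> np.ndarray:
        """Per-class probabilities (N, n_classes, S, S) summing to 1 per pixel.

        Foreground channels are the sigmoid head outputs; the background
        channel is the product of their complements; the stack is then
        normalized per pixel."""
        s = nn.sigmoid(self.forward(batch.astype(nn.DTYPE)))
        bg = np.prod(1.0 - s, axis=1, keepdims=True)
        scores = np.concatenate([bg, s], axis=1)
        return scores / scores.sum(axis=1, keepdims=True)

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v

    def checksum(self) -> str:
        h = hashlib.sha256()
        for p in self.params():
            h.update(np.ascontiguousarray(p.value).tobytes())
        return h.hexdigest()


def _prepare(dataset: PhantomDataset, size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    imgs = np.stack([preprocess(im, size) for im in dataset.images])[:, None].astype(nn.DTYPE)
    masks = np.stack([resize_mask(m, size) for m in dataset.masks])
    return imgs, masks, dataset.subject_ids


def _mean_val_dice(model: UNet, imgs: np.ndarray, masks: np.ndarray,
                   batch: int = 8) -> float:
    scores = []
    for i in range(0, len(imgs), batch):
        probs = model.predict_probs(imgs[i:i + batch])
        labels = probs.argmax(axis=1)
        for pl, tl in zip(labels, masks[i:i + batch]):
            scores.append(np.mean(list(dice_per_class(pl, tl).values())))
    return float(np.mean(scores))


def train(model_config: ModelConfig, train_config: TrainConfig,
          dataset: PhantomDataset) -> tuple[UNet, TrainReport]:
    """Train a U-Net on a phantom dataset with subject-disjoint validation.

    Returns the model restored to the epoch with the highest validation DICE
    together with a per-epoch report.
    """
    all_labels = np.concatenate([np.unique(m.labels) for m in dataset.masks])
    for c in FOREGROUND_CLASSES:
        if c not in all_labels:
            raise ValidationError(
                f"dataset contains no pixels of foreground class {c}; cannot train")

    size = model_config.input_size_px
    imgs, masks, subjects = _prepare(dataset, size)
    train_subj, val_subj = grouped_split(subjects, train_config.split_fractions,
                                         seed=train_config.seed)
    tr = np.isin(subjects, train_subj)
    va = np.isin(subjects, val_subj)
    x_tr, y_tr = imgs[tr], masks[tr]
    x_va, y_va = imgs[va], masks[va]

    model = UNet(model_config, seed=train_config.seed)
    # bias the heads toward the foreground priors so the thin-class DICE
    # gradient is not swamped by the background at the start of training
    fg = list(range(1, model_config.n_classes))
    priors = np.array([max((y_tr == c).mean(), 1e-4) for c in fg])
    model.head.b.value[...] = np.log(priors / (1.0 - priors))
    opt = nn.Adam(model.params(), lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed + 1)
    targets_tr = np.stack([(y_tr == c) for c in fg], axis=1).astype(nn.DTYPE)

    report = TrainReport(optimizer="adam", learning_rate=train_config.learning_rate,
                         train_subjects=list(train_subj), val_subjects=list(val_subj))
    best_state, best_dice, best_epoch = None, -np.inf, 0
    n = len(x_tr)
    for epoch in range(1, train_config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, train_config.batch_size):
            idx = order[i:i + train_config.batch_size]
            opt.zero_grad()
            logits = model.forward(x_tr[idx])
            loss, dlogits = nn.dice_loss_with_grad(logits, targets_tr[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_dice = _mean_val_dice(model, x_va, y_va, train_config.batch_size)
        report.epochs.append(dict(epoch=epoch, train_loss=float(np.mean(losses)),
                                  val_dice=val_dice))
        if val_dice > best_dice:  # strict: ties keep the earliest epoch
            best_dice, best_epoch = val_dice, epoch
            best_state = model.state()

    model.load_state(best_state)
    model.trained = True
    report.selected_epoch = best_epoch
    report.selected_val_dice = float(best_dice)
    report.model_checksum = model.checksum()
    return model, report


def segment(model: UNet, image: np.ndarray) -> tuple[LabelMask, np.ndarray]:
    """Segment one image; returns the argmax label mask at the original
    resolution and the per-class probability grids (n_classes, H, W)."""
    if not getattr(model, "trained", False):
        raise ValidationError("model has not been trained (or loaded from a checkpoint)")
    arr = np.asarray(image, dtype=float)
    x = preprocess(arr, model.config.input_size_px)[None, None]
    probs = model.predict_probs(x)[0].astype(float)  # (C, S, S)
    if probs.shape[1:] != arr.shape:
        up = np.stack([
            resize(p, arr.shape, order=1, mode="edge", preserve_range=True,
                   anti_aliasing=False)
            for p in probs
        ])
        up = np.clip(up, 1e-12, None)
        probs = up / up.sum(axis=0, keepdims=True)
    labels = probs.argmax(axis=0).astype(np.uint8)
    return LabelMask(labels), probs


def save_model(model: UNet, path: str | Path) -> None:
    """Save weights + embedded ModelConfig to a single .npz checkpoint."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path, config_json=np.array(json.dumps(asdict(model.config))),
             trained=np.array(int(model.trained)), **arrays)


def load_model(path: str | Path) -> UNet:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig(**json.loads(str(data["config_json"])))
        model = UNet(cfg, seed=0)
        state = [data[f"param_{i}"] for i in range(len(model.params()))]
        model.load_state(state)
        model.trained = bool(int(data["trained"]))
    return model
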