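"""Segmentation model assembly and SGDM training.

The network follows the DeepLab-v3+ pattern: a residual-bottleneck
encoder (ResNet-50-style stage layout 3/4/6/3, or a tiny 1/1/1/1 variant
with the same block topology), an atrous-spatial-pyramid-pooling (ASPP)
context module at output stride 16, and a decoder that fuses upsampled
ASPP features with stride-4 low-level features, upsamples to full
resolution and sharpens the result with a refinement convolution over
the raw input intensities before the per-pixel softmax over the three
classes.

Training uses stochastic gradient descent with momentum:

    v_{t+1} = mu * v_t - eta * grad L(W_t)
    W_{t+1} = W_t + v_{t+1}

with the class-imbalance-weighted cross-entropy of :mod:`pectseg.imbalance`
as the pixel loss. The dataset is split 70/20/10 into train/validation/
test by default; split sizes use nearest-integer rounding for train and
validation with the remainder going to test (1288 items -> 902/258/128).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .core import N_CLASSES, LabelMask, as_pixels
from .imbalance import ClassWeights, combined_objective, one_vs_rest_class_weights

__all__ = [
    "ModelConfig", "TrainConfig", "OptimizerState", "SegmentationModel",
    "TrainResult", "split_dataset", "build_model", "sgdm_step", "train",
    "predict", "to_input_tensor",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters; ``backbone`` picks the size preset."""

    input_size: tuple[int, int] = (256, 256)
    n_classes: int = N_CLASSES
    backbone: str = "resnet50"  # or "tiny"
    stage_repeats: tuple[int, int, int, int] | None = None
    base_filters: int | None = None
    aspp_rates: tuple[int, ...] | None = None
    pretrained: bool = False
    seed: int = 0

    def resolved(self) -> "ModelConfig":
        presets = {
            "resnet50": dict(stage_repeats=(3, 4, 6, 3), base_filters=64,
                             aspp_rates=(6, 12, 18)),
            "tiny": dict(stage_repeats=(1, 1, 1, 1), base_filters=8,
                         aspp_rates=(1, 2, 4)),
        }
        if self.backbone not in presets:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        p = presets[self.backbone]
        return ModelConfig(
            input_size=tuple(self.input_size),
            n_classes=self.n_classes,
            backbone=self.backbone,
            stage_repeats=self.stage_repeats or p["stage_repeats"],
            base_filters=self.base_filters or p["base_filters"],
            aspp_rates=self.aspp_rates or p["aspp_rates"],
            pretrained=self.pretrained,
            seed=self.seed,
        )

    def validate(self) -> None:
        cfg = self.resolved()
        if any(r < 1 for r in cfg.stage_repeats):
            raise ValueError("stage_repeats must be positive")
        h, w = cfg.input_size
        if h % 16 or w % 16:
            raise ValueError(
                f"input_size {cfg.input_size} must be divisible by the total stride 16")
        if cfg.pretrained:
            raise ValueError("pretrained backbone weights are not available; "
                             "train from random initialization")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters and the train/val/test split."""

    learning_rate: float = 0.001
    momentum: float = 0.9
    epochs: int = 50
    batch_size: int = 2
    lam: float = 1.0  # tuning factor of the class-weight formula
    use_class_weights: bool = True
    include_classification_term: bool = True  # dual-term objective
    split_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class OptimizerState:
    """SGDM state: named weight arrays and their velocities."""

    weights: dict[str, np.ndarray]
    velocity: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for k, w in self.weights.items():
            if k not in self.velocity:
                self.velocity[k] = np.zeros_like(w)
            elif self.velocity[k].shape != w.shape:
                raise ValueError(f"velocity shape mismatch for {k!r}")


def split_dataset(
    n: int, fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition ``range(n)`` into train/val/test index arrays.

    Sizes are ``round(f_train * n)`` and ``round(f_val * n)`` with the
    remainder as test (the rounding that maps 1288 at 70/20/10 onto
    902/258/128). A seed shuffles the indices first; ``seed=None`` keeps
    the natural order.
    """
    if n < 3:
        raise ValueError("need at least 3 items to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_train = round(fractions[0] * n)
    n_val = round(fractions[1] * n)
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"degenerate split: sizes ({n_train}, {n_val}, {n_test}) from {fractions}")
    idx = np.arange(n)
    if seed is not None:
        idx = np.random.default_rng(seed).permutation(n)
    return idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _bottleneck(cin: int, mid: int, cout: int, stride: int, dilation: int,
                rng, name: str) -> nn.Sequential:
    """Residual bottleneck: 1x1 -> 3x3 (stride/dilation) -> 1x1 + skip."""
    main = nn.Sequential(
        nn.Conv2d(cin, mid, 1, rng=rng, name=f"{name}.c1"),
        nn.BatchNorm2d(mid, name=f"{name}.bn1"), nn.ReLU(),
        nn.Conv2d(mid, mid, 3, stride=stride, dilation=dilation, rng=rng,
                  name=f"{name}.c2"),
        nn.BatchNorm2d(mid, name=f"{name}.bn2"), nn.ReLU(),
        nn.Conv2d(mid, cout, 1, rng=rng, name=f"{name}.c3"),
        nn.BatchNorm2d(cout, name=f"{name}.bn3"),
    )
    if cin != cout or stride != 1:
        shortcut = nn.Sequential(
            nn.Conv2d(cin, cout, 1, stride=stride, rng=rng, name=f"{name}.proj"),
            nn.BatchNorm2d(cout, name=f"{name}.projbn"),
        )
    else:
        shortcut = None
    return nn.Sequential(nn.Residual(main, shortcut), nn.ReLU())


class SegmentationModel:
    """Encoder + ASPP + decoder with a per-pixel softmax over 3 classes."""

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        cfg = cfg.resolved()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        b = cfg.base_filters
        h, w = cfg.input_size

        self.stem = nn.Sequential(
            nn.Conv2d(1, b, 7, stride=2, rng=rng, name="stem.conv"),
            nn.BatchNorm2d(b, name="stem.bn"), nn.ReLU())
        self.pool = nn.MaxPool2d(3, 2, 1)

        mids = (b, 2 * b, 4 * b, 8 * b)
        strides = (1, 2, 2, 1)
        dilations = (1, 1, 1, 2)  # final stage trades stride for dilation
        self.stages: list[nn.Sequential] = []
        cin = b
        for si, (mid, reps) in enumerate(zip(mids, cfg.stage_repeats)):
            blocks = []
            cout = 4 * mid
            for r in range(reps):
                blocks.append(_bottleneck(
                    cin, mid, cout,
                    stride=strides[si] if r == 0 else 1,
                    dilation=dilations[si], rng=rng, name=f"s{si + 2}.b{r}"))
                cin = cout
            self.stages.append(nn.Sequential(*blocks))
        enc_out = cin  # 32*b for the full stage plan

        aspp_ch = 4 * b
        self.aspp = nn.ASPP(enc_out, aspp_ch, cfg.aspp_rates, aspp_ch, rng)

        low_ch = 4 * mids[0]  # channels leaving the first stage
        self.low_proj_ch = max(b, low_ch // 4)
        self.lowproj = nn.Sequential(
            nn.Conv2d(low_ch, self.low_proj_ch, 1, rng=rng, name="dec.low.conv"),
            nn.BatchNorm2d(self.low_proj_ch, name="dec.low.bn"), nn.ReLU())
        self.up1 = nn.BilinearUpsample((h // 4, w // 4))
        fuse_ch = 4 * b
        self.fuse = nn.Sequential(
            nn.Conv2d(aspp_ch + self.low_proj_ch, fuse_ch, 3, rng=rng,
                      name="dec.fuse1.conv"),
            nn.BatchNorm2d(fuse_ch, name="dec.fuse1.bn"), nn.ReLU(),
            nn.Conv2d(fuse_ch, fuse_ch, 3, rng=rng, name="dec.fuse2.conv"),
            nn.BatchNorm2d(fuse_ch, name="dec.fuse2.bn"), nn.ReLU())
        self.up2 = nn.BilinearUpsample((h, w))
        refine_ch = 2 * b
        # Refinement over (decoder features ++ raw input) restores the
        # pixel-level intensity cue that strided encoding blurs away.
        self.refine = nn.Sequential(
            nn.Conv2d(fuse_ch + 1, refine_ch, 3, rng=rng, name="dec.refine.conv"),
            nn.BatchNorm2d(refine_ch, name="dec.refine.bn"), nn.ReLU())
        self.classifier = nn.Conv2d(refine_ch, cfg.n_classes, 1, bias=True,
                                    rng=rng, name="head.conv")

    # -- plumbing ----------------------------------------------------------

    def params(self) -> list[nn.Param]:
        out = self.stem.params()
        for s in self.stages:
            out += s.params()
        out += self.aspp.params() + self.lowproj.params() + self.fuse.params()
        out += self.refine.params() + self.classifier.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    def encoder_conv_layer_count(self) -> int:
        """Main-path convolutions in the encoder: stem + 3 per bottleneck."""
        return 1 + 3 * sum(self.cfg.stage_repeats)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data.copy() for p in self.params()}
        for layer in self._bn_layers():
            state[f"{layer.gamma.name}.running_mean"] = layer.running_mean.copy()
            state[f"{layer.gamma.name}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.data[...] = state[p.name]
        for layer in self._bn_layers():
            layer.running_mean[...] = state[f"{layer.gamma.name}.running_mean"]
            layer.running_var[...] = state[f"{layer.gamma.name}.running_var"]

    def _bn_layers(self):
        seen = []

        def walk(layer):
            if isinstance(layer, nn.BatchNorm2d):
                seen.append(layer)
            for attr in ("layers", "branches"):
                for child in getattr(layer, attr, []):
                    walk(child)
            for attr in ("main", "shortcut", "inner", "project"):
                child = getattr(layer, attr, None)
                if child is not None:
                    walk(child)

        for top in [self.stem, *self.stages, self.aspp, self.lowproj,
                    self.fuse, self.refine, self.classifier]:
            walk(top)
        return seen

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[2:] != tuple(self.cfg.input_size):
            raise ValueError(
                f"input spatial size {x.shape[2:]} != configured {self.cfg.input_size}")
        s = self.stem.forward(x, train)
        p = self.pool.forward(s, train)
        l1 = self.stages[0].forward(p, train)
        z = l1
        for stage in self.stages[1:]:
            z = stage.forward(z, train)
        a = self.aspp.forward(z, train)
        u = self.up1.forward(a, train)
        lp = self.lowproj.forward(l1, train)
        cat = np.concatenate([u, lp], axis=1)
        f = self.fuse.forward(cat, train)
        u2 = self.up2.forward(f, train)
        cat2 = np.concatenate([u2, x.astype(np.float32)], axis=1)
        r = self.refine.forward(cat2, train)
        return self.classifier.forward(r, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dr = self.classifier.backward(dlogits)
        dcat2 = self.refine.backward(dr)
        du2 = dcat2[:, :-1]
        df = self.up2.backward(du2)
        dcat = self.fuse.backward(df)
        c_aspp = dcat.shape[1] - self.low_proj_ch
        du = dcat[:, :c_aspp]
        dlp = dcat[:, c_aspp:]
        da = self.up1.backward(du)
        dz = self.aspp.backward(da)
        for stage in reversed(self.stages[1:]):
            dz = stage.backward(dz)
        dl1 = dz + self.lowproj.backward(dlp)
        dp = self.stages[0].backward(dl1)
        ds = self.pool.backward(dp)
        self.stem.backward(ds)

    def probabilities(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (eval mode), summing to 1."""
        return nn.softmax(self.forward(x, train=False), axis=1)


def build_model(cfg: ModelConfig) -> SegmentationModel:
    """Construct a :class:`SegmentationModel` from a validated config."""
    return SegmentationModel(cfg)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def sgdm_step(state: OptimizerState, gradient: dict[str, np.ndarray],
              mu: float, eta: float) -> OptimizerState:
    """One SGDM update: v <- mu*v - eta*g; W <- W + v (applied in place)."""
    for name, w in state.weights.items():
        g = gradient[name]
        if g.shape != w.shape:
            raise ValueError(f"gradient shape mismatch for {name!r}")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"non-finite gradient for {name!r}")
        v = state.velocity[name]
        v *= mu
        v -= eta * g
        w += v
    return state


def to_input_tensor(images) -> np.ndarray:
    """Stack image rasters into an (N, 1, H, W) float32 batch in [0, 1]."""
    arrs = []
    for im in images:
        px = as_pixels(im).astype(np.float32)
        top = float(2 ** getattr(im, "bit_depth", 8) - 1)
        arrs.append(px / top)
    return np.stack(arrs)[:, None]


@dataclass
class TrainResult:
    model: SegmentationModel
    history: pd.DataFrame
    class_weights: ClassWeights
    split: tuple[np.ndarray, np.ndarray, np.ndarray]
    best_epoch: int
    best_val_accuracy: float


def train(model: SegmentationModel, dataset, cfg: TrainConfig) -> TrainResult:
    """Train on a list of (image, mask) pairs; returns the best-val model.

    Class weights are computed from the *training* split only. History
    records per-epoch mean loss and pixel accuracy on the training data
    plus validation loss/accuracy; the weights achieving the best
    validation accuracy are restored into the model at the end.
    """
    cfg.validate()
    pairs = list(dataset)
    train_idx, val_idx, test_idx = split_dataset(len(pairs), cfg.split_fractions,
                                                 seed=cfg.seed)
    masks = [m for _, m in pairs]
    if cfg.use_class_weights:
        weights = one_vs_rest_class_weights([masks[i] for i in train_idx],
                                            lam=cfg.lam,
                                            n_classes=model.cfg.n_classes)
    else:
        weights = ClassWeights(alpha=1.0, beta=1.0, lam=cfg.lam,
                               per_class=(1.0,) * model.cfg.n_classes)
    wvec = np.asarray(weights.per_class)

    x_all = to_input_tensor([im for im, _ in pairs])
    y_all = np.stack([as_pixels(m) for m in masks])

    params = model.params()
    state = OptimizerState(weights={p.name: p.data for p in params})
    rng = np.random.default_rng(cfg.seed)

    history = []
    best_val, best_epoch, best_state = -1.0, -1, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        losses, correct, seen = [], 0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            xb, yb = x_all[batch], y_all[batch]
            model.zero_grad()
            logits = model.forward(xb, train=True)
            l_seg, dlogits = nn.weighted_ce_loss_and_grad(logits, yb, wvec)
            if cfg.include_classification_term:
                # The image-level term duplicates the pixel mean for
                # equal-sized images; the combined objective is their sum.
                loss = combined_objective(l_seg, l_seg).total
                dlogits = dlogits * 2.0
            else:
                loss = combined_objective(0.0, l_seg).total
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss}")
            model.backward(dlogits)
            sgdm_step(state, {p.name: p.grad for p in params},
                      mu=cfg.momentum, eta=cfg.learning_rate)
            losses.append(loss)
            pred = logits.argmax(axis=1)
            correct += int((pred == yb).sum())
            seen += yb.size
        val_loss, val_acc = _evaluate_split(model, x_all, y_all, val_idx, wvec,
                                            cfg)
        history.append(dict(epoch=epoch, loss=float(np.mean(losses)),
                            accuracy=correct / seen,
                            val_loss=val_loss, val_accuracy=val_acc))
        if val_acc > best_val:
            best_val, best_epoch = val_acc, epoch
            best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainResult(model=model, history=pd.DataFrame(history),
                       class_weights=weights,
                       split=(train_idx, val_idx, test_idx),
                       best_epoch=best_epoch, best_val_accuracy=best_val)


def _evaluate_split(model, x_all, y_all, idx, wvec, cfg) -> tuple[float, float]:
    losses, correct, seen = [], 0, 0
    for start in range(0, len(idx), cfg.batch_size):
        batch = idx[start:start + cfg.batch_size]
        logits = model.forward(x_all[batch], train=False)
        l_seg, _ = nn.weighted_ce_loss_and_grad(logits, y_all[batch], wvec)
        losses.append(2.0 * l_seg if cfg.include_classification_term else l_seg)
        pred = logits.argmax(axis=1)
        correct += int((pred == y_all[batch]).sum())
        seen += y_all[batch].size
    return float(np.mean(losses)), correct / seen


def predict(model: SegmentationModel, images, batch_size: int = 4) -> list[LabelMask]:
    """Segment images with a trained model (argmax over class probabilities)."""
    x = to_input_tensor(images)
    out = []
    for start in range(0, len(x), batch_size):
        probs = model.probabilities(x[start:start + batch_size])
        for arr in probs.argmax(axis=1):
            out.append(LabelMask(arr.astype(np.uint8)))
    return out
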