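"""Regression-CNN construction and phase training on numpy tensors.

Named large backbones (ResNet50, EfficientNetB0/B4) are declared but can
only be built where their pretrained weights are available; the
``tiny_test_cnn`` backbone (4 strided conv blocks, ~100k parameters, no
pretraining) is the desk-scale architecture every test and pipeline run
uses on CPU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Conv2d, Dense, GlobalAvgPool, ReLU, Sequential, Softmax

__all__ = [
    "BackboneSpec",
    "HeadSpec",
    "TrainPhase",
    "ChannelStats",
    "CNNModel",
    "ModelBundle",
    "build_model",
    "preprocess",
    "augment",
    "masked_weighted_mse",
    "train",
    "predict",
    "default_phases",
    "pseudo_phase",
]

_INPUT_SIZES = {
    "resnet50": 224,
    "efficientnet_b0": 224,
    "efficientnet_b4": 380,
    "tiny_test_cnn": 64,
}


@dataclass
class BackboneSpec:
    """Backbone identity; ``input_size`` is fixed per architecture."""

    name: str = "tiny_test_cnn"
    input_size: int | None = None
    pretrained: bool = False

    def __post_init__(self) -> None:
        if self.name not in _INPUT_SIZES:
            raise ValueError(f"unknown backbone {self.name!r}")
        expected = _INPUT_SIZES[self.name]
        if self.input_size is None:
            self.input_size = expected
        elif self.input_size != expected:
            raise ValueError(
                f"{self.name} requires input_size {expected}, got {self.input_size}"
            )
        if self.pretrained and self.name == "tiny_test_cnn":
            raise ValueError("tiny_test_cnn has no pretrained weights")

    def scale_rgb(self, x: np.ndarray) -> np.ndarray:
        # Large backbones would apply their framework-specific scaling here;
        # the desk-scale backbone simply maps 8-bit values to [0, 1].
        return x / 255.0


@dataclass
class HeadSpec:
    """Output head: single scalar, 4 linear organs, or 4 softmax proportions."""

    kind: str = "single_linear"
    n_outputs: int = 1
    organ_weights: np.ndarray | None = None
    mask_zero_targets: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("single_linear", "multi_linear", "multi_softmax"):
            raise ValueError(f"unknown head kind {self.kind!r}")
        expected = 1 if self.kind == "single_linear" else 4
        if self.n_outputs != expected:
            raise ValueError(f"{self.kind} head requires {expected} outputs")
        if self.organ_weights is None:
            # flag-leaf (l1) loss terms x20 on proportion heads
            self.organ_weights = (
                np.array([1.0, 1.0, 20.0, 1.0])
                if self.kind == "multi_softmax"
                else np.ones(self.n_outputs)
            )
        self.organ_weights = np.asarray(self.organ_weights, dtype=float)
        if self.organ_weights.shape != (self.n_outputs,):
            raise ValueError("organ_weights must match n_outputs")


@dataclass
class TrainPhase:
    name: str
    epochs: int
    learning_rate: float
    trainable_scope: str = "all"  # {head_only, head_plus_last_block, all}

    def __post_init__(self) -> None:
        if self.trainable_scope not in ("head_only", "head_plus_last_block", "all"):
            raise ValueError(f"unknown trainable_scope {self.trainable_scope!r}")


def default_phases(backbone: BackboneSpec | None = None) -> list[TrainPhase]:
    """Transfer (40 epochs @1e-3, head only) then fine-tune (10 @1e-5, head
    + last conv block).  Without pretrained weights freezing a random
    backbone is pointless, so the unpretrained desk backbone trains all
    layers in both phases."""
    if backbone is not None and not backbone.pretrained:
        # Desk-scale adaptation: with random initial weights the tiny
        # backbone needs a working learning rate everywhere.
        return [
            TrainPhase("transfer", 40, 3e-3, "all"),
            TrainPhase("finetune", 10, 3e-4, "all"),
        ]
    return [
        TrainPhase("transfer", 40, 1e-3, "head_only"),
        TrainPhase("finetune", 10, 1e-5, "head_plus_last_block"),
    ]


def pseudo_phase(backbone: BackboneSpec | None = None, epochs: int = 30) -> TrainPhase:
    """Pseudo-label retraining phase (fresh initialization)."""
    if backbone is not None and not backbone.pretrained:
        return TrainPhase("pseudo", epochs, 3e-3, "all")
    return TrainPhase("pseudo", epochs, 1e-5, "all")


@dataclass
class ChannelStats:
    """Per-channel standardization statistics with split provenance."""

    mean: np.ndarray
    sd: np.ndarray
    source_split: str = "train"

    @classmethod
    def from_images(cls, images: list[np.ndarray], source_split: str = "train") -> "ChannelStats":
        stack = np.stack([np.asarray(im, dtype=float) for im in images])
        mean = stack.mean(axis=(0, 1, 2))
        sd = stack.std(axis=(0, 1, 2))
        sd[sd == 0] = 1.0
        return cls(mean=mean, sd=sd, source_split=source_split)


@dataclass
class CNNModel:
    """A built network plus the specs needed to drive it."""

    net: Sequential
    backbone: BackboneSpec
    head: HeadSpec
    in_channels: int

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    __call__ = forward


@dataclass
class ModelBundle:
    """A trained model with its preprocessing contract and provenance."""

    model: CNNModel
    train_stats: ChannelStats | None
    label_source: str  # {ytrue, ypseu}
    phases: list[TrainPhase]
    seed: int
    history: list[dict] = field(default_factory=list)
    #: target scale divided out before training (1.0 = raw targets)
    y_scale: float | np.ndarray = 1.0


_SCOPE_SETS = {
    "head_only": {"head", "adapter"},
    "head_plus_last_block": {"head", "adapter", "block4"},
    "all": None,
}


def build_model(
    backbone: BackboneSpec, head: HeadSpec, in_channels: int, seed: int = 0
) -> CNNModel:
    """Construct the network; a trainable 1x1 conv maps 6->3 channels ahead
    of the backbone for multispectral input."""
    if in_channels not in (3, 6):
        raise ValueError(f"in_channels must be 3 or 6, got {in_channels}")
    if backbone.name != "tiny_test_cnn":
        raise NotImplementedError(
            f"{backbone.name} requires its pretrained weights, which are not "
            "available in this environment; use tiny_test_cnn"
        )
    rng = np.random.default_rng(seed)
    layers = []
    if in_channels == 6:
        adapter = Conv2d(6, 3, k=1, stride=1, pad=0, scope="adapter", rng=rng)
        # near-identity init: start from a sensible band triplet
        adapter.w.value[...] = 0.0
        for out_ch, in_ch in ((0, 2), (1, 1), (2, 0)):
            adapter.w.value[out_ch, in_ch, 0, 0] = 1.0
        adapter.w.value += rng.normal(0.0, 0.01, adapter.w.value.shape)
        layers.append(adapter)
    widths = [(3, 16), (16, 32), (32, 64), (64, 128)]
    for i, (cin, cout) in enumerate(widths, start=1):
        layers.append(Conv2d(cin, cout, k=3, stride=2, pad=1, scope=f"block{i}", rng=rng))
        layers.append(ReLU())
    layers.append(GlobalAvgPool())
    layers.append(Dense(128, head.n_outputs, scope="head", rng=rng))
    if head.kind == "multi_softmax":
        layers.append(Softmax())
    return CNNModel(net=Sequential(layers), backbone=backbone, head=head, in_channels=in_channels)


# ---------------------------------------------------------------------------
# Preprocessing and augmentation
# ---------------------------------------------------------------------------


def preprocess(
    image: np.ndarray,
    kind: str,
    spec: BackboneSpec,
    train_stats: ChannelStats | None = None,
) -> np.ndarray:
    """Center-crop to square, resize to the backbone size, scale, -> CHW.

    RGB uses the backbone's scaling convention; multispectral BRF is
    standardized channelwise with training-split statistics (required, and
    rejected if computed on any other split — leakage guard).
    """
    from skimage.transform import resize as _resize

    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValueError(f"expected HxWxC image, got {image.shape}")
    h, w, _ = image.shape
    side = min(h, w)
    top, left = (h - side) // 2, (w - side) // 2
    image = image[top : top + side, left : left + side]
    if side != spec.input_size:
        image = _resize(
            image,
            (spec.input_size, spec.input_size),
            preserve_range=True,
            anti_aliasing=side > spec.input_size,
        )
    if kind == "rgb":
        image = spec.scale_rgb(image)
    elif kind == "ms":
        if train_stats is None:
            raise ValueError("multispectral preprocessing requires train_stats")
        if train_stats.source_split != "train":
            raise ValueError(
                f"train_stats computed on {train_stats.source_split!r} split; "
                "only training-split statistics are allowed"
            )
        image = (image - train_stats.mean) / train_stats.sd
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return np.moveaxis(image, -1, 0)  # CHW


def augment(tensor: np.ndarray, seed: int) -> np.ndarray:
    """Independent 0.5-probability vertical and horizontal flips (CHW)."""
    rng = np.random.default_rng(seed)
    out = tensor
    if rng.random() < 0.5:
        out = out[:, ::-1, :]
    if rng.random() < 0.5:
        out = out[:, :, ::-1]
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def masked_weighted_mse(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    head: HeadSpec,
    return_grad: bool = False,
):
    """Weighted MSE restricted to true labels above 0 when masking is on.

    ``loss = sum_j w_j (y_true - y_pred)^2 [included] / #included``; the
    denominator counts included (sample, output) terms, so the loss reduces
    to plain MSE with unit weights and masking off.  Gradients at masked
    positions are exactly zero.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    include = (y_true > 0) if head.mask_zero_targets else np.ones_like(y_true, dtype=bool)
    count = int(include.sum())
    w = head.organ_weights[None, :]
    if count == 0:
        warnings.warn("all targets masked in batch; loss is 0 with no gradient", stacklevel=2)
        loss, grad = 0.0, np.zeros_like(y_pred)
    else:
        diff = np.where(include, y_true - y_pred, 0.0)
        loss = float((w * diff**2).sum() / count)
        grad = -2.0 * w * diff / count
    return (loss, grad) if return_grad else loss


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def predict(model: CNNModel, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Forward pass in evaluation mode, batched."""
    outs = [model.forward(X[i : i + batch_size]) for i in range(0, len(X), batch_size)]
    return np.concatenate(outs, axis=0)


def train(
    model: CNNModel,
    X: np.ndarray,
    y: np.ndarray,
    phases: list[TrainPhase],
    seed: int = 0,
    batch_size: int = 16,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    label_source: str = "ytrue",
    augment_data: bool = True,
    train_stats: ChannelStats | None = None,
) -> ModelBundle:
    """Run the training phases in order with Adam on the masked/weighted MSE.

    Freezing honors each phase's ``trainable_scope``; per-epoch train (and
    optional validation) losses are recorded.  Deterministic for a fixed
    seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    rng = np.random.default_rng(seed)
    history: list[dict] = []

    for phase in phases:
        model.net.set_trainable(_SCOPE_SETS[phase.trainable_scope])
        opt = Adam(model.net.params(), lr=phase.learning_rate)
        for epoch in range(phase.epochs):
            order = rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), batch_size):
                idx = order[start : start + batch_size]
                xb = X[idx]
                if augment_data:
                    xb = np.stack(
                        [augment(im, int(rng.integers(2**31))) for im in xb]
                    )
                yb = y[idx]
                model.net.zero_grad()
                pred = model.forward(xb, train=True)
                loss, grad = masked_weighted_mse(yb, pred, model.head, return_grad=True)
                model.net.backward(grad)
                opt.step()
                losses.append(loss)
            record = {
                "phase": phase.name,
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
            }
            if X_val is not None and y_val is not None and len(X_val):
                pv = predict(model, X_val)
                yv = y_val[:, None] if y_val.ndim == 1 else y_val
                record["val_loss"] = masked_weighted_mse(yv, pv, model.head)
            history.append(record)
    model.net.set_trainable(None)
    return ModelBundle(
        model=model,
        train_stats=train_stats,
        label_source=label_source,
        phases=list(phases),
        seed=seed,
        history=history,
    )
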