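"""The ancestry-identification CNN: Wide module, SE gate, and ANINet.

The Wide module compresses the incoming feature map with a 1 x 1
convolution, feeds the result to two parallel 3 x 3 branches — one
standard, one dilated with rate ``k`` (default 2), which widens the
receptive field at zero extra parameter cost — and concatenates all three
outputs on the channel axis.  An SE block then learns per-channel gates
from globally pooled features.  ANINet stacks two SE-Wide stages
(32 and 64 channels, each followed by batch norm, ReLU and 2 x 2 max
pooling), a ReLU hidden layer (300 units single-mode, 1000 for the fused
local+global mode) and a sigmoid output unit, trained with Adam on the
binary log loss.

Two ablation variants are built from the same config: ``"wide"`` replaces
the SE gate with the identity, ``"plain"`` replaces the whole Wide module
with a single standard 3 x 3 convolution of the same output width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Dense,
    Flatten,
    Layer,
    MaxPool2d,
    ReLU,
    SEBlock,
    sigmoid,
)
from .nn.layers import DTYPE


class ConfigError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclass
class WideSpec:
    """Channel budget of one Wide module.

    ``split`` is (c_1x1, c_3x3, c_dilated) and must sum to ``out_channels``;
    the default rule is (out/2, out/4, out/4).
    """

    out_channels: int
    split: tuple[int, int, int] | None = None
    dilation_rate: int = 2

    def __post_init__(self) -> None:
        if self.split is None:
            c1 = self.out_channels // 2
            c3 = self.out_channels // 4
            self.split = (c1, c3, self.out_channels - c1 - c3)
        if any(c < 1 for c in self.split):
            raise ConfigError("every Wide branch needs >= 1 channel")
        if sum(self.split) != self.out_channels:
            raise ConfigError(
                f"split {self.split} does not sum to out_channels {self.out_channels}"
            )
        if self.dilation_rate < 1:
            raise ConfigError("dilation_rate must be a positive integer")


@dataclass
class SESpec:
    reduction_ratio: int = 4

    def __post_init__(self) -> None:
        if self.reduction_ratio < 1:
            raise ConfigError("reduction_ratio must be >= 1")


@dataclass
class NetworkConfig:
    """Architecture and training hyperparameters.

    ``input_side`` defaults to the network's native 160 but may be reduced
    (any multiple of 4) to trade resolution for speed; ``channels`` is 1
    (global), 3 (local) or 4 (fused).  ``variant`` selects the full model
    ("aninet"), the SE-less ablation ("wide") or a plain-convolution
    baseline ("plain").
    """

    channels: int = 3
    input_side: int = 160
    stage_channels: tuple[int, int] = (32, 64)
    hidden_units: int = 300
    dilation_rate: int = 2
    se_reduction: int = 4
    wide_split: tuple[int, int, int] | None = None
    variant: str = "aninet"
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channels not in (1, 3, 4):
            raise ConfigError("channels must be 1 (global), 3 (local) or 4 (fused)")
        if self.input_side < 8 or self.input_side % 4:
            raise ConfigError("input_side must be a multiple of 4 and >= 8")
        if len(self.stage_channels) != 2:
            raise ConfigError("exactly two convolution stages are defined")
        if self.hidden_units < 1:
            raise ConfigError("hidden_units must be >= 1")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.variant not in ("aninet", "wide", "plain"):
            raise ConfigError(f"unknown variant {self.variant!r}")

    @property
    def input_shape(self) -> tuple[int, int, int]:
        return (self.input_side, self.input_side, self.channels)


class WideBlock(Layer):
    """1x1 -> {3x3, dilated 3x3} multi-branch block with channel concat."""

    def __init__(self, in_ch: int, spec: WideSpec, rng: np.random.Generator | None = None,
                 name: str = "wide"):
        c1, c3, cd = spec.split
        self.spec = spec
        self.conv1 = Conv2d(in_ch, c1, ksize=1, rng=rng, name=f"{name}.1x1")
        self.conv3 = Conv2d(c1, c3, ksize=3, dilation=1, rng=rng, name=f"{name}.3x3")
        self.convd = Conv2d(c1, cd, ksize=3, dilation=spec.dilation_rate, rng=rng,
                            name=f"{name}.dil")
        self._c1 = c1
        self._c3 = c3

    def params(self):
        return self.conv1.params() + self.conv3.params() + self.convd.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        a = self.conv1.forward(x, train)
        b = self.conv3.forward(a, train)
        c = self.convd.forward(a, train)
        return np.concatenate([a, b, c], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        da = dy[:, :self._c1]
        db = dy[:, self._c1:self._c1 + self._c3]
        dc = dy[:, self._c1 + self._c3:]
        da = da + self.conv3.backward(db) + self.convd.backward(dc)
        return self.conv1.backward(da)


def wide_forward(x: np.ndarray, spec: WideSpec, rng: np.random.Generator | None = None,
                 block: WideBlock | None = None) -> np.ndarray:
    """Apply a (freshly initialized or given) Wide module to NCHW input."""
    if block is None:
        block = WideBlock(x.shape[1], spec, rng=rng)
    return block.forward(x)


def se_forward(x: np.ndarray, spec: SESpec | None = None,
               rng: np.random.Generator | None = None,
               block: SEBlock | None = None) -> np.ndarray:
    """Apply a (freshly initialized or given) SE gate to NCHW input."""
    if block is None:
        spec = spec or SESpec()
        block = SEBlock(x.shape[1], reduction=spec.reduction_ratio, rng=rng)
    return block.forward(x)


class Model:
    """A sequential stack with a sigmoid-probability head.

    The final Dense layer emits a logit; :meth:`predict_proba` applies the
    sigmoid.  Training uses the numerically stable log-loss on logits.
    """

    def __init__(self, layers: list[Layer], config: NetworkConfig):
        self.layers = layers
        self.config = config

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x  # logits, shape (N, 1)

    def backward(self, dlogit: np.ndarray) -> None:
        d = dlogit
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
        X = _to_nchw(X, self.config)
        probs = []
        for start in range(0, X.shape[0], batch_size):
            z = self.forward(X[start:start + batch_size], train=False)
            probs.append(sigmoid(z)[:, 0])
        return np.concatenate(probs)


def _to_nchw(X: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """Accept N x H x W x C (or N x H x W for 1 channel) and yield NCHW."""
    X = np.asarray(X, dtype=DTYPE)
    if X.ndim == 3:
        X = X[..., None]
    if X.ndim != 4:
        raise ConfigError(f"expected 4-D input, got shape {X.shape}")
    n, h, w, c = X.shape
    side = config.input_side
    if (h, w, c) != (side, side, config.channels):
        raise ConfigError(
            f"input shape {(h, w, c)} does not match configured {(side, side, config.channels)}"
        )
    return np.ascontiguousarray(X.transpose(0, 3, 1, 2))


def build_aninet(config: NetworkConfig) -> Model:
    """Assemble the classifier described by ``config``.

    Layout: two stages of [feature block -> BatchNorm -> ReLU -> MaxPool 2x2]
    with 32 then 64 output channels, then Flatten -> Dense(hidden, ReLU) ->
    Dense(1, sigmoid head).
    """
    rng = np.random.default_rng(config.seed)
    layers: list[Layer] = []
    in_ch = config.channels
    for stage, out_ch in enumerate(config.stage_channels):
        if config.variant == "plain":
            layers.append(Conv2d(in_ch, out_ch, ksize=3, rng=rng, name=f"s{stage}.conv"))
        else:
            # an explicit split only applies to the stage it sums to
            split = config.wide_split if (
                config.wide_split and sum(config.wide_split) == out_ch
            ) else None
            spec = WideSpec(out_channels=out_ch, split=split,
                            dilation_rate=config.dilation_rate)
            layers.append(WideBlock(in_ch, spec, rng=rng, name=f"s{stage}.wide"))
            layers.append(SEBlock(out_ch, reduction=config.se_reduction,
                                  identity_gate=(config.variant == "wide"),
                                  rng=rng, name=f"s{stage}.se"))
        layers.append(BatchNorm2d(out_ch, name=f"s{stage}.bn"))
        layers.append(ReLU())
        layers.append(MaxPool2d())
        in_ch = out_ch
    feat = (config.input_side // 4) ** 2 * config.stage_channels[-1]
    layers.append(Flatten())
    layers.append(Dense(feat, config.hidden_units, rng=rng, name="hidden"))
    layers.append(ReLU())
    layers.append(Dense(config.hidden_units, 1, rng=rng, name="output"))
    return Model(layers, config)


def _log_loss_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits[:, 0]
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = sigmoid(z)
    return loss, ((p - y) / len(y)).astype(DTYPE)[:, None]


def train(
    model: Model,
    X: np.ndarray,
    y: np.ndarray,
    config: NetworkConfig | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[Model, dict]:
    """Fit with Adam on binary log loss; fully reproducible per config.seed.

    Returns the trained model and a history dict with per-epoch train (and,
    if provided, validation) loss and accuracy.
    """
    config = config or model.config
    y = np.asarray(y, dtype=DTYPE)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise TrainingError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise TrainingError("training data must contain both classes")
    if len(y) < 4:
        raise TrainingError("need at least 2 samples per class")
    Xn = _to_nchw(X, config)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.params(), lr=config.learning_rate)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    if X_val is not None:
        history["val_loss"] = []
        history["val_accuracy"] = []
    n = len(y)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = Xn[idx], y[idx]
            opt.zero_grad()
            logits = model.forward(xb, train=True)
            loss, dlogit = _log_loss_and_grad(logits, yb)
            model.backward(dlogit)
            opt.step()
            epoch_loss += loss * len(idx)
            correct += int(((sigmoid(logits[:, 0]) >= 0.5) == (yb >= 0.5)).sum())
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(correct / n)
        if X_val is not None:
            _recalibrate_batchnorm(model, Xn, config.batch_size)
            val_p = model.predict_proba(X_val)
            yv = np.asarray(y_val, dtype=DTYPE)
            eps = 1e-7
            vp = np.clip(val_p, eps, 1 - eps)
            history["val_loss"].append(
                float(np.mean(-(yv * np.log(vp) + (1 - yv) * np.log(1 - vp))))
            )
            history["val_accuracy"].append(float(np.mean((val_p >= 0.5) == (yv >= 0.5))))
    if X_val is None:
        _recalibrate_batchnorm(model, Xn, config.batch_size)
    return model, history


def _recalibrate_batchnorm(model: Model, Xn: np.ndarray, batch_size: int) -> None:
    """Set BN running statistics to the exact training-set statistics.

    Momentum-averaged running stats are still dominated by their init
    values after few optimizer steps; a single accumulation pass over the
    training data makes inference-mode behavior match what was trained.
    """
    from .nn.layers import BatchNorm2d

    bns = [l for l in model.layers if isinstance(l, BatchNorm2d)]
    if not bns:
        return
    for bn in bns:
        bn.begin_accumulation()
    for start in range(0, Xn.shape[0], batch_size):
        model.forward(Xn[start:start + batch_size], train=True)
    for bn in bns:
        bn.end_accumulation()


def predict(model: Model, X: np.ndarray, threshold: float = 0.5
            ) -> tuple[np.ndarray, np.ndarray]:
    """Sigmoid probabilities and thresholded binary labels."""
    probs = model.predict_proba(X)
    return probs, (probs >= threshold).astype(int)
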