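"""Canonical CNN denoiser with MSE pretraining and a frozen/trainable split.

Architecture (depth D, fully convolutional, same-size output):

* layer 1:        Conv(1 -> F) + ReLU
* layers 2..D-2:  Conv(F -> F) + BatchNorm + ReLU
* layer D-1:      Conv(F -> F) + BatchNorm
* layer D:        Conv(F -> 1), no activation

Pretraining minimizes the per-batch mean of the squared L2 distance between
the denoised output and the noiseless target, on minibatches balanced
between signal-present and signal-absent pairs; the weight state with the
best validation MSE is returned. A per-layer trainable mask partitions the
weights into a frozen subset and the last ``n_train`` layers; frozen layers
keep their batch-norm running statistics fixed (they run in inference mode)
during any later fine-tuning, so "frozen" is bit-exact.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .containers import ImageEnsemble, TARGET, LOWDOSE
from .phantom import InvalidConfigurationError


class InvalidInputError(ValueError):
    pass


@dataclass(frozen=True)
class DenoiserSpec:
    depth_D: int = 7
    filters_per_layer: int = 64
    kernel_side: int = 3

    def __post_init__(self) -> None:
        if self.depth_D < 4:
            raise InvalidConfigurationError("depth_D must be >= 4")
        if self.filters_per_layer < 1 or self.kernel_side % 2 != 1:
            raise InvalidConfigurationError("invalid filters/kernel configuration")

    def manifest(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TrainSettings:
    """Adam optimizer settings shared by pretraining and fine-tuning."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0


class _Block:
    """One convolutional layer with optional batch norm and ReLU."""

    def __init__(self, conv: nn.Conv2d, bn: nn.BatchNorm2d | None, relu: bool):
        self.conv = conv
        self.bn = bn
        self.relu = nn.ReLU() if relu else None

    def forward(self, x: np.ndarray, train: bool, need_grad: bool) -> np.ndarray:
        x = self.conv.forward(x, need_grad)
        if self.bn is not None:
            x = self.bn.forward(x, train, need_grad)
        if self.relu is not None:
            x = self.relu.forward(x, need_grad)
        return x

    def backward(self, dout: np.ndarray, need_dx: bool) -> np.ndarray | None:
        if self.relu is not None:
            dout = self.relu.backward(dout)
        if self.bn is not None:
            dout = self.bn.backward(dout)
        return self.conv.backward(dout, need_dx)

    def named_params(self, prefix: str):
        for name, p in self.conv.params().items():
            yield f"{prefix}.conv.{name}", p, self.conv.grads.get(name)
        if self.bn is not None:
            for name, p in self.bn.params().items():
                yield f"{prefix}.bn.{name}", p, self.bn.grads.get(name)

    def state(self) -> dict:
        s = {"W": self.conv.W.copy(), "b": self.conv.b.copy()}
        if self.bn is not None:
            s.update(
                gamma=self.bn.gamma.copy(), beta=self.bn.beta.copy(),
                running_mean=self.bn.running_mean.copy(),
                running_var=self.bn.running_var.copy(),
            )
        return s

    def load_state(self, s: dict) -> None:
        self.conv.W = s["W"].copy()
        self.conv.b = s["b"].copy()
        if self.bn is not None:
            self.bn.gamma = s["gamma"].copy()
            self.bn.beta = s["beta"].copy()
            self.bn.running_mean = s["running_mean"].copy()
            self.bn.running_var = s["running_var"].copy()


class DenoiserModel:
    """Depth-D CNN denoiser whose layers partition into frozen/trainable."""

    def __init__(self, spec: DenoiserSpec, blocks: list[_Block]):
        self.spec = spec
        self.blocks = blocks
        self.trainable_mask = np.zeros(len(blocks), dtype=bool)

    @property
    def depth(self) -> int:
        return len(self.blocks)

    def set_trainable(self, n_train: int) -> None:
        """Mark the last ``n_train`` convolutional layers trainable."""
        if not 0 <= n_train <= self.depth:
            raise InvalidConfigurationError(
                f"n_train must be in [0, {self.depth}]"
            )
        self.trainable_mask[:] = False
        if n_train:
            self.trainable_mask[self.depth - n_train:] = True

    @property
    def first_trainable(self) -> int:
        idx = np.flatnonzero(self.trainable_mask)
        return int(idx[0]) if idx.size else self.depth

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, mode: str = "eval",
                need_grad: bool = False) -> np.ndarray:
        """Run the network on a (B, 1, H, W) batch.

        mode: 'train' (all layers in training mode), 'finetune' (only
        trainable layers in training mode; frozen batch norms use running
        statistics), or 'eval'.
        """
        first = self.first_trainable
        x = np.ascontiguousarray(x.transpose(1, 0, 2, 3))  # -> (C, B, H, W)
        for i, blk in enumerate(self.blocks):
            if mode == "train":
                train = True
                grad = need_grad
            elif mode == "finetune":
                train = bool(self.trainable_mask[i])
                grad = need_grad and i >= first
            else:
                train = False
                grad = False
            x = blk.forward(x, train, grad)
        return x.transpose(1, 0, 2, 3)

    def backward(self, dout: np.ndarray, from_block: int = 0) -> None:
        """Backpropagate, accumulating gradients for blocks >= from_block.

        ``dout`` is the loss gradient at the network output, (B, 1, H, W).
        """
        dout = np.ascontiguousarray(dout.transpose(1, 0, 2, 3))
        for i in range(self.depth - 1, from_block - 1, -1):
            dout = self.blocks[i].backward(dout, need_dx=i > from_block)

    def named_params(self, trainable_only: bool = False):
        for i, blk in enumerate(self.blocks):
            if trainable_only and not self.trainable_mask[i]:
                continue
            yield from blk.named_params(f"block{i}")

    # -- state ---------------------------------------------------------------
    def state(self) -> list[dict]:
        return [blk.state() for blk in self.blocks]

    def load_state(self, state: list[dict]) -> None:
        for blk, s in zip(self.blocks, state):
            blk.load_state(s)

    def copy(self) -> "DenoiserModel":
        return copy.deepcopy(self)


def build_denoiser(spec: DenoiserSpec, rng_seed) -> DenoiserModel:
    """Construct the depth-D network with seeded He initialization."""
    rng = np.random.default_rng(rng_seed)
    F, k, D = spec.filters_per_layer, spec.kernel_side, spec.depth_D
    blocks = [_Block(nn.Conv2d(1, F, k, rng), None, relu=True)]
    for _ in range(D - 3):
        blocks.append(_Block(nn.Conv2d(F, F, k, rng), nn.BatchNorm2d(F), relu=True))
    blocks.append(_Block(nn.Conv2d(F, F, k, rng), nn.BatchNorm2d(F), relu=False))
    blocks.append(_Block(nn.Conv2d(F, 1, k, rng), None, relu=False))
    return DenoiserModel(spec, blocks)


def _as_batch(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=nn.DTYPE)
    if images.ndim == 2:
        images = images[None]
    if images.ndim != 3 or images.shape[1] != images.shape[2]:
        raise InvalidInputError("expected (n, side, side) images")
    if images.shape[1] < 16:
        raise InvalidInputError("image side must be >= 16")
    return images[:, None]


def apply(model: DenoiserModel, images: np.ndarray,
          batch_size: int = 64) -> np.ndarray:
    """Denoise images in inference mode (batch norm uses running stats)."""
    x = _as_batch(images)
    out = np.empty_like(x)
    for a in range(0, x.shape[0], batch_size):
        out[a : a + batch_size] = model.forward(x[a : a + batch_size], "eval")
    return out[:, 0].astype(np.float64)


def mse_loss(output: np.ndarray, target: np.ndarray) -> float:
    """Per-batch mean of the squared L2 distance per image."""
    diff = output - target
    return float((diff ** 2).sum(axis=(1, 2, 3)).mean())


def validation_mse(model: DenoiserModel, val: ImageEnsemble) -> float:
    den = apply(model, val.variant(LOWDOSE))
    diff = den - val.variant(TARGET)
    return float((diff ** 2).sum(axis=(1, 2)).mean())


def pretrain(model: DenoiserModel, train: ImageEnsemble, val: ImageEnsemble,
             settings: TrainSettings = TrainSettings()
             ) -> tuple[DenoiserModel, dict]:
    """MSE-pretrain the denoiser; returns the best-validation weight state.

    Minibatches are balanced 50/50 between signal-present and signal-absent
    pairs. The training history (per-epoch training loss and validation
    MSE, including the initial state) is returned alongside the model.
    """
    for ens in (train, val):
        if LOWDOSE not in ens.images or TARGET not in ens.images:
            raise InvalidInputError("ensemble lacks paired lowdose/target variants")
    model = model.copy()
    rng = np.random.default_rng(settings.seed)
    opt = nn.Adam(lr=settings.learning_rate)
    x_all = _as_batch(train.variant(LOWDOSE))
    y_all = _as_batch(train.variant(TARGET))
    best_val = validation_mse(model, val)
    best_state = model.state()
    history = {"train_loss": [], "val_mse": [best_val]}
    for _ in range(settings.epochs):
        losses = []
        for idx in nn.balanced_batches(train.labels, settings.batch_size, rng):
            x, y = x_all[idx], y_all[idx]
            out = model.forward(x, "train", need_grad=True)
            losses.append(mse_loss(out, y))
            dout = (2.0 / x.shape[0]) * (out - y).astype(nn.DTYPE)
            model.backward(dout, from_block=0)
            opt.step([(k, p, g) for k, p, g in model.named_params()])
        val_mse = validation_mse(model, val)
        history["train_loss"].append(float(np.mean(losses)) if losses else np.nan)
        history["val_mse"].append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_state = model.state()
    model.load_state(best_state)
    history["best_val_mse"] = best_val
    return model, history
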