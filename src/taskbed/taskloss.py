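"""Hybrid-loss transfer learning: appended observers and constrained fine-tuning.

The fine-tuning stage appends a single-layer network observer to the
pretrained denoiser and minimizes the hybrid loss

    L_hybrid(T1, To) = (1 - lambda) * L_p(T1) + lambda * L_t(T1, To),

jointly over the weights ``T1`` of the last ``n_train`` convolutional layers
of the denoiser and the observer weights ``To``; all earlier layers ``T2``
(including their batch-norm running statistics) stay bit-identical. ``L_p``
is the MSE fidelity term; ``L_t`` is one of

* ``slnn-no``         — binary cross-entropy of a sigmoid single-layer
                        observer (general numerical observer);
* ``slnn-ho``         — the quadratic Hotelling-approximating loss whose
                        minimizer over ``To`` is the Hotelling template
                        of the current denoised batch statistics;
* ``slnn-multiclass`` — categorical cross-entropy over J+1 classes for
                        detection-localization tasks.

Loss conventions: the standalone loss functions report the literature sums
(BCE and categorical CE sum over the batch); inside fine-tuning both L_p
and L_t are reduced to per-batch means before mixing, so the meaning of
lambda does not depend on the batch size. Class-conditional means in the
Hotelling loss are computed from the current (balanced) minibatch.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit

from . import nn
from .containers import ImageEnsemble, TARGET, LOWDOSE
from .denoiser import (
    DenoiserModel, TrainSettings, InvalidInputError, _as_batch, mse_loss, apply,
)
from .phantom import InvalidConfigurationError

OBSERVER_KINDS = ("slnn-no", "slnn-ho", "slnn-multiclass")


class InvalidBatchError(ValueError):
    pass


@dataclass(frozen=True)
class HybridConfig:
    lambda_weight: float = 0.9
    n_trainable_layers: int = 3
    task_observer_kind: str = "slnn-no"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise InvalidConfigurationError("lambda_weight must lie in [0, 1]")
        if self.n_trainable_layers < 0:
            raise InvalidConfigurationError("n_trainable_layers must be >= 0")
        if self.task_observer_kind not in OBSERVER_KINDS:
            raise InvalidConfigurationError(
                f"unknown observer kind {self.task_observer_kind!r}"
            )

    def manifest(self) -> dict:
        return asdict(self)


class AppendedObserver:
    """Single fully connected layer appended to the denoiser output.

    * slnn-no:         scalar logit + bias, sigmoid probability output.
    * slnn-ho:         bias-free linear template, unbounded scalar output.
    * slnn-multiclass: (J+1)-way affine map with softmax output.
    """

    def __init__(self, kind: str, n_pixels: int, n_classes: int = 2,
                 rng: np.random.Generator | None = None):
        if kind not in OBSERVER_KINDS:
            raise InvalidConfigurationError(f"unknown observer kind {kind!r}")
        rng = rng or np.random.default_rng()
        self.kind = kind
        self.n_pixels = n_pixels
        self.n_classes = n_classes
        if kind == "slnn-ho":
            # zero template: the quadratic loss starts exactly at zero
            self.w = np.zeros(n_pixels)
            self.b = None
        elif kind == "slnn-no":
            self.w = rng.standard_normal(n_pixels) / np.sqrt(n_pixels)
            self.b = np.zeros(1)
        else:
            self.w = rng.standard_normal((n_classes, n_pixels)) / np.sqrt(n_pixels)
            self.b = np.zeros(n_classes)
        self.grads: dict[str, np.ndarray] = {}

    def named_params(self):
        yield "observer.w", self.w, self.grads.get("w")
        if self.b is not None:
            yield "observer.b", self.b, self.grads.get("b")

    # -- outputs -------------------------------------------------------------
    def logits(self, images: np.ndarray) -> np.ndarray:
        X = np.asarray(images, dtype=np.float64).reshape(len(images), -1)
        if X.shape[1] != self.n_pixels:
            raise InvalidInputError(
                f"observer expects {self.n_pixels} pixels, got {X.shape[1]}"
            )
        if self.kind == "slnn-multiclass":
            return X @ self.w.T + self.b
        z = X @ self.w
        return z + self.b[0] if self.b is not None else z

    def probabilities(self, images: np.ndarray) -> np.ndarray:
        z = self.logits(images)
        if self.kind == "slnn-multiclass":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        if self.kind == "slnn-no":
            return expit(z)
        raise InvalidInputError("slnn-ho has no probabilistic output")

    def detection_statistic(self, images: np.ndarray) -> np.ndarray:
        """Scalar per-image statistic used for ROC analysis."""
        if self.kind == "slnn-multiclass":
            return 1.0 - self.probabilities(images)[:, 0]
        if self.kind == "slnn-no":
            return self.probabilities(images)
        return self.logits(images)

    def localize(self, images: np.ndarray) -> np.ndarray:
        """Most probable signal class (1..J) per image (multiclass only)."""
        if self.kind != "slnn-multiclass":
            raise InvalidInputError("localization requires slnn-multiclass")
        return 1 + np.argmax(self.probabilities(images)[:, 1:], axis=1)


# ---------------------------------------------------------------------------
# loss functions (value + gradients)
# ---------------------------------------------------------------------------

def physical_loss(denoised: np.ndarray, target: np.ndarray) -> float:
    """Per-batch mean of the squared L2 distance per image."""
    denoised = np.asarray(denoised, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if denoised.shape != target.shape:
        raise InvalidInputError("shape mismatch between denoised and target")
    diff = (denoised - target).reshape(len(denoised), -1)
    return float((diff ** 2).sum(axis=1).mean())


def bce_task_loss(observer: AppendedObserver, denoised: np.ndarray,
                  labels: np.ndarray, reduction: str = "sum"):
    """Binary cross-entropy of the sigmoid observer output.

    Returns ``(loss, dL/dimages, dL/dw, dL/db)``; the default reduction is
    the batch sum. Labels must be binary.
    """
    labels = np.asarray(labels)
    if not np.all(np.isin(labels, (0, 1))):
        raise InvalidInputError("bce_task_loss requires binary labels")
    X = np.asarray(denoised, dtype=np.float64).reshape(len(denoised), -1)
    z = observer.logits(denoised)
    y = labels.astype(np.float64)
    # numerically stable log-sigmoid cross-entropy
    loss = float(np.sum(np.logaddexp(0.0, z) - y * z))
    p = expit(z)
    dz = p - y
    scale = 1.0 / len(y) if reduction == "mean" else 1.0
    dX = scale * np.outer(dz, observer.w)
    dw = scale * (X.T @ dz)
    db = scale * np.array([dz.sum()])
    return loss * scale, dX.reshape(np.shape(denoised)), dw, db


def slnn_ho_task_loss(observer: AppendedObserver, denoised: np.ndarray,
                      labels: np.ndarray):
    """Hotelling-approximating quadratic loss on a balanced batch.

    With a batch of J images, the class-conditional means are the 2/J-scaled
    class sums; the loss is

        (1/J) sum_j [ To^T (x_j - mean_{class(j)}) ]^2  -  2 To^T dmean,

    whose minimizer over To is the batch Hotelling template. Returns
    ``(loss, dL/dimages, dL/dw)``.
    """
    labels = np.asarray(labels)
    y = (labels > 0).astype(np.float64)
    B = len(y)
    if y.sum() == 0 or y.sum() == B:
        raise InvalidBatchError("slnn_ho_task_loss needs both classes in the batch")
    X = np.asarray(denoised, dtype=np.float64).reshape(B, -1)
    w = observer.w
    m0 = (2.0 / B) * (X.T @ (1.0 - y))
    m1 = (2.0 / B) * (X.T @ y)
    dmean = m1 - m0
    centered = X - np.where(y[:, None] > 0, m1[None, :], m0[None, :])
    a = centered @ w
    loss = float((a ** 2).mean() - 2.0 * w @ dmean)
    # gradient wrt the template
    dw = (2.0 / B) * (centered.T @ a) - 2.0 * dmean
    # gradient wrt the images: direct term, class-mean coupling, dmean term
    s0 = float(a @ (1.0 - y))
    s1 = float(a @ y)
    sign = np.where(y > 0, -1.0, 1.0)  # d(-2 w^T dmean)/dx_k
    coef = (2.0 / B) * a - (4.0 / B ** 2) * np.where(y > 0, s1, s0) \
        + (4.0 / B) * sign
    dX = np.outer(coef, w)
    return loss, dX.reshape(np.shape(denoised)), dw


def multiclass_task_loss(observer: AppendedObserver, denoised: np.ndarray,
                         labels: np.ndarray, reduction: str = "sum"):
    """Categorical cross-entropy over J+1 classes (0 = signal absent).

    Returns ``(loss, dL/dimages, dL/dW, dL/db)``.
    """
    labels = np.asarray(labels)
    K = observer.n_classes
    if labels.min() < 0 or labels.max() >= K:
        raise InvalidInputError(f"labels must lie in 0..{K - 1}")
    X = np.asarray(denoised, dtype=np.float64).reshape(len(labels), -1)
    Z = observer.logits(denoised)
    Zs = Z - Z.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(Zs).sum(axis=1))
    logp = Zs - logsumexp[:, None]
    loss = float(-logp[np.arange(len(labels)), labels].sum())
    P = np.exp(logp)
    dZ = P.copy()
    dZ[np.arange(len(labels)), labels] -= 1.0
    scale = 1.0 / len(labels) if reduction == "mean" else 1.0
    dX = scale * (dZ @ observer.w)
    dW = scale * (dZ.T @ X)
    db = scale * dZ.sum(axis=0)
    return loss * scale, dX.reshape(np.shape(denoised)), dW, db


def hybrid_loss(config: HybridConfig, lp_value: float, lt_value: float) -> float:
    """(1 - lambda) * L_p + lambda * L_t."""
    lam = config.lambda_weight
    return (1.0 - lam) * lp_value + lam * lt_value


# ---------------------------------------------------------------------------
# fine-tuning (Procedure: joint update of T1 and To)
# ---------------------------------------------------------------------------

def _task_term(observer: AppendedObserver, denoised: np.ndarray,
               labels: np.ndarray):
    """Mean-reduced task loss with gradients; dispatch on observer kind."""
    if observer.kind == "slnn-no":
        lt, dX, dw, db = bce_task_loss(
            observer, denoised, (labels > 0).astype(int), reduction="mean"
        )
        return lt, dX, {"w": dw, "b": db}
    if observer.kind == "slnn-ho":
        lt, dX, dw = slnn_ho_task_loss(observer, denoised, labels)
        return lt, dX, {"w": dw}
    lt, dX, dW, db = multiclass_task_loss(observer, denoised, labels,
                                          reduction="mean")
    return lt, dX, {"w": dW, "b": db}


def _val_hybrid(model: DenoiserModel, observer: AppendedObserver,
                config: HybridConfig, val: ImageEnsemble) -> float:
    den = apply(model, val.variant(LOWDOSE))
    lp = physical_loss(den, val.variant(TARGET))
    lt, _, _ = _task_term(observer, den, val.labels)
    return hybrid_loss(config, lp, lt)


def finetune(model: DenoiserModel, config: HybridConfig,
             train: ImageEnsemble, val: ImageEnsemble,
             settings: TrainSettings = TrainSettings(), rng_seed: int = 0
             ) -> tuple[DenoiserModel, AppendedObserver, dict]:
    """Jointly tune the last ``n_trainable_layers`` and the appended observer.

    Only the trainable denoiser layers and the observer weights are updated;
    every frozen layer — weights and batch-norm running statistics — is
    bit-identical on return. The weight state with the best validation
    hybrid loss is returned. The history logs per-epoch L_p, L_t, and the
    image-gradient norms contributed by each term (after lambda weighting).
    """
    if config.n_trainable_layers > model.depth:
        raise InvalidConfigurationError("n_trainable_layers exceeds network depth")
    for ens in (train, val):
        if LOWDOSE not in ens.images or TARGET not in ens.images:
            raise InvalidInputError("ensemble lacks paired lowdose/target variants")
    model = model.copy()
    model.set_trainable(config.n_trainable_layers)
    rng = np.random.default_rng(rng_seed)
    side = train.side
    n_classes = int(max(train.labels.max(), 1)) + 1
    observer = AppendedObserver(config.task_observer_kind, side * side,
                                n_classes, rng)
    opt = nn.Adam(lr=settings.learning_rate)
    lam = config.lambda_weight
    first = model.first_trainable
    tune_denoiser = config.n_trainable_layers > 0
    x_all = _as_batch(train.variant(LOWDOSE))
    y_all = _as_batch(train.variant(TARGET))
    best_val = _val_hybrid(model, observer, config, val)
    best = (model.state(), observer.w.copy(),
            None if observer.b is None else observer.b.copy())
    history = {"lp": [], "lt": [], "grad_norm_lp": [], "grad_norm_lt": [],
               "val_hybrid": [best_val]}
    for _ in range(settings.epochs):
        ep = {k: [] for k in ("lp", "lt", "gp", "gt")}
        for idx in nn.balanced_batches(train.labels, settings.batch_size, rng):
            x, y, lab = x_all[idx], y_all[idx], train.labels[idx]
            den = model.forward(x, "finetune", need_grad=tune_denoiser)
            den64 = den[:, 0].astype(np.float64)
            B = len(idx)
            lp = mse_loss(den, y)
            d_lp = (2.0 / B) * (den - y)
            lt, d_lt_img, obs_grads = _task_term(observer, den64, lab)
            d_lt = d_lt_img[:, None, :, :]
            ep["lp"].append(lp)
            ep["lt"].append(lt)
            ep["gp"].append(float(np.linalg.norm((1 - lam) * d_lp)))
            ep["gt"].append(float(np.linalg.norm(lam * d_lt)))
            observer.grads = {k: lam * v for k, v in obs_grads.items()}
            named = list(observer.named_params())
            if tune_denoiser:
                dout = ((1 - lam) * d_lp + lam * d_lt).astype(nn.DTYPE)
                model.backward(dout, from_block=first)
                named += list(model.named_params(trainable_only=True))
            opt.step(named)
        val_h = _val_hybrid(model, observer, config, val)
        history["lp"].append(float(np.mean(ep["lp"])) if ep["lp"] else np.nan)
        history["lt"].append(float(np.mean(ep["lt"])) if ep["lt"] else np.nan)
        history["grad_norm_lp"].append(float(np.mean(ep["gp"])) if ep["gp"] else 0.0)
        history["grad_norm_lt"].append(float(np.mean(ep["gt"])) if ep["gt"] else 0.0)
        history["val_hybrid"].append(val_h)
        if val_h < best_val:
            best_val = val_h
            best = (model.state(), observer.w.copy(),
                    None if observer.b is None else observer.b.copy())
    model.load_state(best[0])
    observer.w = best[1]
    if best[2] is not None:
        observer.b = best[2]
    history["best_val_hybrid"] = best_val
    return model, observer, history
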