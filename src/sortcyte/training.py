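"""Calibrated augmentation and native MLP training for sort classifiers.

The classifier must run single-image inference on a CPU inside the sorting
actuation budget, so the models here are small fully-connected nets trained
with plain gradient descent,

    W_n = W_{n-1} - l * dL/dW,

on categorical cross-entropy, with inputs scaled to [0, 1] by /255.  The
forward/backward pass is written directly in numpy: the update rule *is* the
method, and keeping it explicit makes the finite-difference gradient check
meaningful.

Augmentation ranges are calibrated from measured data characteristics
(session brightness 24-49 grayscale, static noise sd ~ 2.9, median cell tilt
~ 11-13 deg), and applied in a fixed order: rotation -> shifts -> vertical
flip -> multiplicative then additive brightness -> Gaussian noise, clipped
to [0, 255].  Geometric identity settings are bit-exact no-ops.

Also here: per-measurement balanced sampling (so no single session
dominates), learning-rate screening with knee detection, and the offline
doublet filter (15 um proximity label rule, p_doublet > 0.3 cut).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .screening import MLPArchitecture
from .synthetic import CropDataset, GroundTruth, make_doublet_dataset, SyntheticConfig

__all__ = [
    "AugmentConfig",
    "CalibrationReport",
    "TrainConfig",
    "MLPModel",
    "estimate_background",
    "median_tilt",
    "augment",
    "balanced_batch",
    "init_mlp",
    "mlp_forward",
    "loss_and_grads",
    "train",
    "TrainResult",
    "lr_screen",
    "LRScreenResult",
    "knee_from_curve",
    "doublet_label",
    "doublet_filter",
    "train_doublet_classifier",
    "DoubletClassifier",
]

DOUBLET_P_THRESHOLD = 0.3


# --------------------------------------------------------------------------
# calibration

def estimate_background(image: np.ndarray, strip_rows: int = 10,
                        ) -> tuple[float, float]:
    """Background brightness mean and noise sd from the top image strip.

    The strip (``strip_rows`` x full width) lies above the measurement
    channel, so it sees only background.
    """
    image = np.asarray(image, dtype=float)
    if strip_rows <= 0 or strip_rows > image.shape[0]:
        raise ValueError("strip must be 1..height rows tall")
    strip = image[:strip_rows, :]
    return float(strip.mean()), float(strip.std())


def median_tilt(contours: Sequence[np.ndarray]) -> tuple[float, int]:
    """Median absolute tilt (deg) over contours; returns (median, n_degenerate).

    Degenerate (circularly symmetric) contours contribute 0 deg and are
    counted separately.
    """
    from .pipeline import contour_moments
    if not len(contours):
        raise ValueError("no contours")
    tilts, n_degen = [], 0
    for c in contours:
        m = contour_moments(c)
        tilts.append(abs(m.phi_deg))
        n_degen += m.degenerate
    return float(np.median(tilts)), n_degen


@dataclass(frozen=True)
class CalibrationReport:
    """Measured data characteristics that set the augmentation ranges."""

    background_mean: float
    background_sd: float
    median_tilt_deg: float
    strip_rows: int = 10


# --------------------------------------------------------------------------
# augmentation

@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation ranges; defaults follow the calibrated values."""

    rotation_deg: float = 10.0          # uniform in +-rotation_deg
    shift_lr: int = 1                   # uniform integer in +-shift_lr px
    shift_ud: int = 1
    brightness_add: float = 12.0        # uniform in +-brightness_add
    brightness_mult: tuple[float, float] = (0.6, 1.3)
    gauss_noise_sd: float = 3.0
    vflip: bool = True

    def __post_init__(self) -> None:
        if self.brightness_mult[0] <= 0:
            raise ValueError("multiplicative range must be positive")
        if self.gauss_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(rotation_deg=0.0, shift_lr=0, shift_ud=0,
                   brightness_add=0.0, brightness_mult=(1.0, 1.0),
                   gauss_noise_sd=0.0, vflip=False)


def _border_median(image: np.ndarray) -> float:
    """Background estimate for pad values: median of the 1-px border."""
    return float(np.median(np.concatenate([
        image[0, :], image[-1, :], image[1:-1, 0], image[1:-1, -1]])))


def augment(image: np.ndarray, config: AugmentConfig,
            rng: np.random.Generator) -> np.ndarray:
    """One random augmentation draw; 8-bit in, 8-bit out.

    Fixed order (geometric, then photometric, then noise): rotation ->
    left-right / up-down shift -> vertical flip -> multiplicative brightness
    -> additive brightness -> Gaussian noise; the result is clipped to
    [0, 255].  Settings at their identity values skip the corresponding
    step, so the all-identity config is a bit-exact no-op.  Rotation and
    shift pad with the image's border median (background proxy).
    """
    img = np.asarray(image, dtype=float)
    pad = _border_median(img)
    if config.rotation_deg:
        angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
        img = ndimage.rotate(img, angle, reshape=False, order=1,
                             mode="constant", cval=pad)
    dc = rng.integers(-config.shift_lr, config.shift_lr + 1) if config.shift_lr else 0
    dr = rng.integers(-config.shift_ud, config.shift_ud + 1) if config.shift_ud else 0
    if dr or dc:
        img = ndimage.shift(img, (dr, dc), order=0, mode="constant", cval=pad)
    if config.vflip and rng.random() < 0.5:
        img = img[::-1, :]
    m_lo, m_hi = config.brightness_mult
    if (m_lo, m_hi) != (1.0, 1.0):
        img = img * rng.uniform(m_lo, m_hi)
    if config.brightness_add:
        img = img + rng.uniform(-config.brightness_add, config.brightness_add)
    if config.gauss_noise_sd:
        img = img + rng.normal(0.0, config.gauss_noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# balanced sampling

def balanced_batch(group_indices: Sequence[np.ndarray], batch_size: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw a batch with equal contribution from each measurement group.

    ``group_indices`` holds the sample indices of each group.  Each group
    contributes batch_size // n_groups draws; the remainder goes to the
    first groups in order (deterministic).  Groups smaller than their quota
    are sampled with replacement.
    """
    n_groups = len(group_indices)
    if n_groups == 0:
        raise ValueError("no groups")
    if any(len(g) == 0 for g in group_indices):
        raise ValueError("empty measurement group")
    base, rem = divmod(batch_size, n_groups)
    chosen = []
    for gi, idx in enumerate(group_indices):
        quota = base + (1 if gi < rem else 0)
        replace_draws = quota > len(idx)
        chosen.append(rng.choice(np.asarray(idx), size=quota,
                                 replace=replace_draws))
    return np.concatenate(chosen)


def _groups_of(dataset: CropDataset) -> list[np.ndarray]:
    return [np.flatnonzero(dataset.groups == g)
            for g in np.unique(dataset.groups)]


# --------------------------------------------------------------------------
# native MLP

@dataclass
class MLPModel:
    """Weights/biases per layer; ReLU hidden activations, softmax output."""

    architecture: MLPArchitecture
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def copy(self) -> "MLPModel":
        return MLPModel(self.architecture,
                        [w.copy() for w in self.weights],
                        [b.copy() for b in self.biases])

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch (or single) image."""
        X = _to_input(images, self.architecture.input_dim)
        return _forward(self, X)[-1]


def init_mlp(arch: MLPArchitecture, rng: np.random.Generator) -> MLPModel:
    """He-normal weight initialisation, zero biases."""
    dims = arch.layer_dims
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, math.sqrt(2.0 / d_in), (d_in, d_out)))
        biases.append(np.zeros(d_out))
    return MLPModel(arch, weights, biases)


def _to_input(images: np.ndarray, input_dim: int) -> np.ndarray:
    X = np.asarray(images, dtype=float)
    single = X.ndim <= 2 and X.size == input_dim
    X = X.reshape(-1, input_dim) if X.size % input_dim == 0 else None
    if X is None:
        raise ValueError("image size does not match model input dimension")
    return X / 255.0 if not single else X.reshape(1, input_dim) / 255.0


def _forward(model: MLPModel, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer; last entry is the softmax output."""
    acts = [X]
    a = X
    n_layers = len(model.weights)
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        if i < n_layers - 1:
            a = np.maximum(z, 0.0)
        else:
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            a = e / e.sum(axis=1, keepdims=True)
        acts.append(a)
    return acts


def mlp_forward(model: MLPModel, image: np.ndarray) -> np.ndarray:
    """Probability vector for one image (values /255 before the first layer)."""
    X = np.asarray(image, dtype=float).reshape(1, -1)
    if X.shape[1] != model.architecture.input_dim:
        raise ValueError(
            f"image has {X.shape[1]} pixels, model expects "
            f"{model.architecture.input_dim}")
    return _forward(model, X / 255.0)[-1][0]


def loss_and_grads(model: MLPModel, images: np.ndarray, labels: np.ndarray,
                   ) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Mean categorical cross-entropy and its gradients (backpropagation).

    ``labels`` are integer class indices.  Gradients are averaged over the
    batch, matching the W <- W - l * dL/dW update.
    """
    X = _to_input(images, model.architecture.input_dim)
    y = np.asarray(labels, dtype=int)
    n = X.shape[0]
    acts = _forward(model, X)
    probs = acts[-1]
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + eps)))
    delta = probs.copy()
    delta[np.arange(n), y] -= 1.0
    delta /= n
    grads_w: list[np.ndarray] = [None] * len(model.weights)  # type: ignore
    grads_b: list[np.ndarray] = [None] * len(model.biases)   # type: ignore
    for i in range(len(model.weights) - 1, -1, -1):
        grads_w[i] = acts[i].T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ model.weights[i].T) * (acts[i] > 0)
    return loss, grads_w, grads_b


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent settings (W_n = W_{n-1} - l * dL/dW).

    ``momentum`` defaults to 0 — the update rule is then exactly plain
    gradient descent.  Classical momentum can be enabled where convergence
    within a fixed iteration budget matters.
    """

    learning_rate: float = 1e-5
    iterations: int = 30_000
    batch_per_measurement: int = 32
    eval_interval: int = 50
    validation_fraction: float = 0.2
    momentum: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if self.iterations <= 0 or self.eval_interval <= 0:
            raise ValueError("iterations and eval_interval must be positive")


@dataclass
class TrainResult:
    model: MLPModel
    loss_trace: np.ndarray        # per-iteration training loss
    val_iterations: np.ndarray    # iterations at which accuracy was evaluated
    val_accuracy: np.ndarray
    diverged: bool = False

    def smoothed_accuracy(self, window: int = 50) -> np.ndarray:
        """Rolling median of the validation-accuracy trace."""
        import pandas as pd
        return (pd.Series(self.val_accuracy)
                .rolling(window, min_periods=1, center=False)
                .median().to_numpy())


def _split_validation(data: CropDataset, fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stratified-by-group fixed validation split, assembled once."""
    val_idx = []
    for idx in _groups_of(data):
        k = max(1, int(round(fraction * len(idx))))
        val_idx.append(rng.choice(idx, size=k, replace=False))
    val = np.concatenate(val_idx)
    train_mask = np.ones(len(data), dtype=bool)
    train_mask[val] = False
    return np.flatnonzero(train_mask), np.sort(val)


def train(model: MLPModel, data: CropDataset, config: TrainConfig,
          augment_config: AugmentConfig | None = None,
          validation: CropDataset | None = None) -> TrainResult:
    """Gradient-descent training with balanced per-measurement batches.

    The validation set is fixed before the first iteration (either supplied
    or split off stratified by measurement group) and the validation
    accuracy is recorded every ``eval_interval`` iterations.  If the loss
    becomes non-finite the run stops and is flagged as diverged.
    """
    rng = np.random.default_rng(config.seed)
    if validation is None:
        train_idx, val_idx = _split_validation(
            data, config.validation_fraction, rng)
        val_images, val_labels = data.images[val_idx], data.labels[val_idx]
        pool = CropDataset(data.images[train_idx], data.labels[train_idx],
                           data.fluorescence[train_idx], data.groups[train_idx])
    else:
        val_images, val_labels = validation.images, validation.labels
        pool = data
    group_idx = _groups_of(pool)
    batch_size = config.batch_per_measurement * len(group_idx)

    losses = np.empty(config.iterations)
    val_iters, val_accs = [], []
    diverged = False
    vel_w = [np.zeros_like(w) for w in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]
    for it in range(config.iterations):
        batch = balanced_batch(group_idx, batch_size, rng)
        imgs = pool.images[batch]
        if augment_config is not None:
            imgs = np.stack([augment(im, augment_config, rng) for im in imgs])
        loss, gw, gb = loss_and_grads(model, imgs, pool.labels[batch])
        losses[it] = loss
        if not math.isfinite(loss):
            diverged = True
            losses = losses[:it + 1]
            break
        if config.learning_rate:
            for i in range(len(model.weights)):
                vel_w[i] = config.momentum * vel_w[i] - config.learning_rate * gw[i]
                vel_b[i] = config.momentum * vel_b[i] - config.learning_rate * gb[i]
                model.weights[i] += vel_w[i]
                model.biases[i] += vel_b[i]
        if (it + 1) % config.eval_interval == 0:
            pred = model.predict_proba(val_images).argmax(axis=1)
            val_iters.append(it + 1)
            val_accs.append(float(np.mean(pred == val_labels)))
    return TrainResult(model, losses, np.asarray(val_iters),
                       np.asarray(val_accs), diverged)


# --------------------------------------------------------------------------
# learning-rate screening

def knee_from_curve(lrs: np.ndarray, losses: np.ndarray,
                    smooth_window: int = 3) -> tuple[float | None, bool]:
    """Locate the learning-rate knee of a (lr, loss) screening curve.

    The knee is the lr minimising the smoothed derivative d(loss)/d(log lr)
    — the point of steepest loss decrease.  Returns (knee_lr, degenerate);
    degenerate is set when the curve is flat or monotone-increasing (no
    negative slope anywhere), in which case knee_lr is None.
    """
    lrs = np.asarray(lrs, dtype=float)
    losses = np.asarray(losses, dtype=float)
    finite = np.isfinite(losses)
    if finite.sum() < 3:
        return None, True
    lg = np.log10(lrs[finite])
    ls = losses[finite]
    slope = np.gradient(ls, lg)
    if smooth_window > 1 and slope.size >= smooth_window:
        import pandas as pd
        slope = (pd.Series(slope).rolling(smooth_window, min_periods=1,
                                          center=True).median().to_numpy())
    if slope.min() >= -1e-12:
        return None, True
    return float(lrs[finite][int(np.argmin(slope))]), False


@dataclass
class LRScreenResult:
    learning_rates: np.ndarray
    losses: np.ndarray
    knee_lr: float | None
    degenerate: bool


def lr_screen(model: MLPModel, data: CropDataset, lr_grid: Sequence[float],
              iters_per_lr: int = 100,
              augment_config: AugmentConfig | None = None,
              base_config: TrainConfig | None = None) -> LRScreenResult:
    """Short training at each learning rate from a fresh copy of the weights.

    ``lr_grid`` must be sorted ascending (log-spaced is customary).  The
    recorded loss per lr is the mean over the final quarter of its
    iterations; the knee is estimated by :func:`knee_from_curve`.
    """
    lr_grid = np.asarray(list(lr_grid), dtype=float)
    if lr_grid.size == 0:
        raise ValueError("empty learning-rate grid")
    if np.any(np.diff(lr_grid) <= 0):
        raise ValueError("lr grid must be sorted strictly ascending")
    base = base_config or TrainConfig()
    losses = np.empty(lr_grid.size)
    for i, lr in enumerate(lr_grid):
        fresh = model.copy()
        cfg = replace(base, learning_rate=float(lr), iterations=iters_per_lr,
                      eval_interval=iters_per_lr)
        res = train(fresh, data, cfg, augment_config)
        tail = res.loss_trace[-max(1, iters_per_lr // 4):]
        losses[i] = float(np.mean(tail)) if np.all(np.isfinite(tail)) else np.inf
    if lr_grid.size == 1:
        return LRScreenResult(lr_grid, losses, float(lr_grid[0]), False)
    knee, degenerate = knee_from_curve(lr_grid, losses)
    return LRScreenResult(lr_grid, losses, knee, degenerate)


# --------------------------------------------------------------------------
# doublet filter

def doublet_label(truth: GroundTruth) -> str:
    """Ground-truth label: doublet iff >1 object or a neighbour < 15 um."""
    return "doublet" if truth.is_doublet else "single"


def doublet_filter(p_doublet: Sequence[float],
                   p_threshold: float = DOUBLET_P_THRESHOLD) -> np.ndarray:
    """Boolean retain mask: keep events with p_doublet <= threshold."""
    p = np.asarray(p_doublet, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p_doublet must lie in [0, 1]")
    return p <= p_threshold


class DoubletClassifier:
    """Pluggable doublet scorer: wraps any model exposing class-1 probability.

    The shipped default is the package's native MLP trained on synthetic
    36 x 36 crops; any object with a ``predict_proba(images) -> (n, 2)``
    method can stand in.
    """

    def __init__(self, model: MLPModel):
        self.model = model

    def p_doublet(self, images: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(images)[:, 1]


def train_doublet_classifier(config: SyntheticConfig, n_per_class: int,
                             rng: np.random.Generator,
                             hidden_widths: tuple[int, ...] = (96, 80),
                             iterations: int = 5000,
                             learning_rate: float = 1.5e-3,
                             momentum: float = 0.9,
                             ) -> tuple[DoubletClassifier, float]:
    """Train the default doublet classifier on synthetic crops.

    Momentum is on by default here: the doublet task needs it to converge
    inside a practical iteration budget with the /255-scaled raw-pixel
    inputs.  Returns the classifier and its held-out accuracy on a fresh
    synthetic validation set.
    """
    data = make_doublet_dataset(config, n_per_class, rng)
    val = make_doublet_dataset(config, max(100, n_per_class // 3), rng)
    arch = MLPArchitecture(hidden_widths, input_dim=36 * 36, output_dim=2)
    model = init_mlp(arch, rng)
    cfg = TrainConfig(learning_rate=learning_rate, iterations=iterations,
                      batch_per_measurement=128, momentum=momentum,
                      eval_interval=max(1, iterations // 10),
                      seed=int(rng.integers(2**31)))
    train(model, data, cfg, validation=val)
    pred = model.predict_proba(val.images).argmax(axis=1)
    return DoubletClassifier(model), float(np.mean(pred == val.labels))
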