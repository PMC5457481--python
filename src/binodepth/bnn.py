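"""The binocular neural network (BNN).

A small convolutional network for near/far depth discrimination from
30x30x2 stereo patches: 28 binocular kernels (19x19x2, valid convolution,
stride 1) -> linear rectification -> 2x2 max pooling -> softmax readout.
The kernels are initialized as identical left/right Gabors (no disparity
selectivity at the start) and all parameters are learned by mini-batch
gradient descent on the cross-entropy loss with early stopping governed by
an iteration-based patience rule.

For the 2-way (near vs far) network the readout is antisymmetric: a single
1,008-element weight vector w drives the far unit with +w and the near unit
with -w (plus separate biases), giving the model its 21,254 learnable
parameters (20,244 convolutional + 1,010 readout).  N-way variants (N > 2)
use a full M x N readout matrix.

Forward/backward passes are plain NumPy (im2col + matrix products); the
analytic gradients are validated against central finite differences in the
test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .gabor import GaborParams2D, make_gabor_2d
from .stimgen import PatchSet, StereoPair

__all__ = [
    "BNNModel",
    "TrainConfig",
    "DepthSignMap",
    "DriveDecomposition",
    "init_bnn",
    "forward",
    "train",
    "evaluate",
    "lesion",
    "optimal_stimulus",
    "ConvBank",
    "depth_sign_map",
    "drive_decomposition",
    "save_model",
    "load_model",
]


@dataclass
class BNNModel:
    """Parameters and hyperstructure of the binocular network."""

    kernels: np.ndarray  # (K, kh, kw, 2)
    conv_bias: np.ndarray  # (K,)
    w_out: np.ndarray  # (M,) tied (n_out == 2) or (M, n_out)
    b_out: np.ndarray  # (n_out,)
    n_out: int = 2
    pool: int = 2
    softmax_temperature: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n_kernels(self) -> int:
        return self.kernels.shape[0]

    @property
    def kernel_shape(self) -> tuple[int, int]:
        return self.kernels.shape[1:3]

    def conv_parameter_count(self) -> int:
        return int(self.kernels.size + self.conv_bias.size)

    def readout_parameter_count(self) -> int:
        return int(self.w_out.size + self.b_out.size)

    def parameter_count(self) -> int:
        return self.conv_parameter_count() + self.readout_parameter_count()

    def readout_matrix(self) -> np.ndarray:
        """Effective (M, n_out) readout weights (expands the tied 2-way
        parameterization: near = -w, far = +w)."""
        if self.n_out == 2 and self.w_out.ndim == 1:
            return np.stack([-self.w_out, self.w_out], axis=1)
        return self.w_out

    def copy(self) -> "BNNModel":
        return BNNModel(
            kernels=self.kernels.copy(),
            conv_bias=self.conv_bias.copy(),
            w_out=self.w_out.copy(),
            b_out=self.b_out.copy(),
            n_out=self.n_out,
            pool=self.pool,
            softmax_temperature=self.softmax_temperature,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults follow the reference procedure)."""

    learning_rate: float = 0.001
    batch_size: int = 100  # class-balanced: batch_size // n_classes each
    max_epochs: int = 1000
    initial_patience: int = 10_000  # mini-batch iterations without improvement
    patience_factor: float = 2.0
    improvement_threshold: float = 0.5  # percentage points of val accuracy
    shuffle: bool = True
    seed: Optional[int] = None


@dataclass
class DepthSignMap:
    """Spatial far-minus-near output activity map; positive = far."""

    values: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class DriveDecomposition:
    """Excitatory / suppressive split of the readout drive per output.

    ``excitatory + suppressive`` equals the pre-bias logit for each
    stimulus and output unit.
    """

    excitatory: np.ndarray  # (B, n_out)
    suppressive: np.ndarray  # (B, n_out)
    logits: np.ndarray  # (B, n_out), including biases


def init_bnn(
    n_outputs: int = 2,
    n_kernels: int = 28,
    kernel_size: int = 19,
    input_size: int = 30,
    frequency: float = 0.1,
    sigma: float = 3.0,
    init_noise: float = 0.0,
    seed: Optional[int] = None,
    dtype=np.float32,
) -> BNNModel:
    """Gabor-initialized binocular network.

    Kernels start as vertically oriented Gabors (f = 0.1 cycles/px,
    sigma = 3 px) with phases equally spaced in [0, pi] and identical left
    and right fields, so the network has no disparity selectivity at
    initialization.  Convolutional biases and all readout parameters start
    at zero.

    With the exact symmetric initialization the near/far classes are
    indistinguishable and gradient descent sits at a saddle that only
    mini-batch noise escapes, which can take very many iterations.
    ``init_noise`` adds a small Gaussian perturbation (s.d. in kernel
    units, seed-controlled) to the initial kernels to break the symmetry
    immediately; 0 keeps the exact symmetric initialization.
    """
    if n_outputs < 2:
        raise ValueError("need at least two output units")
    phases = np.linspace(0.0, np.pi, n_kernels)
    kernels = np.empty((n_kernels, kernel_size, kernel_size, 2), dtype=dtype)
    for k, phi in enumerate(phases):
        g = make_gabor_2d(
            GaborParams2D(
                amplitude=1.0,
                center=0.0,
                sigma=sigma,
                frequency=frequency,
                phase=phi,
                orientation=np.pi / 2,
            ),
            (kernel_size, kernel_size),
        )
        kernels[k, :, :, 0] = g
        kernels[k, :, :, 1] = g
    if init_noise > 0:
        rng = np.random.default_rng(seed)
        kernels += rng.normal(0.0, init_noise, kernels.shape).astype(dtype)
    out_side = (input_size - kernel_size + 1) // 2
    m = n_kernels * out_side * out_side
    if n_outputs == 2:
        w_out = np.zeros(m, dtype=dtype)
    else:
        w_out = np.zeros((m, n_outputs), dtype=dtype)
    return BNNModel(
        kernels=kernels,
        conv_bias=np.zeros(n_kernels, dtype=dtype),
        w_out=w_out,
        b_out=np.zeros(n_outputs, dtype=dtype),
        n_out=n_outputs,
        meta={"input_size": input_size},
    )


# ---------------------------------------------------------------------------
# forward / backward


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B, H, W, 2) -> (B, oh*ow, kh*kw*2), window order (kh, kw, eye)."""
    v = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (B, oh, ow, 2, kh, kw)
    b, oh, ow = v.shape[:3]
    v = v.transpose(0, 1, 2, 4, 5, 3)  # (B, oh, ow, kh, kw, 2)
    return np.ascontiguousarray(v).reshape(b, oh * ow, kh * kw * 2)


def _stack_pairs(patches) -> np.ndarray:
    """Accepts a PatchSet, an (B,H,W,2) array, or a list of StereoPair."""
    if isinstance(patches, PatchSet):
        return np.stack([patches.left, patches.right], axis=-1)
    if isinstance(patches, StereoPair):
        return np.stack([patches.left, patches.right], axis=-1)[None]
    if isinstance(patches, (list, tuple)) and patches and isinstance(patches[0], StereoPair):
        return np.stack(
            [np.stack([p.left, p.right], axis=-1) for p in patches], axis=0
        )
    x = np.asarray(patches)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[-1] != 2:
        raise ValueError(f"expected stereo patches (B, H, W, 2); got {x.shape}")
    return x


def _forward_cache(model: BNNModel, x: np.ndarray) -> dict:
    b = x.shape[0]
    kh, kw = model.kernel_shape
    k = model.n_kernels
    cols = _im2col(x.astype(model.kernels.dtype, copy=False), kh, kw)
    kf = model.kernels.reshape(k, kh * kw * 2)
    pre = cols @ kf.T + model.conv_bias  # (B, P, K)
    oh = x.shape[1] - kh + 1
    ow = x.shape[2] - kw + 1
    pre_maps = pre.reshape(b, oh, ow, k)
    relu = np.maximum(pre_maps, 0.0)

    p = model.pool
    ph, pw = oh // p, ow // p
    blocks = (
        relu[:, : ph * p, : pw * p, :]
        .reshape(b, ph, p, pw, p, k)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(b, ph, pw, k, p * p)
    )
    pool_idx = np.argmax(blocks, axis=-1)  # first occurrence on ties
    pooled = np.take_along_axis(blocks, pool_idx[..., None], axis=-1)[..., 0]
    a = pooled.transpose(0, 3, 1, 2).reshape(b, k * ph * pw)  # (K, ph, pw) order

    if model.n_out == 2 and model.w_out.ndim == 1:
        z = a @ model.w_out
        logits = np.stack([-z + model.b_out[0], z + model.b_out[1]], axis=1)
    else:
        logits = a @ model.w_out + model.b_out
    t = model.softmax_temperature
    shifted = logits / t - np.max(logits / t, axis=1, keepdims=True)
    e = np.exp(shifted)
    probs = e / e.sum(axis=1, keepdims=True)
    return {
        "x": x,
        "cols": cols,
        "pre_maps": pre_maps,
        "relu": relu,
        "pool_idx": pool_idx,
        "a": a,
        "logits": logits,
        "probs": probs,
        "dims": (b, oh, ow, ph, pw, k),
    }


def forward(model: BNNModel, patches) -> tuple[dict, np.ndarray, np.ndarray]:
    """Run the network on stereo patches.

    Returns (activities, class probabilities, predicted classes), where
    ``activities`` maps layer names to arrays (convolutional maps, rectified
    maps, pooled vector, logits).
    """
    x = _stack_pairs(patches)
    expected = model.meta.get("input_size")
    if expected is not None and (x.shape[1] != expected or x.shape[2] != expected):
        raise ValueError(
            f"expected {expected}x{expected}x2 patches, got {x.shape[1:]} "
            "(use depth_sign_map for larger inputs)"
        )
    cache = _forward_cache(model, x)
    activities = {
        "conv": cache["pre_maps"],
        "rectified": cache["relu"],
        "pooled": cache["a"],
        "logits": cache["logits"],
    }
    return activities, cache["probs"], np.argmax(cache["probs"], axis=1)


def _backward(
    model: BNNModel,
    cache: dict,
    dlogits: np.ndarray,
    need_input_grad: bool = False,
) -> dict:
    b, oh, ow, ph, pw, k = cache["dims"]
    a = cache["a"]
    if model.n_out == 2 and model.w_out.ndim == 1:
        dz = dlogits[:, 1] - dlogits[:, 0]
        dw = a.T @ dz
        da = np.outer(dz, model.w_out)
    else:
        dw = a.T @ dlogits
        da = dlogits @ model.w_out.T
    db = dlogits.sum(axis=0)

    p = model.pool
    d_pooled = da.reshape(b, k, ph, pw).transpose(0, 2, 3, 1)  # (B, ph, pw, K)
    d_blocks = np.zeros((b, ph, pw, k, p * p), dtype=da.dtype)
    np.put_along_axis(d_blocks, cache["pool_idx"][..., None], d_pooled[..., None], axis=-1)
    d_relu = (
        d_blocks.reshape(b, ph, pw, k, p, p)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(b, ph * p, pw * p, k)
    )
    if ph * p != oh or pw * p != ow:
        full = np.zeros((b, oh, ow, k), dtype=da.dtype)
        full[:, : ph * p, : pw * p, :] = d_relu
        d_relu = full
    d_pre = d_relu * (cache["pre_maps"] > 0)
    d_pre_flat = d_pre.reshape(b, oh * ow, k)

    kh, kw = model.kernel_shape
    dkern = np.einsum("bpc,bpk->kc", cache["cols"], d_pre_flat).reshape(
        k, kh, kw, 2
    )
    dbias = d_pre_flat.sum(axis=(0, 1))

    grads = {"kernels": dkern, "conv_bias": dbias, "w_out": dw, "b_out": db}
    if need_input_grad:
        kf = model.kernels.reshape(k, kh * kw * 2)
        dcols = d_pre_flat @ kf  # (B, P, kh*kw*2)
        dcols = dcols.reshape(b, oh, ow, kh, kw, 2)
        dx = np.zeros_like(cache["x"], dtype=float)
        for u in range(kh):
            for v in range(kw):
                dx[:, u : u + oh, v : v + ow, :] += dcols[:, :, :, u, v, :]
        grads["x"] = dx
    return grads


def loss_and_grads(
    model: BNNModel, patches, labels: np.ndarray
) -> tuple[float, dict]:
    """Mean cross-entropy loss and analytic parameter gradients."""
    x = _stack_pairs(patches)
    y = np.asarray(labels, dtype=int)
    cache = _forward_cache(model, x)
    probs = cache["probs"]
    n = len(y)
    eps = np.finfo(probs.dtype).tiny
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + eps)))
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n * model.softmax_temperature
    grads = _backward(model, cache, dlogits)
    return loss, grads


# ---------------------------------------------------------------------------
# training


def _balanced_batches(
    labels: np.ndarray, batch_size: int, n_classes: int, rng: np.random.Generator,
    shuffle: bool,
) -> list[np.ndarray]:
    per_class = batch_size // n_classes
    if per_class * n_classes != batch_size:
        raise ValueError(
            f"batch size {batch_size} cannot be balanced over {n_classes} classes"
        )
    pools = []
    for c in range(n_classes):
        idx = np.flatnonzero(labels == c)
        if len(idx) < per_class:
            raise ValueError(f"class {c} has fewer than {per_class} examples")
        pools.append(rng.permutation(idx) if shuffle else idx)
    n_batches = min(len(p) for p in pools) // per_class
    batches = []
    for i in range(n_batches):
        parts = [p[i * per_class : (i + 1) * per_class] for p in pools]
        batches.append(np.concatenate(parts))
    return batches


def _accuracy(model: BNNModel, x: np.ndarray, y: np.ndarray, chunk: int = 1000) -> float:
    correct = 0
    for i in range(0, len(y), chunk):
        cache = _forward_cache(model, x[i : i + chunk])
        correct += int(np.sum(np.argmax(cache["probs"], axis=1) == y[i : i + chunk]))
    return 100.0 * correct / len(y)


def train(
    model: BNNModel,
    train_set: PatchSet,
    val_set: PatchSet,
    cfg: TrainConfig = TrainConfig(),
):
    """Mini-batch gradient descent with iteration-based patience.

    Each batch is class-balanced. After every epoch the validation accuracy
    is computed; training stops at ``max_epochs`` or once the number of
    mini-batch iterations since the last validation improvement exceeds the
    patience limit, which doubles whenever validation accuracy improves by
    at least ``improvement_threshold`` percentage points.  Returns the
    best-validation model and a history DataFrame.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    x_train = _stack_pairs(train_set).astype(model.kernels.dtype)
    y_train = np.asarray(train_set.labels, dtype=int)
    x_val = _stack_pairs(val_set).astype(model.kernels.dtype)
    y_val = np.asarray(val_set.labels, dtype=int)

    model = model.copy()
    best = model.copy()
    best_acc = -np.inf
    milestone = -np.inf
    patience = cfg.initial_patience
    since_improvement = 0
    iteration = 0
    history = []

    for epoch in range(cfg.max_epochs):
        epoch_loss = 0.0
        batches = _balanced_batches(y_train, cfg.batch_size, model.n_out, rng, cfg.shuffle)
        for idx in batches:
            loss, grads = loss_and_grads(model, x_train[idx], y_train[idx])
            epoch_loss += loss
            model.kernels -= cfg.learning_rate * grads["kernels"].astype(model.kernels.dtype)
            model.conv_bias -= cfg.learning_rate * grads["conv_bias"].astype(model.conv_bias.dtype)
            model.w_out -= cfg.learning_rate * grads["w_out"].astype(model.w_out.dtype)
            model.b_out -= cfg.learning_rate * grads["b_out"].astype(model.b_out.dtype)
            iteration += 1
            since_improvement += 1

        val_acc = _accuracy(model, x_val, y_val)
        if val_acc > best_acc:
            best_acc = val_acc
            best = model.copy()
            since_improvement = 0
        if val_acc >= milestone + cfg.improvement_threshold:
            if np.isfinite(milestone):
                patience = int(patience * cfg.patience_factor)
            milestone = val_acc
        history.append(
            {
                "epoch": epoch,
                "iteration": iteration,
                "train_loss": epoch_loss / max(len(batches), 1),
                "val_accuracy": val_acc,
                "patience": patience,
            }
        )
        if since_improvement >= patience:
            break

    best.meta.update({"val_accuracy": best_acc, "epochs_run": len(history)})
    return best, pd.DataFrame(history)


def evaluate(
    model: BNNModel,
    patches,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    chunk: int = 1000,
) -> tuple[float, tuple[float, float]]:
    """Accuracy (%) with a bootstrap percentile 95% confidence interval."""
    x = _stack_pairs(patches)
    y = np.asarray(labels, dtype=int)
    correct = np.empty(len(y), dtype=bool)
    for i in range(0, len(y), chunk):
        cache = _forward_cache(model, x[i : i + chunk])
        correct[i : i + chunk] = np.argmax(cache["probs"], axis=1) == y[i : i + chunk]
    acc = 100.0 * correct.mean()
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    n = len(y)
    for b in range(n_boot):
        boot[b] = correct[rng.integers(0, n, n)].mean() * 100.0
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return float(acc), ci


def lesion(model: BNNModel, unit_indices: Sequence[int]) -> BNNModel:
    """Remove the named kernels and all their readout weights."""
    idx = np.unique(np.asarray(unit_indices, dtype=int))
    k = model.n_kernels
    if np.any((idx < 0) | (idx >= k)):
        raise IndexError("unit index out of range")
    keep = np.setdiff1d(np.arange(k), idx)
    if len(keep) == 0:
        raise ValueError("cannot lesion every unit")
    m_per = model.w_out.shape[0] // k if model.w_out.ndim >= 1 else 0
    w = model.w_out.reshape(k, m_per, *model.w_out.shape[1:])[keep]
    return BNNModel(
        kernels=model.kernels[keep].copy(),
        conv_bias=model.conv_bias[keep].copy(),
        w_out=w.reshape(-1, *model.w_out.shape[1:]).copy(),
        b_out=model.b_out.copy(),
        n_out=model.n_out,
        pool=model.pool,
        softmax_temperature=model.softmax_temperature,
        meta={**model.meta, "lesioned": idx.tolist()},
    )


def optimal_stimulus(
    model: BNNModel,
    output_unit: int,
    iters: int = 100,
    step: float = 1.0,
    seed: Optional[int] = None,
) -> tuple[list[StereoPair], np.ndarray, np.ndarray]:
    """Gradient-ascent preferred stimulus of an output (complex) unit.

    Starts from uniform random noise and takes ``iters`` gradient steps on
    the unit's pre-softmax activity with respect to the input images.
    Returns (snapshots, objective trace, correlation between consecutive
    iterates); the correlation saturating at 1 indicates a stable image.
    """
    rng = np.random.default_rng(seed)
    size = model.meta.get("input_size", 30)
    x = rng.uniform(-1.0, 1.0, size=(1, size, size, 2))
    onehot = np.zeros((1, model.n_out))
    onehot[0, output_unit] = 1.0

    snapshots = []
    objective = np.empty(iters + 1)
    corr = np.empty(iters)
    prev = x.copy()
    cache = _forward_cache(model, x)
    objective[0] = cache["logits"][0, output_unit]
    for i in range(iters):
        grads = _backward(model, cache, onehot, need_input_grad=True)
        x = x + step * grads["x"]  # ascent on the unit's activity
        cache = _forward_cache(model, x)
        objective[i + 1] = cache["logits"][0, output_unit]
        c = np.corrcoef(prev.ravel(), x.ravel())[0, 1]
        corr[i] = c
        prev = x.copy()
        if i in (0, iters // 2, iters - 1):
            snapshots.append(StereoPair(x[0, :, :, 0].copy(), x[0, :, :, 1].copy()))
    return snapshots, objective, corr


class ConvBank:
    """Precomputed FFT kernels for applying a model's convolutional layer
    to large inputs of a fixed size (used by :func:`depth_sign_map`)."""

    def __init__(self, model: BNNModel, input_shape: tuple[int, int]):
        from scipy.fft import next_fast_len

        kh, kw = model.kernel_shape
        h, w = input_shape
        if h < kh or w < kw:
            raise ValueError("input smaller than the convolutional kernel")
        self.shape = (h, w)
        self.full = (next_fast_len(h + kh - 1), next_fast_len(w + kw - 1))
        self.crop = (slice(kh - 1, h), slice(kw - 1, w))
        kern = np.asarray(model.kernels, dtype=np.float32)[:, ::-1, ::-1, :]
        import scipy.fft as sfft

        self.f_left = sfft.rfft2(kern[..., 0], s=self.full)
        self.f_right = sfft.rfft2(kern[..., 1], s=self.full)
        self.bias = np.asarray(model.conv_bias, dtype=np.float32)

    def rectified_maps(self, left: np.ndarray, right: np.ndarray) -> np.ndarray:
        """ReLU conv maps, shape (oh, ow, K), valid convolution."""
        import scipy.fft as sfft

        fl = sfft.rfft2(left.astype(np.float32), s=self.full)
        fr = sfft.rfft2(right.astype(np.float32), s=self.full)
        maps = sfft.irfft2(fl[None] * self.f_left + fr[None] * self.f_right, s=self.full)
        maps = maps[(slice(None),) + self.crop]
        return np.maximum(np.moveaxis(maps, 0, -1) + self.bias, 0.0)


def depth_sign_map(
    model: BNNModel, pair: StereoPair, bank: Optional[ConvBank] = None
) -> DepthSignMap:
    """Convolutional far-minus-near activity map for an arbitrary-size pair.

    The convolutional layer is applied at the input's native size
    (rectified, no pooling) and each kernel map is weighted by the mean of
    that unit's readout weights (the per-map average of the 36
    position-specific weights).  Positive values mean far, negative near.
    Pass a :class:`ConvBank` when mapping many same-size inputs.
    """
    if model.n_out != 2:
        raise ValueError("depth-sign maps are defined for the 2-way model")
    if bank is None:
        bank = ConvBank(model, (pair.shape[0], pair.shape[1]))
    relu = bank.rectified_maps(pair.left, pair.right)

    k = model.n_kernels
    w_eff = model.readout_matrix()  # (M, 2)
    m_per = w_eff.shape[0] // k
    mean_w = w_eff.reshape(k, m_per, 2).mean(axis=1)  # (K, 2)
    far_map = relu @ mean_w[:, 1] + model.b_out[1]
    near_map = relu @ mean_w[:, 0] + model.b_out[0]
    return DepthSignMap(
        values=far_map - near_map,
        meta={"sign_convention": "positive = far", "input_shape": bank.shape},
    )


def drive_decomposition(model: BNNModel, patches) -> DriveDecomposition:
    """Split each output unit's readout drive into excitatory
    (positive-weight) and suppressive (negative-weight) components."""
    x = _stack_pairs(patches)
    cache = _forward_cache(model, x)
    a = cache["a"]
    w = model.readout_matrix()
    exc = a @ np.maximum(w, 0.0)
    sup = a @ np.minimum(w, 0.0)
    return DriveDecomposition(excitatory=exc, suppressive=sup, logits=cache["logits"])


def save_model(path: str, model: BNNModel) -> None:
    meta = {
        "n_out": model.n_out,
        "pool": model.pool,
        "softmax_temperature": model.softmax_temperature,
        "meta": {k: v for k, v in model.meta.items() if isinstance(v, (int, float, str, list))},
    }
    np.savez(
        path,
        kernels=model.kernels,
        conv_bias=model.conv_bias,
        w_out=model.w_out,
        b_out=model.b_out,
        meta=np.array(json.dumps(meta)),
    )


def load_model(path: str) -> BNNModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        return BNNModel(
            kernels=data["kernels"],
            conv_bias=data["conv_bias"],
            w_out=data["w_out"],
            b_out=data["b_out"],
            n_out=int(meta["n_out"]),
            pool=int(meta["pool"]),
            softmax_temperature=float(meta["softmax_temperature"]),
            meta=meta.get("meta", {}),
        )
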