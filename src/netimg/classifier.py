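"""CNN classifier for network images, implemented in NumPy.

Architecture: three valid (unpadded) convolution stages with 64 kernels of
sizes 5x5, 3x3, 3x3, each followed by 2x2 stride-2 max pooling in ceil mode,
then three ReLU hidden layers (1000, 800, 60 units) and a softmax output over
the classes (normal tissue plus one class per tumor type). On a 100x100
single-channel input the spatial sides run 96->48, 46->23, 21->11, so the
flattened feature vector has 11*11*64 = 7744 entries; ceil-mode pooling is
what carries the odd side 21 to 11 rather than 10.

Training uses mini-batch Adam on categorical cross-entropy with a stratified
75/25 train/test split; every stochastic step (weight init, split,
per-epoch shuffling) is driven by one seed, so runs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.model_selection import train_test_split

from netimg.imaging import NetworkImage

logger = logging.getLogger(__name__)

__all__ = [
    "CNNSpec",
    "TrainConfig",
    "Model",
    "build_model",
    "train",
    "predict",
    "shape_chain",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CNNSpec:
    """Architecture hyperparameters with the printed-network defaults."""

    grid_size: int = 100
    conv_kernels: tuple[tuple[int, int, int], ...] = ((64, 5, 5), (64, 3, 3), (64, 3, 3))
    pool: int = 2
    pool_mode: str = "ceil"  # "floor" breaks the 11x11 contract on G=100
    hidden: tuple[int, ...] = (1000, 800, 60)
    n_classes: int = 12


@dataclass
class TrainConfig:
    """Optimisation settings; the seed drives init, split and shuffling."""

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    test_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def shape_chain(spec: CNNSpec) -> list[tuple[int, int]]:
    """Per-stage (post-conv side, post-pool side) for a square input.

    Valid convolution maps side s to s - k + 1; 2x2 stride-2 pooling maps
    s' to ceil(s'/2) (ceil mode) or floor(s'/2) (floor mode). Raises when a
    stage would produce a non-positive side, naming the stage.
    """
    side = spec.grid_size
    chain = []
    for stage, (_, kh, kw) in enumerate(spec.conv_kernels, start=1):
        if kh != kw:
            raise ValueError("square kernels only")
        conv_side = side - kh + 1
        if conv_side < 1:
            raise ValueError(
                f"convolution stage {stage}: side {side} too small for {kh}x{kw} kernel"
            )
        if spec.pool_mode == "ceil":
            pool_side = -(-conv_side // spec.pool)
        elif spec.pool_mode == "floor":
            pool_side = conv_side // spec.pool
        else:
            raise ValueError(f"unknown pool_mode {spec.pool_mode!r}")
        if pool_side < 1:
            raise ValueError(f"pooling stage {stage}: side {conv_side} pools to nothing")
        chain.append((conv_side, pool_side))
        side = pool_side
    return chain


# ---------------------------------------------------------------------------
# layers


class _Conv:
    """Valid 2D convolution (stride 1) via im2col."""

    def __init__(self, in_ch: int, out_ch: int, k: int):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.W = np.zeros((out_ch, in_ch * k * k))
        self.b = np.zeros(out_ch)

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.in_ch * self.k * self.k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), self.W.shape)
        self.b = np.zeros(self.out_ch)

    def params(self):
        return [("W", self), ("b", self)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # (n,c,h',w',k,k)
        hp, wp = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, hp * wp, c * k * k)
        out = cols @ self.W.T + self.b  # (n, h'*w', out_ch)
        if train:
            self._cols, self._xshape = cols, x.shape
        return out.transpose(0, 2, 1).reshape(n, self.out_ch, hp, wp)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, oc, hp, wp = grad.shape
        g = grad.reshape(n, oc, hp * wp).transpose(0, 2, 1)  # (n, pos, oc)
        self.dW = np.einsum("npo,npf->of", g, self._cols)
        self.db = g.sum(axis=(0, 1))
        dcols = g @ self.W  # (n, pos, c*k*k)
        _, c, h, w = self._xshape
        k = self.k
        dcols = dcols.reshape(n, hp, wp, c, k, k)
        dx = np.zeros(self._xshape)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + hp, j : j + wp] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        del self._cols
        return dx


class _MaxPool:
    """2x2 stride-2 max pooling; ceil mode pads odd sides with -inf."""

    def __init__(self, size: int = 2, mode: str = "ceil"):
        self.size, self.mode = size, mode

    def init(self, rng):
        pass

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.size
        if self.mode == "ceil":
            ph, pw = -(-h // s) * s, -(-w // s) * s
            if (ph, pw) != (h, w):
                pad = np.full((n, c, ph, pw), -np.inf)
                pad[:, :, :h, :w] = x
                x = pad
        else:
            ph, pw = (h // s) * s, (w // s) * s
            x = x[:, :, :ph, :pw]
        win = x.reshape(n, c, ph // s, s, pw // s, s).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(n, c, ph // s, pw // s, s * s)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._in_shape, self._padded = idx, (n, c, h, w), (ph, pw)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        ph, pw = self._padded
        s = self.size
        dflat = np.zeros((n, c, ph // s, pw // s, s * s))
        np.put_along_axis(dflat, self._idx[..., None], grad[..., None], axis=-1)
        dx = (
            dflat.reshape(n, c, ph // s, pw // s, s, s)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, ph, pw)
        )
        return dx[:, :, :h, :w]


class _ReLU:
    def init(self, rng):
        pass

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class _Flatten:
    def init(self, rng):
        pass

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int):
        self.n_in, self.n_out = n_in, n_out
        self.W = np.zeros((n_in, n_out))
        self.b = np.zeros(n_out)

    def init(self, rng: np.random.Generator) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / self.n_in), (self.n_in, self.n_out))
        self.b = np.zeros(self.n_out)

    def params(self):
        return [("W", self), ("b", self)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


# ---------------------------------------------------------------------------
# model


class Model:
    """A built (and, after :func:`train`, fitted) CNN."""

    def __init__(self, spec: CNNSpec):
        self.spec = spec
        self.chain = shape_chain(spec)
        layers: list = []
        in_ch = 1
        for (out_ch, k, _), _sides in zip(spec.conv_kernels, self.chain):
            layers += [_Conv(in_ch, out_ch, k), _ReLU(), _MaxPool(spec.pool, spec.pool_mode)]
            in_ch = out_ch
        layers.append(_Flatten())
        flat = self.chain[-1][1] ** 2 * spec.conv_kernels[-1][0]
        self.flat_size = flat
        n_in = flat
        for h in spec.hidden:
            layers += [_Dense(n_in, h), _ReLU()]
            n_in = h
        layers.append(_Dense(n_in, spec.n_classes))
        self.layers = layers
        self.classes: list[str] | None = None
        self.initialized = False

    @property
    def parameter_count(self) -> int:
        total = 0
        for layer in self.layers:
            for name, owner in layer.params():
                total += getattr(owner, name).size
        return total

    def initialize(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.init(rng)
        self.initialized = True

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)


def build_model(spec: CNNSpec) -> Model:
    """Construct the CNN and log its shape chain and parameter count."""
    model = Model(spec)
    logger.info(
        "CNN G=%d: stages %s, flattened %d, %d parameters",
        spec.grid_size, model.chain, model.flat_size, model.parameter_count,
    )
    return model


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, model: Model, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.slots = []
        for layer in model.layers:
            for name, owner in layer.params():
                p = getattr(owner, name)
                self.slots.append((owner, name, np.zeros_like(p), np.zeros_like(p)))

    def step(self) -> None:
        self.t += 1
        for owner, name, m, v in self.slots:
            g = getattr(owner, "d" + name)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            getattr(owner, name)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _stack(images: Sequence[NetworkImage], grid_size: int) -> np.ndarray:
    x = np.stack([img.pixels for img in images])
    if x.shape[1] != grid_size:
        raise ValueError(
            f"image side {x.shape[1]} does not match model grid size {grid_size}"
        )
    return x[:, None, :, :]


def train(
    model: Model,
    images: Sequence[NetworkImage],
    config: TrainConfig,
) -> tuple[Model, dict[str, list[float]]]:
    """Fit the CNN on labeled network images.

    The labeled images are split 75/25 (stratified by class) into the
    training and testing subsets whose per-epoch accuracies form the
    returned curves. Loss is categorical cross-entropy; optimiser is Adam.
    Returns the fitted model and ``{"train_accuracy": [...],
    "test_accuracy": [...], "loss": [...]}`` of length ``config.epochs``.
    """
    labels = [img.label for img in images]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    if len(classes) > model.spec.n_classes:
        raise ValueError(
            f"{len(classes)} classes present but model has {model.spec.n_classes} outputs"
        )
    model.classes = classes
    class_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_idx[l] for l in labels])
    x = _stack(images, model.spec.grid_size)

    rng = np.random.default_rng(config.seed)
    model.initialize(rng)
    idx_train, idx_test = train_test_split(
        np.arange(len(y)),
        test_size=config.test_fraction,
        stratify=y,
        random_state=config.seed % (2**32),
    )
    x_tr, y_tr = x[idx_train], y[idx_train]
    x_te, y_te = x[idx_test], y[idx_test]

    opt = _Adam(model, config.learning_rate)
    curves: dict[str, list[float]] = {"train_accuracy": [], "test_accuracy": [], "loss": []}
    n = len(y_tr)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = x_tr[batch], y_tr[batch]
            logits = model.logits(xb, train=True)
            probs = _softmax(logits)
            eps = 1e-12
            losses.append(float(-np.log(probs[np.arange(len(yb)), yb] + eps).mean()))
            grad = probs
            grad[np.arange(len(yb)), yb] -= 1.0
            grad /= len(yb)
            model.backward(grad)
            opt.step()
        curves["loss"].append(float(np.mean(losses)))
        curves["train_accuracy"].append(_eval_accuracy(model, x_tr, y_tr))
        curves["test_accuracy"].append(_eval_accuracy(model, x_te, y_te))
    logger.info(
        "trained %d epochs: final train acc %.3f, test acc %.3f",
        config.epochs, curves["train_accuracy"][-1], curves["test_accuracy"][-1],
    )
    return model, curves


def _eval_accuracy(model: Model, x: np.ndarray, y: np.ndarray, batch: int = 64) -> float:
    correct = 0
    for start in range(0, len(y), batch):
        logits = model.logits(x[start : start + batch], train=False)
        correct += int((logits.argmax(axis=1) == y[start : start + batch]).sum())
    return correct / len(y)


def predict(
    model: Model,
    images: Sequence[NetworkImage],
    batch_size: int = 64,
) -> tuple[np.ndarray, list[str]]:
    """Class probabilities and argmax labels for a batch of images.

    Probability rows sum to 1 (softmax); ties on the argmax resolve to the
    lowest class index. Requires a trained model.
    """
    if not model.initialized or model.classes is None:
        raise ValueError("model is not trained")
    x = _stack(images, model.spec.grid_size)
    probs = np.vstack(
        [
            _softmax(model.logits(x[s : s + batch_size], train=False))
            for s in range(0, len(x), batch_size)
        ]
    )
    # output units beyond the trained class vocabulary never receive labels
    hard = probs[:, : len(model.classes)].argmax(axis=1)
    labels = [model.classes[i] for i in hard]
    return probs, labels


def save_model(model: Model, path) -> None:
    """Persist a trained model (architecture, class vocabulary, weights)."""
    if not model.initialized:
        raise ValueError("refusing to save an uninitialized model")
    arrays = {}
    for li, layer in enumerate(model.layers):
        for name, owner in layer.params():
            arrays[f"layer{li}_{name}"] = getattr(owner, name)
    spec = model.spec
    np.savez(
        path,
        grid_size=spec.grid_size,
        conv_kernels=np.array(spec.conv_kernels),
        pool=spec.pool,
        pool_mode=spec.pool_mode,
        hidden=np.array(spec.hidden),
        n_classes=spec.n_classes,
        classes=np.array(model.classes if model.classes else [], dtype=object),
        **arrays,
    )


def load_model(path) -> Model:
    with np.load(path, allow_pickle=True) as data:
        spec = CNNSpec(
            grid_size=int(data["grid_size"]),
            conv_kernels=tuple(tuple(int(v) for v in row) for row in data["conv_kernels"]),
            pool=int(data["pool"]),
            pool_mode=str(data["pool_mode"]),
            hidden=tuple(int(v) for v in data["hidden"]),
            n_classes=int(data["n_classes"]),
        )
        model = Model(spec)
        for li, layer in enumerate(model.layers):
            for name, owner in layer.params():
                getattr(owner, name)[...] = data[f"layer{li}_{name}"]
        classes = [str(c) for c in data["classes"]]
        model.classes = classes or None
        model.initialized = True
    return model
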