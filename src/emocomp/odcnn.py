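"""From-scratch one-dimensional convolutional neural network.

The classifier treats each 13-feature observation as a 1D signal and
passes it through ``depth`` convolutional groups (1D cross-correlation →
ELU → average pooling by an integer factor ``tt``), followed by fully
connected layers down to four output scores, one per emotion class.
Training minimizes the per-sample sum-of-squares error against one-hot
targets by plain mini-batch stochastic gradient descent with learning
factor ``ε`` — no momentum, no adaptive optimizers, no regularizers.

Backpropagation is derived by hand and implemented directly:

* the delta error entering a convolutional group is the full (zero
  padded) convolution of the next layer's deltas with the reversed
  kernels — the adjoint of the forward cross-correlation;
* average pooling backpropagates by zero-order upsampling (each pooled
  delta repeated ``tt`` times, scaled by ``1/tt``) times the activation
  derivative f′(y);
* the weight sensitivity is the valid cross-correlation of the layer
  input with the delta, and the bias sensitivity the sum of deltas.

Every gradient path is validated against central finite differences in
the test-suite.

Note on the 13-length input: a depth-5 stack of valid convolutions with
kernel 7 is geometrically impossible on 13 samples, so convolutional
groups default to `same` zero padding (`valid` remains available and is
shape-checked at construction).  Pooling defaults to ``tt=1`` for the
same reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

N_CLASSES = 4
INPUT_LEN = 13


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def conv1d_valid(signal: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Valid (no padding) 1D cross-correlation.

    ``out[i] = Σ_k signal[i + k] · kernel[k]`` with output length
    ``len(signal) − len(kernel) + 1``.
    """
    signal = np.asarray(signal, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if len(kernel) > len(signal):
        raise ValueError("kernel longer than signal")
    return np.correlate(signal, kernel, mode="valid")


def conv1d_padded(signal: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Full (zero-padded) 1D cross-correlation, length ``n + k − 1``.

    Equivalent to the ordinary full convolution of ``signal`` with the
    reversed kernel; this is the adjoint of :func:`conv1d_valid` and is
    the operation used to backpropagate delta errors through a
    convolutional connection.
    """
    signal = np.asarray(signal, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if signal.size == 0 or kernel.size == 0:
        raise ValueError("empty input")
    return np.convolve(signal, kernel[::-1], mode="full")


def elu(x):
    """Exponential linear unit: x for x ≥ 0, eˣ − 1 otherwise."""
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, x, np.expm1(np.minimum(x, 0.0)))


def elu_prime(x):
    """Derivative of :func:`elu`: 1 for x ≥ 0, eˣ otherwise."""
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, 1.0, np.exp(np.minimum(x, 0.0)))


def downsample(z: np.ndarray, tt: int) -> np.ndarray:
    """Average-pool over consecutive non-overlapping windows of length ``tt``.

    A trailing remainder shorter than ``tt`` is dropped.
    """
    if tt <= 0:
        raise ValueError("pool factor must be >= 1")
    z = np.asarray(z, dtype=float)
    if tt == 1:
        return z.copy()
    m = len(z) // tt
    return z[: m * tt].reshape(m, tt).mean(axis=1)


def upsample_zero_order(d: np.ndarray, tt: int) -> np.ndarray:
    """Adjoint of :func:`downsample`: repeat each entry ``tt`` times, scaled 1/tt."""
    if tt <= 0:
        raise ValueError("pool factor must be >= 1")
    d = np.asarray(d, dtype=float)
    if tt == 1:
        return d.copy()
    return np.repeat(d, tt) / tt


def mse_loss(output: np.ndarray, target: np.ndarray) -> float:
    """Sum of squared errors F_q = Σ_j (z_j − u_j)² for one sample."""
    output = np.asarray(output, dtype=float)
    target = np.asarray(target, dtype=float)
    if output.shape != target.shape:
        raise ValueError("output/target length mismatch")
    return float(np.sum((output - target) ** 2))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class ODCNNConfig:
    """Hyperparameters of the network and its training loop."""

    depth: int = 5
    kernel_size: int = 7
    learning_rate: float = 0.0005
    activation: str = "elu"
    pool_factor: int = 1
    filters_per_layer: int = 16
    mlp_hidden: tuple[int, ...] = (32,)
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    padding_mode: str = "same"
    input_len: int = INPUT_LEN
    n_classes: int = N_CLASSES
    plateau_rel_tol: float = 1e-6
    plateau_window: int = 20

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.pool_factor < 1:
            raise ValueError("pool_factor must be >= 1")
        if self.activation != "elu":
            raise ValueError("only the ELU activation is supported")
        if self.padding_mode not in ("same", "valid"):
            raise ValueError("padding_mode must be 'same' or 'valid'")

    def layer_lengths(self) -> list[int]:
        """Signal length entering each conv group plus the final length.

        Raises if any length would shrink to zero (the shrinking-network
        guard: depth/kernel/pooling must stay geometrically feasible).
        """
        lengths = [self.input_len]
        L = self.input_len
        for d in range(self.depth):
            if self.padding_mode == "valid":
                L = L - self.kernel_size + 1
            if L < 1:
                raise ValueError(
                    f"conv group {d} reduces signal length to {L}; "
                    "use 'same' padding or a shallower/narrower network")
            if L >= 2 * self.pool_factor:
                L = L // self.pool_factor
            lengths.append(L)
        return lengths


@dataclass
class _ConvGroup:
    """One convolutional group: same/valid conv → ELU → average pool."""

    weights: np.ndarray      # (C_out, C_in, K)
    bias: np.ndarray         # (C_out,)
    padding_mode: str
    pool_factor: int         # effective tt for this group (1 = disabled)

    @property
    def kernel_size(self) -> int:
        return self.weights.shape[2]


@dataclass
class _Dense:
    weights: np.ndarray      # (n_out, n_in)
    bias: np.ndarray         # (n_out,)
    activation: str          # "elu" or "linear"


class ODCNNModel:
    """Weights and topology; built from an :class:`ODCNNConfig`."""

    def __init__(self, config: ODCNNConfig):
        self.config = config
        lengths = config.layer_lengths()
        rng = np.random.default_rng(config.seed)
        self.conv_groups: list[_ConvGroup] = []
        c_in = 1
        L = config.input_len
        for d in range(config.depth):
            c_out = config.filters_per_layer
            K = config.kernel_size
            limit = np.sqrt(6.0 / (c_in * K + c_out * K))
            W = rng.uniform(-limit, limit, size=(c_out, c_in, K))
            b = np.zeros(c_out)
            if config.padding_mode == "valid":
                L = L - K + 1
            tt = config.pool_factor if L >= 2 * config.pool_factor else 1
            self.conv_groups.append(_ConvGroup(W, b, config.padding_mode, tt))
            L = L // tt
            c_in = c_out
        assert L == lengths[-1]
        self.flat_dim = L * c_in
        self.dense_layers: list[_Dense] = []
        widths = [self.flat_dim, *config.mlp_hidden, config.n_classes]
        for i in range(len(widths) - 1):
            n_in, n_out = widths[i], widths[i + 1]
            limit = np.sqrt(6.0 / (n_in + n_out))
            W = rng.uniform(-limit, limit, size=(n_out, n_in))
            act = "elu" if i < len(widths) - 2 else "linear"
            self.dense_layers.append(_Dense(W, np.zeros(n_out), act))

    # -- parameter flattening (used by SGD and the finite-difference tests) --

    def parameters(self) -> list[np.ndarray]:
        out = []
        for g in self.conv_groups:
            out += [g.weights, g.bias]
        for d in self.dense_layers:
            out += [d.weights, d.bias]
        return out

    # -- forward ------------------------------------------------------------

    def forward(self, X: np.ndarray, need_cache: bool = True) -> tuple[np.ndarray, dict]:
        """Propagate a batch of feature rows; return (scores, cache).

        ``X`` is (B, input_len); scores are (B, n_classes).  The cache
        holds every intermediate state needed by :meth:`backward`; pass
        ``need_cache=False`` for inference only.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.input_len:
            raise ValueError(
                f"expected {self.config.input_len} features, got {X.shape[1]}")
        cache: dict = {"conv": [], "dense": []}
        t = X[:, :, None]                       # (B, L, C=1)
        B_ = t.shape[0]
        for g in self.conv_groups:
            K = g.kernel_size
            L_in = t.shape[1]
            if g.padding_mode == "same":
                p = K // 2
                tp = np.zeros((B_, L_in + 2 * p, t.shape[2]))
                tp[:, p : p + L_in] = t
            else:
                tp = t
            P = np.lib.stride_tricks.sliding_window_view(tp, K, axis=1)
            # P: (B, L_out, C_in, K) -> (B, L_out, C_in*K)
            L_out = P.shape[1]
            P = P.reshape(B_, L_out, -1)
            Wm = g.weights.reshape(g.weights.shape[0], -1)
            y = P @ Wm.T
            y += g.bias                         # (B, L_out, C_out)
            neg = y < 0
            z = y.copy()
            z[neg] = np.expm1(y[neg])
            if g.pool_factor > 1:
                m = L_out // g.pool_factor
                tnext = z[:, : m * g.pool_factor].reshape(
                    B_, m, g.pool_factor, -1).mean(axis=2)
            else:
                tnext = z
            if need_cache:
                cache["conv"].append({"P": P, "y": y, "L_in": L_in, "z_len": L_out})
            t = tnext
        a = t.reshape(B_, -1)
        for d in self.dense_layers:
            y = a @ d.weights.T + d.bias
            if d.activation == "linear":
                z = y
            else:
                neg = y < 0
                z = y.copy()
                z[neg] = np.expm1(y[neg])
            if need_cache:
                cache["dense"].append({"a": a, "y": y})
            a = z
        cache["flat_shape"] = t.shape
        return a, cache

    # -- backward -----------------------------------------------------------

    def backward(self, cache: dict, scores: np.ndarray, targets: np.ndarray) -> list[np.ndarray]:
        """Gradients of the summed per-sample squared error over the batch.

        Returns arrays aligned with :meth:`parameters`.
        """
        if not cache.get("dense"):
            raise RuntimeError("forward cache missing or stale")
        grads_dense: list[tuple[np.ndarray, np.ndarray]] = []
        delta = 2.0 * (scores - targets)        # dF/dz at the output
        for d, c in zip(reversed(self.dense_layers), reversed(cache["dense"])):
            if d.activation != "linear":
                delta = delta * np.where(c["y"] >= 0, 1.0, np.exp(np.minimum(c["y"], 0.0)))
            gW = delta.T @ c["a"]
            gb = delta.sum(axis=0)
            grads_dense.append((gW, gb))
            delta = delta @ d.weights           # dF/da of the previous layer
        grads_dense.reverse()

        dT = delta.reshape(cache["flat_shape"])  # (B, L, C) gradient w.r.t. last pooled map
        grads_conv: list[tuple[np.ndarray, np.ndarray]] = []
        for g, c in zip(reversed(self.conv_groups), reversed(cache["conv"])):
            B_, L_z = dT.shape[0], c["z_len"]
            if g.pool_factor > 1:
                dZ = np.zeros((B_, L_z, dT.shape[2]))
                m = dT.shape[1]
                rep = np.repeat(dT, g.pool_factor, axis=1) / g.pool_factor
                dZ[:, : m * g.pool_factor] = rep
            else:
                dZ = dT
            y = c["y"]
            dY = dZ * np.where(y >= 0, 1.0, np.exp(np.minimum(y, 0.0)))
            P = c["P"]                           # (B, L_out, C_in*K)
            Wm = g.weights.reshape(g.weights.shape[0], -1)
            gW = np.einsum("blo,blm->om", dY, P).reshape(g.weights.shape)
            gb = dY.sum(axis=(0, 1))
            dP = dY @ Wm                         # (B, L_out, C_in*K)
            K = g.kernel_size
            C_in = g.weights.shape[1]
            L_out = dY.shape[1]
            dP = dP.reshape(B_, L_out, C_in, K)
            if g.padding_mode == "same":
                p = K // 2
                L_pad = c["L_in"] + 2 * p
            else:
                p = 0
                L_pad = c["L_in"]
            dTp = np.zeros((B_, L_pad, C_in))
            for k in range(K):
                dTp[:, k : k + L_out] += dP[:, :, :, k]
            dT = dTp[:, p : p + c["L_in"]] if p else dTp
            grads_conv.append((gW, gb))
        grads_conv.reverse()

        out: list[np.ndarray] = []
        for gW, gb in grads_conv:
            out += [gW, gb]
        for gW, gb in grads_dense:
            out += [gW, gb]
        return out

    def sgd_update(self, grads: list[np.ndarray], lr: float) -> None:
        """In-place step w ← w − ε·∂F/∂w (and likewise for biases)."""
        params = self.parameters()
        if len(params) != len(grads):
            raise ValueError("gradient structure does not match parameters")
        for p, gr in zip(params, grads):
            if not np.all(np.isfinite(gr)):
                raise TrainingDivergedError(-1)
            p -= lr * gr

    # -- prediction & serialization -----------------------------------------

    def predict(self, X: np.ndarray, chunk: int = 1024) -> tuple[np.ndarray, np.ndarray]:
        """Return (argmax labels, raw class scores); ties go to the lowest index."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        parts = [self.forward(X[i : i + chunk], need_cache=False)[0]
                 for i in range(0, len(X), chunk)]
        scores = np.vstack(parts)
        return scores.argmax(axis=1), scores

    def to_json(self) -> str:
        payload = {
            "format": "emocomp-odcnn",
            "version": 1,
            "config": {**self.config.__dict__, "mlp_hidden": list(self.config.mlp_hidden)},
            "conv": [
                {"weights": g.weights.tolist(), "bias": g.bias.tolist(),
                 "padding_mode": g.padding_mode, "pool_factor": g.pool_factor}
                for g in self.conv_groups
            ],
            "dense": [
                {"weights": d.weights.tolist(), "bias": d.bias.tolist(),
                 "activation": d.activation}
                for d in self.dense_layers
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ODCNNModel":
        payload = json.loads(text)
        if payload.get("format") != "emocomp-odcnn":
            raise ValueError("not an ODCNN model container")
        cfg_dict = dict(payload["config"])
        cfg_dict["mlp_hidden"] = tuple(cfg_dict["mlp_hidden"])
        model = cls(ODCNNConfig(**cfg_dict))
        for g, entry in zip(model.conv_groups, payload["conv"]):
            g.weights = np.array(entry["weights"], dtype=float)
            g.bias = np.array(entry["bias"], dtype=float)
        for d, entry in zip(model.dense_layers, payload["dense"]):
            d.weights = np.array(entry["weights"], dtype=float)
            d.bias = np.array(entry["bias"], dtype=float)
        return model

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ODCNNModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# module-level functional API
# ---------------------------------------------------------------------------

def forward(model: ODCNNModel, features: np.ndarray) -> tuple[np.ndarray, dict]:
    return model.forward(features)


def backward(model: ODCNNModel, cache: dict, scores: np.ndarray,
             targets: np.ndarray) -> list[np.ndarray]:
    return model.backward(cache, scores, targets)


def sgd_update(model: ODCNNModel, grads: list[np.ndarray], lr: float) -> ODCNNModel:
    model.sgd_update(grads, lr)
    return model


def predict(model: ODCNNModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return model.predict(features)


@dataclass
class TrainingReport:
    """Evaluation summary of one training or cross-validation run."""

    accuracy: float
    confusion: np.ndarray            # (4, 4) counts, rows = truth
    misclassified: int
    per_class_auc: np.ndarray | None = None
    macro_auc: float | None = None
    loss_curve: list[float] = field(default_factory=list)
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "misclassified": self.misclassified,
            "per_class_auc": None if self.per_class_auc is None else self.per_class_auc.tolist(),
            "macro_auc": self.macro_auc,
            "n": self.n,
        }


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    U = np.zeros((len(y), n_classes))
    U[np.arange(len(y)), y] = 1.0
    return U


def train(features: np.ndarray, labels: np.ndarray,
          config: ODCNNConfig) -> tuple[ODCNNModel, TrainingReport]:
    """Mini-batch SGD training; returns the model and its training-set report.

    Stops early when the mean per-sample loss plateaus (relative change
    below ``plateau_rel_tol`` across ``plateau_window`` epochs); raises
    :class:`TrainingDivergedError` with the epoch index if the loss goes
    non-finite.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    model = ODCNNModel(config)
    U = _one_hot(y, config.n_classes)
    rng = np.random.default_rng(config.seed)
    n = len(X)
    loss_curve: list[float] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            scores, cache = model.forward(X[idx])
            total += float(np.sum((scores - U[idx]) ** 2))
            grads = model.backward(cache, scores, U[idx])
            try:
                model.sgd_update(grads, config.learning_rate)
            except TrainingDivergedError:
                raise TrainingDivergedError(epoch) from None
        mean_loss = total / n
        if not np.isfinite(mean_loss):
            raise TrainingDivergedError(epoch)
        loss_curve.append(mean_loss)
        w = config.plateau_window
        if len(loss_curve) > w:
            prev, cur = loss_curve[-w - 1], loss_curve[-1]
            if abs(prev - cur) <= config.plateau_rel_tol * max(abs(prev), 1e-12):
                break
    pred, _ = model.predict(X)
    conf = np.zeros((config.n_classes, config.n_classes), dtype=int)
    np.add.at(conf, (y, pred), 1)
    acc = float(np.trace(conf)) / n
    report = TrainingReport(accuracy=acc, confusion=conf,
                            misclassified=int(n - np.trace(conf)),
                            loss_curve=loss_curve, n=n)
    return model, report


def cross_validate(features: np.ndarray, labels: np.ndarray,
                   config: ODCNNConfig, k: int = 5) -> TrainingReport:
    """Stratified k-fold cross-validation with metrics pooled over held-out folds."""
    from emocomp.evalstats import confusion_and_accuracy, roc_auc_ovr

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=config.n_classes)
    if np.any((counts > 0) & (counts < k)):
        raise ValueError("every present class needs at least k members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    pooled_true = np.empty(0, dtype=int)
    pooled_pred = np.empty(0, dtype=int)
    pooled_scores = np.empty((0, config.n_classes))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_cfg = replace(config, seed=config.seed + 1000 * (fold + 1))
        model, _ = train(X[tr], y[tr], fold_cfg)
        pred, scores = model.predict(X[te])
        pooled_true = np.concatenate([pooled_true, y[te]])
        pooled_pred = np.concatenate([pooled_pred, pred])
        pooled_scores = np.vstack([pooled_scores, scores])
    conf, acc, mis = confusion_and_accuracy(pooled_true, pooled_pred,
                                            n_classes=config.n_classes)
    per_class, macro = roc_auc_ovr(pooled_true, pooled_scores)
    return TrainingReport(accuracy=acc, confusion=conf, misclassified=mis,
                          per_class_auc=per_class, macro_auc=macro,
                          n=len(pooled_true))


def grid_search(features: np.ndarray, labels: np.ndarray,
                grid: list[ODCNNConfig], k: int = 5):
    """Cross-validate every configuration; return (best config, results table).

    Best = highest pooled accuracy, ties broken by earliest grid position.
    The table mirrors the standard configuration-comparison columns
    (configuration number, depth, kernel size, learning rate, activation,
    model type, accuracy %).
    """
    import pandas as pd

    if not grid:
        raise ValueError("grid must be non-empty")
    rows = []
    best_i, best_acc = 0, -1.0
    for i, cfg in enumerate(grid):
        try:
            report = cross_validate(features, labels, cfg, k=k)
        except TrainingDivergedError:
            # a diverging configuration scores zero instead of aborting the grid
            report = TrainingReport(accuracy=0.0,
                                    confusion=np.zeros((cfg.n_classes,) * 2, dtype=int),
                                    misclassified=len(labels))
        rows.append({
            "configuration": i + 1,
            "network_depth": cfg.depth,
            "kernel_size": cfg.kernel_size,
            "learning_rate": cfg.learning_rate,
            "activation": cfg.activation.upper(),
            "model_type": "ODCNN",
            "accuracy_pct": 100.0 * report.accuracy,
        })
        if report.accuracy > best_acc:
            best_acc, best_i = report.accuracy, i
    return grid[best_i], pd.DataFrame(rows)


def standard_grid(base: ODCNNConfig | None = None) -> list[ODCNNConfig]:
    """The 16-point depth × kernel × learning-rate grid used in the study."""
    base = base or ODCNNConfig()
    combos = [
        (3, 3, 0.00005), (3, 5, 0.00001), (3, 7, 0.0005), (3, 9, 0.0001),
        (4, 3, 0.00005), (4, 5, 0.00001), (4, 7, 0.0005), (4, 9, 0.0001),
        (5, 3, 0.00005), (5, 5, 0.00001), (5, 7, 0.0005), (5, 9, 0.0001),
        (6, 3, 0.00005), (6, 5, 0.00001), (6, 7, 0.0005), (6, 9, 0.0001),
    ]
    return [replace(base, depth=d, kernel_size=ks, learning_rate=lr)
            for d, ks, lr in combos]
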