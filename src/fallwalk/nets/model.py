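"""Window classifiers: CNN, LSTM and ConvLSTM families with task heads.

The reference topology is five 1-D convolutional layers (each followed by
dropout) feeding a single LSTM layer and dense output heads; the CNN family
replaces the recurrent layer with global average pooling over time, and the
LSTM family stacks two or more recurrent layers directly on the raw triaxial
signal.  The main head predicts fall status (2-unit softmax, cross-entropy);
optional auxiliary heads predict subject identity (softmax over the training
vocabulary), gender (sigmoid), or a standardized anthropometric attribute
(linear unit, squared error).  The total training loss is the weighted sum of
the per-head losses, and training records both so the decomposition can be
audited epoch by epoch.

Everything runs on the numpy layer engine in :mod:`fallwalk.nets.layers`;
training is full-batch-deterministic given the spec seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .layers import LSTM, Adam, AvgPool1d, Conv1d, Dense, Dropout, Layer, ReLU, TimeAvg, Transpose, _sigmoid

FAMILIES = ("CNN", "LSTM", "ConvLSTM")
AUX_TASKS = ("identity", "gender", "age", "weight", "height")
LOSS_KINDS = ("binary_cross_entropy", "categorical_cross_entropy", "squared_error")


@dataclass(frozen=True)
class TaskHead:
    task: str  # fall_status | identity | gender | age | weight | height
    output_arity: int
    loss_kind: str
    loss_weight: float = 1.0

    def __post_init__(self):
        if self.task not in ("fall_status",) + AUX_TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.loss_kind not in LOSS_KINDS:
            raise ValueError(f"unknown loss_kind {self.loss_kind!r}")
        if self.loss_weight <= 0:
            raise ValueError("loss_weight must be > 0")


def default_head(task: str, n_subjects: int | None = None, loss_weight: float = 1.0) -> TaskHead:
    """Conventional head for each task."""
    if task == "fall_status":
        return TaskHead("fall_status", 2, "categorical_cross_entropy", loss_weight)
    if task == "identity":
        if not n_subjects or n_subjects < 2:
            raise ValueError("identity head needs the training-subject vocabulary size")
        return TaskHead("identity", n_subjects, "categorical_cross_entropy", loss_weight)
    if task == "gender":
        return TaskHead("gender", 1, "binary_cross_entropy", loss_weight)
    if task in ("age", "weight", "height"):
        return TaskHead(task, 1, "squared_error", loss_weight)
    raise ValueError(f"unknown task {task!r}")


@dataclass
class ModelSpec:
    """Architecture family, layer configuration, heads and optimizer settings.

    ``conv_layer_filters`` defaults to [N, N, N, taper·N, taper·N] with
    N = ``n_filters`` and ``conv_taper`` = 3/4.  ``pool`` > 1 inserts an
    average-pooling stride after each convolution block (off by default) to
    shorten the recurrent sequence on small-compute profiles.
    """

    family: str = "ConvLSTM"
    n_filters: int = 128
    conv_layer_filters: list[int] | None = None
    conv_taper: float = 0.75
    dropout_rate: float = 0.5
    lstm_layers: int | None = None
    kernel_size: int = 9
    pool: int = 1
    pool_layers: int | None = None  # conv layers followed by pooling; None = all
    heads: list[TaskHead] = field(default_factory=lambda: [default_head("fall_status")])
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.lstm_layers is None:
            self.lstm_layers = {"CNN": 0, "ConvLSTM": 1, "LSTM": 2}[self.family]
        if self.family == "ConvLSTM" and self.lstm_layers != 1:
            raise ValueError("ConvLSTM family requires exactly one LSTM layer")
        if self.family == "LSTM" and self.lstm_layers < 2:
            raise ValueError("LSTM family requires two or more LSTM layers")
        if self.family == "CNN" and self.lstm_layers != 0:
            raise ValueError("CNN family takes no LSTM layers")
        if self.conv_layer_filters is None:
            N, tap = self.n_filters, self.conv_taper
            self.conv_layer_filters = [N, N, N, max(1, round(tap * N)), max(1, round(tap * N))]
        if self.family == "ConvLSTM" and len(self.conv_layer_filters) != 5:
            raise ValueError("ConvLSTM reference topology uses 5 convolutional layers")
        mains = [h for h in self.heads if h.task == "fall_status"]
        if len(mains) != 1:
            raise ValueError("exactly one head must have task='fall_status'")


class Network:
    """An untrained (or trained) predictor built from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, input_shape: tuple[int, int]):
        self.spec = spec
        self.input_shape = tuple(input_shape)  # (channels, samples)
        rng = np.random.default_rng(spec.seed)
        self._dropout_rng = np.random.default_rng(spec.seed + 1)
        C, _ = self.input_shape
        trunk: list[Layer] = []
        if spec.family in ("CNN", "ConvLSTM"):
            in_ch = C
            n_pool = len(spec.conv_layer_filters) if spec.pool_layers is None else spec.pool_layers
            for li, f in enumerate(spec.conv_layer_filters):
                trunk.append(Conv1d(in_ch, f, spec.kernel_size, rng))
                trunk.append(ReLU())
                trunk.append(Dropout(spec.dropout_rate, self._dropout_rng))
                if spec.pool > 1 and li < n_pool:
                    trunk.append(AvgPool1d(spec.pool))
                in_ch = f
            if spec.family == "CNN":
                trunk.append(TimeAvg())
                feat = in_ch
            else:
                trunk.append(Transpose())
                trunk.append(LSTM(in_ch, spec.n_filters, rng, return_sequences=False))
                feat = spec.n_filters
        else:  # pure LSTM stack on the raw signal
            trunk.append(Transpose())
            in_dim = C
            for li in range(spec.lstm_layers):
                last = li == spec.lstm_layers - 1
                trunk.append(LSTM(in_dim, spec.n_filters, rng, return_sequences=not last))
                in_dim = spec.n_filters
            feat = spec.n_filters
        self.trunk = trunk
        self.heads = {h.task: Dense(feat, h.output_arity, rng) for h in spec.heads}
        self.head_specs = {h.task: h for h in spec.heads}
        self.trained = False
        self.target_scaling: dict[str, tuple[float, float]] = {}

    # -- plumbing ----------------------------------------------------------
    def params(self):
        out = []
        for layer in self.trunk:
            out.extend(layer.params())
        for d in self.heads.values():
            out.extend(d.params())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 3 or X.shape[1:] != self.input_shape:
            raise ValueError(f"expected window batch of shape (n, {self.input_shape[0]}, {self.input_shape[1]}), got {X.shape}")
        return X

    def forward(self, X: np.ndarray, train: bool = False) -> dict[str, np.ndarray]:
        h = self._check_input(X)
        for layer in self.trunk:
            h = layer.forward(h, train=train)
        return {task: dense.forward(h, train=train) for task, dense in self.heads.items()}

    def backward(self, head_grads: dict[str, np.ndarray]) -> None:
        dfeat = None
        for task, g in head_grads.items():
            d = self.heads[task].backward(g)
            dfeat = d if dfeat is None else dfeat + d
        for layer in reversed(self.trunk):
            dfeat = layer.backward(dfeat)

    # -- inference ---------------------------------------------------------
    def predict(self, X: np.ndarray) -> dict[str, np.ndarray]:
        """Per-window scores per head (dropout off, deterministic).

        fall_status → probability of the faller class in [0, 1]; identity →
        probability vector over the training-subject vocabulary; gender →
        sigmoid probability; regression heads → reals on the standardized
        training scale.
        """
        logits = self.forward(X, train=False)
        out = {}
        for task, z in logits.items():
            kind = self.head_specs[task].loss_kind
            if kind == "categorical_cross_entropy":
                p = _softmax(z)
                out[task] = p[:, 1] if task == "fall_status" else p
            elif kind == "binary_cross_entropy":
                out[task] = _sigmoid(z[:, 0])
            else:
                out[task] = z[:, 0]
        return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _head_loss_grad(kind: str, logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean loss over the batch and its gradient w.r.t. the head logits."""
    B = logits.shape[0]
    if kind == "categorical_cross_entropy":
        p = _softmax(logits)
        yi = np.asarray(y, int)
        loss = float(-np.mean(np.log(p[np.arange(B), yi] + 1e-12)))
        grad = p.copy()
        grad[np.arange(B), yi] -= 1.0
        return loss, grad / B
    if kind == "binary_cross_entropy":
        p = _sigmoid(logits[:, 0])
        yf = np.asarray(y, float)
        loss = float(-np.mean(yf * np.log(p + 1e-12) + (1 - yf) * np.log(1 - p + 1e-12)))
        return loss, ((p - yf) / B)[:, None]
    # squared error
    r = logits[:, 0] - np.asarray(y, float)
    return float(np.mean(r**2)), (2.0 * r / B)[:, None]


@dataclass
class TrainedModel:
    spec: ModelSpec
    network: Network
    history: dict[str, list[float]]
    stopped_epoch: int

    def predict(self, X: np.ndarray) -> dict[str, np.ndarray]:
        return self.network.predict(X)


def build_model(spec: ModelSpec, input_shape: tuple[int, int] = (3, 250)) -> Network:
    """Instantiate an untrained network for (channels, window-length) input."""
    return Network(spec, input_shape)


def _total_loss(net: Network, X, targets) -> tuple[float, dict[str, float]]:
    logits = net.forward(X, train=False)
    per_head = {}
    for task, h in net.head_specs.items():
        loss, _ = _head_loss_grad(h.loss_kind, logits[task], targets[task])
        per_head[task] = loss
    total = sum(net.head_specs[t].loss_weight * l for t, l in per_head.items())
    return float(total), per_head


def train(
    net: Network,
    X_train: np.ndarray,
    y_train: dict[str, np.ndarray],
    X_val: np.ndarray,
    y_val: dict[str, np.ndarray],
) -> TrainedModel:
    """Minimize the weighted multi-head loss with Adam and early stopping.

    Per-epoch history records the realized total training loss alongside each
    head's unweighted loss, so ``loss ≈ Σ weight·head loss`` can be verified;
    validation uses the same weighted total.  Early stopping restores the
    parameters of the best validation epoch.  Reproducible from the spec seed.
    """
    spec = net.spec
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    for split_name, y in (("train", y_train), ("val", y_val)):
        missing = [t for t in net.head_specs if t not in y]
        if missing:
            raise ValueError(f"missing {split_name} labels for heads: {missing}")
    y_train = dict(y_train)
    y_val = dict(y_val)
    for task, h in net.head_specs.items():
        if h.loss_kind == "squared_error":
            mu = float(np.mean(y_train[task]))
            sd = float(np.std(y_train[task])) or 1.0
            net.target_scaling[task] = (mu, sd)
            y_train[task] = (np.asarray(y_train[task], float) - mu) / sd
            y_val[task] = (np.asarray(y_val[task], float) - mu) / sd
    if len(np.unique(np.asarray(y_train["fall_status"], int))) < 2:
        warnings.warn("all training windows share one fall-status class; downstream AUC will be undefined")

    opt = Adam(net.params(), lr=spec.learning_rate)
    shuffle_rng = np.random.default_rng(spec.seed + 2)
    n = len(X_train)
    history: dict[str, list[float]] = {"loss": [], "val_loss": []}
    for task in net.head_specs:
        history[f"loss_{task}"] = []
        history[f"val_loss_{task}"] = []
    best_val = np.inf
    best_params = None
    patience_left = spec.patience
    stopped = spec.epochs
    for epoch in range(spec.epochs):
        order = shuffle_rng.permutation(n)
        tot_sum = 0.0
        head_sums = {t: 0.0 for t in net.head_specs}
        n_batches = 0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            logits = net.forward(X_train[idx], train=True)
            opt.zero_grad()
            grads = {}
            batch_total = 0.0
            for task, h in net.head_specs.items():
                loss, g = _head_loss_grad(h.loss_kind, logits[task], y_train[task][idx])
                head_sums[task] += loss
                batch_total += h.loss_weight * loss
                grads[task] = h.loss_weight * g
            tot_sum += batch_total
            n_batches += 1
            net.backward(grads)
            opt.step()
        history["loss"].append(tot_sum / n_batches)
        for task in net.head_specs:
            history[f"loss_{task}"].append(head_sums[task] / n_batches)
        val_total, val_heads = _total_loss(net, X_val, y_val)
        history["val_loss"].append(val_total)
        for task, l in val_heads.items():
            history[f"val_loss_{task}"].append(l)
        if val_total < best_val - 1e-6:
            best_val = val_total
            best_params = [p.value.copy() for p in net.params()]
            patience_left = spec.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                stopped = epoch + 1
                break
    if best_params is not None:
        for p, v in zip(net.params(), best_params):
            p.value[...] = v
    net.trained = True
    return TrainedModel(spec=spec, network=net, history=history, stopped_epoch=min(stopped, len(history["loss"])))


def predict(model: TrainedModel | Network, X: np.ndarray) -> dict[str, np.ndarray]:
    """Module-level convenience wrapper around the model's ``predict``."""
    net = model.network if isinstance(model, TrainedModel) else model
    if not net.trained:
        raise ValueError("model is not trained")
    return net.predict(X)
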