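"""The frame classifier: a small VGG-style CNN, trained per experiment.

Architecture (fixed by design, configurable in :class:`NetworkSpec`):
four 3x3 valid convolutions with 32, 64, 128 and 256 filters, each
followed by 2x2 max pooling; flatten; two dense layers of 500 units;
dropout 0.5; and an output layer — a single sigmoid unit for binary
problems, K softmax units otherwise. ReLU everywhere else. Adam with
learning rate 1.5e-4, batch size 15, at most 50 epochs with early
stopping on validation loss (patience 5, best weights restored) and
learning-rate reduction on plateau (patience 3).

There is deliberately no pre-trained model: each experiment trains from
scratch on its own labeled frames, with inverse-frequency class weights
compensating the heavy "no object" majority.

The API follows the model/results convention: build a
:class:`FrameClassifier` from data, call :meth:`~FrameClassifier.fit`,
and use the returned :class:`FrameClassifierResults` for prediction,
diagnostics and persistence.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from . import _nn
from .errors import ConsistencyError, FormatError, SchemaError
from .labeling import ClassScheme, ClassWeights, DataSplit, split_train_val
from .stopwatch import PredictionTrack
from .video_io import MODEL_INPUT_SIZE


@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters of the classifier; defaults are the tuned values."""

    input_size: int = MODEL_INPUT_SIZE
    channels: int = 3
    conv_filters: tuple[int, ...] = (32, 64, 128, 256)
    conv_kernel: int = 3
    pool_size: int = 2
    dense_units: tuple[int, ...] = (500, 500)
    dropout_rate: float = 0.5
    conv_padding: str = "valid"
    learning_rate: float = 0.00015
    batch_size: int = 15
    max_epochs: int = 50
    early_stop_patience: int = 5
    lr_plateau_patience: int = 3
    lr_plateau_factor: float = 0.1
    min_learning_rate: float = 1e-6

    def __post_init__(self) -> None:
        if self.conv_kernel != 3 or self.conv_padding != "valid":
            raise ConsistencyError("only 3x3 valid convolutions are implemented")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    epochs_run: int = 0
    stop_reason: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


def build_network(spec: NetworkSpec, K: int, seed: int = 0):
    """Assemble the layer stack; returns ``(net, parameter_count)``."""
    if K < 2:
        raise ConsistencyError("need at least 2 classes")
    rng = np.random.default_rng([seed, 0xC0FFEE])
    layers: list[_nn.Layer] = []
    in_c = spec.channels
    for li, out_c in enumerate(spec.conv_filters):
        layers.append(_nn.Conv3x3(in_c, out_c, rng, skip_input_grad=(li == 0)))
        layers.append(_nn.ReLU())
        layers.append(_nn.MaxPool2())
        in_c = out_c
    layers.append(_nn.Flatten())
    side = spec.input_size
    for _ in spec.conv_filters:
        side = (side - 2) // 2
    n_in = side * side * in_c
    for units in spec.dense_units:
        layers.append(_nn.Dense(n_in, units, rng))
        layers.append(_nn.ReLU())
        n_in = units
    layers.append(_nn.Dropout(spec.dropout_rate, np.random.default_rng([seed, 0xD0])))
    out_units = 1 if K == 2 else K
    layers.append(_nn.Dense(n_in, out_units, rng, init="glorot"))
    net = _nn.Sequential(layers)
    return net, net.param_count()


def _as_float_batch(X, idx: np.ndarray) -> np.ndarray:
    """Gather frames and rescale to [0, 1] float32, one batch at a time."""
    if isinstance(X, np.ndarray):
        batch = X[idx]
    else:  # any indexable frame provider (lazy disk-backed loading)
        batch = np.stack([np.asarray(X[int(i)]) for i in idx])
    if batch.dtype == np.uint8:
        return batch.astype(np.float32) / 255.0
    return batch.astype(np.float32, copy=False)


class FrameClassifier:
    """Supervised per-frame behaviour classifier.

    Parameters
    ----------
    X : array-like
        Labeled frames, shape (N, 150, 150, 3); uint8 in [0, 255] or
        float in [0, 1]. Any integer-indexable provider works, so frames
        can be streamed batch-wise rather than held in float RAM.
    y : ndarray
        Per-frame class indices into ``scheme``.
    scheme : ClassScheme
        The behaviour classes; K = scheme.K decides binary vs multiclass.
    class_weights : ClassWeights, optional
        Loss weights; unweighted training when omitted.
    spec : NetworkSpec, optional
    """

    def __init__(self, X, y, scheme: ClassScheme,
                 class_weights: ClassWeights | None = None,
                 spec: NetworkSpec = NetworkSpec()):
        self.X = X
        self.y = np.asarray(y, dtype=np.int64)
        if len(self.y) != len(X):
            raise ConsistencyError("X and y lengths differ")
        if len(self.y) == 0:
            raise ConsistencyError("empty training set")
        if self.y.min() < 0 or self.y.max() >= scheme.K:
            raise SchemaError("labels outside the class scheme")
        self.scheme = scheme
        self.spec = spec
        self.class_weights = class_weights

    # -- fitting ------------------------------------------------------------

    def fit(self, split: DataSplit | None = None, seed: int = 0,
            epochs: int | None = None, verbose: bool = False,
            on_epoch_end=None) -> "FrameClassifierResults":
        """Train the network; returns results with the best-epoch weights.

        ``epochs`` caps the epoch count below ``spec.max_epochs`` (useful
        for small CPU budgets); callbacks behave identically either way.
        ``on_epoch_end(epoch_index, net, history)`` is invoked after every
        epoch for monitoring.
        """
        spec = self.spec
        K = self.scheme.K
        if split is None:
            split = split_train_val(self.y, ratio=0.8, seed=seed)
        train_idx, val_idx = split.train_idx, split.val_idx
        if len(train_idx) == 0:
            raise ConsistencyError("empty training split")
        net, n_params = build_network(spec, K, seed=seed)
        opt = _nn.Adam(net.params, lr=spec.learning_rate)
        rng = np.random.default_rng([seed, 0x5EED])
        w = None
        if self.class_weights is not None:
            w = self.class_weights.values

        max_epochs = spec.max_epochs if epochs is None else min(epochs, spec.max_epochs)
        history = TrainingHistory()
        best_val = np.inf
        best_weights = net.get_weights()
        since_best = 0
        since_plateau = 0
        binary = K == 2

        for epoch in range(max_epochs):
            t0 = time.time()
            order = train_idx.copy()
            rng.shuffle(order)
            losses, hits, seen = [], 0, 0
            for start in range(0, len(order), spec.batch_size):
                idx = order[start : start + spec.batch_size]
                xb = _as_float_batch(self.X, idx)
                yb = self.y[idx]
                logits = net.forward(xb, train=True)
                sw = None if w is None else w[yb]
                if binary:
                    loss, dlogits = _nn.binary_xent(logits, yb, sw)
                    pred = (logits[:, 0] > 0).astype(np.int64)
                else:
                    loss, dlogits = _nn.softmax_xent(logits, yb, sw)
                    pred = logits.argmax(axis=1)
                net.backward(dlogits)
                opt.step(net.grads)
                losses.append(loss * len(idx))
                hits += int((pred == yb).sum())
                seen += len(idx)
            train_loss = float(np.sum(losses) / seen)
            train_acc = hits / seen

            val_loss, val_acc = self._evaluate(net, val_idx, binary)
            history.train_loss.append(train_loss)
            history.train_acc.append(train_acc)
            history.val_loss.append(val_loss)
            history.val_acc.append(val_acc)
            history.learning_rate.append(opt.lr)
            history.epochs_run = epoch + 1
            if verbose:
                print(
                    f"epoch {epoch + 1}/{max_epochs} "
                    f"loss {train_loss:.4f} acc {train_acc:.3f} "
                    f"val_loss {val_loss:.4f} val_acc {val_acc:.3f} "
                    f"lr {opt.lr:.2e} ({time.time() - t0:.1f}s)"
                )

            if on_epoch_end is not None:
                on_epoch_end(epoch, net, history)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_weights = net.get_weights()
                since_best = 0
                since_plateau = 0
            else:
                since_best += 1
                since_plateau += 1
                if since_plateau > spec.lr_plateau_patience:
                    opt.lr = max(opt.lr * spec.lr_plateau_factor, spec.min_learning_rate)
                    since_plateau = 0
                if since_best > spec.early_stop_patience:
                    history.stop_reason = "early_stop"
                    break
        else:
            history.stop_reason = "max_epochs"
        net.set_weights(best_weights)  # best-validation-loss weights retained
        return FrameClassifierResults(self, net, history, n_params, split, seed)

    def _evaluate(self, net: _nn.Sequential, idx: np.ndarray, binary: bool):
        if len(idx) == 0:
            return float("nan"), float("nan")
        losses, hits = [], 0
        for start in range(0, len(idx), self.spec.batch_size):
            sub = idx[start : start + self.spec.batch_size]
            xb = _as_float_batch(self.X, sub)
            yb = self.y[sub]
            logits = net.forward(xb, train=False)
            if binary:
                loss, _ = _nn.binary_xent(logits, yb)
                pred = (logits[:, 0] > 0).astype(np.int64)
            else:
                loss, _ = _nn.softmax_xent(logits, yb)
                pred = logits.argmax(axis=1)
            losses.append(loss * len(sub))
            hits += int((pred == yb).sum())
        return float(np.sum(losses) / len(idx)), hits / len(idx)


class FrameClassifierResults:
    """A fitted classifier: trained weights, history and diagnostics."""

    def __init__(self, model: FrameClassifier | None, net: _nn.Sequential,
                 history: TrainingHistory, n_params: int,
                 split: DataSplit | None, seed: int):
        self.model = model
        self.net = net
        self.history = history
        self.n_params = n_params
        self.split = split
        self.seed = seed
        self.spec = model.spec if model else NetworkSpec()
        self.scheme = model.scheme if model else None

    # -- inference ----------------------------------------------------------

    def predict_frames(self, frames, fps: float = 25.0, video_id: str = "",
                       batch_size: int = 30) -> PredictionTrack:
        """Class probabilities and hard classes for every frame.

        Softmax rows sum to one; the binary head emits ``(1-p, p)``.
        Ties break toward the lowest class index.
        """
        K = self.scheme.K
        n = len(frames)
        probs = np.empty((n, K), dtype=np.float64)
        for start in range(0, n, batch_size):
            idx = np.arange(start, min(start + batch_size, n))
            xb = _as_float_batch(frames, idx)
            if xb.shape[1:] != (self.spec.input_size, self.spec.input_size,
                                self.spec.channels):
                raise ConsistencyError(
                    f"frames of shape {xb.shape[1:]} do not match the "
                    f"{self.spec.input_size}x{self.spec.input_size} input contract"
                )
            logits = self.net.forward(xb, train=False)
            if K == 2:
                p = _nn.sigmoid(logits[:, 0].astype(np.float64))
                probs[idx] = np.stack([1.0 - p, p], axis=1)
            else:
                probs[idx] = _nn.softmax(logits.astype(np.float64))
        hard = probs.argmax(axis=1)  # argmax takes the first (lowest) maximum
        return PredictionTrack(video_id, probs, hard, fps)

    # -- reporting ----------------------------------------------------------

    @property
    def final_val_loss(self) -> float:
        return self.history.val_loss[-1] if self.history.val_loss else float("nan")

    def summary(self) -> str:
        h = self.history
        lines = [
            "Frame classifier (VGG-style CNN)",
            "=" * 40,
            f"classes:            {self.scheme.names if self.scheme else '?'}",
            f"parameters:         {self.n_params:,}",
            f"epochs run:         {h.epochs_run} ({h.stop_reason or 'running'})",
            f"final train loss:   {h.train_loss[-1]:.4f}" if h.train_loss else "",
            f"final train acc:    {h.train_acc[-1]:.4f}" if h.train_acc else "",
            f"best val loss:      {min(h.val_loss):.4f}" if h.val_loss else "",
            f"final val acc:      {h.val_acc[-1]:.4f}" if h.val_acc else "",
            f"final lr:           {h.learning_rate[-1]:.2e}" if h.learning_rate else "",
        ]
        return "\n".join(line for line in lines if line)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Serialize weights + spec + scheme to an HDF5 model file."""
        with h5py.File(path, "w") as fh:
            fh.attrs["format"] = "explore-frame-classifier"
            fh.attrs["spec"] = json.dumps(asdict(self.spec))
            fh.attrs["scheme"] = json.dumps(
                {"names": list(self.scheme.names), "kinds": list(self.scheme.kinds)}
            )
            fh.attrs["history"] = json.dumps(self.history.as_dict())
            grp = fh.create_group("weights")
            for i, p in enumerate(self.net.params):
                grp.create_dataset(f"p{i:03d}", data=p)


def load_model(path, scheme: ClassScheme | None = None) -> FrameClassifierResults:
    """Load a saved model; optionally check it against an expected scheme."""
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"{path} is not a readable model file: {exc}") from exc
    with fh:
        if fh.attrs.get("format") != "explore-frame-classifier":
            raise FormatError(f"{path} is not an explore model file")
        spec = NetworkSpec(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in json.loads(fh.attrs["spec"]).items()
        })
        sch = json.loads(fh.attrs["scheme"])
        saved_scheme = ClassScheme(tuple(sch["names"]), tuple(sch["kinds"]))
        history = TrainingHistory(**json.loads(fh.attrs["history"]))
        weights = [fh["weights"][k][...] for k in sorted(fh["weights"])]
    if scheme is not None and tuple(scheme.names) != tuple(saved_scheme.names):
        raise SchemaError(
            f"model was trained for classes {saved_scheme.names}, "
            f"project defines {scheme.names}"
        )
    net, n_params = build_network(spec, saved_scheme.K, seed=0)
    net.set_weights([w.astype(np.float32) for w in weights])
    results = FrameClassifierResults(None, net, history, n_params, None, 0)
    results.spec = spec
    results.scheme = saved_scheme
    return results
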