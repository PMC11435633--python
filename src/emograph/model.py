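"""The 4-layer graph-convolutional emotion classifier (DFCGN).

Architecture: dropout on the input windows, then four blocks of
[Chebyshev graph convolution -> max pooling along the feature axis ->
Leaky-ReLU]; only the first block is preceded by dropout.  The 3-node
output is flattened and a single dense layer produces per-class softmax
scores (2-class: positive/negative; 3-class: + neutral).

Each node (EEG channel) carries 125 time samples as its feature vector;
the graph convolution mixes nodes through Chebyshev polynomials of the
rescaled Laplacian and features through per-order weight matrices.  Max
pooling halves the feature axis per block (125 -> 62 -> 31 -> 15 -> 7),
so the flattened representation has 3 x 7 = 21 values by default.

Usage follows the model/results convention::

    model = DFCGNModel(windows, graph=g, config=ModelConfig(), seed=0)
    res = model.fit(TrainConfig(epochs=30))
    print(res.summary())
    proba = res.predict(test_windows.windows)
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .graph import ChannelGraph, cheb_t_stack
from .preprocess import WindowSet, SPLIT_CODES

__all__ = ["ModelConfig", "TrainConfig", "DFCGNModel", "DFCGNResults",
           "build_model", "forward", "count_parameters"]


@dataclass(frozen=True)
class ModelConfig:
    n_gconv_layers: int = 4
    cheb_orders: tuple = (3, 3, 3, 3)
    layer_feature_widths: tuple = (125, 62, 31, 15)   # GConv outputs, pre-pool
    input_features: int = 125
    pool_size: int = 2
    leaky_relu_slope: float = 0.01
    dropout_rate: float = 0.3
    n_classes: int = 3

    def __post_init__(self):
        if self.n_gconv_layers != len(self.cheb_orders) or \
                self.n_gconv_layers != len(self.layer_feature_widths):
            raise ValueError("cheb_orders / widths must match layer count")
        if any(k < 1 for k in self.cheb_orders):
            raise ValueError("Chebyshev orders must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        widths = list(self.layer_feature_widths)
        if any(w <= 0 for w in widths):
            raise ValueError("feature widths must be positive")
        f = self.input_features
        for w in widths:
            if w > f:  # a layer cannot widen beyond its input here
                raise ValueError(
                    f"layer width {w} inconsistent with input width {f}")
            f = w // self.pool_size
            if f < 1:
                raise ValueError("pooling exhausted the feature axis")

    @property
    def flatten_width(self) -> int:
        f = self.layer_feature_widths[-1] // self.pool_size
        return f

    def pooled_widths(self) -> list[int]:
        return [w // self.pool_size for w in self.layer_feature_widths]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 16
    loss: str = "cross_entropy"
    weight_decay: float = 6e-6
    epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning rate / batch size / epochs invalid")
        if self.loss not in ("cross_entropy", "mse"):
            raise ValueError("loss must be cross_entropy or mse")


def _build_network(config: ModelConfig, graph: ChannelGraph, seed: int,
                   n_nodes: int) -> nn.Sequential:
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    layers: list[nn.Layer] = [nn.Dropout(config.dropout_rate, drop_rng)]
    f_in = config.input_features
    for K, f_out in zip(config.cheb_orders, config.layer_feature_widths):
        T = cheb_t_stack(graph, K)
        layers.append(nn.ChebGraphConv(T, f_in, f_out, rng))
        layers.append(nn.MaxPoolFeature(config.pool_size))
        layers.append(nn.LeakyReLU(config.leaky_relu_slope))
        f_in = f_out // config.pool_size
    layers.append(nn.Flatten())
    layers.append(nn.Dense(n_nodes * f_in, config.n_classes, rng))
    return nn.Sequential(*layers)


class DFCGNModel:
    """Graph-convolutional emotion classifier bound to a window set.

    ``data`` may be None for a bare network (shape experiments, functional
    API); ``fit`` then requires windows explicitly.
    """

    def __init__(self, data: WindowSet | None = None,
                 graph: ChannelGraph | None = None,
                 config: ModelConfig | None = None, seed: int = 0):
        from .graph import build_graph
        self.config = config or ModelConfig()
        self.data = data
        self.seed = seed
        if graph is None:
            if data is None:
                raise ValueError("need either a graph or data to build one")
            train = data.split_subset("train")
            src = train if len(train) else data
            pooled = np.asarray(src.windows, dtype=float)
            sig = pooled.transpose(1, 0, 2).reshape(pooled.shape[1], -1)
            graph = build_graph(sig)
        if graph.n_nodes != 3 and data is not None and \
                data.windows.shape[1] != graph.n_nodes:
            raise ValueError("graph node count must match window node count")
        self.graph = graph
        self.network = _build_network(self.config, graph, seed, graph.n_nodes)

    # ------------------------------------------------------------------
    def forward(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        """Softmax class scores for a [B, n_nodes, 125] batch."""
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim == 2:
            batch = batch[None]
        if batch.shape[2] != self.config.input_features:
            raise ValueError(
                f"expected {self.config.input_features} features per node, "
                f"got {batch.shape[2]}")
        return nn.softmax(self.network.forward(batch, training=training))

    def logits(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        return self.network.forward(np.asarray(batch, dtype=np.float64),
                                    training=training)

    def count_parameters(self) -> int:
        return self.network.n_parameters()

    # ------------------------------------------------------------------
    def fit(self, train_config: TrainConfig | None = None,
            data: WindowSet | None = None) -> "DFCGNResults":
        cfg = train_config or TrainConfig()
        data = data if data is not None else self.data
        if data is None:
            raise ValueError("no window set bound to the model")
        train = data.split_subset("train")
        val = data.split_subset("val")
        if len(train) == 0:
            raise ValueError("training split is empty")
        y_train = self._encode_labels(train.labels)
        y_val = self._encode_labels(val.labels) if len(val) else None

        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
        net = self.network
        opt = nn.make_optimizer(cfg.optimizer, net.all_params, net.all_grads,
                                lr=cfg.learning_rate,
                                weight_decay=cfg.weight_decay)
        loss_fn = (nn.softmax_cross_entropy if cfg.loss == "cross_entropy"
                   else nn.mse_loss)
        x_train = np.asarray(train.windows, dtype=np.float64)
        history = []
        best = (-np.inf, net.state())
        n = x_train.shape[0]
        bs = min(cfg.batch_size, n)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            n_b = 0
            for s in range(0, n, bs):
                idx = order[s:s + bs]
                net.zero_grad()
                logits = net.forward(x_train[idx], training=True)
                loss, dlog = loss_fn(logits, y_train[idx])
                net.backward(dlog)
                opt.step()
                ep_loss += loss
                n_b += 1
            tr_logits = net.forward(x_train)
            tr_loss, _ = loss_fn(tr_logits, y_train)
            tr_acc = float((tr_logits.argmax(1) == y_train).mean())
            row = {"epoch": epoch, "train_loss": float(tr_loss),
                   "train_acc": tr_acc}
            if y_val is not None:
                v_logits = net.forward(np.asarray(val.windows, dtype=np.float64))
                v_loss, _ = loss_fn(v_logits, y_val)
                v_acc = float((v_logits.argmax(1) == y_val).mean())
                row.update(val_loss=float(v_loss), val_acc=v_acc)
                if v_acc > best[0]:
                    best = (v_acc, net.state())
            history.append(row)
        if y_val is not None and best[0] > -np.inf:
            net.load_state(best[1])
        return DFCGNResults(self, cfg, pd.DataFrame(history), data)

    # ------------------------------------------------------------------
    def _encode_labels(self, labels: np.ndarray) -> np.ndarray:
        """Map label codes (neg=0, neu=1, pos=2) to class indices.

        3-class: identity.  2-class: negative -> 0, positive -> 1 (neutral
        windows are invalid input in 2-class mode).
        """
        labels = np.asarray(labels)
        if self.config.n_classes == 3:
            return labels.astype(np.int64)
        if np.any(labels == 1):
            raise ValueError("neutral windows present in 2-class mode")
        return (labels == 2).astype(np.int64)


class DFCGNResults:
    """Fit results: learning curves, best-validation weights, predictions."""

    def __init__(self, model: DFCGNModel, train_config: TrainConfig,
                 history: pd.DataFrame, data: WindowSet):
        self.model = model
        self.train_config = train_config
        self.history = history
        self.data = data

    def predict(self, windows: np.ndarray) -> np.ndarray:
        """Softmax scores, dropout off."""
        return self.model.forward(windows, training=False)

    def predict_labels(self, windows: np.ndarray) -> np.ndarray:
        return self.predict(windows).argmax(axis=1)

    def evaluate(self, split: str = "test"):
        """MetricsReport on one split of the bound window set."""
        from .eval import compute_metrics
        sub = self.data.split_subset(split)
        if len(sub) == 0:
            raise ValueError(f"split {split!r} is empty")
        y = self.model._encode_labels(sub.labels)
        return compute_metrics(y, self.predict(sub.windows))

    @property
    def final_train_accuracy(self) -> float:
        return float(self.history["train_acc"].iloc[-1])

    @property
    def best_val_accuracy(self) -> float:
        if "val_acc" not in self.history:
            raise ValueError("no validation split was available")
        return float(self.history["val_acc"].max())

    def summary(self) -> str:
        cfg, m = self.train_config, self.model
        buf = io.StringIO()
        w = buf.write
        w("DFCGN classifier fit\n")
        w("=" * 52 + "\n")
        w(f"{'classes':<28}{m.config.n_classes}\n")
        w(f"{'graph nodes':<28}{m.graph.n_nodes}\n")
        w(f"{'Chebyshev orders':<28}{m.config.cheb_orders}\n")
        w(f"{'feature widths (pre-pool)':<28}{m.config.layer_feature_widths}\n")
        w(f"{'trainable parameters':<28}{m.count_parameters()}\n")
        w(f"{'optimizer':<28}{cfg.optimizer} (lr={cfg.learning_rate}, "
          f"wd={cfg.weight_decay})\n")
        w(f"{'loss':<28}{cfg.loss}\n")
        w(f"{'epochs':<28}{len(self.history)}\n")
        w(f"{'final train accuracy':<28}{self.final_train_accuracy:.4f}\n")
        if "val_acc" in self.history:
            w(f"{'best val accuracy':<28}{self.best_val_accuracy:.4f}\n")
        return buf.getvalue()


# ---------------------------------------------------------------------------
# functional surface

def build_model(config: ModelConfig, graph: ChannelGraph, seed: int = 0,
                ) -> DFCGNModel:
    """Construct an untrained classifier from config + graph alone."""
    return DFCGNModel(data=None, graph=graph, config=config, seed=seed)


def forward(model: DFCGNModel, batch: np.ndarray,
            training_mode: bool = False) -> np.ndarray:
    return model.forward(batch, training=training_mode)


def count_parameters(model: DFCGNModel) -> int:
    return model.count_parameters()
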