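"""Evaluation: metrics, cross-validation, leave-one-subject-out, noise
robustness and classical baselines.

Reported indices (all from the confusion matrix, rows = truth):
accuracy = trace/total; sensitivity (recall), precision and specificity are
macro-averaged one-vs-rest over classes; Cohen's kappa = (p_o - p_e)/(1 - p_e)
with p_e from the row/column marginals.  ROC curves are one-vs-rest per class
by threshold sweep over the softmax score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import WindowSet, SPLIT_CODES, make_splits
from .model import DFCGNModel, DFCGNResults, ModelConfig, TrainConfig
from .graph import build_graph
from . import nn

__all__ = [
    "MetricsReport", "compute_metrics", "train", "kfold_cv", "loo_eval",
    "add_noise_snr", "noise_robustness", "handcrafted_features",
    "baseline_fit",
]


@dataclass
class MetricsReport:
    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    precision: float
    specificity: float
    kappa: float
    roc: dict = field(default_factory=dict)   # class -> (fpr, tpr, thresholds)

    def as_dict(self) -> dict:
        return {"confusion": self.confusion.tolist(),
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "precision": self.precision, "specificity": self.specificity,
                "kappa": self.kappa}


def _roc_points(y_bin: np.ndarray, score: np.ndarray):
    """One-vs-rest ROC by sweeping every observed score as threshold."""
    thresholds = np.concatenate([[np.inf], np.unique(score)[::-1]])
    P = y_bin.sum()
    Nn = len(y_bin) - P
    fpr, tpr = [], []
    for t in thresholds:
        pred = score >= t
        tp = int(np.sum(pred & (y_bin == 1)))
        fp = int(np.sum(pred & (y_bin == 0)))
        tpr.append(tp / P if P else 0.0)
        fpr.append(fp / Nn if Nn else 0.0)
    return np.array(fpr), np.array(tpr), thresholds


def compute_metrics(y_true: np.ndarray, scores: np.ndarray) -> MetricsReport:
    """Confusion matrix + macro-averaged indices from softmax scores.

    ``scores`` may also be a 1-D array of predicted labels (no ROC then).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    if scores.ndim == 2:
        if scores.shape[0] != y_true.shape[0]:
            raise ValueError("y_true and scores lengths differ")
        y_pred = scores.argmax(axis=1)
        n_classes = scores.shape[1]
    else:
        y_pred = scores
        n_classes = int(max(y_true.max(), y_pred.max())) + 1

    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    total = cm.sum()
    acc = cm.trace() / total

    sens, prec, spec = [], [], []
    for c in range(n_classes):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(f"class {c} absent from y_true; "
                          "excluded from macro averages")
            continue
        sens.append(tp / (tp + fn))
        prec.append(tp / (tp + fp) if tp + fp else 0.0)
        spec.append(tn / (tn + fp) if tn + fp else 0.0)

    p_o = acc
    p_e = float((cm.sum(1) * cm.sum(0)).sum()) / total ** 2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0

    roc = {}
    if scores.ndim == 2:
        for c in range(n_classes):
            roc[c] = _roc_points((y_true == c).astype(int), scores[:, c])

    return MetricsReport(cm, float(acc), float(np.mean(sens)),
                         float(np.mean(prec)), float(np.mean(spec)),
                         float(kappa), roc)


# ---------------------------------------------------------------------------
# training wrappers

def train(model: DFCGNModel, windows: WindowSet, cfg: TrainConfig,
          ) -> DFCGNResults:
    """Fit on the train split, tracking val curves; thin functional wrapper."""
    return model.fit(cfg, data=windows)


def kfold_cv(windows: WindowSet, k: int = 5,
             cfg: TrainConfig | None = None,
             model_config: ModelConfig | None = None,
             seed: int = 0) -> list[MetricsReport]:
    """Stratified k-fold over the train+val windows; test split untouched.

    Each fold trains a fresh model on k-1 parts and evaluates on the held
    part; fold assignment is stratified by (participant, class).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    cfg = cfg or TrainConfig()
    pool_mask = np.isin(windows.split,
                        [SPLIT_CODES["train"], SPLIT_CODES["val"]])
    pool = windows.subset(pool_mask)
    rng = np.random.default_rng(seed)
    fold = np.empty(len(pool), dtype=int)
    for pid in np.unique(pool.participant_ids):
        for lab in np.unique(pool.labels):
            idx = np.flatnonzero((pool.participant_ids == pid)
                                 & (pool.labels == lab))
            if idx.size and idx.size < k:
                raise ValueError(f"stratum smaller than k={k}")
            fold[rng.permutation(idx)] = np.arange(idx.size) % k
    reports = []
    for f in range(k):
        split = np.where(fold == f, SPLIT_CODES["test"], SPLIT_CODES["train"])
        ws = WindowSet(pool.windows, pool.labels, pool.participant_ids,
                       split, pool.provenance)
        tr = ws.split_subset("train")
        sig = np.asarray(tr.windows, dtype=float)
        g = build_graph(sig.transpose(1, 0, 2).reshape(sig.shape[1], -1))
        m = DFCGNModel(ws, graph=g, config=model_config, seed=seed + f)
        res = m.fit(cfg)
        reports.append(res.evaluate("test"))
    return reports


def loo_eval(windows: WindowSet, cfg: TrainConfig | None = None,
             model_config: ModelConfig | None = None, seed: int = 0,
             val_ratio: float = 0.2):
    """Leave-one-subject-out: each participant held out entirely once.

    Returns (per-participant accuracy list, mean).  The held-out subject's
    windows never enter training, the graph, or validation.
    """
    cfg = cfg or TrainConfig()
    pids = np.unique(windows.participant_ids)
    if pids.size < 2:
        raise ValueError("leave-one-out needs at least 2 participants")
    accs = []
    for pid in pids:
        test_mask = windows.participant_ids == pid
        split = np.where(test_mask, SPLIT_CODES["test"], SPLIT_CODES["train"])
        # carve a validation share out of the remaining subjects
        rng = np.random.default_rng(np.random.SeedSequence([seed, int(pid)]))
        train_idx = np.flatnonzero(~test_mask)
        n_val = int(round(val_ratio * train_idx.size))
        val_idx = rng.permutation(train_idx)[:n_val]
        split[val_idx] = SPLIT_CODES["val"]
        ws = WindowSet(windows.windows, windows.labels,
                       windows.participant_ids, split, windows.provenance)
        tr = ws.split_subset("train")
        assert not np.any(tr.participant_ids == pid), "leakage audit failed"
        sig = np.asarray(tr.windows, dtype=float)
        g = build_graph(sig.transpose(1, 0, 2).reshape(sig.shape[1], -1))
        m = DFCGNModel(ws, graph=g, config=model_config, seed=seed + int(pid))
        res = m.fit(cfg)
        accs.append(res.evaluate("test").accuracy)
    return accs, float(np.mean(accs))


# ---------------------------------------------------------------------------
# noise robustness

def add_noise_snr(windows: WindowSet, snr_db: float, seed: int = 0,
                  ) -> WindowSet:
    """Add white Gaussian noise at the requested per-window SNR (dB)."""
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    rng = np.random.default_rng(seed)
    x = np.asarray(windows.windows, dtype=np.float64)
    p_sig = (x ** 2).mean(axis=(1, 2))
    noisy = x.copy()
    zero = p_sig == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-power window(s) skipped")
    sigma = np.sqrt(np.where(zero, 0.0, p_sig / 10 ** (snr_db / 10.0)))
    noisy += sigma[:, None, None] * rng.standard_normal(x.shape)
    return WindowSet(noisy, windows.labels, windows.participant_ids,
                     windows.split, windows.provenance)


def noise_robustness(results: DFCGNResults, test: WindowSet, snr_list,
                     seed: int = 0) -> dict:
    """Test accuracy at each SNR (np.inf = clean)."""
    table = {}
    for i, snr in enumerate(snr_list):
        ws = test if np.isinf(snr) else add_noise_snr(test, snr, seed + i)
        y = results.model._encode_labels(ws.labels)
        scores = results.predict(ws.windows)
        table[float(snr)] = float((scores.argmax(1) == y).mean())
    return table


# ---------------------------------------------------------------------------
# handcrafted features and baselines

def handcrafted_features(window: np.ndarray) -> np.ndarray:
    """Six statistics per channel: mean, variance, skewness, kurtosis,
    crest factor (max|x| / RMS) and mean power — 18 values for 3 channels.

    Zero-variance channels get skewness = kurtosis = 0 by convention.
    """
    w = np.asarray(window, dtype=np.float64)
    if w.ndim != 2:
        raise ValueError("window must be [channels, samples]")
    mu = w.mean(axis=1)
    var = w.var(axis=1)
    sd = np.sqrt(var)
    power = (w ** 2).mean(axis=1)
    rms = np.sqrt(power)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (w - mu[:, None]) / sd[:, None]
        skew = np.where(sd > 0, np.nan_to_num((z ** 3)).mean(axis=1), 0.0)
        kurt = np.where(sd > 0, np.nan_to_num((z ** 4)).mean(axis=1), 0.0)
        crest = np.where(rms > 0, np.abs(w).max(axis=1) / np.where(rms > 0, rms, 1.0), 0.0)
    if np.any(sd == 0):
        warnings.warn("zero-variance channel; skew/kurtosis set to 0")
    return np.column_stack([mu, var, skew, kurt, crest, power]).ravel()


def _feature_matrix(ws: WindowSet) -> np.ndarray:
    return np.stack([handcrafted_features(w) for w in ws.windows])


def baseline_fit(windows: WindowSet, method: str,
                 representation: str = "handcrafted", seed: int = 0,
                 cnn_epochs: int = 30) -> MetricsReport:
    """Classical baselines on train/test splits of a window set.

    ``method`` in {knn, svm, mlp, cnn}; ``representation`` is 'handcrafted'
    (18 statistics) or 'raw' (flattened windows, feature learning regime).
    The CNN baseline is four plain 1-D conv layers mirroring the classifier's
    widths, without graph mixing.
    """
    tr = windows.split_subset("train")
    te = windows.split_subset("test")
    if len(tr) == 0 or len(te) == 0:
        raise ValueError("need non-empty train and test splits")
    y_tr, y_te = tr.labels.astype(int), te.labels.astype(int)
    classes = np.unique(windows.labels)
    remap = {c: i for i, c in enumerate(classes)}
    y_tr = np.array([remap[c] for c in y_tr])
    y_te = np.array([remap[c] for c in y_te])

    method = method.lower()
    if method == "cnn":
        return _cnn_baseline(tr, te, y_tr, y_te, len(classes), seed,
                             cnn_epochs)

    if representation == "handcrafted":
        X_tr, X_te = _feature_matrix(tr), _feature_matrix(te)
    elif representation == "raw":
        X_tr = np.asarray(tr.windows, float).reshape(len(tr), -1)
        X_te = np.asarray(te.windows, float).reshape(len(te), -1)
    else:
        raise ValueError("representation must be 'handcrafted' or 'raw'")

    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if method == "knn":
        clf = make_pipeline(StandardScaler(), KNeighborsClassifier(5))
    elif method == "svm":
        clf = make_pipeline(StandardScaler(), SVC(random_state=seed))
    elif method == "mlp":
        clf = make_pipeline(StandardScaler(),
                            MLPClassifier(hidden_layer_sizes=(64,),
                                          max_iter=500, random_state=seed))
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    clf.fit(X_tr, y_tr)
    if hasattr(clf, "predict_proba"):
        try:
            return compute_metrics(y_te, clf.predict_proba(X_te))
        except AttributeError:
            pass
    return compute_metrics(y_te, clf.predict(X_te))


def _cnn_baseline(tr, te, y_tr, y_te, n_classes, seed, epochs):
    rng = np.random.default_rng(seed)
    net = nn.Sequential(
        nn.Conv1d(3, 8, 5, rng), nn.LeakyReLU(0.01),
        nn.Conv1d(8, 8, 5, rng, stride=2), nn.LeakyReLU(0.01),
        nn.Conv1d(8, 8, 5, rng, stride=2), nn.LeakyReLU(0.01),
        nn.Conv1d(8, 8, 5, rng, stride=2), nn.LeakyReLU(0.01),
        nn.Flatten(), nn.Dense(8 * 16, n_classes, rng))
    opt = nn.Adam(net.all_params, net.all_grads, lr=0.001)
    x_tr = np.asarray(tr.windows, np.float64)
    scale = x_tr.std() or 1.0
    x_tr = x_tr / scale
    n = len(x_tr)
    for _ in range(epochs):
        order = rng.permutation(n)
        for s in range(0, n, 16):
            idx = order[s:s + 16]
            net.zero_grad()
            loss, dlog = nn.softmax_cross_entropy(
                net.forward(x_tr[idx], training=True), y_tr[idx])
            net.backward(dlog)
            opt.step()
    scores = nn.softmax(net.forward(np.asarray(te.windows, np.float64) / scale))
    return compute_metrics(y_te, scores)
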