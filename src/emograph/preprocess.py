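"""Preprocessing chain: channel selection, mid-song extraction, class
stacking, sample-budget bookkeeping, fixed-size windowing and split
construction.

The chain turns an annotated session into labelled graph signals: only the
central 20 s of each one-minute song is kept (maximal emotional arousal, no
bleed into the adjacent silences), segments of one emotion are concatenated
("stacked"), and the stacked signal is cut into non-overlapping 125-sample
windows — each window is one 3-node graph signal with 125 features per node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .synthgen import (EmotionSession, ProtocolConfig, Annotation,
                       LABEL_CODES, LABELS)

__all__ = [
    "StackedClassSignal", "WindowSet", "BudgetReport", "WindowConfig",
    "select_channels", "extract_mid_window", "stack_class", "window",
    "compute_budget", "make_splits", "sessions_to_windows",
    "save_windowset_hdf5", "load_windowset_hdf5",
]

SPLITS = ("unassigned", "train", "val", "test")
SPLIT_CODES = {s: i for i, s in enumerate(SPLITS)}


@dataclass(frozen=True)
class WindowConfig:
    size: int = 125
    stride: int = 125
    keep_s: float = 20.0
    target_samples_per_class: int = 125_000

    def __post_init__(self):
        if self.size <= 0 or self.stride <= 0:
            raise ValueError("window size and stride must be positive")


@dataclass
class StackedClassSignal:
    """Time-concatenated segments of one emotion for one participant."""

    signal: np.ndarray            # [n_channels, n_samples]
    label: str
    participant_id: int
    provenance: list = field(default_factory=list)  # (start, end, tag)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[1] == 0:
            raise ValueError("stacked signal must be [channels, samples>0]")
        if not self.provenance:
            self.provenance = [(0, self.signal.shape[1], "real")]
        prev = 0
        for s, e, _tag in self.provenance:
            if s != prev:
                raise ValueError("provenance ranges must partition the signal")
            prev = e
        if prev != self.signal.shape[1]:
            raise ValueError("provenance ranges must cover the signal")


@dataclass
class WindowSet:
    """Labelled tensor of fixed-size graph signals.

    ``windows``: [n, n_nodes, size]; ``labels``/``participant_ids``/``split``
    are aligned per-window vectors. ``provenance`` flags GAN-generated windows.
    """

    windows: np.ndarray
    labels: np.ndarray            # int8 codes, see synthgen.LABEL_CODES
    participant_ids: np.ndarray
    split: np.ndarray             # int8 codes, see SPLIT_CODES
    provenance: np.ndarray | None = None   # 0 = real, 1 = gan

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.participant_ids = np.asarray(self.participant_ids, dtype=np.int16)
        self.split = np.asarray(self.split, dtype=np.int8)
        if self.provenance is None:
            self.provenance = np.zeros(len(self.labels), dtype=np.int8)
        self.provenance = np.asarray(self.provenance, dtype=np.int8)
        n = self.windows.shape[0]
        for name, arr in (("labels", self.labels),
                          ("participant_ids", self.participant_ids),
                          ("split", self.split),
                          ("provenance", self.provenance)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must align with the window axis")

    def __len__(self):
        return self.windows.shape[0]

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(self.windows[mask], self.labels[mask],
                         self.participant_ids[mask], self.split[mask],
                         self.provenance[mask])

    def split_subset(self, name: str) -> "WindowSet":
        return self.subset(self.split == SPLIT_CODES[name])

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        return WindowSet(
            np.concatenate([s.windows for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.participant_ids for s in sets]),
            np.concatenate([s.split for s in sets]),
            np.concatenate([s.provenance for s in sets]))


@dataclass(frozen=True)
class BudgetReport:
    """All sample/window counts implied by a protocol configuration."""

    stacked_real_samples_positive: int
    stacked_real_samples_negative: int
    stacked_real_samples_neutral: int
    target_samples_after_gan: int
    n_windows_per_participant: int
    n_sets_per_class: int
    n_sets_total: int
    n_train: int
    n_val: int
    n_test: int

    def as_dict(self) -> dict:
        return asdict(self)


class ChannelLookupError(KeyError):
    pass


def select_channels(session: EmotionSession, names) -> EmotionSession:
    """Restrict/reorder channels; annotations are untouched."""
    names = list(names)
    index = {c: i for i, c in enumerate(session.channels)}
    missing = [n for n in names if n not in index]
    if missing:
        raise ChannelLookupError(
            f"channel(s) not present in session: {', '.join(missing)}")
    rows = [index[n] for n in names]
    return EmotionSession(session.signal[rows], session.fs,
                          list(session.annotations), session.participant_id,
                          tuple(names))


def extract_mid_window(interval_signal: np.ndarray, fs: float,
                       keep_s: float = 20.0) -> np.ndarray:
    """Centered ``keep_s`` seconds of an interval; offset = floor((L-keep)/2)."""
    keep = int(round(keep_s * fs))
    L = interval_signal.shape[-1]
    if L < keep:
        raise ValueError(f"interval of {L} samples shorter than {keep}")
    start = (L - keep) // 2
    return interval_signal[..., start:start + keep]


def stack_class(segments, label: str, participant_id: int = 0,
                ) -> StackedClassSignal:
    """Concatenate same-emotion segments along time, in the given order."""
    segments = [np.asarray(s) for s in segments]
    if not segments:
        raise ValueError("no segments to stack")
    n_ch = segments[0].shape[0]
    for s in segments:
        if s.ndim != 2 or s.shape[0] != n_ch:
            raise ValueError("all segments must share the channel count")
    return StackedClassSignal(np.concatenate(segments, axis=1), label,
                              participant_id)


def window(signal: StackedClassSignal, size: int = 125, stride: int = 125,
           ) -> WindowSet:
    """Cut into fixed windows; n = floor((T - size)/stride) + 1, else 0."""
    if size <= 0 or stride <= 0:
        raise ValueError("size and stride must be positive")
    x = signal.signal
    n_ch, T = x.shape
    n = (T - size) // stride + 1 if T >= size else 0
    wins = np.empty((n, n_ch, size), dtype=np.float32)
    prov = np.zeros(n, dtype=np.int8)
    gan_ranges = [(s, e) for s, e, tag in signal.provenance if tag == "gan"]
    for i in range(n):
        s = i * stride
        wins[i] = x[:, s:s + size]
        if any(s < ge and gs < s + size for gs, ge in gan_ranges):
            prov[i] = 1
    code = LABEL_CODES[signal.label]
    return WindowSet(wins, np.full(n, code, dtype=np.int8),
                     np.full(n, signal.participant_id, dtype=np.int16),
                     np.zeros(n, dtype=np.int8), prov)


def compute_budget(protocol: ProtocolConfig,
                   window_cfg: WindowConfig = WindowConfig(),
                   ratios=(0.7, 0.2, 0.1)) -> BudgetReport:
    """All bookkeeping counts, from configuration arithmetic alone.

    Defaults reproduce the study's printed numbers: 50,000 stacked real
    samples per valence class (5 songs x 20 s x 500 Hz), 25,000 neutral
    (5 retained silences x 10 s x 500 Hz), 125,000 per class after GAN
    augmentation, 1000 windows per participant per class, 20,000 sets per
    class, 60,000 total, split 42,000 / 12,000 / 6,000.
    """
    fs = protocol.fs
    n_val = protocol.n_songs_per_valence
    stacked_valence = int(n_val * round(window_cfg.keep_s * fs))
    # neutral: the silences after the first n_songs_per_valence songs, in full
    stacked_neutral = int(n_val * round(protocol.silence_duration_s * fs))
    target = window_cfg.target_samples_per_class
    if n_val == 0:
        return BudgetReport(0, 0, 0, 0, 0, 0, 0, 0, 0, 0)
    nw = ((target - window_cfg.size) // window_cfg.stride + 1
          if target >= window_cfg.size else 0)
    n_classes = 3
    per_class = nw * protocol.n_participants
    total = per_class * n_classes
    # per-stratum split counts (round val/test, remainder to train)
    v = int(round(ratios[1] * nw))
    t = int(round(ratios[2] * nw))
    tr = nw - v - t
    scale = protocol.n_participants * n_classes
    return BudgetReport(stacked_valence, stacked_valence, stacked_neutral,
                        target, nw, per_class, total,
                        tr * scale, v * scale, t * scale)


def make_splits(windows: WindowSet, ratios=(0.7, 0.2, 0.1), seed: int = 0,
                ) -> WindowSet:
    """Assign train/val/test per (participant, class) stratum.

    Within each stratum the windows are permuted with a seeded RNG; val and
    test take round(ratio * n) windows each and train takes the remainder.
    """
    ratios = tuple(float(r) for r in ratios)
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    split = np.zeros(len(windows), dtype=np.int8)
    rng = np.random.default_rng(seed)
    for pid in np.unique(windows.participant_ids):
        for lab in np.unique(windows.labels):
            idx = np.flatnonzero((windows.participant_ids == pid)
                                 & (windows.labels == lab))
            if idx.size == 0:
                continue
            n = idx.size
            n_v = int(round(ratios[1] * n))
            n_t = int(round(ratios[2] * n))
            perm = rng.permutation(idx)
            split[perm[:n - n_v - n_t]] = SPLIT_CODES["train"]
            split[perm[n - n_v - n_t:n - n_t]] = SPLIT_CODES["val"]
            split[perm[n - n_t:]] = SPLIT_CODES["test"]
    return WindowSet(windows.windows, windows.labels, windows.participant_ids,
                     split, windows.provenance)


def sessions_to_windows(sessions, window_cfg: WindowConfig = WindowConfig(),
                        channels=("C3", "C4", "Pz"), ratios=(0.7, 0.2, 0.1),
                        seed: int = 0, truncate_to_target: bool = False,
                        ) -> WindowSet:
    """Full real-data chain: channels -> mid-song 20 s -> stack -> window.

    Neutral keeps the silences following the first half of the songs, in
    full (their total matches the valence classes' 20-s economy at the
    default protocol).  With ``truncate_to_target`` the stacked signal is
    clipped to ``target_samples_per_class`` (used after GAN augmentation).
    """
    parts = []
    for sess in sessions:
        sess = select_channels(sess, channels)
        segs = {"positive": [], "negative": [], "neutral": []}
        n_silence_keep = sum(1 for a in sess.annotations
                             if a.label != "neutral") // 2
        silence_i = 0
        for a, sig in sess.intervals():
            if a.label == "neutral":
                if silence_i < n_silence_keep:
                    segs["neutral"].append(sig)
                silence_i += 1
            else:
                segs[a.label].append(
                    extract_mid_window(sig, sess.fs, window_cfg.keep_s))
        for label, seglist in segs.items():
            if not seglist:
                continue
            stacked = stack_class(seglist, label, sess.participant_id)
            if truncate_to_target:
                tgt = window_cfg.target_samples_per_class
                stacked = StackedClassSignal(
                    stacked.signal[:, :tgt], label, sess.participant_id)
            parts.append(window(stacked, window_cfg.size, window_cfg.stride))
    out = WindowSet.concatenate(parts)
    return make_splits(out, ratios, seed)


# ---------------------------------------------------------------------------
# persistence

def save_windowset_hdf5(ws: WindowSet, path, manifest: dict | None = None):
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=ws.windows.astype(np.float32))
        f.create_dataset("labels", data=ws.labels)
        f.create_dataset("participant_ids", data=ws.participant_ids)
        f.create_dataset("split", data=ws.split)
        f.create_dataset("provenance", data=ws.provenance)
        if manifest:
            f.attrs["manifest"] = json.dumps(manifest)


def load_windowset_hdf5(path) -> WindowSet:
    import h5py
    with h5py.File(path, "r") as f:
        return WindowSet(f["windows"][...], f["labels"][...],
                         f["participant_ids"][...], f["split"][...],
                         f["provenance"][...])
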