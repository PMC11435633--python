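"""Seeded synthetic EEG sessions emulating a music-stimulus emotion protocol.

The study protocol this module reproduces: a participant listens to ten
one-minute music pieces (five inducing positive, five negative valence) with a
10-second silence after each, recorded at 500 Hz on channels C3, C4 and Pz.
Song intervals are labelled with their valence; silences are labelled neutral.

Signals are sums of band-limited sinusoids (random frequencies and phases
within each canonical EEG band) plus white Gaussian noise.  Per-class band
weights encode the spectral signatures reported for music-evoked emotions:
frontal alpha asymmetry between left (C3) and right (C4) sites, and
beta-2 / beta-3 / gamma power shifts between positive and negative states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "BANDS", "CHANNELS", "SONG_SEQUENCE", "SONG_TITLES",
    "ProtocolConfig", "ClassSpectrumSpec", "Annotation", "EmotionSession",
    "default_class_spectra", "generate_session", "generate_cohort",
    "save_session_npz", "load_session_npz", "save_session_hdf5",
    "load_session_hdf5", "load_session_edf",
]

#: canonical EEG frequency bands (Hz), inclusive lower / exclusive upper
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta2": (18.0, 22.0),
    "beta3": (22.0, 30.0),
    "gamma": (30.0, 45.0),
}

CHANNELS = ("C3", "C4", "Pz")

#: valence order of the ten pieces as played (5 negative, 5 positive)
SONG_SEQUENCE = ("negative", "positive", "negative", "positive", "positive",
                 "negative", "negative", "positive", "negative", "positive")

#: piece titles, metadata only
SONG_TITLES = (
    "Pishdaramd Esfehani", "Azari 6 and 8", "Pishdaramd Homayoun",
    "Azari 6 and 8", "Bandari 6 and 8", "Afshari", "Pishdaramd Esfehani",
    "Persion 6 and 8", "Pishdaramad Dashti", "Bandari 6 and 8",
)

LABELS = ("negative", "neutral", "positive")
LABEL_CODES = {"negative": 0, "neutral": 1, "positive": 2}


class ConfigurationError(ValueError):
    """Invalid protocol or spectrum configuration."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and montage of one recording session."""

    n_songs_per_valence: int = 5
    song_duration_s: float = 60.0
    silence_duration_s: float = 10.0
    fs: float = 500.0
    channels: tuple[str, ...] = CHANNELS
    n_participants: int = 20

    def __post_init__(self):
        if self.song_duration_s <= 0 or self.silence_duration_s <= 0:
            raise ConfigurationError("durations must be positive")
        if self.fs <= 0:
            raise ConfigurationError("sampling frequency must be positive")
        if self.n_songs_per_valence < 0:
            raise ConfigurationError("n_songs_per_valence must be >= 0")
        if len(self.channels) == 0 or len(set(self.channels)) != len(self.channels):
            raise ConfigurationError("channel list must be non-empty and unique")

    @property
    def n_songs(self) -> int:
        return 2 * self.n_songs_per_valence

    @property
    def song_samples(self) -> int:
        return int(round(self.song_duration_s * self.fs))

    @property
    def silence_samples(self) -> int:
        return int(round(self.silence_duration_s * self.fs))

    @property
    def total_samples(self) -> int:
        return self.n_songs * (self.song_samples + self.silence_samples)


@dataclass(frozen=True)
class ClassSpectrumSpec:
    """Per-emotion relative band-power weights per channel.

    ``weights[label][band]`` is a tuple of one nonnegative weight per channel;
    a sinusoid cluster in that band is scaled by ``amplitude * weight``.
    """

    weights: dict = field(default_factory=lambda: default_class_spectra())
    noise_std: float = 2.0          # microvolts
    amplitude: float = 10.0         # microvolt baseline per unit weight
    n_freqs_per_band: int = 8
    seed: int = 0

    def __post_init__(self):
        for label, bands in self.weights.items():
            if label not in LABELS:
                raise ConfigurationError(f"unknown emotion label {label!r}")
            total = 0.0
            for band, w in bands.items():
                if band not in BANDS:
                    raise ConfigurationError(f"unknown band {band!r}")
                if np.any(np.asarray(w) < 0):
                    raise ConfigurationError("band weights must be >= 0")
                total += float(np.sum(w))
            if total <= 0:
                raise ConfigurationError(
                    f"emotion {label!r} needs at least one positive band weight")
        if self.noise_std < 0:
            raise ConfigurationError("noise_std must be >= 0")


def default_class_spectra() -> dict:
    """Default band weights (C3, C4, Pz) for the three emotion classes.

    Positive valence: left-dominant alpha (stronger at C3), suppressed
    beta-2/beta-3/gamma.  Negative valence: right-dominant alpha, elevated
    beta-2/beta-3/gamma.  Neutral rest: theta-dominant with symmetric alpha.
    """
    return {
        "positive": {
            "theta": (0.3, 0.3, 0.3),
            "alpha": (1.2, 0.5, 0.8),
            "beta2": (0.2, 0.2, 0.2),
            "beta3": (0.15, 0.15, 0.15),
            "gamma": (0.1, 0.1, 0.1),
        },
        "negative": {
            "theta": (0.3, 0.3, 0.3),
            "alpha": (0.5, 1.2, 0.8),
            "beta2": (0.8, 0.8, 0.6),
            "beta3": (0.7, 0.7, 0.5),
            "gamma": (0.5, 0.5, 0.4),
        },
        "neutral": {
            "theta": (1.0, 1.0, 1.0),
            "alpha": (0.7, 0.7, 0.7),
            "beta2": (0.3, 0.3, 0.3),
            "beta3": (0.25, 0.25, 0.25),
            "gamma": (0.15, 0.15, 0.15),
        },
    }


@dataclass(frozen=True)
class Annotation:
    """Labelled half-open sample interval [start, end)."""

    label: str
    start: int
    end: int
    piece_index: int        # song index for songs, -1-based mirror for silences

    def __post_init__(self):
        if self.label not in LABELS:
            raise ConfigurationError(f"unknown label {self.label!r}")
        if not 0 <= self.start < self.end:
            raise ConfigurationError("annotation interval must be non-empty")


@dataclass
class EmotionSession:
    """One participant's annotated multichannel recording (microvolts)."""

    signal: np.ndarray           # [n_channels, n_samples]
    fs: float
    annotations: list[Annotation]
    participant_id: int
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ConfigurationError("signal must be [channels, samples]")
        prev_end = 0
        for a in self.annotations:
            if a.start != prev_end:
                raise ConfigurationError(
                    f"annotations must tile the session; gap/overlap at {a.start}")
            prev_end = a.end
        if self.annotations and prev_end != self.signal.shape[1]:
            raise ConfigurationError("annotations must cover the full session")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def intervals(self, label: str | None = None):
        """Yield (annotation, signal slice) pairs, optionally filtered."""
        for a in self.annotations:
            if label is None or a.label == label:
                yield a, self.signal[:, a.start:a.end]


def _interval_rng(seed: int, participant_id: int, interval_index: int,
                  ) -> np.random.Generator:
    # independent stream per (participant, interval); stable under reordering
    ss = np.random.SeedSequence([seed, participant_id, interval_index])
    return np.random.default_rng(ss)


def _band_signal(rng: np.random.Generator, band: tuple[float, float],
                 n_samples: int, fs: float, n_freqs: int) -> np.ndarray:
    lo, hi = band
    freqs = rng.uniform(lo, hi, size=n_freqs)
    phases = rng.uniform(0.0, 2 * np.pi, size=n_freqs)
    t = np.arange(n_samples) / fs
    # 1/sqrt(n) keeps total band power independent of the cluster size
    return (np.sin(2 * np.pi * freqs[:, None] * t[None, :]
                   + phases[:, None]).sum(axis=0) / np.sqrt(n_freqs))


def _synth_interval(rng: np.random.Generator, label: str,
                    spectra: ClassSpectrumSpec, n_samples: int, fs: float,
                    n_channels: int) -> np.ndarray:
    out = np.zeros((n_channels, n_samples))
    weights = spectra.weights[label]
    for band_name, w in weights.items():
        w = np.broadcast_to(np.asarray(w, dtype=float), (n_channels,))
        if not np.any(w > 0):
            continue
        base = _band_signal(rng, BANDS[band_name], n_samples, fs,
                            spectra.n_freqs_per_band)
        out += spectra.amplitude * w[:, None] * base[None, :]
    if spectra.noise_std > 0:
        out += rng.normal(0.0, spectra.noise_std, size=out.shape)
    return out


def generate_session(protocol: ProtocolConfig, spectra: ClassSpectrumSpec,
                     participant_id: int = 0) -> EmotionSession:
    """Synthesize one annotated session following the play sequence.

    The ten pieces follow the played order (negative, positive, negative,
    positive, positive, negative, negative, positive, negative, positive for
    the default five-per-valence protocol), each followed by one silence.
    """
    n_songs = protocol.n_songs
    if n_songs == len(SONG_SEQUENCE):
        sequence = SONG_SEQUENCE
    else:  # non-default song count: simple alternation keeps the balance
        sequence = tuple(
            "negative" if i % 2 == 0 else "positive" for i in range(n_songs))

    n_ch = len(protocol.channels)
    signal = np.empty((n_ch, protocol.total_samples))
    annotations: list[Annotation] = []
    cursor = 0
    interval_index = 0
    for song_i, valence in enumerate(sequence):
        for label, n in ((valence, protocol.song_samples),
                         ("neutral", protocol.silence_samples)):
            rng = _interval_rng(spectra.seed, participant_id, interval_index)
            signal[:, cursor:cursor + n] = _synth_interval(
                rng, label, spectra, n, protocol.fs, n_ch)
            annotations.append(Annotation(label, cursor, cursor + n, song_i))
            cursor += n
            interval_index += 1
    return EmotionSession(signal, protocol.fs, annotations, participant_id,
                          channels=tuple(protocol.channels))


def generate_cohort(protocol: ProtocolConfig, spectra: ClassSpectrumSpec,
                    n_participants: int | None = None) -> list[EmotionSession]:
    """Generate ``n_participants`` sessions with ids 0..n-1.

    Per-participant randomness derives from the base seed and the participant
    id, so a cohort is reproducible participant-wise regardless of order.
    """
    n = protocol.n_participants if n_participants is None else n_participants
    if n < 1:
        raise ConfigurationError("n_participants must be >= 1")
    return [generate_session(protocol, spectra, participant_id=i)
            for i in range(n)]


# ---------------------------------------------------------------------------
# persistence

def _annotations_to_array(annotations) -> np.ndarray:
    dt = np.dtype([("label", "U16"), ("start", "i8"), ("end", "i8"),
                   ("piece_index", "i8")])
    return np.array([(a.label, a.start, a.end, a.piece_index)
                     for a in annotations], dtype=dt)


def _annotations_from_array(arr) -> list[Annotation]:
    return [Annotation(str(r["label"]), int(r["start"]), int(r["end"]),
                       int(r["piece_index"])) for r in arr]


def save_session_npz(session: EmotionSession, path):
    with open(path, "wb") as f:   # keep the exact filename (no .npz suffix)
        np.savez(f, signal=session.signal, fs=session.fs,
                 annotations=_annotations_to_array(session.annotations),
                 participant_id=session.participant_id,
                 channels=np.array(session.channels))


def load_session_npz(path) -> EmotionSession:
    with np.load(path, allow_pickle=False) as f:
        return EmotionSession(
            f["signal"], float(f["fs"]),
            _annotations_from_array(f["annotations"]),
            int(f["participant_id"]), tuple(str(c) for c in f["channels"]))


def save_session_hdf5(session: EmotionSession, path):
    import h5py
    ann = np.rec.fromarrays(
        [np.array([a.label.encode() for a in session.annotations], dtype="S16"),
         np.array([a.start for a in session.annotations], dtype="i8"),
         np.array([a.end for a in session.annotations], dtype="i8"),
         np.array([a.piece_index for a in session.annotations], dtype="i8")],
        names="label,start,end,piece_index")
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=session.signal)
        f.attrs["fs"] = session.fs
        f.attrs["participant_id"] = session.participant_id
        f.attrs["channels"] = json.dumps(list(session.channels))
        f.create_dataset("annotations", data=ann)


def load_session_hdf5(path) -> EmotionSession:
    import h5py
    with h5py.File(path, "r") as f:
        ann = [Annotation(r["label"].decode(), int(r["start"]), int(r["end"]),
                          int(r["piece_index"])) for r in f["annotations"][...]]
        return EmotionSession(
            f["signal"][...], float(f.attrs["fs"]), ann,
            int(f.attrs["participant_id"]),
            tuple(json.loads(f.attrs["channels"])))


def load_session_edf(path, annotations: list[Annotation],
                     participant_id: int = 0) -> EmotionSession:
    """Read a real recording from EDF (requires mne); annotations supplied
    separately since stimulus timing is not stored in the EDF."""
    import mne
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EmotionSession(raw.get_data() * 1e6, float(raw.info["sfreq"]),
                          annotations, participant_id,
                          tuple(raw.ch_names))
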