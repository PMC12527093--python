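"""Sleep-EDF-style I/O: PSG + hypnogram pairs, stage vocabulary, HDF5 bundles.

Reads EDF/EDF+ polysomnography through :mod:`mne` and expands hypnogram
annotations (R&K vocabulary, 30 s scoring intervals) to one label per epoch.
R&K stages 3 and 4 are merged into AASM N3; MOVEMENT/UNKNOWN epochs are
flagged for removal.  Preprocessed scalogram epochs round-trip through an HDF5
bundle (datasets ``tfr`` [N,3,T,S], ``label`` [N], ``subject`` [N]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "StageLabel",
    "RawRecording",
    "EPOCH_SECONDS",
    "read_sleepedf_pair",
    "map_stages_rk_to_aasm",
    "save_tfr_dataset",
    "load_tfr_dataset",
]

EPOCH_SECONDS = 30


class StageLabel(IntEnum):
    """AASM 5-stage encoding.

    The order W=0, N1=1, N2=2, N3=3, REM=4 is fixed package-wide; every
    confusion matrix and class-weight vector uses it.
    """

    W = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4


@dataclass
class RawRecording:
    """Multichannel PSG signals plus 30 s hypnogram labels for one night.

    ``stages`` keeps the raw annotation vocabulary (e.g. ``"Sleep stage 4"``);
    AASM mapping happens explicitly via :func:`map_stages_rk_to_aasm`.
    """

    subject_id: str
    channel_names: list
    signals: np.ndarray  # [C, L], physical units (microvolt for Sleep-EDF)
    fs: float
    stages: list

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be [channels, samples]")
        if len(self.channel_names) != self.signals.shape[0]:
            raise ValueError("channel_names and signals disagree on channel count")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        max_epochs = self.n_samples // int(EPOCH_SECONDS * self.fs)
        if len(self.stages) > max_epochs:
            raise ValueError(
                f"{len(self.stages)} stage labels but signal only spans "
                f"{max_epochs} whole 30 s epochs")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


# ---------------------------------------------------------------------------
# R&K -> AASM stage vocabulary
# ---------------------------------------------------------------------------

# canonical Sleep-EDF spellings plus common bare forms; None = drop epoch
_RK_VOCAB = {
    "sleep stage w": (StageLabel.W, True),
    "sleep stage 1": (StageLabel.N1, True),
    "sleep stage 2": (StageLabel.N2, True),
    "sleep stage 3": (StageLabel.N3, True),
    "sleep stage 4": (StageLabel.N3, True),  # R&K stage 4 merges into N3
    "sleep stage r": (StageLabel.REM, True),
    "sleep stage ?": (None, False),
    "movement time": (None, False),
    "w": (StageLabel.W, True),
    "1": (StageLabel.N1, True),
    "2": (StageLabel.N2, True),
    "3": (StageLabel.N3, True),
    "4": (StageLabel.N3, True),
    "r": (StageLabel.REM, True),
    "rem": (StageLabel.REM, True),
    "movement": (None, False),
    "unknown": (None, False),
    "?": (None, False),
}


def map_stages_rk_to_aasm(raw_stages) -> tuple[np.ndarray, np.ndarray]:
    """Map R&K annotation strings to AASM labels and a keep mask.

    Returns ``(labels, keep_mask)`` where ``labels[i]`` is the integer
    :class:`StageLabel` (−1 where dropped) and ``keep_mask[i]`` is False for
    MOVEMENT/UNKNOWN epochs.  Unknown vocabulary raises; nothing is silently
    dropped.
    """
    labels = np.empty(len(raw_stages), dtype=np.int64)
    keep = np.empty(len(raw_stages), dtype=bool)
    for i, raw in enumerate(raw_stages):
        key = str(raw).strip().lower()
        if key not in _RK_VOCAB:
            raise ValueError(
                f"unknown stage annotation {raw!r}; expected R&K vocabulary "
                "(W, 1-4, R, MOVEMENT, UNKNOWN or Sleep-EDF spellings)")
        stage, kept = _RK_VOCAB[key]
        labels[i] = int(stage) if stage is not None else -1
        keep[i] = kept
    return labels, keep


# ---------------------------------------------------------------------------
# EDF reading
# ---------------------------------------------------------------------------


def _read_edf_signal_headers(path) -> list[dict]:
    """Parse the per-signal EDF header fields (labels, rates) for validation."""
    with open(path, "rb") as f:
        header = f.read(256)
        n_signals = int(header[252:256].decode("ascii").strip())
        duration = float(header[244:252].decode("ascii").strip())
        sig = f.read(256 * n_signals)

    def field(offset, width):
        start = offset * n_signals
        return [sig[start + i * width:start + (i + 1) * width].decode("ascii").strip()
                for i in range(n_signals)]

    labels = field(0, 16)
    # offsets within the signal header block, in bytes per field
    start = (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80) * n_signals
    samples = [int(sig[start + i * 8:start + (i + 1) * 8].decode("ascii").strip())
               for i in range(n_signals)]
    return [
        {"label": lab, "fs": (n / duration if duration > 0 else 0.0)}
        for lab, n in zip(labels, samples)
    ]


def read_sleepedf_pair(psg_path, hyp_path, channel_names) -> RawRecording:
    """Read a PSG EDF plus hypnogram EDF+ into a :class:`RawRecording`.

    ``channel_names`` selects (and orders) the channels, e.g.
    ``["EEG Fpz-Cz", "EEG Pz-Oz", "EOG horizontal"]``.  Stage annotations are
    expanded to one label per 30 s interval and truncated to the annotated
    span of the signal.
    """
    import mne

    psg_path, hyp_path = Path(psg_path), Path(hyp_path)
    for p in (psg_path, hyp_path):
        if not p.exists():
            raise FileNotFoundError(p)

    headers = _read_edf_signal_headers(psg_path)
    available = [h["label"] for h in headers]
    rates = {}
    for name in channel_names:
        matches = [h for h in headers if h["label"] == name]
        if not matches:
            raise ValueError(
                f"channel {name!r} not found in {psg_path.name}; "
                f"available channels: {available}")
        rates[name] = matches[0]["fs"]
    if len(set(rates.values())) != 1:
        raise ValueError(f"sampling-rate mismatch across requested channels: {rates}")
    fs = float(next(iter(rates.values())))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(psg_path, include=list(channel_names),
                                  preload=True, verbose="error")
    raw.reorder_channels(list(channel_names))
    signals = raw.get_data(units="uV")

    annotations = mne.read_annotations(hyp_path)
    n_max = signals.shape[1] // int(EPOCH_SECONDS * fs)
    stages: list = [None] * n_max
    for onset, duration, desc in zip(annotations.onset, annotations.duration,
                                     annotations.description):
        first = int(round(onset / EPOCH_SECONDS))
        count = int(round(duration / EPOCH_SECONDS))
        if onset % EPOCH_SECONDS or (duration % EPOCH_SECONDS and count):
            raise ValueError(
                f"annotation {desc!r} at onset {onset}s/duration {duration}s "
                "is not aligned to the 30 s scoring grid")
        for k in range(first, min(first + count, n_max)):
            stages[k] = desc
    while stages and stages[-1] is None:
        stages.pop()
    if any(s is None for s in stages):
        gap = stages.index(None)
        raise ValueError(f"hypnogram leaves epoch {gap} unannotated")

    return RawRecording(
        subject_id=psg_path.stem,
        channel_names=list(channel_names),
        signals=signals,
        fs=fs,
        stages=stages,
    )


# ---------------------------------------------------------------------------
# HDF5 scalogram bundles
# ---------------------------------------------------------------------------


def save_tfr_dataset(path, tfr: np.ndarray, labels: np.ndarray, subjects,
                     config=None) -> None:
    """Persist preprocessed epochs: ``tfr`` [N,C,T,S], ``label`` [N], ``subject`` [N]."""
    tfr = np.asarray(tfr, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    if tfr.shape[0] != labels.shape[0] or tfr.shape[0] != len(subjects):
        raise ValueError("tfr, label and subject lengths disagree")
    with h5py.File(path, "w") as f:
        f.create_dataset("tfr", data=tfr)
        f.create_dataset("label", data=labels)
        f.create_dataset("subject", data=np.asarray(
            [str(s) for s in subjects], dtype="S32"))
        if config is not None:
            f.attrs["omega0"] = float(config.omega0)
            f.attrs["scales"] = np.asarray(config.scales, dtype=np.int64)
            f.attrs["target_T"] = int(config.target_T)
            f.attrs["epoch_seconds"] = int(config.epoch_seconds)
            f.attrs["fs"] = float(config.fs)


def load_tfr_dataset(path):
    """Load an HDF5 bundle; returns (tfr, labels, subjects, config-or-None)."""
    from .tfr import ScalogramConfig

    with h5py.File(path, "r") as f:
        tfr = f["tfr"][...]
        labels = f["label"][...]
        subjects = np.array([s.decode() for s in f["subject"][...]])
        config = None
        if "omega0" in f.attrs:
            config = ScalogramConfig(
                omega0=float(f.attrs["omega0"]),
                scales=tuple(int(a) for a in f.attrs["scales"]),
                target_T=int(f.attrs["target_T"]),
                epoch_seconds=int(f.attrs["epoch_seconds"]),
                fs=float(f.attrs["fs"]),
            )
    return tfr, labels, subjects, config
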