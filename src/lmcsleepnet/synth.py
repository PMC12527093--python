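"""Synthetic 3-channel PSG with stage-dependent spectral signatures.

The generator emulates just enough Sleep-EDF structure to exercise the whole
pipeline without a download: three synchronized 100 Hz channels (two "EEG",
one "EOG"), 30 s epochs whose spectral content follows the textbook stage
signatures, and hypnograms with run structure (stages persist for several
epochs, as real hypnograms do).  Defaults:

* W   — continuous 8-12 Hz alpha plus frequent EOG deflections;
* N1  — low-amplitude 4-7 Hz theta;
* N2  — theta background plus 12-14 Hz spindle bursts of 0.5-1 s;
* N3  — high-amplitude 0.5-2 Hz delta;
* REM — mixed 4-8 Hz theta with large slow deflections on the EOG channel.

Stage proportions default to the SleepEDF-20 distribution
(W 21.1%, N1 6.5%, N2 41.3%, N3 13.2%, REM 17.9%).  Amplitudes are arbitrary
units — downstream normalisation removes absolute scale.  This is a test
fixture, not a neurophysiological simulation: there is no 1/f background,
no K-complex morphology, no arousals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_edf import RawRecording, StageLabel

__all__ = [
    "OscComponent",
    "StageSpectralProfile",
    "DEFAULT_PROFILES",
    "SLEEPEDF20_PROPORTIONS",
    "SyntheticDataset",
    "synth_epoch",
    "synth_stage_sequence",
    "synth_dataset",
    "synth_scalogram_arrays",
    "write_edf",
    "write_hypnogram_edf",
]

CHANNEL_NAMES = ["EEG Fpz-Cz", "EEG Pz-Oz", "EOG horizontal"]

SLEEPEDF20_PROPORTIONS = {
    StageLabel.W: 0.211,
    StageLabel.N1: 0.065,
    StageLabel.N2: 0.413,
    StageLabel.N3: 0.132,
    StageLabel.REM: 0.179,
}


@dataclass(frozen=True)
class OscComponent:
    """One oscillatory ingredient: center frequency (Hz), amplitude (a.u.),
    and burst duty-cycle (fraction of the epoch the oscillation is active;
    1.0 = continuous)."""

    freq_hz: float
    amplitude: float
    duty: float = 1.0


@dataclass(frozen=True)
class StageSpectralProfile:
    components: tuple
    noise_sd: float
    eog_event_rate: float = 0.0   # expected deflections per 30 s epoch
    eog_event_amp: float = 0.0
    eog_event_freq: float = 0.5   # deflection shape: one raised-cosine cycle


DEFAULT_PROFILES = {
    StageLabel.W: StageSpectralProfile(
        components=(OscComponent(10.0, 1.0),),
        noise_sd=0.5, eog_event_rate=4.0, eog_event_amp=2.0, eog_event_freq=1.0),
    StageLabel.N1: StageSpectralProfile(
        components=(OscComponent(5.5, 0.6),),
        noise_sd=0.4, eog_event_rate=0.5, eog_event_amp=0.8, eog_event_freq=0.4),
    StageLabel.N2: StageSpectralProfile(
        components=(OscComponent(5.5, 0.5), OscComponent(13.0, 1.3, duty=0.15)),
        noise_sd=0.4),
    StageLabel.N3: StageSpectralProfile(
        components=(OscComponent(1.2, 2.2),),
        noise_sd=0.5),
    StageLabel.REM: StageSpectralProfile(
        components=(OscComponent(6.0, 0.8),),
        noise_sd=0.4, eog_event_rate=3.0, eog_event_amp=3.0, eog_event_freq=0.4),
}

# annotation spellings used when exporting hypnograms; N3 epochs alternate
# between the two R&K deep-sleep spellings to exercise the 3+4 -> N3 merge
_STAGE_TEXT = {
    StageLabel.W: "Sleep stage W",
    StageLabel.N1: "Sleep stage 1",
    StageLabel.N2: "Sleep stage 2",
    StageLabel.REM: "Sleep stage R",
}


@dataclass
class SyntheticDataset:
    recordings: list
    proportions: dict
    seed: int

    @property
    def n_epochs(self) -> int:
        return sum(len(r.stages) for r in self.recordings)


# ---------------------------------------------------------------------------
# epoch synthesis
# ---------------------------------------------------------------------------


def _burst_mask(n: int, fs: float, duty: float, rng: np.random.Generator) -> np.ndarray:
    """0/1 gate covering ~``duty`` of the epoch in 0.5-1 s bursts."""
    mask = np.zeros(n)
    target = duty * n
    covered = 0.0
    guard = 0
    while covered < target and guard < 100:
        length = int(rng.uniform(0.5, 1.0) * fs)
        start = rng.integers(0, max(1, n - length))
        mask[start:start + length] = 1.0
        covered = mask.sum()
        guard += 1
    return mask


def _eog_events(n: int, fs: float, rate: float, amp: float, freq: float,
                rng: np.random.Generator) -> np.ndarray:
    """Sum of raised-cosine deflections (random sign), ~Poisson(rate) per epoch."""
    out = np.zeros(n)
    for _ in range(rng.poisson(rate)):
        length = int(fs / freq)
        start = rng.integers(0, max(1, n - length))
        t = np.arange(min(length, n - start))
        out[start:start + len(t)] += (rng.choice([-1.0, 1.0]) * amp
                                      * 0.5 * (1 - np.cos(2 * np.pi * t / length)))
    return out


def synth_epoch(stage: StageLabel, profile: StageSpectralProfile | None = None,
                fs: float = 100.0, rng: np.random.Generator | None = None) -> np.ndarray:
    """One 30 s epoch as a [3, 30*fs] array (EEG Fpz-Cz, EEG Pz-Oz, EOG)."""
    profile = profile or DEFAULT_PROFILES[StageLabel(stage)]
    rng = rng if rng is not None else np.random.default_rng(0)
    n = int(30 * fs)
    t = np.arange(n) / fs
    for comp in profile.components:
        if comp.freq_hz >= fs / 2:
            raise ValueError(
                f"component frequency {comp.freq_hz} Hz >= Nyquist {fs / 2} Hz")

    channels = []
    for gain in (1.0, 0.8):  # the two EEG derivations differ only in gain
        sig = np.zeros(n)
        for comp in profile.components:
            f = comp.freq_hz * (1.0 + rng.normal(0, 0.03))
            phase = rng.uniform(0, 2 * np.pi)
            wave = comp.amplitude * np.sin(2 * np.pi * f * t + phase)
            if comp.duty < 1.0:
                wave = wave * _burst_mask(n, fs, comp.duty, rng)
            sig += wave
        sig += rng.normal(0, profile.noise_sd, n)
        channels.append(gain * sig)

    eog = 0.3 * channels[0] + rng.normal(0, profile.noise_sd, n)
    if profile.eog_event_rate > 0:
        eog = eog + _eog_events(n, fs, profile.eog_event_rate,
                                profile.eog_event_amp, profile.eog_event_freq, rng)
    channels.append(eog)
    return np.stack(channels)


# ---------------------------------------------------------------------------
# stage sequences and datasets
# ---------------------------------------------------------------------------


def synth_stage_sequence(n_epochs: int, proportions: dict, persistence: float,
                         rng: np.random.Generator) -> list:
    """A stage sequence with run structure and near-exact class proportions.

    Per-stage quotas are fixed to round(p * n) (so realized proportions match
    the request to within rounding), then spent in geometric runs with mean
    length 1/(1 - persistence), emulating hypnogram persistence.
    """
    stages = list(proportions)
    quotas = {s: int(round(proportions[s] * n_epochs)) for s in stages}
    while sum(quotas.values()) < n_epochs:
        quotas[max(stages, key=lambda s: proportions[s])] += 1
    while sum(quotas.values()) > n_epochs:
        quotas[max(stages, key=lambda s: quotas[s])] -= 1
    seq: list = []
    prev = None
    while len(seq) < n_epochs:
        remaining = [s for s in stages if quotas[s] > 0]
        if len(remaining) > 1 and prev is not None and prev in remaining:
            candidates = [s for s in remaining if s != prev]
        else:
            candidates = remaining
        weights = np.array([quotas[s] for s in candidates], dtype=float)
        stage = candidates[rng.choice(len(candidates), p=weights / weights.sum())]
        run = min(1 + rng.geometric(1.0 - persistence), quotas[stage],
                  n_epochs - len(seq))
        seq.extend([stage] * run)
        quotas[stage] -= run
        prev = stage
    return seq


def _stage_text(stage: StageLabel, epoch_index: int) -> str:
    if stage == StageLabel.N3:
        return "Sleep stage 3" if epoch_index % 2 == 0 else "Sleep stage 4"
    return _STAGE_TEXT[stage]


def synth_dataset(n_subjects: int = 20, epochs_per_subject: int = 400,
                  proportions: dict | None = None, seed: int = 0,
                  persistence: float = 0.85,
                  profiles: dict | None = None,
                  fs: float = 100.0) -> SyntheticDataset:
    """Generate ``n_subjects`` synthetic subject-nights, bit-reproducible in
    ``(seed, parameters)``."""
    proportions = proportions or SLEEPEDF20_PROPORTIONS
    profiles = profiles or DEFAULT_PROFILES
    total = sum(proportions.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"proportions must sum to 1, got {total}")
    root = np.random.default_rng(seed)
    recordings = []
    for subj in range(n_subjects):
        rng = np.random.default_rng(root.integers(0, 2**31))
        labels = synth_stage_sequence(epochs_per_subject, proportions,
                                      persistence, rng)
        epochs = [synth_epoch(s, profiles[s], fs, rng) for s in labels]
        recordings.append(RawRecording(
            subject_id=f"synth{subj:02d}",
            channel_names=list(CHANNEL_NAMES),
            signals=np.concatenate(epochs, axis=1),
            fs=fs,
            stages=[_stage_text(s, i) for i, s in enumerate(labels)],
        ))
    return SyntheticDataset(recordings=recordings, proportions=dict(proportions),
                            seed=seed)


def synth_scalogram_arrays(dataset: SyntheticDataset, config=None):
    """Preprocess a synthetic dataset to arrays (tfr [N,3,T,S], labels, subjects)."""
    from .tfr import ScalogramConfig, preprocess_record

    config = config or ScalogramConfig()
    tfrs, labels, subjects = [], [], []
    for rec in dataset.recordings:
        for ep in preprocess_record(rec, config):
            tfrs.append(ep.data)
            labels.append(int(ep.label))
            subjects.append(ep.subject_id)
    return (np.stack(tfrs), np.asarray(labels, dtype=np.int64),
            np.asarray(subjects))


# ---------------------------------------------------------------------------
# EDF fixture writer
# ---------------------------------------------------------------------------


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(recording: RawRecording, path) -> None:
    """Write the signals of a recording as a minimal EDF file (1 s records,
    16-bit samples).  Fixture writer for round-trip tests only."""
    fs = recording.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_records = recording.n_samples // fs
    signals = recording.signals[:, :n_records * fs]
    ns = recording.n_channels

    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field(f"X X X {recording.subject_id}", 80),
        _ascii_field("Startdate 01-JAN-2000 X X X", 80),
        _ascii_field("01.01.00", 8),
        _ascii_field("00.00.00", 8),
        _ascii_field(256 * (1 + ns), 8),
        _ascii_field("", 44),
        _ascii_field(n_records, 8),
        _ascii_field(1, 8),
        _ascii_field(ns, 4),
    ])

    phys_min, phys_max, scaled = [], [], []
    for ch in signals:
        lo, hi = float(ch.min()), float(ch.max())
        if hi <= lo:
            hi = lo + 1.0
        lo, hi = round(lo - 1.0, 2), round(hi + 1.0, 2)
        phys_min.append(lo)
        phys_max.append(hi)
        dig = np.round((ch - lo) / (hi - lo) * 65535.0 - 32768.0)
        scaled.append(dig.astype("<i2"))

    def column(values, width):
        return b"".join(_ascii_field(v, width) for v in values)

    sig_header = b"".join([
        column(recording.channel_names, 16),
        column([""] * ns, 80),
        column(["uV"] * ns, 8),
        column(phys_min, 8),
        column(phys_max, 8),
        column([-32768] * ns, 8),
        column([32767] * ns, 8),
        column([""] * ns, 80),
        column([fs] * ns, 8),
        column([""] * ns, 32),
    ])

    with open(path, "wb") as f:
        f.write(header + sig_header)
        for rec_idx in range(n_records):
            for ch in scaled:
                f.write(ch[rec_idx * fs:(rec_idx + 1) * fs].tobytes())


def write_hypnogram_edf(recording: RawRecording, path,
                        epoch_seconds: int = 30) -> None:
    """Write the stage annotations as an EDF+ annotation-only file."""
    tals = [b"+0\x14\x14\x00"]
    onset = 0
    i = 0
    stages = recording.stages
    while i < len(stages):  # run-length encode consecutive identical stages
        j = i
        while j < len(stages) and stages[j] == stages[i]:
            j += 1
        duration = (j - i) * epoch_seconds
        tals.append(f"+{onset}\x15{duration}\x14{stages[i]}\x14\x00".encode("ascii"))
        onset += duration
        i = j
    payload = b"".join(tals)
    if len(payload) % 2:
        payload += b"\x00"
    n_samples = len(payload) // 2

    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field(f"X X X {recording.subject_id}", 80),
        _ascii_field("Startdate 01-JAN-2000 X X X", 80),
        _ascii_field("01.01.00", 8),
        _ascii_field("00.00.00", 8),
        _ascii_field(256 * 2, 8),
        _ascii_field("EDF+C", 44),
        _ascii_field(1, 8),
        _ascii_field(len(stages) * epoch_seconds, 8),
        _ascii_field(1, 4),
    ])
    sig_header = b"".join([
        _ascii_field("EDF Annotations", 16),
        _ascii_field("", 80),
        _ascii_field("", 8),
        _ascii_field(0, 8),
        _ascii_field(1, 8),
        _ascii_field(-32768, 8),
        _ascii_field(32767, 8),
        _ascii_field("", 80),
        _ascii_field(n_samples, 8),
        _ascii_field("", 32),
    ])
    with open(path, "wb") as f:
        f.write(header + sig_header + payload)


def export_edf_pair(recording: RawRecording, directory) -> tuple[Path, Path]:
    """Write ``<subject>-PSG.edf`` and ``<subject>-Hypnogram.edf``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    psg = directory / f"{recording.subject_id}-PSG.edf"
    hyp = directory / f"{recording.subject_id}-Hypnogram.edf"
    write_edf(recording, psg)
    write_hypnogram_edf(recording, hyp)
    return psg, hyp
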