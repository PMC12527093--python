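"""Morlet-wavelet scalogram preprocessing for 30 s PSG epochs.

Each epoch of each channel is transformed with a complex Morlet continuous
wavelet transform over an integer scale grid (default 1..32), the coefficient
magnitudes are median-downsampled along time from ``epoch_seconds * fs``
points (3000 at 100 Hz) to ``target_T`` (default 200, window m = 15), and the
resulting map is z-scored per channel and epoch.

Conventions (fixed, exposed in :class:`ScalogramConfig`):

* mother wavelet ``phi(t) = exp(-t^2/2) * exp(i*omega0*t)`` with
  ``omega0 = 6.0`` (the standard admissibility-safe Morlet choice);
* L2 scale normalisation: the sampled wavelet at integer scale ``a`` is
  ``psi_a[k] = a^(-1/2) * phi(k/a)`` on a symmetric grid wide enough for the
  Gaussian envelope to fall below 1e-8;
* pseudo-frequency mapping ``f(a) = omega0 * fs / (2*pi*a)``: at fs = 100 Hz
  the grid 1..32 spans ~95.5 Hz down to ~3.0 Hz;
* scalograms are coefficient magnitudes (non-negative), computed by
  zero-padded same-length convolution;
* downsampling windows are non-overlapping; the median of an even window is
  the mean of the two central order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .io_edf import RawRecording, StageLabel, map_stages_rk_to_aasm

__all__ = [
    "ScalogramConfig",
    "TFREpoch",
    "scale_to_frequency",
    "frequency_to_scale",
    "segment_epochs",
    "morlet_bank",
    "cwt_complex",
    "cwt_scalogram",
    "median_downsample",
    "downsample",
    "normalize_tfr",
    "preprocess_record",
]

# half-width of the sampled wavelet in units of the mother wavelet's
# dimensionless time: exp(-t^2/2) < 1e-8 for |t| > sqrt(2*ln(1e8)) ~ 6.07
_ENVELOPE_HALF_WIDTH = 6.1


@dataclass(frozen=True)
class ScalogramConfig:
    omega0: float = 6.0
    scales: tuple = tuple(range(1, 33))
    target_T: int = 200
    epoch_seconds: int = 30
    fs: float = 100.0

    def __post_init__(self):
        scales = tuple(int(a) for a in self.scales)
        object.__setattr__(self, "scales", scales)
        if not scales or min(scales) < 1 or list(scales) != sorted(set(scales)):
            raise ValueError("scales must be strictly increasing positive integers")
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")
        n = self.epoch_samples
        if n % self.target_T != 0:
            raise ValueError(
                f"target_T={self.target_T} must divide the epoch length "
                f"{n} = epoch_seconds*fs")

    @property
    def epoch_samples(self) -> int:
        n = self.epoch_seconds * self.fs
        if n != int(n):
            raise ValueError("epoch_seconds * fs must be an integer sample count")
        return int(n)

    @property
    def window(self) -> int:
        """Downsampling window length m (15 under the defaults)."""
        return self.epoch_samples // self.target_T

    @property
    def n_scales(self) -> int:
        return len(self.scales)


@dataclass
class TFREpoch:
    """One epoch's [C, T, S] scalogram stack with its stage label."""

    data: np.ndarray
    label: StageLabel
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("TFREpoch data must be [channels, time, scales]")


def scale_to_frequency(scale, omega0: float = 6.0, fs: float = 100.0):
    """Pseudo-frequency of an integer scale: f(a) = omega0*fs / (2*pi*a)."""
    return omega0 * fs / (2.0 * np.pi * np.asarray(scale, dtype=float))


def frequency_to_scale(freq_hz, omega0: float = 6.0, fs: float = 100.0):
    """Continuous scale whose pseudo-frequency equals ``freq_hz``."""
    return omega0 * fs / (2.0 * np.pi * np.asarray(freq_hz, dtype=float))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_epochs(record: RawRecording, epoch_seconds: int = 30):
    """Cut a recording into labelled 30 s epochs.

    Returns a list of ``(samples [C, epoch_seconds*fs], StageLabel)`` for the
    kept epochs only: the trailing remainder shorter than one epoch is
    discarded, epochs beyond the annotated span are discarded, and
    MOVEMENT/UNKNOWN epochs are excluded.
    """
    n_per = epoch_seconds * record.fs
    if n_per != int(n_per):
        raise ValueError("epoch_seconds * fs must be an integer sample count")
    n_per = int(n_per)
    n_seg = record.n_samples // n_per
    labels, keep = map_stages_rk_to_aasm(record.stages)
    n_seg = min(n_seg, len(labels))
    out = []
    for i in range(n_seg):
        if not keep[i]:
            continue
        samples = record.signals[:, i * n_per:(i + 1) * n_per]
        out.append((samples, StageLabel(int(labels[i]))))
    return out


# ---------------------------------------------------------------------------
# Morlet CWT
# ---------------------------------------------------------------------------


def morlet_bank(config: ScalogramConfig):
    """Sampled complex Morlet wavelets, one odd-length array per scale."""
    bank = []
    for a in config.scales:
        m = int(np.ceil(_ENVELOPE_HALF_WIDTH * a))
        k = np.arange(-m, m + 1, dtype=np.float64)
        t = k / a
        psi = (a ** -0.5) * np.exp(-0.5 * t * t) * np.exp(1j * config.omega0 * t)
        bank.append(psi)
    return bank


def cwt_complex(signal: np.ndarray, config: ScalogramConfig) -> np.ndarray:
    """Complex CWT coefficients [T, S] of one epoch-length signal.

    Coefficient (tau, a) is the discrete correlation of the signal with the
    conjugated wavelet at scale a, i.e. same-length convolution with the
    conjugated time-reversed wavelet, zero-padded at the boundaries.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("cwt expects a 1-D signal")
    if not np.all(np.isfinite(signal)):
        raise ValueError("non-finite values in CWT input")
    out = np.empty((signal.shape[0], config.n_scales), dtype=np.complex128)
    for j, psi in enumerate(morlet_bank(config)):
        kernel = np.conj(psi[::-1])
        out[:, j] = fftconvolve(signal, kernel, mode="same")
    return out


def cwt_scalogram(epoch_channel: np.ndarray, config: ScalogramConfig) -> np.ndarray:
    """Magnitude scalogram [T_raw, n_scales] of one 30 s epoch channel."""
    epoch_channel = np.asarray(epoch_channel, dtype=np.float64)
    if epoch_channel.shape[-1] != config.epoch_samples:
        raise ValueError(
            f"epoch length {epoch_channel.shape[-1]} != epoch_seconds*fs = "
            f"{config.epoch_samples}")
    return np.abs(cwt_complex(epoch_channel, config))


def _cwt_magnitude_many(signals: np.ndarray, config: ScalogramConfig) -> np.ndarray:
    """Batched magnitude CWT: [M, L] -> [M, L, S] (used by preprocess_record)."""
    if not np.all(np.isfinite(signals)):
        raise ValueError("non-finite values in CWT input")
    m, length = signals.shape
    out = np.empty((m, length, len(config.scales)), dtype=np.float64)
    for j, psi in enumerate(morlet_bank(config)):
        kernel = np.conj(psi[::-1])[None, :]
        out[:, :, j] = np.abs(fftconvolve(signals, kernel, mode="same", axes=-1))
    return out


# ---------------------------------------------------------------------------
# downsampling and normalisation
# ---------------------------------------------------------------------------


def downsample(tfr_map: np.ndarray, target_T: int, mode: str = "median") -> np.ndarray:
    """Reduce the time axis of a [T_raw, S] map to ``target_T`` points using
    non-overlapping windows of m = T_raw/target_T samples.

    ``median`` is the pipeline default (robust to outliers); ``mean`` and
    ``max`` exist only for the downsampling comparison harness.
    """
    tfr_map = np.asarray(tfr_map)
    t_raw = tfr_map.shape[0]
    if t_raw % target_T != 0:
        raise ValueError(
            f"time axis {t_raw} is not divisible by target_T {target_T}")
    m = t_raw // target_T
    windows = tfr_map.reshape(target_T, m, *tfr_map.shape[1:])
    if mode == "median":
        return np.median(windows, axis=1)
    if mode == "mean":
        return windows.mean(axis=1)
    if mode == "max":
        return windows.max(axis=1)
    raise ValueError(f"unknown downsampling mode {mode!r}")


def median_downsample(tfr_map: np.ndarray, target_T: int) -> np.ndarray:
    return downsample(tfr_map, target_T, mode="median")


def normalize_tfr(tfr_map: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Z-score a map: (x - mean) / (sd + eps).  Constant maps go to zero."""
    tfr_map = np.asarray(tfr_map, dtype=np.float64)
    if not np.all(np.isfinite(tfr_map)):
        raise ValueError("non-finite values in normalisation input")
    return (tfr_map - tfr_map.mean()) / (tfr_map.std() + eps)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def preprocess_record(record: RawRecording, config: ScalogramConfig | None = None,
                      downsample_mode: str = "median"):
    """Segment -> CWT magnitude -> median downsample -> per-channel z-score.

    Returns a list of :class:`TFREpoch` with data shaped
    [n_channels, target_T, n_scales] ([3, 200, 32] under the defaults).
    Channels are processed independently; epochs flagged MOVEMENT/UNKNOWN are
    absent.  Deterministic: no randomness anywhere in the pipeline.
    """
    config = config or ScalogramConfig(fs=record.fs)
    if record.n_channels != 3:
        raise ValueError(f"expected 3 channels, got {record.n_channels}")
    if record.fs != config.fs:
        raise ValueError(f"record fs {record.fs} != config fs {config.fs}")
    segments = segment_epochs(record, config.epoch_seconds)
    if not segments:
        return []
    stack = np.stack([s for s, _ in segments])      # [n, C, L]
    labels = [lab for _, lab in segments]
    n, c, length = stack.shape
    mags = _cwt_magnitude_many(stack.reshape(n * c, length), config)
    m = config.window
    windows = mags.reshape(n * c, config.target_T, m, config.n_scales)
    if downsample_mode == "median":
        down = np.median(windows, axis=2)
    elif downsample_mode == "mean":
        down = windows.mean(axis=2)
    elif downsample_mode == "max":
        down = windows.max(axis=2)
    else:
        raise ValueError(f"unknown downsampling mode {downsample_mode!r}")
    mean = down.mean(axis=(1, 2), keepdims=True)
    sd = down.std(axis=(1, 2), keepdims=True)
    normed = ((down - mean) / (sd + 1e-8)).reshape(n, c, config.target_T,
                                                   config.n_scales)
    return [
        TFREpoch(data=normed[i].astype(np.float32), label=labels[i],
                 subject_id=record.subject_id)
        for i in range(n)
    ]
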