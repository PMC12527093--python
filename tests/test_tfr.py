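"""Scalogram preprocessing: segmentation, Morlet CWT, median downsampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _naive
from lmcsleepnet.io_edf import RawRecording, StageLabel
from lmcsleepnet.synth import CHANNEL_NAMES
from lmcsleepnet.tfr import (ScalogramConfig, cwt_complex, cwt_scalogram,
                             downsample, frequency_to_scale, median_downsample,
                             morlet_bank, normalize_tfr, preprocess_record,
                             scale_to_frequency, segment_epochs)


def make_recording(n_epochs, fs=100.0, extra_samples=0, stages=None):
    n = int(n_epochs * 30 * fs) + extra_samples
    rng = np.random.default_rng(0)
    return RawRecording(
        subject_id="t", channel_names=list(CHANNEL_NAMES),
        signals=rng.normal(size=(3, n)), fs=fs,
        stages=stages if stages is not None else ["Sleep stage W"] * n_epochs)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def test_epoch_sample_count_at_100hz():
    """30 s at 100 Hz is exactly 3000 samples per epoch."""
    segs = segment_epochs(make_recording(2), 30)
    assert len(segs) == 2
    assert all(s.shape == (3, 3000) for s, _ in segs)


def test_trailing_remainder_discarded():
    # 95 s at 100 Hz -> floor(9500/3000) = 3 epochs, 500 samples dropped
    rec = make_recording(3, extra_samples=500)
    assert len(segment_epochs(rec, 30)) == 3


def test_labels_bound_epoch_count():
    rec = make_recording(4, stages=["Sleep stage W", "Sleep stage R"])
    segs = segment_epochs(rec, 30)
    assert [lab for _, lab in segs] == [StageLabel.W, StageLabel.REM]


def test_movement_epochs_excluded():
    rec = make_recording(3, stages=["Sleep stage W", "Movement time",
                                    "Sleep stage 2"])
    segs = segment_epochs(rec, 30)
    assert [lab for _, lab in segs] == [StageLabel.W, StageLabel.N2]


def test_short_recording_yields_empty_list():
    rec = make_recording(0, extra_samples=100, stages=[])
    assert segment_epochs(rec, 30) == []


# ---------------------------------------------------------------------------
# Morlet bank
# ---------------------------------------------------------------------------


def test_bank_center_sample_and_shape():
    bank = morlet_bank(ScalogramConfig())
    assert len(bank) == 32
    for a, psi in zip(range(1, 33), bank):
        assert len(psi) % 2 == 1
        center = psi[len(psi) // 2]
        assert center == pytest.approx((a ** -0.5) * (1 + 0j))
        # envelope decayed below threshold at the edges
        assert abs(psi[0]) < 1e-8 and abs(psi[-1]) < 1e-8


def test_bank_support_doubles_with_scale():
    bank = morlet_bank(ScalogramConfig())
    supports = [int(np.sum(np.abs(p) * (a ** 0.5) > 1e-3))
                for a, p in zip(range(1, 33), bank)]
    for a in (2, 4, 8, 16):
        ratio = supports[2 * a - 1] / supports[a - 1]
        assert ratio == pytest.approx(2.0, abs=0.1)


def test_bank_l2_norm_scale_invariant():
    """With the a^(-1/2) prefactor the discrete L2 norm is the same at every
    scale (~pi^(1/4)), the signature of L2 normalisation."""
    bank = morlet_bank(ScalogramConfig())
    norms = np.array([np.linalg.norm(p) for p in bank])
    np.testing.assert_allclose(norms, np.pi ** 0.25, rtol=1e-3)


# ---------------------------------------------------------------------------
# CWT
# ---------------------------------------------------------------------------


def test_zero_epoch_gives_zero_scalogram():
    cfg = ScalogramConfig()
    scal = cwt_scalogram(np.zeros(3000), cfg)
    assert scal.shape == (3000, 32)
    np.testing.assert_array_equal(scal, 0.0)


def test_cwt_is_linear_on_complex_coefficients(rng):
    cfg = ScalogramConfig(scales=tuple(range(1, 9)))
    x = rng.normal(size=3000)
    y = rng.normal(size=3000)
    np.testing.assert_allclose(cwt_complex(x + y, cfg),
                               cwt_complex(x, cfg) + cwt_complex(y, cfg),
                               atol=1e-9)


def test_cwt_matches_direct_correlation_oracle(rng):
    """fft convolution agrees with an explicit zero-padded correlation."""
    cfg = ScalogramConfig(scales=(1, 3, 7))
    x = rng.normal(size=3000)
    got = cwt_complex(x, cfg)
    for j, psi in enumerate(morlet_bank(cfg)):
        m = len(psi) // 2
        xp = np.concatenate([np.zeros(m), x, np.zeros(m)])
        direct = np.array([np.dot(xp[tau:tau + len(psi)], np.conj(psi))
                           for tau in range(3000)])
        np.testing.assert_allclose(got[:, j], direct, atol=1e-9)


@pytest.mark.parametrize("freq", [5.0, 10.0, 20.0])
def test_sinusoid_peak_scale_within_default_grid(freq):
    cfg = ScalogramConfig()
    t = np.arange(3000) / 100.0
    scal = cwt_scalogram(np.sin(2 * np.pi * freq * t), cfg)
    peak = int(np.argmax(scal.mean(axis=0))) + 1
    assert abs(peak - frequency_to_scale(freq)) <= 1.0


def test_peak_scale_agrees_with_pywavelets():
    """Independent cross-check: pywt's complex Morlet (matching envelope B=2,
    center C = omega0/2pi) localises a 10 Hz tone at the same scale."""
    pywt = pytest.importorskip("pywt")
    t = np.arange(3000) / 100.0
    x = np.sin(2 * np.pi * 10.0 * t)
    scales = np.arange(1, 33)
    coef, _ = pywt.cwt(x, scales, f"cmor2.0-{6.0 / (2 * np.pi):.6f}")
    peak_pywt = int(np.argmax(np.abs(coef).mean(axis=1))) + 1
    cfg = ScalogramConfig()
    scal = cwt_scalogram(x, cfg)
    peak_ours = int(np.argmax(scal.mean(axis=0))) + 1
    assert abs(peak_ours - peak_pywt) <= 1


def test_scale_frequency_mapping_round_trip():
    a = np.arange(1, 33)
    np.testing.assert_allclose(frequency_to_scale(scale_to_frequency(a)), a)
    assert scale_to_frequency(1) == pytest.approx(95.49, abs=0.01)
    assert scale_to_frequency(32) == pytest.approx(2.98, abs=0.01)


def test_cwt_rejects_nan():
    with pytest.raises(ValueError):
        cwt_scalogram(np.full(3000, np.nan), ScalogramConfig())


# ---------------------------------------------------------------------------
# median downsampling
# ---------------------------------------------------------------------------


def test_window_arithmetic_3000_to_200():
    cfg = ScalogramConfig()
    assert cfg.epoch_samples == 3000 and cfg.window == 15
    out = median_downsample(np.arange(3000.0)[:, None] * np.ones((1, 4)), 200)
    assert out.shape == (200, 4)
    assert ScalogramConfig(target_T=100).window == 30


def test_constant_map_unchanged():
    out = median_downsample(np.full((3000, 5), 3.25), 200)
    np.testing.assert_array_equal(out, np.full((200, 5), 3.25))


def test_median_is_eighth_order_statistic_and_outlier_proof(rng):
    base = np.arange(1.0, 16.0)
    for _ in range(10):
        window = rng.permutation(base)
        poisoned = window.copy()
        poisoned[rng.integers(0, 15)] = 1e6
        col = np.concatenate([window, poisoned])[:, None]
        out = median_downsample(col, 2)
        assert out[0, 0] == _naive.median_sorted(window) == 8.0
        # a single poisoned sample can move the median at most to a neighbour
        assert out[1, 0] in (8.0, 9.0)


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=15, max_size=15),
       st.integers(0, 14), st.floats(-1e9, 1e9))
def test_median_window_permutation_and_single_outlier_invariance(window, idx, val):
    window = np.asarray(window)
    med = median_downsample(window[:, None], 1)[0, 0]
    assert med == _naive.median_sorted(window)
    shuffled = np.random.default_rng(0).permutation(window)
    assert median_downsample(shuffled[:, None], 1)[0, 0] == med


def test_even_window_median_averages_central_pair():
    out = downsample(np.array([[1.0], [2.0], [10.0], [40.0]]), 1, "median")
    assert out[0, 0] == 6.0


def test_non_divisible_length_rejected():
    with pytest.raises(ValueError, match="3001.*200|200.*3001"):
        median_downsample(np.zeros((3001, 4)), 200)


def test_mean_and_max_modes_exist_for_comparison_harness():
    m = np.arange(30.0)[:, None]
    np.testing.assert_allclose(downsample(m, 2, "mean")[:, 0], [7.0, 22.0])
    np.testing.assert_allclose(downsample(m, 2, "max")[:, 0], [14.0, 29.0])


# ---------------------------------------------------------------------------
# normalisation and full pipeline
# ---------------------------------------------------------------------------


def test_normalize_matches_direct_zscore():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    np.testing.assert_allclose(normalize_tfr(x),
                               [-1.342, -0.447, 0.447, 1.342], atol=1e-3)
    np.testing.assert_array_equal(normalize_tfr(np.full((5, 5), 7.0)), 0.0)
    y = np.random.default_rng(3).normal(size=(20, 8))
    np.testing.assert_allclose(normalize_tfr(normalize_tfr(y)),
                               normalize_tfr(y), atol=1e-6)


def test_preprocess_shapes_and_determinism():
    rec = make_recording(5, stages=["Sleep stage W", "Movement time",
                                    "Sleep stage 2", "Sleep stage 3",
                                    "Sleep stage 4"])
    epochs = preprocess_record(rec)
    assert len(epochs) == 4  # MOVEMENT removed
    assert all(e.data.shape == (3, 200, 32) for e in epochs)
    assert [e.label for e in epochs] == [StageLabel.W, StageLabel.N2,
                                         StageLabel.N3, StageLabel.N3]
    again = preprocess_record(rec)
    for a, b in zip(epochs, again):
        np.testing.assert_array_equal(a.data, b.data)


def test_preprocess_matches_single_epoch_path():
    """The batched pipeline equals segment -> cwt -> median -> z-score done
    one channel at a time."""
    rec = make_recording(2)
    cfg = ScalogramConfig(scales=tuple(range(1, 9)))
    epochs = preprocess_record(rec, cfg)
    seg0 = rec.signals[:, :3000]
    for c in range(3):
        manual = normalize_tfr(
            median_downsample(cwt_scalogram(seg0[c], cfg), cfg.target_T))
        np.testing.assert_allclose(epochs[0].data[c], manual, atol=1e-5)
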