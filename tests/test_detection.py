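"""Detection pipeline: masking, channel selection, filtering, thresholding,
merging and centering."""

import numpy as np
import pytest
from scipy import signal as sps

from conftest import match_events
from ripplemap.containers import LFPRecording
from ripplemap.detection import (
    DetectionConfig,
    RippleEvent,
    detect_and_center,
    detect_ripples,
    filter_and_envelope,
    merge_intervals,
    remove_noise_epochs,
    select_sp_channel,
)
from ripplemap.synthetic import generate_laminar_session


RATE = 2500.0


def test_config_validation():
    with pytest.raises(ValueError):
        DetectionConfig(threshold_sd=6.0)
    with pytest.raises(ValueError):
        DetectionConfig(threshold_sd=1.0)
    with pytest.raises(ValueError):
        DetectionConfig(band=(400.0, 70.0))
    assert DetectionConfig(threshold_sd=2.0).threshold_sd == 2.0


def test_ripple_event_invariant():
    with pytest.raises(ValueError):
        RippleEvent(peak=5, onset=10, offset=20)


# ---------------------------------------------------------------------------
# noise epochs


def test_clean_recording_keeps_everything(laminar):
    mask = remove_noise_epochs(laminar["rec"])
    assert mask.all()


def test_injected_artifact_epoch_masked():
    rng = np.random.default_rng(0)
    sig = rng.normal(0, 1, (2, 10 * int(RATE)))
    sig[:, 3 * int(RATE) + 100] += 40.0  # 20 s.d. spike in epoch 3
    rec = LFPRecording(sig, RATE)
    mask = remove_noise_epochs(rec, epoch_s=1.0)
    ep = np.flatnonzero(~mask)
    assert ep.size == int(RATE)
    assert ep[0] == 3 * int(RATE)


def test_single_channel_noop_and_bad_ksd():
    rec = LFPRecording(np.random.default_rng(1).normal(size=(1, 5000)), RATE)
    assert remove_noise_epochs(rec).all()
    rec2 = LFPRecording(np.random.default_rng(1).normal(size=(2, 5000)), RATE)
    with pytest.raises(ValueError):
        remove_noise_epochs(rec2, k_sd=0.0)
    with pytest.raises(ValueError):
        remove_noise_epochs(rec2, channel_pair=(1, 1))


# ---------------------------------------------------------------------------
# SP channel


def test_sp_channel_from_generator(laminar):
    ch = select_sp_channel(laminar["rec"])
    assert laminar["rec"].layers[ch] == "SP"


def test_sp_channel_trivial_cases():
    rng = np.random.default_rng(2)
    one = LFPRecording(rng.normal(size=(1, 8000)), RATE)
    assert select_sp_channel(one) == 0
    row = rng.normal(size=8000)
    two = LFPRecording(np.vstack([row, row]), RATE)
    assert select_sp_channel(two) == 0  # tie -> lowest index
    with pytest.raises(ValueError):
        select_sp_channel(LFPRecording(np.zeros((2, 8000)), RATE))


# ---------------------------------------------------------------------------
# filter + envelope


def test_passband_tone_preserved_and_envelope_flat():
    t = np.arange(int(2 * RATE)) / RATE
    tone = np.sin(2 * np.pi * 150 * t)
    filtered, env = filter_and_envelope(tone, RATE)
    core = slice(int(0.2 * RATE), int(1.8 * RATE))
    assert np.abs(filtered[core] - tone[core]).max() < 0.05
    assert env[core].std() / env[core].mean() < 0.05
    assert abs(env[core].mean() - 1.0) < 0.05


def test_stopband_attenuation_over_40db():
    t = np.arange(int(2 * RATE)) / RATE
    tone = np.sin(2 * np.pi * 20 * t)
    filtered, _ = filter_and_envelope(tone, RATE)
    core = slice(int(0.2 * RATE), int(1.8 * RATE))
    atten = 20 * np.log10(np.abs(filtered[core]).max())
    assert atten < -40


def test_zero_phase_no_group_delay():
    rng = np.random.default_rng(3)
    t = np.arange(int(2 * RATE)) / RATE
    x = np.sin(2 * np.pi * 150 * t) + 0.5 * np.sin(2 * np.pi * 220 * t + 1.0)
    filtered, _ = filter_and_envelope(x, RATE)
    lags = sps.correlation_lags(x.size, x.size)
    xc = sps.correlate(filtered - filtered.mean(), x - x.mean())
    assert lags[np.argmax(xc)] == 0


def test_envelope_deterministic():
    rng = np.random.default_rng(4)
    x = rng.normal(size=int(2 * RATE))
    _, e1 = filter_and_envelope(x, RATE)
    _, e2 = filter_and_envelope(x.copy(), RATE)
    np.testing.assert_array_equal(e1, e2)


def test_filter_validation():
    with pytest.raises(ValueError):
        filter_and_envelope(np.zeros(100), RATE)  # too short
    t = np.arange(int(2 * RATE)) / RATE
    with pytest.raises(ValueError):
        filter_and_envelope(np.sin(t), 700.0)  # band above Nyquist


# ---------------------------------------------------------------------------
# merging


def test_merge_rule_boundaries():
    gap = int(round(15e-3 * RATE))  # 15 ms in samples
    ten_ms = int(round(10e-3 * RATE))
    twenty_ms = int(round(20e-3 * RATE))
    a = [(0, 100), (100 + ten_ms, 200 + ten_ms)]
    assert len(merge_intervals(a, gap)) == 1
    b = [(0, 100), (100 + twenty_ms, 200 + twenty_ms)]
    assert len(merge_intervals(b, gap)) == 2
    # exactly 15 ms apart: strictly "closer than" -> not merged
    c = [(0, 100), (100 + gap, 200 + gap)]
    assert len(merge_intervals(c, gap)) == 2


def test_merge_idempotent():
    rng = np.random.default_rng(5)
    starts = np.sort(rng.integers(0, 100000, 40))
    iv = [(int(s), int(s + rng.integers(5, 80))) for s in starts]
    once = merge_intervals(iv, 37)
    twice = merge_intervals(once, 37)
    assert once == twice


# ---------------------------------------------------------------------------
# detect + center


def test_flat_trace_yields_no_events():
    flat = np.zeros(int(RATE))
    assert detect_and_center(flat, flat, RATE) == []


def test_empty_mask_rejected():
    x = np.random.default_rng(6).normal(size=int(RATE))
    with pytest.raises(ValueError):
        detect_and_center(x, np.abs(x), RATE, mask=np.zeros(x.size, dtype=bool))


def test_threshold_uses_kept_samples_only():
    rng = np.random.default_rng(7)
    env = np.abs(rng.normal(0, 0.1, int(4 * RATE)))
    env[1000:1100] = 50.0  # huge masked artifact
    filt = rng.normal(0, 0.1, env.size)
    mask = np.ones(env.size, dtype=bool)
    mask[500:1500] = False
    ev_masked = detect_and_center(filt, env, RATE, mask=mask)
    assert all(not (500 <= e.peak < 1500) for e in ev_masked)


def test_detection_fidelity_strong_events():
    """>= 95% recall and precision for events well above the noise floor."""
    rec, truth, _ = generate_laminar_session(n_events=100, amp_range=(2, 5), seed=1)
    table, _ = detect_ripples(rec)
    precision, recall = match_events(
        table["peak_sample"], truth["trough_sample"], rec.sampling_rate, tol_ms=5.0
    )
    assert precision >= 0.95 and recall >= 0.95


def test_centering_hits_injected_trough():
    """Strong events center on the injected trough: 95% within 2 ms, all
    within one ripple cycle."""
    rec, truth, _ = generate_laminar_session(n_events=50, amp_range=(3, 5), seed=2)
    table, _ = detect_ripples(rec)
    d = np.abs(
        table["peak_sample"].to_numpy()[:, None]
        - truth["trough_sample"].to_numpy()[None, :]
    ).min(axis=1)
    rate = rec.sampling_rate
    assert np.mean(d <= 0.002 * rate) >= 0.95
    max_cycle = rate / 80.0  # one period of the slowest ripple
    assert d.max() <= max_cycle


def test_events_sorted_and_events_table(laminar):
    tb = laminar["events"]
    assert tb["peak_sample"].is_monotonic_increasing
    assert (tb["onset_sample"] <= tb["peak_sample"]).all()
    assert (tb["peak_sample"] <= tb["offset_sample"]).all()
    np.testing.assert_allclose(
        tb["peak_s"], tb["peak_sample"] / laminar["rec"].sampling_rate
    )
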