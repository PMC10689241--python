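"""Per-event spectral, temporal and laminar (CSD) features.

Feature definitions: ripple frequency is the spectral peak in the analysis
band after subtracting a fitted exponential decay (the 1/f-like background);
spectral entropy is Shannon entropy (bits) of the 10 Hz-binned, normalized
power spectrum; the MUA index is the spectral area at 300-400 Hz; amplitude
comes from the envelope of the band-passed SP signal; duration from envelope
crossings and from the area under the amplitude-normalized rectified trace;
slopes from linear fits to the 1-10 Hz filtered SP/SR signals around the
peak; and the current source density (CSD) is the second spatial derivative
of the laminar potential (sinks negative, sources positive).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal

from .containers import LAYERS, LFPRecording

logger = logging.getLogger(__name__)

SPECTRAL_BIN_HZ = 10.0


def bin_spectrum(
    waveform: np.ndarray, rate: float, band: tuple[float, float] = (70.0, 400.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed periodogram accumulated into 10 Hz bins over ``band``.

    Returns (bin center frequencies, total power per bin).
    """
    waveform = np.asarray(waveform, dtype=float)
    if not np.any(waveform):
        raise ValueError("all-zero waveform has no defined spectrum")
    # zero-pad for a frequency grid fine enough to populate 10 Hz bins
    nfft = max(waveform.size, int(2 ** np.ceil(np.log2(8 * rate / SPECTRAL_BIN_HZ))))
    f, p = signal.periodogram(waveform, fs=rate, window="hann", nfft=nfft)
    lo, hi = band
    edges = np.arange(lo, hi + SPECTRAL_BIN_HZ, SPECTRAL_BIN_HZ)
    centers = edges[:-1] + SPECTRAL_BIN_HZ / 2
    idx = np.digitize(f, edges) - 1
    power = np.zeros(centers.size)
    valid = (idx >= 0) & (idx < centers.size)
    np.add.at(power, idx[valid], p[valid])
    return centers, power


def spectral_entropy(power_bins: np.ndarray) -> float:
    """Shannon entropy (bits) of a binned spectrum, normalized to sum 1.
    Zero bins contribute nothing (0 * log 0 = 0)."""
    p = np.asarray(power_bins, dtype=float)
    if np.any(p < 0) or p.sum() <= 0:
        raise ValueError("power bins must be nonnegative with positive sum")
    p = p / p.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _whiten(freqs: np.ndarray, power: np.ndarray) -> np.ndarray:
    """Subtract a fitted exponential decay a*exp(-b f).

    The fit runs in the log domain (where the exponential is linear), in two
    passes: the second pass drops the bins the spectral bump occupies
    (residual above the median), so the bump does not drag the background
    up. Falls back to an a/f fit when too few positive bins exist.
    """
    pos = power > 0
    if pos.sum() < 3:
        logger.info("spectral_features: too few positive bins, using 1/f fit")
        a = float(np.sum(power / freqs) / np.sum(1.0 / freqs**2))
        return power - a / freqs
    b, loga = np.polyfit(freqs[pos], np.log(power[pos]), 1)
    resid = power - np.exp(loga + b * freqs)
    keep = pos & (resid <= np.median(resid))
    if keep.sum() >= 3:
        b, loga = np.polyfit(freqs[keep], np.log(power[keep]), 1)
    return power - np.exp(loga + b * freqs)


def spectral_features(
    waveform: np.ndarray, rate: float, band: tuple[float, float] = (70.0, 400.0)
) -> tuple[float, float, float]:
    """(frequency Hz, spectral entropy bits, MUA index).

    Frequency is the peak of the spectral bump after background subtraction;
    entropy is computed on the normalized 10 Hz-binned spectrum; the MUA
    index is the binned power summed over 300-400 Hz.
    """
    centers, power = bin_spectrum(waveform, rate, band)
    # peak location on the fine-grid whitened periodogram (the 10 Hz binning
    # quantizes entropy, not the peak)
    waveform = np.asarray(waveform, dtype=float)
    nfft = max(waveform.size, int(2 ** np.ceil(np.log2(8 * rate / SPECTRAL_BIN_HZ))))
    f, p = signal.periodogram(waveform, fs=rate, window="hann", nfft=nfft)
    sel = (f >= band[0]) & (f <= band[1])
    frequency = float(f[sel][np.argmax(_whiten(f[sel], p[sel]))])
    entropy = spectral_entropy(power)
    mua = float(power[(centers >= 300) & (centers <= 400)].sum())
    return frequency, entropy, mua


def amplitude_duration(
    filtered: np.ndarray,
    envelope: np.ndarray,
    peak: int,
    rate: float,
) -> tuple[float, float, float]:
    """(amplitude, duration_env ms, duration_auc a.u.) around ``peak``.

    Amplitude is the envelope maximum within +-25 ms of the peak. The
    envelope duration is the span of the contiguous crossing of the local
    mean + 1 s.d. around the peak. The AUC duration is the area under the
    amplitude-normalized rectified filtered trace over +-100 ms — invariant
    to amplitude scaling and to zero-padding.
    """
    w100 = int(round(0.100 * rate))
    w25 = int(round(0.025 * rate))
    if peak - w100 < 0 or peak + w100 >= filtered.size:
        raise ValueError("peak +-100 ms exceeds trace bounds")
    env_local = envelope[peak - w100 : peak + w100 + 1]
    amplitude = float(envelope[peak - w25 : peak + w25 + 1].max())
    thr = env_local.mean() + env_local.std()
    above = env_local > thr
    center = w100
    if above[center]:
        left = center
        while left > 0 and above[left - 1]:
            left -= 1
        right = center
        while right < above.size - 1 and above[right + 1]:
            right += 1
        duration_env = (right - left + 1) / rate * 1000
    else:
        duration_env = 0.0
    seg = np.abs(filtered[peak - w100 : peak + w100 + 1])
    m = seg.max()
    duration_auc = float(np.trapezoid(seg / m)) if m > 0 else 0.0
    return amplitude, float(duration_env), duration_auc


def slope_filter(trace: np.ndarray, rate: float) -> np.ndarray:
    """Zero-phase 1-10 Hz band-pass used for slope estimation."""
    sos = signal.butter(2, [1.0, 10.0], btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, trace)


def _fit_slope(y: np.ndarray, rate: float) -> float:
    t_ms = np.arange(y.size) / rate * 1000
    return float(np.polyfit(t_ms, y, 1)[0])


def event_slopes(
    sp_raw: np.ndarray,
    sr_raw: np.ndarray | None,
    peak: int,
    rate: float,
) -> dict[str, float]:
    """Slopes (units/ms) of the 1-10 Hz filtered SP (ripple) and SR
    (sharp-wave) signals, fitted on [peak-25 ms, peak] and [peak, +25 ms].
    Missing SR yields NaN sharp-wave slopes."""
    w = int(round(0.025 * rate))
    if peak - w < 0 or peak + w >= sp_raw.size:
        raise ValueError("peak +-25 ms exceeds trace bounds")
    out = {}
    for name, trace in (("ripple", sp_raw), ("sw", sr_raw)):
        if trace is None:
            out[f"slope_to_peak_{name}"] = np.nan
            out[f"slope_from_peak_{name}"] = np.nan
            continue
        slow = slope_filter(np.asarray(trace, dtype=float), rate)
        out[f"slope_to_peak_{name}"] = _fit_slope(slow[peak - w : peak + 1], rate)
        out[f"slope_from_peak_{name}"] = _fit_slope(slow[peak : peak + w + 1], rate)
    return out


# ---------------------------------------------------------------------------
# CSD


def compute_csd(snapshot: np.ndarray, depths_um: np.ndarray) -> np.ndarray:
    """Second spatial derivative of a laminar snapshot.

    ``CSD_i = (V_{i-1} - 2 V_i + V_{i+1}) / h^2`` at interior channels
    (h in mm); boundary channels are NaN. Sinks negative, sources positive.
    """
    snapshot = np.atleast_2d(np.asarray(snapshot, dtype=float))
    depths_um = np.asarray(depths_um, dtype=float)
    if snapshot.shape[0] < 3:
        raise ValueError("CSD needs at least 3 channels")
    d = np.diff(depths_um)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("channel depths must be monotone")
    h = np.abs(d).mean() / 1000.0  # mm
    csd = np.full_like(snapshot, np.nan)
    csd[1:-1] = (snapshot[:-2] - 2 * snapshot[1:-1] + snapshot[2:]) / h**2
    return csd


MIN_CSD_CHANNELS = 8


def event_csd_table(
    rec: LFPRecording,
    peaks: np.ndarray,
    halfwin_ms: float = 4.0,
    lowpass_hz: float | None = 50.0,
) -> pd.DataFrame:
    """Per-event per-layer CSD summary at the SWR peak.

    Requires at least ``MIN_CSD_CHANNELS`` contiguous channels covering SO
    through SLM. The per-layer value is the CSD at the peak (averaged over
    ``+-halfwin_ms`` for noise robustness) averaged over the interior
    channels labeled for that layer. ``lowpass_hz`` (default 50 Hz,
    zero-phase) isolates the slow sharp-wave sink/source structure: the
    SP-confined ripple otherwise dominates the spatial second derivative at
    adjacent layers. Pass ``None`` for wideband CSD.
    """
    if rec.layers is None:
        raise ValueError("recording must carry layer labels for CSD summaries")
    if rec.n_channels < MIN_CSD_CHANNELS:
        raise ValueError(
            f"per-layer CSD needs >= {MIN_CSD_CHANNELS} contiguous channels"
        )
    present = [l for l in LAYERS if l in rec.layers]
    if present != list(LAYERS):
        raise ValueError("channel map must cover SO through SLM")
    sig = rec.signal
    if lowpass_hz is not None:
        sos = signal.butter(4, lowpass_hz, btype="low", fs=rec.sampling_rate, output="sos")
        sig = signal.sosfiltfilt(sos, sig, axis=1)
    w = max(1, int(round(halfwin_ms * rec.sampling_rate / 1000)))
    lab = np.asarray(rec.layers)
    rows = []
    for ev, p in enumerate(np.asarray(peaks, dtype=int)):
        lo, hi = max(0, p - w), min(rec.n_samples, p + w + 1)
        csd = compute_csd(sig[:, lo:hi], rec.depths_um).mean(axis=1)
        row = {"event_id": ev, "peak_sample": int(p)}
        for l in LAYERS:
            ch = np.flatnonzero(lab == l)
            vals = csd[ch]
            row[f"csd_{l}"] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["sign_convention"] = "sinks negative, sources positive"
    return out


# ---------------------------------------------------------------------------


def compute_features(
    rec: LFPRecording,
    events: pd.DataFrame,
    ctx: dict,
    band: tuple[float, float] = (70.0, 400.0),
    window_ms: float = 25.0,
) -> pd.DataFrame:
    """Feature table for detected events (one row per event).

    ``ctx`` is the context returned by :func:`ripplemap.detection.detect_ripples`
    (filtered SP trace and envelope). Events whose +-100 ms window leaves the
    trace are dropped with a log entry.
    """
    filtered = ctx["filtered"]
    envelope = ctx["envelope"]
    rate = rec.sampling_rate
    sp = rec.signal[ctx["sp_channel"]]
    sr = None
    if rec.layers is not None and "SR" in rec.layers:
        sr = rec.signal[rec.channels_in_layer("SR")].mean(axis=0)
    w = int(round(window_ms / 1000 * rate))
    rows = []
    dropped = 0
    for _, ev in events.iterrows():
        p = int(ev["peak_sample"])
        if p - int(0.1 * rate) < 0 or p + int(0.1 * rate) >= filtered.size:
            dropped += 1
            continue
        wf = filtered[p - w : p + w + 1]
        freq, ent, mua = spectral_features(wf, rate, band)
        amp, dur_env, dur_auc = amplitude_duration(filtered, envelope, p, rate)
        slopes = event_slopes(sp, sr, p, rate)
        rows.append(
            {
                "session": ev.get("session", rec.session),
                "peak_sample": p,
                "frequency": freq,
                "amplitude": amp,
                "entropy": ent,
                "duration_env": dur_env,
                "duration_auc": dur_auc,
                "mua_index": mua,
                **slopes,
            }
        )
    if dropped:
        logger.info("compute_features: dropped %d edge events", dropped)
    return pd.DataFrame(rows)
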