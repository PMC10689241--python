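"""Sharp-wave ripple detection on the pyramidal-layer channel.

Consensus pipeline: mask noisy epochs by cross-channel similarity, pick the
SP channel by ripple-band (100-250 Hz) and multi-unit (300-400 Hz) power,
band-pass 70-400 Hz with a zero-phase FIR of order 512, envelope from the
analytic signal smoothed by a fourth-order Savitzky-Golay filter (33.4 ms)
and two moving means (2.3 and 6.7 ms), threshold at 2-5 s.d. of the
envelope, merge events closer than 15 ms, and center each event on the
filtered-trace minimum near the envelope peak (30 ms window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import rankdata

from .containers import LFPRecording

logger = logging.getLogger(__name__)


@dataclass
class DetectionConfig:
    """Detection parameters; defaults follow the consensus pipeline."""

    band: tuple[float, float] = (70.0, 400.0)
    filter_order: int = 512
    savgol_ms: float = 33.4
    savgol_order: int = 4
    movmean_ms: tuple[float, float] = (2.3, 6.7)
    threshold_sd: float = 3.0
    merge_gap_ms: float = 15.0
    center_window_ms: float = 30.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")
        if not 2.0 <= self.threshold_sd <= 5.0:
            raise ValueError("threshold_sd must be within [2, 5]")


@dataclass
class RippleEvent:
    """One detected event, peak-centered on the filtered-trace trough."""

    peak: int
    onset: int
    offset: int
    session: str = "session0"
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.onset <= self.peak <= self.offset:
            raise ValueError("need onset <= peak <= offset")


def events_to_table(events: list[RippleEvent], rate: float) -> pd.DataFrame:
    """Event list -> delimited-friendly table (0-based samples, seconds)."""
    rows = [
        {
            "session": e.session,
            "peak_sample": e.peak,
            "onset_sample": e.onset,
            "offset_sample": e.offset,
            "peak_s": e.peak / rate,
            "onset_s": e.onset / rate,
            "offset_s": e.offset / rate,
            "validated": e.labels.get("validated", True),
            **{k: v for k, v in e.labels.items() if k != "validated"},
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "session",
            "peak_sample",
            "onset_sample",
            "offset_sample",
            "peak_s",
            "onset_s",
            "offset_s",
            "validated",
        ]
        if not rows
        else None,
    )


# ---------------------------------------------------------------------------


def remove_noise_epochs(
    rec: LFPRecording,
    channel_pair: tuple[int, int] | None = None,
    k_sd: float = 10.0,
    epoch_s: float = 1.0,
) -> np.ndarray:
    """Boolean keep-mask over samples, excluding artifact epochs.

    Two separated channels are summed; non-overlapping epochs of
    ``epoch_s`` containing any sample deviating more than ``k_sd`` standard
    deviations from the mean of the summed signal are dropped whole.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    mask = np.ones(rec.n_samples, dtype=bool)
    if rec.n_channels < 2:
        logger.warning("remove_noise_epochs: single channel, no-op")
        return mask
    if channel_pair is None:
        channel_pair = (0, rec.n_channels - 1)
    a, b = channel_pair
    if a == b:
        raise ValueError("channel_pair must name two distinct channels")
    summed = rec.signal[a] + rec.signal[b]
    mu, sd = summed.mean(), summed.std()
    if sd == 0:
        return mask
    bad = np.abs(summed - mu) > k_sd * sd
    ep = max(1, int(round(epoch_s * rec.sampling_rate)))
    for start in range(0, rec.n_samples, ep):
        if bad[start : start + ep].any():
            mask[start : start + ep] = False
    if not mask.all():
        logger.info(
            "remove_noise_epochs: masked %.1f%% of samples",
            100 * (1 - mask.mean()),
        )
    return mask


def _band_power(x: np.ndarray, rate: float, band: tuple[float, float]) -> float:
    f, p = signal.welch(x, fs=rate, nperseg=min(x.size, 2048))
    sel = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(p[sel], f[sel]))


def select_sp_channel(rec: LFPRecording) -> int:
    """Channel maximizing the rank-sum of ripple-band (100-250 Hz) and
    multi-unit (300-400 Hz) power; ties resolved to the lowest index."""
    if not np.any(rec.signal):
        raise ValueError("all-zero recording")
    if rec.n_channels == 1:
        return 0
    ripple = np.array([_band_power(ch, rec.sampling_rate, (100, 250)) for ch in rec.signal])
    mua = np.array([_band_power(ch, rec.sampling_rate, (300, 400)) for ch in rec.signal])
    score = rankdata(ripple, method="min") + rankdata(mua, method="min")
    return int(np.argmax(score))  # argmax returns the first (lowest) maximum


def _movmean(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    return signal.convolve(x, np.ones(w) / w, mode="same")


def filter_and_envelope(
    trace: np.ndarray, rate: float, cfg: DetectionConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase band-pass plus smoothed analytic-signal envelope.

    The band-pass is a forward-backward FIR of order ``cfg.filter_order``
    (no group delay). The envelope is the analytic-signal magnitude smoothed
    by the Savitzky-Golay stage and the two moving means.
    """
    cfg = cfg or DetectionConfig()
    trace = np.asarray(trace, dtype=float)
    if trace.size <= 3 * cfg.filter_order:
        raise ValueError("trace too short for the requested filter order")
    lo, hi = cfg.band
    if hi >= rate / 2:
        raise ValueError("band upper edge at or above Nyquist")
    taps = signal.firwin(cfg.filter_order + 1, [lo, hi], pass_zero=False, fs=rate)
    filtered = signal.filtfilt(taps, 1.0, trace)
    env = np.abs(signal.hilbert(filtered))
    w = int(round(cfg.savgol_ms * rate / 1000))
    w += (w + 1) % 2  # Savitzky-Golay needs an odd window
    if w > cfg.savgol_order + 1:
        env = signal.savgol_filter(env, w, cfg.savgol_order)
    for ms in cfg.movmean_ms:
        env = _movmean(env, max(1, int(round(ms * rate / 1000))))
    return filtered, np.maximum(env, 0.0)


def _supra_intervals(above: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    return list(zip(starts, ends))


def merge_intervals(
    intervals: list[tuple[int, int]], gap: int
) -> list[tuple[int, int]]:
    """Merge half-open intervals whose separation is strictly below ``gap``.
    Idempotent: merging already-merged intervals changes nothing."""
    if not intervals:
        return []
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = merged[-1]
        if s - pe < gap:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def detect_and_center(
    filtered: np.ndarray,
    envelope: np.ndarray,
    rate: float,
    cfg: DetectionConfig | None = None,
    mask: np.ndarray | None = None,
    session: str = "session0",
) -> list[RippleEvent]:
    """Threshold the envelope, merge nearby events, center on the trough.

    The threshold is mean + ``threshold_sd`` s.d. of the envelope over kept
    samples. Supra-threshold intervals separated by less than the merge gap
    are joined. Each event's peak is the filtered-trace minimum within half
    the centering window of the interval's envelope maximum.
    """
    cfg = cfg or DetectionConfig()
    filtered = np.asarray(filtered, dtype=float)
    envelope = np.asarray(envelope, dtype=float)
    if filtered.shape != envelope.shape:
        raise ValueError("filtered and envelope must share length")
    if mask is None:
        mask = np.ones(filtered.size, dtype=bool)
    if not mask.any():
        raise ValueError("empty keep-mask")
    mu = envelope[mask].mean()
    sd = envelope[mask].std()
    thr = mu + cfg.threshold_sd * sd
    above = (envelope > thr) & mask
    if not above.any():
        return []
    gap = int(round(cfg.merge_gap_ms * rate / 1000))
    half_center = int(round(cfg.center_window_ms / 2 * rate / 1000))
    events = []
    for s, e in merge_intervals(_supra_intervals(above), gap):
        env_peak = s + int(np.argmax(envelope[s:e]))
        lo = max(0, env_peak - half_center)
        hi = min(filtered.size, env_peak + half_center + 1)
        seg = filtered[lo:hi]
        # the trough closest to the envelope peak: among local minima of the
        # filtered trace in the window, prefer depth but break near-ties
        # (within 5%) toward the envelope peak
        mins = np.flatnonzero((seg[1:-1] < seg[:-2]) & (seg[1:-1] <= seg[2:])) + 1
        if mins.size:
            depth = seg[mins]
            cand = mins[depth <= depth.min() * 0.95] if depth.min() < 0 else mins
            peak = lo + int(cand[np.argmin(np.abs(cand + lo - env_peak))])
        else:
            peak = lo + int(np.argmin(seg))
        # the trough may sit just outside the supra-threshold interval
        events.append(
            RippleEvent(
                peak=peak, onset=min(s, peak), offset=max(e - 1, peak), session=session
            )
        )
    events.sort(key=lambda ev: ev.peak)
    return events


def detect_ripples(
    rec: LFPRecording,
    cfg: DetectionConfig | None = None,
    sp_channel: int | None = None,
    mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full detection pass on a recording.

    Returns the event table and a context dict (sp channel, filtered trace,
    envelope, threshold config) reused by feature extraction.
    """
    cfg = cfg or DetectionConfig()
    ch = select_sp_channel(rec) if sp_channel is None else sp_channel
    filtered, envelope = filter_and_envelope(rec.signal[ch], rec.sampling_rate, cfg)
    if mask is None:
        mask = remove_noise_epochs(rec)
    events = detect_and_center(
        filtered, envelope, rec.sampling_rate, cfg, mask=mask, session=rec.session
    )
    table = events_to_table(events, rec.sampling_rate)
    ctx = {
        "sp_channel": ch,
        "filtered": filtered,
        "envelope": envelope,
        "config": cfg,
        "mask": mask,
    }
    logger.info("detect_ripples: %d events on channel %d", len(events), ch)
    return table, ctx
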