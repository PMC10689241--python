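"""Waveform-space construction.

Each validated event becomes one point in a D-dimensional space whose axes
are time samples of the peak-centered, band-passed, z-scored, resampled SP
trace (127 samples at the 2,500 Hz / +-25 ms defaults). Clouds from
different sessions share D and concatenate row-wise.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .containers import WaveformCloud
from .synthetic import window_samples

logger = logging.getLogger(__name__)

DEFAULT_RATE_OUT = 2500.0
DEFAULT_HALFWIDTH_MS = 25.0


def resample_trace(trace: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Polyphase rational resampling (anti-aliasing inherent)."""
    if rate_in == rate_out:
        return np.asarray(trace, dtype=float)
    frac = Fraction(rate_out / rate_in).limit_denominator(10000)
    return signal.resample_poly(np.asarray(trace, dtype=float), frac.numerator, frac.denominator)


def build_waveform_matrix(
    filtered: np.ndarray,
    events: pd.DataFrame,
    rate_in: float,
    rate_out: float = DEFAULT_RATE_OUT,
    halfwidth_ms: float = DEFAULT_HALFWIDTH_MS,
    zscore_scope: str = "session",
    session: str | None = None,
) -> WaveformCloud:
    """Cut peak-centered windows from the filtered SP trace.

    The trace is z-scored (per session over the full filtered trace by
    default, or per event), resampled to ``rate_out``, and cut into windows
    of ``window_samples(halfwidth_ms, rate_out)`` samples centered on each
    event peak. Events whose window leaves the trace are dropped and
    counted. Event metadata (features, labels) rides along row-aligned.
    """
    if "validated" in events.columns:
        events = events[events["validated"].astype(bool)]
    trace = np.asarray(filtered, dtype=float)
    if zscore_scope == "session":
        sd = trace.std()
        if sd == 0:
            raise ValueError("flat trace cannot be z-scored")
        trace = (trace - trace.mean()) / sd
    elif zscore_scope != "event":
        raise ValueError("zscore_scope must be 'session' or 'event'")

    res = resample_trace(trace, rate_in, rate_out)
    D = window_samples(halfwidth_ms, rate_out)
    half = (D - 1) // 2
    rows, kept, dropped = [], [], 0
    for i, ev in events.reset_index(drop=True).iterrows():
        p = int(round(int(ev["peak_sample"]) * rate_out / rate_in))
        if p - half < 0 or p + half >= res.size:
            dropped += 1
            continue
        w = res[p - half : p + half + 1]
        if zscore_scope == "event":
            sd = w.std()
            if sd == 0:
                dropped += 1
                continue
            w = (w - w.mean()) / sd
        rows.append(w)
        kept.append(i)
    if dropped:
        logger.info("build_waveform_matrix: dropped %d edge events", dropped)
    if not rows:
        raise ValueError("no events survived windowing")
    meta = events.reset_index(drop=True).iloc[kept].reset_index(drop=True)
    if session is not None and "session" not in meta.columns:
        meta = meta.assign(session=session)
    return WaveformCloud(
        np.vstack(rows),
        rate=rate_out,
        halfwidth_ms=halfwidth_ms,
        meta=meta,
        provenance={
            "zscore_scope": zscore_scope,
            "rate_in": rate_in,
            "dropped": dropped,
        },
    )
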