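"""Core in-memory containers shared across the pipeline.

The pipeline passes three kinds of objects between stages: a laminar LFP
recording (channels x samples with a depth/layer map), an event table (one
row per sharp-wave ripple, pandas DataFrame), and a waveform cloud (one row
per event, one column per time sample of the peak-centered ripple trace).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical CA1 laminae, superficial to deep recording order
LAYERS = ("SO", "SP", "SR", "SLM")


@dataclass
class LFPRecording:
    """Multichannel LFP with sampling rate and channel depth/layer map.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        LFP in microvolts or arbitrary units.
    sampling_rate : float
        Hz, > 0.
    depths_um : ndarray, shape (n_channels,)
        Monotone channel depths in micrometres.
    layers : sequence of str or None
        Optional per-channel layer label (one of ``LAYERS``).
    session : str
        Session identifier carried into event tables.
    """

    signal: np.ndarray
    sampling_rate: float
    depths_um: np.ndarray | None = None
    layers: tuple[str, ...] | None = None
    session: str = "session0"

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.depths_um is None:
            self.depths_um = np.arange(self.n_channels, dtype=float) * 100.0
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        if self.depths_um.shape[0] != self.n_channels:
            raise ValueError("depths_um length must match channel count")
        d = np.diff(self.depths_um)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("channel depths must be monotone")
        if self.layers is not None:
            self.layers = tuple(self.layers)
            if len(self.layers) != self.n_channels:
                raise ValueError("layers length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channels_in_layer(self, layer: str) -> np.ndarray:
        if self.layers is None:
            raise ValueError("recording has no layer labels")
        return np.flatnonzero(np.asarray(self.layers) == layer)


@dataclass
class WaveformCloud:
    """N x D point cloud of peak-centered ripple waveforms.

    Each row is one event's filtered, z-scored, resampled trace; each column
    one time sample. ``meta`` is row-aligned per-event metadata (features,
    labels, session, event id).
    """

    waveforms: np.ndarray
    rate: float = 2500.0
    halfwidth_ms: float = 25.0
    meta: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=float))
        if not np.all(np.isfinite(self.waveforms)):
            raise ValueError("waveform cloud contains non-finite values")
        if self.meta is None:
            self.meta = pd.DataFrame(index=np.arange(self.n_events))
        if len(self.meta) != self.n_events:
            raise ValueError("metadata rows must align with waveform rows")

    @property
    def n_events(self) -> int:
        return self.waveforms.shape[0]

    @property
    def n_dims(self) -> int:
        return self.waveforms.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times relative to the event peak, in ms."""
        half = (self.n_dims - 1) // 2
        return (np.arange(self.n_dims) - half) / self.rate * 1000.0

    def subset(self, idx: np.ndarray) -> "WaveformCloud":
        idx = np.asarray(idx)
        return WaveformCloud(
            self.waveforms[idx],
            rate=self.rate,
            halfwidth_ms=self.halfwidth_ms,
            meta=self.meta.iloc[idx].reset_index(drop=True),
            provenance=dict(self.provenance),
        )


def concat_clouds(clouds: list[WaveformCloud]) -> WaveformCloud:
    """Concatenate session clouds; D must match, per-session row order kept."""
    dims = {c.n_dims for c in clouds}
    if len(dims) != 1:
        raise ValueError(f"cannot concatenate clouds of differing D: {sorted(dims)}")
    meta = pd.concat([c.meta for c in clouds], ignore_index=True)
    return WaveformCloud(
        np.vstack([c.waveforms for c in clouds]),
        rate=clouds[0].rate,
        halfwidth_ms=clouds[0].halfwidth_ms,
        meta=meta,
        provenance={"concatenated": len(clouds)},
    )
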