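"""Synthetic data with known ground truth.

Three generators feed the test and validation machinery:

* :func:`generate_ripple_set` — ripple-like waveforms built by windowing a
  sinusoid with a Gaussian envelope; frequency, amplitude and duration are
  drawn independently and uniformly, so the noiseless cloud is a 3-parameter
  manifold in waveform space.
* :func:`generate_geometric_object` — point clouds of known topology and
  intrinsic dimension (line, plane, Swiss roll, torus, 5-ball) embedded
  orthonormally in a high-dimensional ambient space with isotropic Gaussian
  noise.
* :func:`generate_laminar_session` — a laminar LFP session whose per-layer
  sink/source magnitudes are programmed linear functions of the ripple
  features, so detection, CSD extraction and decoding are all checkable
  against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import LAYERS, LFPRecording, WaveformCloud

#: Gaussian envelope s.d. (ms) at duration_sd = 1; keeps events inside +-25 ms
BASE_ENVELOPE_SD_MS = 10.0

#: default uniform feature ranges for synthetic ripples
DEFAULT_FREQ_RANGE = (80.0, 240.0)
DEFAULT_AMP_RANGE = (1.0, 5.0)
DEFAULT_DUR_RANGE = (0.5, 2.0)

#: the three-cluster frequency ranges, Hz
CLUSTER_FREQ_RANGES = ((80.0, 100.0), (130.0, 150.0), (190.0, 210.0))

#: known intrinsic dimension per geometric object kind
OBJECT_INTRINSIC_DIM = {"line": 1, "plane": 2, "swissroll": 2, "torus": 2, "hyperball": 5}


@dataclass
class RippleParams:
    """Parameters of a single synthetic ripple."""

    frequency: float
    amplitude: float
    duration_sd: float
    sampling_rate: float = 2500.0
    window_halfwidth_ms: float = 25.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.duration_sd <= 0:
            raise ValueError("duration_sd must be positive")
        if self.sampling_rate < 2 * self.frequency:
            raise ValueError("sampling_rate below Nyquist for requested frequency")


def window_samples(halfwidth_ms: float, rate: float) -> int:
    """Number of samples D in a +-halfwidth window: center sample plus
    ceil(halfwidth*rate/1000) samples each side (127 at 2,500 Hz, +-25 ms)."""
    half = int(np.ceil(halfwidth_ms * rate / 1000.0))
    return 2 * half + 1


def ripple_waveform(params: RippleParams) -> np.ndarray:
    """Noiseless waveform: amplitude * Gaussian envelope * sin(2*pi*f*t)."""
    D = window_samples(params.window_halfwidth_ms, params.sampling_rate)
    half = (D - 1) // 2
    t = (np.arange(D) - half) / params.sampling_rate
    sd_s = params.duration_sd * BASE_ENVELOPE_SD_MS / 1000.0
    envelope = np.exp(-(t**2) / (2 * sd_s**2))
    return params.amplitude * envelope * np.sin(2 * np.pi * params.frequency * t)


def _check_disjoint(ranges: tuple[tuple[float, float], ...]) -> None:
    srt = sorted(ranges)
    for (lo, hi), (lo2, _) in zip(srt[:-1], srt[1:]):
        if hi >= lo2:
            raise ValueError(f"cluster frequency ranges overlap: {ranges}")


def generate_ripple_set(
    n: int = 2000,
    mode: str = "continuous",
    freq_spec=DEFAULT_FREQ_RANGE,
    amp_range: tuple[float, float] = DEFAULT_AMP_RANGE,
    dur_range: tuple[float, float] = DEFAULT_DUR_RANGE,
    noise_rms: float = 0.0,
    rate: float = 2500.0,
    window_ms: float = 25.0,
    seed: int | None = 0,
) -> WaveformCloud:
    """Draw ``n`` synthetic ripples with independent uniform features.

    ``mode='continuous'`` draws frequency uniformly over ``freq_spec`` (one
    range); ``mode='clustered'`` expects >= 2 disjoint ranges and assigns
    events to ranges uniformly. Gaussian noise of s.d. ``noise_rms`` is added
    per sample. The returned cloud's metadata carries the exact drawn
    (frequency, amplitude, duration_sd) per event and, in clustered mode, the
    cluster id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "continuous":
        lo, hi = freq_spec
        if not hi > lo:
            raise ValueError("continuous mode needs a non-degenerate frequency range")
        freq = rng.uniform(lo, hi, n)
        cluster = np.zeros(n, dtype=int)
    elif mode == "clustered":
        ranges = tuple(tuple(map(float, r)) for r in freq_spec)
        if len(ranges) < 2:
            raise ValueError("clustered mode needs >= 2 frequency ranges")
        _check_disjoint(ranges)
        cluster = rng.integers(0, len(ranges), n)
        lows = np.array([r[0] for r in ranges])
        highs = np.array([r[1] for r in ranges])
        freq = rng.uniform(lows[cluster], highs[cluster])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if rate < 2 * np.max(freq):
        raise ValueError("sampling rate below Nyquist for the maximum frequency")

    amp = rng.uniform(*amp_range, n)
    dur = rng.uniform(*dur_range, n)

    D = window_samples(window_ms, rate)
    half = (D - 1) // 2
    t = (np.arange(D) - half) / rate
    sd_s = dur[:, None] * BASE_ENVELOPE_SD_MS / 1000.0
    wf = amp[:, None] * np.exp(-(t[None, :] ** 2) / (2 * sd_s**2)) * np.sin(
        2 * np.pi * freq[:, None] * t[None, :]
    )
    if noise_rms > 0:
        wf = wf + rng.normal(0.0, noise_rms, wf.shape)

    meta = pd.DataFrame(
        {
            "frequency": freq,
            "amplitude": amp,
            "duration": dur,
            "cluster": cluster,
            "event_id": np.arange(n),
        }
    )
    return WaveformCloud(
        wf,
        rate=rate,
        halfwidth_ms=window_ms,
        meta=meta,
        provenance={
            "generator": "synthetic_ripples",
            "mode": mode,
            "noise_rms": noise_rms,
            "seed": seed,
        },
    )


@dataclass
class GroundTruthObject:
    """Specification of a geometric object of known topology/dimension."""

    kind: str
    n_points: int = 1000
    ambient_dim: int = 127
    noise_sd: float = 0.01
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.kind not in OBJECT_INTRINSIC_DIM:
            raise ValueError(
                f"unknown object kind {self.kind!r}; known: {sorted(OBJECT_INTRINSIC_DIM)}"
            )
        if self.n_points < 50:
            raise ValueError("n_points must be >= 50")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def intrinsic_dim(self) -> int:
        return OBJECT_INTRINSIC_DIM[self.kind]


#: torus radii: 10:3 major/minor ratio gives clear scale separation between
#: the two loops; absolute scale keeps the per-dimension ambient noise (0.01)
#: negligible against local neighborhood extent in 127 dimensions
TORUS_MAJOR, TORUS_MINOR = 10.0, 3.0

#: parametric scales of the other objects, chosen with the same criterion
LINE_LENGTH = 100.0
PLANE_SIDE = 20.0
SWISSROLL_SCALE = 20.0
HYPERBALL_RADIUS = 10.0


def _sample_torus(n: int, rng: np.random.Generator) -> np.ndarray:
    # area-uniform sampling: minor angle density prop. to R + r*cos(v)
    u = rng.uniform(0, 2 * np.pi, n)
    v = np.empty(n)
    filled = 0
    while filled < n:
        cand = rng.uniform(0, 2 * np.pi, 2 * (n - filled))
        acc = cand[rng.uniform(0, 1, cand.size) < (TORUS_MAJOR + TORUS_MINOR * np.cos(cand)) / (TORUS_MAJOR + TORUS_MINOR)]
        take = acc[: n - filled]
        v[filled : filled + take.size] = take
        filled += take.size
    R, r = TORUS_MAJOR, TORUS_MINOR
    return np.column_stack(
        [(R + r * np.cos(v)) * np.cos(u), (R + r * np.cos(v)) * np.sin(u), r * np.sin(v)]
    )


def _sample_parametric(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if kind == "line":
        return rng.uniform(0, LINE_LENGTH, (n, 1))
    if kind == "plane":
        return rng.uniform(0, PLANE_SIDE, (n, 2))
    if kind == "swissroll":
        # classic roll: t in [1.5pi, 4.5pi]; outer radius and height ~ 2x scale
        t = rng.uniform(1.5 * np.pi, 4.5 * np.pi, n)
        y = rng.uniform(0, 2 * SWISSROLL_SCALE, n)
        s = SWISSROLL_SCALE / (4.5 * np.pi)
        return np.column_stack([s * t * np.cos(t), y, s * t * np.sin(t)])
    if kind == "torus":
        return _sample_torus(n, rng)
    if kind == "hyperball":
        # uniform in the 5-ball: isotropic direction, radius ~ U^(1/5)
        x = rng.normal(size=(n, 5))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        return x * rng.uniform(0, 1, (n, 1)) ** (1 / 5) * HYPERBALL_RADIUS
    raise ValueError(kind)


def generate_geometric_object(spec: GroundTruthObject) -> np.ndarray:
    """Sample points from the object and embed them in ``ambient_dim``.

    The parametric sample is mapped through a seeded random orthonormal basis
    (QR of a Gaussian matrix), preserving all pairwise distances, then
    isotropic Gaussian noise of s.d. ``noise_sd`` is added in every ambient
    direction.
    """
    rng = np.random.default_rng(spec.seed)
    base = _sample_parametric(spec.kind, spec.n_points, rng)
    d = base.shape[1]
    if spec.ambient_dim < d:
        raise ValueError("ambient_dim smaller than the object's parametric dimension")
    q, _ = np.linalg.qr(rng.normal(size=(spec.ambient_dim, d)))
    x = base @ q.T
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, x.shape)
    return x


# ---------------------------------------------------------------------------
# laminar sessions


@dataclass
class LaminarCouplingSpec:
    """Programmed linear feature -> per-layer sink/source coupling.

    For an event with features normalized to [0, 1] within their draw ranges
    (zf, za, zd), the deflection magnitude of layer L is::

        m_L = intercept + g_freq*zf + g_amp*za + g_dur*zd

    in the sink-negative / source-positive convention. Magnitudes multiply a
    Gaussian temporal kernel and a Gaussian spatial kernel centered on the
    layer, so the laminar CSD at the event peak is an exactly known linear
    function of the drawn features.
    """

    gains: dict = field(
        default_factory=lambda: {
            # (intercept, g_freq, g_amp, g_dur); SR carries the sharp-wave sink
            "SO": (0.5, 0.0, 1.0, 0.0),
            "SP": (0.2, 0.0, 0.0, 0.0),
            "SR": (-1.0, -3.0, -1.5, 0.0),
            "SLM": (0.5, 0.0, 0.0, 2.0),
        }
    )
    channels_per_layer: int = 3
    spacing_um: float = 100.0
    noise_sd: float = 0.05
    background_sd: float = 1.0
    spatial_sd_um: float = 120.0
    temporal_sd_ms: float = 8.0

    def __post_init__(self) -> None:
        missing = [l for l in LAYERS if l not in self.gains]
        if missing:
            raise ValueError(f"coupling spec missing layers: {missing}")
        if all(np.allclose(self.gains[l], 0) for l in LAYERS):
            raise ValueError("at least one layer must have nonzero coupling")


def _normalize(x: np.ndarray, rng_pair: tuple[float, float]) -> np.ndarray:
    lo, hi = rng_pair
    return (x - lo) / (hi - lo)


def generate_laminar_session(
    n_events: int = 200,
    coupling: LaminarCouplingSpec | None = None,
    duration_s: float | None = None,
    rate: float = 2500.0,
    refractory_s: float = 0.25,
    freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
    amp_range: tuple[float, float] = DEFAULT_AMP_RANGE,
    dur_range: tuple[float, float] = DEFAULT_DUR_RANGE,
    seed: int | None = 0,
    session: str = "synthetic0",
) -> tuple[LFPRecording, pd.DataFrame, pd.DataFrame]:
    """Simulate a laminar recording containing ``n_events`` ripples.

    Returns ``(recording, truth_table, true_csd)``: the recording has
    ``4 * channels_per_layer`` channels labeled SO/SP/SR/SLM; the truth table
    holds each event's peak sample and drawn features; ``true_csd`` holds the
    per-layer deflection magnitudes and the exact noiseless per-layer CSD at
    the event peak (second spatial derivative, sinks negative).
    """
    coupling = coupling or LaminarCouplingSpec()
    rng = np.random.default_rng(seed)
    if duration_s is None:
        # ~0.5 events/s, the upper end of physiological SWR rates at rest;
        # denser sessions inflate the envelope s.d. and bias the threshold
        duration_s = max((n_events + 2) * 2.0, (n_events + 2) * refractory_s * 2)
    n_samples = int(round(duration_s * rate))
    min_spacing = int(round(refractory_s * rate))
    margin = int(0.06 * rate) + 1
    if (n_events + 1) * min_spacing + 2 * margin > n_samples:
        raise ValueError("events denser than the refractory gap allows")

    # evenly spaced peaks with uniform jitter inside each slot
    slot = (n_samples - 2 * margin) // n_events
    jitter = rng.integers(0, max(slot - min_spacing, 1), n_events)
    peaks = margin + np.arange(n_events) * slot + jitter

    freq = rng.uniform(*freq_range, n_events)
    amp = rng.uniform(*amp_range, n_events)
    dur = rng.uniform(*dur_range, n_events)
    zf, za, zd = (
        _normalize(freq, freq_range),
        _normalize(amp, amp_range),
        _normalize(dur, dur_range),
    )

    n_per = coupling.channels_per_layer
    n_channels = n_per * len(LAYERS)
    depths = np.arange(n_channels) * coupling.spacing_um
    layer_labels = tuple(l for l in LAYERS for _ in range(n_per))
    layer_centers = {
        l: depths[np.asarray(layer_labels) == l].mean() for l in LAYERS
    }

    # per-event layer magnitudes (exact, pre-noise)
    mags = {
        l: c[0] + c[1] * zf + c[2] * za + c[3] * zd
        for l, c in ((l, coupling.gains[l]) for l in LAYERS)
    }

    # spatial profile: sum of Gaussian bumps centered on each layer
    profile = np.zeros((n_events, n_channels))
    for l in LAYERS:
        w = np.exp(-((depths - layer_centers[l]) ** 2) / (2 * coupling.spatial_sd_um**2))
        profile += np.outer(mags[l], w)

    signal = rng.normal(0.0, coupling.noise_sd, (n_channels, n_samples))
    if coupling.background_sd > 0:
        # common-mode slow background (volume-conducted ongoing activity):
        # constant across depth, so it cancels in the CSD and lies below the
        # ripple band, but it dominates the raw-signal variance as in vivo
        from scipy import signal as sps

        sos = sps.butter(2, 20.0, btype="low", fs=rate, output="sos")
        bg = sps.sosfiltfilt(sos, rng.normal(0.0, 1.0, n_samples))
        bg *= coupling.background_sd / bg.std()
        signal += bg[None, :]

    # temporal kernels
    sd_t = coupling.temporal_sd_ms / 1000.0
    kern_half = int(round(4 * sd_t * rate))
    tk = np.arange(-kern_half, kern_half + 1) / rate
    slow = np.exp(-(tk**2) / (2 * sd_t**2))

    sp_channels = np.flatnonzero(np.asarray(layer_labels) == "SP")
    troughs = np.empty(n_events, dtype=int)
    for i, p in enumerate(peaks):
        rp = RippleParams(freq[i], amp[i], dur[i], sampling_rate=rate)
        rw = ripple_waveform(rp)
        rhalf = (rw.size - 1) // 2
        troughs[i] = p - rhalf + int(np.argmin(rw))
        sl = slice(p - rhalf, p + rhalf + 1)
        for c in sp_channels:
            signal[c, sl] += rw
        sl2 = slice(p - kern_half, p + kern_half + 1)
        signal[:, sl2] += profile[i][:, None] * slow[None, :]

    rec = LFPRecording(
        signal, rate, depths_um=depths, layers=layer_labels, session=session
    )

    truth = pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "peak_sample": peaks,
            "trough_sample": troughs,
            "peak_s": peaks / rate,
            "frequency": freq,
            "amplitude": amp,
            "duration": dur,
        }
    )

    # exact noiseless CSD of the programmed profile at the event peak
    h = coupling.spacing_um / 1000.0  # mm
    csd = np.full((n_events, n_channels), np.nan)
    csd[:, 1:-1] = (profile[:, :-2] - 2 * profile[:, 1:-1] + profile[:, 2:]) / h**2
    csd_rows = {"event_id": np.arange(n_events)}
    lab = np.asarray(layer_labels)
    for l in LAYERS:
        cols = np.flatnonzero(lab == l)
        csd_rows[f"csd_{l}"] = np.nanmean(csd[:, cols], axis=1)
        csd_rows[f"mag_{l}"] = mags[l]
    true_csd = pd.DataFrame(csd_rows)
    return rec, truth, true_csd
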