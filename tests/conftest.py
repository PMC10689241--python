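import numpy as np
import pytest

from ripplemap.detection import detect_ripples
from ripplemap.features import compute_features, event_csd_table
from ripplemap.synthetic import (
    LaminarCouplingSpec,
    generate_laminar_session,
    generate_ripple_set,
)
from ripplemap.waveforms import build_waveform_matrix


@pytest.fixture(scope="session")
def ripple_cloud():
    """2,000 noiseless continuous-frequency synthetic ripples (the standard
    waveform-space test cloud)."""
    return generate_ripple_set(2000, seed=1)


@pytest.fixture(scope="session")
def clustered_cloud():
    return generate_ripple_set(
        2000,
        mode="clustered",
        freq_spec=((80.0, 100.0), (130.0, 150.0), (190.0, 210.0)),
        seed=1,
    )


@pytest.fixture(scope="session")
def laminar():
    """Default-coupling laminar session with the full detection context."""
    rec, truth, true_csd = generate_laminar_session(n_events=120, seed=0)
    table, ctx = detect_ripples(rec)
    return {"rec": rec, "truth": truth, "true_csd": true_csd, "events": table, "ctx": ctx}


@pytest.fixture(scope="session")
def decoding_session():
    """Session with one strongly coupled layer (SO) and one uncoupled layer
    (SLM) placed far enough apart that volume conduction cannot link them."""
    coupling = LaminarCouplingSpec(
        gains={
            "SO": (0.5, -2.0, 1.5, 0.0),
            "SP": (0.2, 0.0, 0.0, 0.0),
            "SR": (-1.0, 0.0, 0.0, 0.0),
            "SLM": (0.5, 0.0, 0.0, 0.0),
        }
    )
    rec, truth, true_csd = generate_laminar_session(
        n_events=250, coupling=coupling, seed=3
    )
    table, ctx = detect_ripples(rec)
    csd = event_csd_table(rec, table["peak_sample"].to_numpy())
    cloud = build_waveform_matrix(ctx["filtered"], table, rec.sampling_rate)
    feats = compute_features(rec, table, ctx)
    n = min(cloud.n_events, len(csd), len(feats))
    return {
        "rec": rec,
        "truth": truth,
        "true_csd": true_csd,
        "events": table,
        "csd": csd.iloc[:n],
        "cloud": cloud,
        "X": cloud.waveforms[:n],
        "features": feats.iloc[:n],
        "coupled": "SO",
        "uncoupled": "SLM",
    }


def match_events(detected_peaks, true_troughs, rate, tol_ms=2.0):
    """Precision/recall of detected peaks against true trough samples."""
    detected_peaks = np.asarray(detected_peaks)
    true_troughs = np.asarray(true_troughs)
    tol = int(round(tol_ms / 1000 * rate))
    d = np.abs(detected_peaks[:, None] - true_troughs[None, :])
    precision = float((d.min(axis=1) <= tol).mean())
    recall = float((d.min(axis=0) <= tol).mean())
    return precision, recall
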