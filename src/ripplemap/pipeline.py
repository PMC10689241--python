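"""End-to-end orchestration of the analysis stages on one configuration.

Stages run in dependency order (simulate -> detect -> features -> cloud ->
topo -> si -> embed -> decode); each persists its artifact and the run
manifest records seeds and per-stage counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io as rio
from .containers import LAYERS

logger = logging.getLogger(__name__)

STAGES = ("simulate", "detect", "features", "cloud", "topo", "si", "embed", "decode")


def run_pipeline(config: dict, seed: int = 0, outdir: Path = Path("run")) -> dict:
    """Run the synthetic pipeline; returns {stage: artifact path}.

    ``config`` keys: ``simulate`` (laminar-session parameters), ``detect``
    (DetectionConfig fields), ``stages`` (subset to run, default all).
    """
    from .decoding import train_csd_decoder
    from .detection import DetectionConfig, detect_ripples
    from .features import compute_features, event_csd_table
    from .geometry import reduce_embedding
    from .structure_index import si_report
    from .synthetic import generate_laminar_session
    from .topology import abid_dimension, betti_numbers, persistence_barcodes, remove_outliers
    from .waveforms import build_waveform_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", STAGES)
    artifacts: dict[str, Path] = {}
    counts: dict[str, int] = {}

    rec, truth, true_csd = generate_laminar_session(
        seed=seed, **config.get("simulate", {})
    )
    rio.write_recording(rec, outdir / "recording.h5")
    rio.write_table(truth, outdir / "truth.tsv")
    artifacts["simulate"] = outdir / "recording.h5"
    counts["events_simulated"] = len(truth)
    if stages == ["simulate"]:
        return artifacts

    det_cfg = DetectionConfig(**config.get("detect", {}))
    events, ctx = detect_ripples(rec, det_cfg)
    rio.write_table(events, outdir / "events.tsv")
    artifacts["detect"] = outdir / "events.tsv"
    counts["events_detected"] = len(events)

    feats = compute_features(rec, events, ctx)
    rio.write_table(feats, outdir / "features.tsv")
    artifacts["features"] = outdir / "features.tsv"
    csd = event_csd_table(rec, events["peak_sample"].to_numpy())
    rio.write_table(csd, outdir / "csd.tsv")

    cloud = build_waveform_matrix(
        ctx["filtered"],
        events.assign(**{c: feats[c].to_numpy() for c in feats.columns if c != "session"}),
        rec.sampling_rate,
        session=rec.session,
    )
    rio.write_cloud(cloud, outdir / "cloud.h5")
    artifacts["cloud"] = outdir / "cloud.h5"
    counts["cloud_events"] = cloud.n_events

    if "topo" in stages:
        filt, removed = remove_outliers(cloud)
        bc = persistence_barcodes(filt, maxdim=0, seed=seed)[0]
        dim = abid_dimension(filt, k=min(50, filt.n_events - 1))
        summary = {
            "betti": betti_numbers(bc),
            "abid": dim.value,
            "outliers_removed": int(removed.size),
        }
        (outdir / "topo.json").write_text(json.dumps(summary, default=str, indent=2))
        artifacts["topo"] = outdir / "topo.json"
        counts["outliers_removed"] = int(removed.size)

    if "si" in stages:
        cols = [c for c in ("frequency", "amplitude", "entropy", "duration_auc") if c in cloud.meta]
        report = si_report(cloud.waveforms, cloud.meta[cols], seed=seed)
        rio.write_table(report, outdir / "si.tsv")
        artifacts["si"] = outdir / "si.tsv"

    if "embed" in stages:
        emb = reduce_embedding(cloud, method=config.get("embed_method", "pca"), d=4, seed=seed)
        rio.write_embedding(emb, outdir / "embedding.h5")
        artifacts["embed"] = outdir / "embedding.h5"

    if "decode" in stages:
        if "cloud" not in artifacts:
            raise RuntimeError("decode requires the cloud stage to run first")
        n = min(cloud.n_events, len(csd))
        bundle = train_csd_decoder(
            cloud.waveforms[:n], csd.iloc[:n], space="original", seed=seed
        )
        rio.write_table(bundle.scores, outdir / "decoder_scores.tsv")
        artifacts["decode"] = outdir / "decoder_scores.tsv"

    rio.RunManifest("pipeline", config, seed=seed, counts=counts).write(
        outdir / "manifest.json"
    )
    artifacts["manifest"] = outdir / "manifest.json"
    return artifacts
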