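"""Containers on disk, run manifests and structured logging.

Tables (events, features, CSD) are delimited text with a typed header;
clouds and embeddings go into HDF5 containers with a metadata block. Every
CLI run emits one JSON manifest with the config snapshot, seeds, versions
and per-stage row counts. Conventions: 0-based sample indices, seconds for
times, half-open [onset, offset) intervals.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .containers import LFPRecording, WaveformCloud

logger = logging.getLogger(__name__)


def write_table(df: pd.DataFrame, path) -> None:
    """Tab-delimited table with a typed header line (# column:dtype ...)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(f"{c}:{df[c].dtype}" for c in df.columns) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh, sep="\t")
    if header.startswith("# "):
        for spec in header[2:].strip().split("\t"):
            col, dtype = spec.rsplit(":", 1)
            if col in df.columns:
                df[col] = df[col].astype(dtype)
    return df


def write_cloud(cloud: WaveformCloud, path) -> None:
    """HDF5 container: waveform matrix + row-aligned metadata + provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("waveforms", data=cloud.waveforms)
        f.attrs["rate"] = cloud.rate
        f.attrs["halfwidth_ms"] = cloud.halfwidth_ms
        f.attrs["provenance"] = json.dumps(cloud.provenance, default=str)
        g = f.create_group("meta")
        for col in cloud.meta.columns:
            vals = cloud.meta[col].to_numpy()
            if vals.dtype == object:
                g.create_dataset(col, data=vals.astype("S"))
            else:
                g.create_dataset(col, data=vals)


def read_cloud(path) -> WaveformCloud:
    with h5py.File(path, "r") as f:
        wf = f["waveforms"][()]
        meta = {}
        for col in f["meta"]:
            v = f["meta"][col][()]
            if v.dtype.kind == "S":
                v = v.astype(str)
            meta[col] = v
        return WaveformCloud(
            wf,
            rate=float(f.attrs["rate"]),
            halfwidth_ms=float(f.attrs["halfwidth_ms"]),
            meta=pd.DataFrame(meta),
            provenance=json.loads(f.attrs["provenance"]),
        )


def write_recording(rec: LFPRecording, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("depths_um", data=rec.depths_um)
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["session"] = rec.session
        if rec.layers is not None:
            f.create_dataset("layers", data=np.asarray(rec.layers, dtype="S"))


def read_recording(path) -> LFPRecording:
    with h5py.File(path, "r") as f:
        layers = None
        if "layers" in f:
            layers = tuple(f["layers"][()].astype(str))
        return LFPRecording(
            f["signal"][()],
            float(f.attrs["sampling_rate"]),
            depths_um=f["depths_um"][()],
            layers=layers,
            session=str(f.attrs["session"]),
        )


def write_embedding(emb, path) -> None:
    """Embedding coordinates + provenance (the fitted handle itself is not
    serialized; refit from the cloud to reproduce)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=emb.coords)
        f.attrs["method"] = emb.method
        f.attrs["seed"] = -1 if emb.seed is None else emb.seed
        f.attrs["provenance"] = json.dumps(emb.provenance, default=str)


@dataclass
class RunManifest:
    """One manifest per CLI run: everything needed to re-run the stage."""

    stage: str
    config: dict
    seed: int | None = None
    counts: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def write(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "stage": self.stage,
            "config": self.config,
            "seed": self.seed,
            "counts": self.counts,
            "inputs": self.inputs,
            "version": __version__,
            "python": platform.python_version(),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        logger.info("manifest written to %s", path)


def load_config(path) -> dict:
    """key=value or JSON config file."""
    text = Path(path).read_text()
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        cfg = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            try:
                cfg[key.strip()] = json.loads(val.strip())
            except json.JSONDecodeError:
                cfg[key.strip()] = val.strip()
        return cfg
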