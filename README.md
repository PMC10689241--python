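# ripplemap

Topological analysis of hippocampal sharp-wave ripple (SWR) waveforms.

SWRs are transient CA1 events combining a stratum-radiatum sharp wave with a
pyramidal-layer high-frequency ripple. Whether they fall into discrete
categories or form a continuum is hard to settle with clustering in a
predefined feature space. `ripplemap` takes the unbiased route: each
detected event becomes one point in a **waveform space** — the 127 samples
of its peak-centered, 70–400 Hz filtered, z-scored pyramidal-layer trace at
2,500 Hz, one dimension per sample — and the question becomes geometric. The
package is aimed at systems neuroscientists working with laminar LFP
recordings and at methodologists who want the estimators with their
calibration machinery.

What it computes on that point cloud:

* **Persistent homology** (own Vietoris–Rips engine, H0–H2 over Z/2 with
  clearing/compression, verified bar-for-bar against a naive full
  reduction), with outlier exclusion, bootstrap subsampling and a
  deterministic Betti-significance rule — are there clusters (b0 > 1),
  loops (b1) or cavities (b2)?
* **Intrinsic dimension** via the angle-based estimator (ABID): for
  isotropic directions in d dimensions E[cos²θ] = 1/d, so each point's
  neighborhood yields d̂ = k(k−1)/Σ_{i≠j}cos²θ; the median over points
  estimates the number of coordinates the cloud really uses.
* **Structure Index**: feature values are split into 10 bins; the k-NN
  overlap between bins forms a directed graph with adjacency A, and
  SI = max(0, 1 − (2/(n²−n))·ΣA) scores how separable the feature's
  gradient is (1 = perfectly ordered, 0 = random), with a calibrated
  permutation test.
* **Embedding geometry** on UMAP/Isomap/PCA reductions: voxelized spatial
  correlation between features (with a toy-model voxel-size validator),
  KDE density-contour regions of interest, centroid statistics with
  bootstrap and label shuffles, rigid (Kabsch) alignment of embeddings via
  shared feature bins, and projection of new events with fitting/alignment
  error baselines.
* **Laminar decoding**: per-layer current source density (CSD, the second
  spatial depth-derivative; sinks negative) predicted from waveform-space
  position by tenfold cross-validated SVR — the embedding refit per
  training fold — scored as explained variance 1 − var(y−y′)/var(y)
  against a shuffled-target chance band, plus an SVC (C=1, RBF) classifier
  of event origin.

A synthetic-data module generates ripples with known feature draws,
geometric ground-truth objects (line, plane, swiss roll, torus, 5-ball) in
127D, and laminar sessions whose per-layer sinks are programmed functions
of the ripple features — so every stage is testable against construction.

## Worked example

```python
import numpy as np
from ripplemap import (
    abid_dimension, betti_numbers, detect_ripples, event_csd_table,
    generate_laminar_session, build_waveform_matrix, compute_features,
    persistence_barcodes, remove_outliers, structure_index, train_csd_decoder,
)

rec, truth, true_csd = generate_laminar_session(n_events=200, seed=0)
events, ctx = detect_ripples(rec)
feats = compute_features(rec, events, ctx)
cloud = build_waveform_matrix(ctx["filtered"], events, rec.sampling_rate)

dim = abid_dimension(cloud, k=50)
filtered, removed = remove_outliers(cloud)
bc = persistence_barcodes(filtered, maxdim=0, seed=0)[0]
si = structure_index(cloud.waveforms, feats["frequency"].to_numpy(),
                     k=10, n_shuffles=50, seed=0)
csd = event_csd_table(rec, events["peak_sample"].to_numpy())
n = min(cloud.n_events, len(csd))
bundle = train_csd_decoder(cloud.waveforms[:n], csd.iloc[:n],
                           space="original", seed=0)
```

prints (via the corresponding report lines):

```text
detected 197 of 200 events on channel 3 (SP)
waveform cloud: 197 events x 127 samples
ABID intrinsic dimension: 2.65
Betti H0 (components): 1  (10 outliers excluded)
SI(frequency) = 0.86, permutation p = 0.020
decoder EV SO: +0.94 (chance band [-0.24, +0.05])
decoder EV SP: +0.98 (chance band [-0.57, -0.04])
decoder EV SR: +0.97 (chance band [-0.25, +0.03])
decoder EV SLM: +0.88 (chance band [-0.41, +0.03])
```

Reading: detection recovers nearly all injected events and centers them on
the ripple trough; the 127-dimensional cloud is one connected component
(a continuum, not discrete clusters) of low intrinsic dimension; ripple
frequency organizes the cloud strongly (SI 0.86, above all 50 label
shuffles); and every layer's sharp-wave CSD — a programmed function of the
ripple features in this synthetic session — is decoded from waveform-space
position with explained variance near 1 while shuffled targets stay at
chance.

There is also a CLI mirroring the stages:

```bash
ripplemap simulate --kind session --seed 0 --out run/sim
ripplemap detect --recording run/sim/recording.h5 --out run/det
ripplemap cloud --recording run/sim/recording.h5 --events run/det/events.tsv --out run/cloud
ripplemap topo --cloud run/cloud/cloud.h5 --maxdim 0 --out run/topo
ripplemap si --cloud run/cloud/cloud.h5 --out run/si
```

Every run writes a JSON manifest (config, seed, versions, row counts).

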