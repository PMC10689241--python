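# Methods

`ripplemap` analyzes hippocampal sharp-wave ripples (SWRs) as points in a
*waveform space*: each detected event contributes the 127 samples of its
peak-centered, 70–400 Hz filtered, z-scored pyramidal-layer (SP) trace at
2,500 Hz, one coordinate per sample. The package characterizes the geometry
and topology of that point cloud, quantifies how ripple features organize
it, and decodes laminar current source density (CSD) from positions in it.
This note documents the models, the estimators, the numerical choices, and
what the synthetic generators do and do not emulate.

## Detection

Consensus SWR detection on the SP channel:

1. **Artifact masking.** Two separated channels are summed; whole epochs
   (1 s, non-overlapping; the epoch length is our choice — the consensus
   criterion specifies only the 10 s.d. rule) containing any sample
   deviating more than 10 s.d. from the mean of the summed signal are
   excluded.
2. **SP channel selection.** The channel maximizing the rank-sum of
   ripple-band (100–250 Hz) and multi-unit (300–400 Hz) Welch power. The
   rank-sum combiner is our choice of how to combine the two criteria; ties
   resolve to the lowest index.
3. **Filtering.** Zero-phase FIR band-pass of order 512, 70–400 Hz
   (`firwin` + `filtfilt`; no group delay).
4. **Envelope.** Magnitude of the analytic signal, smoothed by a 4th-order
   Savitzky–Golay filter (33.4 ms window) and two moving means (2.3 and
   6.7 ms). We read the smoothing cascade as applying to an envelope that
   must first exist, hence the Hilbert magnitude as its input; for a pure
   tone of amplitude *a* the envelope is flat at *a* within 5%.
5. **Thresholding.** mean + *k*·s.d. of the envelope over kept samples,
   *k* ∈ [2, 5] (default 3, the midpoint). Values outside [2, 5] are
   rejected.
6. **Merging.** Supra-threshold intervals strictly closer than 15 ms are
   joined (an exactly-15 ms gap is not merged). Merging is idempotent.
7. **Centering.** Within a 30 ms window (±15 ms) around the interval's
   envelope maximum, the event peak is the *local minimum of the filtered
   trace nearest the envelope peak*, with depth near-ties (within 5% of the
   deepest) broken toward the envelope peak. A plain global argmin misplaces
   ~5% of high-frequency events by one ripple cycle, because neighboring
   troughs of a ~230 Hz event differ by under 1% in depth.

Expert visual validation is out of band: a boolean `validated` column is
honored when present, otherwise all detections pass.

## Event features

* **Frequency** — the peak of the spectral bump in 70–400 Hz after
  subtracting a fitted exponential background. The fit runs in the log
  domain (where *a*·exp(−*b·f*) is linear) in two passes, the second
  excluding the bins the bump occupies (residual above the median); this
  keeps the estimate unbiased (< 1 Hz error on noiseless synthetic ripples
  across 80–240 Hz) including at the band edge, where a single-pass fit
  tilts the residual by ~5 Hz. The peak is located on the fine periodogram
  grid; the 10 Hz binning below quantizes the entropy, not the peak.
* **Spectral entropy** — Shannon entropy (bits) of the Hann periodogram
  accumulated into 10 Hz bins and normalized to sum 1:
  `Entropy = −Σ p(f)·log2 p(f)`. A uniform 32-bin spectrum gives exactly
  5 bits; a one-bin spectrum gives 0.
* **MUA index** — binned power summed over 300–400 Hz.
* **Amplitude** — envelope maximum within ±25 ms of the peak (an envelope
  value *at* the peak would miss the maximum by the smoothing lag; the
  choice is flagged as an interpretation).
* **Duration** — (a) envelope crossing span at the event-local mean + 1 s.d.
  (threshold our choice, reported in ms), and (b) area under the
  amplitude-normalized rectified filtered trace over ±100 ms (a.u.;
  invariant to amplitude scaling and zero-padding).
* **Slopes** — 1–10 Hz zero-phase Butterworth, least-squares line on
  [peak−25 ms, peak] and [peak, peak+25 ms] for SP (ripple) and SR
  (sharp wave); missing SR yields NaN sharp-wave slopes.
* **CSD** — discrete second spatial derivative
  `(V[i−1] − 2V[i] + V[i+1]) / h²` (h in mm), interior channels only, sinks
  negative / sources positive. Per-layer summaries require ≥ 8 contiguous
  channels covering SO→SLM and average the interior channels of each layer
  at the event peak (±4 ms). By default the signals are low-passed at 50 Hz
  (zero-phase) first: the SP-confined ripple otherwise dominates the
  discrete Laplacian at adjacent layers — a genuine volume-conduction
  effect, but the decoding target is the slow sharp-wave sink/source
  structure. Pass `lowpass_hz=None` for wideband CSD.

## Waveform space

±25 ms at 2,500 Hz does not give an integer sample count; we take 63
samples each side of the center sample (127 total, ±25.2 ms effective).
The ±20 ms variant (101 samples) is supported. z-scoring is per session
over the full filtered trace — per-event scoring would erase the amplitude
structure that the feature analysis demonstrably retains. Resampling is
polyphase rational (anti-aliasing inherent). Edge events are dropped and
counted.

## Persistent homology

No Rips backend is assumed: the package includes its own Vietoris–Rips
persistence for H0–H2 over Z/2. H0 comes from union-find over the sorted
edge filtration (Kruskal pairing); H1/H2 from boundary-matrix reduction
with clearing (tetrahedra first; their pivot triangles are skipped in the
triangle reduction) and compression (rows of negative edges dropped).
Columns are sparse sets of row indices; simplex enumeration and face
lookups are vectorized. The engine is verified against a naive
full-reduction oracle (exact bar-for-bar agreement, including infinite
bars) and against clouds of known topology. Filtration values are simplex
diameters; bars alive at the threshold are reported with infinite death and
capped at the threshold for significance purposes.

Practical scale: a few hundred points with an explicit threshold. The
default threshold is the enclosing radius — correct but expensive above
H0; a simplex cap (default 12 × 10⁶ triangles + tetrahedra, plus point
caps of 400/2,000 points for maxdim 2/1) raises an error with guidance
rather than exhausting memory. Bootstrap replicates subsample by maxmin
(farthest-point) landmarks by default: even coverage sharpens the births
of real classes; uniform subsampling is available (and preferable for
Gaussian-tailed clouds, where maxmin over-weights the tails).

**Betti significance.** Barcodes are conventionally read by eye; automated pipelines need a
deterministic rule. A bar is a candidate if its persistence
reaches `floor_frac` (default 0.1) of the threshold; among ≥ 4 candidates
the count is cut at the largest gap of the sorted persistence sequence
(sentinel at the floor). Two further criteria separate sampling noise from
structure, both calibrated on the ground-truth object suite (torus, plane,
circle, blobs, cluster/continuum ripple clouds) and then frozen:

* H0: a finite bar counts only if the component dying at that merge held
  ≥ 5% of the points (≥ 10). Real clusters die as macroscopic components;
  stragglers — however late they merge — die as tiny ones. The engine
  records the absorbed-component size per merge.
* H1/H2: the floor rises to γ × the connectivity scale (the longest MST
  edge), γ = 1.0 for loops and 0.4 for cavities. Coverage-gap classes live
  and die near that scale; real classes outlast it. Noise two-spheres are
  much shorter-lived relative to the sampling scale than noise loops,
  hence the smaller H2 factor.

`consensus_betti` takes the per-group majority vote across bootstrap
replicates.

## Intrinsic dimension (ABID)

For each point, the k = 50 nearest neighbors give unit difference vectors
v̂ᵢ; since E[cos²θ] = 1/d for isotropic directions in d dimensions, the
local estimate is d̂ = k(k−1) / Σ_{i≠j} cos²θᵢⱼ (self-pairs excluded; the
variant including them is available and biased low). The aggregate is the
median. Duplicate neighbors (zero vectors) are dropped from their
neighborhood. The estimate is invariant to rigid motions and uniform
scaling (asserted to 1e−6). A local-PCA baseline (components to 95%
variance) is included as an independent cross-check.

Noise geometry matters: isotropic per-dimension noise of s.d. 0.01 in 127
dimensions has total norm ≈ 0.11, so the ground-truth objects are generated
at scales (line 100, plane 20, swiss roll 20, torus radii 10/3, 5-ball
radius 10) where local neighborhoods dominate that norm; at unit scale the
estimator sees the noise, not the manifold. Torus curvature also biases
ABID upward when neighborhoods span the tube; at the chosen radii and n ≥
1,000 the suite recovers line 1, plane 2, swiss roll 2, torus 2, 5-ball 5
within ±0.5, and the noiseless continuous ripple cloud (3 free parameters)
rounds to 3.

## Structure Index

Feature values are split into ten equal-width bins (equal-count binning is
an option and makes the SI invariant to monotone feature transforms). For
ordered bin pair (U, V), OS_{U→V}(k) is the mean fraction of each u ∈ U's k
nearest neighbors — ranked within U ∪ V \ {u}, Euclidean metric, distance
ties broken by position in the U-then-V ordering — that land in V; the
diagonal is zero. SI = max(0, 1 − (2/(n²−n)) Σ A). k defaults to 3 ×
n_bins (a heuristic — there is no canonical k; every result records the
k used).
A brute-force enumeration oracle (explicit distance matrix and neighbor
lists) matches the production path exactly for N ≤ 50.

Significance: shuffles permute feature values over points. `p_value` is
the calibrated empirical permutation p, (1 + #{shuffle ≥ observed}) /
(n_shuffles + 1) — uniform under the null (type-I ≈ α over 200 calibration
runs). `p_ttest` reports the one-sample one-sided t-test of the shuffle
distribution against the observed SI, a convention used for per-feature
summary tables; as a test it is anticonservative (it compares the observed
value to the standard error of the shuffle *mean*), so calibration and
default inference use the permutation p.

## Embedding geometry

* **Reduction** — UMAP (spectral initialization; stable across seeds up to
  a rigid motion), Isomap, or PCA, with backend-default parameters recorded
  in provenance and a persistent fitted handle for projecting new events.
  The target dimension defaults to the ABID estimate (4 for
  experimental-like data, 3 for noiseless synthetic ripples).
* **Voxel correlation** — grid anchored at the coordinate-wise minimum,
  default minimum occupancy 5; Pearson correlation between per-voxel
  feature means, reported as R². The voxel-size validator simulates on the
  actual embedding an anticorrelated pair *with noise* matched to a spatial
  gradient's scale (A = g + ε, B = −g + ε′) and an independent random pair,
  scoring (R²_anti − 1)² + R²_rand²: too-small voxels fail the
  anticorrelated target (single-event means reproduce raw noise), too-large
  voxels inflate the random-pair R² or become undefined.
* **Density contours** — Gaussian KDE (Scott bandwidth) of the selected
  events on a 200 × 200 grid spanning their extremes, normalized to unit
  mass on the grid; ten levels of equal density *mass* (the "same density
  proportion" wording admits mass or height; mass is implemented and
  logged). ROI membership is decidable for every event (grid-cell lookup);
  combined ROIs intersect.
* **Centroids** — per-group means; distances per 2D projection and at full
  dimension. Bootstraps resample equal counts per unit (session/task);
  undersized units are excluded with a log entry. Shuffles permute group
  labels; p is the empirical exceedance. Calibrated: under exchangeable
  labels the rejection rate at α = 0.05 stays at the nominal level.
* **Rigid alignment** — centers of mass of 20 shared feature bins, paired
  one-to-one; closed-form Kabsch/orthogonal-Procrustes solution on centered
  bin centers with det(R) = +1 enforced. A planted rotation + translation
  is recovered to 1e−6. Fewer than 3 shared bins leaves the rotation
  underdetermined and raises.
* **Fitting new data** — new events project through the fitted handle; a
  pooled re-embedding of reference + control events, rigidly aligned back,
  yields per-event displacement baselines: alignment error (original
  events) and fitting error (control events). Group-separation claims are
  tested against those baselines.

## Decoding

Per-layer regressors (SVR default; ridge "Wiener" filter, Wiener cascade
with a cubic output nonlinearity, XGBoost) under tenfold cross-validation.
In the reduced space the embedding is refit on each training fold and the
test fold projected into it, so no test event shapes the space it is
decoded from (fold embeddings are retained and verifiably distinct). CSD
targets are scaled per layer by s.d. only — no mean subtraction, preserving
sink/source polarity. Performance is the explained variance
1 − var(y − y′)/var(y); a shuffled-target control through the same folds
defines the chance band. Note the chance band's small negative offset is
real: a regressor fitted to pure noise adds prediction variance, so its
expected explained variance is slightly below zero; tests allow a 0.05
margin when asserting the band brackets zero. Predictions for new events
average the ten fold models; per-layer scaling can be inverted on request.

The origin classifier is an SVC (C = 1, RBF kernel) under stratified
tenfold CV, with optional distribution matching of a named feature across
classes (10 equal-width bins, per-bin subsampling to the smaller class)
before training, and label-shuffle significance.

## Synthetic generators: what they emulate, and what they do not

* **Ripples** — amplitude × Gaussian(duration) × sin(2πft), features drawn
  independently and uniformly: frequency 80–240 Hz continuous or three
  disjoint bands (80–100, 130–150, 190–210 Hz), amplitude 1–5 a.u.,
  duration 0.5–2 envelope s.d. with base s.d. 10 ms (keeps events inside
  the ±25 ms window); optional white noise of stated RMS. Amplitude and
  duration ranges are shared across frequency clusters. The noiseless cloud
  is therefore an exact 3-parameter manifold — which is the point: the
  topology and dimension results depend on the number of free parameters,
  not on the absolute ranges.
* **Geometric objects** — parametric samples (area-uniform on the torus via
  rejection) mapped through a seeded random orthonormal basis into 127D
  (distances preserved exactly), plus isotropic Gaussian noise (s.d. 0.01
  per dimension).
* **Laminar sessions** — 12 channels at 100 µm (3 per layer, SO→SLM). Each
  event adds (a) the ripple waveform on the SP channels, (b) a slow
  deflection (Gaussian kernel, 8 ms s.d.) whose per-layer magnitude is a
  programmed linear function of the normalized features through the
  coupling spec (sink-negative), spread across depth by Gaussian spatial
  kernels (120 µm s.d.), (c) white channel noise (s.d. 0.05), and (d) a
  common-mode low-passed background (s.d. 1.0, < 20 Hz) standing in for
  volume-conducted ongoing activity: it dominates the raw-signal variance
  as in vivo (so the 10 s.d. artifact rule does not fire on physiological
  events), is constant across depth (cancels in the CSD) and lies below the
  ripple band. Event rate defaults to ~0.5/s — the upper end of rest SWR
  rates; denser sessions inflate the envelope s.d. and bias the threshold.
  The truth table records every draw, the trough sample, and the exact
  noiseless per-layer CSD of the programmed profile.

Not emulated: spiking, theta/behavioral state structure, conductance-based
biophysics, electrode drift, non-Gaussian artifacts, and the
volume-conduction coupling of *feature-dependent* sinks across nearby
layers is real in the generator (a Gaussian bump's curvature reaches
neighboring layers through 1/h² amplification) — decoupled-layer tests
place the coupled layer (SO) maximally far from the uncoupled one (SLM).
Passing tests therefore show the estimators recover programmed structure
under these idealized conditions; they do not certify performance on real
recordings, where validation against deposited datasets remains the
external check.

## Problem sizes

The suite and the acceptance script run on one CPU: persistence uses ≤ 250
points per replicate (torus, threshold 6.2) and ≤ 2,000 points for H0-only
runs; ABID uses the full 2,000-event clouds; decoding sessions hold 120–250
events; calibration loops use 40–200 repetitions. These sizes are the
package's defaults for desk-scale validation; the same code paths accept
larger inputs.

## Known limitations

* The Rips engine targets a few hundred points up to H2; it is not a
  replacement for optimized C++ backends at thousands of points. The
  backend interface (`rips_persistence`) is the single seam where one could
  be plugged in.
* Betti significance parameters (floor 0.1, component fraction 5%, γ =
  (1.0, 0.4)) are calibrated on the ground-truth suite, not derived; they
  are exposed and logged.
* The equal-width "ten equal bins" reading makes the SI sensitive to
  heavy-tailed features; equal-count mode is provided.
* `duration_env` depends on an envelope-crossing threshold with no canonical
  definition; values are comparable within a configuration only.
* UMAP coordinates are reproducible only per (seed, library version);
  geometry statistics are asserted invariant to rigid motions instead.
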