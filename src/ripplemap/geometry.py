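"""Embedding geometry: dimensionality reduction and everything done on it.

Reduction to the intrinsic dimension (UMAP with spectral initialization,
Isomap, or PCA) keeping a fitted handle for projecting new events; voxel
spatial correlation between features; KDE density-contour regions of
interest; centroid statistics with bootstrap and label-shuffle tests; rigid
(rotation + translation) alignment of two embeddings via feature-bin centers
of mass; and fitting new events into an existing embedding with fitting- and
alignment-error baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import gaussian_kde

from .containers import WaveformCloud

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reduction


@dataclass
class Embedding:
    """Low-dimensional coordinates plus the fitted reducer handle."""

    coords: np.ndarray
    method: str
    reducer: object | None = None
    seed: int | None = None
    meta: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))

    @property
    def n_events(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new points through the fitted reducer."""
        if self.reducer is None:
            raise ValueError("embedding has no fitted reducer handle")
        return np.asarray(self.reducer.transform(np.atleast_2d(X)), dtype=float)


def reduce_embedding(
    cloud,
    method: str = "umap",
    d: int = 4,
    seed: int | None = 0,
) -> Embedding:
    """Reduce a cloud to d dimensions, keeping the fitted reducer.

    UMAP runs with spectral initialization (stable across seeds up to a
    rigid motion); Isomap and PCA are deterministic. Reducer parameters stay
    at backend defaults and are recorded in provenance.
    """
    X = cloud.waveforms if isinstance(cloud, WaveformCloud) else np.atleast_2d(np.asarray(cloud, dtype=float))
    meta = cloud.meta if isinstance(cloud, WaveformCloud) else None
    if d > X.shape[1]:
        raise ValueError("d cannot exceed the ambient dimension")
    m = method.lower()
    if m == "umap":
        import umap

        reducer = umap.UMAP(n_components=d, init="spectral", random_state=seed)
    elif m == "isomap":
        from sklearn.manifold import Isomap

        reducer = Isomap(n_components=d)
    elif m == "pca":
        from sklearn.decomposition import PCA

        reducer = PCA(n_components=d, random_state=seed)
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    coords = np.asarray(reducer.fit_transform(X), dtype=float)
    return Embedding(
        coords,
        method=m,
        reducer=reducer,
        seed=seed,
        meta=meta,
        provenance={"d": d, "n": X.shape[0], "params": str(reducer.get_params() if hasattr(reducer, "get_params") else {})},
    )


# ---------------------------------------------------------------------------
# voxel spatial correlation


def voxelize(
    coords: np.ndarray, voxel_size: float, min_occupancy: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each event to a voxel of the given edge length.

    The grid is anchored at the coordinate-wise minimum. Returns
    (voxel id per event, ids of voxels meeting the occupancy minimum).
    """
    coords = np.atleast_2d(coords)
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    cell = np.floor((coords - coords.min(axis=0)) / voxel_size).astype(int)
    _, ids = np.unique(cell, axis=0, return_inverse=True)
    counts = np.bincount(ids)
    good = np.flatnonzero(counts >= min_occupancy)
    return ids, good


def voxel_spatial_correlation(
    coords: np.ndarray,
    feature_a: np.ndarray,
    feature_b: np.ndarray,
    voxel_size: float = 1.0,
    min_occupancy: int = 5,
) -> tuple[float, float]:
    """(R^2, p) of the Pearson correlation between per-voxel feature means."""
    ids, good = voxelize(coords, voxel_size, min_occupancy)
    if good.size < 2:
        raise ValueError("voxel size too large: fewer than 2 occupied voxels")
    if good.size < 10:
        logger.warning("voxel correlation on only %d voxels", good.size)
    a = np.asarray(feature_a, dtype=float)
    b = np.asarray(feature_b, dtype=float)
    mean_a = np.array([a[ids == v].mean() for v in good])
    mean_b = np.array([b[ids == v].mean() for v in good])
    r, p = stats.pearsonr(mean_a, mean_b)
    return float(r**2), float(p)


def validate_voxel_size(
    coords: np.ndarray,
    candidate_sizes,
    n_sim: int = 20,
    min_occupancy: int = 5,
    seed: int | None = 0,
) -> tuple[float, pd.DataFrame]:
    """Pick the voxel size that best matches the toy-model expectations.

    For each candidate size, an anticorrelated pair (A = g + noise,
    B = -g + noise, where g is a spatial gradient over the embedding and the
    noise matches its scale) and an independent random pair are simulated on
    the actual embedding; the score is ``(R2_anti - 1)^2 + R2_rand^2``
    averaged over simulations. Small voxels fail the anticorrelated target
    (single-event means reproduce the raw noise, attenuating R^2); large
    voxels leave too few voxels and inflate the random-pair R^2. Returns the
    argmin and the per-size diagnostic table.
    """
    sizes = list(candidate_sizes)
    if len(sizes) < 2:
        raise ValueError("need at least 2 candidate sizes")
    rng = np.random.default_rng(seed)
    n = coords.shape[0]
    g = coords[:, 0] - coords[:, 0].mean()
    g = g / g.std()
    rows = []
    for s in sizes:
        r2a, r2r, fails = [], [], 0
        for _ in range(n_sim):
            a = g + rng.normal(size=n)
            b = -g + rng.normal(size=n)
            try:
                ra, _ = voxel_spatial_correlation(coords, a, b, s, min_occupancy)
                rr, _ = voxel_spatial_correlation(
                    coords, rng.normal(size=n), rng.normal(size=n), s, min_occupancy
                )
            except ValueError:
                fails += 1
                continue
            r2a.append(ra)
            r2r.append(rr)
        if fails == n_sim:
            rows.append({"voxel_size": s, "r2_anti": np.nan, "r2_rand": np.nan, "score": np.inf})
            continue
        ra, rr = float(np.mean(r2a)), float(np.mean(r2r))
        rows.append(
            {"voxel_size": s, "r2_anti": ra, "r2_rand": rr, "score": (ra - 1) ** 2 + rr**2}
        )
    table = pd.DataFrame(rows)
    best = float(table.loc[table["score"].idxmin(), "voxel_size"])
    return best, table


# ---------------------------------------------------------------------------
# density contours / ROIs


@dataclass
class ContourROI:
    """Iso-density region of a feature-selected subset of the embedding."""

    feature: str
    value_range: tuple[float, float]
    level_index: int
    density: np.ndarray  # 200 x 200 grid
    grid_x: np.ndarray
    grid_y: np.ndarray
    level_density: float
    selected: np.ndarray  # indices of the events used for the KDE

    def contains(self, points: np.ndarray) -> np.ndarray:
        """ROI membership: density at the point's grid cell reaches the
        level. Points outside the grid are outside the ROI."""
        pts = np.atleast_2d(points)
        ix = np.searchsorted(self.grid_x, pts[:, 0]) - 1
        iy = np.searchsorted(self.grid_y, pts[:, 1]) - 1
        ok = (ix >= 0) & (ix < self.grid_x.size - 1) & (iy >= 0) & (iy < self.grid_y.size - 1)
        out = np.zeros(pts.shape[0], dtype=bool)
        out[ok] = self.density[iy[ok], ix[ok]] >= self.level_density
        return out


GRID_SIZE = 200
N_LEVELS = 10


def density_levels(density: np.ndarray, n_levels: int = N_LEVELS) -> np.ndarray:
    """Density values splitting the total mass into equal proportions.

    Level j (1-based) is the density above which a fraction (n - j)/n of the
    total mass lies; computed from the sorted cumulative grid mass.
    """
    flat = np.sort(density.ravel())[::-1]
    cum = np.cumsum(flat) / flat.sum()
    levels = []
    for j in range(1, n_levels):
        idx = int(np.searchsorted(cum, j / n_levels))
        levels.append(flat[min(idx, flat.size - 1)])
    return np.asarray(levels[::-1])  # ascending density = level 1..n-1 from lowest


def density_roi(
    coords2d: np.ndarray,
    values: np.ndarray,
    value_range: tuple[float, float],
    level_index: int = 6,
    feature: str = "feature",
) -> ContourROI:
    """KDE contour ROI of events whose feature lies in ``value_range``.

    A Gaussian KDE (Scott bandwidth) of the selected events' 2D coordinates
    is evaluated on a 200 x 200 grid spanning their extremes; contour levels
    partition the density mass into 10 equal proportions, and the polygon at
    ``level_index`` (1 = outermost 10%, counted from highest to lowest
    density being 10 .. 1; the customary choice is the 6th or 7th) defines
    the ROI.
    """
    coords2d = np.atleast_2d(coords2d)
    if coords2d.shape[1] != 2:
        raise ValueError("density_roi operates on a 2D projection")
    values = np.asarray(values, dtype=float)
    lo, hi = value_range
    sel = np.flatnonzero((values >= lo) & (values <= hi))
    if sel.size < 30:
        raise ValueError("need at least 30 events in the feature range")
    if not 1 <= level_index <= N_LEVELS:
        raise ValueError(f"level_index must be in 1..{N_LEVELS}")
    pts = coords2d[sel]
    kde = gaussian_kde(pts.T, bw_method="scott")
    gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), GRID_SIZE)
    gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), GRID_SIZE)
    XX, YY = np.meshgrid(gx, gy)
    dens = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(GRID_SIZE, GRID_SIZE)
    dens = dens / dens.sum()  # normalize mass on the grid
    levels = density_levels(dens)
    level_density = float(levels[level_index - 1])
    return ContourROI(
        feature=feature,
        value_range=(float(lo), float(hi)),
        level_index=level_index,
        density=dens,
        grid_x=gx,
        grid_y=gy,
        level_density=level_density,
        selected=sel,
    )


def combine_rois(rois: list[ContourROI], points: np.ndarray) -> np.ndarray:
    """Intersection membership across ROIs (overlapping-ROI semantics)."""
    member = np.ones(np.atleast_2d(points).shape[0], dtype=bool)
    for roi in rois:
        member &= roi.contains(points)
    return member


# ---------------------------------------------------------------------------
# centroid statistics


def centroid_distances(
    coords: np.ndarray, labels: np.ndarray, projections=None
) -> pd.DataFrame:
    """Pairwise Euclidean centroid distances per axis-pair projection and in
    the full space (projection = 'full')."""
    coords = np.atleast_2d(coords)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    if projections is None:
        projections = [(i, j) for i in range(coords.shape[1]) for j in range(i + 1, coords.shape[1])]
    cents = {g: coords[labels == g].mean(axis=0) for g in groups}
    rows = []
    for a_i in range(groups.size):
        for b_i in range(a_i + 1, groups.size):
            a, b = groups[a_i], groups[b_i]
            diff = cents[a] - cents[b]
            rows.append(
                {"group_a": a, "group_b": b, "projection": "full", "distance": float(np.linalg.norm(diff))}
            )
            for pr in projections:
                rows.append(
                    {
                        "group_a": a,
                        "group_b": b,
                        "projection": f"{pr[0]}-{pr[1]}",
                        "distance": float(np.linalg.norm(diff[list(pr)])),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class CentroidAnalysis:
    observed: pd.DataFrame
    bootstrap_mean: float
    bootstrap_sd: float
    shuffle_distribution: np.ndarray
    p_value: float
    sample_size: int


def centroid_analysis(
    coords: np.ndarray,
    labels: np.ndarray,
    units: np.ndarray | None = None,
    sample_size: int = 200,
    n_boot: int = 100,
    n_shuffles: int = 100,
    seed: int | None = 0,
) -> CentroidAnalysis:
    """Centroid separation between two groups with bootstrap and shuffle.

    Bootstraps draw ``sample_size`` events per group (per unit when ``units``
    — session/task identifiers — are given; undersized units are dropped
    with a log entry). Shuffles permute group labels over coordinates. The
    p-value is the fraction of shuffles reaching the observed full-space
    distance.
    """
    coords = np.atleast_2d(coords)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("centroid_analysis compares exactly 2 groups")
    rng = np.random.default_rng(seed)
    if units is None:
        units = np.zeros(len(labels), dtype=int)
    units = np.asarray(units)

    keep_units = []
    for u in np.unique(units):
        sizes = [np.sum((units == u) & (labels == g)) for g in groups]
        if min(sizes) >= sample_size:
            keep_units.append(u)
        else:
            logger.info("centroid_analysis: unit %r below sample size, excluded", u)
    if not keep_units:
        raise ValueError("no unit has enough events per group for the sample size")

    observed = centroid_distances(coords, labels)
    obs_full = observed.loc[observed["projection"] == "full", "distance"].iloc[0]

    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = []
        for u in keep_units:
            for g in groups:
                pool = np.flatnonzero((units == u) & (labels == g))
                idx.append(rng.choice(pool, sample_size, replace=True))
        idx = np.concatenate(idx)
        d = centroid_distances(coords[idx], labels[idx])
        boots[b] = d.loc[d["projection"] == "full", "distance"].iloc[0]

    shuffles = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(labels)
        d = centroid_distances(coords, perm)
        shuffles[s] = d.loc[d["projection"] == "full", "distance"].iloc[0]
    p = float((np.sum(shuffles >= obs_full) + 1) / (n_shuffles + 1))
    return CentroidAnalysis(
        observed=observed,
        bootstrap_mean=float(boots.mean()),
        bootstrap_sd=float(boots.std()),
        shuffle_distribution=shuffles,
        p_value=p,
        sample_size=sample_size,
    )


# ---------------------------------------------------------------------------
# rigid alignment


@dataclass
class RigidTransform:
    """Rotation + translation mapping one embedding onto another."""

    rotation: np.ndarray
    translation: np.ndarray
    residuals: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(R.shape[0]), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation


def _bin_centers_of_mass(coords, values, edges):
    centers, ok = [], []
    for b in range(edges.size - 1):
        if b == edges.size - 2:
            sel = (values >= edges[b]) & (values <= edges[b + 1])
        else:
            sel = (values >= edges[b]) & (values < edges[b + 1])
        if np.sum(sel) > 0:
            centers.append(coords[sel].mean(axis=0))
            ok.append(b)
    return np.asarray(centers), np.asarray(ok)


def align_embeddings(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_bins: int = 20,
) -> tuple[RigidTransform, np.ndarray]:
    """Rigid alignment of embedding B onto embedding A via a shared feature.

    The feature range (pooled) is split into ``n_bins`` bins; the centers of
    mass of each embedding's points per bin are paired one-to-one and the
    least-squares rotation + translation (Kabsch / orthogonal Procrustes on
    centered bin centers, det(R) = +1) is computed and applied to all of B.

    Returns (transform, aligned B coordinates).
    """
    coords_a, coords_b = np.atleast_2d(coords_a), np.atleast_2d(coords_b)
    va, vb = np.asarray(values_a, dtype=float), np.asarray(values_b, dtype=float)
    lo = min(va.min(), vb.min())
    hi = max(va.max(), vb.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    ca, ba = _bin_centers_of_mass(coords_a, va, edges)
    cb, bb = _bin_centers_of_mass(coords_b, vb, edges)
    shared = np.intersect1d(ba, bb)
    if shared.size < 3:
        raise ValueError("fewer than 3 shared non-empty bins: rotation underdetermined")
    pa = ca[np.searchsorted(ba, shared)]
    pb = cb[np.searchsorted(bb, shared)]
    mu_a, mu_b = pa.mean(axis=0), pb.mean(axis=0)
    H = (pb - mu_b).T @ (pa - mu_a)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.eye(H.shape[0])
    D[-1, -1] = sign
    R = Vt.T @ D @ U.T
    T = mu_a - R @ mu_b
    tf = RigidTransform(rotation=R, translation=T, residuals=np.linalg.norm(pa - (pb @ R.T + T), axis=1))
    return tf, tf.apply(coords_b)


# ---------------------------------------------------------------------------
# fitting new data into an existing embedding


@dataclass
class ProjectionResult:
    new_coords: np.ndarray
    fitting_error: np.ndarray
    alignment_error: np.ndarray
    meta: dict = field(default_factory=dict)


def embed_new_events(
    reference: Embedding,
    reference_cloud,
    new_cloud,
    control_cloud,
    feature_values: dict | None = None,
    seed: int | None = 0,
) -> ProjectionResult:
    """Project new events into a fitted embedding, with error baselines.

    New events are projected through the reference's fitted handle. To
    calibrate what "well placed" means, a pooled embedding of the reference
    events plus held-out control events (reference-like) is built with the
    same method and aligned rigidly back onto the reference (using the first
    reference coordinate as the shared alignment feature unless explicit
    ``feature_values`` for both sets are given). The per-event displacement
    of the original events is the alignment error; the displacement between
    a control event's pooled-embedding position and its direct projection is
    the fitting error.
    """
    X_ref = reference_cloud.waveforms if isinstance(reference_cloud, WaveformCloud) else np.asarray(reference_cloud)
    X_new = new_cloud.waveforms if isinstance(new_cloud, WaveformCloud) else np.asarray(new_cloud)
    X_ctl = control_cloud.waveforms if isinstance(control_cloud, WaveformCloud) else np.asarray(control_cloud)
    if X_new.shape[1] != X_ref.shape[1] or X_ctl.shape[1] != X_ref.shape[1]:
        raise ValueError("dimension mismatch between clouds")
    new_coords = reference.transform(X_new)
    ctl_proj = reference.transform(X_ctl)

    pooled = np.vstack([X_ref, X_ctl])
    pooled_emb = reduce_embedding(pooled, method=reference.method, d=reference.d, seed=seed)
    n_ref = X_ref.shape[0]
    if feature_values is None:
        shared_ref = reference.coords[:, 0]
        shared_pool = np.concatenate([shared_ref, ctl_proj[:, 0]])
    else:
        shared_ref = np.asarray(feature_values["reference"])
        shared_pool = np.concatenate([shared_ref, np.asarray(feature_values["control"])])
    _, pooled_aligned = align_embeddings(
        reference.coords, pooled_emb.coords, shared_ref, shared_pool
    )
    alignment_error = np.linalg.norm(pooled_aligned[:n_ref] - reference.coords, axis=1)
    fitting_error = np.linalg.norm(pooled_aligned[n_ref:] - ctl_proj, axis=1)
    return ProjectionResult(
        new_coords=new_coords,
        fitting_error=fitting_error,
        alignment_error=alignment_error,
        meta={"method": reference.method, "n_ref": n_ref, "n_control": X_ctl.shape[0]},
    )
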