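"""Embedding geometry: reduction, voxels, contours, centroids, alignment,
projection of new events."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from ripplemap.geometry import (
    Embedding,
    align_embeddings,
    centroid_analysis,
    centroid_distances,
    combine_rois,
    density_levels,
    density_roi,
    embed_new_events,
    reduce_embedding,
    validate_voxel_size,
    voxel_spatial_correlation,
    voxelize,
)
from ripplemap.structure_index import structure_index
from ripplemap.synthetic import GroundTruthObject, generate_geometric_object


# ---------------------------------------------------------------------------
# reduction


def test_pca_recovers_plane_exactly():
    X = generate_geometric_object(GroundTruthObject("plane", n_points=400, noise_sd=0.0, seed=1))
    emb = reduce_embedding(X, method="pca", d=2, seed=0)
    recon = emb.reducer.inverse_transform(emb.coords)
    assert np.abs(recon - X).max() < 1e-9
    assert emb.d == 2 and emb.n_events == 400


def test_unknown_method_rejected(ripple_cloud):
    with pytest.raises(ValueError):
        reduce_embedding(ripple_cloud, method="tsne", d=3)
    with pytest.raises(ValueError):
        reduce_embedding(np.ones((10, 4)), method="pca", d=8)


def test_si_preserved_in_reduced_space(ripple_cloud):
    """SI of frequency survives reduction to the intrinsic dimension."""
    sub = ripple_cloud.subset(np.arange(600))
    vals = sub.meta["frequency"].to_numpy()
    si_orig = structure_index(sub.waveforms, vals).si
    emb = reduce_embedding(sub, method="pca", d=3, seed=0)
    si_red = structure_index(emb.coords, vals).si
    assert abs(si_orig - si_red) < 0.15


def test_si_stable_across_umap_seeds(ripple_cloud):
    sub = ripple_cloud.subset(np.arange(400))
    vals = sub.meta["frequency"].to_numpy()
    sis = []
    for seed in (0, 1):
        emb = reduce_embedding(sub, method="umap", d=3, seed=seed)
        sis.append(structure_index(emb.coords, vals).si)
    assert abs(sis[0] - sis[1]) < 0.05


def test_embedding_transform_requires_handle():
    emb = Embedding(np.zeros((5, 2)), method="pca", reducer=None)
    with pytest.raises(ValueError):
        emb.transform(np.zeros((2, 10)))


# ---------------------------------------------------------------------------
# voxels


def test_voxel_anticorrelated_and_random_pairs():
    rng = np.random.default_rng(0)
    coords = rng.normal(size=(2000, 4))
    a = rng.normal(size=2000)
    r2_anti, p = voxel_spatial_correlation(coords, a, -a, voxel_size=1.0)
    assert r2_anti == pytest.approx(1.0)
    assert p < 1e-6
    r2_rand, _ = voxel_spatial_correlation(
        coords, rng.normal(size=2000), rng.normal(size=2000), voxel_size=1.0
    )
    assert r2_rand < 0.15


def test_voxel_means_match_direct_correlation():
    """Hand-set voxel means: R^2 equals the direct correlation of the 20
    per-voxel pairs."""
    rng = np.random.default_rng(1)
    # 20 well-separated voxels, 10 events each; the same jitter pattern in
    # every cluster keeps each cluster inside one min-anchored grid cell
    centers = np.column_stack([np.arange(20) * 5.0 + 2.0, np.full(20, 2.0)])
    jitter = rng.uniform(0, 0.5, (10, 2))
    coords = np.repeat(centers, 10, axis=0) + np.tile(jitter, (20, 1))
    mean_a = rng.normal(size=20)
    mean_b = 0.6 * mean_a + rng.normal(0, 0.5, 20)
    a = np.repeat(mean_a, 10) + np.tile(np.linspace(-1, 1, 10), 20)
    b = np.repeat(mean_b, 10) + np.tile(np.linspace(1, -1, 10), 20)
    r2, _ = voxel_spatial_correlation(coords, a, b, voxel_size=5.0, min_occupancy=5)
    expected = np.corrcoef(mean_a, mean_b)[0, 1] ** 2
    assert r2 == pytest.approx(expected, abs=1e-9)


def test_voxelize_partition_and_errors():
    rng = np.random.default_rng(2)
    coords = rng.normal(size=(100, 3))
    ids, good = voxelize(coords, 0.5, min_occupancy=1)
    assert ids.size == 100  # every event in exactly one voxel
    with pytest.raises(ValueError):
        voxelize(coords, -1.0)
    with pytest.raises(ValueError):
        voxel_spatial_correlation(coords, np.ones(100), np.ones(100), voxel_size=100.0)


def test_validate_voxel_size_prefers_intermediate():
    rng = np.random.default_rng(3)
    coords = rng.normal(size=(1500, 4))
    best, table = validate_voxel_size(
        coords, [0.5, 2.5, 8.0], n_sim=8, min_occupancy=1, seed=0
    )
    assert best == 2.5
    t = table.set_index("voxel_size")
    # near-single-event voxels reproduce raw noise: anticorrelated target missed
    assert t.loc[0.5, "r2_anti"] < t.loc[2.5, "r2_anti"]
    # one giant voxel is undefined and excluded from the optimum
    assert np.isinf(t.loc[8.0, "score"])
    with pytest.raises(ValueError):
        validate_voxel_size(coords, [1.0])


# ---------------------------------------------------------------------------
# density contours


def test_contours_nested_for_unimodal_density():
    rng = np.random.default_rng(4)
    coords = rng.normal(size=(500, 2))
    vals = rng.uniform(0, 1, 500)
    rois = [
        density_roi(coords, vals, (0, 1), level_index=j, feature="f") for j in (3, 6, 9)
    ]
    areas = [(r.density >= r.level_density).sum() for r in rois]
    assert areas[0] > areas[1] > areas[2]
    inner = rois[2].density >= rois[2].level_density
    outer = rois[0].density >= rois[0].level_density
    assert np.all(outer[inner])  # level 9 region inside level 3 region


def test_density_levels_partition_mass_equally():
    rng = np.random.default_rng(5)
    coords = rng.normal(size=(800, 2))
    roi = density_roi(coords, np.ones(800) * 0.5, (0, 1), level_index=5)
    levels = density_levels(roi.density)
    masses = [roi.density[roi.density >= lv].sum() for lv in levels]
    expected = np.arange(9, 0, -1) / 10
    np.testing.assert_allclose(sorted(masses), sorted(expected), atol=0.02)


def test_two_blob_roi_membership():
    rng = np.random.default_rng(6)
    coords = np.vstack([rng.normal(0, 0.3, (200, 2)), rng.normal(5, 0.3, (200, 2))])
    roi = density_roi(coords, np.ones(400) * 0.5, (0, 1), level_index=7)
    inside = roi.contains(coords)
    assert inside.mean() > 0.3
    assert roi.contains(np.array([[2.5, 2.5]]))[0] == False  # between the blobs


def test_roi_intersection_selects_conjunctive_events(ripple_cloud):
    """Intersecting the high-frequency ROI with the low-amplitude ROI picks
    out events satisfying both ranges with high purity."""
    sub = ripple_cloud.subset(np.arange(1200))
    emb = reduce_embedding(sub, method="pca", d=2, seed=0)
    f = sub.meta["frequency"].to_numpy()
    a = sub.meta["amplitude"].to_numpy()
    roi_f = density_roi(emb.coords, f, (180, 240), level_index=5, feature="frequency")
    roi_a = density_roi(emb.coords, a, (1.0, 2.5), level_index=5, feature="amplitude")
    member = combine_rois([roi_f, roi_a], emb.coords)
    assert member.sum() >= 20
    purity = np.mean((f[member] >= 150) & (a[member] <= 3.2))
    assert purity >= 0.8


def test_density_roi_validation():
    rng = np.random.default_rng(7)
    coords = rng.normal(size=(100, 2))
    with pytest.raises(ValueError):
        density_roi(coords, np.ones(100), (2, 3))  # empty selection
    with pytest.raises(ValueError):
        density_roi(coords, np.ones(100) * 0.5, (0, 1), level_index=11)
    with pytest.raises(ValueError):
        density_roi(rng.normal(size=(100, 3)), np.ones(100) * 0.5, (0, 1))


# ---------------------------------------------------------------------------
# centroids


def test_identical_groups_zero_distance():
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(300, 3))
    coords = np.vstack([pts, pts])
    labels = np.array(["a"] * 300 + ["b"] * 300)
    res = centroid_analysis(coords, labels, sample_size=100, n_boot=20, n_shuffles=50, seed=0)
    obs = res.observed
    assert obs.loc[obs["projection"] == "full", "distance"].iloc[0] == pytest.approx(0.0)
    assert res.p_value > 0.5


def test_offset_gaussians_distance_recovered_in_right_projection():
    rng = np.random.default_rng(9)
    delta = 2.0
    a = rng.normal(0, 0.5, (800, 3))
    b = rng.normal(0, 0.5, (800, 3))
    b[:, 1] += delta
    coords = np.vstack([a, b])
    labels = np.array(["a"] * 800 + ["b"] * 800)
    d = centroid_distances(coords, labels)
    full = d.loc[d["projection"] == "full", "distance"].iloc[0]
    assert full == pytest.approx(delta, abs=0.1)
    p02 = d.loc[d["projection"] == "0-2", "distance"].iloc[0]
    assert p02 < 0.1  # projections excluding axis 1 see nothing
    res = centroid_analysis(coords, labels, sample_size=200, n_boot=20, n_shuffles=50, seed=1)
    assert res.p_value < 0.05
    assert res.bootstrap_mean == pytest.approx(delta, abs=0.2)


def test_label_shuffle_calibration():
    """Under exchangeable labels the shuffle test rejects at ~alpha."""
    rng = np.random.default_rng(10)
    rejections = 0
    n_rep = 40
    for rep in range(n_rep):
        coords = rng.normal(size=(80, 2))
        labels = np.array(["a", "b"] * 40)
        res = centroid_analysis(
            coords, labels, sample_size=20, n_boot=5, n_shuffles=40, seed=rep
        )
        rejections += res.p_value <= 0.05
    assert rejections / n_rep <= 0.15


def test_undersized_units_excluded():
    rng = np.random.default_rng(11)
    coords = rng.normal(size=(120, 2))
    labels = np.array(["a", "b"] * 60)
    units = np.array([0] * 100 + [1] * 20)  # unit 1 below sample size
    res = centroid_analysis(coords, labels, units=units, sample_size=30, n_boot=5, n_shuffles=20, seed=0)
    assert res.sample_size == 30
    with pytest.raises(ValueError):
        centroid_analysis(coords, labels, sample_size=1000)


# ---------------------------------------------------------------------------
# rigid alignment


def test_alignment_identity_and_offset():
    rng = np.random.default_rng(12)
    A = rng.normal(size=(400, 4))
    vals = A @ np.array([1.0, 0.5, -0.3, 0.2])
    tf, aligned = align_embeddings(A, A, vals, vals)
    np.testing.assert_allclose(tf.rotation, np.eye(4), atol=1e-8)
    np.testing.assert_allclose(tf.translation, 0.0, atol=1e-8)
    offset = np.array([2.0, -1.0, 0.5, 3.0])
    tf, aligned = align_embeddings(A, A + offset, vals, vals)
    np.testing.assert_allclose(tf.rotation, np.eye(4), atol=1e-7)
    np.testing.assert_allclose(tf.translation, -offset, atol=1e-7)
    np.testing.assert_allclose(aligned, A, atol=1e-7)


def test_alignment_recovers_planted_rigid_motion():
    rng = np.random.default_rng(13)
    A = rng.normal(size=(500, 4))
    vals = A @ np.array([1.0, 0.5, -0.3, 0.2]) + rng.normal(0, 0.05, 500)
    R0 = special_ortho_group.rvs(4, random_state=7)
    T0 = np.array([1.0, -2.0, 0.5, 3.0])
    B = A @ R0.T + T0  # b_i = R0 a_i + T0
    tf, aligned = align_embeddings(A, B, vals, vals)
    # the recovered map inverts the planted motion
    np.testing.assert_allclose(tf.rotation, R0.T, atol=1e-6)
    np.testing.assert_allclose(tf.translation, -R0.T @ T0, atol=1e-6)
    np.testing.assert_allclose(aligned, A, atol=1e-6)
    assert np.linalg.det(tf.rotation) == pytest.approx(1.0)


def test_alignment_needs_shared_bins():
    rng = np.random.default_rng(14)
    A = rng.normal(size=(50, 3))
    with pytest.raises(ValueError):
        align_embeddings(A, A + 10, np.zeros(50) + 1.0, np.zeros(50) + 99.0, n_bins=20)


# ---------------------------------------------------------------------------
# fitting new events into an embedding


@pytest.fixture(scope="module")
def projection_setting(ripple_cloud):
    ref = ripple_cloud.subset(np.arange(500))
    ctl = ripple_cloud.subset(np.arange(500, 800))
    emb = reduce_embedding(ref, method="pca", d=3, seed=0)
    return ref, ctl, emb


def test_training_events_project_onto_themselves(projection_setting):
    ref, _, emb = projection_setting
    proj = emb.transform(ref.waveforms)
    np.testing.assert_allclose(proj, emb.coords, atol=1e-8)


def test_heldout_fitting_error_matches_alignment_error(projection_setting):
    ref, ctl, emb = projection_setting
    res = embed_new_events(emb, ref, ctl, ctl, seed=0)
    med_fit = np.median(res.fitting_error)
    med_align = np.median(res.alignment_error)
    spread = res.alignment_error.std() + 1e-12
    assert abs(med_fit - med_align) < 3 * spread
    assert res.new_coords.shape == (300, 3)


def test_distinct_cluster_exceeds_error_baselines(projection_setting, clustered_cloud):
    ref, ctl, emb = projection_setting
    new = clustered_cloud.subset(np.arange(200))
    res = embed_new_events(emb, ref, new, ctl, seed=0)
    with pytest.raises(ValueError):
        embed_new_events(emb, ref, new.waveforms[:, :50], ctl, seed=0)
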