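import numpy as np
import pytest
from scipy.spatial.distance import pdist

from neuroscore.dissim import (
    FISHER_Z_CAP,
    DissimilarityMatrix,
    build_expert_model,
)
from neuroscore.firstlevel import ContrastZMap, zmap_from_betas
from neuroscore.scoring import (
    InfonetConfig,
    infonet_score,
    mds_embed,
    rsa_score,
    svm_category_accuracy,
    univariate_score,
)
from neuroscore.searchlight import SearchlightResult


def _zmap(z):
    z = np.asarray(z, dtype=float)
    coords = np.column_stack([np.arange(z.size), np.zeros((z.size, 2), dtype=int)])
    return ContrastZMap(
        z=z, contrast_name="images_gt_baseline", voxel_coords=coords,
        grid_shape=(z.size, 1, 1), affine=np.eye(4))


def _slr_from_dms(dms):
    n = len(dms)
    return SearchlightResult(
        centers=np.arange(n), neighborhoods=[np.arange(5) for _ in range(n)],
        dms=list(dms), radius_voxels=3.0, min_voxels=5)


class TestUnivariateScore:
    def test_mean_of_top_two(self):
        rec = univariate_score(_zmap(np.arange(1.0, 101.0)), 0.02)
        assert rec.score == pytest.approx(99.5)
        assert set(rec.contributing_voxels) == {98, 99}

    def test_constant_positive_map(self):
        rec = univariate_score(_zmap(np.full(50, 2.7)), 0.1)
        assert rec.score == pytest.approx(2.7)

    def test_all_negative_flagged_missing(self):
        with pytest.warns(RuntimeWarning):
            rec = univariate_score(_zmap(-np.arange(1.0, 21.0)), 0.05)
        assert not np.isfinite(rec.score)
        assert "missing_empty_mask" in rec.flags

    def test_voxel_permutation_invariance(self):
        z = np.random.default_rng(0).normal(size=200)
        perm = np.random.default_rng(1).permutation(200)
        assert univariate_score(_zmap(z)).score == pytest.approx(
            univariate_score(_zmap(z[perm])).score)


class TestRsaScore:
    def test_perfect_match_capped_and_flagged(self):
        em = build_expert_model(seed=0)
        rec = rsa_score(_slr_from_dms([em.dm] * 3), em)
        assert rec.score == pytest.approx(FISHER_Z_CAP)
        assert "fisher_z_capped" in rec.flags

    def test_noise_dms_mostly_dropped(self):
        # null: P(fisher z >= 2) means rho >= tanh(2) ~ 0.964 - essentially never
        em = build_expert_model(seed=0)
        rng = np.random.default_rng(3)
        n_dropped = 0
        for _ in range(20):
            dms = [
                DissimilarityMatrix(rng.uniform(0.2, 1.8, 276), em.dm.item_ids)
                for _ in range(10)
            ]
            rec = rsa_score(_slr_from_dms(dms), em)
            n_dropped += "dropped_no_survivors" in rec.flags
        assert n_dropped >= 19

    def test_planted_centers_survive(self):
        em = build_expert_model(seed=0)
        rng = np.random.default_rng(4)
        near = []
        for _ in range(5):  # monotone jitter keeps spearman rho ~ 1
            vals = em.dm.values + rng.normal(0, 1e-4, 276)
            near.append(DissimilarityMatrix(np.clip(vals, 0, 2), em.dm.item_ids))
        noise = [
            DissimilarityMatrix(rng.uniform(0.2, 1.8, 276), em.dm.item_ids)
            for _ in range(5)
        ]
        rec = rsa_score(_slr_from_dms(near + noise), em)
        assert set(range(5)) <= set(rec.contributing_voxels)
        assert rec.score >= np.arctanh(0.8)


class TestMdsEmbed:
    def test_equilateral_triangle(self):
        dm = DissimilarityMatrix(np.ones(3), ("a", "b", "c"))
        coords = mds_embed(dm, n_dims=2)
        d = pdist(coords)
        np.testing.assert_allclose(d, 1.0, atol=1e-9)

    def test_planar_points_recovered(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(24, 2))
        dm = DissimilarityMatrix(pdist(pts), [f"i{k}" for k in range(24)])
        coords = mds_embed(dm, n_dims=2)
        np.testing.assert_allclose(pdist(coords), pdist(pts), atol=1e-6)

    def test_jitter_free_expert_model_three_point_clusters(self):
        em = build_expert_model(jitter_sd=0.0)
        coords = mds_embed(em.dm, n_dims=2)
        for lab in set(em.labels):
            assert np.ptp(coords[em.labels == lab], axis=0).max() < 1e-8

    def test_deterministic(self):
        em = build_expert_model(seed=1)
        np.testing.assert_array_equal(mds_embed(em.dm), mds_embed(em.dm))

    def test_insufficient_positive_eigenvalues_padded(self):
        # 3 collinear points: 1-D geometry, second axis zero-padded
        dm = DissimilarityMatrix(np.array([1.0, 2.0, 1.0]), ("a", "b", "c"))
        with pytest.warns(RuntimeWarning, match="positive eigenvalue"):
            coords = mds_embed(dm, n_dims=3)
        assert np.allclose(coords[:, 2], 0)

    def test_nonmetric_variant_runs(self):
        em = build_expert_model(seed=2)
        coords = mds_embed(em.dm, variant="nonmetric")
        assert coords.shape == (24, 2)


class TestSvmCategoryAccuracy:
    def test_separable_clusters_perfect(self):
        rng = np.random.default_rng(6)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        labels = np.repeat(["a", "b", "c"], 8)
        coords = centers[np.repeat(np.arange(3), 8)] + rng.normal(0, 0.1, (24, 2))
        assert svm_category_accuracy(coords, labels) == 1.0

    def test_single_class_degenerate(self):
        coords = np.random.default_rng(7).normal(size=(6, 2))
        with pytest.warns(RuntimeWarning, match="single category"):
            assert svm_category_accuracy(coords, ["x"] * 6) == 1.0

    def test_shuffled_labels_loo_near_chance(self):
        # permutation null, frozen from the simulation itself: mean LOO
        # accuracy over 50 seeded shuffles should sit near 1/3 (LOO on
        # shuffled labels has a slight pessimistic bias)
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(24, 2))
        base = np.repeat(["a", "b", "c"], 8)
        accs = []
        for s in range(50):
            labels = np.random.default_rng(s).permutation(base)
            accs.append(svm_category_accuracy(coords, labels, eval_mode="leave_one_out"))
        se = np.std(accs) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 1 / 3) <= max(3 * se, 0.12)

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(24, 2))
        labels = np.repeat(["a", "b", "c"], 8)
        assert svm_category_accuracy(coords, labels) == svm_category_accuracy(coords, labels)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            svm_category_accuracy(np.ones((3, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            svm_category_accuracy(np.full((3, 2), np.nan), ["a", "b", "c"])


class TestInfonetScore:
    def test_expert_subject_high_score_overlapping_blobs(self, small_cohort):
        co = small_cohort
        betas = co.betas[("001", 1)]  # e = 0.95
        cfg = InfonetConfig(n_boot_per_scale=50, seed=1)
        rec, networks = infonet_score(
            betas, co.expert_model.categories, cfg, brain_mask=co.mask)
        assert rec.score >= 0.8
        # argmax network centers overlap planted info blobs
        coords = np.argwhere(co.mask)
        info = {tuple(v) for v in co.ground_truth.info_blob_voxels}
        centers = {tuple(coords[i]) for i in rec.contributing_voxels}
        jaccard = len(centers & info) / len(centers | info)
        overlap = len(centers & info) / len(centers)
        assert overlap >= 0.3 or jaccard >= 0.3

    def test_score_in_unit_interval_and_deterministic(self, small_cohort):
        co = small_cohort
        betas = co.betas[("000", 1)]
        cfg = InfonetConfig(n_boot_per_scale=50, seed=2)
        rec1, _ = infonet_score(betas, co.expert_model.categories, cfg, brain_mask=co.mask)
        rec2, _ = infonet_score(betas, co.expert_model.categories, cfg, brain_mask=co.mask)
        assert 0.0 <= rec1.score <= 1.0
        assert rec1.score == rec2.score
        np.testing.assert_array_equal(rec1.contributing_voxels, rec2.contributing_voxels)

    def test_fallback_root_network_still_scores(self, small_cohort):
        co = small_cohort
        betas = co.betas[("000", 1)]
        cfg = InfonetConfig(n_boot_per_scale=50, seed=3, au_threshold=0.9999999)
        rec, networks = infonet_score(
            betas, co.expert_model.categories, cfg, brain_mask=co.mask)
        assert np.isfinite(rec.score)
        assert len(networks) >= 1

    def test_empty_robust_mask_flagged_missing(self, small_cohort):
        co = small_cohort
        betas = co.betas[("000", 1)]
        neg = _zmap(-np.ones(betas.n_voxels))
        neg.voxel_coords = betas.voxel_coords
        neg.grid_shape = betas.grid_shape
        with pytest.warns(RuntimeWarning):
            rec, networks = infonet_score(
                betas, co.expert_model.categories, InfonetConfig(), zmap=neg,
                brain_mask=co.mask)
        assert not np.isfinite(rec.score)
        assert "missing_empty_mask" in rec.flags
        assert networks == []

    def test_score_max_over_networks(self, small_cohort):
        co = small_cohort
        betas = co.betas[("001", 1)]
        cfg = InfonetConfig(n_boot_per_scale=50, seed=4)
        rec, networks = infonet_score(
            betas, co.expert_model.categories, cfg, brain_mask=co.mask)
        assert rec.score == pytest.approx(max(n.svm_accuracy for n in networks))
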