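import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from neuroscore.firstlevel import fit_item_glm
from neuroscore.synthdata import (
    SyntheticCohortSpec,
    default_event_table,
    generate_cohort,
    generate_timeseries,
    simulate_random_responder,
)


def _info_positions(cohort):
    """Positions of planted informational voxels within the in-mask voxel list."""
    coords = np.argwhere(cohort.mask)
    flat = np.ravel_multi_index(coords.T, cohort.mask.shape)
    pos = {f: i for i, f in enumerate(flat)}
    info_flat = np.ravel_multi_index(
        cohort.ground_truth.info_blob_voxels.T, cohort.mask.shape
    )
    return np.array([pos[f] for f in info_flat])


def _within_minus_between(betas, positions, categories, item_ids):
    d = pdist(betas.betas[:, positions], metric="correlation")
    labels = np.array([categories[i] for i in item_ids])
    same = pdist(labels[:, None], lambda a, b: float(a[0] == b[0])).astype(bool)
    return d[same].mean() - d[~same].mean()


SMALL = dict(n_subjects_per_group=1, grid_dims=(16, 16, 16), n_runs=1)


class TestGenerateCohort:
    def test_deterministic_bit_identical(self):
        spec = SyntheticCohortSpec(**SMALL, seed=11)
        a, b = generate_cohort(spec), generate_cohort(spec)
        for key in a.betas:
            np.testing.assert_array_equal(a.betas[key].betas, b.betas[key].betas)
        pd.testing.assert_frame_equal(a.behavior, b.behavior)
        np.testing.assert_array_equal(
            a.ground_truth.info_blob_voxels, b.ground_truth.info_blob_voxels
        )

    def test_e_zero_no_category_signal(self):
        # averaged over seeds, within-minus-between category distance ~ 0
        diffs = []
        for seed in range(12):
            spec = SyntheticCohortSpec(
                **SMALL, expertise=(0.0, 0.5), seed=seed)
            co = generate_cohort(spec)
            info = _info_positions(co)
            diffs.append(_within_minus_between(
                co.betas[("000", 1)], info,
                co.ground_truth.item_categories, co.betas[("000", 1)].item_ids,
            ))
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 0.01

    def test_e_one_noise_free_strict_category_structure(self):
        spec = SyntheticCohortSpec(
            **SMALL, expertise=(0.0, 1.0), noise_sd=1e-12, seed=2)
        co = generate_cohort(spec)
        betas = co.betas[("001", 1)]
        info = _info_positions(co)
        d = pdist(betas.betas[:, info], metric="correlation")
        labels = np.array(
            [co.ground_truth.item_categories[i] for i in betas.item_ids]
        )
        same = pdist(labels[:, None], lambda a, b: float(a[0] == b[0])).astype(bool)
        assert d[same].max() < d[~same].min()

    def test_monotone_planted_signal_in_e(self):
        # mean within-minus-between distance decreases monotonically in e
        means = []
        for e in (0.0, 0.35, 0.7, 1.0):
            diffs = []
            for seed in range(20):
                spec = SyntheticCohortSpec(
                    **SMALL, expertise=(0.0, e), seed=seed)
                co = generate_cohort(spec)
                info = _info_positions(co)
                bm = co.betas[("001", 1)]
                diffs.append(_within_minus_between(
                    bm, info, co.ground_truth.item_categories, bm.item_ids))
            means.append(np.mean(diffs))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_task_blobs_carry_no_item_information(self):
        # label-permutation test of category structure in task-blob patterns
        spec = SyntheticCohortSpec(**SMALL, expertise=(0.0, 1.0), seed=5)
        co = generate_cohort(spec)
        coords = np.argwhere(co.mask)
        flat = np.ravel_multi_index(coords.T, co.mask.shape)
        pos = {f: i for i, f in enumerate(flat)}
        task = np.array([
            pos[f] for f in np.ravel_multi_index(
                co.ground_truth.task_blob_voxels.T, co.mask.shape)
        ])
        bm = co.betas[("001", 1)]
        observed = _within_minus_between(
            bm, task, co.ground_truth.item_categories, bm.item_ids)
        rng = np.random.default_rng(0)
        ids = list(bm.item_ids)
        null = []
        for _ in range(200):
            perm = rng.permutation(ids)
            null.append(_within_minus_between(
                bm, task, dict(zip(perm, [co.ground_truth.item_categories[i] for i in ids])),
                bm.item_ids))
        p = np.mean(np.abs(null) >= abs(observed))
        assert p > 0.05

    def test_behavior_expertise_coupling(self):
        spec = SyntheticCohortSpec(
            n_subjects_per_group=10, grid_dims=(16, 16, 16), n_runs=1, seed=3)
        co = generate_cohort(spec)
        e = [co.ground_truth.expertise[s] for s in co.behavior["subject_id"]]
        r, _ = pearsonr(e, co.behavior["fbd_acc_run1"])
        assert r > 0.5

    def test_group_is_thresholded_expertise(self, small_cohort):
        gt = small_cohort.ground_truth
        for sid, e in gt.expertise.items():
            assert gt.groups[sid] == ("expert" if e >= 0.5 else "novice")

    def test_blobs_disjoint_and_inside_mask(self, small_cohort):
        gt = small_cohort.ground_truth
        task = {tuple(v) for v in gt.task_blob_voxels}
        info = {tuple(v) for v in gt.info_blob_voxels}
        assert not task & info
        for v in task | info:
            assert small_cohort.mask[v]

    def test_explicit_blob_center_on_boundary_raises(self):
        spec = SyntheticCohortSpec(
            **SMALL,
            blob_centers=tuple((1, 1, 1) for _ in range(7)),
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_cohort(spec)

    def test_accuracies_in_range_and_missing_allowed(self):
        spec = SyntheticCohortSpec(
            n_subjects_per_group=8, grid_dims=(16, 16, 16), n_runs=2,
            p_missing_inventory=0.5, seed=4)
        co = generate_cohort(spec)
        acc_cols = [c for c in co.behavior if c.endswith("acc") or "acc_run" in c]
        vals = co.behavior[acc_cols].to_numpy().ravel()
        finite = vals[np.isfinite(vals)]
        assert np.all((finite >= 0) & (finite <= 1))
        assert co.behavior["sci_acc"].isna().any()
        assert co.behavior["fbd_acc_run1"].notna().all()

    def test_cohort_write_round_trip(self, small_cohort, tmp_path):
        small_cohort.write(tmp_path)
        assert (tmp_path / "behavior.tsv").exists()
        assert (tmp_path / "expert_dm.tsv").exists()
        spec_back = SyntheticCohortSpec.from_json(tmp_path / "cohort_spec.json")
        assert spec_back == small_cohort.spec


class TestRandomResponder:
    def test_chance_calibration_10k_trials(self):
        acc = simulate_random_responder(10_000, seed=1)
        assert abs(acc - 0.5) <= 3 * 0.005  # 3 * SE at n = 1e4

    def test_single_trial_binary(self):
        assert simulate_random_responder(1, seed=0) in (0.0, 1.0)

    def test_mean_over_seeds(self):
        # binomial expectation: mean accuracy over 100 seeds at n = 1000
        accs = [simulate_random_responder(1000, seed=s) for s in range(100)]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.005)

    def test_invalid_n_trials(self):
        with pytest.raises(ValueError):
            simulate_random_responder(0)


class TestGenerateTimeseries:
    @pytest.fixture(scope="class")
    def tiny_betas(self):
        spec = SyntheticCohortSpec(
            n_subjects_per_group=1, grid_dims=(8, 8, 8), n_items=6, n_runs=1,
            n_task_blobs=1, n_info_blobs=1, blob_radius=1.0,
            n_visual_clusters=2, expertise=(0.2, 0.9), seed=6)
        co = generate_cohort(spec)
        return co.betas[("000", 1)]

    def test_noise_free_forward_model_is_linear(self, tiny_betas):
        timing = default_event_table(tiny_betas.item_ids, include_response=False)
        series = generate_timeseries(tiny_betas, timing, tr=2.5, noise_sd=0.0)
        doubled = dataclasses.replace(tiny_betas, betas=2 * tiny_betas.betas)
        series2 = generate_timeseries(doubled, timing, tr=2.5, noise_sd=0.0)
        np.testing.assert_allclose(series2, 2 * series, atol=1e-12)

    def test_single_voxel_equals_convolved_regressor(self):
        from neuroscore.firstlevel import ItemBetaMaps, build_design

        bm = ItemBetaMaps(
            subject_id="s", run_id=1, betas=np.array([[1.0], [0.0], [0.0]]),
            voxel_coords=np.array([[1, 1, 1]]), grid_shape=(3, 3, 3),
            affine=np.eye(4), item_ids=("a", "b", "c"))
        timing = default_event_table(bm.item_ids, include_response=False)
        series = generate_timeseries(bm, timing, tr=2.5, noise_sd=0.0, n_scans=40)
        X, ids, _, _ = build_design(timing, 40, 2.5)
        np.testing.assert_allclose(series[1, 1, 1], X[:, ids.index("a")], atol=1e-12)

    def test_glm_round_trip_recovers_betas(self, tiny_betas):
        timing = default_event_table(tiny_betas.item_ids, include_response=True)
        series = generate_timeseries(tiny_betas, timing, tr=2.5, noise_sd=0.0)
        fit = fit_item_glm(series, timing, tr=2.5, mask=tiny_betas.mask_array())
        assert fit.betas.item_ids == tiny_betas.item_ids
        np.testing.assert_allclose(fit.betas.betas, tiny_betas.betas, atol=1e-8)

    def test_invalid_tr(self, tiny_betas):
        timing = default_event_table(tiny_betas.item_ids)
        with pytest.raises(ValueError):
            generate_timeseries(tiny_betas, timing, tr=0.0)

    def test_overlapping_trials_rejected(self, tiny_betas):
        timing = pd.DataFrame({
            "onset": [0.0, 3.0], "duration": [6.0, 6.0],
            "trial_type": list(tiny_betas.item_ids[:2]),
        })
        with pytest.raises(ValueError, match="overlap"):
            generate_timeseries(tiny_betas, timing, tr=2.5)
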