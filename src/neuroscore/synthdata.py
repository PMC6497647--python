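"""Seeded synthetic cohorts with planted ground truth.

The generative model for a subject's item beta at voxel v is

    beta[i, v] = a_task * 1[v in any blob]
               + w_cat * e * mu[cat(i), v] * 1[v in info blob]
               + w_vis * nu[vis(i), v] * 1[v in info blob]
               + N(0, noise_sd^2)

where ``e`` is the subject's latent expertise in [0, 1], ``mu`` are three
fixed equidistant zero-sum category prototype patterns over the informational
voxels and ``nu`` are visual-cluster prototypes (in a subspace orthogonal to
the category patterns) whose clusters cross the categories, so visual
structure cannot proxy category structure.  Prototypes sum to zero across
clusters at every voxel, so the planted item information cannot leak into the
mean-of-items univariate contrast.
Task blobs activate but carry no item information; group membership is the
thresholded view ``expert iff e >= 0.5``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import nibabel as nib

from neuroscore.dissim import ExpertModel, build_expert_model, write_categories_tsv, write_dm_tsv
from neuroscore.firstlevel import ItemBetaMaps, build_design

__all__ = [
    "SyntheticCohortSpec",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "simulate_random_responder",
    "generate_timeseries",
    "default_event_table",
]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """All knobs of the synthetic generative model.

    ``expertise`` may list explicit per-subject values; when ``None``, half
    the subjects draw e ~ U(0, 0.5) (novices) and half e ~ U(0.5, 1)
    (experts), so the marginal is uniform on [0, 1] with balanced groups.
    """

    n_subjects_per_group: int = 10
    grid_dims: tuple[int, int, int] = (16, 16, 16)
    n_items: int = 24
    n_runs: int = 4
    expertise: tuple[float, ...] | None = None
    n_task_blobs: int = 4
    n_info_blobs: int = 3
    blob_radius: float = 2.0
    blob_centers: tuple[tuple[int, int, int], ...] | None = None
    a_task: float = 1.0
    w_cat: float = 1.0
    w_vis: float = 0.5
    noise_sd: float = 0.5
    n_visual_clusters: int = 4
    # behavioral model: accuracy = clip(base + slope * e + N(0, behav_noise_sd^2))
    fbd_base: tuple[float, ...] = (0.45, 0.55, 0.63, 0.68)
    fbd_slope: tuple[float, ...] = (0.40, 0.28, 0.20, 0.18)
    sci_base: float = 0.05
    sci_slope: float = 0.70
    fci_base: float = 0.20
    fci_slope: float = 0.65
    behav_noise_sd: float = 0.05
    p_missing_inventory: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects_per_group", "n_items", "n_runs",
                     "n_task_blobs", "n_info_blobs", "n_visual_clusters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.expertise is not None:
            e = np.asarray(self.expertise, dtype=float)
            if np.any((e < 0) | (e > 1)):
                raise ValueError("expertise values must lie in [0, 1]")
        if len(self.fbd_base) < self.n_runs or len(self.fbd_slope) < self.n_runs:
            raise ValueError("fbd_base/fbd_slope must cover every run")
        if self.n_items % 3 != 0:
            raise ValueError("n_items must split into 3 equal categories")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticCohortSpec":
        raw = json.loads(Path(path).read_text())
        for key in ("grid_dims", "expertise", "fbd_base", "fbd_slope", "blob_centers"):
            if raw.get(key) is not None:
                raw[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in raw[key]
                )
        return cls(**raw)


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    expertise: dict[str, float]
    task_blob_voxels: np.ndarray   # k x 3 grid indices
    info_blob_voxels: np.ndarray   # k x 3 grid indices
    item_categories: dict[str, str]
    item_visual_clusters: dict[str, int]

    @property
    def groups(self) -> dict[str, str]:
        return {s: ("expert" if e >= 0.5 else "novice") for s, e in self.expertise.items()}


@dataclass(frozen=True)
class SyntheticCohort:
    """Everything :func:`generate_cohort` produces, bundled."""

    spec: SyntheticCohortSpec
    mask: np.ndarray
    affine: np.ndarray
    betas: dict[tuple[str, int], ItemBetaMaps]
    behavior: pd.DataFrame
    ground_truth: GroundTruth
    expert_model: ExpertModel

    @property
    def subject_ids(self) -> list[str]:
        return sorted({s for s, _ in self.betas})

    def write(self, out_dir: str | Path) -> None:
        """Persist the cohort: beta NIfTIs, mask, behavior TSV, spec JSON."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        nib.save(
            nib.Nifti1Image(self.mask.astype(np.uint8), self.affine),
            out_dir / "brain_mask.nii.gz",
        )
        beta_dir = out_dir / "betas"
        for bm in self.betas.values():
            bm.to_nifti_dir(beta_dir)
        self.behavior.to_csv(out_dir / "behavior.tsv", sep="\t", index=False)
        self.spec.to_json(out_dir / "cohort_spec.json")
        write_dm_tsv(self.expert_model.dm, out_dir / "expert_dm.tsv")
        write_categories_tsv(self.expert_model.categories, out_dir / "expert_categories.tsv")
        gt = self.ground_truth
        pd.DataFrame(
            {"subject_id": list(gt.expertise), "expertise": list(gt.expertise.values()),
             "group": [gt.groups[s] for s in gt.expertise]}
        ).to_csv(out_dir / "ground_truth_expertise.tsv", sep="\t", index=False)


def _ball_voxels(center: np.ndarray, radius: float, dims: tuple[int, int, int]) -> np.ndarray:
    r = int(np.floor(radius))
    offs = np.array(
        [(i, j, k) for i in range(-r, r + 1) for j in range(-r, r + 1)
         for k in range(-r, r + 1) if i * i + j * j + k * k <= radius**2]
    )
    vox = center[None, :] + offs
    return vox


def _brain_mask(dims: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal brain mask leaving a margin inside the grid box."""
    grid = np.indices(dims).reshape(3, -1).T
    center = (np.array(dims) - 1) / 2.0
    semi = np.array(dims) / 2.0 - 1.5
    inside = (((grid - center) / semi) ** 2).sum(axis=1) <= 1.0
    mask = np.zeros(dims, dtype=bool)
    mask[tuple(grid[inside].T)] = True
    return mask


def _place_blobs(
    spec: SyntheticCohortSpec, mask: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint task and info blob voxel sets, each fully inside the mask."""
    dims = spec.grid_dims
    n_blobs = spec.n_task_blobs + spec.n_info_blobs
    occupied = np.zeros(dims, dtype=bool)
    centers: list[np.ndarray] = []

    if spec.blob_centers is not None:
        if len(spec.blob_centers) != n_blobs:
            raise ValueError(f"need {n_blobs} blob centers")
        candidates = [np.asarray(c, dtype=int) for c in spec.blob_centers]
    else:
        candidates = None

    if candidates is None:
        # centers whose whole ball lies in-mask: erode the mask by the ball
        ball_offs = _ball_voxels(np.zeros(3, dtype=int), spec.blob_radius, dims)
        struct = np.zeros(tuple(2 * int(spec.blob_radius) + 1 for _ in range(3)), dtype=bool)
        struct[tuple((ball_offs + int(spec.blob_radius)).T)] = True
        from scipy.ndimage import binary_erosion

        valid = binary_erosion(mask, structure=struct, border_value=0)
        sites = np.argwhere(valid)
        if sites.shape[0] == 0:
            raise ValueError("mask too small for the requested blob radius")
        order = rng.permutation(sites.shape[0])
        queue = iter(sites[order])
    tries = 0
    while len(centers) < n_blobs:
        if candidates is not None:
            c = candidates[len(centers)]
        else:
            c = next(queue, None)
            if c is None:
                raise ValueError(
                    "could not place disjoint blobs inside the mask; "
                    "reduce count/radius or enlarge the grid"
                )
        vox = _ball_voxels(c, spec.blob_radius, dims)
        ok = (
            np.all(vox >= 0) and np.all(vox < np.array(dims))
            and mask[tuple(vox.T)].all() and not occupied[tuple(vox.T)].any()
        )
        if ok:
            centers.append(np.asarray(c))
            occupied[tuple(vox.T)] = True
        elif candidates is not None:
            raise ValueError(
                f"blob at {tuple(c)} (radius {spec.blob_radius}) overlaps the "
                "mask boundary or another blob"
            )
        tries += 1

    task_vox = np.vstack(
        [_ball_voxels(c, spec.blob_radius, dims) for c in centers[: spec.n_task_blobs]]
    )
    info_vox = np.vstack(
        [_ball_voxels(c, spec.blob_radius, dims) for c in centers[spec.n_task_blobs:]]
    )
    return task_vox, info_vox


def _item_labels(
    spec: SyntheticCohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    item_ids = [f"item{i:02d}" for i in range(spec.n_items)]
    per_cat = spec.n_items // 3
    cat = np.repeat(np.arange(3), per_cat)
    # random balanced visual-cluster assignment, re-drawn until every cluster
    # crosses categories; randomization keeps visual similarity independent of
    # category membership in expectation over cohorts
    base = np.arange(spec.n_items) % spec.n_visual_clusters
    for _ in range(1000):
        vis = rng.permutation(base)
        spans = all(
            len(set(cat[vis == v])) >= 2 for v in range(spec.n_visual_clusters)
        )
        if spans:
            return cat, vis, item_ids
    raise ValueError("could not draw visual clusters crossing categories")


def _simplex_prototypes(k: int, basis: np.ndarray) -> np.ndarray:
    """K unit prototype patterns from simplex vertices in a (K-1)-dim basis.

    The returned K x n_voxels rows have unit norm, pairwise inner product
    -1/(K-1) and sum exactly to zero, so balanced cluster assignments leave
    the across-item mean untouched at every voxel.
    """
    if basis.shape[1] != k - 1:
        raise ValueError("basis must have K-1 orthonormal columns")
    centered = np.eye(k) - np.ones((k, k)) / k
    u, s, _ = np.linalg.svd(centered)
    vertices = u[:, : k - 1] * s[: k - 1]
    vertices /= np.linalg.norm(vertices, axis=1, keepdims=True)
    return vertices @ basis.T


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort; bit-reproducible for a fixed seed."""
    dims = spec.grid_dims
    master = np.random.SeedSequence(spec.seed)
    anat_rng = np.random.default_rng(master.spawn(1)[0])

    mask = _brain_mask(dims)
    task_vox, info_vox = _place_blobs(spec, mask, anat_rng)
    coords = np.argwhere(mask)
    flat = np.ravel_multi_index(coords.T, dims)
    pos_of_flat = {f: i for i, f in enumerate(flat)}
    task_idx = np.array([pos_of_flat[f] for f in np.ravel_multi_index(task_vox.T, dims)])
    info_idx = np.array([pos_of_flat[f] for f in np.ravel_multi_index(info_vox.T, dims)])

    cat, vis, item_ids = _item_labels(spec, anat_rng)
    n_info = info_idx.size
    n_basis = 2 + (spec.n_visual_clusters - 1)
    if n_info < n_basis:
        raise ValueError("info blobs too small to carry the prototype patterns")
    # Prototype patterns over info voxels: the K category (and visual-cluster)
    # prototypes are simplex vertices in a (K-1)-dim orthonormal basis, so
    # they are equidistant, zero-sum across categories at every voxel (no
    # leak of category signal into the mean-of-items univariate contrast),
    # and the category and visual subspaces are mutually orthogonal.
    q, _ = np.linalg.qr(anat_rng.normal(size=(n_info, n_basis)))
    mu = _simplex_prototypes(3, q[:, :2]) * np.sqrt(n_info)
    nu = _simplex_prototypes(spec.n_visual_clusters, q[:, 2:]) * np.sqrt(n_info)

    # children of the master sequence: 0 = anatomy (above), 1 = expertise,
    # 2.. = one stream per subject
    n_sub = 2 * spec.n_subjects_per_group
    sub_seqs = np.random.SeedSequence(spec.seed).spawn(n_sub + 2)[2:]
    if spec.expertise is not None:
        if len(spec.expertise) != n_sub:
            raise ValueError(f"expertise must list {n_sub} values")
        expertise = np.asarray(spec.expertise, dtype=float)
    else:
        e_rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
        expertise = np.concatenate(
            [e_rng.uniform(0.0, 0.5, spec.n_subjects_per_group),
             e_rng.uniform(0.5, 1.0, spec.n_subjects_per_group)]
        )

    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    signal = np.zeros((spec.n_items, coords.shape[0]))
    signal[:, task_idx] += spec.a_task
    signal[:, info_idx] += spec.a_task
    cat_pattern = np.zeros_like(signal)
    cat_pattern[:, info_idx] = mu[cat]
    vis_pattern = np.zeros_like(signal)
    vis_pattern[:, info_idx] = spec.w_vis * nu[vis]

    betas: dict[tuple[str, int], ItemBetaMaps] = {}
    behavior_rows = []
    subject_ids = [f"{i:03d}" for i in range(n_sub)]
    for s_i, (sid, e, seq) in enumerate(zip(subject_ids, expertise, sub_seqs)):
        rng = np.random.default_rng(seq)
        for run in range(1, spec.n_runs + 1):
            noise = rng.normal(0.0, spec.noise_sd, size=signal.shape)
            b = signal + spec.w_cat * e * cat_pattern + vis_pattern + noise
            betas[(sid, run)] = ItemBetaMaps(
                subject_id=sid, run_id=run, betas=b, voxel_coords=coords,
                grid_shape=dims, affine=affine, item_ids=tuple(item_ids),
            )
        row = {"subject_id": sid, "group": "expert" if e >= 0.5 else "novice"}
        for run in range(1, spec.n_runs + 1):
            acc = spec.fbd_base[run - 1] + spec.fbd_slope[run - 1] * e
            row[f"fbd_acc_run{run}"] = float(
                np.clip(acc + rng.normal(0, spec.behav_noise_sd), 0, 1)
            )
        missing = rng.uniform() < spec.p_missing_inventory
        if missing:
            row["sci_acc"] = np.nan
            row["fci_acc"] = np.nan
        else:
            row["sci_acc"] = float(np.clip(
                spec.sci_base + spec.sci_slope * e + rng.normal(0, spec.behav_noise_sd), 0, 1))
            row["fci_acc"] = float(np.clip(
                spec.fci_base + spec.fci_slope * e + rng.normal(0, spec.behav_noise_sd), 0, 1))
        behavior_rows.append(row)

    expert_model_cats = dict(zip(item_ids, (("cantilever", "truss", "vertical_load")[c] for c in cat)))
    expert = build_expert_model(
        n_items=spec.n_items,
        category_sizes=(spec.n_items // 3,) * 3,
        seed=spec.seed + 1,
    )
    gt = GroundTruth(
        expertise=dict(zip(subject_ids, map(float, expertise))),
        task_blob_voxels=task_vox,
        info_blob_voxels=info_vox,
        item_categories=expert_model_cats,
        item_visual_clusters={iid: int(v) for iid, v in zip(item_ids, vis)},
    )
    return SyntheticCohort(
        spec=spec, mask=mask, affine=affine, betas=betas,
        behavior=pd.DataFrame(behavior_rows), ground_truth=gt, expert_model=expert,
    )


def simulate_random_responder(n_trials: int, seed: int = 0) -> float:
    """Accuracy of a uniformly random responder on 2-AFC trials (chance 0.5)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    return float(rng.integers(0, 2, size=n_trials).mean())


def default_event_table(
    item_ids: Sequence[str],
    stimulus_duration: float = 6.0,
    iti: float = 4.0,
    include_response: bool = True,
    response_duration: float = 2.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """One trial per item: 6 s stimulus-consideration boxcar, optional
    response period (modeled then discarded), fixation gaps between trials."""
    order = list(range(len(item_ids)))
    if seed is not None:
        np.random.default_rng(seed).shuffle(order)
    rows = []
    t = iti
    for idx in order:
        rows.append({"onset": t, "duration": stimulus_duration,
                     "trial_type": str(item_ids[idx])})
        t += stimulus_duration
        if include_response:
            rows.append({"onset": t, "duration": response_duration,
                         "trial_type": "response"})
            t += response_duration
        t += iti
    return pd.DataFrame(rows)


def generate_timeseries(
    betas: ItemBetaMaps,
    timing: pd.DataFrame,
    tr: float = 2.5,
    noise_sd: float = 0.0,
    n_scans: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Forward model: 4-D series = HRF-convolved boxcars weighted by betas + white noise.

    The regressor construction is shared with the GLM (:func:`build_design`),
    so a noise-free series round-trips through :func:`fit_item_glm` exactly.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    end = (timing["onset"] + timing["duration"]).max()
    if n_scans is None:
        n_scans = int(np.ceil((end + 20.0) / tr))
    item_rows = timing[~timing["trial_type"].astype(str).isin(["response"])]
    starts = item_rows.sort_values("onset")
    overlap = (starts["onset"] + starts["duration"]).to_numpy()[:-1] > starts["onset"].to_numpy()[1:]
    if overlap.any():
        raise ValueError("item windows overlap in the timing table")

    X_items, item_ids, X_nuis, _ = build_design(timing, n_scans, tr)
    if tuple(item_ids) != betas.item_ids:
        raise ValueError("timing trial_types do not match beta item_ids")
    Y = X_items @ betas.betas  # T x V
    if noise_sd > 0:
        Y = Y + np.random.default_rng(seed).normal(0, noise_sd, size=Y.shape)
    series = np.zeros(betas.grid_shape + (n_scans,))
    series[tuple(betas.voxel_coords.T)] = Y.T
    return series
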