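"""The three neural scores: univariate, searchlight-RSA and informational-network.

All three condense one subject-run's item-level activity patterns into a
scalar.  The univariate score averages contrast z over the top-activation
mask; the RSA score averages Fisher-z Spearman agreement with the expert
model over supra-threshold searchlight locations; the informational-network
score clusters activation-masked searchlight DMs into reliable networks,
embeds each network's average DM in 2-D and reports the best network's
radial-SVM category-decoding accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import eigh
from sklearn.svm import SVC

from neuroscore.dissim import (
    FISHER_Z_CAP,
    DissimilarityMatrix,
    ExpertModel,
    average_dm,
    spearman_dm_similarity,
)
from neuroscore.firstlevel import ContrastZMap, ItemBetaMaps, robust_range_mask, zmap_from_betas
from neuroscore.netclust import (
    DEFAULT_SCALES,
    cut_networks,
    hierarchical_cluster,
    multiscale_bootstrap_au,
)
from neuroscore.searchlight import SearchlightResult, searchlight_dms, sphere_neighborhoods

__all__ = [
    "InformationalNetwork",
    "NeuralScoreRecord",
    "InfonetConfig",
    "univariate_score",
    "rsa_score",
    "mds_embed",
    "svm_category_accuracy",
    "infonet_score",
]

log = logging.getLogger(__name__)


@dataclass
class NeuralScoreRecord:
    """One subject-run-method scalar score plus its contributing voxels."""

    subject_id: str
    run_id: int
    method: str                       # "infonet" | "rsa" | "univariate"
    score: float                      # nan when flagged missing/dropped
    contributing_voxels: np.ndarray   # positions into the in-mask voxel list
    flags: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return np.isfinite(self.score)


@dataclass
class InformationalNetwork:
    """A reliable cluster of searchlight DMs with its decoded structure."""

    member_centers: np.ndarray
    au: float
    height: float
    average_dm: DissimilarityMatrix
    embedding: np.ndarray             # n_items x 2
    svm_accuracy: float

    def __post_init__(self) -> None:
        if self.embedding.shape[0] != self.average_dm.n_items:
            raise ValueError("embedding rows must equal n_items")
        if not 0.0 <= self.svm_accuracy <= 1.0:
            raise ValueError("svm accuracy must be in [0, 1]")


def univariate_score(
    zmap: ContrastZMap, top_fraction: float = 0.02
) -> NeuralScoreRecord:
    """Mean contrast z over the top-``top_fraction`` positive-z voxel mask."""
    mask = robust_range_mask(zmap, top_fraction)
    if not mask.any():
        return NeuralScoreRecord(
            subject_id="", run_id=0, method="univariate", score=float("nan"),
            contributing_voxels=np.array([], dtype=int), flags=["missing_empty_mask"],
        )
    idx = np.flatnonzero(mask)
    return NeuralScoreRecord(
        subject_id="", run_id=0, method="univariate",
        score=float(zmap.z[idx].mean()), contributing_voxels=idx,
        diagnostics={"n_mask_voxels": int(idx.size), "top_fraction": top_fraction},
    )


def _capped_fisher_z(rho: float) -> tuple[float, bool]:
    if abs(rho) >= 1.0:
        return float(np.sign(rho) * FISHER_Z_CAP), True
    return float(np.arctanh(rho)), False


def rsa_score(
    slr: SearchlightResult, expert: ExpertModel, z_threshold: float = 2.0
) -> NeuralScoreRecord:
    """Mean Fisher-z Spearman(DM, expert DM) over centers with z >= threshold.

    Subjects with no surviving center are flagged ``dropped`` (score nan).
    Perfect correlations (rho = +/-1, infinite Fisher z) are capped at
    +/-atanh(1 - 1e-16) and flagged rather than dropped.
    """
    zs = np.empty(slr.n_centers)
    any_capped = False
    for i, dm in enumerate(slr.dms):
        rho = spearman_dm_similarity(dm, expert.dm)
        zs[i], capped = _capped_fisher_z(rho)
        any_capped = any_capped or capped
    surviving = zs >= z_threshold
    flags = ["fisher_z_capped"] if any_capped else []
    if not surviving.any():
        return NeuralScoreRecord(
            subject_id="", run_id=0, method="rsa", score=float("nan"),
            contributing_voxels=np.array([], dtype=int),
            flags=flags + ["dropped_no_survivors"],
            diagnostics={"n_centers": slr.n_centers, "max_z": float(zs.max())},
        )
    return NeuralScoreRecord(
        subject_id="", run_id=0, method="rsa",
        score=float(zs[surviving].mean()),
        contributing_voxels=slr.centers[surviving],
        flags=flags,
        diagnostics={
            "n_centers": slr.n_centers,
            "n_surviving_centers": int(surviving.sum()),
            "z_threshold": z_threshold,
        },
    )


def mds_embed(
    dm: DissimilarityMatrix, n_dims: int = 2, variant: str = "classical"
) -> np.ndarray:
    """Project a DM into ``n_dims`` coordinates by multidimensional scaling.

    ``classical`` (default) is the Torgerson solution: double-center the
    squared-distance matrix and take the top eigenvectors scaled by the root
    eigenvalues; deterministic, with signs fixed so each coordinate's largest
    component is positive.  ``nonmetric`` refines the classical solution by
    stress minimization (fixed iteration cap).  When fewer than ``n_dims``
    positive eigenvalues exist, missing coordinates are zero-padded with a
    warning.
    """
    D = dm.square()
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, n_dims))
    n_pos = int(np.sum(vals[:n_dims] > 1e-12))
    if n_pos < n_dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); padding {n_dims - n_pos} "
            "MDS coordinate(s) with zeros",
            RuntimeWarning,
        )
    for d in range(n_pos):
        coords[:, d] = vecs[:, d] * np.sqrt(vals[d])
    # deterministic sign convention
    for d in range(n_dims):
        col = coords[:, d]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, d] = -col
    if variant == "classical":
        return coords
    if variant == "nonmetric":
        from sklearn.manifold import smacof

        coords, _ = smacof(
            D, metric=False, n_components=n_dims, init=coords, n_init=1,
            max_iter=300, eps=1e-6, random_state=0, normalized_stress=False,
        )
        return coords
    raise ValueError(f"unknown MDS variant {variant!r}")


def svm_category_accuracy(
    coords: np.ndarray,
    labels: Sequence[str],
    cost: float = 1.0,
    kernel_width: float = 0.5,
    eval_mode: str = "resubstitution",
) -> float:
    """Radial-kernel SVM decoding accuracy of category labels from coordinates.

    One-vs-one multiclass soft-margin SVM with fixed hyperparameters
    (``cost`` = 1, ``kernel_width`` = gamma = 1/n_features = 0.5 in 2-D);
    accuracy is the fraction of items predicted correctly, by default under
    resubstitution (fit on all items, predict all items).  A single-class
    label set short-circuits to 1.0 (degenerate; warning issued).
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if coords.ndim != 2 or coords.shape[0] != labels.shape[0]:
        raise ValueError("coords must be items x dims aligned with labels")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    if len(set(labels)) < 2:
        warnings.warn("single category label present; accuracy trivially 1.0",
                      RuntimeWarning)
        return 1.0
    if eval_mode == "resubstitution":
        clf = SVC(C=cost, kernel="rbf", gamma=kernel_width)
        clf.fit(coords, labels)
        pred = clf.predict(coords)
        return float(np.mean(pred == labels))
    if eval_mode == "leave_one_out":
        correct = 0
        n = coords.shape[0]
        for i in range(n):
            keep = np.arange(n) != i
            if len(set(labels[keep])) < 2:
                continue
            clf = SVC(C=cost, kernel="rbf", gamma=kernel_width)
            clf.fit(coords[keep], labels[keep])
            correct += int(clf.predict(coords[i:i + 1])[0] == labels[i])
        return float(correct / n)
    raise ValueError(f"unknown eval_mode {eval_mode!r}")


@dataclass(frozen=True)
class InfonetConfig:
    """Tunables of the informational-network score pipeline."""

    top_fraction: float = 0.02
    radius_voxels: float = 3.0
    min_voxels: int = 10
    scales: tuple[float, ...] = DEFAULT_SCALES
    n_boot_per_scale: int = 100
    au_threshold: float = 0.95
    min_network_size: int = 2
    svm_cost: float = 1.0
    svm_kernel_width: float = 0.5
    svm_eval_mode: str = "resubstitution"
    seed: int = 0


def infonet_score(
    betas: ItemBetaMaps,
    expert_categories: Mapping[str, str],
    config: InfonetConfig = InfonetConfig(),
    zmap: ContrastZMap | None = None,
    brain_mask: np.ndarray | None = None,
) -> tuple[NeuralScoreRecord, list[InformationalNetwork]]:
    """Informational-network neural score for one subject-run.

    Pipeline: top-activation voxel mask -> searchlight DMs at centers inside
    that mask -> bootstrapped hierarchical clustering into reliable networks
    -> average DM per network -> 2-D MDS -> radial-SVM 3-way category
    decoding -> score = accuracy of the best network.  Ties on accuracy break
    toward the larger network, then the lower merge height.

    ``zmap`` defaults to the beta-level images > baseline contrast
    (:func:`~neuroscore.firstlevel.zmap_from_betas`); ``brain_mask`` defaults
    to the betas' own voxel mask.
    """
    labels = [expert_categories[i] for i in betas.item_ids]
    if zmap is None:
        zmap = zmap_from_betas(betas)
    if brain_mask is None:
        brain_mask = betas.mask_array()

    rr = robust_range_mask(zmap, config.top_fraction)
    record = NeuralScoreRecord(
        subject_id=betas.subject_id, run_id=betas.run_id, method="infonet",
        score=float("nan"), contributing_voxels=np.array([], dtype=int),
    )
    if not rr.any():
        record.flags.append("missing_empty_mask")
        return record, []

    candidate_centers = np.flatnonzero(rr)
    centers, hoods = sphere_neighborhoods(
        brain_mask, config.radius_voxels, config.min_voxels,
        centers=candidate_centers,
    )
    if centers.size == 0:
        record.flags.append("missing_no_centers")
        return record, []
    slr = searchlight_dms(betas, centers, hoods,
                          config.radius_voxels, config.min_voxels)
    record.diagnostics["n_surviving_centers"] = slr.n_centers

    if slr.n_centers == 1:
        networks_members = [frozenset([0])]
        heights = {frozenset([0]): 0.0}
        aus = {frozenset([0]): float("nan")}
        record.flags.append("single_center")
    else:
        stack = slr.dm_stack()
        dend = hierarchical_cluster(stack)
        support = multiscale_bootstrap_au(
            stack, dend, scales=config.scales,
            n_boot_per_scale=config.n_boot_per_scale, seed=config.seed,
        )
        networks_members = cut_networks(
            dend, support, config.au_threshold, config.min_network_size
        )
        node_of = {dend.members[k]: k for k in range(dend.n_nodes)}
        heights, aus = {}, {}
        for mset in networks_members:
            if mset in node_of:
                k = node_of[mset]
                heights[mset] = float(dend.heights[k])
                aus[mset] = float(support.au[k])
            else:  # singleton fallback sets
                heights[mset] = 0.0
                aus[mset] = float("nan")

    networks: list[InformationalNetwork] = []
    for mset in networks_members:
        members = sorted(mset)
        avg = average_dm([slr.dms[i] for i in members])
        coords = mds_embed(avg, n_dims=2)
        acc = svm_category_accuracy(
            coords, labels, cost=config.svm_cost,
            kernel_width=config.svm_kernel_width, eval_mode=config.svm_eval_mode,
        )
        networks.append(InformationalNetwork(
            member_centers=slr.centers[members], au=aus[mset],
            height=heights[mset], average_dm=avg, embedding=coords,
            svm_accuracy=acc,
        ))

    # max accuracy; ties -> larger network, then lower merge height
    best = min(
        networks,
        key=lambda nw: (-nw.svm_accuracy, -nw.member_centers.size, nw.height),
    )
    record.score = float(best.svm_accuracy)
    record.contributing_voxels = best.member_centers.copy()
    record.diagnostics["n_networks"] = len(networks)
    record.diagnostics["best_network_size"] = int(best.member_centers.size)
    return record, networks
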