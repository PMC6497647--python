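"""Bootstrapped hierarchical clustering of searchlight DMs into networks.

Searchlight DMs (observations) are agglomerated with average linkage under
correlation distance.  Cluster reliability is assessed by multiscale
bootstrap: condensed-DM coordinates (features) are resampled with replacement
at several scales r, the tree is rebuilt per replicate, and each original
node's recovery frequency BP_r is recorded.  Fitting

    Phi^{-1}(1 - BP_r) = v * sqrt(r) + c / sqrt(r)

by least squares over informative scales yields the approximately unbiased
p-value au = 1 - Phi(v - c); bp is the ordinary bootstrap proportion (r = 1).
Networks are then the maximal non-nested nodes with au above threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.special import ndtr, ndtri

__all__ = [
    "Dendrogram",
    "NodeSupport",
    "hierarchical_cluster",
    "multiscale_bootstrap_au",
    "cut_networks",
    "DEFAULT_SCALES",
]

log = logging.getLogger(__name__)

DEFAULT_SCALES: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))


@dataclass
class Dendrogram:
    """Binary merge tree over m observations (scipy linkage encoding).

    Internal node k (0-based, k in [0, m-2]) corresponds to linkage row k and
    has height ``heights[k]`` and member set ``members[k]``.  The root is node
    m - 2.
    """

    linkage_matrix: np.ndarray
    n_obs: int
    heights: np.ndarray = field(init=False)
    members: list[frozenset[int]] = field(init=False)

    def __post_init__(self) -> None:
        Z = np.asarray(self.linkage_matrix, dtype=float)
        if Z.shape != (self.n_obs - 1, 4):
            raise ValueError("linkage matrix shape does not match n_obs")
        if np.any(np.diff(Z[:, 2]) < -1e-12):
            raise ValueError("merge heights must be nondecreasing")
        self.heights = Z[:, 2].copy()
        self.members = _node_members(Z, self.n_obs)

    @property
    def n_nodes(self) -> int:
        return self.n_obs - 1

    @property
    def root(self) -> int:
        return self.n_obs - 2

    def to_newick(self, labels: Sequence[str] | None = None) -> str:
        """Newick string with branch lengths from merge heights."""
        if labels is None:
            labels = [f"dm{i}" for i in range(self.n_obs)]
        Z = self.linkage_matrix

        def h(node: int) -> float:
            return 0.0 if node < self.n_obs else Z[node - self.n_obs, 2]

        def rec(node: int) -> str:
            if node < self.n_obs:
                return str(labels[node])
            a, b = int(Z[node - self.n_obs, 0]), int(Z[node - self.n_obs, 1])
            hn = h(node)
            return (
                f"({rec(a)}:{hn - h(a):.6g},{rec(b)}:{hn - h(b):.6g})"
            )

        return rec(self.n_obs + self.n_nodes - 1) + ";"


def _node_members(Z: np.ndarray, m: int) -> list[frozenset[int]]:
    members: list[frozenset[int]] = []
    for k in range(Z.shape[0]):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        sa = frozenset([a]) if a < m else members[a - m]
        sb = frozenset([b]) if b < m else members[b - m]
        members.append(sa | sb)
    return members


def _cluster_stack(stack: np.ndarray, method: str, metric: str) -> np.ndarray:
    if metric == "correlation":
        d = pdist(stack, metric="correlation")
        d = np.clip(d, 0.0, None)
    else:
        d = pdist(stack, metric=metric)
    return linkage(d, method=method)


def hierarchical_cluster(
    dm_stack: np.ndarray, method: str = "average", metric: str = "correlation"
) -> Dendrogram:
    """Agglomerate the m condensed DMs (rows) of ``dm_stack``.

    Observation-pair distance defaults to 1 - Pearson correlation between
    condensed vectors, with average linkage.
    """
    stack = np.asarray(dm_stack, dtype=float)
    if stack.ndim != 2 or stack.shape[0] < 2:
        raise ValueError("dm_stack must be m x p with m >= 2")
    if metric == "correlation" and np.any(stack.std(axis=1) == 0):
        raise ValueError("constant DM rows have undefined correlation distance")
    Z = _cluster_stack(stack, method, metric)
    return Dendrogram(linkage_matrix=Z, n_obs=stack.shape[0])


@dataclass
class NodeSupport:
    """Per-internal-node bootstrap support, aligned with Dendrogram node ids."""

    bp: np.ndarray           # ordinary bootstrap proportion (scale r = 1)
    au: np.ndarray           # approximately unbiased p-value
    v: np.ndarray
    c: np.ndarray
    fit_residual: np.ndarray
    flags: list[set[str]]    # per node: {"never_recovered", "always_recovered",
                             #            "degenerate_fit", "single_scale"}
    scales: tuple[float, ...]
    n_boot_per_scale: int
    bp_by_scale: np.ndarray  # n_scales x n_nodes recovery frequencies

    def to_json(self, dendrogram: Dendrogram, path: str | Path) -> None:
        nodes = [
            {
                "node": k,
                "members": sorted(dendrogram.members[k]),
                "height": float(dendrogram.heights[k]),
                "bp": float(self.bp[k]),
                "au": float(self.au[k]),
                "flags": sorted(self.flags[k]),
            }
            for k in range(dendrogram.n_nodes)
        ]
        Path(path).write_text(json.dumps(nodes, indent=2))


def multiscale_bootstrap_au(
    dm_stack: np.ndarray,
    dendrogram: Dendrogram,
    scales: Sequence[float] = DEFAULT_SCALES,
    n_boot_per_scale: int = 100,
    seed: int = 0,
    method: str = "average",
    metric: str = "correlation",
) -> NodeSupport:
    """Multiscale-bootstrap AU p-values for every internal node.

    At each scale r, ``ceil(r * p)`` of the p condensed-entry coordinates are
    resampled with replacement and the tree rebuilt; a node is *recovered*
    when some node of the replicate tree has an identical member set.
    """
    stack = np.asarray(dm_stack, dtype=float)
    m, p = stack.shape
    scales = tuple(float(s) for s in scales)
    single_scale = len(scales) == 1
    if not single_scale and len(scales) < 3:
        raise ValueError("need >= 3 scales (or exactly 1 for plain bootstrap)")
    if n_boot_per_scale < 20:
        raise ValueError("n_boot_per_scale must be >= 20")

    n_nodes = dendrogram.n_nodes
    target_sets = dendrogram.members
    counts = np.zeros((len(scales), n_nodes), dtype=int)
    rng = np.random.default_rng(seed)
    for si, r in enumerate(scales):
        n_feat = int(np.ceil(r * p))
        for _ in range(n_boot_per_scale):
            idx = rng.integers(0, p, size=n_feat)
            sub = stack[:, idx]
            sd = sub.std(axis=1)
            if metric == "correlation" and np.any(sd == 0):
                # constant replicate rows: fall back to jittered copy to keep
                # the replicate count; contributes as a non-recovery draw
                sub = sub + rng.normal(0, 1e-12, size=sub.shape)
            Zb = _cluster_stack(sub, method, metric)
            rep_sets = set(_node_members(Zb, m))
            for k in range(n_nodes):
                if target_sets[k] in rep_sets:
                    counts[si, k] += 1

    bp_by_scale = counts / n_boot_per_scale
    if 1.0 in scales:
        bp = bp_by_scale[scales.index(1.0)].copy()
    else:
        bp = bp_by_scale[int(np.argmin(np.abs(np.array(scales) - 1.0)))].copy()

    au = np.full(n_nodes, np.nan)
    v_arr = np.full(n_nodes, np.nan)
    c_arr = np.full(n_nodes, np.nan)
    resid = np.full(n_nodes, np.nan)
    flags: list[set[str]] = [set() for _ in range(n_nodes)]

    sq = np.sqrt(np.asarray(scales))
    for k in range(n_nodes):
        bps = bp_by_scale[:, k]
        if single_scale:
            flags[k].add("single_scale")
            continue
        if np.all(bps == 0):
            au[k] = 0.0
            flags[k].add("never_recovered")
            continue
        if np.all(bps == 1):
            au[k] = 1.0
            flags[k].add("always_recovered")
            continue
        use = (bps > 0) & (bps < 1)
        if use.sum() < 2:
            # not enough informative scales for the two-parameter fit
            au[k] = float(bp[k])
            flags[k].add("degenerate_fit")
            continue
        z = ndtri(1.0 - bps[use])
        A = np.column_stack([sq[use], 1.0 / sq[use]])
        # weight by the inverse sampling variance of z: var(BP) = BP(1-BP)/n
        # propagated through the probit, w = phi(z)^2 * n / (BP (1 - BP))
        phi = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
        w = phi**2 * n_boot_per_scale / (bps[use] * (1.0 - bps[use]))
        sw = np.sqrt(w)
        coef, res, _, _ = np.linalg.lstsq(A * sw[:, None], z * sw, rcond=None)
        v_arr[k], c_arr[k] = coef
        resid[k] = float(res[0]) if res.size else 0.0
        au[k] = float(1.0 - ndtr(v_arr[k] - c_arr[k]))

    return NodeSupport(
        bp=bp, au=au, v=v_arr, c=c_arr, fit_residual=resid, flags=flags,
        scales=scales, n_boot_per_scale=n_boot_per_scale, bp_by_scale=bp_by_scale,
    )


def cut_networks(
    dendrogram: Dendrogram,
    support: NodeSupport,
    au_threshold: float = 0.95,
    min_size: int = 2,
) -> list[frozenset[int]]:
    """Maximal reliable clusters: the highest nodes with au >= threshold.

    The root node (the full observation set, trivially recovered in every
    replicate) is not a candidate.  Returned sets are pairwise non-nested
    (therefore disjoint on a tree).  When nothing qualifies, falls back to
    the single root set so a score can still be produced (warning logged).
    """
    if not 0 < au_threshold < 1:
        raise ValueError("au_threshold must be in (0, 1)")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    candidates = [
        k for k in range(dendrogram.n_nodes)
        if k != dendrogram.root
        and np.isfinite(support.au[k])
        and support.au[k] >= au_threshold
        and len(dendrogram.members[k]) >= min_size
    ]
    # keep maximal sets only
    keep: list[int] = []
    for k in sorted(candidates, key=lambda k: -len(dendrogram.members[k])):
        if not any(dendrogram.members[k] < dendrogram.members[j] for j in keep):
            keep.append(k)
    if not keep:
        log.warning("no node reached au >= %.2f; falling back to the root network",
                    au_threshold)
        return [dendrogram.members[dendrogram.root]]
    return [dendrogram.members[k] for k in sorted(keep)]
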