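"""Volumetric searchlight neighborhoods and per-center dissimilarity matrices."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from neuroscore.dissim import DegeneratePatternError, DissimilarityMatrix, condensed_correlation_dm
from neuroscore.firstlevel import ItemBetaMaps

__all__ = ["SearchlightResult", "sphere_neighborhoods", "searchlight_dms"]

log = logging.getLogger(__name__)


@dataclass
class SearchlightResult:
    """One condensed DM per retained searchlight center.

    ``centers`` and neighborhood members are positions into the in-mask voxel
    list of the ItemBetaMaps the searchlight was run on (the row order of
    ``np.argwhere(mask)``), so they align directly with beta columns.
    """

    centers: np.ndarray                  # positions into the voxel list
    neighborhoods: list[np.ndarray]      # per-center member positions
    dms: list[DissimilarityMatrix]
    radius_voxels: float
    min_voxels: int
    n_dropped_degenerate: int = 0

    def __post_init__(self) -> None:
        if not (len(self.centers) == len(self.neighborhoods) == len(self.dms)):
            raise ValueError("centers, neighborhoods and dms must align 1:1")

    @property
    def n_centers(self) -> int:
        return len(self.centers)

    def dm_stack(self) -> np.ndarray:
        """Centers x pairs matrix of condensed DM values."""
        return np.array([dm.values for dm in self.dms])

    def save(self, prefix: str | Path) -> None:
        """Persist the DM stack (.npz) with a JSON sidecar."""
        prefix = Path(prefix)
        np.savez_compressed(
            prefix.with_suffix(".npz"), dm_stack=self.dm_stack(),
            centers=self.centers,
        )
        sidecar = {
            "radius_voxels": self.radius_voxels,
            "min_voxels": self.min_voxels,
            "item_ids": list(self.dms[0].item_ids) if self.dms else [],
            "n_centers": self.n_centers,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def sphere_neighborhoods(
    mask: np.ndarray,
    radius_voxels: float = 3.0,
    min_voxels: int = 10,
    centers: np.ndarray | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Spherical in-mask neighborhoods around every in-mask voxel.

    A voxel v belongs to center c's neighborhood when the Euclidean distance
    between their integer grid indices is <= ``radius_voxels`` (isotropic
    voxels; distances in voxel-index units).  Centers whose neighborhood has
    fewer than ``min_voxels`` members are dropped.

    Parameters
    ----------
    mask
        3-D boolean brain mask.
    centers
        Optional subset of candidate centers, as positions into the
        ``np.argwhere(mask)`` voxel list; defaults to every in-mask voxel.

    Returns
    -------
    (centers, neighborhoods)
        Retained center positions and, per center, the member positions —
        both indexing into the in-mask voxel list.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius_voxels < 1:
        raise ValueError("radius_voxels must be >= 1")
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise ValueError("mask is empty")
    tree = cKDTree(coords)
    if centers is None:
        centers = np.arange(coords.shape[0])
    else:
        centers = np.asarray(centers, dtype=int)
    kept_centers: list[int] = []
    neighborhoods: list[np.ndarray] = []
    member_lists = tree.query_ball_point(coords[centers], r=radius_voxels + 1e-9)
    for c, members in zip(centers, member_lists):
        members = np.sort(np.asarray(members, dtype=int))
        if members.size >= min_voxels:
            kept_centers.append(int(c))
            neighborhoods.append(members)
    return np.asarray(kept_centers, dtype=int), neighborhoods


def searchlight_dms(
    betas: ItemBetaMaps,
    centers: np.ndarray,
    neighborhoods: Sequence[np.ndarray],
    radius_voxels: float = 3.0,
    min_voxels: int = 10,
) -> SearchlightResult:
    """Condensed correlation-distance DM at every searchlight center.

    Centers whose item x member-voxel submatrix contains a zero-variance item
    row are dropped (count logged); raising only when *all* centers drop.
    """
    n_voxels = betas.n_voxels
    kept_c, kept_n, dms = [], [], []
    dropped = 0
    for c, members in zip(centers, neighborhoods):
        if np.any(members >= n_voxels) or np.any(members < 0):
            raise ValueError("neighborhood references voxels outside the beta mask")
        sub = betas.betas[:, members]
        try:
            dm = condensed_correlation_dm(sub, betas.item_ids)
        except DegeneratePatternError:
            dropped += 1
            continue
        kept_c.append(int(c))
        kept_n.append(np.asarray(members))
        dms.append(dm)
    if dropped:
        log.info("searchlight: dropped %d center(s) with degenerate patterns", dropped)
    if not kept_c:
        raise ValueError("all searchlight centers dropped (degenerate patterns)")
    return SearchlightResult(
        centers=np.asarray(kept_c, dtype=int), neighborhoods=kept_n, dms=dms,
        radius_voxels=radius_voxels, min_voxels=min_voxels,
        n_dropped_degenerate=dropped,
    )
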