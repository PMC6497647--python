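"""Group localization of contributing voxels and standard-mesh sizing."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import nibabel as nib

__all__ = [
    "GroupLocalizationMap",
    "group_localization",
    "standard_mesh_vertex_count",
    "CATEGORY_CODES",
]

#: integer encoding of the per-voxel category layer
CATEGORY_CODES = {"none": 0, "expert_only": 1, "novice_only": 2, "both": 3}


@dataclass
class GroupLocalizationMap:
    """Per-voxel contribution counts by group and the derived category layer."""

    expert_count: np.ndarray
    novice_count: np.ndarray
    category: np.ndarray  # CATEGORY_CODES values
    grid_shape: tuple[int, int, int]
    affine: np.ndarray

    def histogram(self) -> pd.DataFrame:
        """Per-voxel total-count histogram over contributing voxels."""
        total = self.expert_count + self.novice_count
        counts = np.bincount(total[total > 0].ravel())
        return pd.DataFrame(
            {"n_subjects": np.arange(len(counts)), "n_voxels": counts}
        ).query("n_subjects > 0")

    def write(self, out_dir: str | Path, prefix: str = "localization") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, arr in (
            ("expert_count", self.expert_count),
            ("novice_count", self.novice_count),
            ("category", self.category),
        ):
            nib.save(
                nib.Nifti1Image(arr.astype(np.uint8), self.affine),
                out_dir / f"{prefix}_{name}.nii.gz",
            )
        self.histogram().to_csv(out_dir / f"{prefix}_histogram.tsv", sep="\t", index=False)


def group_localization(
    contributing: Mapping[str, np.ndarray],
    groups: Mapping[str, str],
    grid_shape: tuple[int, int, int],
    voxel_coords: np.ndarray,
    affine: np.ndarray | None = None,
) -> GroupLocalizationMap:
    """Overlay per-subject contributing-voxel sets on a common grid.

    Parameters
    ----------
    contributing
        subject_id -> contributing voxel positions (into the shared in-mask
        voxel list ``voxel_coords``).
    groups
        subject_id -> "expert" | "novice".
    voxel_coords
        The shared ``n_voxels x 3`` grid coordinates all subjects' positions
        refer to (subjects must share one grid).

    The per-voxel category is a pure function of the two count layers:
    both > 0 -> both; expert only -> expert_only; novice only -> novice_only.
    """
    if affine is None:
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
    voxel_coords = np.asarray(voxel_coords, dtype=int)
    if voxel_coords.ndim != 2 or voxel_coords.shape[1] != 3:
        raise ValueError("voxel_coords must be n_voxels x 3")
    if np.any(voxel_coords < 0) or np.any(voxel_coords >= np.array(grid_shape)):
        raise ValueError("voxel_coords fall outside the common grid")

    expert_count = np.zeros(grid_shape, dtype=int)
    novice_count = np.zeros(grid_shape, dtype=int)
    for sid, positions in contributing.items():
        if sid not in groups:
            raise ValueError(f"no group label for subject {sid}")
        positions = np.asarray(positions, dtype=int)
        if positions.size == 0:
            continue
        if positions.max() >= voxel_coords.shape[0] or positions.min() < 0:
            raise ValueError(f"subject {sid}: voxel positions outside the common grid")
        target = expert_count if groups[sid] == "expert" else novice_count
        np.add.at(target, tuple(voxel_coords[positions].T), 1)

    category = np.zeros(grid_shape, dtype=int)
    category[(expert_count > 0) & (novice_count == 0)] = CATEGORY_CODES["expert_only"]
    category[(expert_count == 0) & (novice_count > 0)] = CATEGORY_CODES["novice_only"]
    category[(expert_count > 0) & (novice_count > 0)] = CATEGORY_CODES["both"]
    return GroupLocalizationMap(
        expert_count=expert_count, novice_count=novice_count, category=category,
        grid_shape=tuple(grid_shape), affine=affine,
    )


def standard_mesh_vertex_count(linear_divisions: int, n_hemispheres: int = 2) -> int:
    """Vertex count of icosahedral standard meshes: (10 * ld^2 + 2) per hemisphere.

    Subdividing each icosahedron edge into ``ld`` segments gives
    V + E*(ld-1) + F*(ld-1)*(ld-2)/2 vertices with V=12, E=30, F=20, which
    simplifies to 10*ld^2 + 2.  ld = 32 over two hemispheres yields 20,484.
    """
    if linear_divisions < 1:
        raise ValueError("linear_divisions must be >= 1")
    if n_hemispheres < 1:
        raise ValueError("n_hemispheres must be >= 1")
    return n_hemispheres * (10 * linear_divisions**2 + 2)
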