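"""Item-level GLM beta estimation and univariate contrast machinery.

The GLM models one HRF-convolved boxcar regressor per stimulus item (the
stimulus-consideration window) plus an intercept; the between-trial fixation
period is the unmodeled baseline.  Columns whose ``trial_type`` is listed in
``drop_regressors`` (by default the response period) are modeled and then
discarded from the returned betas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

import nibabel as nib

__all__ = [
    "ItemBetaMaps",
    "ContrastZMap",
    "FirstLevelFit",
    "double_gamma_hrf",
    "build_design",
    "fit_item_glm",
    "contrast_zmap",
    "zmap_from_betas",
    "robust_range_mask",
    "RankDeficientDesignError",
]

log = logging.getLogger(__name__)

#: clamp for z values produced from infinite / overflowing t statistics
Z_CLAMP = 40.0


class RankDeficientDesignError(ValueError):
    """GLM design matrix is rank deficient."""


@dataclass
class ItemBetaMaps:
    """Per-item activity patterns for one subject and run.

    ``betas`` is an ``n_items x n_voxels`` matrix over the in-mask voxels
    listed in ``voxel_coords`` (``n_voxels x 3`` integer grid indices, the
    row order of ``np.argwhere(mask)``).
    """

    subject_id: str
    run_id: int
    betas: np.ndarray
    voxel_coords: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        self.item_ids = tuple(str(i) for i in self.item_ids)
        if self.betas.ndim != 2:
            raise ValueError("betas must be items x voxels")
        if self.betas.shape[0] != len(self.item_ids):
            raise ValueError("item count does not match item_ids")
        if self.betas.shape[1] != self.voxel_coords.shape[0]:
            raise ValueError("voxel count does not match voxel_coords")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas must be finite")

    @property
    def n_items(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def mask_array(self) -> np.ndarray:
        mask = np.zeros(self.grid_shape, dtype=bool)
        mask[tuple(self.voxel_coords.T)] = True
        return mask

    def to_nifti_dir(self, out_dir: str | Path) -> list[Path]:
        """Write one volume per item: sub-<id>_run-<r>_item-<item>.nii.gz."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, item in enumerate(self.item_ids):
            vol = np.zeros(self.grid_shape, dtype=np.float32)
            vol[tuple(self.voxel_coords.T)] = self.betas[i]
            img = nib.Nifti1Image(vol, self.affine)
            p = out_dir / f"sub-{self.subject_id}_run-{self.run_id}_item-{item}.nii.gz"
            nib.save(img, p)
            paths.append(p)
        return paths

    @classmethod
    def from_nifti_dir(
        cls, beta_dir: str | Path, subject_id: str, run_id: int, mask: np.ndarray,
        affine: np.ndarray | None = None,
    ) -> "ItemBetaMaps":
        beta_dir = Path(beta_dir)
        pattern = f"sub-{subject_id}_run-{run_id}_item-*.nii*"
        paths = sorted(beta_dir.glob(pattern))
        if not paths:
            raise FileNotFoundError(f"no beta volumes matching {pattern} in {beta_dir}")
        coords = np.argwhere(mask)
        betas, item_ids = [], []
        for p in paths:
            img = nib.load(p)
            vol = np.asarray(img.dataobj, dtype=float)
            betas.append(vol[tuple(coords.T)])
            item_ids.append(p.name.split("item-")[1].split(".nii")[0])
            if affine is None:
                affine = img.affine
        return cls(
            subject_id=subject_id, run_id=run_id, betas=np.array(betas),
            voxel_coords=coords, grid_shape=mask.shape, affine=affine,
            item_ids=tuple(item_ids),
        )


@dataclass
class ContrastZMap:
    """Per-in-mask-voxel contrast z values, aligned with an ItemBetaMaps voxel list."""

    z: np.ndarray
    contrast_name: str
    voxel_coords: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z values must be finite")

    def to_nifti(self, path: str | Path) -> None:
        vol = np.zeros(self.grid_shape, dtype=np.float32)
        vol[tuple(self.voxel_coords.T)] = self.z
        nib.save(nib.Nifti1Image(vol, self.affine), path)


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF: 6 s peak, 16 s undershoot, 1/6 ratio; peak 1."""
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, a=6.0) - stats.gamma.pdf(t, a=16.0) / 6.0
    h = np.where(t < 0, 0.0, h)
    peak = h.max()
    return h / peak if peak > 0 else h


def build_design(
    timing: pd.DataFrame,
    n_scans: int,
    tr: float = 2.5,
    oversample: int = 50,
    drop_regressors: Sequence[str] = ("response",),
) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
    """Per-condition HRF-convolved boxcar regressors sampled at scan times.

    ``timing`` is a BIDS-style events table with ``onset``, ``duration`` and
    ``trial_type`` columns (seconds).  Returns ``(X_items, item_ids,
    X_nuisance, nuisance_ids)`` where nuisance columns are the modeled-then-
    discarded conditions listed in ``drop_regressors``.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    required = {"onset", "duration", "trial_type"}
    if not required <= set(timing.columns):
        raise ValueError(f"timing table needs columns {sorted(required)}")
    dt = tr / oversample
    t_hi = np.arange(0, n_scans * tr + dt, dt)
    hrf = double_gamma_hrf(np.arange(0, 32 + dt, dt))
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)

    conditions = list(dict.fromkeys(timing["trial_type"].astype(str)))
    cols: dict[str, np.ndarray] = {}
    for cond in conditions:
        rows = timing[timing["trial_type"].astype(str) == cond]
        boxcar = np.zeros_like(t_hi)
        for onset, dur in zip(rows["onset"], rows["duration"]):
            boxcar[(t_hi >= onset) & (t_hi < onset + dur)] = 1.0
        reg = np.convolve(boxcar, hrf)[: t_hi.size] * dt
        cols[cond] = reg[scan_idx]

    item_ids = [c for c in conditions if c not in drop_regressors]
    nuis_ids = [c for c in conditions if c in drop_regressors]
    X_items = np.column_stack([cols[c] for c in item_ids]) if item_ids else np.empty((n_scans, 0))
    X_nuis = np.column_stack([cols[c] for c in nuis_ids]) if nuis_ids else np.empty((n_scans, 0))
    return X_items, item_ids, X_nuis, nuis_ids


@dataclass
class FirstLevelFit:
    """OLS fit bundle: betas plus what contrast machinery needs."""

    betas: ItemBetaMaps
    residual_variance: np.ndarray
    dof: int
    design: np.ndarray        # full design incl. nuisance + intercept
    item_columns: np.ndarray  # indices of the item regressors within design


def fit_item_glm(
    series: np.ndarray,
    timing: pd.DataFrame,
    tr: float = 2.5,
    mask: np.ndarray | None = None,
    subject_id: str = "sub",
    run_id: int = 1,
    affine: np.ndarray | None = None,
    drop_regressors: Sequence[str] = ("response",),
) -> FirstLevelFit:
    """Ordinary least squares item-level GLM on a 4-D series.

    ``series`` is ``(nx, ny, nz, T)``.  One regressor per trial_type plus an
    intercept; fixation is the implicit baseline.  Returns betas for the item
    regressors only, per-voxel residual variance and the residual dof.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must be 4-D (x, y, z, time)")
    n_scans = series.shape[3]
    if mask is None:
        mask = np.ones(series.shape[:3], dtype=bool)
    if affine is None:
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
    coords = np.argwhere(mask)
    Y = series[tuple(coords.T)].T  # T x V

    X_items, item_ids, X_nuis, _ = build_design(
        timing, n_scans, tr, drop_regressors=drop_regressors
    )
    X = np.column_stack([X_items, X_nuis, np.ones(n_scans)])
    n_reg = X.shape[1]
    if n_scans < n_reg + 2:
        raise ValueError("need at least 2 more time points than regressors")
    rank = np.linalg.matrix_rank(X)
    if rank < n_reg:
        # identify (approximately) collinear columns by pivoted QR
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [
            (item_ids + ["<nuisance/intercept>"] * (n_reg - len(item_ids)))[i]
            for i in np.flatnonzero(diag < 1e-10 * diag.max())
        ]
        raise RankDeficientDesignError(
            f"design matrix rank {rank} < {n_reg}; collinear columns: {bad}"
        )

    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = n_scans - rank
    resid_var = (resid**2).sum(axis=0) / dof

    item_cols = np.arange(len(item_ids))
    betas = ItemBetaMaps(
        subject_id=subject_id, run_id=run_id, betas=coef[item_cols],
        voxel_coords=coords, grid_shape=mask.shape, affine=affine,
        item_ids=tuple(item_ids),
    )
    return FirstLevelFit(
        betas=betas, residual_variance=resid_var, dof=dof,
        design=X, item_columns=item_cols,
    )


def _t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Convert t to z by probability matching, stable in both tails."""
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    # survival-function route keeps precision for large |t|
    with np.errstate(divide="ignore"):
        z[pos] = -ndtri(stats.t.sf(t[pos], dof))
        z[~pos] = ndtri(stats.t.cdf(t[~pos], dof))
    return np.clip(z, -Z_CLAMP, Z_CLAMP)


def contrast_zmap(
    fit: FirstLevelFit,
    contrast_weights: np.ndarray | None = None,
    contrast_name: str = "images_gt_baseline",
) -> ContrastZMap:
    """Per-voxel contrast z map from an OLS fit.

    Default weights are the mean over item regressors (stimulus images
    versus the implicit fixation baseline).  t is converted to z via the
    normal quantile of the t cumulative probability at the fit's dof.
    """
    n_items = len(fit.item_columns)
    if contrast_weights is None:
        contrast_weights = np.full(n_items, 1.0 / n_items)
    contrast_weights = np.asarray(contrast_weights, dtype=float)
    if contrast_weights.shape != (n_items,):
        raise ValueError("contrast weights length must equal the item regressor count")

    c = np.zeros(fit.design.shape[1])
    c[fit.item_columns] = contrast_weights
    xtx_inv = np.linalg.pinv(fit.design.T @ fit.design)
    c_var_unit = float(c @ xtx_inv @ c)

    effect = contrast_weights @ fit.betas.betas
    se = np.sqrt(fit.residual_variance * c_var_unit)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    degenerate = (se == 0) & (effect != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} voxel(s) with zero residual variance and "
            f"nonzero contrast; z clamped to +/-{Z_CLAMP}",
            RuntimeWarning,
        )
        t[degenerate] = np.sign(effect[degenerate]) * np.inf
    t[(se == 0) & (effect == 0)] = 0.0
    z = _t_to_z(t, fit.dof)
    return ContrastZMap(
        z=z, contrast_name=contrast_name, voxel_coords=fit.betas.voxel_coords,
        grid_shape=fit.betas.grid_shape, affine=fit.betas.affine,
    )


def zmap_from_betas(
    betas: ItemBetaMaps, contrast_name: str = "images_gt_baseline"
) -> ContrastZMap:
    """Beta-level contrast z map: mean item beta against a global noise scale.

    Used when only the item beta maps are available (no time series).  The
    GLM contrast's standard error comes from scan-noise residual variance,
    which is the same for informative and merely-active voxels; the
    across-item beta variance is *not* a noise estimate (it contains the item
    pattern itself).  We therefore scale the per-voxel mean beta by a robust
    global noise estimate (1.4826 * MAD of all betas, background-dominated):
    z = mean(beta) * sqrt(n_items) / sigma_hat.
    """
    b = betas.betas
    n = b.shape[0]
    mean = b.mean(axis=0)
    med = np.median(b)
    sigma = 1.4826 * np.median(np.abs(b - med))
    if sigma == 0:
        warnings.warn("degenerate beta distribution (MAD = 0); z set to 0",
                      RuntimeWarning)
        z = np.zeros_like(mean)
    else:
        z = np.clip(mean * np.sqrt(n) / sigma, -Z_CLAMP, Z_CLAMP)
    return ContrastZMap(
        z=z, contrast_name=contrast_name, voxel_coords=betas.voxel_coords,
        grid_shape=betas.grid_shape, affine=betas.affine,
    )


def robust_range_mask(zmap: ContrastZMap | np.ndarray, top_fraction: float = 0.02) -> np.ndarray:
    """Boolean mask of the top fraction of voxels by positive contrast z.

    The threshold is the ``1 - top_fraction`` quantile of the *positive* z
    values only; ties at the threshold are all included.  Returns an
    all-False mask (with a warning) when no z is positive.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    z = zmap.z if isinstance(zmap, ContrastZMap) else np.asarray(zmap, dtype=float)
    pos = z[z > 0]
    if pos.size == 0:
        warnings.warn("no positive z values; robust-range mask is empty", RuntimeWarning)
        return np.zeros_like(z, dtype=bool)
    threshold = np.quantile(pos, 1.0 - top_fraction)
    return z >= threshold
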