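"""Dissimilarity-matrix data model and the pairwise-distance operations.

Every neural score in this package is built on item-by-item dissimilarity
matrices (DMs).  A DM over ``n`` items is stored condensed: the row-major
upper triangle of the square form, a vector of ``n*(n-1)/2`` nonnegative
correlation distances.  All consumers share this ordering (the same one used
by :func:`scipy.spatial.distance.squareform`), which prevents silent pair
misalignment between, e.g., a searchlight DM and the expert model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

__all__ = [
    "DissimilarityMatrix",
    "ExpertModel",
    "DegeneratePatternError",
    "AlignmentError",
    "condensed_correlation_dm",
    "spearman_dm_similarity",
    "fisher_z",
    "FISHER_Z_CAP",
    "average_dm",
    "build_expert_model",
    "read_dm_tsv",
    "write_dm_tsv",
    "read_categories_tsv",
    "write_categories_tsv",
]

#: atanh(1 - 1e-16): the largest finite Fisher z representable before the
#: transform diverges; used by callers that need to cap rho = +/-1.
FISHER_Z_CAP = math.atanh(1.0 - 1e-16)


class DegeneratePatternError(ValueError):
    """An item's activity pattern has zero variance, so its correlation
    distance to any other item is undefined."""


class AlignmentError(ValueError):
    """Two DMs do not share the same item set / ordering."""


def _n_items_from_condensed(length: int) -> int:
    # invert m = n(n-1)/2
    n = (1 + math.isqrt(1 + 8 * length)) // 2
    if n * (n - 1) // 2 != length:
        raise ValueError(f"invalid condensed length {length}")
    return n


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric item-distance structure, stored condensed.

    Parameters
    ----------
    values
        Condensed vector of length ``n_items*(n_items-1)/2`` holding the
        row-major upper triangle; correlation-distance units in ``[0, 2]``.
    item_ids
        Ordered item identifiers; the pair ordering of ``values`` follows
        this ordering.
    """

    values: np.ndarray
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))
        if values.ndim != 1:
            raise ValueError("condensed values must be one-dimensional")
        n = len(self.item_ids)
        if n < 2:
            raise ValueError("a DM needs at least 2 items")
        if values.shape[0] != n * (n - 1) // 2:
            raise ValueError(
                f"condensed length {values.shape[0]} does not match "
                f"{n} items (expected {n * (n - 1) // 2})"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("DM entries must be finite")
        if np.any(values < 0):
            raise ValueError("DM entries must be nonnegative")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    def square(self) -> np.ndarray:
        """Square form: symmetric with exactly-zero diagonal."""
        return squareform(self.values, checks=False)

    @classmethod
    def from_square(
        cls, matrix: np.ndarray, item_ids: Sequence[str] | None = None
    ) -> "DissimilarityMatrix":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("square DM must be a square 2-D array")
        if not np.allclose(matrix, matrix.T, atol=1e-12):
            raise ValueError("square DM must be symmetric")
        if item_ids is None:
            item_ids = [f"item{i:02d}" for i in range(matrix.shape[0])]
        sym = 0.5 * (matrix + matrix.T)
        np.fill_diagonal(sym, 0.0)
        return cls(squareform(sym, checks=False), tuple(item_ids))

    def pair_index(self, id_a: str, id_b: str) -> int:
        """Condensed index of the unordered pair (id_a, id_b)."""
        i = self.item_ids.index(id_a)
        j = self.item_ids.index(id_b)
        if i == j:
            raise ValueError("diagonal pairs are not stored")
        i, j = min(i, j), max(i, j)
        n = self.n_items
        return n * i - i * (i + 1) // 2 + (j - i - 1)


@dataclass(frozen=True)
class ExpertModel:
    """An expert dissimilarity model plus its 3-way item category labels."""

    dm: DissimilarityMatrix
    categories: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cats = dict(self.categories)
        object.__setattr__(self, "categories", cats)
        if set(cats) != set(self.dm.item_ids):
            raise AlignmentError("category keys must coincide with dm.item_ids")
        labels = sorted(set(cats.values()))
        if len(labels) != 3:
            raise ValueError(f"expected exactly 3 category labels, got {labels}")
        for lab in labels:
            if sum(1 for v in cats.values() if v == lab) < 2:
                raise ValueError(f"category {lab!r} has fewer than 2 items")

    @property
    def labels(self) -> np.ndarray:
        """Category label per item, in ``dm.item_ids`` order."""
        return np.array([self.categories[i] for i in self.dm.item_ids])


def condensed_correlation_dm(
    patterns: np.ndarray, item_ids: Sequence[str] | None = None
) -> DissimilarityMatrix:
    """Pairwise correlation distances (1 - Pearson r) between item patterns.

    Parameters
    ----------
    patterns
        ``n_items x n_features`` real matrix; one activity pattern per row.
    item_ids
        Optional item identifiers (defaults to ``item00, item01, ...``).

    Raises
    ------
    DegeneratePatternError
        If any item row has zero variance (names the offending item).
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2:
        raise ValueError("patterns must be 2-D (items x features)")
    n, p = patterns.shape
    if n < 3:
        raise ValueError("need at least 3 items")
    if p < 2:
        raise ValueError("need at least 2 features")
    if item_ids is None:
        item_ids = [f"item{i:02d}" for i in range(n)]
    sd = patterns.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(str(item_ids[i]) for i in bad)
        raise DegeneratePatternError(f"zero-variance pattern for item(s): {names}")
    d = pdist(patterns, metric="correlation")
    # numerical fuzz can place perfect correlations at -1e-16
    return DissimilarityMatrix(np.clip(d, 0.0, 2.0), tuple(item_ids))


def spearman_dm_similarity(
    dm_a: DissimilarityMatrix, dm_b: DissimilarityMatrix
) -> float:
    """Spearman rank correlation between two condensed DMs (average-rank ties)."""
    if dm_a.item_ids != dm_b.item_ids:
        raise AlignmentError(
            "DMs must share the same item set and ordering: "
            f"{dm_a.item_ids[:3]}... vs {dm_b.item_ids[:3]}..."
        )
    rho = spearmanr(dm_a.values, dm_b.values).statistic
    return float(rho)


def fisher_z(r: float) -> float:
    """Variance-stabilizing Fisher transform z = atanh(r); requires |r| < 1."""
    r = float(r)
    if not abs(r) < 1:
        raise ValueError(f"fisher_z requires |r| < 1, got {r}")
    return math.atanh(r)


def average_dm(dms: Sequence[DissimilarityMatrix]) -> DissimilarityMatrix:
    """Entrywise arithmetic mean of DMs sharing one item ordering."""
    if len(dms) == 0:
        raise ValueError("cannot average an empty list of DMs")
    ids = dms[0].item_ids
    for dm in dms[1:]:
        if dm.item_ids != ids:
            raise AlignmentError("all DMs must share the same item ordering")
    return DissimilarityMatrix(
        np.mean([dm.values for dm in dms], axis=0), ids
    )


_DEFAULT_CATEGORY_NAMES = ("cantilever", "truss", "vertical_load")


def build_expert_model(
    n_items: int = 24,
    category_sizes: Sequence[int] = (8, 8, 8),
    within_d: float = 0.4,
    between_d: float = 1.2,
    jitter_sd: float = 0.05,
    seed: int = 0,
    category_names: Sequence[str] = _DEFAULT_CATEGORY_NAMES,
) -> ExpertModel:
    """Synthetic stand-in for an expert's complete pairwise-distance ratings.

    Pair distance is ``within_d`` for same-category pairs and ``between_d``
    otherwise, plus seeded symmetric jitter truncated at +/-3 sd so the
    within/between ordering is always preserved.

    Raises
    ------
    ValueError
        If ``jitter_sd`` is large enough (3 sd exceeding half the
        between-within gap) that jitter could invert the ordering.
    """
    category_sizes = tuple(int(s) for s in category_sizes)
    if len(category_sizes) != 3:
        raise ValueError("exactly 3 categories are expected")
    if sum(category_sizes) != n_items:
        raise ValueError("category_sizes must sum to n_items")
    if not (0 <= within_d < between_d):
        raise ValueError("require 0 <= within_d < between_d")
    gap = between_d - within_d
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be nonnegative")
    if jitter_sd > 0 and 3.0 * jitter_sd >= gap / 2.0:
        raise ValueError(
            f"jitter_sd={jitter_sd} can invert the within/between ordering "
            f"(need 3*jitter_sd < (between_d - within_d)/2 = {gap / 2})"
        )

    item_ids = tuple(f"item{i:02d}" for i in range(n_items))
    labels: list[str] = []
    for name, size in zip(category_names, category_sizes):
        labels.extend([name] * size)
    label_arr = np.array(labels)

    rng = np.random.default_rng(seed)
    same = label_arr[:, None] == label_arr[None, :]
    base = np.where(same, within_d, between_d).astype(float)
    if jitter_sd > 0:
        jit = np.clip(
            rng.normal(0.0, jitter_sd, size=base.shape),
            -3.0 * jitter_sd,
            3.0 * jitter_sd,
        )
        jit = 0.5 * (jit + jit.T)
        base = base + jit
    np.fill_diagonal(base, 0.0)
    dm = DissimilarityMatrix.from_square(base, item_ids)
    return ExpertModel(dm=dm, categories=dict(zip(item_ids, labels)))


# ---------------------------------------------------------------------------
# TSV persistence


def write_dm_tsv(dm: DissimilarityMatrix, path: str | Path) -> None:
    """Write the square form with item_ids as header row and index column."""
    df = pd.DataFrame(dm.square(), index=dm.item_ids, columns=dm.item_ids)
    df.to_csv(path, sep="\t", index_label="item_id")


def read_dm_tsv(path: str | Path) -> DissimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise AlignmentError(f"row/column item ids disagree in {path}")
    return DissimilarityMatrix.from_square(df.to_numpy(), tuple(df.columns))


def write_categories_tsv(categories: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"item_id": list(categories), "category": list(categories.values())}
    ).to_csv(path, sep="\t", index=False)


def read_categories_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"item_id", "category"} <= set(df.columns):
        raise ValueError(f"{path} must have item_id and category columns")
    return dict(zip(df["item_id"], df["category"]))


def read_expert_model(dm_path: str | Path, categories_path: str | Path) -> ExpertModel:
    """Load an expert model from its DM TSV and category TSV."""
    return ExpertModel(
        dm=read_dm_tsv(dm_path), categories=read_categories_tsv(categories_path)
    )
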