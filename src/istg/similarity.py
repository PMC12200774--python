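"""Pairwise image distances and the similarity index over a cohort.

The distance between two scalar maps (FA or MD) on a common, rigidly
pre-aligned grid is the Euclidean norm of their voxelwise difference.  The
FA and MD distance matrices are min-max normalized to (0, 1] over the
pairs, and the similarity of a pair is

    s(A, B) = 1 / d~_FA(A, B) + 1 / d~_MD(A, B)

so the most similar pairs carry the heaviest edges of the similarity graph
fed to community detection.  A small floor (1e-6) on normalized distances
keeps s finite for the closest pair while preserving the similarity
ranking.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .volumes import Mask, ScalarVolume

__all__ = [
    "EPS_DISTANCE",
    "DistanceMatrix",
    "SimilarityGraph",
    "pairwise_scalar_distance",
    "normalize_distances",
    "similarity_index",
]

#: Floor applied to normalized distances so reciprocal weights stay finite.
EPS_DISTANCE = 1e-6


def _check_square(ids: Sequence[str], values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    n = len(ids)
    if values.shape != (n, n):
        raise ValueError(f"{what} must be {n}x{n}, got {values.shape}")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError(f"{what} must be symmetric")
    if np.any(np.diag(values) != 0):
        raise ValueError(f"{what} must have a zero diagonal")
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise ValueError(f"{what} must be finite and nonnegative")
    return values


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with a zero diagonal."""

    ids: list
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = _check_square(self.ids, self.values, "distance matrix")
        if self.normalized:
            off = self.values[~np.eye(len(self.ids), dtype=bool)]
            if off.size and (off.min() < EPS_DISTANCE - 1e-15 or off.max() > 1 + 1e-12):
                raise ValueError("normalized distances must lie in [eps, 1]")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, normalized: bool = False) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float), normalized=normalized)


@dataclasses.dataclass
class SimilarityGraph:
    """Fully-connected weighted graph of pairwise image similarity."""

    ids: list
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.weights = _check_square(self.ids, self.weights, "similarity weights")
        off = self.weights[~np.eye(len(self.ids), dtype=bool)]
        if off.size and off.min() <= 0:
            raise ValueError("off-diagonal similarity weights must be positive")

    @property
    def total_weight(self) -> float:
        """Sum of edge weights (each undirected edge counted once)."""
        return float(np.triu(self.weights, 1).sum())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.weights, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityGraph":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))


def pairwise_scalar_distance(
    maps: Sequence[ScalarVolume],
    ids: Sequence | None = None,
    mask: Mask | None = None,
) -> DistanceMatrix:
    """Euclidean pairwise distance between scalar maps on a common grid.

    Entry (A, B) is ``sqrt(sum_v (A_v - B_v)^2)`` over all voxels (or the
    mask when given).  Maps must already live on one grid — in the pipeline
    they derive from scans rigidly aligned to the initial target.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps for pairwise distances")
    ref = maps[0]
    for m in maps[1:]:
        if m.shape != ref.shape or not np.allclose(m.affine, ref.affine, atol=1e-6):
            raise ValueError("all maps must share shape and affine")
    if ids is None:
        ids = [str(i) for i in range(len(maps))]
    if len(ids) != len(maps):
        raise ValueError("ids must match maps")
    if mask is not None:
        if mask.shape != ref.shape:
            raise ValueError("mask shape does not match the maps")
        data = np.stack([m.values[mask.values] for m in maps])
    else:
        data = np.stack([m.values.ravel() for m in maps])
    diff2 = (
        np.square(data).sum(axis=1)[:, None]
        + np.square(data).sum(axis=1)[None, :]
        - 2.0 * data @ data.T
    )
    values = np.sqrt(np.maximum(diff2, 0.0))
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)
    return DistanceMatrix(ids, values, normalized=False)


def normalize_distances(d: DistanceMatrix, mode: str = "minmax") -> DistanceMatrix:
    """Normalize the off-diagonal distances into (0, 1].

    ``mode="minmax"`` rescales the off-diagonal entries to
    ``(x - min) / (max - min)`` and floors them at :data:`EPS_DISTANCE`;
    the closest pair then sits at the floor and its reciprocal similarity
    weight is enormous (1/eps), which concentrates the similarity graph's
    mass on single pairs.  ``mode="max"`` divides by the maximum instead,
    which also maps into (0, 1] but keeps the closest pair's weight at the
    natural dynamic range of the distances — this is the variant the
    pipeline uses, since reciprocal weights stay finite without an
    arbitrary floor.  If all pairs are equidistant the off-diagonal is set
    to 1 with a warning.
    """
    if d.normalized:
        raise ValueError("distance matrix is already normalized")
    n = len(d.ids)
    if n < 2:
        raise ValueError("need at least 2 scans")
    off = ~np.eye(n, dtype=bool)
    vals = d.values[off]
    dmin, dmax = vals.min(), vals.max()
    out = np.zeros_like(d.values)
    if dmax <= 0 or (mode == "minmax" and dmax - dmin <= 0):
        warnings.warn("all pairs equidistant; normalized distances set to 1")
        out[off] = 1.0
    elif mode == "minmax":
        out[off] = np.maximum((d.values[off] - dmin) / (dmax - dmin), EPS_DISTANCE)
    elif mode == "max":
        out[off] = np.maximum(d.values[off] / dmax, EPS_DISTANCE)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return DistanceMatrix(d.ids, out, normalized=True)


def similarity_index(
    d_fa_norm: DistanceMatrix, d_md_norm: DistanceMatrix
) -> SimilarityGraph:
    """Similarity weights ``1/d~_FA + 1/d~_MD`` from normalized distances."""
    if not (d_fa_norm.normalized and d_md_norm.normalized):
        raise ValueError("both distance matrices must be normalized")
    if d_fa_norm.ids != d_md_norm.ids:
        raise ValueError("distance matrices refer to different scan ids")
    n = len(d_fa_norm.ids)
    off = ~np.eye(n, dtype=bool)
    weights = np.zeros((n, n))
    weights[off] = 1.0 / d_fa_norm.values[off] + 1.0 / d_md_norm.values[off]
    return SimilarityGraph(d_fa_norm.ids, weights)
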