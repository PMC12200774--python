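"""Stratifying a cohort into homogeneous subgroups.

Three strategies: Louvain community detection on the image-similarity
graph (greedy weighted-modularity maximization in two alternating phases),
binning by chronological age, and the trivial single-group baseline.

The Louvain implementation follows the classic two-phase scheme: phase one
greedily reassigns nodes to neighboring communities while the modularity

    Q = sum_c [ Sigma_in,c / (2m) - gamma * (Sigma_tot,c / (2m))^2 ]

improves, phase two aggregates communities into super-nodes, and the
phases repeat until the overall modularity gain drops below ``gain_tol``
(default 1e-9).  Node visit order is shuffled by the seed; among equal-gain
moves a node keeps its current community, so a given seed always yields
the same partition.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .similarity import SimilarityGraph

__all__ = [
    "Partition",
    "louvain_partition",
    "modularity",
    "partition_by_age",
    "single_partition",
]


@dataclasses.dataclass
class Partition:
    """Assignment of scan ids to 0-based, contiguous subgroup indices."""

    ids: list
    labels: dict
    method: str
    modularity: float | None = None
    resolution: float = 1.0

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        missing = [i for i in self.ids if i not in self.labels]
        if missing:
            raise ValueError(f"unlabeled ids: {missing}")
        used = sorted({self.labels[i] for i in self.ids})
        if used != list(range(len(used))):
            raise ValueError(f"subgroup indices must be contiguous from 0, got {used}")

    @property
    def n_groups(self) -> int:
        return len({self.labels[i] for i in self.ids})

    def groups(self) -> list[list]:
        out: list[list] = [[] for _ in range(self.n_groups)]
        for i in self.ids:
            out[self.labels[i]].append(i)
        return out

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[i] for i in self.ids], dtype=int)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"id": self.ids, "label": [self.labels[i] for i in self.ids]}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, method: str = "file") -> "Partition":
        df = pd.read_csv(path)
        return cls(list(df["id"]), dict(zip(df["id"], df["label"].astype(int))), method)


def _compact_labels(raw: Sequence[int], ids: Sequence) -> dict:
    """Relabel to contiguous 0-based indices in order of first appearance."""
    mapping: dict[int, int] = {}
    labels = {}
    for i, lab in zip(ids, raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        labels[i] = mapping[lab]
    return labels


def modularity(g: SimilarityGraph, partition: Partition, resolution: float = 1.0) -> float:
    """Weighted Newman-Girvan modularity of a partition at resolution gamma."""
    missing = [i for i in g.ids if i not in partition.labels]
    if missing:
        raise ValueError(f"partition does not label nodes: {missing}")
    labels = np.array([partition.labels[i] for i in g.ids])
    return _modularity_arrays(g.weights, labels, resolution)


def _modularity_arrays(A: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    two_m = A.sum()
    if two_m <= 0:
        raise ValueError("graph has no edge weight")
    k = A.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        in_c = labels == c
        q += A[np.ix_(in_c, in_c)].sum() / two_m - gamma * (k[in_c].sum() / two_m) ** 2
    return float(q)


def _louvain_phase1(
    A: np.ndarray, gamma: float, rng: np.random.Generator, gain_tol: float
) -> np.ndarray:
    """Greedy node-to-community moves; returns community labels."""
    n = A.shape[0]
    two_m = A.sum()
    m = two_m / 2.0
    k = A.sum(axis=1)
    comm = np.arange(n)
    sigma_tot = k.copy()
    order = rng.permutation(n)
    improved = True
    while improved:
        improved = False
        for i in order:
            c_old = comm[i]
            sigma_tot[c_old] -= k[i]
            # weight from i to each community (self-loop excluded: it moves
            # with the node and cancels in the gain comparison)
            w_i = A[i].copy()
            w_i[i] = 0.0
            k_i_to = np.bincount(comm, weights=w_i, minlength=n)
            gains = (k_i_to - gamma * k[i] * sigma_tot / two_m) / m
            c_best = c_old
            g_best = gains[c_old]
            candidates = np.flatnonzero(w_i > 0)
            for c in np.unique(comm[candidates]):
                if gains[c] > g_best + 1e-15:
                    g_best = gains[c]
                    c_best = c
            if c_best != c_old and (g_best - gains[c_old]) > gain_tol:
                comm[i] = c_best
                improved = True
            sigma_tot[comm[i]] += k[i]
    return comm


def _aggregate(A: np.ndarray, comm: np.ndarray) -> np.ndarray:
    uniq, inv = np.unique(comm, return_inverse=True)
    nc = len(uniq)
    M = np.zeros((nc, A.shape[0]))
    M[inv, np.arange(A.shape[0])] = 1.0
    return M @ A @ M.T


def louvain_partition(
    g: SimilarityGraph,
    resolution: float = 1.0,
    gain_tol: float = 1e-9,
    seed: int = 0,
) -> Partition:
    """Louvain community detection on the similarity graph."""
    n = len(g.ids)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    A = g.weights.astype(float).copy()
    rng = np.random.default_rng(seed)

    node_labels = np.arange(n)  # community of each original node
    q_prev = _modularity_arrays(g.weights, node_labels, resolution)
    while True:
        comm = _louvain_phase1(A, resolution, rng, gain_tol)
        uniq, inv = np.unique(comm, return_inverse=True)
        node_labels = inv[node_labels]
        q_new = _modularity_arrays(g.weights, node_labels, resolution)
        if q_new - q_prev < gain_tol or len(uniq) == A.shape[0]:
            break
        q_prev = q_new
        A = _aggregate(A, comm)

    labels = _compact_labels(node_labels, g.ids)
    part = Partition(g.ids, labels, method="louvain", resolution=resolution)
    part.modularity = modularity(g, part, resolution)
    return part


def partition_by_age(
    ids: Sequence,
    ages: Mapping,
    cutoffs: Sequence[float] = (3.0, 6.0),
) -> Partition:
    """Half-open age binning: [0, c1), [c1, c2), ..., [ck, inf)."""
    ids = list(ids)
    missing = [i for i in ids if i not in ages or ages[i] is None or np.isnan(ages[i])]
    if missing:
        raise ValueError(f"missing age for ids: {missing}")
    cutoffs = sorted(cutoffs)
    raw = [int(np.digitize(float(ages[i]), cutoffs, right=False)) for i in ids]
    n_bins_used = len(set(raw))
    if n_bins_used < len(cutoffs) + 1:
        warnings.warn(
            f"{len(cutoffs) + 1 - n_bins_used} empty age bin(s) dropped; "
            "subgroup indices re-compacted"
        )
    # compact while preserving age ordering of the bins
    order = {b: j for j, b in enumerate(sorted(set(raw)))}
    labels = {i: order[b] for i, b in zip(ids, raw)}
    return Partition(ids, labels, method="age")


def single_partition(ids: Sequence) -> Partition:
    """All scans in one subgroup (the no-clustering baseline)."""
    ids = list(ids)
    if not ids:
        raise ValueError("need at least 1 id")
    return Partition(ids, {i: 0 for i in ids}, method="single")
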