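"""Canonical indexing and typed containers for connectomes, edges, and partitions.

A connectome is a symmetric ``V x V`` matrix of functional connectivity
values (e.g. z-scored Pearson correlations between atlas node time series).
All computation in this package operates on the vectorized upper triangle:
the ``E = V(V-1)/2`` off-diagonal values enumerated row-major over pairs
``(i, j)`` with ``i < j``.  That enumeration is THE canonical edge order;
every module consumes and emits it.

Node indices are 0-based internally and 1-based in all text-file I/O.
Diagonal entries (self-connections) are ignored throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConnbenchError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ConnbenchError, ValueError):
    pass


class FormatError(ConnbenchError, ValueError):
    """Malformed input file or matrix."""


class InvalidPartitionError(ConnbenchError, ValueError):
    pass


class InvalidSampleError(ConnbenchError, ValueError):
    pass


@dataclass(frozen=True)
class EdgeIndexMap:
    """Bijection between node pairs ``(i, j)``, ``i < j``, and linear edge ids.

    The linear order is row-major over the upper triangle:
    ``(0,1), (0,2), ..., (0,V-1), (1,2), ...``.
    """

    n_nodes: int
    row: np.ndarray = field(repr=False)  # node i of each edge
    col: np.ndarray = field(repr=False)  # node j of each edge

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def linear(self, i: int, j: int) -> int:
        """Linear index of the edge between nodes ``i`` and ``j`` (0-based)."""
        if i == j:
            raise InvalidArgumentError("self-connections have no edge index")
        if i > j:
            i, j = j, i
        if not (0 <= i < j < self.n_nodes):
            raise InvalidArgumentError(f"node pair ({i}, {j}) out of range")
        v = self.n_nodes
        # edges before row i, plus offset within row i
        return i * (2 * v - i - 1) // 2 + (j - i - 1)

    def pair(self, e: int) -> tuple[int, int]:
        """Node pair of linear edge id ``e``."""
        if not (0 <= e < self.n_edges):
            raise InvalidArgumentError(f"edge index {e} out of range")
        return int(self.row[e]), int(self.col[e])


def build_edge_index(n_nodes: int) -> EdgeIndexMap:
    """Build the canonical upper-triangle edge index for ``n_nodes`` nodes."""
    if not isinstance(n_nodes, (int, np.integer)) or n_nodes < 1:
        raise InvalidArgumentError(f"n_nodes must be a positive integer, got {n_nodes!r}")
    row, col = np.triu_indices(int(n_nodes), k=1)
    return EdgeIndexMap(n_nodes=int(n_nodes), row=row.astype(np.int64), col=col.astype(np.int64))


@dataclass
class EdgeVector:
    """Values over all edges, in canonical order, tied to an :class:`EdgeIndexMap`."""

    values: np.ndarray
    index: EdgeIndexMap

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.index.n_edges,):
            raise InvalidArgumentError(
                f"edge vector length {self.values.shape} does not match "
                f"n_edges={self.index.n_edges}"
            )

    def __len__(self) -> int:
        return self.index.n_edges


def vectorize_upper(matrix: np.ndarray, index: EdgeIndexMap, atol: float = 1e-8) -> EdgeVector:
    """Vectorize the upper triangle of a symmetric matrix into canonical edge order.

    The matrix must be symmetric within ``atol``; the diagonal is ignored.
    """
    matrix = np.asarray(matrix, dtype=float)
    v = index.n_nodes
    if matrix.shape != (v, v):
        raise FormatError(f"expected a {v}x{v} matrix, got shape {matrix.shape}")
    asym = np.abs(matrix - matrix.T)
    if asym.size and asym.max() > atol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise FormatError(
            f"matrix is not symmetric: |M[{i},{j}] - M[{j},{i}]| = {asym[i, j]:.3g} > {atol:g}"
        )
    return EdgeVector(matrix[index.row, index.col], index)


def devectorize_upper(edges: EdgeVector, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: rebuild the symmetric matrix.

    The diagonal (undefined for correlation connectomes) is filled with
    ``diagonal``.
    """
    idx = edges.index
    mat = np.full((idx.n_nodes, idx.n_nodes), float(diagonal))
    mat[idx.row, idx.col] = edges.values
    mat[idx.col, idx.row] = edges.values
    return mat


@dataclass
class Partition:
    """Node-to-community map inducing an edge-to-network-pair map.

    ``K`` communities induce ``K(K+1)/2`` unordered community pairs
    ("network pairs"); within-community pairs ``(k, k)`` are distinct from
    between-community pairs ``(k, l)``, ``k != l``.
    """

    node_community: np.ndarray  # integer community code per node, 0-based
    labels: tuple[str, ...]  # community code -> original label

    def __post_init__(self) -> None:
        self.node_community = np.asarray(self.node_community, dtype=np.int64)
        if self.node_community.ndim != 1:
            raise InvalidPartitionError("node_community must be one label per node")
        k = len(self.labels)
        if self.node_community.size and not (
            0 <= self.node_community.min() and self.node_community.max() < k
        ):
            raise InvalidPartitionError("community codes out of range of labels")

    @classmethod
    def from_labels(cls, node_labels) -> "Partition":
        """Build from one community label per node (any hashable labels)."""
        node_labels = list(node_labels)
        seen: dict = {}
        codes = []
        for lab in node_labels:
            if lab not in seen:
                seen[lab] = len(seen)
            codes.append(seen[lab])
        return cls(np.array(codes, dtype=np.int64), tuple(str(k) for k in seen))

    @property
    def n_nodes(self) -> int:
        return self.node_community.size

    @property
    def n_communities(self) -> int:
        return len(self.labels)

    @property
    def n_network_pairs(self) -> int:
        k = self.n_communities
        return k * (k + 1) // 2

    def pair_code(self, a: int, b: int) -> int:
        """Linear code of the unordered community pair ``{a, b}``.

        Enumeration is row-major over ``a <= b``, mirroring the edge order
        but including the diagonal (within-community) pairs.
        """
        if a > b:
            a, b = b, a
        k = self.n_communities
        if not (0 <= a <= b < k):
            raise InvalidPartitionError(f"community pair ({a}, {b}) out of range")
        return a * (2 * k - a + 1) // 2 + (b - a)

    def pair_members(self, code: int) -> tuple[int, int]:
        k = self.n_communities
        for a in range(k):
            n_row = k - a
            if code < n_row:
                return a, a + code
            code -= n_row
        raise InvalidPartitionError(f"network-pair code out of range")

    def pair_label(self, code: int) -> str:
        a, b = self.pair_members(code)
        return f"{self.labels[a]}-{self.labels[b]}"

    def is_within_pair(self, code: int) -> bool:
        a, b = self.pair_members(code)
        return a == b


def assign_network_pairs(partition: Partition, index: EdgeIndexMap) -> np.ndarray:
    """Map each edge to the linear code of its unordered community pair.

    Returns an int64 array of length ``n_edges`` with values in
    ``[0, K(K+1)/2)``.
    """
    if partition.n_nodes != index.n_nodes:
        raise InvalidPartitionError(
            f"partition covers {partition.n_nodes} nodes but index has {index.n_nodes}"
        )
    comm = partition.node_community
    a = comm[index.row]
    b = comm[index.col]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    k = partition.n_communities
    return lo * (2 * k - lo + 1) // 2 + (hi - lo)


@dataclass
class PairedSample:
    """Per-subject connectomes under two conditions (e.g. task and rest).

    ``condition_a`` and ``condition_b`` are ``(n_subjects, n_edges)`` arrays
    sharing one :class:`EdgeIndexMap`.  ``null_run_b`` optionally carries a
    second rest run per subject, used to build fake (null) task contrasts.
    """

    condition_a: np.ndarray
    condition_b: np.ndarray
    index: EdgeIndexMap
    null_run_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.condition_a = np.atleast_2d(np.asarray(self.condition_a, dtype=float))
        self.condition_b = np.atleast_2d(np.asarray(self.condition_b, dtype=float))
        if self.condition_a.shape != self.condition_b.shape:
            raise InvalidSampleError(
                f"condition shapes differ: {self.condition_a.shape} vs {self.condition_b.shape}"
            )
        if self.condition_a.shape[1] != self.index.n_edges:
            raise InvalidSampleError(
                f"samples have {self.condition_a.shape[1]} edges, index expects "
                f"{self.index.n_edges}"
            )
        if self.null_run_b is not None:
            self.null_run_b = np.atleast_2d(np.asarray(self.null_run_b, dtype=float))
            if self.null_run_b.shape != self.condition_b.shape:
                raise InvalidSampleError("second null run shape mismatch")

    @property
    def n_subjects(self) -> int:
        return self.condition_a.shape[0]

    @property
    def has_null_runs(self) -> bool:
        return self.null_run_b is not None
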