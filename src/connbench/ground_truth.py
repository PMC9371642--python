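"""Full-population ground-truth estimation and its characterization.

Benchmarking against real-data-derived truth works by designating the full
population sample as the reference: per-edge paired Cohen's d estimated on
the whole population is treated as exact, and detections in resampled
subgroups are classified by whether their direction matches the ground
truth sign.  Network-level truth pools the edgewise statistics within each
network pair using the same permutation recipe as the cNBS procedure, for
internal consistency.

Two derived variants probe robustness: a *weak* map (effect sizes shrunk by
a multiplicative factor) and a *sparse* map (effects with |d| below a
cutoff declared null, so that detections there count as false positives).

:func:`network_heterogeneity` quantifies between- versus within-network
variance of the effect map with a one-way F statistic, against two shuffle
nulls: permuting node-community memberships, and permuting edge values
separately within the within-community and between-community edge sets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (EdgeIndexMap, InvalidArgumentError, InvalidPartitionError,
                   InvalidSampleError, PairedSample, Partition,
                   assign_network_pairs)
from .graph import edge_components
from .inference import cnbs_stats, storey_qvalues
from .stats import (PermutationEngine, paired_differences, paired_t_and_d,
                    perm_t_matrix, permutation_pvalue, permutation_pvalues)

__all__ = ["GroundTruthMap", "HeterogeneityResult", "estimate_ground_truth",
           "derive_variant", "count_clusters_at_threshold",
           "network_heterogeneity"]


@dataclass
class GroundTruthMap:
    """Per-edge and per-network effect sizes, signs and significance masks.

    ``sign_edge`` is ``sign(d_edge)`` except in the sparse variant, where it
    is zeroed wherever ``|d_edge|`` falls below ``sparsity_cutoff`` (those
    elements are treated as null when classifying detections).  ``d_edge``
    is retained unchanged for bookkeeping in all variants except *weak*,
    which shrinks it.
    """

    d_edge: np.ndarray
    sign_edge: np.ndarray
    sig_edge: np.ndarray
    d_network: np.ndarray
    sign_network: np.ndarray
    sig_network: np.ndarray
    whole_brain_nonnull: bool
    variant: str = "full"
    sparsity_cutoff: float = 0.0

    @property
    def n_edges(self) -> int:
        return self.d_edge.size


def estimate_ground_truth(population: PairedSample, partition: Partition,
                          alpha: float = 0.05, storey_lambda: float = 0.5,
                          n_permutations: int = 1000,
                          seed: int = 0) -> GroundTruthMap:
    """Estimate the ground truth from the full population.

    Edge level: paired Cohen's d; significance from two-sided t p-values
    with Storey FDR at ``alpha``.  Network level: pooled (mean) d and t per
    network pair; significance from two-sided permutation p-values of the
    pooled t against sign-flip nulls, Storey-FDR corrected at ``alpha``.
    The whole brain is declared non-null iff any edge is significant.
    """
    if population.n_subjects < 3:
        raise InvalidSampleError(
            f"ground truth needs >= 3 subjects, got {population.n_subjects}"
        )
    diffs = paired_differences(population)
    stats = paired_t_and_d(diffs)
    if np.any(stats.zero_variance):
        raise InvalidSampleError("degenerate population: zero-variance edges")
    _, q = storey_qvalues(stats.p_two, storey_lambda)
    sig_edge = q <= alpha
    sign_edge = np.sign(stats.d).astype(np.int8)

    pair_map = assign_network_pairs(partition, population.index)
    n_pairs = partition.n_network_pairs
    d_network = cnbs_stats(stats.d, pair_map, n_pairs)
    t_network = cnbs_stats(stats.t, pair_map, n_pairs)
    engine = PermutationEngine(n_permutations, seed)
    perm_t = perm_t_matrix(diffs, engine)
    counts = np.bincount(pair_map, minlength=n_pairs).astype(float)
    null_T = (perm_t @ _one_hot(pair_map, n_pairs)) / counts[None, :]
    p_net = permutation_pvalues(t_network, null_T, "two")
    _, q_net = storey_qvalues(p_net, storey_lambda)
    sig_network = q_net <= alpha
    sign_network = np.sign(d_network).astype(np.int8)

    return GroundTruthMap(
        d_edge=stats.d, sign_edge=sign_edge, sig_edge=sig_edge,
        d_network=d_network, sign_network=sign_network,
        sig_network=sig_network, whole_brain_nonnull=bool(sig_edge.any()),
    )


def _one_hot(codes: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((codes.size, n))
    out[np.arange(codes.size), codes] = 1.0
    return out


def derive_variant(gt: GroundTruthMap, kind: str, param: float) -> GroundTruthMap:
    """Derive the *weak* or *sparse* ground-truth variant.

    ``weak``: multiply all effect sizes by ``param`` (< 1 weakens), signs
    preserved.  ``sparse``: zero the sign and significance of every element
    with ``|d| < param`` (those become null); d is kept for bookkeeping.
    """
    if param <= 0:
        raise InvalidArgumentError(f"variant parameter must be > 0, got {param}")
    if kind == "weak":
        return replace(gt, d_edge=gt.d_edge * param,
                       d_network=gt.d_network * param, variant="weak")
    if kind == "sparse":
        null_e = np.abs(gt.d_edge) < param
        null_n = np.abs(gt.d_network) < param
        sign_edge = np.where(null_e, 0, gt.sign_edge).astype(np.int8)
        sig_edge = gt.sig_edge & ~null_e
        sign_network = np.where(null_n, 0, gt.sign_network).astype(np.int8)
        sig_network = gt.sig_network & ~null_n
        return replace(gt, sign_edge=sign_edge, sig_edge=sig_edge,
                       sign_network=sign_network, sig_network=sig_network,
                       whole_brain_nonnull=bool(sig_edge.any()),
                       variant="sparse", sparsity_cutoff=param)
    raise InvalidArgumentError(f"unknown variant kind {kind!r}")


def count_clusters_at_threshold(d_edge: np.ndarray, cutoff: float,
                                index: EdgeIndexMap) -> tuple[int, int]:
    """Count positive and negative clusters of contiguous supra-|d| edges.

    Components are computed separately on ``d > cutoff`` and ``d < -cutoff``
    (edges connected through shared nodes form one cluster).
    """
    if cutoff <= 0:
        raise InvalidArgumentError(f"cutoff must be positive, got {cutoff}")
    d_edge = np.asarray(d_edge, dtype=float)
    n_pos = len(edge_components(d_edge > cutoff, index))
    n_neg = len(edge_components(d_edge < -cutoff, index))
    return n_pos, n_neg


@dataclass
class HeterogeneityResult:
    """One-way F of effect sizes grouped by network pair, with shuffle nulls."""

    F: float
    p_node_shuffle: float
    p_edge_shuffle: float
    n_shuffles: int


def _anova_f(values: np.ndarray, groups: np.ndarray, n_groups: int) -> float:
    """Between- over within-group mean square (one-way ANOVA F)."""
    counts = np.bincount(groups, minlength=n_groups)
    sums = np.bincount(groups, weights=values, minlength=n_groups)
    means = np.divide(sums, counts, out=np.zeros(n_groups), where=counts > 0)
    grand = values.mean()
    present = counts > 0
    k = int(present.sum())
    n = values.size
    ss_between = float(np.sum(counts[present] * (means[present] - grand) ** 2))
    ss_within = float(np.sum((values - means[groups]) ** 2))
    if k < 2 or n <= k:
        raise InvalidPartitionError("need >= 2 groups and within-group replication")
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def network_heterogeneity(d_edge: np.ndarray, partition: Partition,
                          index: EdgeIndexMap, n_shuffles: int = 1000,
                          seed: int = 0) -> HeterogeneityResult:
    """F statistic for between- vs within-network-pair variance of ``d``.

    Significance against two permutation nulls: (1) shuffling the
    node-to-community memberships and regrouping edges, and (2) shuffling
    edge values separately within the within-community and the
    between-community edge sets (preserving that coarse structure).
    """
    d_edge = np.asarray(d_edge, dtype=float)
    pair_map = assign_network_pairs(partition, index)
    n_pairs = partition.n_network_pairs
    counts = np.bincount(pair_map, minlength=n_pairs)
    if np.count_nonzero(counts) < 2 or np.any(counts[counts > 0] < 2):
        raise InvalidPartitionError(
            "heterogeneity needs >= 2 network pairs with >= 2 edges each"
        )
    f_obs = _anova_f(d_edge, pair_map, n_pairs)

    rng = np.random.default_rng(seed)
    comm = partition.node_community
    within_pair = np.array([partition.is_within_pair(k) for k in range(n_pairs)])
    is_within_edge = within_pair[pair_map]

    f_node = np.empty(n_shuffles)
    f_edge = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuffled = Partition(rng.permutation(comm), partition.labels)
        f_node[s] = _anova_f(d_edge, assign_network_pairs(shuffled, index), n_pairs)
        perm_d = d_edge.copy()
        wi = np.flatnonzero(is_within_edge)
        bi = np.flatnonzero(~is_within_edge)
        perm_d[wi] = perm_d[rng.permutation(wi)]
        perm_d[bi] = perm_d[rng.permutation(bi)]
        f_edge[s] = _anova_f(perm_d, pair_map, n_pairs)

    return HeterogeneityResult(
        F=f_obs,
        p_node_shuffle=permutation_pvalue(f_obs, f_node, "ge"),
        p_edge_shuffle=permutation_pvalue(f_obs, f_edge, "ge"),
        n_shuffles=n_shuffles,
    )
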