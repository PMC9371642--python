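"""The seven inferential procedures, spanning four levels of inference.

Level        Procedure id   Error rate   Method
-----------  -------------  -----------  ------------------------------------------
edge         ``edge-fwer``  FWER         Bonferroni on parametric one-sided t p-values
edge         ``edge-fdr``   FDR          Storey q-values on parametric p-values
cluster      ``nbs``        FWER         network-based statistic: supra-threshold
                                         components vs permutation max-size null
cluster      ``nbs-tfce``   FWER         threshold-free cluster enhancement vs
                                         permutation max-score null
network      ``cnbs-fwer``  FWER         pooled network statistics (cNBS), permutation
                                         p-values, Bonferroni across network pairs
network      ``cnbs-fdr``   FDR         cNBS with Simes (Benjamini-Hochberg step-up)
whole-brain  ``mv-cnbs``    FWER         Mahalanobis distance of the pooled-network
                                         statistic vector from its permutation null

All procedures except the whole-brain omnibus are directional: two one-sided
analyses are run per contrast (task > rest and task < rest).  By default
each tail is tested at ``alpha/2`` so that the combined familywise error of
the two directional analyses is controlled at the nominal ``alpha``; set
``alpha_tail=alpha`` for independent directional analyses at full level.

What a detection *means* differs by level: a significant edge implies an
effect at that edge; a significant cluster implies an effect for at least
one edge within it; a significant network implies an effect for the pooled
network but not for any particular edge; the whole-brain test is a signless
test of inequality of the pooled-network vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import (ConnbenchError, EdgeIndexMap, InvalidArgumentError,
                   InvalidPartitionError, Partition)
from .graph import edge_components, max_component_sizes, tfce_null_maxima, tfce_scores
from .stats import (EdgeStatResult, PermutationEngine, paired_t_and_d,
                    perm_t_matrix, permutation_pvalues)

__all__ = [
    "DetectionResult", "TFCEParams", "InferenceSettings", "PROCEDURES",
    "edge_bonferroni", "storey_qvalues", "edge_storey_fdr", "nbs_cluster",
    "tfce_transform", "nbs_tfce", "cnbs_stats", "cnbs_network", "mv_cnbs",
    "simes_stepup", "run_procedure_suite",
]

#: procedure id -> level of inference
PROCEDURES: dict[str, str] = {
    "edge-fwer": "edge",
    "edge-fdr": "edge",
    "nbs": "cluster",
    "nbs-tfce": "cluster",
    "cnbs-fwer": "network",
    "cnbs-fdr": "network",
    "mv-cnbs": "whole_brain",
}

#: procedures that control (weak- and strong-sense) FWER
FWER_PROCEDURES = ("edge-fwer", "nbs", "nbs-tfce", "cnbs-fwer", "mv-cnbs")
#: procedures that control FDR
FDR_PROCEDURES = ("edge-fdr", "cnbs-fdr")


@dataclass(frozen=True)
class TFCEParams:
    """TFCE exponents and integration steps (classical defaults)."""

    extent_exponent: float = 0.5
    height_exponent: float = 2.0
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.extent_exponent <= 0 or self.height_exponent < 0 or self.n_steps < 1:
            raise InvalidArgumentError(f"invalid TFCE parameters: {self}")


@dataclass(frozen=True)
class InferenceSettings:
    """Tunable knobs shared by the procedures.

    ``alpha_tail=None`` means ``alpha/2`` per one-sided analysis (combined
    directional FWER controlled at ``alpha``).  ``cdt`` is the NBS
    cluster-determining threshold on the one-sided t statistic; when None it
    is derived from ``cdt_p`` (one-sided p) at the sample's degrees of
    freedom.
    """

    alpha: float = 0.05
    alpha_tail: float | None = None
    cdt: float | None = None
    cdt_p: float = 0.01
    tfce: TFCEParams = field(default_factory=TFCEParams)
    storey_lambda: float = 0.5
    mv_ridge: float = 1e-6
    cnbs_p_method: str = "gaussian"

    def tail_level(self) -> float:
        if not (0 < self.alpha < 1):
            raise InvalidArgumentError(f"alpha must be in (0,1), got {self.alpha}")
        return self.alpha / 2 if self.alpha_tail is None else self.alpha_tail

    def cdt_value(self, df: int) -> float:
        if self.cdt is not None:
            if self.cdt <= 0:
                raise InvalidArgumentError(f"cdt must be positive, got {self.cdt}")
            return float(self.cdt)
        return float(sps.t.isf(self.cdt_p, df))


@dataclass
class DetectionResult:
    """Detections of one procedure on one contrast.

    ``element_ids``/``element_signs``/``element_p`` list the *detected*
    elements (edges, clusters, or network pairs) with their tail sign and
    corrected p (or q).  ``edge_signs`` maps every edge to the sign of the
    detection implicating it (0 = not implicated).  Network-level results
    additionally carry ``pair_signs`` over all network pairs; the
    whole-brain result is a signless binary detection and implicates all
    edges when significant.
    """

    procedure: str
    level: str
    alpha: float
    element_ids: list[str]
    element_signs: np.ndarray
    element_p: np.ndarray
    edge_signs: np.ndarray
    pair_signs: np.ndarray | None = None
    pair_map: np.ndarray | None = None  # edge -> network pair, network level only
    wb_detected: bool | None = None
    wb_p: float | None = None

    @property
    def n_detected(self) -> int:
        if self.level == "whole_brain":
            return int(bool(self.wb_detected))
        return len(self.element_ids)

    def implicated_mask(self) -> np.ndarray:
        if self.level == "whole_brain":
            n = self.edge_signs.size
            return np.full(n, bool(self.wb_detected))
        return self.edge_signs != 0


# ---------------------------------------------------------------------------
# edge level


def edge_bonferroni(stats: EdgeStatResult, alpha: float = 0.05,
                    alpha_tail: float | None = None) -> DetectionResult:
    """Bonferroni-corrected one-sided edge tests (FWER control)."""
    s = InferenceSettings(alpha=alpha, alpha_tail=alpha_tail)
    at = s.tail_level()
    m = stats.t.size
    thr = at / m
    pos = stats.p_pos <= thr
    neg = stats.p_neg <= thr
    return _edge_level_result("edge-fwer", alpha, pos, neg,
                              np.minimum(stats.p_pos * m, 1.0),
                              np.minimum(stats.p_neg * m, 1.0))


def storey_qvalues(pvals: np.ndarray, lam: float = 0.5) -> tuple[float, np.ndarray]:
    """Storey q-values with a fixed-lambda pi0 estimate.

    ``pi0 = min(1, #{p > lam} / (m (1 - lam)))``;
    ``q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j)`` (step-up).
    """
    if not (0 < lam < 1):
        raise InvalidArgumentError(f"lambda must be in (0,1), got {lam}")
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise InvalidArgumentError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgumentError("p-values must be in [0,1]")
    m = p.size
    # floor at 1/m guards the degenerate all-p-below-lambda case, where the
    # raw estimate collapses to 0 and every q-value with it
    pi0 = min(1.0, max(np.count_nonzero(p > lam) / (m * (1.0 - lam)), 1.0 / m))
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    np.clip(q_sorted, 0.0, 1.0, out=q_sorted)
    q = np.empty(m)
    q[order] = q_sorted
    return pi0, q


def edge_storey_fdr(stats: EdgeStatResult, alpha: float = 0.05, lam: float = 0.5,
                    alpha_tail: float | None = None) -> DetectionResult:
    """Storey FDR-corrected one-sided edge tests."""
    s = InferenceSettings(alpha=alpha, alpha_tail=alpha_tail, storey_lambda=lam)
    at = s.tail_level()
    _, q_pos = storey_qvalues(stats.p_pos, lam)
    _, q_neg = storey_qvalues(stats.p_neg, lam)
    return _edge_level_result("edge-fdr", alpha, q_pos <= at, q_neg <= at,
                              q_pos, q_neg)


def _edge_level_result(procedure: str, alpha: float, pos: np.ndarray,
                       neg: np.ndarray, p_pos: np.ndarray,
                       p_neg: np.ndarray) -> DetectionResult:
    edge_signs = np.zeros(pos.size, dtype=np.int8)
    edge_signs[pos] = 1
    edge_signs[neg] = -1  # mutually exclusive for any usable alpha
    ids, signs, pvals = [], [], []
    for e in np.flatnonzero(pos):
        ids.append(f"edge:{e}")
        signs.append(1)
        pvals.append(p_pos[e])
    for e in np.flatnonzero(neg):
        ids.append(f"edge:{e}")
        signs.append(-1)
        pvals.append(p_neg[e])
    level = "cluster" if procedure == "nbs-tfce" else "edge"
    return DetectionResult(procedure, level, alpha, ids,
                           np.array(signs, dtype=np.int8),
                           np.array(pvals, dtype=float), edge_signs)


# ---------------------------------------------------------------------------
# cluster level


def _nbs_from_stats(t_obs: np.ndarray, perm_t: np.ndarray, index: EdgeIndexMap,
                    cdt: float, alpha: float, alpha_tail: float) -> DetectionResult:
    n_perm = perm_t.shape[0]
    edge_signs = np.zeros(index.n_edges, dtype=np.int8)
    ids, signs, pvals = [], [], []
    for sign in (1, -1):
        comps = edge_components(sign * t_obs > cdt, index)
        if not comps:
            continue
        null_max = max_component_sizes(perm_t, index, cdt, sign)
        for c_i, comp in enumerate(comps):
            p = (1 + np.count_nonzero(null_max >= comp.size)) / (n_perm + 1)
            if p <= alpha_tail:
                tag = "pos" if sign > 0 else "neg"
                ids.append(f"cluster:{tag}:{c_i}")
                signs.append(sign)
                pvals.append(p)
                edge_signs[comp] = sign
    return DetectionResult("nbs", "cluster", alpha, ids,
                           np.array(signs, dtype=np.int8),
                           np.array(pvals, dtype=float), edge_signs)


def nbs_cluster(diffs: np.ndarray, engine: PermutationEngine, index: EdgeIndexMap,
                cdt: float | None = None, alpha: float = 0.05,
                settings: InferenceSettings | None = None) -> DetectionResult:
    """NBS cluster inference: supra-threshold components vs max-size null."""
    s = settings or InferenceSettings(alpha=alpha, cdt=cdt)
    stats = paired_t_and_d(diffs)
    perm_t = perm_t_matrix(diffs, engine)
    return _nbs_from_stats(stats.t, perm_t, index, s.cdt_value(stats.df),
                           s.alpha, s.tail_level())


def tfce_transform(tvals: np.ndarray, index: EdgeIndexMap,
                   params: TFCEParams) -> np.ndarray:
    """TFCE scores of the positive part of a statistic map.

    ``tfce(e) = sum_k extent_k(e)^E * h_k^H * dh`` over heights
    ``h_k = k * dh``, ``dh = max(t)/n_steps``; all-nonpositive maps score 0.
    """
    return tfce_scores(tvals, index, params.n_steps, params.extent_exponent,
                       params.height_exponent)


def _tfce_from_stats(t_obs: np.ndarray, perm_t: np.ndarray, index: EdgeIndexMap,
                     params: TFCEParams, alpha: float,
                     alpha_tail: float) -> DetectionResult:
    n_perm = perm_t.shape[0]
    edge_signs = np.zeros(index.n_edges, dtype=np.int8)
    ids, signs, pvals = [], [], []
    for sign in (1, -1):
        scores = tfce_scores(sign * t_obs, index, params.n_steps,
                             params.extent_exponent, params.height_exponent)
        if not np.any(scores > 0):
            continue
        null_max = np.sort(tfce_null_maxima(perm_t, index, params.n_steps,
                                            params.extent_exponent,
                                            params.height_exponent, sign))
        hits = n_perm - np.searchsorted(null_max, scores, side="left")
        p = (1 + hits) / (n_perm + 1)
        det = p <= alpha_tail
        edge_signs[det] = sign
        for e in np.flatnonzero(det):
            ids.append(f"edge:{e}")
            signs.append(sign)
            pvals.append(p[e])
    return DetectionResult("nbs-tfce", "cluster", alpha, ids,
                           np.array(signs, dtype=np.int8),
                           np.array(pvals, dtype=float), edge_signs)


def nbs_tfce(diffs: np.ndarray, engine: PermutationEngine, index: EdgeIndexMap,
             params: TFCEParams | None = None, alpha: float = 0.05,
             settings: InferenceSettings | None = None) -> DetectionResult:
    """Threshold-free NBS: per-edge TFCE scores vs max-score permutation null."""
    s = settings or InferenceSettings(alpha=alpha,
                                      tfce=params or TFCEParams())
    stats = paired_t_and_d(diffs)
    perm_t = perm_t_matrix(diffs, engine)
    return _tfce_from_stats(stats.t, perm_t, index, s.tfce, s.alpha, s.tail_level())


# ---------------------------------------------------------------------------
# network level


def cnbs_stats(tvals: np.ndarray, pair_map: np.ndarray,
               n_pairs: int) -> np.ndarray:
    """Pooled network statistics: mean edgewise t within each network pair."""
    counts = np.bincount(pair_map, minlength=n_pairs)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0)
        raise InvalidPartitionError(
            f"network pair(s) {empty.tolist()} contain no edges"
        )
    sums = np.bincount(pair_map, weights=tvals, minlength=n_pairs)
    return sums / counts


def simes_stepup(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Simes (Benjamini-Hochberg) step-up rejection mask at level ``alpha``."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = alpha * np.arange(1, m + 1) / m
    ok = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if ok.any():
        k = np.max(np.flatnonzero(ok))
        reject[order[: k + 1]] = True
    return reject


def _cnbs_from_stats(t_obs: np.ndarray, perm_t: np.ndarray, partition: Partition,
                     pair_map: np.ndarray, index: EdgeIndexMap, alpha: float,
                     alpha_tail: float, correction: str, procedure: str,
                     p_method: str = "gaussian") -> DetectionResult:
    n_pairs = partition.n_network_pairs
    counts = np.bincount(pair_map, minlength=n_pairs)
    if np.any(counts == 0):
        raise InvalidPartitionError("every network pair must contain >= 1 edge")
    obs_T = cnbs_stats(t_obs, pair_map, n_pairs)
    null_T = perm_t @ _pair_indicator(pair_map, n_pairs)  # (P, n_pairs) means
    if p_method == "gaussian":
        # the pooled statistic is a mean over many edges, so its sign-flip
        # null is close to Gaussian; calibrating a normal tail on the null
        # draws gives p-values below the 1/(P+1) permutation granularity,
        # which Bonferroni across network pairs requires
        mu = null_T.mean(axis=0)
        sd = null_T.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise InvalidArgumentError("degenerate permutation null for a network pair")
        z = (obs_T - mu) / sd
    elif p_method != "permutation":
        raise InvalidArgumentError(f"unknown cnbs p method {p_method!r}")
    pair_signs = np.zeros(n_pairs, dtype=np.int8)
    ids, signs, pvals = [], [], []
    edge_signs = np.zeros(index.n_edges, dtype=np.int8)
    for sign, tail in ((1, "ge"), (-1, "le")):
        if p_method == "gaussian":
            p_k = sps.norm.sf(z) if sign > 0 else sps.norm.cdf(z)
        else:
            p_k = permutation_pvalues(obs_T, null_T, tail)
        if correction == "bonferroni":
            det = p_k <= alpha_tail / n_pairs
        elif correction == "simes":
            det = simes_stepup(p_k, alpha_tail)
        else:
            raise InvalidArgumentError(f"unknown correction {correction!r}")
        for k in np.flatnonzero(det):
            pair_signs[k] = sign
            ids.append(f"network:{partition.pair_label(k)}")
            signs.append(sign)
            pvals.append(p_k[k])
            edge_signs[pair_map == k] = sign
    return DetectionResult(procedure, "network", alpha, ids,
                           np.array(signs, dtype=np.int8),
                           np.array(pvals, dtype=float), edge_signs,
                           pair_signs=pair_signs, pair_map=pair_map)


def _pair_indicator(pair_map: np.ndarray, n_pairs: int) -> np.ndarray:
    """(E, n_pairs) column-normalized indicator so ``t @ M`` is a pooled mean."""
    counts = np.bincount(pair_map, minlength=n_pairs).astype(float)
    ind = np.zeros((pair_map.size, n_pairs))
    ind[np.arange(pair_map.size), pair_map] = 1.0 / counts[pair_map]
    return ind


def cnbs_network(diffs: np.ndarray, partition: Partition, engine: PermutationEngine,
                 index: EdgeIndexMap, alpha: float = 0.05,
                 correction: str = "bonferroni",
                 settings: InferenceSettings | None = None) -> DetectionResult:
    """cNBS network inference: pooled statistics vs permutation nulls.

    ``correction='bonferroni'`` controls FWER across network pairs;
    ``'simes'`` applies the Benjamini-Hochberg step-up (FDR control).
    """
    from .core import assign_network_pairs

    s = settings or InferenceSettings(alpha=alpha)
    stats = paired_t_and_d(diffs)
    perm_t = perm_t_matrix(diffs, engine)
    pair_map = assign_network_pairs(partition, index)
    procedure = "cnbs-fwer" if correction == "bonferroni" else "cnbs-fdr"
    return _cnbs_from_stats(stats.t, perm_t, partition, pair_map, index,
                            s.alpha, s.tail_level(), correction, procedure,
                            s.cnbs_p_method)


# ---------------------------------------------------------------------------
# whole brain


def mahalanobis_sq(x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
    """Squared Mahalanobis distance of ``x`` from ``(mu, cov)``."""
    delta = np.asarray(x, dtype=float) - np.asarray(mu, dtype=float)
    try:
        sol = np.linalg.solve(np.asarray(cov, dtype=float), delta)
    except np.linalg.LinAlgError as exc:
        raise ConnbenchError(
            f"singular covariance in Mahalanobis distance: {exc}"
        ) from exc
    return float(delta @ sol)


def _mv_cnbs_from_stats(t_obs: np.ndarray, perm_t: np.ndarray, partition: Partition,
                        pair_map: np.ndarray, index: EdgeIndexMap, alpha: float,
                        ridge: float) -> DetectionResult:
    n_pairs = partition.n_network_pairs
    n_perm = perm_t.shape[0]
    if n_perm < n_pairs + 2:
        raise InvalidArgumentError(
            f"need at least n_pairs + 2 = {n_pairs + 2} permutations to "
            f"estimate the null covariance, got {n_perm}"
        )
    obs_T = cnbs_stats(t_obs, pair_map, n_pairs)
    null_T = perm_t @ _pair_indicator(pair_map, n_pairs)

    mu = null_T.mean(axis=0)
    cov = np.cov(null_T, rowvar=False, ddof=1)
    eps = ridge * np.trace(cov) / n_pairs
    cov_r = cov + eps * np.eye(n_pairs)
    d2_obs = mahalanobis_sq(obs_T, mu, cov_r)

    # leave-one-out null distances: each permutation draw scored against the
    # moments of the remaining draws, so it is exchangeable with the observed
    s1 = null_T.sum(axis=0)
    s2 = null_T.T @ null_T
    n1 = n_perm - 1
    mu_loo = (s1[None, :] - null_T) / n1  # (P, K)
    outer = np.einsum("pi,pj->pij", null_T, null_T)
    outer_mu = np.einsum("pi,pj->pij", mu_loo, mu_loo)
    cov_loo = (s2[None, :, :] - outer - n1 * outer_mu) / (n1 - 1)
    tr = np.trace(cov_loo, axis1=1, axis2=2)
    cov_loo = cov_loo + (ridge * tr / n_pairs)[:, None, None] * np.eye(n_pairs)[None, :, :]
    delta = null_T - mu_loo
    try:
        sol = np.linalg.solve(cov_loo, delta[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError as exc:
        raise ConnbenchError(
            f"singular leave-one-out null covariance: {exc}"
        ) from exc
    d2_null = np.einsum("pi,pi->p", delta, sol)

    p = (1 + np.count_nonzero(d2_null >= d2_obs)) / (n_perm + 1)
    detected = p <= alpha
    edge_signs = np.zeros(index.n_edges, dtype=np.int8)
    ids = ["whole_brain"] if detected else []
    return DetectionResult("mv-cnbs", "whole_brain", alpha, ids,
                           np.array([0] * len(ids), dtype=np.int8),
                           np.array([p] * len(ids), dtype=float), edge_signs,
                           wb_detected=bool(detected), wb_p=p)


def mv_cnbs(diffs: np.ndarray, partition: Partition, engine: PermutationEngine,
            index: EdgeIndexMap, alpha: float = 0.05,
            settings: InferenceSettings | None = None) -> DetectionResult:
    """Whole-brain omnibus test on the pooled-network statistic vector.

    The observed cNBS vector is compared with the permutation null cloud via
    squared Mahalanobis distance (ridge-regularized moments estimated from
    the null draws); the null distances are computed leave-one-out so they
    are exchangeable with the observed one.  Signless test of inequality.
    """
    from .core import assign_network_pairs

    s = settings or InferenceSettings(alpha=alpha)
    stats = paired_t_and_d(diffs)
    perm_t = perm_t_matrix(diffs, engine)
    pair_map = assign_network_pairs(partition, index)
    return _mv_cnbs_from_stats(stats.t, perm_t, partition, pair_map, index,
                               s.alpha, s.mv_ridge)


# ---------------------------------------------------------------------------
# shared fast path


def run_procedure_suite(diffs: np.ndarray, engine: PermutationEngine,
                        index: EdgeIndexMap, partition: Partition | None,
                        procedures: tuple[str, ...] = tuple(PROCEDURES),
                        settings: InferenceSettings | None = None,
                        ) -> dict[str, DetectionResult]:
    """Run several procedures on one contrast, sharing the permutation null.

    The edgewise statistics and the full permuted-t ensemble are computed
    once; every requested procedure consumes them.  This is the hot path of
    the benchmarking harness.
    """
    from .core import assign_network_pairs

    s = settings or InferenceSettings()
    unknown = set(procedures) - set(PROCEDURES)
    if unknown:
        raise InvalidArgumentError(f"unknown procedure(s): {sorted(unknown)}")
    stats = paired_t_and_d(diffs)
    needs_perm = any(p not in ("edge-fwer", "edge-fdr") for p in procedures)
    perm_t = perm_t_matrix(diffs, engine) if needs_perm else None
    needs_pairs = any(p.startswith(("cnbs", "mv")) for p in procedures)
    pair_map = None
    if needs_pairs:
        if partition is None:
            raise InvalidPartitionError("network-level procedures need a partition")
        pair_map = assign_network_pairs(partition, index)

    at = s.tail_level()
    out: dict[str, DetectionResult] = {}
    for proc in procedures:
        if proc == "edge-fwer":
            out[proc] = edge_bonferroni(stats, s.alpha, at)
        elif proc == "edge-fdr":
            out[proc] = edge_storey_fdr(stats, s.alpha, s.storey_lambda, at)
        elif proc == "nbs":
            out[proc] = _nbs_from_stats(stats.t, perm_t, index,
                                        s.cdt_value(stats.df), s.alpha, at)
        elif proc == "nbs-tfce":
            out[proc] = _tfce_from_stats(stats.t, perm_t, index, s.tfce,
                                         s.alpha, at)
        elif proc == "cnbs-fwer":
            out[proc] = _cnbs_from_stats(stats.t, perm_t, partition, pair_map,
                                         index, s.alpha, at, "bonferroni", proc,
                                         s.cnbs_p_method)
        elif proc == "cnbs-fdr":
            out[proc] = _cnbs_from_stats(stats.t, perm_t, partition, pair_map,
                                         index, s.alpha, at, "simes", proc,
                                         s.cnbs_p_method)
        elif proc == "mv-cnbs":
            out[proc] = _mv_cnbs_from_stats(stats.t, perm_t, partition, pair_map,
                                            index, s.alpha, s.mv_ridge)
    return out
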