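"""Paired-sample edgewise statistics and the sign-flip permutation engine.

The basic design throughout is a paired contrast between two conditions
measured on the same subjects (e.g. task vs rest connectivity).  Per edge,
the test statistic is the one-sample t of the within-subject differences,
and the effect size is the paired Cohen's d (mean difference divided by the
standard deviation of differences).

The permutation scheme exploits exchangeability of the condition labels
within subject: each permutation draw independently flips the sign of each
subject's difference vector with probability 1/2.  All nonparametric
procedures in :mod:`connbench.inference` share this engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import InvalidArgumentError, InvalidSampleError, PairedSample

__all__ = [
    "EdgeStatResult",
    "PermutationEngine",
    "paired_differences",
    "paired_t_and_d",
    "permuted_stats",
    "permutation_pvalue",
    "perm_t_matrix",
]


@dataclass
class EdgeStatResult:
    """Edgewise paired t statistics, p-values and Cohen's d.

    ``p_pos`` is the one-sided p for the positive tail (``P(T >= t_obs)``),
    ``p_neg`` for the negative tail.  ``zero_variance`` flags degenerate
    edges whose differences have zero sample standard deviation; for those,
    t is 0 (zero mean) or signed infinity (nonzero mean).
    """

    t: np.ndarray
    df: int
    p_two: np.ndarray
    p_pos: np.ndarray
    p_neg: np.ndarray
    d: np.ndarray
    zero_variance: np.ndarray

    @property
    def n(self) -> int:
        return self.df + 1


def paired_differences(sample: PairedSample) -> np.ndarray:
    """Per-subject difference vectors, ``condition_a - condition_b``.

    Returns an ``(n_subjects, n_edges)`` array.
    """
    if sample.n_subjects < 2:
        raise InvalidSampleError(
            f"need at least 2 subjects for a paired contrast, got {sample.n_subjects}"
        )
    return sample.condition_a - sample.condition_b


def paired_t_and_d(diffs: np.ndarray) -> EdgeStatResult:
    """Edgewise one-sample t and Cohen's d of paired differences.

    ``t = mean / (sd / sqrt(n))`` and ``d = mean / sd`` with the sample
    standard deviation (``n - 1`` denominator).  p-values come from the t
    reference distribution with ``df = n - 1``.
    """
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n = diffs.shape[0]
    if n < 2:
        raise InvalidSampleError(f"need n >= 2 paired differences, got {n}")
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    zero_var = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(zero_var, np.where(mean == 0.0, 0.0, np.sign(mean) * np.inf), mean / sd)
        t = np.where(zero_var, d, mean / (sd / np.sqrt(n)))
    df = n - 1
    # t reference handles +-inf correctly: sf(inf) = 0, cdf(inf) = 1
    p_pos = sps.t.sf(t, df)
    p_neg = sps.t.cdf(t, df)
    p_two = 2.0 * np.minimum(p_pos, p_neg)
    np.clip(p_two, 0.0, 1.0, out=p_two)
    return EdgeStatResult(t=t, df=df, p_two=p_two, p_pos=p_pos, p_neg=p_neg, d=d,
                          zero_variance=zero_var)


@dataclass(frozen=True)
class PermutationEngine:
    """Reproducible sign-flip permutation draws for a paired design.

    Draw 0 is reserved as the identity (observed) labeling; draws
    ``1..n_permutations`` are random.  Each draw is derived from
    ``(seed, draw)`` so any single draw can be regenerated in isolation.
    """

    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise InvalidArgumentError("need at least one permutation")

    def signs(self, n_subjects: int, draw: int) -> np.ndarray:
        """+-1 flip vector for one draw (draw 0 = all +1, the identity)."""
        if not (0 <= draw <= self.n_permutations):
            raise IndexError(
                f"draw {draw} out of range [0, {self.n_permutations}]"
            )
        if draw == 0:
            return np.ones(n_subjects)
        rng = np.random.default_rng((int(self.seed), int(draw)))
        return rng.integers(0, 2, size=n_subjects) * 2.0 - 1.0

    def sign_matrix(self, n_subjects: int) -> np.ndarray:
        """All random draws stacked: ``(n_permutations, n_subjects)`` of +-1."""
        return np.stack(
            [self.signs(n_subjects, k) for k in range(1, self.n_permutations + 1)]
        )


def permuted_stats(diffs: np.ndarray, engine: PermutationEngine, draw: int) -> EdgeStatResult:
    """Edgewise statistics after applying one sign-flip draw to ``diffs``."""
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    signs = engine.signs(diffs.shape[0], draw)
    return paired_t_and_d(signs[:, None] * diffs)


def perm_t_matrix(diffs: np.ndarray, engine: PermutationEngine) -> np.ndarray:
    """t statistics for every random permutation draw, shape ``(P, n_edges)``.

    Sign flips leave the per-edge sum of squared differences unchanged, so
    only the permuted means require a matrix product; the permuted variance
    follows from ``var = (ss - n * mean^2) / (n - 1)``.  This makes the full
    null ensemble a single BLAS call, which the cluster-, network- and
    whole-brain procedures all share.
    """
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n = diffs.shape[0]
    if n < 2:
        raise InvalidSampleError(f"need n >= 2, got {n}")
    signs = engine.sign_matrix(n)  # (P, n)
    means = signs @ diffs / n  # (P, E)
    ss = np.einsum("ij,ij->j", diffs, diffs)  # invariant under sign flips
    var = (ss[None, :] - n * means**2) / (n - 1)
    np.clip(var, 0.0, None, out=var)  # guard tiny negative round-off
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var == 0.0,
                     np.where(means == 0.0, 0.0, np.sign(means) * np.inf),
                     means / np.sqrt(var / n))
    return t


def permutation_pvalue(observed: float, null_samples: np.ndarray, tail: str = "ge") -> float:
    """Permutation p-value with the +1 convention (never exactly 0).

    ``p = (1 + #{null <relation> observed}) / (P + 1)`` where the relation is
    ``>=`` for ``tail='ge'``, ``<=`` for ``'le'``, and ``|null| >= |observed|``
    for ``'two'``.  Ties count against the observed statistic (conservative).
    """
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size == 0:
        raise InvalidArgumentError("null_samples must be nonempty")
    if tail == "ge":
        hits = np.count_nonzero(null_samples >= observed)
    elif tail == "le":
        hits = np.count_nonzero(null_samples <= observed)
    elif tail == "two":
        hits = np.count_nonzero(np.abs(null_samples) >= abs(observed))
    else:
        raise InvalidArgumentError(f"unknown tail {tail!r}")
    return (1 + hits) / (null_samples.size + 1)


def permutation_pvalues(observed: np.ndarray, null_samples: np.ndarray,
                        tail: str = "ge") -> np.ndarray:
    """Vectorized :func:`permutation_pvalue` over columns.

    ``observed`` has shape ``(m,)`` and ``null_samples`` shape ``(P, m)``;
    each column is its own null distribution.
    """
    null_samples = np.asarray(null_samples, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if null_samples.size == 0:
        raise InvalidArgumentError("null_samples must be nonempty")
    if tail == "ge":
        hits = np.count_nonzero(null_samples >= observed[None, :], axis=0)
    elif tail == "le":
        hits = np.count_nonzero(null_samples <= observed[None, :], axis=0)
    elif tail == "two":
        hits = np.count_nonzero(np.abs(null_samples) >= np.abs(observed)[None, :], axis=0)
    else:
        raise InvalidArgumentError(f"unknown tail {tail!r}")
    return (1 + hits) / (null_samples.shape[0] + 1)
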