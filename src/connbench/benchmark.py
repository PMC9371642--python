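"""Empirical benchmarking of the inferential procedures by group resampling.

The harness treats a large simulated (or loaded) population as the study
universe.  The ground truth is estimated once on the full population; then,
at each of ``R`` repetitions, a group of ``n`` subjects is resampled
without replacement, inference is run, and detections are classified
against the ground truth by *sign*: a detection is a true positive iff its
direction matches the ground-truth effect sign, a false positive iff it is
in the opposite direction, falls on a null element (sparse variants), or
occurs at all under the fake (two-rest-runs) task contrast.

Power is accounted at the level the procedure localizes to — edges for
edge- and cluster-level procedures (a cluster detection credits its
implicated edges), network pairs for network procedures, one element for
the whole brain.  Error measures are accounted at the level of the claim a
detection makes: a cluster claim is false only when the cluster contains no
same-direction true effect, a network claim only when the pooled direction
is wrong (member edges are *not* individually asserted — that cost shows up
in spatial precision instead).

Six accuracy measures are aggregated per experiment cell:

* power — per-element true-positive rate across repetitions, averaged over
  non-null elements, plus the proportion of elements at or above a power
  threshold (default 80%);
* empirical FDR — per-repetition FP/(TP+FP): edge counts for edge- and
  cluster-level procedures, claim counts for network and whole-brain;
* spatial extent of false positives — per-repetition fraction of the
  connectome implicated by false claims, averaged over repetitions;
* spatial precision — fraction of all implicated edges overlapping
  same-sign ground-truth effects (undefined for the whole-brain test);
* strong-sense FWER — fraction of real-contrast repetitions with >= 1
  false claim;
* weak-sense FWER — fraction of fake-contrast repetitions with >= 1
  detection.

FWER validity follows the binomial criterion: the empirical rate must fall
below the 95% upper confidence bound around the nominal level,
``alpha + 1.96 * sqrt(alpha (1 - alpha) / R)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (InvalidArgumentError, InvalidSampleError, PairedSample,
                   Partition)
from .graph import edge_components
from .ground_truth import GroundTruthMap
from .inference import (PROCEDURES, DetectionResult, InferenceSettings,
                        run_procedure_suite)
from .stats import PermutationEngine, paired_differences

__all__ = [
    "ExperimentConfig", "BenchmarkSummary", "Classification",
    "resample_groups", "make_fake_contrast", "classify_detections",
    "run_repetitions", "compute_metrics", "run_benchmark",
    "power_by_effect_size", "run_experiment_grid", "grid_cells",
    "fwer_upper_bound", "summaries_to_frame",
]

_CONTRAST_CODES = {"real_task": 0, "fake_task": 1}
_SEED_MASK = 0x7FFFFFFF


def fwer_upper_bound(alpha: float, repetitions: int) -> float:
    """95% binomial upper confidence bound around the nominal level."""
    return alpha + 1.96 * np.sqrt(alpha * (1 - alpha) / repetitions)


@dataclass(frozen=True)
class ExperimentConfig:
    """One benchmarking experiment cell (procedure x contrast x group size)."""

    procedure: str
    contrast: str = "real_task"
    group_size: int = 40
    repetitions: int = 100
    alpha: float = 0.05
    n_permutations: int = 500
    base_seed: int = 0
    variant: str = "full"
    settings: InferenceSettings | None = None

    def __post_init__(self) -> None:
        if self.procedure not in PROCEDURES:
            raise InvalidArgumentError(f"unknown procedure {self.procedure!r}")
        if self.contrast not in _CONTRAST_CODES:
            raise InvalidArgumentError(f"unknown contrast {self.contrast!r}")
        if self.repetitions < 1:
            raise InvalidArgumentError("repetitions must be >= 1")


def _rep_seeds(base_seed: int, contrast: str, group_size: int,
               rep: int) -> tuple[int, int, int]:
    """Independent (resample, shuffle, permutation) seeds for one repetition.

    Derived from the experiment coordinates through a SeedSequence so any
    repetition can be re-run in isolation; the procedure axis deliberately
    shares these seeds so every procedure sees the same resampled groups.
    """
    ss = np.random.SeedSequence(
        (int(base_seed), _CONTRAST_CODES[contrast], int(group_size), int(rep))
    )
    a, b, c = (int(x) & _SEED_MASK for x in ss.generate_state(3))
    return a, b, c


def resample_groups(population: PairedSample, n: int, rep_seed: int) -> PairedSample:
    """Draw ``n`` subjects without replacement from the population."""
    if n > population.n_subjects:
        raise InvalidArgumentError(
            f"cannot draw {n} subjects from a population of {population.n_subjects}"
        )
    rng = np.random.default_rng(rep_seed)
    idx = rng.choice(population.n_subjects, size=n, replace=False)
    null_b = population.null_run_b[idx] if population.has_null_runs else None
    return PairedSample(population.condition_a[idx], population.condition_b[idx],
                        population.index, null_run_b=null_b)


def make_fake_contrast(sample: PairedSample, rep_seed: int) -> PairedSample:
    """Null contrast from the two rest runs, labels shuffled per subject."""
    if not sample.has_null_runs:
        raise InvalidSampleError("fake contrast needs a second rest run per subject")
    rng = np.random.default_rng(rep_seed)
    swap = rng.integers(0, 2, size=sample.n_subjects).astype(bool)
    a = np.where(swap[:, None], sample.null_run_b, sample.condition_b)
    b = np.where(swap[:, None], sample.condition_b, sample.null_run_b)
    return PairedSample(a, b, sample.index)


@dataclass
class Classification:
    """Sign-matched true/false-positive accounting of one repetition.

    Two granularities coexist, mirroring what each measure means:

    * ``tp_elements``/``fp_elements`` live at the procedure's *power* level
      (edges for edge- and cluster-level procedures, network pairs for
      network procedures, a single element for the whole brain) and drive
      the per-element TPR;
    * error measures are counted at the procedure's *claim* level — what a
      detection actually asserts.  An edge detection asserts that edge's
      direction; a cluster detection asserts at least one same-direction
      effect within the cluster (so a cluster is a false claim only if it
      contains none); a network detection asserts the pooled direction of
      its pair; the whole-brain detection asserts some effect exists.
      ``n_fp_claims`` counts false claims (strong-sense FWER); the FDR
      numerators/denominators (``n_fp_fdr``/``n_tp_fdr``) are edge counts
      for edge- and cluster-level procedures and claim counts otherwise;
      ``fp_extent_edges`` marks the edges implicated by false claims.
    """

    level: str
    tp_elements: np.ndarray  # bool over elements at the procedure's power level
    fp_elements: np.ndarray
    n_tp_fdr: int
    n_fp_fdr: int
    n_fp_claims: int
    fp_extent_edges: np.ndarray  # bool over edges
    n_implicated: int
    n_implicated_tp: int
    any_detection: bool

    @property
    def any_fp(self) -> bool:
        return self.n_fp_claims > 0


def classify_detections(result: DetectionResult, gt: GroundTruthMap,
                        contrast: str = "real_task",
                        index=None) -> Classification:
    """Classify one repetition's detections against the ground truth.

    Real contrast: a detection is a true positive iff its direction matches
    the ground-truth effect sign at its level (elements with sign 0, as in
    sparse variants, count any detection as FP); cluster-level power is
    accounted per implicated edge, while cluster-level *error* is accounted
    per cluster claim (``index`` is needed to group detected edges into
    clusters; when omitted, each detected edge is its own claim).  Fake
    contrast: every detection is a false positive.  Whole-brain: TP iff
    detected and the ground truth is non-null (signless).
    """
    if contrast not in _CONTRAST_CODES:
        raise InvalidArgumentError(f"unknown contrast {contrast!r}")
    fake = contrast == "fake_task"
    n_edges = gt.n_edges
    zeros_e = np.zeros(n_edges, dtype=bool)

    if result.level == "whole_brain":
        det = bool(result.wb_detected)
        tp = det and not fake and gt.whole_brain_nonnull
        fp = det and not tp
        return Classification("whole_brain", np.array([tp]), np.array([fp]),
                              int(tp), int(fp), int(fp),
                              np.full(n_edges, fp), 0, 0, det)

    if result.edge_signs.size != n_edges:
        raise InvalidArgumentError(
            "detection result and ground truth disagree on edge count")
    det_e = result.edge_signs
    implicated = det_e != 0
    if fake:
        tp_edges = zeros_e
        fp_edges = implicated
    else:
        tp_edges = implicated & (det_e == gt.sign_edge) & (gt.sign_edge != 0)
        fp_edges = implicated & ~tp_edges

    if result.level == "network":
        if result.pair_signs is None:
            raise InvalidArgumentError("network-level result lacks pair signs")
        det_k = result.pair_signs
        det_mask = det_k != 0
        if fake:
            tp_k = np.zeros_like(det_mask)
            fp_k = det_mask
        else:
            tp_k = det_mask & (det_k == gt.sign_network) & (gt.sign_network != 0)
            fp_k = det_mask & ~tp_k
        fp_extent = zeros_e.copy()
        if result.pair_map is not None:
            for k in np.flatnonzero(fp_k):
                fp_extent |= result.pair_map == k
        elif fp_k.any():
            fp_extent = implicated.copy()
        return Classification("network", tp_k, fp_k,
                              int(tp_k.sum()), int(fp_k.sum()),
                              int(fp_k.sum()), fp_extent,
                              int(implicated.sum()), int(tp_edges.sum()),
                              bool(det_mask.any()))

    if result.level == "cluster":
        # group same-sign detected edges into cluster claims
        n_tp_claims = n_fp_claims = 0
        fp_extent = zeros_e.copy()
        for sign in (1, -1):
            mask = det_e == sign
            if not mask.any():
                continue
            if index is not None:
                comps = edge_components(mask, index)
            else:
                comps = [np.array([e]) for e in np.flatnonzero(mask)]
            for comp in comps:
                if fake or not np.any(gt.sign_edge[comp] == sign):
                    n_fp_claims += 1
                    fp_extent[comp] = True
                else:
                    n_tp_claims += 1
        return Classification("cluster", tp_edges, fp_edges,
                              int(tp_edges.sum()), int(fp_edges.sum()),
                              n_fp_claims, fp_extent,
                              int(implicated.sum()), int(tp_edges.sum()),
                              bool(implicated.any()))

    # edge level: claims are the edges themselves
    return Classification("edge", tp_edges, fp_edges,
                          int(tp_edges.sum()), int(fp_edges.sum()),
                          int(fp_edges.sum()), fp_edges.copy(),
                          int(implicated.sum()), int(tp_edges.sum()),
                          bool(implicated.any()))


@dataclass
class BenchmarkSummary:
    """Aggregated accuracy measures for one experiment cell."""

    procedure: str
    level: str
    contrast: str
    group_size: int
    repetitions: int
    alpha: float
    variant: str = "full"
    tpr_per_element: np.ndarray | None = None
    mean_power: float = np.nan
    mean_power_se: float = np.nan  # Monte-Carlo se from per-repetition spread
    prop_power_ge: dict[float, float] = field(default_factory=dict)
    mean_fdr: float = np.nan
    fp_spatial_extent: float = np.nan
    spatial_precision: float = np.nan
    fwer_strong: float = np.nan
    fwer_weak: float = np.nan

    @property
    def fwer_upper(self) -> float:
        return fwer_upper_bound(self.alpha, self.repetitions)

    @property
    def fwer_valid(self) -> bool:
        """Valid control: each measured FWER falls below the 95% upper bound."""
        ok = True
        if not np.isnan(self.fwer_strong):
            ok &= self.fwer_strong <= self.fwer_upper
        if not np.isnan(self.fwer_weak):
            ok &= self.fwer_weak <= self.fwer_upper
        return bool(ok)

    def to_row(self) -> dict:
        row = {
            "procedure": self.procedure, "level": self.level,
            "contrast": self.contrast, "group_size": self.group_size,
            "repetitions": self.repetitions, "alpha": self.alpha,
            "variant": self.variant, "mean_power": self.mean_power,
            "mean_power_se": self.mean_power_se, "mean_fdr": self.mean_fdr,
            "fp_spatial_extent": self.fp_spatial_extent,
            "spatial_precision": self.spatial_precision,
            "fwer_strong": self.fwer_strong, "fwer_weak": self.fwer_weak,
            "fwer_valid": self.fwer_valid,
        }
        for thr, prop in self.prop_power_ge.items():
            row[f"prop_power_ge_{thr:g}"] = prop
        return row


def compute_metrics(classifications: list[Classification], gt: GroundTruthMap,
                    procedure: str, contrast: str, group_size: int,
                    alpha: float, variant: str = "full",
                    power_thresholds: tuple[float, ...] = (0.8,),
                    ) -> BenchmarkSummary:
    """Aggregate the six accuracy measures over classified repetitions."""
    if not classifications:
        raise InvalidArgumentError("need at least one repetition")
    level = classifications[0].level
    r = len(classifications)
    summary = BenchmarkSummary(procedure, level, contrast, group_size, r,
                               alpha, variant)

    if contrast == "fake_task":
        summary.fwer_weak = float(np.mean([c.any_detection for c in classifications]))
        return summary

    tpr = np.mean([c.tp_elements for c in classifications], axis=0)
    summary.tpr_per_element = tpr
    if level == "whole_brain":
        nonnull = np.array([gt.whole_brain_nonnull])
    elif level == "network":
        nonnull = gt.sign_network != 0
    else:
        nonnull = gt.sign_edge != 0
    if nonnull.any():
        summary.mean_power = float(tpr[nonnull].mean())
        # mean power equals the mean over repetitions of the per-repetition
        # TP fraction among non-null elements; the spread of that fraction
        # captures between-element dependence, so its se is the honest MC se
        per_rep = np.array([c.tp_elements[nonnull].mean() for c in classifications])
        summary.mean_power_se = float(per_rep.std(ddof=1) / np.sqrt(r)) if r > 1 else np.nan
        summary.prop_power_ge = {
            thr: float(np.mean(tpr[nonnull] >= thr)) for thr in power_thresholds
        }
    summary.fwer_strong = float(np.mean([c.any_fp for c in classifications]))

    n_edges = gt.n_edges
    fdr, extent, precisions = [], [], []
    for c in classifications:
        fdr.append(c.n_fp_fdr / max(1, c.n_tp_fdr + c.n_fp_fdr))
        extent.append(np.count_nonzero(c.fp_extent_edges) / n_edges)
        if level != "whole_brain" and c.n_implicated > 0:
            precisions.append(c.n_implicated_tp / c.n_implicated)
    summary.mean_fdr = float(np.mean(fdr))
    summary.fp_spatial_extent = float(np.mean(extent))
    summary.spatial_precision = float(np.mean(precisions)) if precisions else np.nan
    return summary


def run_repetitions(population: PairedSample, partition: Partition | None,
                    procedures: tuple[str, ...], contrast: str, group_size: int,
                    repetitions: int, n_permutations: int = 500,
                    base_seed: int = 0,
                    settings: InferenceSettings | None = None,
                    ) -> dict[str, list[DetectionResult]]:
    """Resampling loop: per repetition, resample -> inference, all procedures.

    The permutation null ensemble is shared across procedures within a
    repetition, and all procedures see the same resampled groups.  Fully
    reproducible given ``base_seed``; detections can be re-classified
    against any ground-truth variant afterwards.
    """
    settings = settings or InferenceSettings()
    out: dict[str, list[DetectionResult]] = {p: [] for p in procedures}
    for rep in range(repetitions):
        rs, fs, ps = _rep_seeds(base_seed, contrast, group_size, rep)
        sample = resample_groups(population, group_size, rs)
        if contrast == "fake_task":
            sample = make_fake_contrast(sample, fs)
        diffs = paired_differences(sample)
        engine = PermutationEngine(n_permutations, ps)
        dets = run_procedure_suite(diffs, engine, population.index, partition,
                                   procedures, settings)
        for p in procedures:
            out[p].append(dets[p])
    return out


def run_benchmark(config: ExperimentConfig, population: PairedSample,
                  gt: GroundTruthMap, partition: Partition | None,
                  ) -> BenchmarkSummary:
    """Run one experiment cell end to end (see :class:`ExperimentConfig`)."""
    dets = run_repetitions(population, partition, (config.procedure,),
                           config.contrast, config.group_size,
                           config.repetitions, config.n_permutations,
                           config.base_seed, config.settings)
    classes = [classify_detections(d, gt, config.contrast, population.index)
               for d in dets[config.procedure]]
    return compute_metrics(classes, gt, config.procedure, config.contrast,
                           config.group_size, config.alpha, config.variant)


def power_by_effect_size(tpr_per_element: np.ndarray, d_element: np.ndarray,
                         bins: np.ndarray, repetitions: int | None = None,
                         ) -> pd.DataFrame:
    """Mean power binned by absolute ground-truth effect size.

    Returns one row per bin with the bin edges, element count, mean TPR
    (NaN for empty bins) and, when ``repetitions`` is given, a binomial
    Monte-Carlo standard error of the bin mean.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.size < 2:
        raise InvalidArgumentError("need at least one bin (two bin edges)")
    tpr = np.asarray(tpr_per_element, dtype=float)
    mag = np.abs(np.asarray(d_element, dtype=float))
    which = np.digitize(mag, bins) - 1
    rows = []
    for b in range(bins.size - 1):
        members = tpr[which == b]
        row = {"d_low": bins[b], "d_high": bins[b + 1], "n_elements": members.size,
               "mean_power": float(members.mean()) if members.size else np.nan}
        if repetitions is not None and members.size:
            var = np.sum(members * (1 - members) / repetitions)
            row["mc_se"] = float(np.sqrt(var) / members.size)
        elif repetitions is not None:
            row["mc_se"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def grid_cells(procedures, contrasts, group_sizes) -> list[tuple[str, str, int]]:
    """Enumerate the experiment grid (Cartesian product of the three axes)."""
    procedures, contrasts, group_sizes = (list(procedures), list(contrasts),
                                          list(group_sizes))
    if not (procedures and contrasts and group_sizes):
        raise InvalidArgumentError("all grid axes must be nonempty")
    return list(itertools.product(procedures, contrasts, group_sizes))


def run_experiment_grid(population: PairedSample, gt: GroundTruthMap,
                        partition: Partition | None,
                        procedures: tuple[str, ...] = tuple(PROCEDURES),
                        contrasts: tuple[str, ...] = ("real_task", "fake_task"),
                        group_sizes: tuple[int, ...] = (40,),
                        repetitions: int = 100, n_permutations: int = 500,
                        alpha: float = 0.05, base_seed: int = 0,
                        settings: InferenceSettings | None = None,
                        variant: str = "full",
                        keep_detections: bool = False,
                        ):
    """Execute the full experiment grid; one summary per cell.

    Returns ``(summaries, detections)`` where ``summaries`` maps
    ``(procedure, contrast, group_size)`` to a :class:`BenchmarkSummary`
    and ``detections`` (populated when ``keep_detections``) maps
    ``(contrast, group_size)`` to the per-procedure detection lists, so
    results can be re-classified against other ground-truth variants
    without re-running inference.
    """
    cells = grid_cells(procedures, contrasts, group_sizes)
    summaries: dict[tuple[str, str, int], BenchmarkSummary] = {}
    detections: dict[tuple[str, int], dict[str, list[DetectionResult]]] = {}
    for contrast in contrasts:
        for n in group_sizes:
            dets = run_repetitions(population, partition, tuple(procedures),
                                   contrast, n, repetitions, n_permutations,
                                   base_seed, settings)
            if keep_detections:
                detections[(contrast, n)] = dets
            for proc in procedures:
                classes = [classify_detections(d, gt, contrast, population.index)
                           for d in dets[proc]]
                summaries[(proc, contrast, n)] = compute_metrics(
                    classes, gt, proc, contrast, n, alpha, variant)
    assert len(summaries) == len(cells)
    return summaries, detections


def summaries_to_frame(summaries: dict) -> pd.DataFrame:
    """Flatten a grid-summary dict into a tidy DataFrame."""
    return pd.DataFrame([s.to_row() for s in summaries.values()])
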