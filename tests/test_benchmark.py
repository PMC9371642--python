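"""Resampling harness, sign-matched classification, and accuracy measures."""

import numpy as np
import pytest

import connbench as cb
from connbench.benchmark import Classification
from connbench.core import InvalidArgumentError, InvalidSampleError
from connbench.inference import DetectionResult


def _gt_simple(n_edges=6, signs=(1, 1, -1, -1, 0, 0)):
    signs = np.array(signs, dtype=np.int8)
    return cb.GroundTruthMap(
        d_edge=signs * 0.5, sign_edge=signs, sig_edge=signs != 0,
        d_network=np.array([0.5, -0.5]),
        sign_network=np.array([1, -1], dtype=np.int8),
        sig_network=np.array([True, True]), whole_brain_nonnull=True,
    )


def _edge_result(edge_signs, procedure="edge-fwer", level="edge"):
    edge_signs = np.array(edge_signs, dtype=np.int8)
    det = np.flatnonzero(edge_signs)
    return DetectionResult(procedure, level, 0.05,
                           [f"edge:{e}" for e in det],
                           edge_signs[det], np.full(det.size, 0.01),
                           edge_signs)


class TestResampleGroups:
    def test_full_draw_is_identity_up_to_order(self, tiny_population):
        s = cb.resample_groups(tiny_population, tiny_population.n_subjects, 0)
        assert np.array_equal(np.sort(s.condition_a, axis=0),
                              np.sort(tiny_population.condition_a, axis=0))

    def test_deterministic(self, tiny_population):
        a = cb.resample_groups(tiny_population, 10, 42)
        b = cb.resample_groups(tiny_population, 10, 42)
        assert np.array_equal(a.condition_a, b.condition_a)

    def test_oversized_draw_rejected(self, tiny_population):
        with pytest.raises(InvalidArgumentError):
            cb.resample_groups(tiny_population, 10_000, 0)

    def test_inclusion_frequency_uniform(self, index4):
        pop = cb.PairedSample(np.arange(20)[:, None] * np.ones((20, 6)),
                              np.zeros((20, 6)), index4)
        counts = np.zeros(20)
        reps = 1000
        for r in range(reps):
            s = cb.resample_groups(pop, 5, r)
            counts[s.condition_a[:, 0].astype(int)] += 1
        freq = counts / reps
        se = np.sqrt(0.25 * 0.75 / reps)
        assert np.all(np.abs(freq - 0.25) < 3.5 * se)


class TestFakeContrast:
    def test_identical_runs_zero_diffs(self, index4):
        rest = np.random.default_rng(0).normal(size=(6, 6))
        pop = cb.PairedSample(np.ones((6, 6)), rest, index4, null_run_b=rest)
        fake = cb.make_fake_contrast(pop, 3)
        assert np.all(cb.paired_differences(fake) == 0.0)

    def test_rows_are_swapped_or_not(self, tiny_population):
        fake = cb.make_fake_contrast(tiny_population, 11)
        r1, r2 = tiny_population.condition_b, tiny_population.null_run_b
        for s in range(fake.n_subjects):
            straight = np.array_equal(fake.condition_a[s], r1[s])
            swapped = np.array_equal(fake.condition_a[s], r2[s])
            assert straight != swapped or np.array_equal(r1[s], r2[s])

    def test_mean_difference_null(self, tiny_population):
        # across subjects and shuffles the expected difference is zero
        diffs = []
        for seed in range(40):
            fake = cb.make_fake_contrast(tiny_population, seed)
            diffs.append(cb.paired_differences(fake).mean())
        run_sd = np.std(tiny_population.condition_b - tiny_population.null_run_b)
        se = run_sd / np.sqrt(len(diffs) * tiny_population.n_subjects)
        assert abs(np.mean(diffs)) < 3 * se

    def test_deterministic(self, tiny_population):
        a = cb.make_fake_contrast(tiny_population, 5)
        b = cb.make_fake_contrast(tiny_population, 5)
        assert np.array_equal(a.condition_a, b.condition_a)

    def test_missing_second_run_rejected(self, index4):
        pop = cb.PairedSample(np.ones((3, 6)), np.zeros((3, 6)), index4)
        with pytest.raises(InvalidSampleError):
            cb.make_fake_contrast(pop, 0)


class TestClassifyDetections:
    def test_edge_sign_match_is_tp(self):
        gt = _gt_simple()
        c = cb.classify_detections(_edge_result([1, 0, 0, 0, 0, 0]), gt)
        assert c.tp_elements[0] and not c.any_fp

    def test_edge_sign_mismatch_is_fp(self):
        gt = _gt_simple()
        c = cb.classify_detections(_edge_result([0, 0, 1, 0, 0, 0]), gt)
        assert c.fp_elements[2] and c.any_fp and c.n_fp_claims == 1

    def test_null_element_detection_is_fp(self):
        gt = _gt_simple()  # edges 4, 5 are null (sparse-style)
        c = cb.classify_detections(_edge_result([0, 0, 0, 0, 1, 0]), gt)
        assert c.fp_elements[4] and c.any_fp

    def test_fake_contrast_all_fp(self):
        gt = _gt_simple()
        c = cb.classify_detections(_edge_result([1, 0, -1, 0, 0, 0]), gt,
                                   "fake_task")
        assert not c.tp_elements.any() and c.n_fp_claims == 2

    def test_cluster_claim_true_if_any_member_matches(self, index4):
        gt = _gt_simple()
        # edges 0 and 2 share node structure; gt signs are (+,-): a positive
        # cluster over {0, 1} contains edge 0 with matching sign -> TP claim,
        # but edge 1's gt sign is + as well
        res = _edge_result([1, 1, 0, 0, 0, 0], "nbs", "cluster")
        c = cb.classify_detections(res, gt, "real_task", index4)
        assert c.n_fp_claims == 0
        assert c.tp_elements[0] and c.tp_elements[1]

    def test_cluster_claim_false_if_no_member_matches(self, index4):
        gt = _gt_simple()
        # positive detection over edges with gt signs (-, 0): false claim
        res = _edge_result([0, 0, 1, 0, 1, 0], "nbs", "cluster")
        c = cb.classify_detections(res, gt, "real_task", index4)
        assert c.n_fp_claims >= 1
        assert c.fp_elements[2] and c.fp_elements[4]
        assert c.fp_extent_edges.any()

    def test_network_claim_uses_pooled_sign(self, index4):
        gt = _gt_simple()
        pair_map = np.array([0, 0, 0, 1, 1, 1])
        res = DetectionResult("cnbs-fwer", "network", 0.05, ["network:a"],
                              np.array([1], dtype=np.int8), np.array([0.01]),
                              np.where(pair_map == 0, 1, 0).astype(np.int8),
                              pair_signs=np.array([1, 0], dtype=np.int8),
                              pair_map=pair_map)
        c = cb.classify_detections(res, gt)
        assert c.tp_elements[0] and not c.any_fp
        # wrong pooled direction becomes a false claim implicating its edges
        res.pair_signs = np.array([-1, 0], dtype=np.int8)
        res.edge_signs = np.where(pair_map == 0, -1, 0).astype(np.int8)
        c = cb.classify_detections(res, gt)
        assert c.fp_elements[0] and c.n_fp_claims == 1
        assert np.array_equal(c.fp_extent_edges, pair_map == 0)

    def test_whole_brain(self):
        gt = _gt_simple()
        res = DetectionResult("mv-cnbs", "whole_brain", 0.05, ["whole_brain"],
                              np.array([0], dtype=np.int8), np.array([0.002]),
                              np.zeros(6, dtype=np.int8), wb_detected=True,
                              wb_p=0.002)
        c = cb.classify_detections(res, gt)
        assert c.tp_elements[0] and not c.any_fp
        c_fake = cb.classify_detections(res, gt, "fake_task")
        assert c_fake.fp_elements[0] and c_fake.any_fp


class TestComputeMetrics:
    def _cls(self, tp, fp, n_edges=100):
        tp_e = np.zeros(n_edges, dtype=bool)
        fp_e = np.zeros(n_edges, dtype=bool)
        tp_e[:tp] = True
        fp_e[tp:tp + fp] = True
        return Classification("edge", tp_e, fp_e, tp, fp, fp, fp_e,
                              tp + fp, tp, tp + fp > 0)

    def test_tpr_and_power(self):
        gt = cb.GroundTruthMap(
            d_edge=np.full(100, 0.5), sign_edge=np.ones(100, dtype=np.int8),
            sig_edge=np.ones(100, dtype=bool), d_network=np.array([0.5]),
            sign_network=np.array([1], dtype=np.int8),
            sig_network=np.array([True]), whole_brain_nonnull=True)
        # element 0 is TP in 4 of 5 repetitions
        classes = [self._cls(1, 0) for _ in range(4)] + [self._cls(0, 0)]
        s = cb.compute_metrics(classes, gt, "edge-fwer", "real_task", 40, 0.05)
        assert s.tpr_per_element[0] == pytest.approx(0.8)
        assert s.mean_power == pytest.approx(0.8 / 100)
        assert s.prop_power_ge[0.8] == pytest.approx(0.01)
        assert s.fwer_strong == 0.0

    def test_fdr_and_extent(self):
        gt = cb.GroundTruthMap(
            d_edge=np.full(100, 0.5), sign_edge=np.ones(100, dtype=np.int8),
            sig_edge=np.ones(100, dtype=bool), d_network=np.array([0.5]),
            sign_network=np.array([1], dtype=np.int8),
            sig_network=np.array([True]), whole_brain_nonnull=True)
        classes = [self._cls(8, 2)]  # 2 FP among 10 detections, E=100
        s = cb.compute_metrics(classes, gt, "edge-fdr", "real_task", 40, 0.05)
        assert s.mean_fdr == pytest.approx(0.2)
        assert s.fp_spatial_extent == pytest.approx(0.02)
        assert s.spatial_precision == pytest.approx(0.8)
        assert s.fwer_strong == 1.0

    def test_weak_fwer_validity_bound(self):
        # 25 of 500 fake-contrast repetitions with a detection: 5%, valid
        gt = _gt_simple()
        classes = []
        for r in range(500):
            det = r < 25
            classes.append(Classification(
                "edge", np.zeros(6, dtype=bool), np.full(6, det),
                0, int(det), int(det), np.full(6, det), int(det), 0, det))
        s = cb.compute_metrics(classes, gt, "edge-fwer", "fake_task", 40, 0.05)
        assert s.fwer_weak == pytest.approx(0.05)
        assert s.fwer_upper == pytest.approx(0.069, abs=0.001)
        assert s.fwer_valid

    def test_perfect_single_repetition(self, tiny_spec, tiny_population):
        """A procedure detecting everything correctly: power 1, no FP."""
        index = cb.build_edge_index(8)
        partition = cb.equal_partition(8, 2)
        spec = cb.GeneratorSpec(index=index, partition=partition,
                                delta=np.full(index.n_edges, -1.8),
                                n_subjects=60, seed=33)
        pop = cb.simulate_population(spec)
        gt = cb.estimate_ground_truth(pop, partition, seed=1)
        config = cb.ExperimentConfig("edge-fdr", "real_task", 50, 1,
                                     n_permutations=60, base_seed=2)
        s = cb.run_benchmark(config, pop, gt, partition)
        assert s.mean_power == 1.0
        assert s.fwer_strong == 0.0


class TestPowerByEffectSize:
    def test_flat_curve(self):
        out = cb.power_by_effect_size(np.full(50, 0.6),
                                      np.linspace(-1, 1, 50),
                                      np.array([0.0, 0.5, 1.0]))
        assert np.allclose(out["mean_power"], 0.6)

    def test_step_curve(self):
        d = np.linspace(0.0, 1.0, 100)
        tpr = (d > 0.5).astype(float)
        out = cb.power_by_effect_size(tpr, d, np.array([0.0, 0.5, 1.01]))
        assert out["mean_power"][0] == pytest.approx(0.0)
        assert out["mean_power"][1] == pytest.approx(1.0)

    def test_empty_bin_is_nan(self):
        out = cb.power_by_effect_size(np.ones(5), np.full(5, 0.1),
                                      np.array([0.0, 0.2, 0.4]))
        assert np.isnan(out["mean_power"][1])

    def test_needs_a_bin(self):
        with pytest.raises(InvalidArgumentError):
            cb.power_by_effect_size(np.ones(5), np.ones(5), np.array([0.5]))


class TestGrid:
    def test_paper_grid_enumerates_to_168(self):
        procedures = list(cb.PROCEDURES)
        tasks = ["emotion", "gambling", "language", "motor", "relational",
                 "social", "wm", "fake"]
        cells = cb.grid_cells(procedures, tasks, [40, 80, 120])
        assert len(cells) == 7 * 8 * 3 == 168

    def test_single_cell(self):
        assert len(cb.grid_cells(["edge-fwer"], ["real_task"], [40])) == 1

    def test_empty_axis_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cb.grid_cells([], ["real_task"], [40])

    def test_tiny_grid_runs_and_is_deterministic(self, tiny_spec,
                                                 tiny_population):
        gt = cb.estimate_ground_truth(tiny_population, tiny_spec.partition,
                                      seed=0)
        kwargs = dict(procedures=("edge-fdr", "cnbs-fdr", "mv-cnbs"),
                      contrasts=("real_task", "fake_task"), group_sizes=(25,),
                      repetitions=3, n_permutations=60, base_seed=9)
        s1, _ = cb.run_experiment_grid(tiny_population, gt,
                                       tiny_spec.partition, **kwargs)
        s2, _ = cb.run_experiment_grid(tiny_population, gt,
                                       tiny_spec.partition, **kwargs)
        assert len(s1) == 6
        f1 = cb.summaries_to_frame(s1)
        f2 = cb.summaries_to_frame(s2)
        assert f1.equals(f2)

    def test_grid_invariant_to_procedure_order(self, tiny_spec,
                                               tiny_population):
        gt = cb.estimate_ground_truth(tiny_population, tiny_spec.partition,
                                      seed=0)
        base = dict(contrasts=("real_task",), group_sizes=(25,),
                    repetitions=2, n_permutations=60, base_seed=4)
        s1, _ = cb.run_experiment_grid(tiny_population, gt, tiny_spec.partition,
                                       procedures=("edge-fwer", "nbs"), **base)
        s2, _ = cb.run_experiment_grid(tiny_population, gt, tiny_spec.partition,
                                       procedures=("nbs", "edge-fwer"), **base)
        for key in s1:
            assert s1[key].to_row() == s2[key].to_row()

    def test_rep_seed_isolation(self, tiny_spec, tiny_population):
        """Any repetition reproduces in isolation from the base seed."""
        dets = cb.run_repetitions(tiny_population, tiny_spec.partition,
                                  ("edge-fdr",), "real_task", 20, 3,
                                  n_permutations=50, base_seed=77)
        from connbench.benchmark import _rep_seeds
        rs, fs, ps = _rep_seeds(77, "real_task", 20, 2)
        sample = cb.resample_groups(tiny_population, 20, rs)
        redo = cb.run_procedure_suite(
            cb.paired_differences(sample), cb.PermutationEngine(50, ps),
            tiny_population.index, tiny_spec.partition, ("edge-fdr",))
        assert np.array_equal(redo["edge-fdr"].edge_signs,
                              dets["edge-fdr"][2].edge_signs)
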