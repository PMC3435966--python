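"""Evaluation metrics: dRGB distances, summary means, Spearman association."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

import tpscolor as tc
from tpscolor.errors import InvalidInputError
from tpscolor.metrics import MAX_DELTA, PatchEvaluation


class TestDeltaRGB:
    def test_identical_colors_distance_zero(self):
        assert tc.delta_rgb((5, 5, 5), (5, 5, 5)) == 0.0

    def test_cube_diagonal(self):
        d = tc.delta_rgb((0, 0, 0), (255, 255, 255))
        assert d == pytest.approx(255 * math.sqrt(3))
        assert d == pytest.approx(MAX_DELTA)

    def test_hand_arithmetic_example(self):
        # sqrt(9 + 16 + 144) = 13
        assert tc.delta_rgb((10, 20, 30), (13, 24, 42)) == pytest.approx(13.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            tc.delta_rgb((0, 0, -1), (0, 0, 0))
        with pytest.raises(InvalidInputError):
            tc.delta_rgb((0, 0, 0), (256, 0, 0))

    def test_all_distances_bounded_by_diagonal(self, rng):
        a = rng.uniform(0, 255, (200, 3))
        b = rng.uniform(0, 255, (200, 3))
        d = tc.delta_rgb_rows(a, b)
        assert np.all(d >= 0) and np.all(d <= MAX_DELTA)


class TestSummaryDistances:
    def test_within_mean_of_fit_patches(self):
        deltas = {"a": 3.0, "b": 4.0, "c": 5.0, "z": 100.0}
        assert tc.within_distance(deltas, {"a", "b", "c"}) == pytest.approx(4.0)

    def test_holdout_mean_of_non_fit_patches(self):
        deltas = {"a": 3.0, "b": 4.0, "c": 5.0, "z": 100.0}
        assert tc.holdout_distance(deltas, {"a", "b", "c"}) == pytest.approx(100.0)

    def test_perfect_interpolation_gives_zero_within(self):
        deltas = {f"p{i}": 0.0 for i in range(24)}
        assert tc.within_distance(deltas, set(deltas)) == 0.0

    def test_means_match_naive_sums_and_are_order_invariant(self, rng):
        ids = [f"p{i}" for i in range(40)]
        vals = rng.uniform(0, MAX_DELTA, 40)
        deltas = dict(zip(ids, vals))
        fit_ids = set(rng.choice(ids, size=15, replace=False))
        naive_fit = sum(deltas[i] for i in fit_ids) / len(fit_ids)
        naive_rest = sum(v for k, v in deltas.items() if k not in fit_ids) / 25
        assert tc.within_distance(deltas, fit_ids) == pytest.approx(naive_fit)
        assert tc.holdout_distance(deltas, fit_ids) == pytest.approx(naive_rest)
        shuffled = dict(sorted(deltas.items(), key=lambda kv: kv[1]))
        assert tc.within_distance(shuffled, fit_ids) == pytest.approx(naive_fit)

    def test_empty_sides_rejected(self):
        deltas = {"a": 1.0, "b": 2.0}
        with pytest.raises(InvalidInputError):
            tc.within_distance(deltas, set())
        with pytest.raises(InvalidInputError):
            tc.holdout_distance(deltas, {"a", "b"})


def measurement_set(colors_by_id, image_id=""):
    return tc.PatchMeasurementSet(
        [
            tc.PatchMeasurement(pid, np.asarray(rgb, float), 1)
            for pid, rgb in colors_by_id.items()
        ],
        image_id=image_id,
    )


class TestInterDistance:
    def test_identical_conditions_give_zero(self):
        m = {"c1": measurement_set({"a": (1, 2, 3), "h": (9, 9, 9)}),
             "c2": measurement_set({"a": (5, 5, 5), "h": (9, 9, 9)})}
        assert tc.inter_distance(m, {"a"}) == 0.0

    def test_two_conditions_single_pair(self):
        m = {"c1": measurement_set({"a": (0, 0, 0), "h": (10, 10, 10)}),
             "c2": measurement_set({"a": (0, 0, 0), "h": (13, 14, 10)})}
        assert tc.inter_distance(m, {"a"}) == pytest.approx(5.0)

    def test_matches_brute_force_triple_loop(self, rng):
        labels = ["c1", "c2", "c3", "c4"]
        patch_ids = [f"p{i}" for i in range(12)]
        fit_ids = set(patch_ids[:5])
        data = {
            lab: {pid: rng.uniform(0, 255, 3) for pid in patch_ids}
            for lab in labels
        }
        m = {lab: measurement_set(data[lab]) for lab in labels}
        holdout = [p for p in patch_ids if p not in fit_ids]
        per_patch = []
        for pid in holdout:
            acc, cnt = 0.0, 0
            for a, b in combinations(labels, 2):
                acc += math.dist(data[a][pid], data[b][pid])
                cnt += 1
            per_patch.append(acc / cnt)
        assert tc.inter_distance(m, fit_ids) == pytest.approx(
            sum(per_patch) / len(per_patch)
        )

    def test_fewer_than_two_conditions_rejected(self):
        with pytest.raises(InvalidInputError):
            tc.inter_distance({"c1": measurement_set({"a": (1, 1, 1)})}, set())


def evaluation_from_pairs(pairs):
    per_patch = [
        PatchEvaluation(f"h{i}", d, False, m) for i, (m, d) in enumerate(pairs)
    ]
    return tc.CalibrationEvaluation(per_patch, None, None)


class TestNearestControlAssociation:
    def test_monotone_relation_gives_rho_one(self):
        ev = evaluation_from_pairs([(float(i), float(i * 2)) for i in range(12)])
        rho, n, p = tc.nearest_control_association(ev)
        assert rho == pytest.approx(1.0)
        assert n == 12
        assert p < 0.001

    def test_constant_errors_are_flagged_undefined(self):
        ev = evaluation_from_pairs([(float(i), 3.0) for i in range(8)])
        with pytest.raises(InvalidInputError, match="zero variance"):
            tc.nearest_control_association(ev)

    def test_matches_rank_then_pearson_oracle(self, rng):
        pairs = list(zip(rng.uniform(0, 50, 20), rng.uniform(0, 30, 20)))
        ev = evaluation_from_pairs(pairs)
        rho, n, p = tc.nearest_control_association(ev)
        x = np.array([a for a, _ in pairs])
        y = np.array([b for _, b in pairs])
        rx = np.argsort(np.argsort(x))
        ry = np.argsort(np.argsort(y))
        rho_oracle = np.corrcoef(rx, ry)[0, 1]  # no ties in continuous draws
        assert rho == pytest.approx(rho_oracle, abs=1e-12)
        t = rho_oracle * math.sqrt((n - 2) / (1 - rho_oracle**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=n - 2), rel=1e-9)

    def test_exact_permutation_for_tiny_samples(self):
        # monotone n=5: one-in-120 chance each tail, two-sided
        ev = evaluation_from_pairs([(float(i), float(i)) for i in range(5)])
        rho, n, p = tc.nearest_control_association(ev)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)

    def test_too_few_holdout_patches_rejected(self):
        ev = evaluation_from_pairs([(1.0, 2.0)] * 4)
        with pytest.raises(InvalidInputError):
            tc.nearest_control_association(ev)


class TestEvaluateMeasurements:
    def test_summary_matches_component_metrics(self, rng, checker24):
        ref_rgb = {p.patch_id: p.rgb_ref for p in checker24.patches}
        noisy = {
            p.patch_id: np.clip(np.asarray(p.rgb_ref) + rng.normal(0, 4, 3), 0, 255)
            for p in checker24.patches
        }
        fit_ids = set(checker24.patch_ids[:12])
        ev = tc.evaluate_measurements(measurement_set(noisy), ref_rgb, fit_ids)
        deltas = {
            pid: math.dist(noisy[pid], np.asarray(ref_rgb[pid], float))
            for pid in noisy
        }
        assert ev.within_distance == pytest.approx(
            tc.within_distance(deltas, fit_ids)
        )
        assert ev.distance_from_reference == pytest.approx(
            tc.holdout_distance(deltas, fit_ids)
        )
        frame = ev.to_frame()
        assert set(frame.columns) >= {"patch_id", "delta_rgb", "used_in_fit"}
        holdout_rows = frame[~frame.used_in_fit]
        assert holdout_rows.min_dist_to_control.notna().all()
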