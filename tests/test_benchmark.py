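"""Matching rule, performance metrics, PR-AUC and quality metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from punctakit import (
    match_calls,
    new_call_table,
    pr_auc,
    pr_sweep,
    precision_recall_fscore,
    snr,
    spot_density,
    trim_xy_border,
    zero_voxel_proportion,
)
from punctakit.benchmark import MatchResult, PRPoint
from punctakit.stack import FilteredStack


def points_table(coords):
    xs, ys, zs = zip(*coords) if coords else ((), (), ())
    return new_call_table(x=xs, y=ys, z=zs, intensity=np.ones(len(coords)))


def naive_greedy_match(calls, ref, xy_tol=4.0, z_tol=2.0):
    """Transparent closest-first oracle: enumerate all pairs, accept in
    (xy distance, |dz|, call index) order, one-to-one."""
    pairs = []
    for ci in range(len(calls)):
        for ri in range(len(ref)):
            d = float(np.hypot(calls.x[ci] - ref.x[ri], calls.y[ci] - ref.y[ri]))
            dz = abs(float(calls.z[ci] - ref.z[ri]))
            if d <= xy_tol and dz <= z_tol:
                pairs.append((d, dz, ci, ri))
    pairs.sort()
    used_c, used_r, tp = set(), set(), 0
    for _, _, ci, ri in pairs:
        if ci in used_c or ri in used_r:
            continue
        used_c.add(ci)
        used_r.add(ri)
        tp += 1
    return tp


def exhaustive_max_matching(calls, ref, xy_tol=4.0, z_tol=2.0):
    """Largest one-to-one assignment within tolerance, by brute force."""
    pairs = [
        (ci, ri)
        for ci in range(len(calls))
        for ri in range(len(ref))
        if np.hypot(calls.x[ci] - ref.x[ri], calls.y[ci] - ref.y[ri]) <= xy_tol
        and abs(calls.z[ci] - ref.z[ri]) <= z_tol
    ]
    for size in range(min(len(calls), len(ref)), 0, -1):
        for combo in itertools.combinations(pairs, size):
            cs = {c for c, _ in combo}
            rs = {r for _, r in combo}
            if len(cs) == size and len(rs) == size:
                return size
    return 0


class TestMatchCalls:
    def test_identical_sets_all_matched(self):
        pts = [(3, 4, 1), (10, 10, 2), (20, 5, 0)]
        m = match_calls(points_table(pts), points_table(pts))
        assert (m.tp, m.fp, m.fn) == (3, 0, 0)

    def test_xy_distance_five_not_matched(self):
        m = match_calls(points_table([(15, 10, 3)]), points_table([(10, 10, 3)]))
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_xy_distance_four_inclusive(self):
        m = match_calls(points_table([(14, 10, 3)]), points_table([(10, 10, 3)]))
        assert m.tp == 1

    @pytest.mark.parametrize("dz,expected_tp", [(2, 1), (3, 0)])
    def test_z_tolerance_inclusive_at_two(self, dz, expected_tp):
        m = match_calls(points_table([(10, 10, 5 + dz)]), points_table([(10, 10, 5)]))
        assert m.tp == expected_tp

    def test_closer_call_wins_other_is_fp(self):
        calls = points_table([(11, 10, 0), (13, 10, 0)])
        ref = points_table([(10, 10, 0)])
        m = match_calls(calls, ref)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.pairs[0][0] == 0  # the closer call (index 0) matched

    def test_counts_partition_both_sets(self, rng):
        calls = points_table(list(zip(rng.uniform(0, 30, 12),
                                      rng.uniform(0, 30, 12),
                                      rng.integers(0, 6, 12))))
        ref = points_table(list(zip(rng.uniform(0, 30, 9),
                                    rng.uniform(0, 30, 9),
                                    rng.integers(0, 6, 9))))
        m = match_calls(calls, ref)
        assert m.tp + m.fp == len(calls)
        assert m.tp + m.fn == len(ref)

    def test_swap_symmetry(self, rng):
        calls = points_table(list(zip(rng.uniform(0, 25, 8),
                                      rng.uniform(0, 25, 8),
                                      rng.integers(0, 5, 8))))
        ref = points_table(list(zip(rng.uniform(0, 25, 6),
                                    rng.uniform(0, 25, 6),
                                    rng.integers(0, 5, 6))))
        m1 = match_calls(calls, ref)
        m2 = match_calls(ref, calls)
        assert m1.tp == m2.tp and m1.fp == m2.fn and m1.fn == m2.fp

    def test_agrees_with_naive_closest_first_oracle(self, rng):
        for _ in range(30):
            nc, nr = rng.integers(1, 9, 2)
            calls = points_table(list(zip(rng.uniform(0, 20, nc),
                                          rng.uniform(0, 20, nc),
                                          rng.integers(0, 8, nc))))
            ref = points_table(list(zip(rng.uniform(0, 20, nr),
                                        rng.uniform(0, 20, nr),
                                        rng.integers(0, 8, nr))))
            assert match_calls(calls, ref).tp == naive_greedy_match(calls, ref)

    def test_optimal_on_well_separated_sets(self, rng):
        """With references >= 2 tolerances apart, greedy closest-first is
        provably the maximum assignment; check against brute force."""
        for _ in range(10):
            nr = int(rng.integers(2, 7))
            refs = []
            while len(refs) < nr:
                cand = (rng.uniform(0, 60), rng.uniform(0, 60), rng.integers(0, 8))
                if all(np.hypot(cand[0] - r[0], cand[1] - r[1]) > 8 for r in refs):
                    refs.append(cand)
            calls = [
                (r[0] + rng.uniform(-2, 2), r[1] + rng.uniform(-2, 2), r[2])
                for r in refs
                if rng.uniform() < 0.8
            ]
            calls_t, ref_t = points_table(calls), points_table(refs)
            assert match_calls(calls_t, ref_t).tp == exhaustive_max_matching(
                calls_t, ref_t
            )


class TestPrecisionRecallF:
    def _m(self, tp, fp, fn):
        return MatchResult(pairs=[], tp=tp, fp=fp, fn=fn)

    def test_perfect_calls_give_f_one(self):
        p = precision_recall_fscore(self._m(10, 0, 0))
        assert p.precision == 1.0 and p.recall == 1.0 and p.f_score == 1.0

    def test_zero_recall_gives_f_zero(self):
        p = precision_recall_fscore(self._m(0, 0, 5))
        assert p.recall == 0.0
        assert p.precision is None  # no calls at all: 0/0
        m = self._m(0, 3, 5)
        p2 = precision_recall_fscore(m)
        assert p2.precision == 0.0 and p2.f_score == 0.0

    def test_hand_computed_f(self):
        # R = 12/20 = 0.6, P = 12/15 = 0.8 -> F = 2*0.48/1.4
        p = precision_recall_fscore(self._m(12, 3, 8))
        assert p.f_score == pytest.approx(0.685714285714, abs=1e-9)

    def test_harmonic_mean_between_p_and_r(self, rng):
        for _ in range(20):
            tp = int(rng.integers(1, 50))
            fp = int(rng.integers(0, 50))
            fn = int(rng.integers(0, 50))
            p = precision_recall_fscore(self._m(tp, fp, fn))
            assert min(p.precision, p.recall) - 1e-12 <= p.f_score
            assert p.f_score <= max(p.precision, p.recall) + 1e-12

    def test_empty_everything_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_fscore(self._m(0, 0, 0))


class TestPRAUC:
    def test_perfect_point_gives_unit_area(self):
        assert pr_auc([PRPoint(0, 1.0, 1.0, 1.0)]) == pytest.approx(1.0)

    def test_single_partial_recall_point(self):
        # vertices (0,1)-(0.5,1)-(0.5,0): rectangle of area 0.5 over recall
        assert pr_auc([PRPoint(0, 0.5, 1.0, None)]) == pytest.approx(0.5)

    def test_all_zero_precision(self):
        pts = [PRPoint(t, 0.5, 0.0, 0.0) for t in range(3)]
        assert pr_auc(pts) == 0.0

    def test_invariant_to_duplicates_and_order(self, rng):
        base = [PRPoint(t, r, p, None) for t, (r, p) in enumerate(
            zip(np.linspace(0.9, 0.1, 9), np.linspace(0.2, 1.0, 9)))]
        shuffled = list(base)
        rng.shuffle(shuffled)
        doubled = base + base
        a = pr_auc(base)
        assert pr_auc(shuffled) == pytest.approx(a)
        assert pr_auc(doubled) == pytest.approx(a)

    def test_result_clipped_to_unit_interval(self):
        pts = [PRPoint(0, 1.0, 1.0, None), PRPoint(1, 0.5, 1.0, None)]
        assert 0.0 <= pr_auc(pts) <= 1.0


class TestSweep:
    def test_sweep_matches_per_threshold_matching(self, rng):
        calls = points_table(list(zip(rng.uniform(0, 40, 25),
                                      rng.uniform(0, 40, 25),
                                      rng.integers(0, 8, 25))))
        calls["intensity"] = rng.uniform(10, 100, 25)
        ref = points_table(list(zip(rng.uniform(0, 40, 10),
                                    rng.uniform(0, 40, 10),
                                    rng.integers(0, 8, 10))))
        thresholds = [10, 30, 50, 70, 90]
        points = pr_sweep(calls, ref, thresholds)
        for t, point in zip(thresholds, points):
            retained = calls[calls.intensity >= t].reset_index(drop=True)
            m = match_calls(retained, ref)
            expected = precision_recall_fscore(m, threshold=t)
            assert point.recall == expected.recall
            assert point.precision == expected.precision


class TestScalarMetrics:
    def test_snr_examples(self):
        assert snr(100, 10) == 10
        assert snr(0, 10) == 0
        assert snr(200, 20) == snr(100, 10)
        with pytest.raises(ValueError):
            snr(100, 0)

    def test_spot_density_formula(self):
        assert spot_density(100, 90, 90, 50) == pytest.approx(0.1)
        assert spot_density(0, 90, 90, 50) == 0
        assert spot_density(1, 9, 9, 5) == pytest.approx(1.0)

    def test_zero_voxel_proportion_flags_at_cutoff(self):
        def f(frac_zero):
            n = 1000
            v = np.ones((1, 10, 100))
            v.ravel()[: int(frac_zero * n)] = 0.0
            return FilteredStack(voxels=v, slice_means=np.array([v.mean()]),
                                 trim_radius=0)

        zvp, flagged = zero_voxel_proportion(f(1.0))
        assert zvp == 1.0 and flagged
        zvp, flagged = zero_voxel_proportion(f(0.5))
        assert zvp == 0.5 and not flagged
        zvp, flagged = zero_voxel_proportion(f(0.7))
        assert zvp == pytest.approx(0.7) and flagged


class TestBorderTrim:
    def test_seven_pixel_trim_inclusive_bounds(self):
        pts = points_table([(6, 20, 0), (7, 20, 0), (56, 20, 0), (57, 20, 0),
                            (20, 6, 0), (20, 57, 0), (30, 30, 0)])
        out = trim_xy_border(pts, width=64, height=64, margin=7)
        kept = set(zip(out.x, out.y))
        assert kept == {(7, 20), (56, 20), (30, 30)}
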