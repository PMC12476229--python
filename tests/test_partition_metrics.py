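import numpy as np
import pytest
import sklearn.metrics as skm

import clustival as cv
from clustival import UndefinedMetricError
from clustival.partition import _ncr_raw

from conftest import brute_force_pair_counts, random_hard_partition


def _pc_ct(truth, pred):
    ct = cv.contingency(truth, pred)
    return cv.pair_counts(ct), ct


class TestRandAndWallace:
    def test_identical_partitions(self):
        pc, _ = _pc_ct(["A", "A", "B", "B"], [1, 1, 2, 2])
        assert cv.rand_index(pc) == 1.0
        assert cv.wallace_homogeneity(pc) == 1.0
        assert cv.wallace_completeness(pc) == 1.0

    def test_crossing_example(self):
        pc, _ = _pc_ct(["A", "A", "B", "B"], [1, 2, 1, 2])
        assert cv.rand_index(pc) == pytest.approx(1 / 3)
        assert cv.wallace_homogeneity(pc) == 0.0
        assert cv.wallace_completeness(pc) == 0.0

    def test_single_cluster_prediction(self):
        pc, _ = _pc_ct(["A", "A", "B", "B"], [1, 1, 1, 1])
        assert cv.rand_index(pc) == pytest.approx(1 / 3)
        assert cv.wallace_homogeneity(pc) == pytest.approx(1 / 3)
        assert cv.wallace_completeness(pc) == 1.0

    def test_all_singletons_raises(self):
        pc, _ = _pc_ct(["A", "A"], [1, 2])
        with pytest.raises(UndefinedMetricError):
            cv.wallace_homogeneity(pc)


class TestAdjustedIndices:
    def test_ari_examples(self):
        pc, _ = _pc_ct(["A", "A", "B", "B"], [1, 2, 1, 2])
        assert cv.adjusted_rand_index(pc) == pytest.approx(-0.5)
        pc, _ = _pc_ct(["A", "B", "A", "B"], [1, 1, 1, 1])
        assert cv.adjusted_rand_index(pc) == 0.0
        pc, _ = _pc_ct(["A", "A", "B"], ["A", "A", "B"])
        assert cv.adjusted_rand_index(pc) == 1.0

    def test_ari_both_trivial(self):
        pc, _ = _pc_ct(["A", "A"], [1, 1])
        assert cv.adjusted_rand_index(pc) == 1.0

    def test_adjusted_wallace_example(self):
        pc, ct = _pc_ct(["A", "A", "B", "B"], [1, 2, 1, 2])
        awh, awc = cv.adjusted_wallace(pc, ct)
        assert awc == pytest.approx(-0.5)
        assert awh == pytest.approx(-0.5)

    def test_trivial_partition_raises(self):
        pc, ct = _pc_ct(["A", "A", "B", "B"], [1, 1, 1, 1])
        with pytest.raises(UndefinedMetricError):
            cv.adjusted_wallace(pc, ct)

    def test_ari_matches_sklearn(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 80))
            t = random_hard_partition(rng, n, int(rng.integers(2, 6)))
            p = random_hard_partition(rng, n, int(rng.integers(2, 6)))
            pc, _ = _pc_ct(t, p)
            assert cv.adjusted_rand_index(pc) == pytest.approx(
                skm.adjusted_rand_score(t.codes, p.codes), abs=1e-12)

    def test_ari_is_harmonic_mean_of_adjusted_wallace(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 60))
            t = random_hard_partition(rng, n, int(rng.integers(2, 5)))
            p = random_hard_partition(rng, n, int(rng.integers(2, 5)))
            pc, ct = _pc_ct(t, p)
            awh, awc = cv.adjusted_wallace(pc, ct)
            if abs(awh + awc) < 1e-12:
                continue
            hm = 2 * awh * awc / (awh + awc)
            assert cv.adjusted_rand_index(pc) == pytest.approx(hm, abs=1e-10)


class TestNCR:
    def test_identical(self):
        assert cv.ncr(cv.contingency([0, 0, 1, 1], [0, 0, 1, 1])) == 1.0

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            cv.ncr(cv.contingency(["A", "A"], [1, 2]))

    def test_raw_value_matches_per_class_enumeration(self, rng):
        # oracle: enumerate pairs per ground-truth class directly
        for _ in range(10):
            n = int(rng.integers(8, 30))
            t = random_hard_partition(rng, n, 3)
            p = random_hard_partition(rng, n, 3)
            concordances = []
            for cls in range(3):
                good = tot = 0
                for i in range(n):
                    for j in range(i + 1, n):
                        in_i, in_j = t.codes[i] == cls, t.codes[j] == cls
                        if not (in_i or in_j):
                            continue
                        tot += 1
                        same_t = t.codes[i] == t.codes[j]
                        same_p = p.codes[i] == p.codes[j]
                        if same_t == same_p:
                            good += 1
                concordances.append(good / tot)
            ct = cv.contingency(t, p)
            assert _ncr_raw(ct) == pytest.approx(np.mean(concordances), abs=1e-12)

    def test_penalizes_small_class_errors_more(self):
        # classes of size 2 and 6; one element misassigned either from the
        # small or from the large class
        truth = ["S"] * 2 + ["L"] * 6
        err_small = ["L"] + ["S"] * 1 + ["L"] * 6          # small-class element absorbed
        err_large = ["S"] * 2 + ["S"] + ["L"] * 5          # large-class element absorbed
        ncr_small = cv.ncr(cv.contingency(truth, err_small), seed=7)
        ncr_large = cv.ncr(cv.contingency(truth, err_large), seed=7)
        assert ncr_small < ncr_large
        # whereas ARI prefers the error in the small class less strongly
        ari_small = cv.adjusted_rand_index(cv.pair_counts(cv.contingency(truth, err_small)))
        ari_large = cv.adjusted_rand_index(cv.pair_counts(cv.contingency(truth, err_large)))
        assert (ncr_large - ncr_small) > (ari_large - ari_small)


class TestEntropySuite:
    def test_identical_balanced(self):
        res = cv.entropy_suite(cv.contingency(["A", "A", "B", "B"], [1, 1, 2, 2]))
        assert res["MI"] == pytest.approx(1.0)  # 1 bit
        for k in ("EH", "EC", "VM", "NMI", "AMI"):
            assert res[k] == pytest.approx(1.0)

    def test_single_cluster_prediction(self):
        res = cv.entropy_suite(cv.contingency(["A", "A", "B", "B"], [1, 1, 1, 1]))
        assert res["MI"] == 0.0
        assert res["EH"] == 0.0
        assert res["EC"] == 1.0
        assert res["VM"] == 0.0

    def test_independent_margins(self):
        res = cv.entropy_suite(cv.contingency(["A", "A", "B", "B"], [1, 2, 1, 2]))
        assert res["MI"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            t = random_hard_partition(rng, n, int(rng.integers(2, 5)))
            p = random_hard_partition(rng, n, int(rng.integers(2, 5)))
            res = cv.entropy_suite(cv.contingency(t, p))
            assert res["EH"] == pytest.approx(skm.homogeneity_score(t.codes, p.codes), abs=1e-9)
            assert res["EC"] == pytest.approx(skm.completeness_score(t.codes, p.codes), abs=1e-9)
            assert res["VM"] == pytest.approx(skm.v_measure_score(t.codes, p.codes), abs=1e-9)
            assert res["NMI"] == pytest.approx(
                skm.normalized_mutual_info_score(t.codes, p.codes, average_method="arithmetic"),
                abs=1e-9)
            assert res["AMI"] == pytest.approx(
                skm.adjusted_mutual_info_score(t.codes, p.codes, average_method="arithmetic"),
                abs=1e-7)

    def test_mi_bounded_by_entropies(self, rng):
        for _ in range(20):
            t = random_hard_partition(rng, 40, 3)
            p = random_hard_partition(rng, 40, 4)
            ct = cv.contingency(t, p)
            res = cv.entropy_suite(ct)
            h_g = -np.sum([s / 40 * np.log2(s / 40) for s in ct.row_sums])
            h_p = -np.sum([s / 40 * np.log2(s / 40) for s in ct.col_sums])
            assert -1e-12 <= res["MI"] <= min(h_g, h_p) + 1e-12


class TestWeightedFMeasure:
    def test_identical(self):
        assert cv.weighted_f_measure(cv.contingency(["A", "B"], [1, 2])) == 1.0

    def test_merged_classes(self):
        ct = cv.contingency(["A", "A", "B", "B"], [1, 1, 1, 1])
        assert cv.weighted_f_measure(ct) == pytest.approx(2 / 3)

    def test_class_size_weighting(self):
        # class A (3 elements) matched perfectly, class B (1 element) absorbed
        ct = cv.contingency(["A", "A", "A", "B"], [1, 1, 1, 1])
        # class A: precision 3/4, recall 1 -> F = 6/7; class B: p 1/4, r 1 -> F = 2/5
        expected = 0.75 * (6 / 7) + 0.25 * (2 / 5)
        assert cv.weighted_f_measure(ct) == pytest.approx(expected)


class TestRangesAndProperties:
    def test_printed_ranges_on_random_pairs(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 50))
            t = random_hard_partition(rng, n, int(rng.integers(2, 5)))
            p = random_hard_partition(rng, n, int(rng.integers(2, 5)))
            pc, ct = _pc_ct(t, p)
            unit = [cv.rand_index(pc), cv.wallace_homogeneity(pc),
                    cv.wallace_completeness(pc), cv.weighted_f_measure(ct)]
            res = cv.entropy_suite(ct)
            unit += [res["EH"], res["EC"], res["VM"], res["NMI"]]
            assert all(-1e-9 <= v <= 1 + 1e-9 for v in unit)
            awh, awc = cv.adjusted_wallace(pc, ct)
            signed = [cv.adjusted_rand_index(pc), awh, awc, res["AMI"]]
            assert all(-1 - 1e-9 <= v <= 1 + 1e-9 for v in signed)

    def test_homogeneity_metrics_invariant_to_pure_split(self):
        # splitting a pure cluster in two leaves WH, MI, EH unchanged
        truth = ["A"] * 4 + ["B"] * 4
        merged = [1] * 4 + [2] * 4
        split = [1] * 4 + [2, 2, 3, 3]
        pc_m, ct_m = _pc_ct(truth, merged)
        pc_s, ct_s = _pc_ct(truth, split)
        assert cv.wallace_homogeneity(pc_m) == cv.wallace_homogeneity(pc_s) == 1.0
        em, es = cv.entropy_suite(ct_m), cv.entropy_suite(ct_s)
        assert em["MI"] == pytest.approx(es["MI"])
        assert em["EH"] == pytest.approx(es["EH"]) == 1.0
        # completeness metrics must drop
        assert cv.wallace_completeness(pc_s) < cv.wallace_completeness(pc_m)

    def test_chance_neutrality_direction(self, rng):
        # adjusted metrics center on 0; raw RI/WC/EC do not
        aris, awcs, ris, wcs = [], [], [], []
        for _ in range(150):
            t = random_hard_partition(rng, 100, 4)
            p = random_hard_partition(rng, 100, 4)
            pc, ct = _pc_ct(t, p)
            aris.append(cv.adjusted_rand_index(pc))
            awcs.append(cv.adjusted_wallace(pc, ct)[1])
            ris.append(cv.rand_index(pc))
            wcs.append(cv.wallace_completeness(pc))
        for vals in (aris, awcs):
            se = np.std(vals) / np.sqrt(len(vals))
            assert abs(np.mean(vals)) < 3 * se
        assert np.mean(ris) > 0.5
        assert np.mean(wcs) > 0.1
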