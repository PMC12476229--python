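import numpy as np
import pytest

import clustival as cv
from clustival.simulate import _grid_coords

from conftest import random_hard_partition


@pytest.fixture(scope="module")
def grid12():
    toy = cv.grid_toy(cv.GridToyConfig(width=12, height=12, n_errors=4))
    ctx = cv.spatial_neighbors(toy["coords"], 4)
    return toy, ctx


class TestSpatialNeighbors:
    def test_unit_grid_k4_is_rook_adjacency(self):
        # on a grid large enough for interior spots to dominate the
        # median, the k=4 radius is the grid spacing -> rook adjacency
        coords = _grid_coords(10, 10)
        ctx = cv.spatial_neighbors(coords, 4)
        assert ctx.radius == pytest.approx(1.0)
        center = 5 * 10 + 5
        got = sorted(ctx.neighbors[center].tolist())
        assert got == sorted([center - 1, center + 1, center - 10, center + 10])

    def test_border_spots_have_fewer_neighbors(self):
        coords = _grid_coords(10, 10)
        ctx = cv.spatial_neighbors(coords, 4)
        assert len(ctx.neighbors[0]) == 2        # corner
        assert len(ctx.neighbors[5 * 10 + 5]) == 4

    def test_scaling_coordinates_preserves_neighbors(self):
        coords = _grid_coords(6, 4)
        c1 = cv.spatial_neighbors(coords, 4)
        c2 = cv.spatial_neighbors(coords * 2.0, 4)
        assert c2.radius == pytest.approx(2 * c1.radius)
        for a, b in zip(c1.neighbors, c2.neighbors):
            assert sorted(a.tolist()) == sorted(b.tolist())

    def test_identical_coords_raise(self):
        with pytest.raises(cv.InputError):
            cv.spatial_neighbors(np.zeros((5, 2)), 2)


class TestSmoothLabels:
    def test_half_and_half_neighborhood(self):
        # spot A with neighbors {A, A, B, B} at alpha = 0.5
        coords = np.array([[0.0, 0.0], [1, 0], [-1, 0], [0, 1], [0, -1]])
        ctx = cv.spatial_neighbors(coords, 4)
        W = cv.smooth_labels(["A", "A", "A", "B", "B"], ctx, 0.5)
        assert W.W[0].tolist() == [0.75, 0.25]

    def test_alpha_one_recovers_hard_labels(self, grid12):
        toy, ctx = grid12
        W = cv.smooth_labels(toy["truth"], ctx, 1.0)
        np.testing.assert_array_equal(W.W, toy["truth"].one_hot())

    def test_total_disagreement_gives_self_weight(self):
        # default alpha = 0.5: a spot with no agreeing neighbor keeps
        # exactly half of its own-label membership
        lab = ["B"] * 9
        lab[4] = "A"
        ctx = cv.spatial_neighbors(_grid_coords(3, 3), 4)
        W = cv.smooth_labels(lab, ctx)
        assert W.W[4, W.categories.index("A")] == pytest.approx(0.5)


class TestNsPairMetrics:
    def test_perfect_prediction_scores_one(self, grid12):
        toy, ctx = grid12
        res = cv.ns_pair_metrics(toy["truth"], toy["truth"], ctx, adjusted=False)
        assert res["nsRI"] == 1.0
        assert res["nsWC"] == 1.0
        assert res["nsWH"] == 1.0

    def test_alpha_one_collapses_to_crisp(self, grid12):
        toy, ctx = grid12
        pred = toy["predictions"]["P2"]
        res = cv.ns_pair_metrics(toy["truth"], pred, ctx, alpha_self=1.0, adjusted=False)
        pc = cv.pair_counts(cv.contingency(toy["truth"], pred))
        assert res["nsRI"] == pytest.approx(cv.rand_index(pc), abs=1e-12)
        assert res["nsWC"] == pytest.approx(cv.wallace_completeness(pc), abs=1e-12)
        assert res["nsWH"] == pytest.approx(cv.wallace_homogeneity(pc), abs=1e-12)

    def test_boundary_errors_preferred_over_interior(self, grid12):
        toy, ctx = grid12
        r_bound = cv.ns_pair_metrics(toy["truth"], toy["predictions"]["P1"], ctx,
                                     n_perm=30, seed=0)
        r_inter = cv.ns_pair_metrics(toy["truth"], toy["predictions"]["P2"], ctx,
                                     n_perm=30, seed=0)
        for key in ("nsRI", "nsWC", "nsWH", "nsARI", "nsAWC", "nsAWH"):
            assert r_bound[key] > r_inter[key]

    def test_interior_placement_invariance(self, grid12):
        toy, ctx = grid12
        rs = [cv.ns_pair_metrics(toy["truth"], toy["predictions"][p], ctx, adjusted=False)
              for p in ("P2", "P3", "P4")]
        for key in ("nsRI", "nsWC", "nsWH"):
            assert rs[0][key] == pytest.approx(rs[1][key], abs=1e-12)
            assert rs[0][key] == pytest.approx(rs[2][key], abs=1e-12)


class TestSpatialRiAri:
    def test_original_mode_weight_at_zero_distance(self):
        p = cv.SpatialDecayParams(mode="original")
        assert p.f(0.0) == pytest.approx(0.8)

    def test_modified_decay_rate_constant(self):
        p = cv.SpatialDecayParams()
        d1, d2 = 0.15, 0.6
        slope = -(np.log(p.f(d2)) - np.log(p.f(d1))) / (d2 - d1)
        assert slope == pytest.approx(4.0)

    def test_zero_alpha_equals_rand_index(self, grid12, rng):
        toy, _ = grid12
        pred = random_hard_partition(rng, toy["truth"].n, 3)
        res = cv.spatial_ri_ari(toy["truth"], pred, toy["coords"],
                                cv.SpatialDecayParams(alpha=0.0), adjusted=False)
        ri = cv.rand_index(cv.pair_counts(cv.contingency(toy["truth"], pred)))
        assert res["spatialRI"] == pytest.approx(ri, abs=1e-12)

    def test_all_zero_distances_closed_form(self, rng):
        # coincident spots (plus one distinct to define a scale): the
        # original-mode spatial RI adds alpha per wrongly-grouped pair
        t = [0, 0, 1, 1]
        p = [0, 0, 0, 0]
        coords = np.zeros((4, 2))
        res = cv.spatial_ri_ari(t, p, coords, cv.SpatialDecayParams(mode="original"),
                                adjusted=False)
        pc = cv.pair_counts(cv.contingency(t, p))
        ri = cv.rand_index(pc)
        frac_wrongly_grouped = pc.c / pc.n_pairs
        assert res["spatialRI"] == pytest.approx(ri + 0.8 * frac_wrongly_grouped)

    @pytest.mark.parametrize("mode", ["original", "modified"])
    def test_decay_monotonicity(self, mode):
        p = cv.SpatialDecayParams(mode=mode)
        d = np.linspace(0.0, 1.4, 40)
        assert (np.diff(p.f(d)) < 0).all()
        assert (np.diff(p.h(d)) > 0).all()

    def test_ari_decreases_with_error_domain_separation(self, grid12):
        # the same wrongly-labeled block, placed farther from the domain
        # it is assigned to, is penalized more
        toy, _ = grid12
        near = cv.spatial_ri_ari(toy["truth"], toy["predictions"]["P4"], toy["coords"])
        far = cv.spatial_ri_ari(toy["truth"], toy["predictions"]["P2"], toy["coords"])
        assert near["spatialARI"] > far["spatialARI"]
        assert near["spatialRI"] > far["spatialRI"]


class TestPas:
    def test_uniform_map_is_zero(self, grid12):
        _, ctx = grid12
        assert cv.pas(["A"] * ctx.n, ctx)["dataset"] == 0.0

    def test_checkerboard_is_one(self):
        toy = cv.grid_toy(cv.GridToyConfig(width=8, height=8, layout="checkerboard"))
        ctx = cv.spatial_neighbors(toy["coords"], 4)
        assert cv.pas(toy["truth"], ctx)["dataset"] == 1.0

    def test_constructed_abnormal_fraction(self):
        # 10x10 single-domain grid with 7 isolated flipped spots: each
        # flipped spot disagrees with all rook neighbors, and no normal
        # spot gains a strict majority of disagreeing neighbors
        coords = _grid_coords(10, 10)
        lab = np.array(["A"] * 100, dtype=object)
        for cx, cy in [(1, 1), (4, 1), (7, 1), (1, 5), (4, 5), (7, 5), (4, 8)]:
            lab[cy * 10 + cx] = "B"
        ctx = cv.spatial_neighbors(coords, 4)
        assert cv.pas(lab, ctx)["dataset"] == pytest.approx(0.07)


class TestChaos:
    def test_interleaved_labeling_scores_higher(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, size=(80, 2))
        compact = (coords[:, 0] > 5).astype(int)
        interleaved = np.arange(80) % 2
        assert cv.chaos(interleaved, coords)["dataset"] > \
            cv.chaos(compact, coords)["dataset"]

    def test_unit_line_single_domain(self):
        coords = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        res = cv.chaos(["A"] * 6, coords)
        assert res["dataset"] == pytest.approx(1 / 5)  # normalized spacing

    def test_duplicated_spots_reduce_score(self):
        coords = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        doubled = np.vstack([coords, coords])
        res = cv.chaos(["A"] * 12, doubled)
        assert res["dataset"] == pytest.approx(0.0)


class TestElsa:
    def test_homogeneous_neighborhood_zero(self, grid12):
        _, ctx = grid12
        with pytest.warns(UserWarning):
            scores = cv.elsa(["A"] * ctx.n, ctx)["element"]
        assert np.nanmax(scores) == 0.0

    def test_two_two_split_hand_value(self):
        # center spot A, 4 rook neighbors split 2 A / 2 B, binary d:
        # E_a = 0.5, E_c = 1, ELSA = 0.5
        coords = np.array([[0.0, 0.0], [1, 0], [-1, 0], [0, 1], [0, -1]])
        ctx = cv.spatial_neighbors(coords, 4)
        scores = cv.elsa(["A", "A", "A", "B", "B"], ctx)["element"]
        assert scores[0] == pytest.approx(0.5)

    def test_uniform_category_mix_max_entropy(self):
        coords = np.array([[0.0, 0.0], [1, 0], [-1, 0], [0, 1], [0, -1]])
        ctx = cv.spatial_neighbors(coords, 4)
        scores = cv.elsa(["A", "B", "B", "C", "C"], ctx)["element"]
        # neighborhood uniform over 2 of min(3, 4) categories; E_c =
        # entropy(0.5, 0.5) / log2(3); E_a = 1
        assert scores[0] == pytest.approx(1.0 / np.log2(3))

    def test_scores_in_unit_interval(self, grid12, rng):
        toy, ctx = grid12
        lab = random_hard_partition(rng, ctx.n, 4)
        s = cv.elsa(lab, ctx)["element"]
        assert np.nanmin(s) >= 0 and np.nanmax(s) <= 1


class TestSpc:
    def test_identical_partitions_all_one(self):
        assert (cv.spc([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0).all()

    def test_mean_equals_rand_index(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 100))
            t = random_hard_partition(rng, n, 3)
            p = random_hard_partition(rng, n, 3)
            ri = cv.rand_index(cv.pair_counts(cv.contingency(t, p)))
            assert cv.spc(t, p).mean() == pytest.approx(ri, abs=1e-12)

    def test_same_combination_same_score(self, rng):
        t = random_hard_partition(rng, 50, 3)
        p = random_hard_partition(rng, 50, 3)
        s = cv.spc(t, p)
        for g in range(3):
            for c in range(3):
                sel = (t.codes == g) & (p.codes == c)
                if sel.sum() > 1:
                    assert np.ptp(s[sel]) == 0.0

    def test_exclude_negatives_variant(self):
        s = cv.spc([0, 0, 1, 1], [0, 1, 2, 3], exclude_negatives=True)
        # element 0: pairs (0,1) same-class split (counted, discordant),
        # (0,2) and (0,3) diff-diff (excluded) -> 0/1
        assert s[0] == 0.0

    def test_spatial_spc_bounds_and_perfect(self, grid12):
        toy, ctx = grid12
        s = cv.spatial_spc(toy["truth"], toy["truth"], ctx)
        assert (s == 1.0).all()
        s2 = cv.spatial_spc(toy["truth"], toy["predictions"]["P1"], ctx)
        assert s2.min() >= 0 and s2.max() <= 1


class TestNsAccuracy:
    def test_perfect_prediction(self, grid12):
        toy, ctx = grid12
        assert cv.ns_accuracy(toy["truth"], toy["truth"], ctx) == 1.0

    def test_misassigned_spot_counts_neighbor_fraction(self):
        # center spot predicted B while 2 of its 4 neighbors are truly B
        coords = np.array([[0.0, 0.0], [1, 0], [-1, 0], [0, 1], [0, -1]])
        ctx = cv.spatial_neighbors(coords, 4)
        truth = ["A", "A", "A", "B", "B"]
        pred = ["B", "A", "A", "B", "B"]
        expected = (4 + 2 / 4) / 5
        assert cv.ns_accuracy(truth, pred, ctx) == pytest.approx(expected)

    def test_interior_error_far_from_predicted_domain(self, grid12):
        toy, ctx = grid12
        # P2's interior errors sit wholly inside domain A: each
        # misclassified spot has no truly-B neighbor
        acc = cv.ns_accuracy(toy["truth"], toy["predictions"]["P2"], ctx)
        n = toy["truth"].n
        assert acc == pytest.approx((n - 4) / n)

    def test_boundary_beats_interior(self, grid12):
        toy, ctx = grid12
        a1 = cv.ns_accuracy(toy["truth"], toy["predictions"]["P1"], ctx)
        a2 = cv.ns_accuracy(toy["truth"], toy["predictions"]["P2"], ctx)
        a3 = cv.ns_accuracy(toy["truth"], toy["predictions"]["P3"], ctx)
        assert a1 > a2
        assert a2 == pytest.approx(a3, abs=1e-12)

    def test_hungarian_matching_of_disjoint_vocabulary(self, grid12):
        toy, ctx = grid12
        relabeled = np.where(
            np.array([toy["truth"].categories[c] for c in toy["truth"].codes]) == "A",
            "c1", "c2")
        assert cv.ns_accuracy(toy["truth"], relabeled, ctx) == 1.0
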