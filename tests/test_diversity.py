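"""Diversity panel: aggregation, evenness, ordination, PD, FRic."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from commassembly import (
    CommunityMatrix,
    SurveyDetections,
    bray_curtis,
    faith_pd,
    fric,
    nmds,
    ordination_transform,
    read_newick,
    richness_evenness,
    simulate_tree,
    summarize,
    survey_aggregate,
)
from commassembly.simulate import SimConfig, simulate_dataset


class TestSurveyAggregate:
    def test_max_over_repeats_single_transect(self):
        counts = np.array([[[2, 0], [1, 3]]])  # 1 transect, 2 repeats, 2 species
        det = SurveyDetections(counts, ["a", "b"])
        assert survey_aggregate(det).tolist() == [2, 3]

    def test_sum_of_transect_maxima(self):
        counts = np.array(
            [[[2, 3], [1, 1]], [[1, 0], [0, 1]]]
        )  # transect maxima (2,3) and (1,1)
        det = SurveyDetections(counts, ["a", "b"])
        assert survey_aggregate(det).tolist() == [3, 4]

    def test_single_repeat_identity(self):
        counts = np.array([[[4, 1, 0]]])
        det = SurveyDetections(counts, ["a", "b", "c"])
        assert survey_aggregate(det).tolist() == [4, 1, 0]


class TestRichnessEvenness:
    def test_equal_abundances_maximally_even(self):
        sr, se = richness_evenness(np.array([3, 3, 3, 3]))
        assert sr == 4
        assert se == pytest.approx(1.0)

    def test_hand_shannon_value(self):
        sr, se = richness_evenness(np.array([1, 1, 2]))
        assert sr == 3
        assert se == pytest.approx(0.9464, abs=1e-4)

    def test_single_species_undefined(self):
        sr, se = richness_evenness(np.array([5]))
        assert sr == 1
        assert np.isnan(se)


class TestOrdinationTransform:
    def test_hand_two_by_two(self):
        rel = pd.DataFrame([[0.8, 0.2], [0.2, 0.8]], columns=["x", "y"])
        # sqrt of (4,1)/(1,4) pattern then column-max then row-sum scaling
        m = ordination_transform(rel * 5)  # same after internal use of values
        expect = np.array([[2 / 3, 1 / 3], [1 / 3, 2 / 3]])
        assert np.allclose(m.to_numpy(), expect)

    def test_column_maxima_unity_before_row_scaling(self):
        rng = np.random.default_rng(0)
        rel = pd.DataFrame(rng.random((4, 6)))
        m = np.sqrt(rel.to_numpy())
        m = m / m.max(axis=0)
        assert np.allclose(m.max(axis=0), 1.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        rel = pd.DataFrame(rng.random((5, 8)))
        out = ordination_transform(rel)
        assert np.allclose(out.sum(axis=1), 1.0)


class TestBrayCurtis:
    def test_hand_value(self):
        m = pd.DataFrame([[1, 2, 0], [0, 2, 4]])
        assert bray_curtis(m).data[0, 1] == pytest.approx(5 / 9)

    def test_identical_and_disjoint(self):
        m = pd.DataFrame([[1, 2], [1, 2], [0, 0]])
        m.iloc[2] = [3, 0]
        m2 = pd.DataFrame([[1, 2, 0, 0], [0, 0, 3, 1]])
        assert bray_curtis(m).data[0, 1] == 0.0
        assert bray_curtis(m2).data[0, 1] == 1.0

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.integers(0, 20, size=(6, 10)))
        d = bray_curtis(m).data
        assert (d >= 0).all() and (d <= 1).all()
        assert np.array_equal(d, d.T)


class TestNMDS:
    def test_three_points_embed_exactly(self):
        d = DistanceMatrix(
            np.array([[0, 1, 2], [1, 0, 1.5], [2, 1.5, 0]]), ids=list("abc")
        )
        with pytest.warns(UserWarning, match="zero stress"):
            res = nmds(d, k_dims=2, seed=0)
        assert res.stress < 1e-4

    def test_euclidean_input_near_zero_stress(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 2))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(7)])
        assert nmds(d, seed=1).stress < 1e-3

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 4))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(8)])
        a = nmds(d, seed=5)
        b = nmds(d, seed=5)
        assert a.stress == b.stress
        assert np.array_equal(a.coordinates.to_numpy(), b.coordinates.to_numpy())


class TestFaithPD:
    def test_hand_edge_sums(self, three_tip_tree):
        assert faith_pd(three_tip_tree, {"A", "B"}) == 3.0
        assert faith_pd(three_tip_tree, {"A", "B"}, include_root=False) == 2.0
        assert faith_pd(three_tip_tree, {"A", "B", "C"}) == 5.0

    def test_matches_frozen_picante_values(self, five_tip_tree):
        # reference values computed independently with R picante::pd
        assert faith_pd(five_tip_tree, {"A", "B", "E"}) == pytest.approx(5.0)
        assert faith_pd(five_tip_tree, {"B", "C", "D"}) == pytest.approx(3.9)

    def test_monotone_under_species_addition(self):
        rng = np.random.default_rng(6)
        t = simulate_tree(20, seed=6)
        labels = t.tip_labels
        community = set(rng.choice(labels, 4, replace=False))
        pd_prev = faith_pd(t, community)
        for extra in labels:
            if extra in community:
                continue
            community.add(extra)
            pd_next = faith_pd(t, community)
            assert pd_next >= pd_prev - 1e-12
            pd_prev = pd_next
        assert pd_prev == pytest.approx(t.total_branch_length)

    def test_empty_community_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            faith_pd(three_tip_tree, set())


class TestFRic:
    def test_unit_square_and_triangle(self):
        coords = pd.DataFrame(
            [[0, 0], [1, 0], [0, 1], [1, 1]], index=list("abcd"),
            columns=["PCo1", "PCo2"],
        )
        assert fric(coords, ["a", "b", "c", "d"]) == pytest.approx(1.0)
        assert fric(coords, ["a", "b", "c"]) == pytest.approx(0.5)

    def test_hull_monotone_under_subsets(self):
        rng = np.random.default_rng(7)
        coords = pd.DataFrame(
            rng.normal(size=(20, 2)), index=[f"s{i}" for i in range(20)],
            columns=["PCo1", "PCo2"],
        )
        pool_vol = fric(coords, coords.index)
        sub_vol = fric(coords, coords.index[:8])
        assert sub_vol <= pool_vol + 1e-12

    def test_small_community_reduces_dimension(self):
        coords = pd.DataFrame(
            np.arange(12).reshape(4, 3), index=list("abcd"),
            columns=["PCo1", "PCo2", "PCo3"],
        )
        with pytest.warns(UserWarning, match="axes"):
            v = fric(coords, ["a", "b", "c"])  # 3 points in 3 axes -> 2 axes
        assert v >= 0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_monte_carlo_hull_area(self, seed):
        """Hull area agrees with a hit-or-miss Monte Carlo estimate."""
        from scipy.spatial import Delaunay

        rng = np.random.default_rng(40 + seed)
        pts = rng.normal(size=(12, 2))
        coords = pd.DataFrame(pts, index=[f"s{i}" for i in range(12)],
                              columns=["PCo1", "PCo2"])
        vol = fric(coords, coords.index)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        box = np.prod(hi - lo)
        sample = rng.uniform(lo, hi, size=(200_000, 2))
        inside = Delaunay(pts).find_simplex(sample) >= 0
        estimate = box * inside.mean()
        assert vol == pytest.approx(estimate, rel=0.02)


@pytest.fixture(scope="module")
def study():
    cfg = SimConfig(n_species=40, seed=17,
                    richness={("high", "wintering"): 12,
                              ("high", "breeding"): 14,
                              ("mid", "wintering"): 12,
                              ("mid", "breeding"): 12,
                              ("low", "wintering"): 10,
                              ("low", "breeding"): 12})
    return simulate_dataset(cfg)


class TestSummarize:

    def test_six_rows_and_invariants(self, study):
        cm = CommunityMatrix(study.observed.astype(int), study.metadata)
        out = summarize(cm, study.tree, study.traits)
        assert out.shape[0] == 6
        assert (out["SR"] >= 1).all()
        assert out["SE"].between(0, 1).all()
        assert (out["PD"] >= 0).all()
        assert (out["FRic"] >= 0).all()
        assert (out["PW"].between(0, 1)).all()

    def test_zero_abundance_species_is_inert(self, study):
        cm = CommunityMatrix(study.observed.astype(int), study.metadata)
        out1 = summarize(cm, study.tree, study.traits)
        padded = study.observed.astype(int).copy()
        # a species recorded in the table but never observed
        dead = [s for s in padded.columns if padded[s].sum() == 0]
        if not dead:
            pytest.skip("every species observed in this draw")
        cm2 = CommunityMatrix(padded.drop(columns=dead[:1]), study.metadata)
        out2 = summarize(cm2, study.tree, study.traits)
        pd.testing.assert_frame_equal(out1, out2)
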