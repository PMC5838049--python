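"""Simulators: tree shape, trait signal endpoints, assembly regimes, surveys."""

import numpy as np
import pandas as pd
import pytest

from commassembly import (
    AssemblyRegime,
    SimConfig,
    assemble_community,
    gower,
    simulate_binary_traits,
    simulate_continuous_traits,
    simulate_dataset,
    simulate_survey,
    simulate_tree,
    survey_aggregate,
    write_newick,
)


class TestSimulateTree:
    def test_tip_count_and_binary_shape(self):
        t = simulate_tree(5, seed=0)
        assert t.n_tips == 5
        assert t.n_nodes == 9  # binary tree: n tips + n-1 internals

    def test_ultrametric_with_positive_edges(self):
        t = simulate_tree(40, seed=2)
        assert t.is_ultrametric
        assert np.nanmin(t.lengths[: t.root]) > 0

    def test_seed_determinism(self):
        assert write_newick(simulate_tree(12, seed=9)) == write_newick(
            simulate_tree(12, seed=9)
        )
        assert write_newick(simulate_tree(12, seed=9)) != write_newick(
            simulate_tree(12, seed=10)
        )

    def test_too_few_species(self):
        with pytest.raises(ValueError):
            simulate_tree(1)


class TestContinuousTraits:
    def test_lambda_zero_decorrelates_sisters(self):
        """With no signal the sister tips of a deep cherry are uncorrelated;
        at lambda=1 their Brownian covariance equals the MRCA depth."""
        from commassembly import read_newick

        t = read_newick("((A:0.1,B:0.1):9.9,C:10);")
        x0 = simulate_continuous_traits(t, 1000, 0.0, seed=1).data.T
        x1 = simulate_continuous_traits(t, 1000, 1.0, seed=2).data.T
        cov0 = np.cov(x0["A"], x0["B"])[0, 1]
        cov1 = np.cov(x1["A"], x1["B"])[0, 1]
        assert abs(cov0) < 0.5  # theoretical 0, tip variance 10
        assert cov1 == pytest.approx(9.9, abs=1.0)

    def test_star_tree_iid_tips(self):
        from commassembly import read_newick

        t = read_newick("(A:1,B:1,C:1,D:1);")
        x = simulate_continuous_traits(t, 2000, 1.0, seed=3).data
        c = np.corrcoef(x.to_numpy())
        off = c[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_lambda_out_of_range(self, tree128):
        with pytest.raises(ValueError):
            simulate_continuous_traits(tree128, 1, 1.5)

    def test_determinism(self, tree128):
        a = simulate_continuous_traits(tree128, 3, 0.7, seed=5).data
        b = simulate_continuous_traits(tree128, 3, 0.7, seed=5).data
        pd.testing.assert_frame_equal(a, b)


class TestBinaryTraits:
    def test_prevalence_realized_exactly(self, tree128):
        tt = simulate_binary_traits(tree128, 10, 1.0, 0.5, seed=4)
        assert (tt.data.sum(axis=0) == 64).all()

    def test_degenerate_prevalence_rejected(self, tree128):
        with pytest.raises(ValueError):
            simulate_binary_traits(tree128, 1, 1.0, 0.001)
        with pytest.raises(ValueError):
            simulate_binary_traits(tree128, 1, 1.0, 1.0)


@pytest.fixture(scope="module")
def pool():
    tree = simulate_tree(60, seed=21)
    cont = simulate_continuous_traits(tree, 2, 1.0, seed=22)
    binr = simulate_binary_traits(tree, 15, 1.0, 0.5, seed=23)
    from commassembly import TraitTable

    traits = TraitTable(
        pd.concat([cont.data, binr.data], axis=1),
        {**cont.types, **binr.types},
    )
    return traits, gower(traits).data


class TestAssembleCommunity:

    @staticmethod
    def _mean_pairwise(gd, idx):
        sub = gd[np.ix_(idx, idx)]
        return sub[~np.eye(len(idx), dtype=bool)].mean()

    def test_richness_and_minimum_abundance(self, pool):
        traits, _ = pool
        row = assemble_community(traits, AssemblyRegime("neutral"), 20, seed=1)
        assert (row > 0).sum() == 20
        assert row[row > 0].min() >= 1
        assert row.dtype.kind == "i"

    def test_richness_exceeding_pool_rejected(self, pool):
        traits, _ = pool
        with pytest.raises(ValueError):
            assemble_community(traits, AssemblyRegime("neutral"), 61)

    def test_determinism(self, pool):
        traits, _ = pool
        a = assemble_community(traits, AssemblyRegime("filtering", 5.0), 20, seed=3)
        b = assemble_community(traits, AssemblyRegime("filtering", 5.0), 20, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_filtering_contracts_trait_space(self, pool):
        """Strong filtering pulls mean pairwise Gower distance below the
        pool-random expectation in nearly all draws."""
        traits, gd = pool
        rng = np.random.default_rng(0)
        sp = {s: i for i, s in enumerate(traits.species)}
        rand_means = [
            self._mean_pairwise(gd, rng.choice(60, 20, replace=False))
            for _ in range(300)
        ]
        expect = np.mean(rand_means)
        hits = 0
        for s in range(100):
            row = assemble_community(
                traits, AssemblyRegime("filtering", 30.0), 20, seed=s
            )
            idx = [sp[s_] for s_ in row.index[row > 0]]
            hits += self._mean_pairwise(gd, idx) < expect
        assert hits >= 90

    def test_limiting_similarity_expands_trait_space(self, pool):
        traits, gd = pool
        rng = np.random.default_rng(1)
        sp = {s: i for i, s in enumerate(traits.species)}
        expect = np.mean(
            [
                self._mean_pairwise(gd, rng.choice(60, 20, replace=False))
                for _ in range(300)
            ]
        )
        hits = 0
        for s in range(100):
            row = assemble_community(
                traits, AssemblyRegime("limiting_similarity", 30.0), 20, seed=s
            )
            idx = [sp[s_] for s_ in row.index[row > 0]]
            hits += self._mean_pairwise(gd, idx) > expect
        assert hits >= 90


class TestSurvey:
    def test_perfect_detection_single_transect(self):
        truth = pd.Series([3, 0, 5], index=["a", "b", "c"])
        det = simulate_survey(truth, n_transects=1, n_repeats=4, detect_p=1.0, seed=0)
        assert (det.counts == truth.to_numpy()).all()
        agg = survey_aggregate(det)
        pd.testing.assert_series_equal(agg, truth.rename("abundance"))

    def test_zero_detection_all_zero(self):
        truth = pd.Series([3, 2], index=["a", "b"])
        det = simulate_survey(truth, detect_p=0.0, seed=0)
        assert det.counts.sum() == 0

    def test_aggregate_bounded_by_truth(self):
        truth = pd.Series([10, 4, 7], index=["a", "b", "c"])
        det = simulate_survey(truth, n_transects=3, n_repeats=8, detect_p=0.6, seed=5)
        agg = survey_aggregate(det)
        assert (agg <= truth).all()


class TestDatasetBundle:
    def test_bit_identical_under_seed(self):
        cfg = SimConfig(n_species=30, seed=8,
                        richness={("high", "wintering"): 10,
                                  ("high", "breeding"): 12,
                                  ("mid", "wintering"): 10,
                                  ("mid", "breeding"): 10,
                                  ("low", "wintering"): 9,
                                  ("low", "breeding"): 11})
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert write_newick(a.tree) == write_newick(b.tree)
        pd.testing.assert_frame_equal(a.traits.data, b.traits.data)
        pd.testing.assert_frame_equal(a.observed, b.observed)

    def test_study_shape(self):
        cfg = SimConfig(n_species=40, seed=3,
                        richness={("high", "wintering"): 12,
                                  ("high", "breeding"): 14,
                                  ("mid", "wintering"): 12,
                                  ("mid", "breeding"): 12,
                                  ("low", "wintering"): 10,
                                  ("low", "breeding"): 12})
        study = simulate_dataset(cfg)
        assert study.truth.shape == (6, 40)
        assert study.traits.data.shape == (40, 17)
        assert set(study.metadata["season"]) == {"wintering", "breeding"}
        # survey estimates never exceed the truth
        assert (study.observed.to_numpy() <= study.truth.to_numpy()).all()
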