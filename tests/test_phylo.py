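import itertools

import numpy as np
import pandas as pd
import pytest

import phylocomm as pc
from phylocomm.io import parse_tree_newick
from phylocomm.phylo import _holm_progressive

from conftest import distance_dict, naive_alpha_mpd, naive_beta_mpd


class TestCopheneticDistances:
    def test_two_tip(self):
        dm = pc.cophenetic_distances(parse_tree_newick("(A:1,B:1);"))
        d = distance_dict(dm)
        assert d[("A", "B")] == pytest.approx(2.0)

    def test_nested_path_sums(self, dm4):
        d = distance_dict(dm4)
        assert d[("A", "B")] == pytest.approx(2.0)
        assert d[("A", "C")] == pytest.approx(4.0)
        assert d[("C", "D")] == pytest.approx(2.0)

    def test_zero_diagonal_and_symmetry(self, big_dm):
        assert np.abs(np.diag(big_dm.values)).max() == 0.0
        np.testing.assert_allclose(big_dm.values, big_dm.values.T)


class TestAlphaMpd:
    def test_two_taxa_equals_their_distance(self, dm4):
        for w in (0.5, 0.9):
            f = pd.Series({"A": w, "B": 1 - w})
            assert pc.alpha_mpd(f, dm4) == pytest.approx(2.0)

    def test_printed_formula_example(self):
        dm = pc.DistanceMatrix(("x", "y", "z"),
                               np.array([[0, 2, 4], [2, 0, 2], [4, 2, 0]],
                                        dtype=float))
        f = pd.Series({"x": 0.5, "y": 0.25, "z": 0.25})
        # 0.5*mean(2,4) + 0.25*mean(2,2) + 0.25*mean(4,2) = 2.75
        assert pc.alpha_mpd(f, dm) == pytest.approx(2.75)

    def test_order_invariance(self, dm4):
        f1 = pd.Series({"A": 0.2, "C": 0.3, "D": 0.5})
        f2 = f1.loc[["D", "A", "C"]]
        assert pc.alpha_mpd(f1, dm4) == pytest.approx(pc.alpha_mpd(f2, dm4))

    def test_singleton_undefined(self, dm4):
        assert np.isnan(pc.alpha_mpd(pd.Series({"A": 1.0}), dm4))

    @pytest.mark.parametrize("n_tips,seed", [(3, 0), (4, 1), (5, 2), (6, 3)])
    def test_matches_naive_oracle_exhaustively(self, n_tips, seed):
        tree = pc.simulate_yule_tree(n_tips, seed)
        dm = pc.cophenetic_distances(tree)
        d = distance_dict(dm)
        rng = np.random.default_rng(seed + 100)
        tips = list(dm.ids)
        for r in range(2, n_tips + 1):
            for combo in itertools.combinations(tips, r):
                w = rng.dirichlet(np.ones(r))
                f = dict(zip(combo, w))
                fs = pd.Series(f)
                assert pc.alpha_mpd(fs, dm) == pytest.approx(
                    naive_alpha_mpd(f, d), abs=1e-12)


class TestAlphaMpdProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_convex_combination_of_pair_distances(self, dm4, weights):
        # focal-weighted MPD is a convex combination of per-focal partner
        # means, so it lies within the present-taxon pair-distance range
        taxa = list(dm4.ids)[:len(weights)]
        f = pd.Series(weights, index=taxa)
        sub = dm4.loc(taxa)
        off = sub[np.triu_indices(len(taxa), k=1)]
        val = pc.alpha_mpd(f, dm4)
        assert off.min() - 1e-12 <= val <= off.max() + 1e-12

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=4),
           st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_branch_length_scaling_is_exact(self, dm4, weights, c):
        taxa = list(dm4.ids)[:len(weights)]
        f = pd.Series(weights, index=taxa)
        scaled = pc.DistanceMatrix(dm4.ids, dm4.values * c)
        assert pc.alpha_mpd(f, scaled) == pytest.approx(
            c * pc.alpha_mpd(f, dm4), rel=1e-12)


class TestEnvironmentalOptimum:
    def test_single_sample_otu(self):
        f = pd.DataFrame({"o1": [0.4, 0.0], "o2": [0.6, 1.0]},
                         index=["s1", "s2"])
        env = pd.Series({"s1": 5.0, "s2": 9.0})
        opt = pc.environmental_optimum(f, env)
        assert opt["o1"] == pytest.approx(5.0)

    def test_equal_counts_weighted_mean(self):
        f = pd.DataFrame({"o1": [0.5, 0.5]}, index=["s1", "s2"])
        env = pd.Series({"s1": 4.0, "s2": 8.0})
        assert pc.environmental_optimum(f, env)["o1"] == pytest.approx(6.0)

    def test_constant_env(self):
        f = pd.DataFrame({"o1": [0.3, 0.7], "o2": [0.7, 0.3]},
                         index=["s1", "s2"])
        env = pd.Series({"s1": 7.0, "s2": 7.0})
        np.testing.assert_allclose(pc.environmental_optimum(f, env), 7.0)

    def test_absent_otu_excluded(self):
        f = pd.DataFrame({"o1": [1.0], "gone": [0.0]}, index=["s1"])
        opt = pc.environmental_optimum(f, pd.Series({"s1": 2.0}))
        assert "gone" not in opt.index


class TestPhylogenyPoolNull:
    def test_pool_equals_richness_is_permutation(self, dm4):
        f = pd.Series({"A": 0.7, "B": 0.3})
        null = pc.phylogeny_pool_null(f, ["A", "B"], seed=1)
        assert set(null.index) == {"A", "B"}
        assert sorted(null.values) == sorted(f.values)

    def test_conserves_sum_and_richness(self, dm4):
        f = pd.Series({"A": 0.5, "C": 0.25, "D": 0.25})
        null = pc.phylogeny_pool_null(f, list(dm4.ids), seed=2)
        assert null.sum() == pytest.approx(1.0)
        assert len(null) == 3

    def test_uniform_pair_frequencies(self, dm4):
        f = pd.Series({"A": 0.6, "B": 0.4})
        rng = np.random.default_rng(3)
        from collections import Counter

        counts = Counter()
        n = 10_000
        for _ in range(n):
            null = pc.phylogeny_pool_null(f, list(dm4.ids), rng=rng)
            counts[frozenset(null.index)] += 1
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        for pair in itertools.combinations("ABCD", 2):
            freq = counts[frozenset(pair)] / n
            assert abs(freq - 1 / 6) < 3 * se + 1e-12


class TestAlphaNri:
    def test_exhaustive_null_mean_four_tips(self, dm4):
        # 2-taxon communities from a 4-taxon pool: 6 pairs with MPD values
        # (2,2,4,4,4,4) -> null mean 10/3
        f = pd.Series({"A": 0.5, "B": 0.5})
        res = pc.alpha_nri(f, dm4, n_rand=10_000, seed=11)
        assert res.null_mean == pytest.approx(10 / 3, rel=0.02)
        assert res.observed == pytest.approx(2.0)
        assert res.nri > 0          # within-clade pair: clustered
        assert res.nri == -res.ses

    def test_cross_clade_pair_negative_nri(self, dm4):
        res = pc.alpha_nri(pd.Series({"A": 0.5, "C": 0.5}), dm4,
                           n_rand=5000, seed=12)
        assert res.observed == pytest.approx(4.0)
        assert res.nri < 0

    def test_singleton_flagged(self, dm4):
        res = pc.alpha_nri(pd.Series({"A": 1.0}), dm4, n_rand=10, seed=1)
        assert res.flagged and np.isnan(res.nri)

    def test_null_sd_zero_flagged(self):
        # star tree with equal branch lengths: every pair at distance 2
        star = parse_tree_newick("(A:1,B:1,C:1,D:1);")
        dm = pc.cophenetic_distances(star)
        res = pc.alpha_nri(pd.Series({"A": 0.5, "B": 0.5}), dm,
                           n_rand=50, seed=1)
        assert res.flagged and np.isnan(res.ses)

    def test_scale_invariance(self, big_dm, big_optima):
        # multiplying branch lengths by c scales MPD by c, leaves NRI alone
        f = pd.Series(0.0, index=list(big_dm.ids))
        rng = np.random.default_rng(21)
        chosen = rng.choice(len(f), 40, replace=False)
        f.iloc[chosen] = rng.dirichlet(np.ones(40))
        scaled = pc.DistanceMatrix(big_dm.ids, big_dm.values * 3.0)
        a = pc.alpha_nri(f, big_dm, n_rand=199, seed=33)
        b = pc.alpha_nri(f, scaled, n_rand=199, seed=33)
        assert b.observed == pytest.approx(3.0 * a.observed, rel=1e-12)
        assert b.nri == pytest.approx(a.nri, rel=1e-9)


class TestBetaMpd:
    def test_identical_singletons_zero(self, dm4):
        a = pd.Series({"A": 1.0})
        assert pc.beta_mpd(a, a, dm4) == 0.0

    def test_disjoint_singletons(self, dm4):
        assert pc.beta_mpd(pd.Series({"A": 1.0}), pd.Series({"B": 1.0}),
                           dm4) == pytest.approx(2.0)

    def test_mixed_weights(self, dm4):
        v = pc.beta_mpd(pd.Series({"A": 0.5, "B": 0.5}),
                        pd.Series({"A": 1.0}), dm4)
        assert v == pytest.approx(1.0)

    def test_empty_sample_rejected(self, dm4):
        with pytest.raises(ValueError):
            pc.beta_mpd(pd.Series({"A": 0.0}), pd.Series({"B": 1.0}), dm4)

    @pytest.mark.parametrize("n_tips,seed", [(4, 4), (5, 5), (6, 6)])
    def test_matches_naive_oracle(self, n_tips, seed):
        tree = pc.simulate_yule_tree(n_tips, seed)
        dm = pc.cophenetic_distances(tree)
        d = distance_dict(dm)
        rng = np.random.default_rng(seed)
        tips = list(dm.ids)
        for _ in range(30):
            r1 = rng.integers(1, n_tips + 1)
            r2 = rng.integers(1, n_tips + 1)
            c1 = rng.choice(tips, r1, replace=False)
            c2 = rng.choice(tips, r2, replace=False)
            f1 = dict(zip(c1, rng.dirichlet(np.ones(r1))))
            f2 = dict(zip(c2, rng.dirichlet(np.ones(r2))))
            assert pc.beta_mpd(pd.Series(f1), pd.Series(f2), dm) == \
                pytest.approx(naive_beta_mpd(f1, f2, d), abs=1e-12)


class TestBetaNri:
    def test_formula_identity(self, dm4):
        res = pc.beta_nri(pd.Series({"A": 0.5, "B": 0.5}),
                          pd.Series({"C": 0.6, "D": 0.4}), dm4,
                          n_rand=500, seed=9)
        assert res.beta_nri == pytest.approx(
            (res.beta_mpd_observed - res.null_mean) / res.null_sd, abs=1e-12)

    def test_filtered_same_environment_pairs_converge(self, big_tree, big_dm,
                                                      big_optima):
        from phylocomm.synth import AssemblyScenario

        sd = float(big_optima.std(ddof=1))
        sc = AssemblyScenario("filtering", 500, 80, filter_breadth=0.2 * sd,
                              env_value=1.5 * sd)
        rng = np.random.default_rng(41)
        below = 0
        for _ in range(8):
            p1 = pc.assemble_community(big_tree, big_optima, sc, rng=rng)
            p2 = pc.assemble_community(big_tree, big_optima, sc, rng=rng)
            res = pc.beta_nri(p1, p2, big_dm, n_rand=199, seed=rng)
            below += res.beta_nri < -2
        assert below >= 7


class TestGroupMeanBeta:
    def _results(self):
        return pd.DataFrame([
            {"sample_i": "a1", "sample_j": "a2", "beta_mpd_observed": 0.5,
             "beta_nri": -3.0},
            {"sample_i": "b1", "sample_j": "b2", "beta_mpd_observed": 0.52,
             "beta_nri": -4.0},
            {"sample_i": "b1", "sample_j": "b3", "beta_mpd_observed": 0.54,
             "beta_nri": -5.0},
            {"sample_i": "b2", "sample_j": "b3", "beta_mpd_observed": 0.56,
             "beta_nri": -6.0},
        ])

    def _meta(self):
        return pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B",
                          "b3": "B", "lonely": "C"})

    def test_group_of_two_mean_is_pair_value(self):
        out = pc.group_mean_beta(self._results(), self._meta())
        row = out[out.group == "A"].iloc[0]
        assert row["mean"] == pytest.approx(0.5)
        assert row["sd"] == 0.0
        assert row["n_pairs"] == 1

    def test_three_members_three_pairs(self):
        out = pc.group_mean_beta(self._results(), self._meta())
        row = out[out.group == "B"].iloc[0]
        assert row["n_pairs"] == 3
        assert row["mean"] == pytest.approx(0.54)

    def test_four_replicates_six_pairs(self, dm4, big_dm):
        f = pd.DataFrame(
            np.random.default_rng(1).dirichlet(np.ones(4), size=4),
            index=["r1", "r2", "r3", "r4"], columns=list(dm4.ids))
        res = pc.beta_nri_pairs(f, dm4, n_rand=19, seed=2)
        meta = pd.Series({s: "G" for s in f.index})
        out = pc.group_mean_beta(res, meta)
        assert out.iloc[0]["n_pairs"] == 6

    def test_display_format(self):
        out = pc.group_mean_beta(self._results(), self._meta())
        assert out.iloc[0]["display"].count("±") == 1

    def test_singleton_group_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            out = pc.group_mean_beta(self._results(), self._meta())
        assert "C" not in set(out.group)


class TestMantelCorrelogram:
    def test_holm_progressive_monotone_in_k(self):
        assert _holm_progressive([0.01]) == [pytest.approx(0.01)]
        adj = _holm_progressive([0.04, 0.01, 0.5])
        assert adj[0] == pytest.approx(0.04)
        # class 2 corrected within the first two tests: 0.01 is the smaller
        # of (0.04, 0.01), so its Holm factor is 2
        assert adj[1] == pytest.approx(0.02)
        assert adj[2] == pytest.approx(0.5)

    def test_conserved_traits_significant_at_short_distances(self):
        tree = pc.simulate_yule_tree(60, 51)
        opt = pc.evolve_trait_bm(tree, 1.0, 0.0, 52)
        dm = pc.cophenetic_distances(tree)
        dopt = pc.trait_distance_matrix(opt.loc[list(dm.ids)])
        classes = pc.mantel_correlogram(dm, dopt, n_classes=20, n_perm=99,
                                        seed=53)
        first = [c for c in classes if c.n_pairs > 0][:3]
        assert any(c.significant and c.mantel_r > 0 for c in first)

    def test_type_one_rate_with_permuted_traits(self):
        tree = pc.simulate_yule_tree(40, 61)
        opt = pc.evolve_trait_bm(tree, 1.0, 0.0, 62)
        dm = pc.cophenetic_distances(tree)
        rng = np.random.default_rng(63)
        vals = opt.loc[list(dm.ids)].to_numpy()
        sig = tot = 0
        for _ in range(25):
            shuffled = pd.Series(rng.permutation(vals), index=list(dm.ids))
            classes = pc.mantel_correlogram(
                dm, pc.trait_distance_matrix(shuffled), n_classes=20,
                n_perm=99, seed=rng.integers(2 ** 31))
            for c in classes:
                if np.isfinite(c.mantel_r):
                    tot += 1
                    sig += c.significant
        assert sig / tot <= 0.10

    def test_empty_classes_flagged_not_raised(self, dm4):
        dopt = pc.trait_distance_matrix(
            pd.Series([0.0, 1.0, 2.0, 3.0], index=list(dm4.ids)))
        classes = pc.mantel_correlogram(dm4, dopt, n_classes=10, n_perm=19,
                                        seed=1)
        assert len(classes) == 10
        empties = [c for c in classes if c.n_pairs == 0]
        assert empties and all(np.isnan(c.mantel_r) for c in empties)
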