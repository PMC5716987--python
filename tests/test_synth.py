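import io as _io

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import phylocomm as pc
from phylocomm.io import parse_tree_newick
from phylocomm.synth import AssemblyScenario, default_design


def _newick(tree):
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


class TestYuleTree:
    def test_two_tips(self):
        tree = pc.simulate_yule_tree(2, 0)
        assert tree.count(tips=True) == 2
        internals = [n for n in tree.traverse(include_self=True)
                     if not n.is_tip()]
        assert len(internals) == 1

    def test_binary_node_count_and_depth(self):
        tree = pc.simulate_yule_tree(64, 5)
        assert tree.count(tips=True) == 64
        internals = [n for n in tree.traverse(include_self=True)
                     if not n.is_tip()]
        assert len(internals) == 63
        depths = [tip.accumulate_to_ancestor(tree) for tip in tree.tips()]
        assert min(depths) > 0

    def test_deterministic(self):
        assert _newick(pc.simulate_yule_tree(20, 7)) == \
            _newick(pc.simulate_yule_tree(20, 7))

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            pc.simulate_yule_tree(1, 0)


class TestBrownianTrait:
    def test_sigma_zero_is_root_value(self):
        tree = pc.simulate_yule_tree(10, 1)
        opt = pc.evolve_trait_bm(tree, 0.0, 3.5, 2)
        assert (opt == 3.5).all()

    def test_negative_sigma_errors(self):
        tree = pc.simulate_yule_tree(4, 1)
        with pytest.raises(ValueError):
            pc.evolve_trait_bm(tree, -1.0)

    def test_deterministic(self):
        tree = pc.simulate_yule_tree(12, 3)
        a = pc.evolve_trait_bm(tree, 1.0, 0.0, 9)
        b = pc.evolve_trait_bm(tree, 1.0, 0.0, 9)
        pd.testing.assert_series_equal(a, b)

    def test_two_tip_variance_matches_closed_form(self):
        # Var(tipA - tipB) = sigma2 * (pathA + pathB) for independent branches
        tree = parse_tree_newick("(A:0.7,B:1.3);")
        sigma2 = 2.0
        diffs = [
            (lambda o: o["A"] - o["B"])(pc.evolve_trait_bm(tree, sigma2, 0.0, s))
            for s in range(4000)
        ]
        expected = sigma2 * 2.0
        assert np.var(diffs) == pytest.approx(expected, rel=0.10)


class TestAssembleCommunity:
    def test_neutral_full_pool(self):
        tree = pc.simulate_yule_tree(8, 1)
        opt = pc.evolve_trait_bm(tree, 1.0, 0.0, 2)
        sc = AssemblyScenario("neutral", 8, 8)
        prof = pc.assemble_community(tree, opt, sc, seed=3)
        assert set(prof.index) == set(opt.index)
        assert prof.sum() == pytest.approx(1.0)

    def test_wide_filter_matches_neutral_distribution(self):
        # filter_breadth -> infinity: chosen-taxon optima indistinguishable
        # from neutral draws (two-sample KS over 500 draws each)
        tree = pc.simulate_yule_tree(40, 11)
        opt = pc.evolve_trait_bm(tree, 1.0, 0.0, 12)
        wide = AssemblyScenario("filtering", 40, 5, filter_breadth=1e9)
        neutral = AssemblyScenario("neutral", 40, 5)
        rng = np.random.default_rng(13)
        got_w, got_n = [], []
        for _ in range(500):
            got_w += list(opt[pc.assemble_community(tree, opt, wide,
                                                    rng=rng).index])
            got_n += list(opt[pc.assemble_community(tree, opt, neutral,
                                                    rng=rng).index])
        assert sps.ks_2samp(got_w, got_n).pvalue > 0.01

    def test_overdispersion_greedy_picks_cross_clade(self, balanced4):
        opt = pd.Series(0.0, index=["A", "B", "C", "D"])
        sc = AssemblyScenario("overdispersion", 4, 2)
        rng = np.random.default_rng(5)
        for _ in range(40):
            chosen = set(pc.assemble_community(balanced4, opt, sc,
                                               rng=rng).index)
            # cross-clade pairs have distance 4, within-clade 2
            assert chosen not in ({"A", "B"}, {"C", "D"})

    def test_filtering_with_no_eligible_taxa(self):
        tree = pc.simulate_yule_tree(6, 1)
        # optima so far from env that all weights underflow to zero
        opt = pd.Series(1e6, index=[t.name for t in tree.tips()])
        sc = AssemblyScenario("filtering", 6, 3, filter_breadth=1e-3,
                              env_value=0.0)
        opt.iloc[0] = 0.0  # a single eligible taxon, need 3
        with pytest.raises(ValueError, match="eligible|weight"):
            pc.assemble_community(tree, opt, sc, seed=2)


class TestCountsFromProfile:
    def test_depth_zero_disallowed(self):
        with pytest.raises(ValueError):
            pc.counts_from_profile([1.0], 0, seed=1)

    def test_point_mass(self):
        counts = pc.counts_from_profile([1.0, 0.0], 100, seed=1)
        assert counts.tolist() == [100, 0]

    def test_frequencies_within_three_se(self):
        p = np.array([0.5, 0.3, 0.2])
        depth = 10_000
        counts = pc.counts_from_profile(p, depth, seed=4)
        se = np.sqrt(p * (1 - p) * depth)
        assert (np.abs(counts - depth * p) < 3 * se + 1e-9).all()


class TestCorrelatedCounts:
    def test_identity_basis_near_zero_correlation(self):
        cc = pc.generate_correlated_counts(np.eye(20), 200, 20, 20_000, seed=1)
        r = np.corrcoef(cc.log_basis, rowvar=False)
        np.fill_diagonal(r, 0)
        assert np.abs(r).max() < 0.2

    def test_planted_pair_recovered_in_log_basis(self):
        corr = np.eye(10)
        corr[1, 4] = corr[4, 1] = 0.9
        cc = pc.generate_correlated_counts(corr, 500, 10, 20_000, seed=2)
        r = np.corrcoef(cc.log_basis, rowvar=False)
        assert r[1, 4] == pytest.approx(0.9, abs=0.05)

    def test_deterministic(self):
        a = pc.generate_correlated_counts(np.eye(5), 10, 5, 1000, seed=3)
        b = pc.generate_correlated_counts(np.eye(5), 10, 5, 1000, seed=3)
        assert a.table == b.table

    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99],
                        [0.99, 1.0, 0.99],
                        [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="semi-definite"):
            pc.generate_correlated_counts(bad, 10, 3, 100, seed=1)


class TestMakeStudy:
    def test_default_design_28_samples(self):
        study = pc.make_study(n_tips=60, n_taxa_community=20, seed=1)
        assert study.table.shape[0] == 28
        assert len(study.truth) == 28
        assert set(study.metadata.groups) == {
            "Control", "NK", "NP", "NPK", "OM", "OMN", "PK"}
        # every table OTU is a tree tip
        tips = {t.name for t in study.tree.tips()}
        assert set(study.table.otu_ids) <= tips

    def test_all_neutral_design(self):
        design = {g: AssemblyScenario("neutral", 40, 10)
                  for g in ("a", "b")}
        study = pc.make_study(n_tips=40, design=design, seed=2)
        assert all(v["process"] == "neutral" for v in study.truth.values())

    def test_same_seed_byte_identical_on_disk(self, tmp_path):
        for sub in ("x", "y"):
            pc.make_study(n_tips=40, n_taxa_community=12,
                          seed=9).write(tmp_path / sub)
        for fname in ("otu_table.tsv", "tree.nwk", "metadata.tsv",
                      "truth.json", "optima.tsv"):
            assert (tmp_path / "x" / fname).read_bytes() == \
                (tmp_path / "y" / fname).read_bytes(), fname

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            pc.make_study(n_tips=40, design={}, seed=1)

    def test_gradient_design_breadths_ordered(self):
        design = default_design(100, 30, trait_sd=1.0)
        assert design["NK"].filter_breadth < design["Control"].filter_breadth
        assert design["PK"].filter_breadth == max(
            s.filter_breadth for s in design.values())
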