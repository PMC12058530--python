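"""Fitch parsimony, recall and breakpoint permutation enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from heterokit import invphylo, synthio


class TestSpeciesTree:
    def test_default_tree_leaves_and_lengths(self, ape_tree):
        assert set(ape_tree.leaf_names()) == {
            "human", "chimpanzee", "bonobo", "gorilla",
            "Bornean_orangutan", "Sumatran_orangutan",
        }
        lengths = {b.branch_id: b.length for b in ape_tree.branches()}
        assert lengths["chimpanzee"] == pytest.approx(1.7)
        assert lengths["Bornean_orangutan"] == pytest.approx(0.9)
        assert lengths["human"] == pytest.approx(6.0)
        assert lengths["gorilla"] == pytest.approx(10.75)

    def test_siamang_variant_adds_outgroup(self):
        tree = invphylo.default_ape_tree(include_siamang=True)
        assert "siamang" in tree.leaf_names()
        clades = {b.branch_id: set(b.clade) for b in tree.branches()}
        assert clades["siamang"] == {"siamang"}

    def test_newick_round_trip(self, ape_tree):
        again = invphylo.SpeciesTree.from_newick(ape_tree.to_newick())
        assert set(again.leaf_names()) == set(ape_tree.leaf_names())
        assert again.total_length() == pytest.approx(ape_tree.total_length())

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError):
            invphylo.SpeciesTree.from_newick("(a:-1,b:1);")


def _brute_force_min_changes(tree, states):
    """Minimum changes over all internal labellings, root fixed to 0."""
    nodes = list(tree.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    root = tree.tree.seed_node
    best = None
    for assignment in itertools.product([0, 1], repeat=len(internal)):
        labels = dict(zip((id(n) for n in internal), assignment))
        if labels[id(root)] != 0:
            continue
        for leaf in (n for n in nodes if n.is_leaf()):
            name = invphylo.SpeciesTree._label(leaf)
            labels[id(leaf)] = states.get(name)
        changes = 0
        for node in nodes:
            if node.parent_node is None:
                continue
            a, b = labels[id(node)], labels[id(node.parent_node)]
            if a is not None and b is not None and a != b:
                changes += 1
        best = changes if best is None else min(best, changes)
    return best


class TestFitchAssign:
    def test_singleton_assigned_to_terminal_branch(self):
        tree = invphylo.default_ape_tree(include_siamang=True)
        char = {leaf: 0 for leaf in tree.leaf_names()}
        char["siamang"] = 1
        changes, branch, recurrent = invphylo.fitch_assign(char, tree)
        assert (changes, branch, recurrent) == (1, "siamang", False)

    def test_pan_clade_assigned_to_ancestral_branch(self, ape_tree):
        char = {leaf: 0 for leaf in ape_tree.leaf_names()}
        char["chimpanzee"] = char["bonobo"] = 1
        changes, branch, recurrent = invphylo.fitch_assign(char, ape_tree)
        assert (changes, branch, recurrent) == (1, "pan", False)

    def test_discordant_character_is_recurrent(self, ape_tree):
        char = {leaf: 0 for leaf in ape_tree.leaf_names()}
        char["chimpanzee"] = char["gorilla"] = 1
        changes, branch, recurrent = invphylo.fitch_assign(char, ape_tree)
        assert changes >= 2 and branch is None and recurrent

    def test_all_absent_character_needs_no_change(self, ape_tree):
        char = {leaf: 0 for leaf in ape_tree.leaf_names()}
        assert invphylo.fitch_assign(char, ape_tree)[0] == 0

    def test_all_missing_rejected(self, ape_tree):
        char = {leaf: None for leaf in ape_tree.leaf_names()}
        with pytest.raises(ValueError):
            invphylo.fitch_assign(char, ape_tree)

    def test_matches_brute_force_on_all_64_characters(self, ape_tree):
        leaves = ape_tree.leaf_names()
        for bits in itertools.product([0, 1], repeat=6):
            char = dict(zip(leaves, bits))
            changes = invphylo._sankoff_min_changes(ape_tree, char)
            assert changes == _brute_force_min_changes(ape_tree, char), char

    def test_missing_leaves_pruned(self, ape_tree):
        char = {leaf: 0 for leaf in ape_tree.leaf_names()}
        char["chimpanzee"] = 1
        char["bonobo"] = None  # only chimp visible: single terminal gain
        changes, branch, recurrent = invphylo.fitch_assign(char, ape_tree)
        assert changes == 1 and not recurrent
        assert branch in ("chimpanzee", "pan")  # clades identical once pruned

    def test_heterozygous_treated_as_missing_in_table_assignment(self, ape_tree):
        row = {"event": "inv0"}
        for leaf in ape_tree.leaf_names():
            row[f"{leaf}_hap1"] = "reference"
            row[f"{leaf}_hap2"] = "reference"
        row["gorilla_hap1"] = "inverted"  # heterozygous
        char = invphylo.genotypes_to_character(row, ape_tree.leaf_names())
        assert char["gorilla"] is None
        char_inc = invphylo.genotypes_to_character(
            row, ape_tree.leaf_names(), het_as_present=True
        )
        assert char_inc["gorilla"] == 1

    def test_simulation_round_trip_recovers_every_branch(self, ape_tree):
        cfg = synthio.SimConfig(
            inversion=synthio.InversionConfig(n_events=200, recurrent_fraction=0.0)
        )
        geno, truth = synthio.simulate_inversions_on_tree(ape_tree, cfg, seed=3)
        assign = invphylo.assign_inversions(geno, ape_tree)
        merged = assign.merge(truth, on="event", suffixes=("", "_truth"))
        assert (merged["branch"] == merged["branches"]).all()
        assert not merged["recurrent"].any()

    def test_recurrent_fraction_reflected_in_assignment_rate(self, ape_tree):
        cfg = synthio.SimConfig(
            inversion=synthio.InversionConfig(n_events=400, recurrent_fraction=0.3)
        )
        geno, truth = synthio.simulate_inversions_on_tree(ape_tree, cfg, seed=13)
        assign = invphylo.assign_inversions(geno, ape_tree)
        frac_assigned = assign["assigned"].mean()
        # nested double-hits can still look single-branch, so allow slack
        assert 0.6 <= frac_assigned <= 0.85


class TestBranchRegression:
    def test_proportional_counts_r2_one(self):
        slope, r2 = invphylo.branch_count_regression([2, 4, 6], [1, 2, 3])
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_counts_r2_zero(self):
        _, r2 = invphylo.branch_count_regression([5, 5, 5], [1, 2, 3])
        assert r2 == pytest.approx(0.0)

    def test_zero_length_variance_rejected(self):
        with pytest.raises(ValueError):
            invphylo.branch_count_regression([1, 2, 3], [2, 2, 2])

    def test_poisson_simulation_reaches_high_r2(self, ape_tree):
        cfg = synthio.SimConfig(
            inversion=synthio.InversionConfig(n_events=500, recurrent_fraction=0.0)
        )
        _, truth = synthio.simulate_inversions_on_tree(ape_tree, cfg, seed=9)
        counts = truth["branches"].value_counts()
        branches = ape_tree.branches()
        y = [counts.get(b.branch_id, 0) for b in branches]
        x = [b.length for b in branches]
        _, r2 = invphylo.branch_count_regression(y, x)
        assert r2 > 0.8


class TestRecall:
    def _calls(self, ivs, chrom="chr1"):
        return pd.DataFrame(
            [dict(chrom=chrom, start=s, end=e) for s, e in ivs]
        )

    def test_identical_lists_full_recall(self):
        calls = self._calls([(100, 200), (500, 900)])
        n, pct = invphylo.recall_vs_previous(calls, calls)
        assert (n, pct) == (2, 100.0)

    def test_disjoint_lists_zero_recall(self):
        cur = self._calls([(100, 200)])
        prev = self._calls([(5_000, 6_000)])
        assert invphylo.recall_vs_previous(cur, prev) == (0, 0.0)

    def test_reciprocal_threshold_enforced(self):
        # overlap 100 of prev(1000) and of cur(110): recip = 0.1 vs 0.91
        cur = self._calls([(900, 1_010)])
        prev = self._calls([(0, 1_000)])
        assert invphylo.recall_vs_previous(cur, prev)[0] == 0
        cur = self._calls([(400, 1_100)])  # overlap 600: 0.6 and 0.857
        assert invphylo.recall_vs_previous(cur, prev)[0] == 1

    def test_empty_previous_rejected(self):
        with pytest.raises(ValueError):
            invphylo.recall_vs_previous(self._calls([(1, 2)]), self._calls([]))

    def test_invariant_under_joint_coordinate_shift(self):
        rng = np.random.default_rng(4)
        starts = rng.integers(0, 1_000_000, 30)
        cur = self._calls([(s, s + 10_000) for s in starts])
        prev = self._calls([(s + 3_000, s + 13_000) for s in starts[:20]])
        base = invphylo.recall_vs_previous(cur, prev)
        shift = 1_234_567
        cur2 = cur.assign(start=cur["start"] + shift, end=cur["end"] + shift)
        prev2 = prev.assign(start=prev["start"] + shift, end=prev["end"] + shift)
        assert invphylo.recall_vs_previous(cur2, prev2) == base


class TestEnrichment:
    LENGTHS = {"chr1": 10_000_000}

    # irregular spacing: breakpoint hits stay nearly independent under the
    # length-preserving null, matching the independence expectation
    FEATURE_STARTS = [350_000, 1_700_000, 2_200_000, 3_900_000, 4_550_000,
                      5_800_000, 6_350_000, 7_400_000, 8_150_000, 9_600_000]

    def _features_10pct(self):
        return pd.DataFrame([
            dict(chrom="chr1", start=s, end=s + 100_000)
            for s in self.FEATURE_STARTS
        ])

    def test_genome_wide_features_give_unit_fold(self):
        features = pd.DataFrame([dict(chrom="chr1", start=0, end=10_000_000)])
        inv = pd.DataFrame([
            dict(chrom="chr1", start=s, end=s + 50_000)
            for s in range(100_000, 2_000_000, 100_000)
        ])
        res = invphylo.breakpoint_feature_enrichment(
            inv, features, self.LENGTHS, n_perm=100, seed=1, pad_bp=0
        )
        assert res["fold"] == pytest.approx(1.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_empty_features_warn_and_p_one(self):
        inv = pd.DataFrame([dict(chrom="chr1", start=100, end=200_000)])
        with pytest.warns(UserWarning):
            res = invphylo.breakpoint_feature_enrichment(
                inv, pd.DataFrame(columns=["chrom", "start", "end"]),
                self.LENGTHS, n_perm=100, seed=1,
            )
        assert res["p_value"] == 1.0 and np.isnan(res["fold"])

    def test_constructed_enrichment_matches_analytic_expectation(self):
        """All 50 breakpoint pairs inside a 10% cover: fold near
        1 / (1 - 0.9^2) ~ 5.26 and P at the permutation floor."""
        rng = np.random.default_rng(42)
        feats = self._features_10pct()
        rows = []
        for _ in range(50):
            k1, k2 = sorted(rng.choice(10, 2, replace=False))
            s = self.FEATURE_STARTS[k1] + int(rng.integers(0, 100_000))
            e = self.FEATURE_STARTS[k2] + int(rng.integers(0, 100_000))
            rows.append(dict(chrom="chr1", start=s, end=e))
        inv = pd.DataFrame(rows)
        res = invphylo.breakpoint_feature_enrichment(
            inv, feats, self.LENGTHS, n_perm=1_000, seed=42, pad_bp=0
        )
        assert res["observed"] == 50
        assert 4.0 <= res["fold"] <= 7.0
        assert res["p_value"] <= 0.001

    def test_p_floor_with_plus_one_correction(self):
        inv = pd.DataFrame([dict(chrom="chr1", start=0, end=100_000)])
        res = invphylo.breakpoint_feature_enrichment(
            inv, self._features_10pct(), self.LENGTHS, n_perm=100, seed=2
        )
        assert res["p_value"] >= 1 / 101

    def test_gap_exclusion_respected(self):
        gaps = pd.DataFrame([dict(chrom="chr1", start=0, end=9_000_000)])
        feats = pd.DataFrame([dict(chrom="chr1", start=9_000_000, end=10_000_000)])
        inv = pd.DataFrame([dict(chrom="chr1", start=9_100_000, end=9_200_000)])
        res = invphylo.breakpoint_feature_enrichment(
            inv, feats, self.LENGTHS, gap_intervals=gaps, n_perm=100, seed=3,
            pad_bp=0,
        )
        # null placements squeezed into the feature-rich gap-free tail
        assert res["null_mean"] == pytest.approx(1.0)
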