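"""Physicochemical categorisation, window z-scores and convergence."""

import math

import pytest

import lineagesel as ls
from lineagesel.radicality_convergence import (
    AMINO_ACIDS,
    neutral_category_distribution,
    single_step_aa_pairs,
)
from lineagesel.substitution_mapping import SubstitutionEvent

from conftest import labeled_tree, make_alignment


def toy_property(values, default=0.0):
    row = {aa: default for aa in AMINO_ACIDS}
    row.update(values)
    return ls.PropertyTable(values={"toy": row})


def ns_event(branch, site, from_aa, to_aa, cls="foreground",
             from_codon="ATT", to_codon="GTT"):
    return SubstitutionEvent(
        branch_id=branch, parent_id="p", branch_class=cls, site=site,
        from_codon=from_codon, to_codon=to_codon, n_syn=0.0, n_nonsyn=1.0,
        from_aa=from_aa, to_aa=to_aa,
    )


class TestCategorizeChanges:
    def test_maximal_change_lands_in_category_8(self, mito):
        # W=8 against everything at 0; W<->others reachable (e.g. W<->R via CGA>TGA)
        cat_map = ls.categorize_changes(toy_property({"W": 8.0}), mito)
        pair = next(p for p in cat_map.categories["toy"] if "W" in p)
        assert cat_map.categories["toy"][pair] == 8

    def test_boundary_value_goes_to_higher_category(self, mito):
        # max |delta| = 8 -> width 1; a pair at exactly 5.0 sits on the 5/6 edge
        cat_map = ls.categorize_changes(
            toy_property({"W": 8.0, "C": 5.0}), mito
        )
        cw = cat_map.category("toy", "C", "G")  # |5-0| = 5.0, reachable TGT<->GGT
        assert cw == 6

    def test_known_bins_with_width_one(self, mito):
        props = toy_property({"W": 8.0, "S": 0.5, "P": 2.1, "H": 7.9})
        cat_map = ls.categorize_changes(props, mito)
        assert cat_map.category("toy", "S", "A") == 1   # 0.5 -> cat 1
        assert cat_map.category("toy", "P", "A") == 3   # 2.1 -> cat 3
        assert cat_map.category("toy", "H", "R") == 8   # 7.9 -> cat 8

    def test_symmetric_and_scale_invariant(self, mito):
        table = ls.load_property_table()
        cat_map = ls.categorize_changes(table, mito)
        for prop, cats in cat_map.categories.items():
            assert all(1 <= c <= 8 for c in cats.values())
        scaled = ls.PropertyTable(
            values={p: {aa: 3.0 * v for aa, v in row.items()}
                    for p, row in table.values.items()}
        )
        assert ls.categorize_changes(scaled, mito).categories == cat_map.categories

    def test_constant_property_rejected(self, mito):
        with pytest.raises(ValueError, match="constant"):
            ls.categorize_changes(toy_property({}), mito)

    def test_default_table_has_31_properties(self):
        assert len(ls.load_property_table().properties) == 31


class TestNeutralDistribution:
    def test_category_proportions_sum_to_one(self, mito):
        cat_map = ls.categorize_changes(ls.load_property_table(), mito)
        null = neutral_category_distribution(cat_map, mito)
        for prop, ps in null.items():
            assert sum(ps) == pytest.approx(1.0)
            assert all(p >= 0 for p in ps)

    def test_every_single_step_pair_categorised(self, mito):
        cat_map = ls.categorize_changes(ls.load_property_table(), mito)
        for pair in single_step_aa_pairs(mito):
            for prop in cat_map.categories:
                assert cat_map.categories[prop][pair] in range(1, 9)


class TestWindowZScores:
    def test_plugin_formula(self):
        # z = (n - N p) / sqrt(N p (1-p)) with N=10, p=0.1, n=5
        z = (5 - 10 * 0.1) / math.sqrt(10 * 0.1 * 0.9)
        assert z == pytest.approx(4.216370, abs=1e-5)

    def test_observed_equals_expected_gives_z_zero(self, mito):
        """An event mix matching the neutral proportions exactly yields z=0."""
        cat_map = ls.categorize_changes(ls.load_property_table(), mito)
        events = [ns_event("b1", 3, "I", "V")]
        scores = ls.window_z_scores(events, cat_map, mito, protein_length=30)
        null = neutral_category_distribution(cat_map, mito)
        for ws in scores:
            p_c = null[ws.property][ws.category - 1]
            expected_z = (ws.observed - 1 * p_c) / math.sqrt(p_c * (1 - p_c))
            assert ws.z == pytest.approx(expected_z)
            assert ws.p == pytest.approx(0.5) or ws.z != 0

    def test_windows_without_events_emit_nothing(self, mito):
        cat_map = ls.categorize_changes(ls.load_property_table(), mito)
        events = [ns_event("b1", 1, "I", "V")]
        scores = ls.window_z_scores(events, cat_map, mito, protein_length=100,
                                    window=20)
        assert all(ws.start <= 1 <= ws.start + 19 for ws in scores)

    def test_window_longer_than_protein_rejected(self, mito):
        cat_map = ls.categorize_changes(ls.load_property_table(), mito)
        with pytest.raises(ValueError, match="window"):
            ls.window_z_scores([], cat_map, mito, protein_length=10, window=20)

    def test_category_counts_partition_window_total(self, mito):
        cat_map = ls.categorize_changes(ls.load_property_table(), mito)
        events = [ns_event("b1", s, a, b) for s, (a, b) in
                  zip([2, 3, 5, 7], [("I", "V"), ("S", "P"), ("D", "N"), ("A", "T")])]
        scores = ls.window_z_scores(events, cat_map, mito, protein_length=10,
                                    window=10)
        by_prop = {}
        for ws in scores:
            by_prop.setdefault(ws.property, 0)
            by_prop[ws.property] += ws.observed
        # every property sees all 4 events across its categories
        assert set(by_prop.values()) == {4}


class TestRadicalEvents:
    def _burst_fixture(self, mito):
        """15 identical radical changes crammed into one 20-codon window,
        against a sparse benign background elsewhere."""
        table = toy_property({"W": 8.0, "R": 8.0})  # W<->R radical under toy
        cat_map = ls.categorize_changes(table, mito)
        assert cat_map.category("toy", "R", "G") == 8  # |8-0|
        burst = [ns_event(f"b{i}", 100 + (i % 10), "R", "G",
                          from_codon="CGT", to_codon="GGT") for i in range(15)]
        background = [ns_event(f"c{i}", 300 + 3 * i, "I", "V") for i in range(5)]
        zscores = ls.window_z_scores(burst + background, cat_map, mito,
                                     protein_length=381, window=20)
        return cat_map, burst, background, zscores

    def test_burst_flagged_background_not(self, mito):
        cat_map, burst, background, zscores = self._burst_fixture(mito)
        flagged = ls.radical_events(burst + background, zscores, cat_map=cat_map)
        assert set(map(id, burst)) <= set(map(id, flagged))
        assert not any(e in flagged for e in background)

    def test_low_category_event_never_flagged(self, mito):
        cat_map, burst, background, zscores = self._burst_fixture(mito)
        flagged = ls.radical_events(background, zscores, cat_map=cat_map)
        assert flagged == []


class TestFindConvergent:
    NEWICK = ("((f1:1,b1:1):1,((f2:1,b2:1):1,((f3:1,b3:1):1,"
              "((f4:1,f5:1):1,(b4:1,b5:1):1):1):1):1);")

    def _setup(self, mito, fg_with_pro, n_fg=5):
        """f1..f5 foreground; selected ones carry Pro (CCT) at site 2."""
        tree = labeled_tree(self.NEWICK, foreground={f"f{i}" for i in range(1, 6)})
        rows = {}
        for leaf in tree.leaf_taxa:
            codon = "CCT" if leaf in fg_with_pro else "TCT"  # Pro vs Ser
            rows[leaf] = ["ATT", codon]
        aln = make_alignment(rows)
        events = ls.map_events(ls.fitch_states(aln, tree), tree, mito)
        return tree, aln, events

    def test_three_independent_lineages_reported(self, mito):
        tree, aln, events = self._setup(mito, {"f1", "f2", "f3"})
        sites = ls.find_convergent(events, tree, aln, mito, min_lineages=3)
        assert len(sites) == 1
        hit = sites[0]
        assert (hit.site, hit.derived_aa, hit.n_lineages) == (2, "P", 3)

    def test_two_lineages_not_reported_at_min_three(self, mito):
        tree, aln, events = self._setup(mito, {"f1", "f2"})
        assert ls.find_convergent(events, tree, aln, mito, min_lineages=3) == []

    def test_shared_clade_counts_as_one_lineage(self, mito):
        tree, aln, events = self._setup(mito, {"f4", "f5"})
        assert ls.find_convergent(events, tree, aln, mito, min_lineages=3) == []
        sites = ls.find_convergent(events, tree, aln, mito, min_lineages=1)
        assert len(sites) == 1 and sites[0].n_lineages == 1

    def test_derived_aa_present_in_background_rejected(self, mito):
        tree = labeled_tree(self.NEWICK, foreground={f"f{i}" for i in range(1, 6)})
        rows = {}
        for leaf in tree.leaf_taxa:
            codon = "CCT" if leaf in {"f1", "f2", "f3", "b5"} else "TCT"
            rows[leaf] = [codon]
        aln = make_alignment(rows)
        events = ls.map_events(ls.fitch_states(aln, tree), tree, mito)
        assert ls.find_convergent(events, tree, aln, mito, min_lineages=3) == []

    def test_invariant_to_event_order(self, mito):
        tree, aln, events = self._setup(mito, {"f1", "f2", "f3"})
        fwd = ls.find_convergent(events, tree, aln, mito, min_lineages=3)
        rev = ls.find_convergent(list(reversed(events)), tree, aln, mito,
                                 min_lineages=3)
        assert fwd == rev

    def test_min_lineages_one_means_any_foreground_novelty(self, mito):
        tree, aln, events = self._setup(mito, {"f1"})
        sites = ls.find_convergent(events, tree, aln, mito, min_lineages=1)
        assert [s.site for s in sites] == [2]
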