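import math

import numpy as np
import pytest
import scipy.stats

from phyloconcord.concordance import (
    QuartetTable,
    all_quartet_frequencies,
    branch_quartet_support,
    classify_split_support,
    coalescent_length_from_support,
    correlate_quartet_tables,
    count_quartet_topologies,
    minor_topology_chisq,
)
from phyloconcord.msc import SimulationConfig, as_species_tree_cu, simulate_gene_trees
from phyloconcord.tree import GeneTreeSet, Split, parse_newick


def make_set(newicks, taxa=None):
    return GeneTreeSet([parse_newick(n) for n in newicks], taxa=taxa or ())


class TestCountQuartetTopologies:
    def test_direct_count(self):
        gts = make_set(
            ["((A,B),(C,D));", "((A,B),(C,D));", "((A,C),(B,D));"]
        )
        assert count_quartet_topologies(gts, ["A", "B", "C", "D"]) == (2, 1, 0, 0, 0)

    def test_all_missing(self):
        gts = make_set(["((A,B),C);", "((A,C),B);"], taxa=("A", "B", "C", "D"))
        assert count_quartet_topologies(gts, ["A", "B", "C", "D"]) == (0, 0, 0, 0, 2)

    def test_unresolved_counted(self):
        gts = make_set(["(A,B,C,D);", "((A,B),(C,D));"])
        assert count_quartet_topologies(gts, ["A", "B", "C", "D"]) == (1, 0, 0, 1, 0)

    def test_quartet_outside_reference(self):
        gts = make_set(["((A,B),(C,D));"])
        with pytest.raises(ValueError):
            count_quartet_topologies(gts, ["A", "B", "C", "Z"])

    def test_msc_frequency_matches_closed_form(self, msc_trees_t1):
        n1, n2, n3, unres, miss = count_quartet_topologies(
            msc_trees_t1, ["A", "B", "C", "D"]
        )
        f1 = n1 / (n1 + n2 + n3)
        assert f1 == pytest.approx(1 - (2 / 3) * math.exp(-1), abs=0.02)
        assert unres == miss == 0


class TestAllQuartetFrequencies:
    def test_single_subset(self):
        gts = make_set(["((A,B),(C,D));"])
        assert all_quartet_frequencies(gts).n_quartets == 1

    def test_c_7_4_subsets(self, msc_trees_t1):
        # 5 taxa -> C(5,4) = 5; a 7-taxon set gives 35
        assert all_quartet_frequencies(msc_trees_t1).n_quartets == 5
        gts = make_set(["(((A,B),(C,D)),((E,F),G));"] * 3)
        assert all_quartet_frequencies(gts).n_quartets == 35

    def test_deterministic_serialisation(self, tmp_path, msc_trees_t1):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        all_quartet_frequencies(msc_trees_t1).to_tsv(p1)
        all_quartet_frequencies(msc_trees_t1).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_binary_full_trees_have_no_unresolved_rows(self, msc_trees_t1):
        table = all_quartet_frequencies(msc_trees_t1)
        assert (table.counts[:, 3] == 0).all()
        assert (table.counts[:, 4] == 0).all()
        assert np.allclose(table.frequencies().sum(axis=1), 1.0)

    def test_taxon_permutation_metamorphic(self, msc_trees_t1):
        table = all_quartet_frequencies(msc_trees_t1)
        mapping = {"A": "E", "B": "D", "C": "C", "D": "B", "E": "A"}
        renamed = []
        for g in msc_trees_t1:
            dup = g.copy()
            for leaf in dup.leaves():
                leaf.label = mapping[leaf.label]
            renamed.append(parse_newick(dup.newick()))
        table2 = all_quartet_frequencies(GeneTreeSet(renamed))
        # same multiset of resolved count triples, per-subset
        def row_key(table, row):
            labels = tuple(sorted(table.taxa[i] for i in table.subsets[row]))
            return labels

        rows1 = {}
        for r in range(table.n_quartets):
            labels = tuple(
                sorted(mapping[table.taxa[i]] for i in table.subsets[r])
            )
            rows1[labels] = sorted(table.counts[r, :3])
        rows2 = {
            row_key(table2, r): sorted(table2.counts[r, :3])
            for r in range(table2.n_quartets)
        }
        assert rows1 == rows2

    def test_too_few_taxa(self):
        gts = make_set(["((A,B),C);"])
        with pytest.raises(ValueError):
            all_quartet_frequencies(gts)


class TestBranchQuartetSupport:
    def test_perfect_concordance(self, balanced5):
        gts = make_set([balanced5.newick()] * 10)
        for split in (
            Split({"A", "B"}, {"C", "D", "E"}),
            Split({"A", "B", "C"}, {"D", "E"}),
        ):
            bs = branch_quartet_support(gts, balanced5, split)
            assert (bs.q1, bs.q2, bs.q3) == (1.0, 0.0, 0.0)

    def test_zero_length_branch_is_uninformative(self):
        sp = as_species_tree_cu(parse_newick("(((A:1,B:1):0,C:1):1,D:1);"))
        gts = simulate_gene_trees(sp, SimulationConfig(n_trees=3000, seed=3))
        bs = branch_quartet_support(gts, sp, Split({"A", "B"}, {"C", "D"}))
        for q in (bs.q1, bs.q2, bs.q3):
            assert q == pytest.approx(1 / 3, abs=0.03)

    def test_msc_t1_closed_form(self, balanced5, msc_trees_t1):
        bs = branch_quartet_support(
            msc_trees_t1, balanced5, Split({"A", "B"}, {"C", "D", "E"})
        )
        assert bs.q1 == pytest.approx(1 - (2 / 3) * math.exp(-1), abs=0.02)
        assert bs.q1 + bs.q2 + bs.q3 == pytest.approx(1.0, abs=1e-9)

    def test_unknown_branch_rejected(self, balanced5, msc_trees_t1):
        with pytest.raises(ValueError):
            branch_quartet_support(
                msc_trees_t1, balanced5, Split({"A", "C"}, {"B", "D", "E"})
            )


class TestCoalescentLengthFromSupport:
    def test_star_limit(self):
        assert coalescent_length_from_support(1 / 3) == 0.0

    def test_inverse_of_concordance_formula(self):
        q1 = 1 - (2 / 3) * math.exp(-1)
        assert coalescent_length_from_support(q1) == pytest.approx(1.0, abs=1e-12)

    def test_clipping_below_one_third(self):
        assert coalescent_length_from_support(0.2) == 0.0

    def test_ceiling_at_perfect_support(self):
        assert coalescent_length_from_support(1.0) == 10.0
        assert coalescent_length_from_support(1.0, ceiling=4.0) == 4.0

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            coalescent_length_from_support(1.2)

    def test_recovers_t_from_simulation(self):
        # parameter recovery across the estimable range (small-n smoke)
        for t in (0.5, 1.0):
            sp = as_species_tree_cu(parse_newick(f"(((A:1,B:1):{t},C:1):1,D:1);"))
            gts = simulate_gene_trees(sp, SimulationConfig(n_trees=4000, seed=8))
            bs = branch_quartet_support(gts, sp, Split({"A", "B"}, {"C", "D"}))
            est = coalescent_length_from_support(bs.q1)
            assert est == pytest.approx(t, rel=0.15)


def table_from_freqs(freq_rows, taxa=("A", "B", "C", "D")):
    """Build a single-subset QuartetTable from resolved frequencies."""
    counts = np.array([[int(round(1000 * f)) for f in freq_rows] + [0, 0]])
    return QuartetTable(
        taxa=taxa, subsets=np.array([[0, 1, 2, 3]]), counts=counts, n_trees=1000
    )


class TestCorrelateQuartetTables:
    def test_self_correlation_exact(self, msc_trees_t1):
        t = all_quartet_frequencies(msc_trees_t1)
        r2, slope, intercept, p = correlate_quartet_tables(t, t)
        assert (r2, slope, intercept) == (1.0, 1.0, 0.0)

    def test_hand_worked_least_squares(self):
        # x = (.5,.3,.2), y = (.4,.4,.2): R^2 = 4/7 by hand
        ta = table_from_freqs([0.5, 0.3, 0.2])
        tb = table_from_freqs([0.4, 0.4, 0.2])
        r2, slope, intercept, p = correlate_quartet_tables(ta, tb)
        assert r2 == pytest.approx(4 / 7, abs=1e-12)

    def test_constant_predictor_rejected(self):
        ta = table_from_freqs([1 / 3, 1 / 3, 1 / 3])
        tb = table_from_freqs([0.4, 0.4, 0.2])
        with pytest.raises(ValueError):
            correlate_quartet_tables(ta, tb)

    def test_mismatched_taxa_rejected(self):
        ta = table_from_freqs([0.5, 0.3, 0.2])
        tb = table_from_freqs([0.5, 0.3, 0.2], taxa=("A", "B", "C", "E"))
        with pytest.raises(ValueError):
            correlate_quartet_tables(ta, tb)


class TestMinorTopologyChisq:
    def test_identical_proportions(self):
        chi2, df, p = minor_topology_chisq((10, 10), (10, 10))
        assert chi2 == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_worked_example_vs_scipy(self):
        chi2, df, p = minor_topology_chisq((30, 20), (25, 25))
        assert chi2 == pytest.approx(1.0101, abs=1e-3)
        assert p == pytest.approx(0.315, abs=1e-3)
        ref = scipy.stats.chi2_contingency(
            [[30, 20], [25, 25]], correction=False
        )
        assert chi2 == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            minor_topology_chisq((0, 0), (10, 10))

    def test_zero_column_allowed(self):
        chi2, df, p = minor_topology_chisq((10, 0), (12, 0))
        assert chi2 == 0.0


class TestClassifySplitSupport:
    split = Split({"A", "B"}, {"C", "D"})

    def test_strongly_supported(self):
        gts = make_set(["((A,B)98,(C,D)97);"])
        s = classify_split_support(gts, self.split)
        assert s.categories == ["strongly_supported"]

    def test_weakly_supported(self):
        # the only edges inducing {A,B}|{C,D,E} carry support < 75
        gts = make_set(["((A,B)60,(C,(D,E)90)55);"])
        split5 = Split({"A", "B"}, {"C", "D", "E"})
        s = classify_split_support(gts, split5)
        assert s.categories == ["weakly_supported"]

    def test_highest_support_edge_wins(self):
        # a rooted 4-taxon tree represents the AB|CD edge twice; the
        # stronger representative decides the category
        gts = make_set(["((A,B)60,(C,D)99);"])
        s = classify_split_support(gts, self.split)
        assert s.categories == ["strongly_supported"]

    def test_weakly_rejected_after_contraction(self):
        # conflicting edge has support 60 < 75: contracting it leaves the
        # split compatible
        gts = make_set(["((A,C)60,(B,D)60);"])
        s = classify_split_support(gts, self.split)
        assert s.categories == ["weakly_rejected"]

    def test_strongly_rejected(self):
        gts = make_set(["((A,C)95,(B,D)95);"])
        s = classify_split_support(gts, self.split)
        assert s.categories == ["strongly_rejected"]

    def test_missing_support_policy(self):
        gts = make_set(["((A,C),(B,D));"])
        with pytest.raises(ValueError):
            classify_split_support(gts, self.split)
        s = classify_split_support(gts, self.split, missing_support="high")
        assert s.categories == ["strongly_rejected"]

    def test_proportions_sum_to_one(self):
        gts = make_set(
            [
                "((A,B)98,(C,D)97);",
                "((A,B)60,(C,D)99);",
                "((A,C)60,(B,D)60);",
                "((A,C)95,(B,D)95);",
            ]
        )
        s = classify_split_support(gts, self.split)
        assert sum(s.proportions.values()) == pytest.approx(1.0)
        assert s.n_categorized == 4

    def test_restriction_to_split_taxa(self):
        # extra taxa E/F are irrelevant; the split is an edge of the
        # restricted tree
        gts = make_set(["(((A,B)90,(E,F)90)85,(C,D)92);"])
        s = classify_split_support(gts, self.split)
        assert s.categories == ["strongly_supported"]
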