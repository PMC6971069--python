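"""Clade-state evaluation and (non-homoplasious) synapomorphy calling."""

import pytest

from cbcscope.errors import RegionLookupError, TopologyError
from cbcscope.seqio import MultipleAlignment
from cbcscope.synapomorphy import (
    POLYMORPHIC,
    PairedClass,
    Phylogeny,
    SynapomorphyClass,
    clade_state,
    classify_paired_synapomorphy,
    classify_synapomorphy,
    scan,
)
from cbcscope.synthetic_data import make_clade_alignment

BALANCED = Phylogeny.from_newick("((A,B),(C,D));")


def maln_of(**rows):
    return MultipleAlignment(rows=rows)


class TestCladeState:
    def test_shared_state(self):
        m = maln_of(A="G", B="G", C="U", D="U")
        assert clade_state(m, 1, {"A", "B"}) == "G"

    def test_polymorphic(self):
        m = maln_of(A="G", B="U", C="U", D="U")
        assert clade_state(m, 1, {"A", "B"}) is POLYMORPHIC

    def test_unknown_tip_is_lookup_error(self):
        m = maln_of(A="G", B="G")
        with pytest.raises(RegionLookupError):
            clade_state(m, 1, {"A", "Z"})


class TestClassifySynapomorphy:
    def test_unique_derived_state_is_nhs(self):
        m = maln_of(A="G", B="G", C="U", D="U")
        call = classify_synapomorphy(m, 1, {"A", "B"}, BALANCED)
        assert call.klass is SynapomorphyClass.NHS
        assert call.derived_state == ("G",)

    def test_state_recurring_outside_is_homoplasious(self):
        m = maln_of(A="G", B="G", C="U", D="G")
        call = classify_synapomorphy(m, 1, {"A", "B"}, BALANCED)
        assert call.klass is SynapomorphyClass.HOMOPLASIOUS_SYNAPOMORPHY

    def test_non_monophyletic_clade_is_topology_error(self):
        m = maln_of(A="G", B="G", C="G", D="U")
        with pytest.raises(TopologyError):
            classify_synapomorphy(m, 1, {"A", "B", "C"}, BALANCED)

    def test_state_shared_with_sister_not_synapomorphic(self):
        m = maln_of(A="G", B="G", C="G", D="G")
        call = classify_synapomorphy(m, 1, {"A", "B"}, BALANCED)
        assert call.klass is SynapomorphyClass.NOT_SYNAPOMORPHIC

    def test_single_tip_clade_is_autapomorphy(self):
        m = maln_of(A="G", B="U", C="U", D="U")
        call = classify_synapomorphy(m, 1, {"A"}, BALANCED)
        assert call.klass is SynapomorphyClass.AUTAPOMORPHY

    def test_polymorphic_clade_not_synapomorphic(self):
        m = maln_of(A="G", B="U", C="C", D="C")
        call = classify_synapomorphy(m, 1, {"A", "B"}, BALANCED)
        assert call.klass is SynapomorphyClass.NOT_SYNAPOMORPHIC

    def test_full_tip_set_clade_not_synapomorphic(self):
        m = maln_of(A="G", B="G", C="G", D="G")
        call = classify_synapomorphy(m, 1, {"A", "B", "C", "D"}, BALANCED)
        assert call.klass is SynapomorphyClass.NOT_SYNAPOMORPHIC

    def test_diagnostic_gap_reported_as_indel_synapomorphy(self):
        m = maln_of(A="-", B="-", C="U", D="U")
        call = classify_synapomorphy(m, 1, {"A", "B"}, BALANCED)
        assert call.klass is SynapomorphyClass.NHS
        assert call.is_indel


class TestClassifyPairedSynapomorphy:
    def test_unique_compensated_pair_is_nhs_cbc(self):
        m = maln_of(A="AU", B="AU", C="GC", D="GC")
        call = classify_paired_synapomorphy(m, (1, 2), {"A", "B"}, BALANCED)
        assert call.klass is SynapomorphyClass.NHS
        assert call.paired_klass is PairedClass.CBC

    def test_one_sided_conserved_change_is_hemi_cbc(self):
        m = maln_of(A="GU", B="GU", C="GC", D="GC")
        call = classify_paired_synapomorphy(m, (1, 2), {"A", "B"}, BALANCED)
        assert call.klass is SynapomorphyClass.NHS
        assert call.paired_klass is PairedClass.HEMI_CBC

    def test_double_pyrimidine_swap_unique_to_clade_is_nhs(self):
        # ten taxa; every outside member carries U,C at the couple
        tips = {f"T{i}": "UC" for i in range(8)}
        tips.update(A="CU", B="CU")
        newick = "((A,B),(T0,(T1,(T2,(T3,(T4,(T5,(T6,T7))))))));"
        tree = Phylogeny.from_newick(newick)
        m = maln_of(**tips)
        call = classify_paired_synapomorphy(m, (1, 2), {"A", "B"}, tree)
        assert call.klass is SynapomorphyClass.NHS
        assert call.paired_klass is None  # U.C / C.U are not complementary pairs

    def test_pair_equal_to_outside_not_synapomorphic(self):
        m = maln_of(A="GC", B="GC", C="GC", D="GC")
        call = classify_paired_synapomorphy(m, (1, 2), {"A", "B"}, BALANCED)
        assert call.klass is SynapomorphyClass.NOT_SYNAPOMORPHIC


class TestScan:
    TREE = "((A,B),(C,(D,E)));"

    def test_planted_nhs_recovered_exactly(self):
        maln, truth = make_clade_alignment(
            self.TREE, nhs_spec={"A,B": 4, "D,E": 2}, n_neutral=40, seed=9
        )
        tree = Phylogeny.from_newick(self.TREE)
        calls = scan(maln, tree, {"X": ["A", "B"], "Y": ["D", "E"]})
        nhs = [c for c in calls if c.klass is SynapomorphyClass.NHS]
        assert len(nhs) == 6
        planted_cols = {
            (p["positions"][0], tuple(p["clade"])) for p in truth.planted
        }
        assert {(c.columns[0], tuple(sorted(c.clade))) for c in nhs} == planted_cols
        # a column diagnostic for one clade may additionally score as a
        # homoplasious retention for the other clade, but never as NHS
        assert all(
            c.klass is SynapomorphyClass.HOMOPLASIOUS_SYNAPOMORPHY
            for c in calls
            if c.klass is not SynapomorphyClass.NHS
        )

    def test_identical_rows_yield_no_calls(self):
        m = MultipleAlignment(rows={t: "ACGUACGU" for t in "ABCDE"})
        tree = Phylogeny.from_newick(self.TREE)
        assert scan(m, tree, {"X": ["A", "B"]}) == []

    def test_full_tip_clade_yields_no_calls(self):
        maln, _ = make_clade_alignment(self.TREE, nhs_spec={"A,B": 3}, n_neutral=20, seed=4)
        tree = Phylogeny.from_newick(self.TREE)
        assert scan(maln, tree, {"all": list("ABCDE")}) == []

    def test_calls_invariant_under_tip_reordering(self):
        maln, _ = make_clade_alignment(self.TREE, nhs_spec={"A,B": 3}, n_neutral=30, seed=5)
        tree = Phylogeny.from_newick(self.TREE)
        reordered = MultipleAlignment(
            rows={t: maln.rows[t] for t in sorted(maln.rows, reverse=True)}
        )
        a = [(c.columns, tuple(sorted(c.clade)), c.klass) for c in scan(maln, tree, {"X": ["A", "B"]})]
        b = [
            (c.columns, tuple(sorted(c.clade)), c.klass)
            for c in scan(reordered, tree, {"X": ["A", "B"]})
        ]
        assert a == b

    def test_nhs_is_subset_of_synapomorphies(self):
        # {D,E} fixed for G, absent from sister C but recurring in A and B:
        # synapomorphic yet homoplasious, so it must not be called NHS
        rows = {"A": "G", "B": "G", "C": "U", "D": "G", "E": "G"}
        m = MultipleAlignment(rows=rows)
        tree = Phylogeny.from_newick(self.TREE)
        calls = scan(m, tree, {"Y": ["D", "E"]})
        assert [c.klass for c in calls] == [SynapomorphyClass.HOMOPLASIOUS_SYNAPOMORPHY]

    def test_non_monophyletic_requested_clade_is_topology_error(self):
        m = MultipleAlignment(rows={t: "A" for t in "ABCDE"})
        tree = Phylogeny.from_newick(self.TREE)
        with pytest.raises(TopologyError):
            scan(m, tree, {"bad": ["A", "C"]})
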