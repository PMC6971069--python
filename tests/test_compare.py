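"""Variable sites, pair-change classification, gap-aware distances."""

import pytest

from cbcscope.compare import (
    GapMode,
    GapPolicy,
    SiteClass,
    classify_pair_change,
    compare_structured,
    p_distance,
    variable_sites,
)
from cbcscope.errors import UndefinedDistanceError
from cbcscope.seqio import PairwiseAlignment
from cbcscope.structure import map_structure, parse_dotbracket
from cbcscope.synthetic_data import make_template, plant_changes, structured_pair

COUNT = GapPolicy(GapMode.COUNT_GAPS)
EXCLUDE = GapPolicy(GapMode.EXCLUDE_GAPS)


class TestVariableSites:
    def test_identical_rows_no_sites(self):
        aln = PairwiseAlignment(row_a="ACGU", row_b="ACGU")
        assert variable_sites(aln, COUNT) == []

    def test_gap_column_policy(self):
        aln = PairwiseAlignment(row_a="AC-U", row_b="ACGU")
        assert variable_sites(aln, COUNT) == [3]
        assert variable_sites(aln, EXCLUDE) == []

    def test_substitution_counts_under_both_policies(self):
        aln = PairwiseAlignment(row_a="ACGU", row_b="ACGA")
        assert variable_sites(aln, COUNT) == [4]
        assert variable_sites(aln, EXCLUDE) == [4]

    def test_gap_vs_gap_never_counted(self):
        aln = PairwiseAlignment(row_a="A-GU", row_b="A-GA")
        assert variable_sites(aln, COUNT) == [4]

    def test_masked_and_ambiguous_columns_skipped(self):
        aln = PairwiseAlignment(row_a="ACGU", row_b="UCNU")
        assert variable_sites(aln, COUNT, masked_columns=frozenset({1})) == []

    def test_unequal_rows_rejected(self):
        from cbcscope.errors import FormatError

        with pytest.raises(FormatError):
            PairwiseAlignment(row_a="ACGU", row_b="ACGUA")


class TestClassifyPairChange:
    @pytest.mark.parametrize(
        "before,after,expected",
        [
            (("G", "C"), ("A", "U"), SiteClass.CBC),
            (("A", "U"), ("U", "A"), SiteClass.CBC),
            (("G", "C"), ("G", "U"), SiteClass.HEMI_CBC),
            (("A", "U"), ("G", "U"), SiteClass.HEMI_CBC),
            (("G", "C"), ("G", "A"), SiteClass.UNCOUPLED),
            (("G", "A"), ("G", "C"), SiteClass.UNCOUPLED),  # before non-complementary
            (("A", "U"), ("C", "G"), SiteClass.CBC),
        ],
    )
    def test_classification_table(self, before, after, expected):
        assert classify_pair_change(before, after) is expected

    def test_identical_pair_yields_no_record(self):
        assert classify_pair_change(("G", "C"), ("G", "C")) is None

    def test_ambiguity_code_excluded(self):
        assert classify_pair_change(("G", "N"), ("A", "U")) is None


class TestPDistance:
    def test_hand_enumerated_example(self):
        # 10 columns, 2 substitutions (cols 1 and 4), 1 gap column (col 7)
        aln = PairwiseAlignment(row_a="ACGUACGUAC", row_b="UCGAAC-UAC")
        assert p_distance(aln, COUNT) == pytest.approx(0.30)
        assert p_distance(aln, EXCLUDE) == pytest.approx(2 / 9)

    def test_identical_rows_zero(self):
        aln = PairwiseAlignment(row_a="ACGU", row_b="ACGU")
        assert p_distance(aln, COUNT) == 0.0
        assert p_distance(aln, EXCLUDE) == 0.0

    def test_all_gap_columns_undefined_without_gaps(self):
        aln = PairwiseAlignment(row_a="ACGU", row_b="----")
        with pytest.raises(UndefinedDistanceError):
            p_distance(aln, EXCLUDE)

    @pytest.mark.parametrize("seed", range(25))
    def test_with_gaps_never_below_without_gaps(self, seed):
        import random

        rng = random.Random(seed)
        n = rng.randint(5, 60)
        row_a, row_b = [], []
        for _ in range(n):
            a = rng.choice("ACGU")
            r = rng.random()
            if r < 0.15:
                b = "-"
            elif r < 0.4:
                b = rng.choice("ACGU")
            else:
                b = a
            row_a.append(a)
            row_b.append(b)
        aln = PairwiseAlignment(row_a="".join(row_a), row_b="".join(row_b))
        try:
            no_gaps = p_distance(aln, EXCLUDE)
        except UndefinedDistanceError:
            return
        assert p_distance(aln, COUNT) >= no_gaps


class TestCompareStructured:
    def test_identical_rows_all_zero(self):
        aln = PairwiseAlignment(row_a="GGAAACC", row_b="GGAAACC")
        saln = map_structure(parse_dotbracket("((...))"), aln)
        rep = compare_structured(saln)
        assert rep.variable_sites_with_gaps == 0
        assert all(v == 0 for v in rep.class_counts.values())

    def test_planted_class_counts_recovered(self):
        counts = {"CBC": 3, "HEMI_CBC": 2, "UNCOUPLED": 1, "LOOP_SUBSTITUTION": 4, "INDEL": 2}
        saln, truth = structured_pair(17, counts)
        rep = compare_structured(saln)
        assert rep.class_counts["CBC"] == 3
        assert rep.class_counts["hemi-CBC"] == 2
        assert rep.class_counts["uncoupled"] == 1
        assert rep.class_counts["loop-substitution"] == 4
        assert rep.class_counts["indel"] == 2

    def test_partition_identity(self):
        counts = {"CBC": 4, "HEMI_CBC": 3, "UNCOUPLED": 2, "LOOP_SUBSTITUTION": 5, "INDEL": 3}
        saln, _ = structured_pair(23, counts)
        rep = compare_structured(saln)
        cc = rep.class_counts
        assert (
            2 * cc["CBC"] + cc["hemi-CBC"] + cc["uncoupled"] + cc["loop-substitution"] + cc["indel"]
            == rep.variable_sites_with_gaps
        )

    def test_counts_symmetric_under_row_swap(self):
        # no indels, so the structure lies on identical coordinates in both rows
        counts = {"CBC": 3, "HEMI_CBC": 2, "UNCOUPLED": 2, "LOOP_SUBSTITUTION": 3}
        seq, st = make_template(31, n_helices=5, helix_len=6, loop_len=6, spacer_len=8)
        _, truth = plant_changes(seq, st, counts, seed=32)
        fwd = PairwiseAlignment(row_a=truth.params["row_a"], row_b=truth.params["row_b"])
        rev = PairwiseAlignment(row_a=truth.params["row_b"], row_b=truth.params["row_a"])
        rep_f = compare_structured(map_structure(st, fwd, reference_row="a"))
        rep_r = compare_structured(map_structure(st, rev, reference_row="b"))
        assert rep_f.class_counts == rep_r.class_counts
        assert rep_f.variable_sites_with_gaps == rep_r.variable_sites_with_gaps
        assert rep_f.distance_with_gaps == rep_r.distance_with_gaps

    def test_per_helix_tallies_count_substitution_columns(self):
        # one CBC (2 columns) planted in a single-helix template
        seq, st = make_template(41, n_helices=1, helix_len=8, loop_len=6, spacer_len=4)
        _, truth = plant_changes(seq, st, {"CBC": 1}, seed=42)
        aln = PairwiseAlignment(row_a=truth.params["row_a"], row_b=truth.params["row_b"])
        rep = compare_structured(map_structure(st, aln))
        assert rep.per_helix == {"H1": 2}

    def test_primer_masked_columns_excluded(self):
        aln = PairwiseAlignment(row_a="ACGUACGU", row_b="UCGUACGA")
        saln = map_structure(
            parse_dotbracket("........"), aln, primer_mask=frozenset({1})
        )
        rep = compare_structured(saln, GapPolicy(GapMode.COUNT_GAPS, mask_primer=True))
        assert rep.variable_sites_with_gaps == 1  # only column 8
        rep2 = compare_structured(saln, GapPolicy(GapMode.COUNT_GAPS, mask_primer=False))
        assert rep2.variable_sites_with_gaps == 2

    def test_ambiguous_columns_logged(self):
        aln = PairwiseAlignment(row_a="ACGU", row_b="NCGA")
        saln = map_structure(parse_dotbracket("...."), aln)
        rep = compare_structured(saln)
        assert rep.ambiguous_columns == (1,)
        assert rep.variable_sites_with_gaps == 1
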