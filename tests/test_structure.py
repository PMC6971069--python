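"""Structure parsing, template transfer, and the maximum-pairing fold."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from cbcscope.errors import ConsistencyError, FormatError, PseudoknotError
from cbcscope.seqio import PairwiseAlignment
from cbcscope.structure import (
    SecondaryStructure,
    fold_max_pairing,
    is_complementary,
    map_structure,
    parse_dotbracket,
    parse_structure,
    transfer_structure,
    write_ct,
)


class TestParsing:
    def test_dotbracket_pairs(self):
        st_ = parse_dotbracket("((...))")
        assert st_.pairs == {(1, 7), (2, 6)}

    def test_ct_equivalent_to_dotbracket(self, tmp_path):
        db = parse_dotbracket("((..((...))..))")
        ct_path = tmp_path / "m.ct"
        write_ct(db, "GGAAGGAAACCAACC", ct_path)
        assert parse_structure(ct_path).pairs == db.pairs

    @pytest.mark.parametrize("text", ["(()", "())", ")("])
    def test_unmatched_brackets_rejected(self, text):
        with pytest.raises(FormatError):
            parse_dotbracket(text)

    def test_pseudoknot_brackets_rejected(self):
        with pytest.raises(PseudoknotError):
            parse_dotbracket("((..[[..))..]]")

    def test_crossing_pairs_rejected(self):
        with pytest.raises(PseudoknotError):
            SecondaryStructure(seq_id="x", pairs=frozenset({(1, 5), (3, 7)}))

    def test_helix_label_on_unpaired_position_rejected(self):
        with pytest.raises(FormatError):
            SecondaryStructure(
                seq_id="x", pairs=frozenset({(1, 7)}), helix_labels={3: "49"}
            )


class TestComplementarity:
    @pytest.mark.parametrize(
        "b1,b2,expected",
        [
            ("A", "U", True),
            ("U", "A", True),
            ("G", "C", True),
            ("G", "U", True),  # wobble
            ("U", "G", True),
            ("A", "G", False),
            ("C", "U", False),
            ("A", "A", False),
        ],
    )
    def test_pairing_table(self, b1, b2, expected):
        assert is_complementary(b1, b2) is expected

    @pytest.mark.parametrize("b1,b2", [("N", "U"), ("A", "R")])
    def test_ambiguity_is_indeterminate(self, b1, b2):
        assert is_complementary(b1, b2) is None


class TestMapStructure:
    def test_gap_free_mapping_is_identity(self):
        aln = PairwiseAlignment(row_a="GGAAACC", row_b="GGAAACC")
        st_ = parse_dotbracket("((...))")
        saln = map_structure(st_, aln)
        assert saln.column_context[1].partner_column == 7
        assert saln.column_context[2].partner_column == 6
        assert 3 not in saln.column_context

    def test_gap_shifts_columns(self):
        aln = PairwiseAlignment(row_a="G-GAAACC", row_b="GUGAAACC")
        st_ = parse_dotbracket("((...))")  # on the ungapped row_a
        saln = map_structure(st_, aln)
        assert saln.column_context[1].partner_column == 8
        assert saln.column_context[3].partner_column == 7

    def test_structure_longer_than_row_rejected(self):
        aln = PairwiseAlignment(row_a="GGG", row_b="GGG")
        with pytest.raises(ConsistencyError):
            map_structure(SecondaryStructure(seq_id="", pairs=frozenset({(1, 9)})), aln)


class TestTransfer:
    def test_identity_alignment_preserves_structure(self):
        st_ = SecondaryStructure(
            seq_id="a", pairs=frozenset({(1, 7), (2, 6)}), helix_labels={1: "H1", 7: "H1"}
        )
        aln = PairwiseAlignment(row_a="GGAAACC", row_b="GGAAACC", id_a="a", id_b="b")
        out, flags = transfer_structure(st_, aln)
        assert out.pairs == st_.pairs
        assert out.helix_labels == st_.helix_labels
        assert flags == []

    def test_query_gap_drops_pair_with_flag(self):
        st_ = SecondaryStructure(seq_id="a", pairs=frozenset({(1, 7), (2, 6)}))
        aln = PairwiseAlignment(row_a="GGAAACC", row_b="-GAAACC", id_a="a", id_b="b")
        out, flags = transfer_structure(st_, aln)
        assert out.pairs == {(1, 5)}  # template (2,6) on the 6-nt query
        assert [f.kind for f in flags] == ["dropped_gap"]
        assert flags[0].template_pair == (1, 7)

    def test_non_complementary_pair_kept_and_flagged(self):
        st_ = SecondaryStructure(seq_id="a", pairs=frozenset({(1, 7)}))
        aln = PairwiseAlignment(row_a="GGAAACC", row_b="AGAAACG", id_a="a", id_b="b")
        out, flags = transfer_structure(st_, aln)
        assert out.pairs == {(1, 7)}
        assert [f.kind for f in flags] == ["non_complementary"]

    def test_transfer_never_pairs_gap_columns_and_stays_nested(self):
        rng = random.Random(0)
        template = parse_dotbracket("((((...))))..((...))")
        seq = "GGGGAAACCCCAAGGAAACC"
        for _ in range(25):
            # random query: delete a few template positions, mutate others
            row_a, row_b = [], []
            for c in seq:
                if rng.random() < 0.2:
                    row_a.append(c)
                    row_b.append("-")
                else:
                    row_a.append(c)
                    row_b.append(rng.choice("ACGU") if rng.random() < 0.3 else c)
            aln = PairwiseAlignment(row_a="".join(row_a), row_b="".join(row_b))
            out, _ = transfer_structure(template, aln)
            # SecondaryStructure construction re-validates nestedness; pairs are
            # on ungapped query positions by construction
            n_query = len(aln.degapped("b"))
            assert all(1 <= i < j <= n_query for i, j in out.pairs)


class TestFold:
    def test_hairpin(self):
        st_ = fold_max_pairing("GGGAAACCC", min_loop=3)
        assert len(st_.pairs) == 3

    def test_no_complementary_bases(self):
        assert fold_max_pairing("AAAA").pairs == frozenset()

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_enumeration_oracle(self, seed, brute_force_fold):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(1, 12)))
        st_ = fold_max_pairing(seq, min_loop=3)
        assert len(st_.pairs) == brute_force_fold(seq, min_loop=3)
        for i, j in st_.pairs:
            assert j - i > 3
            assert is_complementary(seq[i - 1], seq[j - 1]) is True

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=1, max_size=11))
    def test_enumeration_equivalence_property(self, seq):
        from conftest import enumerate_max_pairs

        assert len(fold_max_pairing(seq, min_loop=3).pairs) == enumerate_max_pairs(
            seq, min_loop=3
        )

    def test_deterministic(self):
        seq = "GCGCAAAAGCGCAAAAGGCC"
        assert fold_max_pairing(seq).pairs == fold_max_pairing(seq).pairs
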