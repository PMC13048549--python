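"""Dot-bracket parsing, end windows, hairpin-to-duplex projection and
structure-difference classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirunwind.sequence_io import MirnaRecord, locate_mature_in_hairpin
from mirunwind.structure_model import (
    DotBracketError,
    DuplexStructure,
    SecondaryStructure,
    annotate_loops,
    classify_difference,
    extract_hairpin_duplex,
    insert_separator,
    parse_dotbracket,
    render_dotbracket,
)
from mirunwind.synthetic import FixtureSpec, make_duplex, make_hairpin


@st.composite
def balanced_dotbrackets(draw, max_leaves=12):
    def build(depth):
        if depth > 3:
            return "." * draw(st.integers(0, 2))
        parts = draw(st.lists(st.sampled_from(["dot", "pair"]), max_size=4))
        out = []
        for p in parts:
            if p == "dot":
                out.append(".")
            else:
                out.append("(" + build(depth + 1) + ")")
        return "".join(out)

    return build(0)


class TestDotBracket:
    @pytest.mark.parametrize(
        "db,expected",
        [
            ("((..))", {1: 6, 6: 1, 2: 5, 5: 2}),
            ("....", {}),
            ("((..&..))", {1: 8, 8: 1, 2: 7, 7: 2}),
        ],
    )
    def test_parse_examples(self, db, expected):
        assert parse_dotbracket(db) == expected

    @pytest.mark.parametrize("bad,pos", [("((.)", 1), (".))", 2), ("(.a)", 3)])
    def test_errors_carry_position(self, bad, pos):
        with pytest.raises(DotBracketError, match=f"position {pos}"):
            parse_dotbracket(bad)

    @given(balanced_dotbrackets())
    @settings(max_examples=80, derandomize=True)
    def test_render_parse_roundtrip(self, db):
        pairs = parse_dotbracket(db)
        assert parse_dotbracket(render_dotbracket(pairs, len(db))) == pairs

    def test_render_rejects_non_involution(self):
        with pytest.raises(DotBracketError):
            render_dotbracket({1: 2, 2: 3, 3: 1}, 3)


class TestEndWindows:
    @pytest.fixture()
    def duplex(self):
        d = make_duplex(FixtureSpec(seed=3))
        return d.structure

    def test_window_composition(self, duplex):
        L1, L = duplex.len5p, len(duplex)
        assert duplex.end_window("5p_end", 2) == frozenset({1, 2, L - 1, L})
        assert duplex.end_window("3p_end", 2) == frozenset({L1 - 1, L1, L1 + 1, L1 + 2})

    @pytest.mark.parametrize("end", ["5p_end", "3p_end"])
    def test_windows_nest(self, duplex, end):
        for n in range(1, 4):
            assert duplex.end_window(end, n) < duplex.end_window(end, n + 1)

    def test_opposite_windows_disjoint(self, duplex):
        for n in range(1, 5):
            for m in range(1, 5):
                assert not duplex.end_window("5p_end", n) & duplex.end_window("3p_end", m)


class TestExtractHairpinDuplex:
    def test_perfect_stem_gives_full_ladder(self):
        # 10-bp stem, arms are exactly the two stem strands
        arm = "GGCAUGCAGC"
        comp = "GCUGCAUGCC"
        hairpin = arm + "AAAA" + comp
        db = "(" * 10 + "...." + ")" * 10
        fold = SecondaryStructure(sequence=hairpin, dotbracket=db)
        rec = locate_mature_in_hairpin(
            MirnaRecord(name="m", hairpin_seq=hairpin, seq5p=arm, seq3p=comp)
        )
        duplex = extract_hairpin_duplex(rec, fold)
        assert len(duplex.interstrand_pairs()) == 10
        assert duplex.plain_dotbracket == "(" * 10 + ")" * 10

    def test_loop_paired_arm_position_becomes_unpaired(self):
        # position 4 of the arm pairs into the loop region in the hairpin
        hairpin = "GGGUAAAACCC"
        db = "((((...))))"  # pairs 1-11, 2-10, 3-9 inter-arm; 4-8 reaches the loop
        fold = SecondaryStructure(sequence=hairpin, dotbracket=db)
        rec = MirnaRecord(
            name="m", hairpin_seq=hairpin, seq5p="GGGU", seq3p="CCC", pos5p=(1, 4), pos3p=(9, 11)
        )
        duplex = extract_hairpin_duplex(rec, fold)
        # hairpin pairs 4-8 and 5-7 leave the duplex region -> unpaired
        assert duplex.plain_dotbracket == "(((.)))"

    @pytest.mark.parametrize("seed", range(6))
    def test_projection_matches_planted_duplex(self, seed):
        hp = make_hairpin(FixtureSpec(seed=seed, n_mismatch=1, n_bulge=1))
        rec = MirnaRecord(
            name="m",
            hairpin_seq=hp.sequence,
            seq5p=hp.duplex.seq5p,
            seq3p=hp.duplex.seq3p,
            pos5p=hp.pos5p,
            pos3p=hp.pos3p,
        )
        duplex = extract_hairpin_duplex(rec, hp.structure)
        assert duplex.plain_dotbracket == hp.duplex.structure.plain_dotbracket

    @pytest.mark.parametrize("seed", range(6))
    def test_pair_subset_property(self, seed):
        hp = make_hairpin(FixtureSpec(seed=seed, n_mismatch=2))
        rec = MirnaRecord(
            name="m",
            hairpin_seq=hp.sequence,
            seq5p=hp.duplex.seq5p,
            seq3p=hp.duplex.seq3p,
            pos5p=hp.pos5p,
            pos3p=hp.pos3p,
        )
        duplex = extract_hairpin_duplex(rec, hp.structure)
        # map duplex coordinates back to hairpin coordinates
        region = list(range(hp.pos5p[0], hp.pos5p[1] + 1)) + list(
            range(hp.pos3p[0], hp.pos3p[1] + 1)
        )
        for i, j in duplex.pairs.items():
            assert hp.structure.pairs.get(region[i - 1]) == region[j - 1]


class TestAnnotateLoops:
    def test_perfect_duplex_with_overhangs_has_no_features(self):
        d = make_duplex(FixtureSpec(seed=5))
        assert annotate_loops(d.structure) == []

    def test_single_bulge_pattern(self):
        # 4 pairs, one extra unpaired nucleotide on strand 1
        db = "((.((&))))"
        seq = "GGAGC&GCCC"
        duplex = DuplexStructure(sequence=seq, dotbracket=db, strand_break=5)
        assert annotate_loops(duplex) == [("bulge", (3,))]

    def test_mismatch_pattern(self):
        db = "((.((&)).))"
        seq = "GGAGC&GCACC"
        duplex = DuplexStructure(sequence=seq, dotbracket=db, strand_break=5)
        assert annotate_loops(duplex) == [("mismatch", (3, 8))]


class TestClassifyDifference:
    def _ss(self, seq, db):
        return SecondaryStructure(sequence=seq, dotbracket=db)

    def test_equal_strings_are_identical(self):
        a = self._ss("GGGAAACCC", "(((...)))")
        assert classify_difference(a, a) == "identical"

    def test_difference_at_first_position_is_terminal(self):
        a = self._ss("GGGAAAACCC&GGG", "(((....)))&...")
        b = self._ss("GGGAAAACCC&GGG", ".((....)).&...")
        assert classify_difference(a, b, terminal_margin=4) == "terminal"

    def test_central_difference_detected(self):
        # duplex losing an interior pair: the difference sits mid-helix
        seq = "GGGGGGGGGG&CCCCCCCCCC"
        a = self._ss(seq, "((((((((((&))))))))))")
        b = self._ss(seq, "((((.(((((&))))).))))")
        assert classify_difference(a, b, terminal_margin=4) == "central"

    def test_symmetric_in_arguments(self):
        seq = "GGGAAAACCC&GGG"
        a = self._ss(seq, "(((....)))&...")
        b = self._ss(seq, ".((....)).&...")
        assert classify_difference(a, b) == classify_difference(b, a)

    def test_sequence_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_difference(self._ss("AAAA", "...."), self._ss("CCCC", "...."))
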