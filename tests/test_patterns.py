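"""Pattern grammar parsing and structured-motif matching."""

import numpy as np
import pytest

from selenoscan.patterns import (
    Alternation,
    BackRef,
    Literal,
    PatternParseError,
    Segment,
    match_all,
    parse_pattern,
    to_dot_bracket,
)

from _oracle import oracle_matches

R1 = "r1={au,ua,gc,cg,gu,ug} "


class TestParse:
    def test_literal_only(self):
        spec = parse_pattern("GAA")
        assert spec.elements == (Literal("GAA"),)

    def test_full_element_list_in_order(self):
        spec = parse_pattern(
            R1 + "p1=3...10 GAA p2=3...6 3...19 r1~p2[0,1,1] A r1~p1[1,1,1]"
        )
        kinds = [type(e).__name__ for e in spec.elements]
        assert kinds == ["Segment", "Literal", "Segment", "Segment",
                        "BackRef", "Literal", "BackRef"]
        assert spec.elements[0] == Segment("p1", 3, 10)
        assert spec.elements[4].budgets == (0, 1, 1)
        assert spec.elements[6].segment_name == "p1"

    def test_alternation_binds_branches(self):
        spec = parse_pattern(R1 + "NNGAN p1=7...15 8...20 r1~p1[2,1,1] "
                             "(NGANN | NAANN)")
        alt = spec.elements[-1]
        assert isinstance(alt, Alternation)
        assert [br[0].text for br in alt.branches] == ["NGANN", "NAANN"]

    def test_undeclared_backref_rejected(self):
        with pytest.raises(PatternParseError):
            parse_pattern(R1 + "r1~p9[0,0,0]")

    @pytest.mark.parametrize("bad", [
        "p1=10...3",           # inverted range
        "r1~p1[0,0,0]",        # rule and segment undeclared
        "(GAA | )",            # empty branch
        "GAA )",               # stray paren
        "XYZ123",              # unknown token
    ])
    def test_parse_errors(self, bad):
        with pytest.raises(PatternParseError):
            parse_pattern(bad)


class TestMatch:
    def test_literal_anywhere(self):
        ms = match_all(parse_pattern("GAA"), "UGAAC")
        assert [(m.start, m.end) for m in ms] == [(1, 4)]

    def test_exact_reverse_complement_stem(self):
        spec = parse_pattern(R1 + "p1=3...3 r1~p1[0,0,0]")
        ms = match_all(spec, "GACGUC")
        assert len(ms) == 1
        assert ms[0].bindings["p1"] == (0, 3)
        assert ms[0].backrefs[0].interval == (3, 6)

    def test_wobble_pairs_permitted(self):
        # G.U wobbles are pairs under r1, not mismatches
        spec = parse_pattern(R1 + "p1=3...3 r1~p1[0,0,0]")
        ms = match_all(spec, "GACGUU")
        assert len(ms) == 1
        assert ms[0].backrefs[0].mismatches == 0

    def test_one_mismatch_stem(self):
        # brute-force verified: GGGG + loop AAAA + partner CCCA leaves one
        # non-pairing position, within a [1,0,0] budget
        spec = parse_pattern(R1 + "p1=4...4 4...4 r1~p1[1,0,0]")
        ms = match_all(spec, "GGGGAAAACCCA")
        assert any(m.bindings["p1"] == (0, 4) and m.backrefs[0].mismatches == 1
                   for m in ms)

    def test_no_match_when_budget_too_small(self):
        spec = parse_pattern(R1 + "p1=4...4 4...4 r1~p1[0,0,0]")
        assert match_all(spec, "GGGGAAAACCCA") == []

    def test_n_never_pairs(self):
        spec = parse_pattern(R1 + "p1=3...3 r1~p1[0,0,0]")
        assert match_all(spec, "GACGUN") == []
        assert match_all(spec, "GANGUC") == []

    def test_deletion_shortens_partner(self):
        spec = parse_pattern(R1 + "p1=4...4 r1~p1[0,1,0]")
        ms = match_all(spec, "GGCCGCC")  # partner GCC: 3 nt, one deletion
        assert any(m.backrefs[0].deletions == 1
                   and m.backrefs[0].interval == (4, 7) for m in ms)

    def test_insertion_lengthens_partner(self):
        spec = parse_pattern(R1 + "p1=3...3 r1~p1[0,0,1]")
        ms = match_all(spec, "GGCAGCC")  # partner GCC plus an inserted A
        assert any(m.backrefs[0].insertions == 1
                   and m.backrefs[0].interval == (3, 7) for m in ms)


class TestOracleEquivalence:
    """The fast matcher equals the naive enumerator exactly."""

    PATTERNS = [
        R1 + "p1=3...5 2...6 r1~p1[1,1,1]",
        R1 + "NNGAN p1=4...6 3...6 r1~p1[2,1,1] (NGANN | NAANN)",
        R1 + "p1=3...4 GAA p2=2...3 3...5 r1~p2[0,1,1] A r1~p1[1,1,1]",
        "RYSW 2...4 GAN",
    ]

    @pytest.mark.parametrize("pat", PATTERNS)
    def test_random_sequences(self, pat):
        spec = parse_pattern(pat)
        rng = np.random.default_rng(12345)
        for _ in range(60):
            length = int(rng.integers(10, 45))
            seq = "".join(rng.choice(list("ACGUACGUACGUN"), size=length))
            got = {m.key for m in match_all(spec, seq)}
            want = oracle_matches(spec, seq)
            assert got == want, f"disagreement on {seq!r}"

    def test_budget_monotonicity(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGU"), size=25))
            prev: set = set()
            for m, d, i in [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1),
                            (2, 1, 1)]:
                spec = parse_pattern(R1 + f"p1=3...5 2...4 r1~p1[{m},{d},{i}]")
                cur = {(k[0], k[1]) for k in
                       (mm.key for mm in match_all(spec, seq))}
                assert prev <= cur
                prev = cur

    def test_determinism(self):
        spec = parse_pattern(self.PATTERNS[1])
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGU"), size=50))
        a = match_all(spec, seq)
        b = match_all(spec, seq)
        assert a == b


class TestDotBracket:
    def test_three_pair_stem(self):
        spec = parse_pattern(R1 + "p1=3...3 r1~p1[0,0,0]")
        m = match_all(spec, "GACGUC")[0]
        assert to_dot_bracket(m) == "((()))"

    def test_literal_only_all_dots(self):
        m = match_all(parse_pattern("GAA"), "GAA")[0]
        assert to_dot_bracket(m) == "..."

    def test_mismatch_rendered_unpaired(self):
        spec = parse_pattern(R1 + "p1=4...4 4...4 r1~p1[1,0,0]")
        m = [x for x in match_all(spec, "GGGGAAAACCCA")
             if x.bindings["p1"] == (0, 4) and x.end == 12][0]
        db = to_dot_bracket(m)
        assert db.count("(") == db.count(")") == 3
        assert db[11] == "."  # the non-pairing outermost position
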