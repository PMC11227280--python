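"""SECIS structural models: validation, scanning, classification, statistics."""

import numpy as np
import pytest

from selenoscan.patterns import Literal, Segment, match_all
from selenoscan.secis import (
    SecisClass,
    SecisModelParams,
    builtin_patterns,
    classify_euryarchaeal,
    composition_profiles,
    scan_window,
    structure_from_match,
    validate_candidate,
)
from selenoscan.seqio import Utr3Window, to_rna
from selenoscan.simulate import build_secis, plant_in_window

from _oracle import ss_triplet_brute

# A worked type I element: AUGA core, perfect 7-bp stem, 8-nt apical loop,
# CGAAA tail carrying the 3' GA dinucleotide.
WORKED_TYPE_I = "AUGAGGCUCGGUAAAAAAAAACCGAGCCGAAA"


def _window(seq_dna: str) -> Utr3Window:
    return Utr3Window("c", 0, len(seq_dna), "+", seq_dna, 0)


def _best_type1_structure(seq_rna: str):
    pat = builtin_patterns()[SecisClass.ESECIS_I]
    ms = match_all(pat, seq_rna)
    assert ms, "no raw pattern match"
    # the perfect-stem interpretation: no deletions/insertions
    m = next(m for m in ms
             if m.backrefs[0].deletions == 0 and m.backrefs[0].insertions == 0
             and m.start == 0 and m.end == len(seq_rna))
    return structure_from_match(SecisClass.ESECIS_I, m, seq_rna)


class TestBuiltinPatterns:
    def test_all_parse(self):
        pats = builtin_patterns()
        assert set(pats) == set(SecisClass)

    def test_type_one_layout(self):
        spec = builtin_patterns()[SecisClass.ESECIS_I]
        assert spec.elements[0] == Literal("NNGAN")
        loop = spec.elements[2]
        assert isinstance(loop, Segment) and (loop.min_len, loop.max_len) == (8, 20)

    def test_easecis_layout(self):
        spec = builtin_patterns()[SecisClass.EASECIS]
        assert any(isinstance(e, Literal) and e.text == "GAA"
                   for e in spec.elements)
        final = spec.elements[-1]
        assert final.segment_name == "p1" and final.budgets == (1, 1, 1)


class TestValidation:
    def test_worked_type_one_accepts(self):
        s = _best_type1_structure(WORKED_TYPE_I)
        ok, reasons = validate_candidate(
            s, SecisModelParams.default(SecisClass.ESECIS_I), WORKED_TYPE_I
        )
        assert ok, reasons
        assert s.upper_stem_len == 7
        assert s.apical_loop[1] - s.apical_loop[0] == 8

    def test_short_loop_rejected_by_params(self):
        s = _best_type1_structure(WORKED_TYPE_I)
        tight = SecisModelParams(
            SecisClass.ESECIS_I, upper_stem=(7, 15), upper_stem_mismatch_max=2,
            apical_loop=(9, 20),
        )
        ok, reasons = validate_candidate(s, tight, WORKED_TYPE_I)
        assert not ok
        assert any("apical loop" in r for r in reasons)

    def test_excess_mismatches_rejected(self):
        s = _best_type1_structure(WORKED_TYPE_I)
        strict = SecisModelParams(
            SecisClass.ESECIS_I, upper_stem=(7, 15),
            upper_stem_mismatch_max=-1, apical_loop=(8, 20),
        )
        ok, reasons = validate_candidate(s, strict, WORKED_TYPE_I)
        assert not ok and any("mismatches" in r for r in reasons)


class TestScanWindow:
    @pytest.mark.parametrize("cls", list(SecisClass))
    def test_planted_element_recovered(self, cls, rng):
        for _ in range(3):
            wseq, plant, off = plant_in_window(cls, rng)
            w = Utr3Window("c", 0, len(wseq), "+", wseq, 30)
            cands = scan_window(w, [SecisModelParams.default(cls)])
            assert any(
                c.model_class is cls
                and c.window_start < off + len(plant)
                and off < c.window_end
                for c in cands
            ), f"planted {cls} not recovered"

    def test_all_a_window_empty(self):
        w = _window("A" * 630)
        assert scan_window(w) == []

    def test_candidates_validate_and_clear_threshold(self, rng):
        wseq, _plant, _off = plant_in_window(SecisClass.ESECIS_I, rng)
        w = Utr3Window("c", 0, len(wseq), "+", wseq, 30)
        params = SecisModelParams.default(SecisClass.ESECIS_I)
        for c in scan_window(w, [params]):
            ok, reasons = validate_candidate(c.structure, params,
                                             to_rna(w.sequence))
            assert ok, reasons
            assert c.delta_g < -5.0

    def test_minus_strand_candidate_coordinates(self, rng):
        wseq, plant, off = plant_in_window(SecisClass.ESECIS_I, rng,
                                           window_len=200)
        w = Utr3Window("c", 1000, 1200, "-", wseq, 30)
        cands = scan_window(w, [SecisModelParams.default(SecisClass.ESECIS_I)])
        assert cands
        for c in cands:
            assert 1000 <= c.start < c.end <= 1200
            assert c.strand == "-"


class TestEuryarchaealFlags:
    def test_planted_canonical_flag(self, rng):
        for want in (True, False):
            plant = build_secis(SecisClass.EASECIS, rng, canonical_ss=want)
            wseq = plant.sequence + "ACGT" * 10
            w = _window(wseq)
            cands = scan_window(w, [SecisModelParams.default(SecisClass.EASECIS)])
            assert cands
            hits = [c for c in cands if c.window_start == 0]
            assert hits
            flags = classify_euryarchaeal(hits[0])
            assert flags.has_SS_triplet == want

    def test_triplet_flag_matches_brute_force(self, rng):
        for _ in range(20):
            plant = build_secis(SecisClass.EASECIS, rng)
            w = _window(plant.sequence)
            cands = scan_window(w, [SecisModelParams.default(SecisClass.EASECIS)])
            for c in cands:
                expect = ss_triplet_brute(
                    c.sequence, c.structure.upper_stem_pairs,
                    offset=c.structure.start,
                )
                assert classify_euryarchaeal(c).has_SS_triplet == expect

    def test_core_motif_binning(self, rng):
        wseq, _plant, off = plant_in_window(SecisClass.ESECIS_I, rng)
        w = Utr3Window("c", 0, len(wseq), "+", wseq, 30)
        for c in scan_window(w, [SecisModelParams.default(SecisClass.ESECIS_I)]):
            motif = classify_euryarchaeal(c).core_motif
            assert motif in ("AUGA_GA", "GUGA_GA", "AUGA_AA", "other")


class TestCompositionProfiles:
    class _C:
        def __init__(self, core, run):
            self.core_context = core
            self.adenine_run = run

    def test_two_core_variants(self):
        cands = [self._C("AUGA_GA", "AAAAA"), self._C("GUGA_GA", "AAAAA")]
        prof = composition_profiles(cands, "core")
        freqs = prof.frequencies
        assert freqs.loc[0, "A"] == pytest.approx(0.5)
        assert freqs.loc[0, "G"] == pytest.approx(0.5)
        assert freqs.loc[2, "G"] == pytest.approx(1.0)

    def test_empty_candidate_list_flagged(self):
        prof = composition_profiles([], "core")
        assert prof.empty and prof.n_sequences == 0
        assert int(prof.counts.to_numpy().sum()) == 0

    def test_planted_adenine_prefix_frequency_one(self, rng):
        from selenoscan.secis import candidate_from_structure
        from selenoscan.seqio import to_rna

        cands = []
        for _ in range(40):
            plant = build_secis(SecisClass.ESECIS_I, rng, adenine_prefix=5)
            w = _window(plant.sequence)
            cands.append(candidate_from_structure(
                plant.structure, w, to_rna(plant.sequence)))
        prof = composition_profiles(cands, "apical_adenines")
        freqs = prof.frequencies
        for pos in range(5):
            assert freqs.loc[pos, "A"] == pytest.approx(1.0)

    def test_column_frequencies_sum_to_one(self):
        cands = [self._C("AUGA_GA", "AAGCA"), self._C("AUGA_AA", "AAAAA")]
        prof = composition_profiles(cands, "apical_adenines")
        sums = prof.frequencies.sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_unknown_region(self):
        with pytest.raises(ValueError):
            composition_profiles([], "stem")
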