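"""Sec/TGA pair finding, ORF extension, trait classification, operons."""

import itertools

import numpy as np
import pytest

from selenoscan.finder import (
    AlignmentFormatError,
    AlignmentRecord,
    SearchThresholds,
    classify_sec_trait,
    detect_operon_pairs,
    extend_orf,
    find_sec_tga_pairs,
    find_selenoproteins,
    inventory_machinery,
    local_align_protein_vs_sixframe,
    read_tabular_alignments,
    MACHINERY_COMPONENTS,
)
from selenoscan.seqio import GeneAnnotation, GenomeRecord, reverse_complement

from _oracle import brute_force_operon_pairs


def _aln(**kw):
    base = dict(query_id="q", subject_id="c", percent_identity=100.0,
                length=3, qstart=1, qend=3, sstart=10, send=18,
                evalue=1e-9, bitscore=50.0, qseq="MKU", sseq="MK*")
    base.update(kw)
    return AlignmentRecord(**base)


class TestTabularAlignments:
    HEADER14 = ("q1\tc1\t95.0\t40\t2\t0\t1\t40\t100\t219\t1e-20\t80.5\t"
                "MKUAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA\t"
                "MK*AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA\n")

    def test_well_formed_line(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(self.HEADER14)
        (rec,) = read_tabular_alignments(p)
        assert rec.strand == "+" and not rec.below_threshold
        assert rec.qseq.startswith("MKU")

    def test_minus_strand_decoded(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(self.HEADER14.replace("\t100\t219\t", "\t219\t100\t"))
        (rec,) = read_tabular_alignments(p)
        assert rec.strand == "-"

    def test_below_threshold_flagged_not_dropped(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(self.HEADER14.replace("1e-20", "0.5"))
        (rec,) = read_tabular_alignments(p)
        assert rec.below_threshold

    def test_plain_outfmt6_is_dialect_error(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("q\tc\t90\t10\t1\t0\t1\t10\t1\t30\t1e-5\t20\n")
        with pytest.raises(AlignmentFormatError) as e:
            read_tabular_alignments(p)
        assert "qseq/sseq" in str(e.value)

    def test_truncated_row_names_row_number(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(self.HEADER14 + "q\tc\t90\n")
        with pytest.raises(AlignmentFormatError) as e:
            read_tabular_alignments(p)
        assert "row 2" in str(e.value)


class TestSecTgaPairs:
    def test_plus_strand_arithmetic(self):
        #           1         10:  M  K  *
        genome = GenomeRecord("c", "AAAAAAAAA" + "ATGAAATGA" + "CCC")
        pairs = find_sec_tga_pairs(_aln(), genome)
        assert pairs == [(3, (15, 18), "+")]
        assert genome.sequence[15:18] == "TGA"

    def test_non_tga_stop_not_returned(self):
        genome = GenomeRecord("c", "AAAAAAAAA" + "ATGAAATAA" + "CCC")
        assert find_sec_tga_pairs(_aln(), genome) == []

    def test_query_u_on_subject_gap_skipped(self):
        genome = GenomeRecord("c", "AAAAAAAAA" + "ATGAAA" + "CCCCCC")
        aln = _aln(qseq="MKU", sseq="MK-", send=15, length=3)
        assert find_sec_tga_pairs(aln, genome) == []

    def test_minus_strand_arithmetic(self):
        fwd = "ATGAAATGA"  # M K U(stop) on the coding strand
        genome = GenomeRecord("c", "GG" + reverse_complement(fwd) + "TT")
        # coding strand runs 11 -> 3 in 1-based plus coordinates
        aln = _aln(sstart=11, send=3)
        pairs = find_sec_tga_pairs(aln, genome)
        assert len(pairs) == 1
        (qpos, (cs, ce), strand) = pairs[0]
        assert strand == "-" and qpos == 3
        assert reverse_complement(genome.sequence[cs:ce]) == "TGA"

    def test_wrong_contig_is_inconsistency(self):
        with pytest.raises(Exception):
            find_sec_tga_pairs(_aln(subject_id="other"),
                               GenomeRecord("c", "ACGT" * 10))


class TestExtendOrf:
    def test_simple_readthrough_orf(self):
        genome = GenomeRecord("c", "CCC" + "ATGAAATGAGGGTAA" + "CC")
        call = extend_orf(genome, 9, "+")
        assert call.protein == "MKUG"
        assert (call.start, call.end) == (3, 18)
        assert call.sec_positions == (3,)

    def test_no_upstream_start_flagged(self):
        genome = GenomeRecord("c", "AAATAACCCTGAGGGTAA")
        call = extend_orf(genome, 9, "+")
        assert call.start_missing
        assert call.start == 6  # first codon after the bounding TAA

    def test_minus_strand_mirrors_plus(self):
        fwd = "CCCATGAAATGAGGGTAACC"
        genome = GenomeRecord("c", reverse_complement(fwd))
        n = len(fwd)
        call = extend_orf(genome, n - 9 - 3, "-")
        assert call.protein == "MKUG"
        assert (n - call.end, n - call.start) == (3, 18)

    def test_not_a_tga_codon_raises(self):
        with pytest.raises(Exception):
            extend_orf(GenomeRecord("c", "ATGAAATAA"), 0, "+")

    def test_missing_stop_flagged(self):
        genome = GenomeRecord("c", "ATGTGAAAAAAA")
        call = extend_orf(genome, 3, "+")
        assert call.stop_missing


class TestTraitCriterion:
    FULL = {c: True for c in MACHINERY_COMPONENTS}

    def test_full_machinery_one_hit_is_positive(self):
        rep = classify_sec_trait(self.FULL, 1)
        assert rep.verdict == "Sec+" and rep.reasons == ()

    def test_two_machinery_genes_insufficient(self):
        rep = classify_sec_trait({"SecS": True, "EFSec": True}, 3)
        assert rep.verdict == "Sec-"
        assert any("machinery" in r for r in rep.reasons)

    def test_no_selenoprotein_insufficient(self):
        rep = classify_sec_trait(self.FULL, 0)
        assert rep.verdict == "Sec-"
        assert any("selenoprotein" in r for r in rep.reasons)

    def test_exhaustive_truth_table_default_and_strict(self):
        for bits in itertools.product([False, True], repeat=5):
            machinery = dict(zip(MACHINERY_COMPONENTS, bits))
            count = sum(bits)
            for n_hits in (0, 1, 2):
                default = classify_sec_trait(machinery, n_hits)
                assert (default.verdict == "Sec+") == (count >= 3 and n_hits >= 1)
                strict = classify_sec_trait(machinery, n_hits,
                                            require_trna=True)
                expect = (count >= 3 and n_hits >= 1
                          and machinery["tRNA-Sec"])
                assert (strict.verdict == "Sec+") == expect
                # strict differs exactly on tRNA-absent rows that pass default
                differs = default.verdict != strict.verdict
                assert differs == (count >= 3 and n_hits >= 1
                                   and not machinery["tRNA-Sec"])

    def test_inventory_from_product_labels(self):
        anns = [
            GeneAnnotation("c", 0, 300, "+", "g1", "selD"),
            GeneAnnotation("c", 400, 493, "+", "t", "tRNA-Sec", coding=False),
            GeneAnnotation("c", 600, 900, "-", "g2", "unrelated"),
        ]
        inv = inventory_machinery(anns)
        assert inv["SelD"] and inv["tRNA-Sec"]
        assert not inv["SecS"]


class TestOperonPairs:
    def _g(self, start, end, strand, label, cid="c"):
        return GeneAnnotation(cid, start, end, strand,
                              f"{label}_{start}", label)

    def test_short_gap_pair_found(self):
        anns = [self._g(100, 1000, "+", "hdrA"), self._g(1030, 1600, "+", "frhD")]
        ((a, b, gap),) = detect_operon_pairs(anns)
        assert gap == 30 and a.product_label == "hdrA"

    def test_opposite_strands_empty(self):
        anns = [self._g(100, 1000, "+", "hdrA"), self._g(1030, 1600, "-", "frhD")]
        assert detect_operon_pairs(anns) == []

    def test_gap_above_max_empty(self):
        anns = [self._g(100, 1000, "+", "hdrA"), self._g(1500, 2100, "+", "frhD")]
        assert detect_operon_pairs(anns) == []

    def test_matches_brute_force_on_random_sets(self, rng):
        labels = ["hdrA", "frhD", "selD", "frhA", None]
        for _ in range(30):
            anns = []
            for contig in ("c1", "c2"):
                pos = 0
                for _k in range(int(rng.integers(0, 12))):
                    pos += int(rng.integers(0, 120))
                    length = int(rng.integers(1, 10)) * 3
                    label = labels[int(rng.integers(0, len(labels)))]
                    anns.append(GeneAnnotation(
                        contig, pos, pos + length,
                        "+" if rng.random() < 0.5 else "-",
                        f"g{contig}{pos}", label))
                    pos += length
            got = {(a.gene_id, b.gene_id) for a, b, _ in detect_operon_pairs(anns)}
            want = {(a.gene_id, b.gene_id)
                    for a, b, _ in brute_force_operon_pairs(anns)}
            assert got == want


class TestSixFrameAligner:
    def test_identity_alignment_no_gaps(self):
        from selenoscan.simulate import back_translate

        rng = np.random.default_rng(4)
        protein = "MSEKVVLTQYSHGAGCGCKIAPKVLDUILSG"
        nt = back_translate(protein, rng)
        genome = GenomeRecord("c", "CCAGGC" + nt + "TTGCAG")
        rec = local_align_protein_vs_sixframe(protein, genome)
        assert "-" not in rec.qseq and "-" not in rec.sseq
        assert rec.qstart == 1 and rec.qend == len(protein)
        assert rec.evalue < 1e-6

    def test_reverse_strand_planted_gene(self):
        from selenoscan.simulate import back_translate

        rng = np.random.default_rng(5)
        protein = "MVEKIAVDPITRIEGHLRIEAHUDNGVVTDAWS"
        nt = back_translate(protein, rng)
        genome = GenomeRecord("c", "GCA" + reverse_complement(nt) + "TGC")
        rec = local_align_protein_vs_sixframe(protein, genome)
        assert rec.strand == "-"
        pairs = find_sec_tga_pairs(rec, genome)
        assert len(pairs) == 1

    def test_self_score_beats_shuffles(self):
        rng = np.random.default_rng(6)
        protein = "MAKIGVFVCHCGTNIAGTVDVPAUVEYASTLPNVVHAEDN"
        from selenoscan.simulate import back_translate

        nt = back_translate(protein, rng)
        genome = GenomeRecord("c", nt)
        self_score = local_align_protein_vs_sixframe(protein, genome).bitscore
        chars = np.array(list(protein))
        for _ in range(50):
            rng.shuffle(chars)
            shuf = "".join(chars)
            try:
                score = local_align_protein_vs_sixframe(shuf, genome).bitscore
            except ValueError:
                score = 0.0
            assert self_score >= score

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            local_align_protein_vs_sixframe("", GenomeRecord("c", "ACGTAA"))


class TestEndToEnd:
    def test_planted_sec_codons_recovered(self, small_sim):
        truth = {(t.contig_id, t.sec_codon_start, t.strand)
                 for t in small_sim.truth if t.kind == "gene"}
        hits = find_selenoproteins(small_sim.genomes,
                                   queries=small_sim.queries)
        found = {(h.contig_id, h.sec_codon_start, h.strand) for h in hits}
        assert truth <= found  # recall 1.0 at zero mutation rate
        assert found <= truth  # precision 1.0
        for h in hits:
            g = next(x for x in small_sim.genomes if x.id == h.contig_id)
            codon = g.sequence[h.sec_codon_start:h.sec_codon_end]
            if h.strand == "-":
                codon = reverse_complement(codon)
            assert codon == "TGA"

    def test_u_exactly_at_tga_positions(self, small_sim):
        hits = find_selenoproteins(small_sim.genomes,
                                   queries=small_sim.queries)
        for h in hits:
            g = next(x for x in small_sim.genomes if x.id == h.contig_id)
            orf = g.sequence[h.orf_start:h.orf_end]
            if h.strand == "-":
                orf = reverse_complement(orf)
            for i, aa in enumerate(h.protein):
                codon = orf[3 * i:3 * i + 3]
                assert (aa == "U") == (codon == "TGA")

    def test_short_protein_flagged(self):
        thr = SearchThresholds()
        genome = GenomeRecord(
            "c", "TAA" + "ATG" + "AAA" * 5 + "TGA" + "AAA" * 3 + "TAA")
        call = extend_orf(genome, 3 + 3 + 15, "+")
        assert len(call.protein) < thr.min_protein_len_aa
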