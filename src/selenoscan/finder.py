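"""Selenoprotein gene finding via Sec/TGA alignment pairs and UGA read-through.

The detection signal is an alignment column in which a query selenoprotein's
Sec residue (``U``) lines up with a genomic TGA codon.  Around each verified
Sec/TGA pair an open reading frame is extended in-frame — upstream to a
start codon bounded by the first in-frame TAA/TAG, downstream to the first
in-frame TAA/TAG, with TGA read through as Sec — and the hit is labelled
with the family of its supporting query.  An organism's Sec-utilization
verdict combines the machinery inventory (SecS, EFSec, PSTK, SelD,
tRNA-Sec) with the selenoprotein tally: Sec+ requires at least three
machinery genes and at least one selenoprotein.

Production inputs are tabular tblastn/JackHMMER-style alignments carrying
the aligned sequence strings; a small Smith-Waterman six-frame aligner
(:func:`local_align_protein_vs_sixframe`) makes the pipeline self-contained
at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import (
    GeneAnnotation,
    GenomeRecord,
    reverse_complement,
    six_frame_translations,
    translate_readthrough,
)

__all__ = [
    "SearchThresholds",
    "AlignmentRecord",
    "SelenoproteinHit",
    "SecTraitReport",
    "AlignmentFormatError",
    "AlignmentInconsistencyError",
    "MACHINERY_COMPONENTS",
    "read_tabular_alignments",
    "find_sec_tga_pairs",
    "extend_orf",
    "assign_family",
    "classify_sec_trait",
    "detect_operon_pairs",
    "local_align_protein_vs_sixframe",
    "find_selenoproteins",
    "inventory_machinery",
]

MACHINERY_COMPONENTS = ("SecS", "EFSec", "PSTK", "SelD", "tRNA-Sec")

_STOPS = ("TAA", "TAG")
_STARTS = ("ATG", "GTG", "TTG")  # archaeal alternative starts accepted


class AlignmentFormatError(ValueError):
    """Raised for malformed tabular alignment input (names the row)."""


class AlignmentInconsistencyError(ValueError):
    """Raised when alignment coordinate arithmetic leaves the contig."""


@dataclass(frozen=True)
class SearchThresholds:
    """Homology-search bookkeeping thresholds."""

    tblastn_evalue: float = 0.01
    min_alignment_coverage: float = 0.25  # of query or subject
    hmm_evalue: float = 0.05
    ortholog_evalue: float = 0.001
    min_protein_len_aa: int = 35

    def __post_init__(self) -> None:
        if not 0 < self.min_alignment_coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        for f in ("tblastn_evalue", "hmm_evalue", "ortholog_evalue",
                  "min_protein_len_aa"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass(frozen=True)
class AlignmentRecord:
    """One protein-vs-nucleotide local alignment (tblastn-style)."""

    query_id: str
    subject_id: str
    percent_identity: float
    length: int
    qstart: int  # 1-based inclusive, amino acids
    qend: int
    sstart: int  # 1-based inclusive, nucleotides; sstart > send on '-' strand
    send: int
    evalue: float
    bitscore: float
    qseq: str    # aligned query (gaps '-')
    sseq: str    # aligned subject translation (gaps '-')
    qlen: int | None = None
    slen: int | None = None
    below_threshold: bool = False

    def __post_init__(self) -> None:
        if len(self.qseq) != len(self.sseq):
            raise AlignmentFormatError(
                f"{self.query_id} vs {self.subject_id}: aligned strings differ "
                f"in length ({len(self.qseq)} vs {len(self.sseq)})"
            )

    @property
    def strand(self) -> str:
        return "+" if self.sstart <= self.send else "-"

    @property
    def query_coverage(self) -> float | None:
        if not self.qlen:
            return None
        return (self.qend - self.qstart + 1) / self.qlen


_DIALECT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send "
    "evalue bitscore qseq sseq"
).split()


def read_tabular_alignments(path: str | Path,
                            thresholds: SearchThresholds | None = None,
                            ) -> list[AlignmentRecord]:
    """Parse extended outfmt-6-like TSV (``std qseq sseq`` [+ qlen slen]).

    Records failing the thresholds are retained but flagged
    ``below_threshold``.  A 12-column file (plain outfmt 6) raises an
    explicit dialect error; a truncated row raises a row-level parse error.
    """
    thr = thresholds or SearchThresholds()
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for rowno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) == 12:
                raise AlignmentFormatError(
                    f"{path}:{rowno}: dialect lacks qseq/sseq columns "
                    "(plain outfmt 6?)"
                )
            if len(f) < 14:
                raise AlignmentFormatError(
                    f"{path}: row {rowno} truncated: expected >=14 columns, "
                    f"got {len(f)}"
                )
            try:
                rec = AlignmentRecord(
                    query_id=f[0], subject_id=f[1],
                    percent_identity=float(f[2]), length=int(f[3]),
                    qstart=int(f[6]), qend=int(f[7]),
                    sstart=int(f[8]), send=int(f[9]),
                    evalue=float(f[10]), bitscore=float(f[11]),
                    qseq=f[12].upper(), sseq=f[13].upper(),
                    qlen=int(f[14]) if len(f) > 14 else None,
                    slen=int(f[15]) if len(f) > 15 else None,
                )
            except (ValueError, IndexError) as exc:
                raise AlignmentFormatError(
                    f"{path}: row {rowno}: {exc}"
                ) from exc
            flag = rec.evalue > thr.tblastn_evalue
            cov = rec.query_coverage
            if cov is not None and cov < thr.min_alignment_coverage:
                flag = True
            records.append(replace(rec, below_threshold=flag))
    return records


def find_sec_tga_pairs(aln: AlignmentRecord, genome: GenomeRecord,
                       ) -> list[tuple[int, tuple[int, int], str]]:
    """Verified Sec/TGA pairs from one alignment.

    For each query ``U`` (or subject ``*``) at a column where the subject is
    not gapped, the column is mapped through frame/strand arithmetic to a
    genomic codon and kept only when the coding-strand codon is TGA.
    Returns ``(query Sec position (1-based aa), (codon start, codon end)
    0-based half-open on the plus strand, strand)`` triples.
    """
    if aln.subject_id != genome.id:
        raise AlignmentInconsistencyError(
            f"alignment subject {aln.subject_id!r} != contig {genome.id!r}"
        )
    out = []
    qpos = aln.qstart - 1  # next query residue index (0-based)
    soff = 0               # subject aa offset within the alignment
    plus = aln.strand == "+"
    for qc, sc in zip(aln.qseq, aln.sseq):
        q_here = qpos if qc != "-" else None
        if qc != "-":
            qpos += 1
        if sc == "-":
            continue
        if (qc == "U" or sc == "*") and qc != "-":
            if plus:
                cs = (aln.sstart - 1) + 3 * soff
            else:
                cs = (aln.sstart - 1) - 3 * soff - 2
            if cs < 0 or cs + 3 > len(genome):
                raise AlignmentInconsistencyError(
                    f"{aln.query_id} vs {genome.id}: codon [{cs},{cs + 3}) "
                    "outside contig"
                )
            codon = genome.sequence[cs:cs + 3]
            coding = codon if plus else reverse_complement(codon)
            if coding == "TGA":
                out.append((q_here + 1, (cs, cs + 3), aln.strand))
        soff += 1
    return out


@dataclass(frozen=True)
class OrfCall:
    start: int   # genomic 0-based half-open, stop codon included when found
    end: int
    strand: str
    protein: str  # with U at read-through TGA codons
    sec_positions: tuple[int, ...]  # 1-based residue numbers that are U
    start_missing: bool = False
    stop_missing: bool = False


def extend_orf(genome: GenomeRecord, tga_codon_start: int, strand: str,
               starts: tuple[str, ...] = _STARTS) -> OrfCall:
    """Extend an in-frame ORF around a (putative Sec) TGA codon.

    Upstream extension is bounded by the first in-frame TAA/TAG and takes
    the farthest upstream start codon inside that bound (longest ORF);
    downstream extension runs to the first in-frame TAA/TAG with TGA read
    through.  Missing starts/stops at contig edges are flagged, not errors.
    """
    seq = genome.sequence
    n = len(seq)
    if strand == "-":
        # mirror into reverse-complement coordinates and recurse on '+'
        rc = GenomeRecord(genome.id, reverse_complement(seq))
        rc_start = n - tga_codon_start - 3
        call = extend_orf(rc, rc_start, "+", starts)
        return OrfCall(
            start=n - call.end, end=n - call.start, strand="-",
            protein=call.protein, sec_positions=call.sec_positions,
            start_missing=call.start_missing, stop_missing=call.stop_missing,
        )
    if not (0 <= tga_codon_start and tga_codon_start + 3 <= n):
        raise AlignmentInconsistencyError(
            f"TGA codon start {tga_codon_start} outside contig"
        )
    if seq[tga_codon_start:tga_codon_start + 3] != "TGA":
        raise AlignmentInconsistencyError(
            f"codon at {tga_codon_start} is "
            f"{seq[tga_codon_start:tga_codon_start + 3]!r}, not TGA"
        )
    # downstream
    end = None
    stop_missing = False
    p = tga_codon_start + 3
    while p + 3 <= n:
        codon = seq[p:p + 3]
        if codon in _STOPS:
            end = p + 3
            break
        p += 3
    if end is None:
        end = p
        stop_missing = True
    # upstream
    best_start = None
    start_missing = False
    p = tga_codon_start - 3
    boundary = None
    while p >= 0:
        codon = seq[p:p + 3]
        if codon in _STOPS:
            boundary = p
            break
        if codon in starts:
            best_start = p  # keeps updating: farthest upstream wins
        p -= 3
    if best_start is None:
        start_missing = True
        best_start = (boundary + 3) if boundary is not None else (
            tga_codon_start % 3
        )
    protein = translate_readthrough(seq[best_start:end], 0, readthrough_tga=True)
    secpos = tuple(i + 1 for i, aa in enumerate(protein) if aa == "U")
    return OrfCall(best_start, end, "+", protein, secpos,
                   start_missing, stop_missing)


@dataclass(frozen=True)
class SelenoproteinHit:
    """A TGA-recoded gene call anchored on a verified Sec codon."""

    contig_id: str
    family: str
    sec_codon_start: int  # 0-based, plus-strand leftmost base of the TGA
    sec_codon_end: int
    strand: str
    orf_start: int
    orf_end: int
    protein: str
    supports: tuple[str, ...] = ()
    passed_length_filter: bool = True
    start_missing: bool = False
    stop_missing: bool = False
    has_secis: bool = False

    def __post_init__(self) -> None:
        if "U" not in self.protein:
            raise ValueError("selenoprotein hit without U in protein")


def assign_family(hit: SelenoproteinHit, query_id: str,
                  family_map: dict[str, str] | None = None,
                  min_protein_len_aa: int = 35) -> SelenoproteinHit:
    """Label a hit with its supporting query's family and length-filter flag."""
    family = (family_map or {}).get(query_id, query_id.split("|")[0])
    return replace(
        hit,
        family=family,
        supports=tuple(sorted(set(hit.supports) | {query_id})),
        passed_length_filter=len(hit.protein) >= min_protein_len_aa,
    )


def dedup_hits(hits: list[SelenoproteinHit]) -> list[SelenoproteinHit]:
    """Merge hits on identical genomic Sec codons, pooling their supports."""
    merged: dict[tuple, SelenoproteinHit] = {}
    for h in hits:
        key = (h.contig_id, h.sec_codon_start, h.strand)
        if key in merged:
            prev = merged[key]
            merged[key] = replace(
                prev, supports=tuple(sorted(set(prev.supports) | set(h.supports)))
            )
        else:
            merged[key] = h
    return sorted(merged.values(),
                  key=lambda h: (h.contig_id, h.sec_codon_start))


# ---------------------------------------------------------------------------
# Trait classification

@dataclass(frozen=True)
class SecTraitReport:
    """Per-organism machinery inventory and Sec+/Sec- verdict."""

    organism_id: str
    machinery: dict[str, bool]
    machinery_count: int
    selenoprotein_tally: dict[str, int]
    selenoprotein_count: int
    verdict: str  # "Sec+" | "Sec-"
    reasons: tuple[str, ...]


def classify_sec_trait(machinery: dict[str, bool],
                       selenoprotein_hits,
                       organism_id: str = "",
                       min_machinery: int = 3,
                       min_selenoproteins: int = 1,
                       require_trna: bool = False) -> SecTraitReport:
    """Apply the two-part Sec-utilization criterion.

    Sec+ requires (i) at least ``min_machinery`` distinct Sec-machinery
    genes (tRNA-Sec counts toward the tally; with ``require_trna`` it is
    additionally mandatory) and (ii) at least ``min_selenoproteins`` known
    selenoprotein genes.  Presence/absence only: multiple copies of one
    component count once.
    """
    presence = {c: bool(machinery.get(c, False)) for c in MACHINERY_COMPONENTS}
    count = sum(presence.values())
    if isinstance(selenoprotein_hits, int):
        tally: dict[str, int] = {"selenoprotein": selenoprotein_hits} if selenoprotein_hits else {}
        n_hits = selenoprotein_hits
    else:
        tally = {}
        for h in selenoprotein_hits:
            tally[h.family] = tally.get(h.family, 0) + 1
        n_hits = sum(tally.values())
    reasons = []
    if count < min_machinery:
        reasons.append(
            f"only {count} Sec-machinery genes (need >={min_machinery})"
        )
    if require_trna and not presence["tRNA-Sec"]:
        reasons.append("tRNA-Sec absent (strict mode)")
    if n_hits < min_selenoproteins:
        reasons.append(
            f"only {n_hits} selenoprotein genes (need >={min_selenoproteins})"
        )
    verdict = "Sec+" if not reasons else "Sec-"
    return SecTraitReport(
        organism_id=organism_id, machinery=presence, machinery_count=count,
        selenoprotein_tally=tally, selenoprotein_count=n_hits,
        verdict=verdict, reasons=tuple(reasons),
    )


_MACHINERY_SYNONYMS = {
    "secs": "SecS", "efsec": "EFSec", "pstk": "PSTK", "seld": "SelD",
    "trna-sec": "tRNA-Sec", "trnasec": "tRNA-Sec", "sectrna": "tRNA-Sec",
}


def inventory_machinery(annotations: list[GeneAnnotation]) -> dict[str, bool]:
    """Presence map of Sec-machinery components from product labels."""
    present = {c: False for c in MACHINERY_COMPONENTS}
    for g in annotations:
        if not g.product_label:
            continue
        comp = _MACHINERY_SYNONYMS.get(g.product_label.strip().lower())
        if comp:
            present[comp] = True
    return present


# ---------------------------------------------------------------------------
# Operon adjacency

def detect_operon_pairs(annotations: list[GeneAnnotation],
                        labels: tuple[str, str] = ("hdrA", "frhD"),
                        max_gap_nt: int = 60,
                        ) -> list[tuple[GeneAnnotation, GeneAnnotation, int]]:
    """Adjacent same-strand gene pairs with the two labels and a short gap.

    A pair qualifies when the two labels occur consecutively (no other
    same-strand gene between them on the contig) on one strand with an
    intergenic distance of at most ``max_gap_nt``.  Either label order is
    accepted; returned as (upstream gene, downstream gene, gap).
    """
    want = {labels[0].lower(), labels[1].lower()}
    pairs = []
    by_group: dict[tuple[str, str], list[GeneAnnotation]] = {}
    for g in annotations:
        by_group.setdefault((g.contig_id, g.strand), []).append(g)
    for group in by_group.values():
        group.sort(key=lambda g: (g.start, g.end))
        for a, b in zip(group, group[1:]):
            la = (a.product_label or "").lower()
            lb = (b.product_label or "").lower()
            if {la, lb} != want:
                continue
            gap = b.start - a.end
            if gap <= max_gap_nt:
                pairs.append((a, b, gap))
    return pairs


# ---------------------------------------------------------------------------
# Self-contained six-frame aligner

_EXT_MATRIX = None


def _extended_blosum62(sec_stop_bonus: float = 8.0):
    """BLOSUM62 extended with a U row scored like C, and U-vs-* rewarded."""
    global _EXT_MATRIX
    if _EXT_MATRIX is not None and _EXT_MATRIX[0] == sec_stop_bonus:
        return _EXT_MATRIX[1]
    b62 = substitution_matrices.load("BLOSUM62")
    alpha = b62.alphabet + "U"
    m = substitution_matrices.Array(alphabet=alpha, dims=2)
    for a in b62.alphabet:
        for b in b62.alphabet:
            m[a, b] = b62[a, b]
    for a in b62.alphabet:
        c = b62["C", a]
        m["U", a] = m[a, "U"] = c
    m["U", "U"] = b62["C", "C"]
    m["U", "*"] = m["*", "U"] = sec_stop_bonus
    _EXT_MATRIX = (sec_stop_bonus, m)
    return m


def local_align_protein_vs_sixframe(query: str, genome: GenomeRecord,
                                    sec_stop_bonus: float = 8.0,
                                    open_gap: float = -11.0,
                                    extend_gap: float = -1.0,
                                    ) -> AlignmentRecord:
    """Best six-frame Smith-Waterman alignment of a Sec-containing protein.

    Scores U like cysteine against residues and gives U-vs-stop(``*``) a
    configurable bonus so that Sec/TGA columns out-score chance.  Returns
    the best frame's alignment in :class:`AlignmentRecord` form with a
    Karlin-Altschul e-value estimate (BLOSUM62 gapped parameters,
    lambda = 0.267, K = 0.041) over the query x six-frame search space, so the
    standard homology-search thresholds remain meaningful.
    """
    if not query or not len(genome.sequence):
        raise ValueError("empty query or genome")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _extended_blosum62(sec_stop_bonus)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    best = None
    search_space_aa = 0
    for frame, trans in six_frame_translations(genome.sequence):
        if not trans:
            continue
        search_space_aa += len(trans)
        alns = aligner.align(trans, query.upper())
        if len(alns) == 0:
            continue
        aln = alns[0]
        if best is None or aln.score > best[1].score:
            best = (frame, aln, trans)
    if best is None:
        raise ValueError("no alignment found in any frame")
    frame, aln, trans = best
    (tstart, tend), (qstart, qend) = (
        (aln.coordinates[0][0], aln.coordinates[0][-1]),
        (aln.coordinates[1][0], aln.coordinates[1][-1]),
    )
    sseq_aligned, qseq_aligned = str(aln[0]), str(aln[1])
    n = len(genome.sequence)
    if frame > 0:
        off = frame - 1
        sstart = off + 3 * tstart + 1
        send = off + 3 * tend
    else:
        off = -frame - 1
        sstart = n - (off + 3 * tstart)
        send = n - (off + 3 * tend) + 1
    ncols = len(qseq_aligned)
    ident = sum(1 for a, b in zip(qseq_aligned, sseq_aligned)
                if a == b and a != "-")
    # effective search space spans all six reading frames
    evalue = 0.041 * len(query) * search_space_aa * np.exp(-0.267 * aln.score)
    return AlignmentRecord(
        query_id="query", subject_id=genome.id,
        percent_identity=100.0 * ident / ncols if ncols else 0.0,
        length=ncols,
        qstart=qstart + 1, qend=qend,
        sstart=sstart, send=send,
        evalue=float(evalue), bitscore=float(aln.score),
        qseq=qseq_aligned, sseq=sseq_aligned,
        qlen=len(query),
    )


# ---------------------------------------------------------------------------
# End-to-end helper

def find_selenoproteins(genomes: list[GenomeRecord],
                        queries: dict[str, str] | None = None,
                        alignments: list[AlignmentRecord] | None = None,
                        thresholds: SearchThresholds | None = None,
                        ) -> list[SelenoproteinHit]:
    """Find selenoprotein genes from queries (via the built-in aligner) or
    from precomputed tabular alignments.

    Alignments flagged below-threshold are excluded from hit building.
    Hits on identical Sec codons are merged; proteins shorter than the
    length threshold are flagged rather than dropped.
    """
    thr = thresholds or SearchThresholds()
    by_id = {g.id: g for g in genomes}
    recs: list[tuple[str, AlignmentRecord]] = []
    if alignments is not None:
        recs.extend((a.query_id, a) for a in alignments if not a.below_threshold)
    if queries is not None:
        for qid, qseq in queries.items():
            for g in genomes:
                try:
                    rec = local_align_protein_vs_sixframe(qseq, g)
                except ValueError:
                    continue
                if rec.evalue > thr.tblastn_evalue:
                    continue
                cov = rec.query_coverage
                if cov is not None and cov < thr.min_alignment_coverage:
                    continue
                recs.append((qid, replace(rec, query_id=qid)))
    hits: list[SelenoproteinHit] = []
    for qid, rec in recs:
        genome = by_id.get(rec.subject_id)
        if genome is None:
            continue
        for _qpos, (cs, ce), strand in find_sec_tga_pairs(rec, genome):
            orf = extend_orf(genome, cs, strand)
            if "U" not in orf.protein:
                continue
            hit = SelenoproteinHit(
                contig_id=genome.id, family=qid,
                sec_codon_start=cs, sec_codon_end=ce, strand=strand,
                orf_start=orf.start, orf_end=orf.end, protein=orf.protein,
                start_missing=orf.start_missing, stop_missing=orf.stop_missing,
            )
            hits.append(assign_family(hit, qid,
                                      min_protein_len_aa=thr.min_protein_len_aa))
    return dedup_hits(hits)
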