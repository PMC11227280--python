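"""Sequence and annotation I/O, coordinate conventions, and genetic-code utilities.

All coordinates are 0-based half-open internally.  GFF3 files are converted
from/to 1-based inclusive at the parsing boundary; BED files are already
0-based half-open.  Sequences are stored in the DNA alphabet (``T``); ``U``
is accepted on input and normalised to ``T``.  Transliteration back to RNA
happens only at the pattern-matching/presentation boundary
(:func:`to_rna`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "GenomeRecord",
    "GeneAnnotation",
    "Utr3Window",
    "FastaFormatError",
    "AnnotationFormatError",
    "CoordinateError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "write_report",
    "read_report",
    "reverse_complement",
    "to_rna",
    "to_dna",
    "extract_utr3_window",
    "translate_readthrough",
]

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised on malformed FASTA input (names the offending record/line)."""


class AnnotationFormatError(ValueError):
    """Raised on malformed GFF3/BED input (names the offending line)."""


class CoordinateError(ValueError):
    """Raised when an interval does not lie on its contig."""


@dataclass(frozen=True)
class GenomeRecord:
    """A contig (e.g. one sequence of a metagenome-assembled genome)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaFormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise FastaFormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus on a contig; 0-based half-open, strand '+' or '-'."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    product_label: str | None = None
    coding: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"gene {self.gene_id!r}: bad interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if self.coding and (self.end - self.start) % 3 != 0:
            raise CoordinateError(
                f"gene {self.gene_id!r}: coding length {self.end - self.start} "
                "is not a multiple of 3"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Utr3Window:
    """Transcript-oriented window around the 3' end of a gene.

    ``sequence`` reads 5'->3' relative to the transcript (reverse-complemented
    for minus-strand genes) and is stored in the DNA alphabet.
    ``offset_of_stop`` is the index within the window of the first position
    past the gene's 3' end (i.e. the number of gene-overlapping nucleotides
    kept upstream).
    """

    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str
    offset_of_stop: int

    def __len__(self) -> int:
        return self.end - self.start

    def to_genomic(self, pos: int) -> int:
        """Map a window position to a genomic (plus-strand) position."""
        if not 0 <= pos < len(self):
            raise CoordinateError(f"window position {pos} outside [0,{len(self)})")
        if self.strand == "+":
            return self.start + pos
        return self.end - 1 - pos

    def interval_to_genomic(self, wstart: int, wend: int) -> tuple[int, int]:
        """Map a half-open window interval to a half-open genomic interval."""
        if self.strand == "+":
            return self.start + wstart, self.start + wend
        return self.end - wend, self.end - wstart


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """DNA -> RNA transliteration (the single T/U boundary)."""
    return seq.replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Lowercase is uppercased and ``U`` mapped to ``T``.  Empty sequences and
    duplicate ids raise :class:`FastaFormatError`.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[GenomeRecord] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.sequence) if isinstance(rec, GenomeRecord) else rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 / BED

def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise AnnotationFormatError(f"bad GFF3 attribute {part!r}")
        k, v = part.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Read a (subset) GFF3 file into gene annotations.

    Only the 9 mandatory columns are interpreted; ``ID`` and ``product``
    attributes populate ``gene_id`` and ``product_label``.  Feature types
    other than CDS/gene/tRNA are kept verbatim (``coding`` is True only for
    CDS features).
    """
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            contig, _source, ftype, start, end, _score, strand, _frame, attr = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationFormatError(f"{path}:{lineno}: bad coordinates") from exc
            attrs = _parse_gff3_attributes(attr)
            genes.append(
                GeneAnnotation(
                    contig_id=contig,
                    start=start_i - 1,  # GFF3 is 1-based inclusive
                    end=end_i,
                    strand=strand,
                    gene_id=attrs.get("ID", f"{contig}:{start}-{end}"),
                    product_label=attrs.get("product"),
                    coding=(ftype == "CDS"),
                )
            )
    return genes


def write_gff3(genes: Iterable[GeneAnnotation], path: str | Path,
               source: str = "selenoscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = "CDS" if g.coding else "gene"
            attrs = f"ID={g.gene_id}"
            if g.product_label:
                attrs += f";product={g.product_label}"
            fh.write(
                "\t".join(
                    [g.contig_id, source, ftype, str(g.start + 1), str(g.end),
                     ".", g.strand, ".", attrs]
                )
                + "\n"
            )


def read_bed(path: str | Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise AnnotationFormatError(f"{path}:{lineno}: BED needs >=3 columns")
            row = {"contig_id": f[0], "start": int(f[1]), "end": int(f[2])}
            if len(f) > 3:
                row["name"] = f[3]
            if len(f) > 4:
                row["score"] = f[4]
            if len(f) > 5:
                row["strand"] = f[5]
            rows.append(row)
    return rows


def _as_row(obj) -> dict:
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, dict):
        return dict(obj)
    raise TypeError(f"cannot serialise {type(obj).__name__}")


def write_bed(records: Iterable, path: str | Path) -> None:
    """Write records carrying contig_id/start/end(/name/score/strand) as BED."""
    with open(path, "w") as fh:
        for rec in records:
            row = _as_row(rec)
            name = row.get("name") or row.get("gene_id") or row.get("model_class") or "."
            score = str(row.get("score", 0))
            strand = row.get("strand", ".")
            fh.write(
                f"{row['contig_id']}\t{row['start']}\t{row['end']}\t{name}\t{score}\t{strand}\n"
            )


def write_report(records: Sequence, path: str | Path, format: str = "tsv",
                 columns: Sequence[str] | None = None) -> None:
    """Write a homogeneous record collection as TSV, BED or JSON.

    TSV/JSON round-trip losslessly for flat dataclasses; BED keeps the
    coordinate fields plus a name column.  An empty collection yields a
    header-only TSV / empty JSON list.
    """
    format = format.lower()
    if format == "bed":
        write_bed(records, path)
        return
    rows = [_as_row(r) for r in records]
    if format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_cell(row.get(c)) for c in columns) + "\n")


def _cell(v) -> str:
    if v is None:
        return ""
    if isinstance(v, (list, tuple, dict)):
        return json.dumps(v)
    return str(v)


def read_report(path: str | Path, format: str = "json"):
    if format.lower() == "json":
        with open(path) as fh:
            return json.load(fh)
    raise ValueError(f"read_report supports json, not {format!r}")


# ---------------------------------------------------------------------------
# Windows and translation

def extract_utr3_window(genome: GenomeRecord, gene: GeneAnnotation,
                        upstream: int = 30, downstream: int = 600) -> Utr3Window:
    """Extract the 3'-UTR search window around a gene's 3' end.

    The window spans ``upstream`` nt into the gene (measured from the
    annotated CDS end, stop codon included) and ``downstream`` nt past it,
    clamped at contig boundaries; the returned sequence is
    transcript-oriented (reverse-complemented for minus-strand genes).
    """
    if gene.contig_id != genome.id or gene.end > len(genome):
        raise CoordinateError(
            f"gene {gene.gene_id!r} does not lie on contig {genome.id!r}"
        )
    if gene.strand == "+":
        gstart = max(0, gene.end - upstream)
        gend = min(len(genome), gene.end + downstream)
        seq = genome.sequence[gstart:gend]
        offset = gene.end - gstart
    else:
        gstart = max(0, gene.start - downstream)
        gend = min(len(genome), gene.start + upstream)
        seq = reverse_complement(genome.sequence[gstart:gend])
        offset = gend - gene.start
    return Utr3Window(genome.id, gstart, gend, gene.strand, seq, offset)


def _build_codon_table() -> dict[str, str]:
    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:  # TAA, TAG, TGA
        table[stop] = "*"
    return table


_CODON_TABLE = _build_codon_table()


def translate_readthrough(nt: str, frame: int = 0, readthrough_tga: bool = True) -> str:
    """Translate with optional UGA->Sec read-through.

    TAA/TAG always terminate; TGA yields ``U`` and translation continues when
    ``readthrough_tga`` is set, otherwise it terminates.  Codons containing
    ``N`` translate to ``X``; a trailing partial codon is ignored.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    nt = to_dna(nt.upper())
    out: list[str] = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            out.append("X")
            continue
        aa = _CODON_TABLE[codon]
        if aa == "*":
            if codon == "TGA" and readthrough_tga:
                out.append("U")
                continue
            break
        out.append(aa)
    return "".join(out)


def translate(nt: str, frame: int = 0) -> str:
    """Standard translation, stopping at the first stop codon."""
    return translate_readthrough(nt, frame, readthrough_tga=False)


def six_frame_translations(seq: str) -> list[tuple[int, str]]:
    """All six frames as (frame, translation-with-*-for-stops).

    Frames 1..3 are the plus strand offsets 0..2; frames -1..-3 the minus
    strand offsets 0..2 of the reverse complement.  Stops are kept as ``*``
    so that alignment against Sec-containing queries can see them.
    """
    out = []
    rc = reverse_complement(seq)
    for off in range(3):
        out.append((off + 1, _translate_all(seq, off)))
        out.append((-(off + 1), _translate_all(rc, off)))
    return out


def _translate_all(nt: str, frame: int) -> str:
    out = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        out.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(out)
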