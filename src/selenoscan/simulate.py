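"""Deterministic benchmark-genome generator with a machine-readable truth ledger.

Plants selenoprotein genes (one in-frame TGA each), Sec-machinery genes and
3'-UTR SECIS elements of each structural class into random-background
contigs with controlled GC, on both strands, without overlap.  Every planted
SECIS is constructed to satisfy its model's constraints *including* the
free-energy criterion (resampled until it does), and every planted gene is
preceded by an in-frame stop so that the planted open reading frame is
exactly recoverable; the truth ledger records coordinates, classes and the
structural parameters actually drawn.

Family protein templates are short fixed synthetic sequences (one Sec each)
loosely echoing the compositions of the archaeal selenoprotein families
they stand for; they carry family labels so that query-based search and
family assignment are meaningful without external databases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import secis as _secis
from .energy import evaluate as _energy_eval, normalize_hairpins
from .seqio import (
    GeneAnnotation,
    GenomeRecord,
    reverse_complement,
    to_dna,
    to_rna,
    write_fasta,
    write_gff3,
)
from .secis import (
    SecisClass,
    SecisModelParams,
    SecisStructure,
    validate_candidate,
)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SecisPlant",
    "SimResult",
    "CapacityError",
    "FAMILY_TEMPLATES",
    "build_secis",
    "plant_in_window",
    "simulate",
    "dinucleotide_shuffle",
    "shuffle_negative_controls",
]

# Synthetic family templates (fixed; one U per family, length >= 35 aa).
FAMILY_TEMPLATES: dict[str, str] = {
    "selD": "MSEKVVLTQYSHGAGCGCKIAPKVLDUILSGLPATENPNLLVGTETSDDAAVYKLNDE",
    "frhA": "MVEKIAVDPITRIEGHLRIEAHUDNGVVTDAWSSGTMFRGLEIILKGRDPRDAQHFTQ",
    "hdrA": "MAKIGVFVCHCGTNIAGTVDVPAUVEYASTLPNVVHAEDNLYTCSQDTQEKIIEDIKE",
    "frhD": "MSDLAIFKCQGCGAQLQTVEAUGKELCCNGCKLVYEVLHENNLGNAKVGLDTIKSEMN",
    "prxL": "MVLKLGDKAPDFELPDQNGKUVRLSDFKGKKVVLYFYPKDDTPGCTKEACDFRDNLGE",
    "ahpF": "MLDTNMKTQLKAYLEKLTKPVELIATLDDSAKSAEIKELLUEIAELSDKVTFKEVDVT",
    "dsbA": "MKKIALLVALLAVFSAAHAEEYVEGKUYTELSKPVSSAPAVVEFFSFYCPHCYQFEEV",
}

_MACHINERY_TEMPLATE = "MADKLVSGLEKAGYEVVAVNDPFIDLNYMVYMFQYDSTHGKFHGTVKAENGKLVING"

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in __import__(
    "Bio.Data.CodonTable", fromlist=["standard_dna_table"]
).standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()


class CapacityError(ValueError):
    """Too many planted elements for the configured contig length."""


@dataclass
class SimConfig:
    """Generator configuration; ``seed`` fixes all output bit-exactly."""

    seed: int = 0
    organism_id: str = "org1"
    n_contigs: int = 4
    contig_length: int = 10000
    gc: float = 0.45
    plant_counts: dict[str, int] = field(
        default_factory=lambda: {"selD": 2, "frhA": 2, "hdrA": 2, "frhD": 2,
                                 "prxL": 2}
    )
    secis_class_by_family: dict[str, str] = field(
        default_factory=lambda: {"selD": "eSECIS_II"}
    )  # unlisted families default to type I
    easecis_cofraction: float = 0.0  # chance of an extra eaSECIS downstream
    machinery: tuple[str, ...] = ("SecS", "EFSec", "PSTK", "SelD", "tRNA-Sec")
    co_plant_hdra_frhd: bool = True
    hdra_frhd_gap: int = 20
    stem_gc: float = 0.85
    adenine_prefix: int = 5
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("GC fraction must be in (0, 1)")
        if any(v < 0 for v in self.plant_counts.values()):
            raise ValueError("plant counts must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "machinery" in data:
            data["machinery"] = tuple(data["machinery"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["machinery"] = list(self.machinery)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass(frozen=True)
class TruthRecord:
    kind: str            # gene | secis | machinery
    contig_id: str
    start: int           # genomic 0-based half-open
    end: int
    strand: str
    label: str           # family or SECIS class
    gene_id: str
    sec_codon_start: int | None = None  # plus-strand leftmost base of TGA
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SecisPlant:
    """One constructed SECIS element with its as-drawn parameters."""

    model_class: SecisClass
    sequence: str  # DNA, transcript orientation
    structure: SecisStructure  # coordinates relative to sequence
    core_variant: str
    delta_g: float
    params: dict

    def __len__(self) -> int:
        return len(self.sequence)


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(["A", "C", "G", "T"], size=n, p=probs))


_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _stem(rng: np.random.Generator, n: int, gc: float) -> tuple[str, str]:
    """A perfect Watson-Crick stem: (5' arm, 3' arm), RNA letters."""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arm5 = "".join(rng.choice(["A", "C", "G", "U"], size=n, p=probs))
    arm3 = "".join(_WC[c] for c in reversed(arm5))
    return arm5, arm3


def build_secis(model_class: SecisClass, rng: np.random.Generator,
                stem_gc: float = 0.85, adenine_prefix: int = 5,
                canonical_ss: bool | None = None,
                energy_threshold: float = _secis.ENERGY_THRESHOLD,
                max_tries: int = 500) -> SecisPlant:
    """Draw a SECIS element satisfying every constraint of its model.

    Structural parameters are sampled uniformly within the model ranges with
    perfect (mismatch-free) stems at the configured GC bias; draws are
    rejected until the fixed-structure free energy clears the threshold.
    ``canonical_ss`` (eaSECIS only) forces/suppresses the canonical three
    consecutive S-S pairs in the upper stem.
    """
    for _ in range(max_tries):
        plant = _draw_secis(model_class, rng, stem_gc, adenine_prefix,
                            canonical_ss)
        if plant.delta_g < energy_threshold:
            params = SecisModelParams.default(model_class)
            ok, reasons = validate_candidate(
                plant.structure, params, to_rna(plant.sequence)
            )
            if not ok:  # pragma: no cover - construction guarantees validity
                raise AssertionError(f"planted element invalid: {reasons}")
            return plant
    raise RuntimeError(
        f"could not draw a {model_class.value} element below "
        f"{energy_threshold} kcal/mol in {max_tries} tries"
    )


def _loop_seq(rng: np.random.Generator, n: int, prefix: int) -> str:
    pre = "A" * min(prefix, n)
    rest = "".join(rng.choice(["A", "C", "G", "U"], size=n - len(pre)))
    return pre + rest


def _draw_secis(model_class, rng, stem_gc, adenine_prefix, canonical_ss):
    if model_class is SecisClass.ESECIS_I:
        L1 = int(rng.integers(7, 16))
        loop_n = int(rng.integers(8, 21))
        tetra = "AUGA" if rng.random() < 0.8 else "GUGA"
        lit5 = tetra + str(rng.choice(["A", "C", "G", "U"]))
        arm5, arm3 = _stem(rng, L1, stem_gc)
        loop = _loop_seq(rng, loop_n, adenine_prefix)
        di = "GA" if rng.random() < 0.8 else "AA"
        lit3 = str(rng.choice(["A", "C", "G", "U"])) + di + "".join(
            rng.choice(["A", "C", "G", "U"], size=2)
        )
        seq = lit5 + arm5 + loop + arm3 + lit3
        o = 0
        iv_lit5 = (o, o + 5)
        iv_p1 = (5, 5 + L1)
        iv_loop = (iv_p1[1], iv_p1[1] + loop_n)
        iv_q1 = (iv_loop[1], iv_loop[1] + L1)
        iv_lit3 = (iv_q1[1], iv_q1[1] + 5)
        pairs = tuple(
            (iv_p1[0] + k, iv_q1[1] - 1 - k) for k in range(L1)
        )
        structure = SecisStructure(
            model_class, 0, len(seq), core5=iv_lit5, core3=iv_lit3,
            upper_stem_pairs=pairs, upper_stem_len=L1,
            upper_stem_mismatches=0, apical_loop=iv_loop,
            adenine_run=(iv_loop[0], min(iv_loop[0] + 5, iv_loop[1])),
        )
        params = {"upper_stem": L1, "apical_loop": loop_n}
        core = f"{tetra}_{di}"
    elif model_class is SecisClass.ESECIS_II:
        L1 = int(rng.integers(6, 15))
        b5_n = int(rng.integers(3, 7))
        L2 = int(rng.integers(2, 9))
        loop_n = int(rng.integers(2, 7))
        g3_n = int(rng.integers(max(1, 4 - b5_n), min(7, 13 - b5_n)))
        tetra = "AUGA" if rng.random() < 0.8 else "GUGA"
        flank5 = str(rng.choice(["C", "G"]))
        lit5 = tetra + flank5
        arm5, arm3 = _stem(rng, L1, stem_gc)
        marm5, marm3 = _stem(rng, L2, stem_gc)
        b5 = _loop_seq(rng, b5_n, adenine_prefix)
        loop = "".join(rng.choice(["A", "C", "G", "U"], size=loop_n))
        g3 = "".join(rng.choice(["A", "C", "G", "U"], size=g3_n))
        di = "GA" if rng.random() < 0.8 else "AA"
        flank3 = _WC[flank5]  # the literal N pairing with the 5' flank
        lit3 = flank3 + di + "".join(rng.choice(["A", "C", "G", "U"], size=2))
        seq = lit5 + arm5 + b5 + marm5 + loop + marm3 + g3 + arm3 + lit3
        pos = 5
        iv_p1 = (pos, pos + L1); pos += L1
        iv_b5 = (pos, pos + b5_n); pos += b5_n
        iv_p2 = (pos, pos + L2); pos += L2
        iv_loop = (pos, pos + loop_n); pos += loop_n
        iv_q2 = (pos, pos + L2); pos += L2
        iv_g3 = (pos, pos + g3_n); pos += g3_n
        iv_q1 = (pos, pos + L1); pos += L1
        iv_lit3 = (pos, pos + 5)
        stem_pairs = tuple((iv_p1[0] + k, iv_q1[1] - 1 - k) for k in range(L1))
        stem_pairs = tuple(sorted(stem_pairs + ((4, iv_lit3[0]),)))
        mini_pairs = tuple((iv_p2[0] + k, iv_q2[1] - 1 - k) for k in range(L2))
        structure = SecisStructure(
            model_class, 0, len(seq), core5=(0, 5), core3=iv_lit3,
            upper_stem_pairs=stem_pairs, upper_stem_len=L1 + 1,
            upper_stem_mismatches=0, apical_loop=iv_loop,
            ministem_pairs=mini_pairs, ministem_len=L2,
            ministem_mismatches=0, bulge5=iv_b5, bulge3=iv_g3,
            adenine_run=(iv_b5[0], min(iv_b5[0] + 5, iv_b5[1])),
        )
        params = {"upper_stem": L1 + 1, "ministem": L2,
                  "bulge": b5_n + g3_n, "apical_loop": loop_n}
        core = f"{tetra}_{di}"
    elif model_class is SecisClass.EASECIS:
        L1 = int(rng.integers(3, 11))
        L2 = int(rng.integers(3, 7))
        loop_n = int(rng.integers(3, 20))
        canon = bool(rng.random() < 0.5) if canonical_ss is None else canonical_ss
        if canon:
            arm5_u = "".join(rng.choice(["C", "G"], size=3)) + "".join(
                rng.choice(["A", "C", "G", "U"],
                           p=[(1 - stem_gc) / 2, stem_gc / 2, stem_gc / 2,
                              (1 - stem_gc) / 2], size=L2 - 3)
            ) if L2 > 3 else "".join(rng.choice(["C", "G"], size=3))
        else:
            # an A/U pair in every window of three kills the S-S triplet
            arm5_u = ""
            for k in range(L2):
                if k % 3 == 1:
                    arm5_u += str(rng.choice(["A", "U"]))
                else:
                    arm5_u += str(rng.choice(["C", "G"]))
        arm3_u = "".join(_WC[c] for c in reversed(arm5_u))
        arm5_l, arm3_l = _stem(rng, L1, stem_gc)
        loop = _loop_seq(rng, loop_n, adenine_prefix)
        seq = arm5_l + "GAA" + arm5_u + loop + arm3_u + "A" + arm3_l
        pos = 0
        iv_p1 = (0, L1); pos = L1
        iv_gaa = (pos, pos + 3); pos += 3
        iv_p2 = (pos, pos + L2); pos += L2
        iv_loop = (pos, pos + loop_n); pos += loop_n
        iv_q2 = (pos, pos + L2); pos += L2
        iv_a = (pos, pos + 1); pos += 1
        iv_q1 = (pos, pos + L1)
        lower = tuple((iv_p1[0] + k, iv_q1[1] - 1 - k) for k in range(L1))
        upper = tuple((iv_p2[0] + k, iv_q2[1] - 1 - k) for k in range(L2))
        structure = SecisStructure(
            model_class, 0, len(seq), core5=iv_gaa, core3=iv_a,
            upper_stem_pairs=upper, upper_stem_len=L2,
            upper_stem_mismatches=0, apical_loop=iv_loop,
            lower_stem_pairs=lower, lower_stem_len=L1,
            lower_stem_mismatches=0,
            adenine_run=(iv_loop[0], min(iv_loop[0] + 5, iv_loop[1])),
        )
        params = {"lower_stem": L1, "upper_stem": L2, "apical_loop": loop_n,
                  "canonical_ss": canon}
        core = "GAA_A"
    else:  # pragma: no cover
        raise ValueError(model_class)
    dg = _energy_eval(seq, normalize_hairpins(structure.all_pairs))
    return SecisPlant(model_class, to_dna(seq), structure, core, dg, params)


def plant_in_window(model_class: SecisClass, rng: np.random.Generator,
                    window_len: int = 630, gc: float = 0.45,
                    offset: int | None = None, **kwargs,
                    ) -> tuple[str, SecisPlant, int]:
    """A random window of ``window_len`` nt with one planted element.

    Returns (window sequence (DNA), plant, offset of the element).
    """
    plant = build_secis(model_class, rng, **kwargs)
    if len(plant) > window_len:
        raise CapacityError("window shorter than the element")
    if offset is None:
        offset = int(rng.integers(0, window_len - len(plant) + 1))
    left = _rand_seq(rng, offset, gc)
    right = _rand_seq(rng, window_len - offset - len(plant), gc)
    return left + plant.sequence + right, plant, offset


# ---------------------------------------------------------------------------
# Gene construction

def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous back-translation; U becomes TGA; TAA appended."""
    codons = []
    for aa in protein:
        if aa == "U":
            codons.append("TGA")
        else:
            codons.append(str(rng.choice(_CODONS_BY_AA[aa])))
    codons.append("TAA")
    return "".join(codons)


def _mutate(nt: str, rate: float, rng: np.random.Generator,
            protected: set[int]) -> str:
    if rate <= 0:
        return nt
    chars = list(nt)
    for i in range(len(chars)):
        if i in protected:
            continue
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


@dataclass
class SimResult:
    config: SimConfig
    genomes: list[GenomeRecord]
    annotations: list[GeneAnnotation]
    truth: list[TruthRecord]
    queries: dict[str, str]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genomes": outdir / "genomes.fasta",
            "annotations": outdir / "annotations.gff3",
            "truth": outdir / "truth.tsv",
            "queries": outdir / "queries.fasta",
            "config": outdir / "config.yaml",
        }
        write_fasta(self.genomes, paths["genomes"])
        write_gff3(self.annotations, paths["annotations"])
        with open(paths["truth"], "w") as fh:
            fh.write("kind\tcontig_id\tstart\tend\tstrand\tlabel\tgene_id\t"
                     "sec_codon_start\tparams\n")
            for t in self.truth:
                fh.write(
                    f"{t.kind}\t{t.contig_id}\t{t.start}\t{t.end}\t{t.strand}"
                    f"\t{t.label}\t{t.gene_id}\t"
                    f"{'' if t.sec_codon_start is None else t.sec_codon_start}"
                    f"\t{json.dumps(t.params, sort_keys=True)}\n"
                )
        write_fasta(list(self.queries.items()), paths["queries"])
        self.config.to_yaml(paths["config"])
        return paths


def _cassette_for_gene(family: str, rng: np.random.Generator,
                       cfg: SimConfig) -> tuple[str, dict]:
    """Build guard + gene + 3'-UTR(+SECIS) in transcript orientation.

    Returns (cassette DNA, layout) with cassette-relative intervals.
    """
    protein = FAMILY_TEMPLATES[family]
    gene_nt = back_translate(protein, rng)
    sec_rel = 3 * protein.index("U")  # codon start within gene
    protected = set(range(sec_rel, sec_rel + 3))
    gene_nt = _mutate(gene_nt, cfg.mutation_rate, rng, protected)
    cls = SecisClass(cfg.secis_class_by_family.get(family, "eSECIS_I"))
    plant = build_secis(cls, rng, stem_gc=cfg.stem_gc,
                        adenine_prefix=cfg.adenine_prefix)
    utr_off = int(rng.integers(3, 41))
    cassette = ("TAA" + gene_nt + _rand_seq(rng, utr_off, cfg.gc)
                + plant.sequence)
    layout = {
        "gene": (3, 3 + len(gene_nt)),
        "sec_codon": 3 + sec_rel,
        "secis": (len(cassette) - len(plant), len(cassette)),
        "secis_plant": plant,
        "family": family,
        "extra": [],
    }
    if rng.random() < cfg.easecis_cofraction:
        ea = build_secis(SecisClass.EASECIS, rng, stem_gc=cfg.stem_gc,
                         adenine_prefix=cfg.adenine_prefix)
        gap = int(rng.integers(5, 21))
        start = len(cassette) + gap
        cassette += _rand_seq(rng, gap, cfg.gc) + ea.sequence
        layout["extra"].append(((start, start + len(ea)), ea))
    cassette += _rand_seq(rng, 10, cfg.gc)
    return cassette, layout


def _cassette_hdra_frhd(rng: np.random.Generator, cfg: SimConfig,
                        ) -> tuple[str, dict]:
    """hdrA + frhD co-planted on one strand with a short intergenic gap."""
    p_hdra, p_frhd = FAMILY_TEMPLATES["hdrA"], FAMILY_TEMPLATES["frhD"]
    nt_a = back_translate(p_hdra, rng)
    nt_d = back_translate(p_frhd, rng)
    cls = SecisClass(cfg.secis_class_by_family.get("frhD", "eSECIS_I"))
    plant = build_secis(cls, rng, stem_gc=cfg.stem_gc,
                        adenine_prefix=cfg.adenine_prefix)
    gap = cfg.hdra_frhd_gap
    utr_off = int(rng.integers(3, 41))
    # the intergenic gap keeps frhD's reading frame stop-free and in frame
    # with its own guardless start (hdrA's TAA stop bounds it upstream)
    inter = _rand_seq(rng, gap - gap % 3, cfg.gc)
    while _has_inframe_stop_or_start(inter):
        inter = _rand_seq(rng, gap - gap % 3, cfg.gc)
    cassette = ("TAA" + nt_a + inter + nt_d
                + _rand_seq(rng, utr_off, cfg.gc) + plant.sequence
                + _rand_seq(rng, 10, cfg.gc))
    a_iv = (3, 3 + len(nt_a))
    d_iv = (a_iv[1] + len(inter), a_iv[1] + len(inter) + len(nt_d))
    layout = {
        "pair": True,
        "hdrA": a_iv,
        "frhD": d_iv,
        "sec_codon_hdrA": 3 + 3 * p_hdra.index("U"),
        "sec_codon_frhD": d_iv[0] + 3 * p_frhd.index("U"),
        "secis": (d_iv[1] + len(inter) * 0 + utr_off,
                  d_iv[1] + utr_off + len(plant)),
        "secis_plant": plant,
        "gap": len(inter),
    }
    return cassette, layout


def _has_inframe_stop_or_start(nt: str) -> bool:
    for i in range(0, len(nt) - 2, 3):
        if nt[i:i + 3] in ("TAA", "TAG", "TGA", "ATG", "GTG", "TTG"):
            return True
    return False


def _place_iv(rel: tuple[int, int], p: int, clen: int, strand: str,
              ) -> tuple[int, int]:
    if strand == "+":
        return p + rel[0], p + rel[1]
    return p + clen - rel[1], p + clen - rel[0]


def simulate(config: SimConfig) -> SimResult:
    """Generate genomes, annotations, truth ledger and query proteins."""
    rng = np.random.default_rng(config.seed)
    cassettes: list[tuple[str, dict]] = []
    counts = dict(config.plant_counts)
    if config.co_plant_hdra_frhd:
        n_pairs = min(counts.get("hdrA", 0), counts.get("frhD", 0))
        for _ in range(n_pairs):
            cassettes.append(_cassette_hdra_frhd(rng, config))
        counts["hdrA"] = counts.get("hdrA", 0) - n_pairs
        counts["frhD"] = counts.get("frhD", 0) - n_pairs
    for family in sorted(counts):
        if family not in FAMILY_TEMPLATES:
            raise ValueError(f"unknown family {family!r}")
        for _ in range(counts[family]):
            cassettes.append(_cassette_for_gene(family, rng, config))
    for comp in config.machinery:
        if comp == "tRNA-Sec":
            cassettes.append((_rand_seq(rng, 93, config.gc),
                              {"machinery": comp, "noncoding": True}))
        else:
            nt = back_translate(_MACHINERY_TEMPLATE, rng)
            cassettes.append(("TAA" + nt, {"machinery": comp,
                                           "gene": (3, 3 + len(nt))}))

    order = rng.permutation(len(cassettes))
    per_contig: list[list[int]] = [[] for _ in range(config.n_contigs)]
    for k, idx in enumerate(order):
        per_contig[k % config.n_contigs].append(int(idx))

    genomes: list[GenomeRecord] = []
    annotations: list[GeneAnnotation] = []
    truth: list[TruthRecord] = []
    gene_serial = 0

    for ci in range(config.n_contigs):
        contig_id = f"{config.organism_id}_c{ci + 1}"
        parts: list[str] = []
        cursor = 0
        for idx in per_contig[ci]:
            cassette, layout = cassettes[idx]
            strand = "+" if rng.random() < 0.5 else "-"
            gap = int(rng.integers(80, 200))
            placed = cassette if strand == "+" else reverse_complement(cassette)
            if cursor + gap + len(placed) > config.contig_length:
                raise CapacityError(
                    f"contig {contig_id}: {cursor + gap + len(placed)} nt of "
                    f"plantings exceed contig length {config.contig_length}"
                )
            parts.append(_rand_seq(rng, gap, config.gc))
            p = cursor + gap
            parts.append(placed)
            cursor = p + len(placed)
            clen = len(cassette)
            gene_serial += 1
            if "machinery" in layout:
                comp = layout["machinery"]
                if layout.get("noncoding"):
                    iv = (p, p + clen)
                    ann = GeneAnnotation(contig_id, iv[0], iv[1], strand,
                                         f"mach_{gene_serial}", comp,
                                         coding=False)
                else:
                    iv = _place_iv(layout["gene"], p, clen, strand)
                    ann = GeneAnnotation(contig_id, iv[0], iv[1], strand,
                                         f"mach_{gene_serial}", comp)
                annotations.append(ann)
                truth.append(TruthRecord("machinery", contig_id, iv[0], iv[1],
                                         strand, comp, ann.gene_id))
                continue
            if layout.get("pair"):
                for fam in ("hdrA", "frhD"):
                    iv = _place_iv(layout[fam], p, clen, strand)
                    sc_rel = layout[f"sec_codon_{fam}"]
                    sc = (p + sc_rel if strand == "+"
                          else p + clen - sc_rel - 3)
                    gid = f"{fam}_{gene_serial}"
                    annotations.append(GeneAnnotation(contig_id, iv[0], iv[1],
                                                      strand, gid, fam))
                    truth.append(TruthRecord(
                        "gene", contig_id, iv[0], iv[1], strand, fam, gid,
                        sec_codon_start=sc,
                        params={"co_planted": True, "gap": layout["gap"]},
                    ))
                plant = layout["secis_plant"]
                iv = _place_iv(layout["secis"], p, clen, strand)
                truth.append(TruthRecord(
                    "secis", contig_id, iv[0], iv[1], strand,
                    plant.model_class.value, f"frhD_{gene_serial}",
                    params={**plant.params, "core": plant.core_variant,
                            "delta_g": plant.delta_g},
                ))
                continue
            fam = layout["family"]
            gid = f"{fam}_{gene_serial}"
            iv = _place_iv(layout["gene"], p, clen, strand)
            sc_rel = layout["sec_codon"]
            sc = p + sc_rel if strand == "+" else p + clen - sc_rel - 3
            annotations.append(GeneAnnotation(contig_id, iv[0], iv[1], strand,
                                              gid, fam))
            truth.append(TruthRecord(
                "gene", contig_id, iv[0], iv[1], strand, fam, gid,
                sec_codon_start=sc,
                params={"mutation_rate": config.mutation_rate},
            ))
            plant = layout["secis_plant"]
            s_iv = _place_iv(layout["secis"], p, clen, strand)
            truth.append(TruthRecord(
                "secis", contig_id, s_iv[0], s_iv[1], strand,
                plant.model_class.value, gid,
                params={**plant.params, "core": plant.core_variant,
                        "delta_g": plant.delta_g},
            ))
            for (e_iv, ea) in layout["extra"]:
                g_iv = _place_iv(e_iv, p, clen, strand)
                truth.append(TruthRecord(
                    "secis", contig_id, g_iv[0], g_iv[1], strand,
                    ea.model_class.value, gid,
                    params={**ea.params, "core": ea.core_variant,
                            "delta_g": ea.delta_g, "co_planted_ea": True},
                ))
        if cursor < config.contig_length:
            parts.append(_rand_seq(rng, config.contig_length - cursor,
                                   config.gc))
        genomes.append(GenomeRecord(contig_id, "".join(parts)))

    queries = {fam: FAMILY_TEMPLATES[fam]
               for fam in sorted(set(config.plant_counts) & set(FAMILY_TEMPLATES))}
    annotations.sort(key=lambda a: (a.contig_id, a.start))
    truth.sort(key=lambda t: (t.contig_id, t.start, t.kind))
    return SimResult(config, genomes, annotations, truth, queries)


# ---------------------------------------------------------------------------
# Negative controls

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson dinucleotide-preserving shuffle."""
    if len(seq) <= 2 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = sorted(edges)
    for _ in range(1000):
        last_edge: dict[str, str] = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = str(rng.choice(edges[v]))
        # every vertex must reach `last` via designated last edges
        for v in last_edge:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover
        return seq
    out_lists: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        out_lists[v] = rest
    result = [seq[0]]
    ptr = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = out_lists[cur][ptr[cur]]
        ptr[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)


def shuffle_negative_controls(records: list[GenomeRecord], seed: int,
                              ) -> list[GenomeRecord]:
    """Per-record dinucleotide shuffles destroying planted structure."""
    rng = np.random.default_rng(seed)
    return [GenomeRecord(r.id + "_shuf", dinucleotide_shuffle(r.sequence, rng))
            for r in records]
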