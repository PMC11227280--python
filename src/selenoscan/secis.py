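"""Structural models of archaeal SECIS elements and candidate classification.

Three model classes are supported:

* **eSECIS type I** — eukaryote-like element without a ministem: a GA_[G/A]A
  non-Watson-Crick quartet core, an upper stem of 7-15 bp with at most two
  mismatches, and an apical loop of 8-20 nt.
* **eSECIS type II** — as type I but with a 2-8 bp ministem (at most one
  mismatch) inside the apical region: a 4-12 nt bulge separates upper stem
  and ministem and the apical loop shrinks to 2-6 nt.
* **eaSECIS** — euryarchaeal-style element: a 3-10 bp lower stem and a
  3-6 bp upper stem separated by a GAA_A bulge, with a 3-19 nt apical loop.
  The canonical euryarchaeal form additionally shows three consecutive
  S-S (C/G-G/C) pairs in the upper stem, recorded here as a feature flag
  rather than a filter.

Candidates come from structured-motif pattern matches
(:mod:`selenoscan.patterns`), are validated against the model constraints,
scored with the fixed-structure nearest-neighbor evaluator
(:mod:`selenoscan.energy`) and kept when their free energy is below the
-5.0 kcal/mol threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from . import energy as _energy
from .patterns import (
    BackRefRealization,
    PatternMatch,
    PatternSpec,
    parse_pattern,
)
from .seqio import Utr3Window, to_rna

__all__ = [
    "SecisClass",
    "SecisModelParams",
    "SecisStructure",
    "SecisCandidate",
    "EaFeatureFlags",
    "CompositionProfile",
    "builtin_patterns",
    "structure_from_match",
    "validate_candidate",
    "scan_window",
    "classify_euryarchaeal",
    "composition_profiles",
    "ENERGY_THRESHOLD",
]

ENERGY_THRESHOLD = -5.0  # kcal/mol; candidates must be strictly below

TYPE_I_PATTERN = (
    "r1={au,ua,gc,cg,gu,ug} NNGAN p1=7...15 8...20 r1~p1[2,1,1] (NGANN | NAANN)"
)
TYPE_II_PATTERN = (
    "r1={au,ua,gc,cg,gu,ug} NNGAN p1=6...14 3...6 p2=2...8 2...6 "
    "r1~p2[1,1,1] 1...6 r1~p1[2,1,1] (NGANN | NAANN)"
)
EASECIS_PATTERN = (
    "r1={au,ua,gc,cg,gu,ug} p1=3...10 GAA p2=3...6 3...19 r1~p2[0,1,1] A r1~p1[1,1,1]"
)


class SecisClass(str, Enum):
    ESECIS_I = "eSECIS_I"
    ESECIS_II = "eSECIS_II"
    EASECIS = "eaSECIS"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class SecisModelParams:
    """Length ranges, mismatch budgets and the energy threshold of a model."""

    model_class: SecisClass
    upper_stem: tuple[int, int]
    upper_stem_mismatch_max: int
    apical_loop: tuple[int, int]
    ministem: tuple[int, int] | None = None
    ministem_mismatch_max: int = 0
    bulge: tuple[int, int] | None = None
    lower_stem: tuple[int, int] | None = None
    lower_stem_mismatch_max: int = 0
    energy_threshold: float = ENERGY_THRESHOLD

    @staticmethod
    def default(model_class: SecisClass) -> "SecisModelParams":
        if model_class is SecisClass.ESECIS_I:
            return SecisModelParams(
                model_class, upper_stem=(7, 15), upper_stem_mismatch_max=2,
                apical_loop=(8, 20),
            )
        if model_class is SecisClass.ESECIS_II:
            return SecisModelParams(
                model_class, upper_stem=(7, 15), upper_stem_mismatch_max=2,
                apical_loop=(2, 6), ministem=(2, 8), ministem_mismatch_max=1,
                bulge=(4, 12),
            )
        if model_class is SecisClass.EASECIS:
            return SecisModelParams(
                model_class, upper_stem=(3, 6), upper_stem_mismatch_max=0,
                apical_loop=(3, 19), lower_stem=(3, 10),
                lower_stem_mismatch_max=1,
            )
        raise ValueError(model_class)


def default_models() -> list[SecisModelParams]:
    return [SecisModelParams.default(c) for c in SecisClass]


_PATTERNS: dict[SecisClass, PatternSpec] | None = None


def builtin_patterns() -> dict[SecisClass, PatternSpec]:
    """The three built-in search patterns, parsed once and cached."""
    global _PATTERNS
    if _PATTERNS is None:
        _PATTERNS = {
            SecisClass.ESECIS_I: parse_pattern(TYPE_I_PATTERN),
            SecisClass.ESECIS_II: parse_pattern(TYPE_II_PATTERN),
            SecisClass.EASECIS: parse_pattern(EASECIS_PATTERN),
        }
    return _PATTERNS


# ---------------------------------------------------------------------------
# Structures

@dataclass(frozen=True)
class SecisStructure:
    """A pattern match interpreted as a candidate SECIS structure.

    All coordinates are on the searched (window) string.  ``*_pairs`` hold
    rule-satisfying base pairs only; ``*_mismatches`` count aligned stem
    columns whose bases do not pair.
    """

    model_class: SecisClass
    start: int
    end: int
    core5: tuple[int, int]            # NNGAN literal (eSECIS) or GAA (eaSECIS)
    core3: tuple[int, int]            # NGANN/NAANN literal (eSECIS) or A (ea)
    upper_stem_pairs: tuple[tuple[int, int], ...]
    upper_stem_len: int
    upper_stem_mismatches: int
    apical_loop: tuple[int, int]
    ministem_pairs: tuple[tuple[int, int], ...] = ()
    ministem_len: int = 0
    ministem_mismatches: int = 0
    bulge5: tuple[int, int] | None = None
    bulge3: tuple[int, int] | None = None
    lower_stem_pairs: tuple[tuple[int, int], ...] = ()
    lower_stem_len: int = 0
    lower_stem_mismatches: int = 0
    adenine_run: tuple[int, int] = (0, 0)  # first <=5 loop/bulge nucleotides

    @property
    def all_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            sorted(self.lower_stem_pairs + self.upper_stem_pairs + self.ministem_pairs)
        )


def _aligned_len(br: BackRefRealization) -> int:
    return len(br.pairs) + len(br.mismatch_positions)


def structure_from_match(model_class: SecisClass, match: PatternMatch,
                         seq: str) -> SecisStructure:
    """Interpret a raw pattern match of the given class as a structure."""
    iv = match.element_intervals
    if model_class is SecisClass.ESECIS_I:
        lit5, p1, loop, q1, lit3 = iv
        br1 = match.backrefs[0]
        return SecisStructure(
            model_class, match.start, match.end,
            core5=lit5, core3=lit3,
            upper_stem_pairs=br1.pairs,
            upper_stem_len=p1[1] - p1[0],
            upper_stem_mismatches=br1.mismatches,
            apical_loop=loop,
            adenine_run=(loop[0], min(loop[0] + 5, loop[1])),
        )
    if model_class is SecisClass.ESECIS_II:
        lit5, p1, b5, p2, loop, q2, b3, q1, lit3 = iv
        br2, br1 = match.backrefs
        # the final N of the 5' literal counts as the first stem base pair
        # when it pairs with the first N of the 3' literal under the rule
        flank = (lit5[1] - 1, lit3[0])
        pairs = br1.pairs
        stem_len = p1[1] - p1[0]
        if (seq[flank[0]], seq[flank[1]]) in br1_rule_pairs():
            pairs = tuple(sorted(pairs + (flank,)))
            stem_len += 1
        return SecisStructure(
            model_class, match.start, match.end,
            core5=lit5, core3=lit3,
            upper_stem_pairs=pairs,
            upper_stem_len=stem_len,
            upper_stem_mismatches=br1.mismatches,
            apical_loop=loop,
            ministem_pairs=br2.pairs,
            ministem_len=p2[1] - p2[0],
            ministem_mismatches=br2.mismatches,
            bulge5=b5, bulge3=b3,
            adenine_run=(b5[0], min(b5[0] + 5, b5[1])),
        )
    if model_class is SecisClass.EASECIS:
        p1, gaa, p2, loop, q2, a3, q1 = iv
        br2, br1 = match.backrefs
        return SecisStructure(
            model_class, match.start, match.end,
            core5=gaa, core3=a3,
            upper_stem_pairs=br2.pairs,
            upper_stem_len=p2[1] - p2[0],
            upper_stem_mismatches=br2.mismatches,
            apical_loop=loop,
            lower_stem_pairs=br1.pairs,
            lower_stem_len=p1[1] - p1[0],
            lower_stem_mismatches=br1.mismatches,
            adenine_run=(loop[0], min(loop[0] + 5, loop[1])),
        )
    raise ValueError(model_class)


def br1_rule_pairs() -> frozenset:
    from .patterns import RULE_R1_PAIRS

    return RULE_R1_PAIRS


def validate_candidate(structure: SecisStructure, params: SecisModelParams,
                       seq: str) -> tuple[bool, list[str]]:
    """Check every length range, mismatch budget and core motif of the model.

    Returns (accepted, reasons); ``reasons`` enumerates each violated
    constraint and is empty on acceptance.
    """
    reasons: list[str] = []
    cls = params.model_class
    if structure.model_class is not cls:
        return False, [f"structure class {structure.model_class} != {cls}"]

    lo, hi = params.upper_stem
    if not lo <= structure.upper_stem_len <= hi:
        reasons.append(f"upper stem {lo}-{hi} bp (got {structure.upper_stem_len})")
    if structure.upper_stem_mismatches > params.upper_stem_mismatch_max:
        reasons.append(
            f"upper stem mismatches <= {params.upper_stem_mismatch_max} "
            f"(got {structure.upper_stem_mismatches})"
        )
    lo, hi = params.apical_loop
    loop_len = structure.apical_loop[1] - structure.apical_loop[0]
    if not lo <= loop_len <= hi:
        reasons.append(f"apical loop {lo}-{hi} (got {loop_len})")

    if cls is SecisClass.ESECIS_II:
        lo, hi = params.ministem
        if not lo <= structure.ministem_len <= hi:
            reasons.append(f"ministem {lo}-{hi} bp (got {structure.ministem_len})")
        if structure.ministem_mismatches > params.ministem_mismatch_max:
            reasons.append(
                f"ministem mismatches <= {params.ministem_mismatch_max} "
                f"(got {structure.ministem_mismatches})"
            )
        blen = (structure.bulge5[1] - structure.bulge5[0]) + (
            structure.bulge3[1] - structure.bulge3[0]
        )
        lo, hi = params.bulge
        if not lo <= blen <= hi:
            reasons.append(f"bulge {lo}-{hi} nt (got {blen})")

    if cls is SecisClass.EASECIS:
        lo, hi = params.lower_stem
        if not lo <= structure.lower_stem_len <= hi:
            reasons.append(f"lower stem {lo}-{hi} bp (got {structure.lower_stem_len})")
        if structure.lower_stem_mismatches > params.lower_stem_mismatch_max:
            reasons.append(
                f"lower stem mismatches <= {params.lower_stem_mismatch_max} "
                f"(got {structure.lower_stem_mismatches})"
            )
        if seq[structure.core5[0]:structure.core5[1]] != "GAA":
            reasons.append("GAA bulge motif absent")
        if seq[structure.core3[0]:structure.core3[1]] != "A":
            reasons.append("3' bulge adenine absent")
    else:
        # core motif GA_[G/A]A: GA on the 5' side, [G/A]A on the 3' side
        c5 = seq[structure.core5[0]:structure.core5[1]]
        c3 = seq[structure.core3[0]:structure.core3[1]]
        if c5[2:4] != "GA":
            reasons.append(f"5' core GA absent (got {c5})")
        if not (c3[1] in "GA" and c3[2] == "A"):
            reasons.append(f"3' core [G/A]A absent (got {c3})")

    return (not reasons), reasons


# ---------------------------------------------------------------------------
# Candidates

@dataclass(frozen=True)
class SecisCandidate:
    """A located, validated, energy-filtered SECIS candidate."""

    contig_id: str
    gene_id: str | None
    strand: str
    start: int                      # genomic, 0-based half-open
    end: int
    window_start: int               # window coordinates of the match span
    window_end: int
    model_class: SecisClass
    core_context: str               # e.g. "AUGA_GA"
    apical_loop_seq: str
    adenine_run: str
    delta_g: float
    dot_bracket: str
    structure: SecisStructure = field(compare=False, repr=False)
    sequence: str = field(compare=False, default="")
    co_reported: bool = False

    @property
    def n_stem_pairs(self) -> int:
        return len(self.structure.all_pairs)


def _core_context(structure: SecisStructure, seq: str) -> str:
    """Core motif context: 5' tetranucleotide ending in GA + 3' dinucleotide."""
    if structure.model_class is SecisClass.EASECIS:
        g0 = structure.core5[0]
        tetra = seq[max(0, g0 - 2):g0 + 2]
        a3 = structure.core3[0]
        di = seq[max(0, a3 - 1):a3 + 1]
    else:
        tetra = seq[structure.core5[0]:structure.core5[0] + 4]
        di = seq[structure.core3[0] + 1:structure.core3[0] + 3]
    return f"{tetra}_{di}"


def _dot_bracket(structure: SecisStructure) -> str:
    chars = ["."] * (structure.end - structure.start)
    for i, j in structure.all_pairs:
        chars[i - structure.start] = "("
        chars[j - structure.start] = ")"
    return "".join(chars)


def candidate_from_structure(structure: SecisStructure, window: Utr3Window,
                             seq: str, gene_id: str | None = None,
                             delta_g: float | None = None) -> SecisCandidate:
    """Score a validated structure and wrap it as a candidate."""
    sub = seq[structure.start:structure.end]
    if delta_g is None:
        dg = _energy.evaluate(
            seq, _energy.normalize_hairpins(structure.all_pairs)
        )
    else:
        dg = delta_g
    gstart, gend = window.interval_to_genomic(structure.start, structure.end)
    return SecisCandidate(
        contig_id=window.contig_id,
        gene_id=gene_id,
        strand=window.strand,
        start=gstart,
        end=gend,
        window_start=structure.start,
        window_end=structure.end,
        model_class=structure.model_class,
        core_context=_core_context(structure, seq),
        apical_loop_seq=seq[structure.apical_loop[0]:structure.apical_loop[1]],
        adenine_run=seq[structure.adenine_run[0]:structure.adenine_run[1]],
        delta_g=dg,
        dot_bracket=_dot_bracket(structure),
        structure=structure,
        sequence=sub,
    )


def _overlaps(a: SecisCandidate, b: SecisCandidate) -> bool:
    return a.window_start < b.window_end and b.window_start < a.window_end


def _dedup_same_class(cands: list[SecisCandidate]) -> list[SecisCandidate]:
    """Collapse overlapping same-class candidates to the lowest-energy one.

    Ties break to the leftmost start, then the longer stem.
    """
    ranked = sorted(
        cands,
        key=lambda c: (c.delta_g, c.window_start, -c.n_stem_pairs,
                       c.window_end),
    )
    kept: list[SecisCandidate] = []
    for c in ranked:
        if not any(_overlaps(c, k) for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.window_start)
    return kept


def scan_window(window: Utr3Window,
                models: list[SecisModelParams] | None = None,
                gene_id: str | None = None,
                patterns: dict[SecisClass, PatternSpec] | None = None,
                ) -> list[SecisCandidate]:
    """Scan one 3'-UTR window for SECIS candidates of the requested models.

    Pipeline per model: pattern match -> structure building -> constraint
    validation -> fixed-structure energy -> threshold filter -> per-locus
    deduplication (lowest free energy wins).  When a type I and a type II
    candidate survive on overlapping loci, both are reported with
    ``co_reported`` set.
    """
    from .patterns import match_all

    if models is None:
        models = default_models()
    pats = patterns or builtin_patterns()
    seq = to_rna(window.sequence)
    dg_cache: dict[tuple, float] = {}
    by_class: dict[SecisClass, list[SecisCandidate]] = {}
    for params in models:
        cls = params.model_class
        accepted: list[SecisCandidate] = []
        for m in match_all(pats[cls], seq):
            structure = structure_from_match(cls, m, seq)
            ok, _reasons = validate_candidate(structure, params, seq)
            if not ok:
                continue
            pairs = structure.all_pairs
            dg = dg_cache.get(pairs)
            if dg is None:
                dg = _energy.evaluate(
                    seq, _energy.normalize_hairpins(pairs), validate=False
                )
                dg_cache[pairs] = dg
            if dg < params.energy_threshold:
                accepted.append(
                    candidate_from_structure(structure, window, seq, gene_id,
                                             delta_g=dg)
                )
        by_class[cls] = _dedup_same_class(accepted)

    out: list[SecisCandidate] = []
    t1 = by_class.get(SecisClass.ESECIS_I, [])
    t2 = by_class.get(SecisClass.ESECIS_II, [])
    for a in t1:
        flag = any(_overlaps(a, b) for b in t2)
        out.append(replace(a, co_reported=flag) if flag else a)
    for b in t2:
        flag = any(_overlaps(b, a) for a in t1)
        out.append(replace(b, co_reported=flag) if flag else b)
    out.extend(by_class.get(SecisClass.EASECIS, []))
    out.sort(key=lambda c: (c.window_start, c.model_class.value))
    return out


# ---------------------------------------------------------------------------
# Euryarchaeal features and composition statistics

@dataclass(frozen=True)
class EaFeatureFlags:
    has_SS_triplet: bool
    core_motif: str  # AUGA_GA | GUGA_GA | AUGA_AA | other


def classify_euryarchaeal(candidate: SecisCandidate) -> EaFeatureFlags:
    """Canonical-eaSECIS feature flags for a candidate.

    ``has_SS_triplet`` is true when three consecutive pairs of the upper
    stem are both C or G; ``core_motif`` bins the bulge-flanking context.
    """
    seq = candidate.sequence
    off = candidate.structure.start
    pairs = sorted(candidate.structure.upper_stem_pairs)
    ss = [seq[i - off] in "CG" and seq[j - off] in "CG" for i, j in pairs]
    triplet = any(all(ss[k:k + 3]) and len(ss[k:k + 3]) == 3
                  for k in range(len(ss) - 2))
    motif = candidate.core_context
    if motif not in ("AUGA_GA", "GUGA_GA", "AUGA_AA"):
        motif = "other"
    return EaFeatureFlags(has_SS_triplet=triplet, core_motif=motif)


@dataclass
class CompositionProfile:
    """Position-by-nucleotide counts for a candidate region."""

    region: str
    counts: pd.DataFrame  # index: position (0-based), columns: A C G U
    n_sequences: int

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = self.counts.div(totals, axis=0)
        return freq

    @property
    def empty(self) -> bool:
        return int(self.counts.to_numpy().sum()) == 0


def composition_profiles(candidates: list[SecisCandidate], region: str,
                         ) -> CompositionProfile:
    """Aligned nucleotide counts over the core or the unpaired-adenine region.

    ``region`` is ``"core"`` (the core tetranucleotide plus the 3' GA/AA
    dinucleotide context, 6 positions) or ``"apical_adenines"`` (the first
    five loop/bulge nucleotides).  Frequencies are normalised per column;
    an empty candidate list yields an all-zero, flagged-empty profile.
    """
    if region == "core":
        strings = [c.core_context.replace("_", "") for c in candidates]
        width = 6
    elif region == "apical_adenines":
        strings = [c.adenine_run for c in candidates]
        width = 5
    else:
        raise ValueError(f"unknown region {region!r}")
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(width, name="position"),
        columns=list("ACGU"), dtype=int,
    )
    for s in strings:
        for pos, base in enumerate(s[:width]):
            if base in "ACGU":
                counts.loc[pos, base] += 1
    return CompositionProfile(region=region, counts=counts,
                              n_sequences=len(strings))
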