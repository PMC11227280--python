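# Methods

## The annotation problem

A selenoprotein gene looks, to a standard gene caller, like two genes: the
in-frame UGA that encodes selenocysteine is read as a stop. Detection
therefore combines two signals. First, homology: a column in a
protein-vs-genome alignment where a query's Sec residue (`U`) sits over a
genomic TGA codon. Second, structure: a SECIS element — a characteristic
stem-loop — in the 3′-UTR of the putative gene. `selenoscan` implements
both signal paths, the trait-level classifier that combines them, and a
synthetic benchmark that plants known instances so every stage can be
scored against ground truth.

## Structured-motif matching

SECIS models are expressed in a small PatScan-style grammar: literals over
IUPAC codes, named length-ranged segments, alternation, and stem
back-references `rule~seg[m,d,i]` that match the reverse of a bound
segment under a pairing rule (here `r1` = Watson–Crick + G·U) with at most
`m` non-pairing aligned columns, `d` deletions and `i` insertions.
Deletions shorten and insertions lengthen the partner relative to the
segment, following the PatScan budget convention.

Semantics are deliberately exhaustive: a match is any (start, full
binding) assignment, where a binding fixes every segment length, branch
choice and partner length. This is what makes exact equivalence testing
against a naive enumerator possible (`tests/_oracle.py`), and it is the
semantics the per-locus deduplication downstream relies on. Internally the
matcher memoizes suffix completions keyed on (element index, position, the
bindings the suffix still references) — memoization is only installed at
indices where a bound segment drops out of the suffix's needs, since
elsewhere every key is unique — and back-reference feasibility is decided
by closed-form register scans for the ≤1-deletion/≤1-insertion budgets the
built-in patterns use (a general small DP covers larger budgets). The
reported alignment for a feasible back-reference is a deterministic
representative: the ungapped register when it fits the budgets, otherwise
the minimum-mismatch single-indel register; match *sets* are independent
of this choice.

`N` matches the wildcard `N` in patterns but never satisfies a pairing
rule — a conservative treatment of ambiguous bases. G·U is a pair under
`r1`, not a mismatch; deployments of similar grammars differ on this
point, so it is stated here explicitly.

## SECIS models and validation

The three model classes and their defaults:

| class      | core            | stems                         | loops                  |
|------------|-----------------|-------------------------------|------------------------|
| eSECIS I   | `GA_[G/A]A`     | upper 7–15 bp, ≤2 mismatches  | apical 8–20 nt         |
| eSECIS II  | `GA_[G/A]A`     | upper 7–15 bp ≤2 mm; ministem 2–8 bp ≤1 mm | bulge 4–12 nt, apical 2–6 nt |
| eaSECIS    | `GAA_A` bulge   | lower 3–10 bp, upper 3–6 bp   | apical 3–19 nt         |

The printed type II pattern carries `p1=6...14` while the model states an
upper stem of 7–15 bp; these are reconciled by counting the final `N` of
the 5′ `NNGAN` literal as the first stem base pair when it pairs under
`r1`, so pattern and model agree without altering either. The 5′ flanking
nucleotide of the core GA and the `[G/A]` choice on the 3′ side are
*recorded* (as the `AUGA_GA`-style core context) but not used to reject:
the models require only `GA_[G/A]A`, and the flank variation is a reported
observable, not a filter. The canonical euryarchaeal S–S stem triplet is
likewise a feature flag, never a rejection criterion.

`validate_candidate` re-checks every length range and mismatch budget
against the built structure and returns the full list of violated
constraints, so the validator can also certify generator output.

## Free-energy evaluation

Candidates are scored by evaluating the *fixed* candidate structure with a
nearest-neighbor model (Turner-style published parameters at 37 °C):
stacking terms for adjacent pairs (Watson–Crick and G·U), hairpin, bulge
and internal-loop initiations by size with logarithmic extrapolation, an
internal-loop asymmetry term, a terminal AU/GU helix-end penalty, and
simplified loop terminal-mismatch bonuses (closing-pair-dependent for
hairpins, a flat per-side bonus for internal loops of five or more
nucleotides). Free folding is deliberately not used: a fixed-structure
evaluator is deterministic and dependency-free, and the −5.0 kcal/mol
acceptance threshold applies to the candidate hairpin alone, not to a
whole-window fold. Before evaluation, innermost pairs that would enclose a
hairpin loop shorter than 3 nt (which the type II grammar can declare) are
unpaired, since such pairs cannot form physically.

Against a reference implementation evaluating the identical structures,
the evaluator agrees in sign on all 20 frozen test cases with a maximum
absolute deviation of 1.6 kcal/mol — adequate for a −5.0 kcal/mol
threshold whose passing candidates are typically far below it. Structures
with duplicated, crossing or non-canonical pairs are rejected with
explicit errors; an empty pairing map scores exactly 0.

Overlapping candidates of one class collapse to the lowest-ΔG candidate,
ties broken by leftmost start then longer stem; free energy is the
paper-trail ranking signal, and the tie-breaks make output deterministic.
When type I and type II both validate on one locus, both are reported with
a `co_reported` flag rather than silently merged.

## ORF extension and the Sec/TGA path

Around each verified Sec/TGA codon the ORF is extended in-frame:
downstream to the first TAA/TAG (TGA reads through as `U`), upstream
bounded by the first in-frame TAA/TAG, taking the farthest upstream
ATG/GTG/TTG inside that bound (the longest-ORF rule; alternative starts
reflect archaeal usage). Missing starts or stops at contig edges set flags
rather than raising. Every TGA inside the ORF becomes `U`; hits are
recorded per verified codon and merged when they share a genomic codon.
Proteins shorter than 35 aa are flagged (excluded from downstream
phylogenetic use), not dropped.

The built-in six-frame Smith–Waterman aligner exists so the pipeline is
self-contained without external search tools: BLOSUM62 extended with a
`U` row scored like cysteine and a +8 U-vs-stop bonus, gap open/extend
−11/−1, with a Karlin–Altschul e-value estimate (λ = 0.267, K = 0.041)
over the query × six-frame search space so the standard e-value (0.01) and
coverage (25%) thresholds stay meaningful. It reports one best local
alignment per genome, which is why the benchmark generator spreads genes
across many contigs; production inputs are tabular tblastn/JackHMMER
results with aligned sequence strings (`-outfmt "6 std qseq sseq"`,
optionally `qlen slen` appended).

## Trait criterion

Sec+ requires (i) at least three distinct Sec-machinery genes — SecS,
EFSec, PSTK, SelD, tRNA-Sec, presence/absence only — and (ii) at least one
selenoprotein gene. tRNA-Sec counts toward the tally but is not
independently mandatory by default, because the criterion's parenthetical
"(including tRNA-Sec)" admits both readings; a strict mode makes it
mandatory, and the classifier is a pure function tested against the
exhaustive 2⁵ × {0,1,2} table in both modes. tRNA presence is consumed as
an annotation label (product `tRNA-Sec`); tRNA structure prediction is out
of scope.

Operon candidates are hdrA–frhD pairs adjacent on one strand (no other
same-strand gene between them) with an intergenic gap ≤ 60 nt by default;
either label order is accepted.

## Synthetic benchmark

The generator defines the study conditions the tests measure under:

* background contigs of i.i.d. nucleotides at a configurable GC fraction
  (default 0.45, a mid-range archaeal value);
* family protein templates — short fixed synthetic sequences, one Sec
  each, ≥ 58 aa — so family assignment is meaningful without external
  databases; genes are random synonymous back-translations with the Sec
  codon as TGA and a TAA stop;
* an in-frame TAA guard immediately upstream of each planted start, which
  makes the planted ORF the unique longest-ORF answer and lets ORF
  recovery be scored exactly;
* per-gene 3′-UTR SECIS elements drawn uniformly within the model ranges
  with perfect stems at a configurable GC bias (default 0.85) and a 5-nt
  adenine loop prefix; draws are rejected until the fixed-structure energy
  clears −5.0 kcal/mol, because a planted element is by definition one
  that satisfies *all* model criteria including the energy filter;
* selD genes carry type II elements and the other families type I,
  mirroring the observed class preference; eaSECIS elements can be
  co-planted downstream at a configurable fraction;
* hdrA–frhD pairs co-planted on one strand with an 18–20 nt stop-free
  intergenic gap sharing a single downstream SECIS;
* machinery complements as labelled annotations (tRNA-Sec non-coding);
* both strands used at random; placement is collision-free by
  construction, and overfull configurations raise a capacity error.

What the generator does **not** emulate: realistic codon usage, sequencing
error, assembly artifacts, truncated bins, or homologous interference
between families. Passing benchmarks therefore demonstrate correctness of
the *method* under clean conditions, not expected sensitivity on real
MAGs, where alignment quality and contamination dominate.

Negative controls are Altschul–Erikson dinucleotide-preserving shuffles;
the shuffled-window false-positive rate is reported by the acceptance
script as a tracked metric (a few candidates per 630-nt shuffled window is
expected — the type II grammar is permissive by design, exactly why the
energy filter and per-locus deduplication exist) and is intentionally not
bounded by an assertion.

## Problem sizes and numerical choices

The test suite and acceptance script use: 500 random strings (length
40–60) for oracle equivalence with the built-in patterns truncated to a
≤40 nt span; 200 planted 630-nt windows per SECIS class (the −30/+600
search window) for recall; 100 planted genes on 96 contigs for Sec-codon
precision/recall — one cassette per contig because the desk aligner
reports one best alignment per genome; 50 random ≤50-gene annotation sets
for operon parity; and a two-run CLI chain for byte-level determinism.
All randomness flows from a single named seed (numpy `default_rng`);
energies are rounded to 0.01 kcal/mol; window coordinates are 0-based
half-open internally with GFF3 converted at the boundary, and DNA is the
internal alphabet with a single T→U transliteration at the
pattern-matching boundary.

## Known limitations

* The energy model omits sequence-dependent loop mismatch tables and
  special hairpin rules; it is a thresholding evaluator, not a folding
  engine.
* The built-in aligner's e-value is an estimate with fixed gapped
  parameters, not a BLAST statistic; it reports a single best local
  alignment per genome.
* Window-level deduplication does not merge candidates across the two
  eSECIS classes; co-reported loci are flagged instead.
* The trait classifier trusts annotation product labels for machinery
  presence; it does not verify orthology.
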