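# selenoscan

Selenocysteine (Sec, the 21st amino acid) is encoded by UGA — normally a
stop codon — and its insertion is directed by a cis-acting stem-loop in the
mRNA, the SECIS element. In archaea and eukaryotes the SECIS sits in the
3′-UTR of the selenoprotein gene, which makes selenoprotein annotation a
two-signal problem: an in-frame TGA that aligns with a Sec residue of a
known selenoprotein family, plus a qualifying RNA structure downstream of
the gene. `selenoscan` implements that pipeline for archaeal genomes and
metagenome-assembled genomes (MAGs), for comparative genomicists who want
to map the Sec-utilization trait across many bins.

## What it computes

**SECIS structural models.** Three classes are built in, expressed as
structured-motif patterns with pairing-rule back-references:

* *eSECIS type I* (eukaryote-like, no ministem) — quartet core
  `5'-GA_[G/A]A-3'`, upper stem 7–15 bp (≤2 mismatches), apical loop
  8–20 nt; search pattern
  `r1={au,ua,gc,cg,gu,ug} NNGAN p1=7...15 8...20 r1~p1[2,1,1] (NGANN | NAANN)`
* *eSECIS type II* (with ministem) — same core and upper stem, ministem
  2–8 bp (≤1 mismatch), 4–12 nt bulge, apical loop 2–6 nt
* *eaSECIS* (euryarchaeal-like) — lower stem 3–10 bp, upper stem 3–6 bp,
  `GAA_A` bulge, apical loop 3–19 nt; the canonical form's three
  consecutive S–S (C/G–G/C) pairs are recorded as a feature flag

A back-reference `r1~p1[m,d,i]` matches the reverse of segment `p1` under
pairing rule `r1` (Watson–Crick plus G·U wobble) with at most `m`
non-pairing columns, `d` deletions and `i` insertions. Matching is
exhaustive over segment lengths, so the engine can be checked exactly
against a brute-force enumerator.

**Scanning.** For every selenoprotein gene the window 30 nt upstream to
600 nt downstream of the 3′ end is extracted (transcript-oriented),
pattern matches are built into candidate structures, validated against the
model constraints, scored with a fixed-structure nearest-neighbor
free-energy evaluator, and kept when ΔG < −5.0 kcal/mol; overlapping
candidates of one class collapse to the lowest-energy one.

**Selenoprotein gene finding.** Tabular protein-vs-genome alignments
(tblastn-style, with aligned sequence strings) are parsed and every
query-Sec/subject-TGA column is verified against the genome; around each
verified codon an ORF is extended in-frame — TGA read through as `U`,
TAA/TAG terminating — and labelled with the supporting query's family.
A built-in six-frame Smith–Waterman aligner (BLOSUM62 extended with a
U row and a U-vs-stop bonus) makes the pipeline self-contained at desk
scale; real tblastn/JackHMMER tables are the production input.

**Trait classification.** An organism is called Sec+ when it has at least
three Sec-machinery genes (SecS, EFSec, PSTK, SelD, tRNA-Sec) and at least
one selenoprotein gene. hdrA–frhD gene pairs on one strand with a short
intergenic gap are reported as operon candidates, and motif-composition
profiles (core hexanucleotide context, unpaired-adenine run) summarise the
reported candidates.

**Benchmarking.** A deterministic generator plants selenoprotein genes,
machinery complements and SECIS elements of every class into
GC-controlled random contigs on both strands, with a machine-readable
truth ledger, plus dinucleotide-preserving shuffles as negative controls.

## Worked example

```python
from selenoscan import extract_utr3_window, scan_window
from selenoscan.simulate import SimConfig, simulate
from selenoscan.finder import (find_selenoproteins, classify_sec_trait,
                               inventory_machinery)

sim = simulate(SimConfig(seed=7, n_contigs=4, contig_length=3000,
                         plant_counts={"selD": 1, "frhA": 1,
                                       "hdrA": 1, "frhD": 1}))
genomes = {g.id: g for g in sim.genomes}
for gene in [a for a in sim.annotations
             if a.product_label in ("selD", "frhA", "hdrA", "frhD")]:
    window = extract_utr3_window(genomes[gene.contig_id], gene)
    for c in scan_window(window, gene_id=gene.gene_id):
        print(f"{c.gene_id:10s} {c.model_class.value:9s} "
              f"{c.contig_id}:{c.start}-{c.end}({c.strand})  "
              f"dG={c.delta_g:6.2f}  core={c.core_context}")

hits = find_selenoproteins(sim.genomes, queries=sim.queries)
report = classify_sec_trait(inventory_machinery(sim.annotations), hits,
                            organism_id="org1")
print(len(hits), "hits;", report.verdict)
```

prints (abridged):

```
selD_6     eSECIS_I  org1_c3:429-472(-)  dG=-15.63  core=GUGA_GA
selD_6     eSECIS_II org1_c3:429-472(-)  dG=-22.22  core=GUGA_GA
frhD_7     eSECIS_I  org1_c4:128-166(-)  dG=-19.72  core=AUGA_GA
hdrA_7     eSECIS_I  org1_c4:128-166(-)  dG=-19.72  core=AUGA_GA
frhA_8     eSECIS_I  org1_c4:911-958(+)  dG=-27.63  core=AUGA_GA
4 hits; Sec+
```

Each line is one SECIS candidate: its gene, structural class, genomic
interval and strand, the free energy of the candidate hairpin and the
core context (`AUGA_GA` is the canonical quartet; `GUGA_GA` a known
variant). The co-planted hdrA–frhD pair reports the *same* candidate at
org1_c4:128–166 — neighbouring genes sharing one 3′-UTR structure — and
the organism is Sec+ (5 machinery genes, 4 selenoproteins).

The same stages are available as a command-line tool:

```bash
selenoscan simulate --out sim/
selenoscan scan-secis --genomes sim/genomes.fasta \
    --annotations sim/annotations.gff3 --out scan/
selenoscan find-selenoproteins --genomes sim/genomes.fasta \
    --queries sim/queries.fasta --out find/
selenoscan classify-trait --machinery sim/annotations.gff3 \
    --hits find/selenoprotein_hits.tsv --out trait/
selenoscan logo-stats --candidates scan/secis_candidates.tsv --out logo/
```

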