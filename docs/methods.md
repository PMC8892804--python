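# Methods

This note documents the models, rules and numerical choices behind
`isoforge`, and what the synthetic test data can and cannot show.

## Coordinate and element conventions

All internal coordinates are 0-based half-open; GTF I/O converts to/from the
1-based inclusive convention at the file boundary only. A splice junction is
the strand-aware pair *(donor, acceptor)* = (last transcribed base of the
upstream exon, first transcribed base of the downstream exon) in genomic
coordinates; junction equality requires chromosome, strand and both
coordinates. The CDS stored on a transcript *includes* the stop codon, so the
C-terminal element ("stop site") is the genomic coordinate of the last base
of the stop codon; either convention works as long as sample and reference
are decomposed identically, which they are (both pass through
`extract_cds_elements`).

## Abundance and transcript filters

CPM = FLNC count / total FLNC reads × 10⁶, with the denominator taken over
the whole input abundance table before any filtering. The > 1 CPM retention
filter is strict, and it is applied to the input transcript table as given
(whether it should precede or follow 5′-degradation collapse is not
specified anywhere authoritative; collapse is out of scope here).
Intrapriming flags fire when the A fraction in the 20 nt of genome downstream
of the 3′ end is ≥ 0.95 (strand-aware: genomic T on the minus strand).
Windows truncated by a chromosome end are evaluated over the available bases
with a logged warning; a zero-length window never flags.

## ORF calling

Candidates are every ATG-initiated frame of ≥ 50 nt, ending at the first
in-frame stop or — flagged 3′-incomplete — at the transcript end; at most 50
are kept, longest first. Selection is two-tier:

1. **Annotated-start override.** Any candidate whose ATG coincides with a
   reference-annotated translation start of the gene wins; among several, the
   upstream-most (tie: longer ORF, then lexicographic protein). Whether the
   coding score should participate among annotated candidates is genuinely
   open; this implementation follows the literal upstream-most rule, which
   keeps the override total and score-independent.
2. **Scored selection.** Otherwise, maximise
   `coding_score × penalty^upstream_atg_count` with `penalty = 0.99`
   (configurable in (0, 1]). The exact functional form of this 5′-weighting
   is a design choice: one multiplicative decay constant reproduces the
   intended qualitative behaviour (a candidate with no upstream ATGs beats an
   equally-scored candidate with several) while remaining a single tunable.
   Ties break upstream-most → longest → lexicographic protein, so selection
   is total and deterministic.

When no external CPAT-style score table is supplied, the fallback coding
score is `tanh(3·f)` of the ORF's length fraction *f* of the transcript —
0 at zero length, strictly increasing, ≈ 1 for a full-length ORF. It is a
stand-in ordering device, not a calibrated coding-potential model.

Identical proteins within a gene collapse to one entry; the base accession is
the smallest member under plain byte order (`PB.1.10 < PB.1.2`), documented
prominently because it surprises; a natural-order sort is available behind
`OrfCallConfig.natural_sort`. Identical sequences under two genes stay
separate (grouping is within gene) and are logged.

## Protein classification

Element equality is exact genomic-coordinate equality; a ± N nt terminal
tolerance is exposed (`terminal_tolerance_nt`) but defaults to 0. Decisions
taken where the class definitions underdetermine behaviour:

* **pISM is restricted to the 5′-degradation signature** (junction chain is a
  3′-terminal sub-chain — possibly the full chain — of a reference chain,
  same stop site, unannotated start). 3′-side truncations fall through to
  pNIC/pNNC by element membership.
* **Mono-exonic CDSs** can be pFSM only by exact start+stop match to a
  mono-exonic reference chain; otherwise they classify by element membership
  (both termini known → pNIC, else pNNC) and never pISM, because the junction
  rules are vacuous.
* The N-terminus is compared as a genomic start coordinate, not as an AA
  sequence, keeping the three element kinds homogeneous.
* Products of transcripts whose gene has no annotated CDS, and transcripts
  that received no ORF, take the class `other` and are excluded from database
  building.

The transcript-level classifier is deliberately minimal (FSM / ISM / NIC /
NNC on junction chains) — enough for the cross-tabulation; the finer
transcript sub-categories (antisense, fusion, …) are out of scope.
Mono-exonic transcripts are FSM when the gene has a mono-exonic reference
isoform and NIC otherwise (no splice site exists to be novel).

## High-confidence genes and the hybrid database

A gene is high-confidence iff *every* observed transcript has exonic length
within [1, 4] kb, the *gene-summed* CPM is ≥ 3, and (by default) all
transcripts are polyadenylated. Both aggregation choices (every-transcript
for length/polyA, gene-sum for CPM) are configurable, since per-transcript
vs per-gene semantics are not pinned down by the filtering rationale.

Cross-database mapping is same-gene, equal-length, positional (Hamming)
comparison in rounds k = 0, 1, 2; earlier rounds take precedence, ties break
by lexicographic target accession. No indel alignment: length discordance
already means "distinct", so gaps cannot help. Gene categories are decided by
the set relations of mapped sample isoforms vs covered reference isoforms;
the "no sample isoform mapped → Distinct" test runs first, which makes the
five categories total even for the degenerate empty-reference case.

## Inference: parsimony, rescue, resolve

Proteins with identical mapped-peptide sets merge into indistinguishable
groups before the greedy cover; the cover retains the group explaining the
most unclaimed peptides, tie-broken by larger total peptide count then
smallest member accession — fixed tie-breaks so results are reproducible
across runs and platforms. Elimination labels:

* **case1** — peptide set strictly contained in one retained group's set;
* **case2** — covered jointly by ≥ 2 retained groups, each of which carries
  at least one peptide the eliminated protein cannot explain ("additional
  peptide evidence");
* **case_other** — anything else.

Rescue reinstates case1/case2 proteins with CPM strictly above 25 (strict
comparisons throughout: > 25 CPM, > 90 %, > 30 %) as singleton groups
annotated with their case, leaving the parsimony result untouched — this
keeps rescue auditable rather than rewriting group membership. Resolve
computes member abundance fractions within a group (member CPM / group CPM);
a strict-maximum member above 0.90 resolves the group, otherwise ≥ 2 members
above 0.30 flag co-expression, otherwise the group stays unresolved with its
fractions reported. Zero-CPM groups stay unresolved (logged).

Peptide matching treats I and L as distinct by default (`equate_il` switches
search-engine-style equivalence on), and modified/unmodified forms of one
base sequence are separate identifications (keyed `sequence[modifications]`).
Digestion uses `pyteomics.parser.cleave` with explicit specificity regexes
(trypsin `[KR](?!P)`, Lys-C `K`, Arg-C `R(?!P)`, Glu-C `E`, Asp-N before D,
chymotrypsin `F/Y/L` not before P and `W` not before M/P), ≤ 2 missed
cleavages, 7–50 AA detectability window. Protein-level FDR is *not*
recomputed — peptide inputs are assumed post-FDR.

The permutation test draws |tested| proteins uniformly without replacement
from the eliminated pool per permutation and uses the add-one p-value
estimator `(1 + #{null ≥ observed}) / (N + 1)`, which is valid (conservative,
never 0) and reproducible under a fixed seed.

## Synthetic data: what it emulates and what it does not

Each synthetic locus is a six-exon gene whose UTRs and introns are drawn from
{C, G, T} and whose coding body is built from {C, G, T} codons — alphabets
chosen so no ATG or stop codon can arise by accident, making ORF truth
unambiguous. Start codons are planted at three known positions (primary,
annotated alternative, never-annotated internal), each preceded by an
arginine codon so that suffix proteins digest to exact peptide subsets of
the full protein. Eleven named perturbation recipes force transcript and
protein classes by construction (exon skipping against an annotated or
unannotated junction, novel donor, retained intron, alternative-start
recombination, UTR-only and CDS-truncating 5′ degradation, intrapriming
extension, non-coding isoform), on either strand. Abundances realise exact
CPM targets by working at a library size of 10⁶ reads with a filler
background transcript absorbing the remainder.

Passing tests on these loci show the *rules* are implemented exactly — they
do not show robustness to properties of real data the generator omits:
sequencing error, truncation-length distributions, paralogy and cross-gene
peptide sharing, biased codon usage (only 10 amino acids occur in synthetic
proteins), PTM-bearing peptides, or FDR-controlled peptide noise. The demo
bundle scales the high-confidence length window to 0.2–4.0 kb in its config
file because synthetic isoforms are compact; library defaults remain
1–4 kb / 3 CPM / polyA.

Problem sizes used by the automated checks — 1,000 random ≤ 3 kb transcripts
for the ORF oracle, 500 random ≤ 8 × ≤ 12 instances for the parsimony oracle,
500 null runs × 99 permutations for test calibration, exhaustive |S|,|R| ≤ 3
for gene categories — were chosen as the smallest sizes that exercise every
rule path while keeping the whole suite fast on one CPU.

## Known limitations

* Candidate ORFs start only at ATG; non-canonical (CTG) starts and upstream
  short ORFs are out of scope.
* The coding-score fallback orders candidates by length fraction only; with
  real data, supply CPAT scores via `--scores`.
* pISM detection presumes degradation from the 5′ side; unusual 3′ artifacts
  will surface as pNIC/pNNC.
* Rescue emits singleton groups; merged-membership reporting of rescued
  isoforms is representable (`members` is a tuple) but not produced.
* The permutation validation takes the ground-truth set as an explicit input;
  constructing one (e.g. from an independent multi-protease dataset) is the
  caller's responsibility.
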