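# isoforge

Long-read proteogenomics toolkit: build a sample-specific, full-length protein
isoform database from long-read RNA-seq transcript models, classify the
predicted protein isoforms against a reference annotation, and perform
protein inference that uses transcript abundance to *rescue* isoforms that
peptide parsimony would discard and to *resolve* ambiguous protein groups.

## Who this is for

Bottom-up mass-spectrometry proteomics identifies peptides, not proteins;
shared peptides make protein-isoform identification ambiguous and heavily
dependent on the search database. Full-length transcript sequencing (PacBio /
ONT) yields complete isoform models — and per-isoform abundance — for the same
sample. `isoforge` is for researchers who have both data types and want
isoform-resolved protein identifications: it covers everything between a set
of collapsed transcript isoform models (GTF + FASTA + full-length read counts)
and protein groups, taking identified peptides (post-FDR) as input on the
proteomics side.

## What it computes

**ORF calling.** For each transcript, all ATG-initiated candidate ORFs
(≥ 50 nt, up to 50 candidates) are ranked. Any ORF whose ATG matches a
reference-annotated translation start is selected outright (upstream-most if
several); otherwise the selected ORF maximises

&nbsp;&nbsp;&nbsp;&nbsp;*score* = *coding score* × 0.99^(# upstream ATGs),

weighting starts near the 5′ end. Transcripts yielding identical proteins are
collapsed into one database entry (base accession = alphanumerically smallest
member; CPM = Σ member CPM, with CPM = FLNC reads / total reads × 10⁶; only
transcripts > 1 CPM are analysed and intrapriming artifacts — ≥ 95 % genomic A
in the 20 nt downstream of the 3′ end — are removed).

**Protein isoform classification.** Each predicted protein is reduced to
three genomic element kinds — N-terminal start site, CDS splice junctions,
C-terminal stop site — and compared with the gene's annotated repertoire:
`pFSM` (all elements match one annotated isoform), `pNIC` (all elements
known, combination novel), `pNNC` (≥ 1 novel element), `pISM` (5′-degradation
signature: junction suffix + annotated stop + unannotated internal start).
A minimal transcript-level FSM/ISM/NIC/NNC classifier supports
cross-tabulation (e.g. 5′-UTR-truncated transcripts are transcript-level ISM
but protein-level FSM).

**Hybrid database.** Genes whose transcript sampling is plausibly complete
(all isoforms 1–4 kb, gene ≥ 3 CPM, polyadenylated; configurable) contribute
sample-derived entries; all other protein-coding genes contribute reference
entries. Entries are cross-mapped between databases in rounds of 0, 1, then 2
amino-acid substitutions (equal length required), and each gene receives a
sample-vs-reference category: Match / Subset / Superset / Partial Overlap /
Distinct.

**Rescue & Resolve inference.** Peptides are mapped to entries through
in-silico digestion (trypsin + five alternative proteases, ≤ 2 missed
cleavages, 7–50 AA window). Greedy parsimony retains the fewest protein
groups covering all peptides. Eliminated isoforms whose peptides are a strict
subset of a retained group (Case 1) or jointly explained by ≥ 2 retained
groups with additional evidence (Case 2) are *rescued* as singleton groups
when their transcript abundance exceeds 25 CPM. Ambiguous multi-member groups
(Case 3) are *resolved* to a dominant member (> 90 % of group abundance) or
flagged co-expressed (≥ 2 members > 30 %). A permutation test
(default N = 1000) compares the validation rate of rescued/resolved isoforms
against randomly drawn eliminated isoforms.

All of this is driven by a synthetic-locus generator (`isoforge.simulate`)
that constructs genes whose isoform classes and inference outcomes are forced
by construction, so the entire pipeline is testable without any downloads.

## Worked example

```
$ forge simulate --out inputs --seed 7
demo bundle: 13 sample isoforms, 226 peptides -> inputs

$ forge build-db --transcripts inputs/sample_transcripts.fasta \
    --sample-gtf inputs/sample.gtf --abundance inputs/abundance.tsv \
    --reference inputs/reference.gtf --genome inputs/genome.fasta \
    --polya inputs/polya.tsv --config inputs/config.yaml --out stage
hybrid database: 9 entries (3 high-confidence genes)

$ forge infer --peptides inputs/peptides.tsv --db stage/hybrid_db.fasta \
    --reference-db stage/reference_db.fasta --config inputs/config.yaml --out stage
6 protein groups (2 rescued, 1 resolved), 15 novel peptides
```

The demo contains three genes. Thirteen isoforms reduce to ten unique
proteins (two transcripts differing only in UTRs share one entry); one
isoform is removed as an intrapriming artifact and one as non-coding, and the
pISM product is excluded from the database, leaving 9 hybrid entries.
Inference retains four groups; two high-abundance isoforms whose peptides are
subsets of better-covered isoforms are rescued (Case 1, > 25 CPM); one
ambiguous pair at a 95:5 abundance ratio is resolved to its dominant member;
and 15 peptides from a translated retained intron are absent from the
reference databases, i.e. novel. Stage outputs (`classification.tsv`,
`gene_categories.tsv`, `protein_groups.tsv`, `novel_peptides.tsv`, FASTA
databases in the `<gene>|<accession>|<class>|<CPM>` header dialect) land in
`stage/`.

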