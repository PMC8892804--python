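"""Stage orchestration: ORF calling -> classification -> database -> inference.

Each ``run_*`` function wraps the library operations of one pipeline stage,
reads/writes the plain-text interchange formats, and returns the in-memory
results so stages can also be chained directly in Python.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import io
from .abundance import compute_cpm, filter_min_cpm, intrapriming_flag
from .classify import (
    build_reference_catalog,
    classify_proteins,
    classify_transcript,
    cross_tabulate_classes,
)
from .config import PipelineConfig
from .database import (
    build_hybrid_database,
    classify_gene_category,
    make_reference_protein_db,
    map_accessions,
    select_high_confidence_genes,
)
from .inference import (
    find_novel_peptides,
    infer_parsimonious,
    map_peptides,
    rescue,
    resolve,
)
from .model import (
    GeneCategory,
    ProteinClassification,
    ProteinEntry,
    ProteinGroup,
    TranscriptModel,
    extract_cds_elements,
)
from .orfs import call_orfs, refine_orf_database, translate_orf

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def splice_sequence(tx: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced transcript-orientation sequence from a genome."""
    chrom = genome[tx.chrom]
    parts = [chrom[iv.start : iv.end] for iv in tx.exons]
    seq = "".join(parts).upper()
    if tx.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def reference_protein_sequences(
    reference_transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
) -> list[tuple[str, str, str]]:
    """(gene, accession, protein) for every CDS-bearing reference transcript."""
    out = []
    for tx in reference_transcripts:
        if not tx.cds:
            continue
        chrom = genome[tx.chrom]
        nt = "".join(chrom[iv.start : iv.end] for iv in tx.cds).upper()
        if tx.strand == "-":
            nt = nt.translate(_COMPLEMENT)[::-1]
        out.append((tx.gene_id, tx.transcript_id, translate_orf(nt)))
    return out


# ---------------------------------------------------------------------------
# ORF calling stage
# ---------------------------------------------------------------------------


@dataclass
class OrfCallResult:
    entries: list[ProteinEntry]
    transcripts: list[TranscriptModel]  # post-filter, with called CDS attached
    cpm: dict[str, float]
    excluded_noncoding: list[str] = field(default_factory=list)
    excluded_intraprimed: list[str] = field(default_factory=list)


def run_orf_call(
    sample_gtf: str | Path,
    transcript_fasta: str | Path,
    abundance_tsv: str | Path,
    reference_gtf: Optional[str | Path] = None,
    genome_fasta: Optional[str | Path] = None,
    scores_tsv: Optional[str | Path] = None,
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> OrfCallResult:
    """Filter transcripts, call one ORF each, and refine to unique entries."""
    config = config or PipelineConfig()
    transcripts = io.read_gtf(sample_gtf)
    seqs = io.read_fasta(transcript_fasta)
    for tx in transcripts:
        if tx.transcript_id not in seqs:
            raise ValueError(f"{tx.transcript_id}: sequence missing from FASTA")
        tx.sequence = seqs[tx.transcript_id]
        tx.validate()

    counts = io.read_abundance_table(abundance_tsv)
    records = compute_cpm(counts)
    cpm = {r.transcript_id: r.cpm for r in records}
    keep = filter_min_cpm(records, config.filters.min_cpm)
    transcripts = [tx for tx in transcripts if tx.transcript_id in keep]

    excluded_intraprimed = []
    genome = io.read_fasta(genome_fasta) if genome_fasta else None
    if genome is not None:
        kept = []
        for tx in transcripts:
            if intrapriming_flag(
                tx,
                genome,
                config.filters.intrapriming_window_nt,
                config.filters.intrapriming_a_fraction,
            ):
                excluded_intraprimed.append(tx.transcript_id)
                log.info("%s: intrapriming artifact; excluded", tx.transcript_id)
            else:
                kept.append(tx)
        transcripts = kept

    known_starts_by_gene = None
    reference_proteins_by_gene: Optional[dict[str, set[str]]] = None
    if reference_gtf is not None:
        reference = io.read_gtf(reference_gtf)
        catalogs = build_reference_catalog(reference)
        known_starts_by_gene = {g: c.known_starts for g, c in catalogs.items()}
        if genome is not None:
            reference_proteins_by_gene = {}
            for gene, _acc, aa in reference_protein_sequences(reference, genome):
                reference_proteins_by_gene.setdefault(gene, set()).add(aa)

    coding_scores = io.read_coding_scores(scores_tsv) if scores_tsv else None
    called = call_orfs(
        transcripts,
        known_starts_by_gene,
        reference_proteins_by_gene,
        coding_scores,
        config.orf_calling,
    )
    excluded_noncoding = [
        tx.transcript_id for tx in transcripts if tx.transcript_id not in called
    ]

    by_id = {tx.transcript_id: tx for tx in transcripts}
    coding = []
    for tid, orf in called.items():
        tx = by_id[tid]
        coding.append(
            tx.with_cds_from_transcript_span(orf.orf_start, orf.orf_end)
        )
        coding[-1].sequence = tx.sequence

    entries = refine_orf_database(
        {tid: (orf.aa_sequence, cpm[tid], by_id[tid].gene_id) for tid, orf in called.items()},
        config.orf_calling,
    )
    coding_by_id = {tx.transcript_id: tx for tx in coding}
    for entry in entries:
        base_tx = coding_by_id[entry.accession]
        entry.genomic_model = base_tx
        entry.cds_elements = extract_cds_elements(base_tx)
        entry.cds_transcript_start = called[entry.accession].orf_start

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_gtf(coding, out_dir / "sample_cds.gtf")
        pd.DataFrame(
            {
                "base_accession": [e.accession for e in entries],
                "gene": [e.gene for e in entries],
                "members": ["|".join(e.members) for e in entries],
                "cpm": [round(e.cpm, 6) for e in entries],
                "aa_length": [len(e.sequence) for e in entries],
                "sequence": [e.sequence for e in entries],
            }
        ).to_csv(out_dir / "orf_refined.tsv", sep="\t", index=False)
    return OrfCallResult(
        entries=entries,
        transcripts=coding,
        cpm=cpm,
        excluded_noncoding=excluded_noncoding,
        excluded_intraprimed=excluded_intraprimed,
    )


# ---------------------------------------------------------------------------
# classification stage
# ---------------------------------------------------------------------------


@dataclass
class ClassifyResult:
    protein_classes: dict[str, ProteinClassification]
    transcript_classes: dict[str, str]
    crosstab: pd.DataFrame


def run_classify(
    sample_cds_gtf: str | Path | Sequence[TranscriptModel],
    reference_gtf: str | Path | Sequence[TranscriptModel],
    full_sample_gtf: Optional[str | Path | Sequence[TranscriptModel]] = None,
    out_dir: Optional[str | Path] = None,
) -> ClassifyResult:
    """SQANTI-Protein classification plus the transcript-level cross-tab.

    ``full_sample_gtf`` may supply the complete isoform set (including
    non-coding transcripts that received no ORF); those are classified at the
    transcript level and assigned the protein class 'other'.
    """

    def _load(src):
        return io.read_gtf(src) if isinstance(src, (str, Path)) else list(src)

    sample = _load(sample_cds_gtf)
    reference = _load(reference_gtf)
    full = _load(full_sample_gtf) if full_sample_gtf is not None else sample

    catalogs = build_reference_catalog(reference)
    ref_chains_by_gene: dict[str, list] = {}
    for tx in reference:
        ref_chains_by_gene.setdefault(tx.gene_id, []).append(tx.splice_junctions())

    cds_by_id = {tx.transcript_id: tx for tx in sample}
    transcript_classes = {}
    protein_samples = {}
    other: dict[str, ProteinClassification] = {}
    for tx in full:
        transcript_classes[tx.transcript_id] = classify_transcript(
            tx.splice_junctions(), ref_chains_by_gene.get(tx.gene_id, [])
        )
        coding = cds_by_id.get(tx.transcript_id)
        if coding is not None and coding.cds:
            protein_samples[tx.transcript_id] = (
                tx.gene_id,
                extract_cds_elements(coding),
            )
        else:
            other[tx.transcript_id] = ProteinClassification(
                tx.transcript_id, "other", "no-called-orf"
            )
    protein_classes = classify_proteins(protein_samples, catalogs)
    protein_classes.update(other)
    crosstab = cross_tabulate_classes(
        transcript_classes, {a: c.pclass for a, c in protein_classes.items()}
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        accs = sorted(protein_classes)
        pd.DataFrame(
            {
                "accession": accs,
                "transcript_class": [
                    transcript_classes.get(a, "unclassified") for a in accs
                ],
                "protein_class": [protein_classes[a].pclass for a in accs],
                "subclass": [protein_classes[a].subclass for a in accs],
                "novel_elements": [
                    ";".join(protein_classes[a].novel_elements) for a in accs
                ],
            }
        ).to_csv(out_dir / "classification.tsv", sep="\t", index=False)
        crosstab.to_csv(out_dir / "class_crosstab.tsv", sep="\t")
    return ClassifyResult(protein_classes, transcript_classes, crosstab)


# ---------------------------------------------------------------------------
# database stage
# ---------------------------------------------------------------------------


@dataclass
class BuildDbResult:
    hybrid: list[ProteinEntry]
    reference_db: list[ProteinEntry]
    hc_genes: set[str]
    categories: list[GeneCategory]


def run_build_db(
    orf_result: OrfCallResult,
    protein_classes: Mapping[str, ProteinClassification],
    polya: Mapping[str, bool],
    reference_proteins: Sequence[tuple[str, str, str]],
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> BuildDbResult:
    """Select high-confidence genes and assemble the hybrid protein database."""
    config = config or PipelineConfig()
    candidates = []
    for entry in orf_result.entries:
        cls = protein_classes.get(entry.accession)
        entry.pclass = cls.pclass if cls else "other"
        if entry.pclass in ("pFSM", "pNIC", "pNNC"):
            candidates.append(entry)

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in orf_result.transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    hc_genes = select_high_confidence_genes(
        by_gene, orf_result.cpm, polya, config.high_confidence
    )

    reference_db = make_reference_protein_db(reference_proteins)
    hybrid = build_hybrid_database(candidates, hc_genes, reference_db)
    mapping = map_accessions(candidates, reference_db)
    map_by_acc = {m.accession_a: m.accession_b for m in mapping}

    categories = []
    ref_by_gene: dict[str, set[str]] = {}
    for e in reference_db:
        ref_by_gene.setdefault(e.gene, set()).add(e.accession)
    for gene in sorted(hc_genes):
        sample_accs = {e.accession for e in candidates if e.gene == gene}
        if not sample_accs:
            continue
        categories.append(
            classify_gene_category(
                gene, sample_accs, ref_by_gene.get(gene, set()), map_by_acc
            )
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_protein_fasta(hybrid, out_dir / "hybrid_db.fasta")
        io.write_protein_fasta(reference_db, out_dir / "reference_db.fasta")
        pd.DataFrame(
            [
                {
                    "accession_a": m.accession_a,
                    "accession_b": m.accession_b,
                    "n_mismatch": m.n_mismatch,
                    "round": m.round,
                }
                for m in mapping
            ]
        ).to_csv(out_dir / "accession_mapping.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "category": c.category,
                    "n_sample": c.n_sample,
                    "n_reference": c.n_reference,
                    "n_shared": c.n_shared,
                    "n_novel": c.n_novel,
                }
                for c in categories
            ]
        ).to_csv(out_dir / "gene_categories.tsv", sep="\t", index=False)
    return BuildDbResult(hybrid, reference_db, hc_genes, categories)


# ---------------------------------------------------------------------------
# inference stage
# ---------------------------------------------------------------------------


@dataclass
class InferResult:
    groups: list[ProteinGroup]  # retained (+ rescued) groups, resolved
    eliminated: list[tuple[str, str]]
    novel_peptides: set[str]
    unmapped: frozenset[str]


def run_infer(
    peptides: Sequence[str],
    db_entries: Sequence[ProteinEntry],
    reference_dbs: Sequence[Sequence[ProteinEntry]] = (),
    config: Optional[PipelineConfig] = None,
    rescue_resolve: bool = True,
    out_dir: Optional[str | Path] = None,
) -> InferResult:
    """Map peptides, run parsimony, and optionally rescue & resolve.

    Member abundances are taken from the database entries' CPM fields
    (reference entries carry no transcript support and count as 0).
    """
    config = config or PipelineConfig()
    icfg = config.inference
    pmap = map_peptides(peptides, db_entries, icfg)
    groups, eliminated = infer_parsimonious(pmap)
    abundances = {e.accession: e.cpm for e in db_entries}
    if rescue_resolve:
        groups = groups + rescue(eliminated, abundances, icfg, pmap)
    groups = resolve(groups, abundances, icfg)
    novel = (
        find_novel_peptides(pmap.peptides, reference_dbs, icfg)
        if reference_dbs
        else set()
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {
                    "members": "|".join(g.members),
                    "n_peptides": len(g.peptides),
                    "status": g.status,
                    "resolution": g.resolution,
                    "fractions": ";".join(
                        f"{m}:{g.abundance_fractions[m]:.4f}"
                        for m in sorted(g.abundance_fractions)
                    ),
                }
                for g in groups
            ]
        ).to_csv(out_dir / "protein_groups.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(eliminated), columns=["accession", "case"]
        ).to_csv(out_dir / "eliminated.tsv", sep="\t", index=False)
        io.write_peptides(sorted(novel), out_dir / "novel_peptides.tsv")
    return InferResult(groups, eliminated, novel, pmap.unmapped)
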