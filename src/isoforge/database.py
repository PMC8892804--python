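"""High-confidence gene selection, hybrid database assembly and cross-mapping.

The hybrid database uses sample-derived protein entries for genes whose
transcript sampling is judged complete (length window, abundance floor,
polyadenylation) and reference entries for every other protein-coding gene, so
that downstream peptide identification never loses reference coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .config import HighConfidenceConfig
from .model import GeneCategory, ProteinEntry, TranscriptModel

log = logging.getLogger(__name__)

__all__ = [
    "AccessionMapping",
    "select_high_confidence_genes",
    "make_reference_protein_db",
    "build_hybrid_database",
    "map_accessions",
    "classify_gene_category",
]


def select_high_confidence_genes(
    transcripts_by_gene: Mapping[str, Sequence[TranscriptModel]],
    cpm: Mapping[str, float],
    polya: Mapping[str, bool],
    config: Optional[HighConfidenceConfig] = None,
) -> set[str]:
    """Genes whose observed transcripts are plausibly fully sampled.

    A gene qualifies iff every observed transcript has exonic length within
    [min_len_kb, max_len_kb], the gene's summed CPM is >= min_gene_cpm, and
    (when required) all transcripts are 3'-polyadenylated.
    """
    config = config or HighConfidenceConfig()
    selected = set()
    for gene, txs in transcripts_by_gene.items():
        if not txs:
            log.info("gene %s has zero transcripts; excluded", gene)
            continue
        lengths_ok = all(
            config.min_len_kb <= tx.exonic_length / 1000.0 <= config.max_len_kb
            for tx in txs
        )
        gene_cpm = sum(cpm.get(tx.transcript_id, 0.0) for tx in txs)
        polya_ok = (not config.require_polya) or all(
            polya.get(tx.transcript_id, False) for tx in txs
        )
        if lengths_ok and gene_cpm >= config.min_gene_cpm and polya_ok:
            selected.add(gene)
    return selected


def make_reference_protein_db(
    translations: Iterable[tuple[str, str, str]],
) -> list[ProteinEntry]:
    """Collapse identical reference protein sequences within each gene.

    ``translations`` yields (gene, transcript-name accession, aa_sequence).
    The representative accession is the first by lexicographic transcript name.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for gene, accession, aa in translations:
        groups.setdefault((gene, aa), []).append(accession)
    entries = []
    for (gene, aa), members in groups.items():
        members = sorted(members)
        entries.append(
            ProteinEntry(
                accession=members[0],
                gene=gene,
                sequence=aa,
                pclass="reference",
                members=tuple(members),
            )
        )
    entries.sort(key=lambda e: (e.gene, e.accession))
    return entries


def build_hybrid_database(
    sample_entries: Sequence[ProteinEntry],
    hc_genes: set[str],
    reference_entries: Sequence[ProteinEntry],
) -> list[ProteinEntry]:
    """Sample entries for high-confidence genes, reference entries elsewhere.

    No gene contributes from both sources.  Sample entries are expected to be
    pre-filtered to pFSM/pNIC/pNNC upstream.
    """
    db = [e for e in sample_entries if e.gene in hc_genes]
    sample_genes = {e.gene for e in sample_entries}
    db += [e for e in reference_entries if e.gene not in hc_genes]
    reference_genes = {e.gene for e in reference_entries}
    for gene in hc_genes - sample_genes:
        log.warning("high-confidence gene %s has no sample entries", gene)
    covered = {e.gene for e in db}
    for gene in (sample_genes | reference_genes) - covered - hc_genes:
        log.warning("gene %s absent from both database sources", gene)
    return db


@dataclass(frozen=True)
class AccessionMapping:
    accession_a: str
    accession_b: str
    n_mismatch: int
    round: int


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def map_accessions(
    db_a: Sequence[ProteinEntry],
    db_b: Sequence[ProteinEntry],
    max_mismatch: int = 2,
) -> list[AccessionMapping]:
    """Iteratively map entries across databases, tolerating AA substitutions.

    Round k (k = 0..max_mismatch) matches still-unmapped ``db_a`` entries to
    same-gene, equal-length ``db_b`` entries at exactly k positional
    substitutions; earlier rounds take precedence, each ``db_a`` entry maps at
    most once, and ties within a round break by lexicographic target
    accession.  Length-discordant pairs are never compared (no indel
    alignment), matching the rule that differing lengths mean distinct entries.
    """
    by_gene_len: dict[tuple[str, int], list[ProteinEntry]] = {}
    for e in db_b:
        by_gene_len.setdefault((e.gene, len(e.sequence)), []).append(e)
    for bucket in by_gene_len.values():
        bucket.sort(key=lambda e: e.accession)

    mappings: list[AccessionMapping] = []
    unmapped = sorted(db_a, key=lambda e: e.accession)
    for k in range(max_mismatch + 1):
        still = []
        for ea in unmapped:
            hit = None
            for eb in by_gene_len.get((ea.gene, len(ea.sequence)), []):
                if _hamming(ea.sequence, eb.sequence) == k:
                    hit = eb
                    break  # bucket sorted: first hit is lexicographic smallest
            if hit is not None:
                mappings.append(AccessionMapping(ea.accession, hit.accession, k, k))
            else:
                still.append(ea)
        unmapped = still
    return mappings


def classify_gene_category(
    gene_id: str,
    sample_accessions: set[str],
    reference_accessions: set[str],
    mapping: Mapping[str, str],
) -> GeneCategory:
    """Per-gene sample-vs-reference isoform repertoire category.

    With M the sample isoforms mapped into the reference set: Match (all
    sample mapped, all reference covered), Subset (all sample mapped, some
    reference uncovered), Superset (all reference covered plus novel sample
    isoforms), PartialOverlap (some but not all reference covered, plus novel
    isoforms), Distinct (no sample isoform mapped).  The Distinct test runs
    first, which makes the rules total even for an empty reference set.
    """
    if not sample_accessions:
        raise ValueError(f"{gene_id}: empty sample isoform set")
    mapped = {
        s
        for s in sample_accessions
        if s in mapping and mapping[s] in reference_accessions
    }
    covered = {mapping[s] for s in mapped}
    novel = sample_accessions - mapped
    n = dict(
        n_sample=len(sample_accessions),
        n_reference=len(reference_accessions),
        n_shared=len(mapped),
        n_novel=len(novel),
    )
    if not mapped:
        category = "Distinct"
    elif not novel and covered == reference_accessions:
        category = "Match"
    elif not novel:
        category = "Subset"
    elif covered == reference_accessions:
        category = "Superset"
    else:
        category = "PartialOverlap"
    return GeneCategory(gene_id, category, **n)
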