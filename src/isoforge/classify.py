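"""Protein- and transcript-level isoform classification against a reference.

A predicted protein isoform is decomposed into three element kinds — the
N-terminal start site, the CDS-internal splice junctions and the C-terminal
stop site, all in genomic coordinates — and compared to the union of elements
annotated for the gene:

* **pFSM** — the full (start, junction chain, stop) triple equals that of some
  annotated protein isoform.
* **pISM** — the 5'-degradation signature: the junction chain is a contiguous
  3'-terminal sub-chain of an annotated chain with the same stop site, but the
  start is unannotated (the true ATG was lost and an internal one used).
* **pNIC** — every element is individually annotated but the combination is
  novel (e.g. a known alternative start paired with a known skipping event).
* **pNNC** — at least one element (start, junction or stop) is itself novel.
* **other** — products of transcripts whose gene has no annotated CDS
  (non-coding/intergenic space), which are excluded from database building.

Element equality is exact genomic-coordinate equality; an optional ±N nt
terminal tolerance is exposed but defaults to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import (
    CdsElements,
    IntegrityError,
    Junction,
    ProteinClassification,
    TranscriptModel,
    extract_cds_elements,
)

log = logging.getLogger(__name__)

__all__ = [
    "ReferenceGeneCatalog",
    "build_reference_catalog",
    "classify_protein",
    "classify_proteins",
    "classify_transcript",
    "cross_tabulate_classes",
]

PROTEIN_CLASSES = ("pFSM", "pISM", "pNIC", "pNNC", "other")
TRANSCRIPT_CLASSES = ("FSM", "ISM", "NIC", "NNC")


@dataclass
class ReferenceGeneCatalog:
    """Annotated CDS element sets of one gene (unions over its isoforms)."""

    gene_id: str
    chrom: str
    strand: str
    known_starts: set[int] = field(default_factory=set)
    known_stops: set[int] = field(default_factory=set)
    known_junctions: set[Junction] = field(default_factory=set)
    reference_cds_chains: list[CdsElements] = field(default_factory=list)

    def add_chain(self, chain: CdsElements) -> None:
        if chain.chrom != self.chrom or chain.strand != self.strand:
            raise IntegrityError(
                f"{self.gene_id}: reference isoforms on mixed chromosome/strand"
            )
        self.known_starts.add(chain.start_site)
        self.known_stops.add(chain.stop_site)
        self.known_junctions.update(chain.junctions)
        self.reference_cds_chains.append(chain)


def build_reference_catalog(
    reference_transcripts: Iterable[TranscriptModel],
) -> dict[str, ReferenceGeneCatalog]:
    """Per-gene element catalogs from CDS-bearing reference transcripts.

    Genes whose transcripts carry exons but no CDS are omitted with a log entry.
    """
    catalogs: dict[str, ReferenceGeneCatalog] = {}
    coding_genes = set()
    seen_genes = set()
    for tx in reference_transcripts:
        seen_genes.add(tx.gene_id)
        if not tx.cds:
            continue
        coding_genes.add(tx.gene_id)
        chain = extract_cds_elements(tx)
        cat = catalogs.get(tx.gene_id)
        if cat is None:
            cat = ReferenceGeneCatalog(tx.gene_id, tx.chrom, tx.strand)
            catalogs[tx.gene_id] = cat
        cat.add_chain(chain)
    for gene in seen_genes - coding_genes:
        log.info("gene %s has exons but no CDS; omitted from protein catalog", gene)
    return catalogs


def _is_suffix(sub: Sequence, full: Sequence) -> bool:
    n = len(sub)
    return n <= len(full) and tuple(full[len(full) - n :]) == tuple(sub)


def _is_contiguous_subchain(sub: Sequence, full: Sequence) -> bool:
    sub, full = tuple(sub), tuple(full)
    n = len(sub)
    if n == 0 or n > len(full):
        return False
    return any(full[i : i + n] == sub for i in range(len(full) - n + 1))


def classify_protein(
    accession: str,
    sample: CdsElements,
    catalog: ReferenceGeneCatalog,
    terminal_tolerance_nt: int = 0,
) -> ProteinClassification:
    """Classify one predicted protein isoform against its gene's catalog."""
    if sample.chrom != catalog.chrom or sample.strand != catalog.strand:
        raise IntegrityError(
            f"{accession}: sample on {sample.chrom}{sample.strand}, catalog on "
            f"{catalog.chrom}{catalog.strand}"
        )

    def site_known(site: int, known: set[int]) -> bool:
        if terminal_tolerance_nt == 0:
            return site in known
        return any(abs(site - k) <= terminal_tolerance_nt for k in known)

    start_known = site_known(sample.start_site, catalog.known_starts)
    stop_known = site_known(sample.stop_site, catalog.known_stops)

    for chain in catalog.reference_cds_chains:
        if (
            sample.junctions == chain.junctions
            and site_known(sample.start_site, {chain.start_site})
            and site_known(sample.stop_site, {chain.stop_site})
        ):
            return ProteinClassification(accession, "pFSM", "reference-match")

    # 5'-degradation signature: multi-exonic CDS whose junctions form a
    # 3'-terminal sub-chain of a reference chain with the same stop, but with
    # an internal (unannotated) start.  Mono-exonic CDSs never take this path.
    if sample.junctions and not start_known:
        for chain in catalog.reference_cds_chains:
            if sample.stop_site == chain.stop_site and _is_suffix(
                sample.junctions, chain.junctions
            ):
                return ProteinClassification(
                    accession, "pISM", "5prime-degradation", ("novel-n-terminus",)
                )

    novel: list[str] = []
    if not start_known:
        novel.append("novel-n-terminus")
    for j in sample.junctions:
        if j not in catalog.known_junctions:
            novel.append(f"novel-junction:{j.donor}-{j.acceptor}")
    if not stop_known:
        novel.append("novel-c-terminus")

    if novel:
        kinds = sorted({n.split(":")[0] for n in novel})
        return ProteinClassification(accession, "pNNC", ",".join(kinds), tuple(novel))
    return ProteinClassification(accession, "pNIC", "known-combination")


def classify_proteins(
    samples: Mapping[str, tuple[str, CdsElements]],
    catalogs: Mapping[str, ReferenceGeneCatalog],
) -> dict[str, ProteinClassification]:
    """Classify many isoforms; genes absent from the catalog yield 'other'.

    ``samples`` maps accession -> (gene_id, CdsElements).
    """
    out = {}
    for acc, (gene, elements) in samples.items():
        cat = catalogs.get(gene)
        if cat is None:
            out[acc] = ProteinClassification(acc, "other", "no-reference-cds")
        else:
            out[acc] = classify_protein(acc, elements, cat)
    return out


def classify_transcript(
    sample_chain: Sequence[Junction],
    reference_chains: Iterable[Sequence[Junction]],
) -> str:
    """Minimal transcript-level splice-match class: FSM/ISM/NIC/NNC.

    FSM: exact junction-chain match.  ISM: contiguous sub-chain of a reference
    chain.  NIC: only known junctions in a novel combination.  NNC: at least
    one novel junction.  A mono-exonic sample is FSM when the gene has a
    mono-exonic reference isoform and NIC otherwise (no splice site can be
    novel).
    """
    chains = [tuple(c) for c in reference_chains]
    sample = tuple(sample_chain)
    if sample in chains:
        return "FSM"
    if not sample:
        return "NIC"
    if any(_is_contiguous_subchain(sample, c) for c in chains):
        return "ISM"
    known = {j for c in chains for j in c}
    return "NIC" if all(j in known for j in sample) else "NNC"


def cross_tabulate_classes(
    transcript_classes: Mapping[str, str],
    protein_classes: Mapping[str, str],
) -> pd.DataFrame:
    """Contingency table of transcript class x protein class per isoform.

    Isoforms present in only one classification are counted under an
    ``unclassified`` margin on the missing axis.
    """
    ids = sorted(set(transcript_classes) | set(protein_classes))
    rows = [transcript_classes.get(i, "unclassified") for i in ids]
    cols = [protein_classes.get(i, "unclassified") for i in ids]
    return pd.crosstab(
        pd.Series(rows, name="transcript_class"),
        pd.Series(cols, name="protein_class"),
    )
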