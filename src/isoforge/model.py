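"""Core domain types for long-read proteogenomics.

All genomic coordinates are internally 0-based, half-open ``[start, end)``.
GTF input/output converts from/to the 1-based inclusive convention at the I/O
boundary only (see :mod:`isoforge.io`).

A splice junction is represented strand-aware as ``(donor, acceptor)`` where
*donor* is the genomic coordinate of the last transcribed base of the upstream
exon and *acceptor* the first transcribed base of the downstream exon, both in
transcription order.  Junction equality therefore requires chromosome, strand
and both coordinates to agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "IntegrityError",
    "GenomicInterval",
    "Junction",
    "TranscriptModel",
    "CdsElements",
    "AbundanceRecord",
    "CandidateORF",
    "ProteinEntry",
    "ProteinClassification",
    "GeneCategory",
    "PeptideProteinMap",
    "ProteinGroup",
    "extract_cds_elements",
]

STRANDS = ("+", "-")


class IntegrityError(ValueError):
    """Structural inconsistency in a transcript or annotation model."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must precede end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Junction:
    """A splice junction in genomic coordinates, transcription-order donor/acceptor."""

    chrom: str
    strand: str
    donor: int
    acceptor: int


@dataclass
class TranscriptModel:
    """A sample or reference transcript isoform.

    Parameters
    ----------
    exons
        Exon intervals on a single chromosome/strand, sorted by genomic start,
        non-overlapping.
    cds
        Optional coding intervals (subset of exonic space).  By package
        convention the CDS *includes* the stop codon.
    sequence
        Optional spliced nucleotide sequence in transcript (5'->3') orientation.
    flnc_count
        Optional full-length non-chimeric read count supporting the isoform.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: Optional[list[GenomicInterval]] = None
    sequence: Optional[str] = None
    flnc_count: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if not self.exons:
            raise IntegrityError(f"{self.transcript_id}: transcript has no exons")
        chrom = self.exons[0].chrom
        strand = self.exons[0].strand
        for ex in self.exons:
            if ex.chrom != chrom or ex.strand != strand:
                raise IntegrityError(
                    f"{self.transcript_id}: exons on mixed chromosome/strand"
                )
        starts = [ex.start for ex in self.exons]
        if starts != sorted(starts):
            raise IntegrityError(f"{self.transcript_id}: exons not sorted by start")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise IntegrityError(f"{self.transcript_id}: overlapping exons")
        if self.cds is not None:
            for iv in self.cds:
                if not any(ex.contains(iv) for ex in self.exons):
                    raise IntegrityError(
                        f"{self.transcript_id}: CDS interval outside exonic space"
                    )
            cstarts = [iv.start for iv in self.cds]
            if cstarts != sorted(cstarts):
                raise IntegrityError(f"{self.transcript_id}: CDS not sorted by start")
        if self.sequence is not None and len(self.sequence) != self.exonic_length:
            raise IntegrityError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                f"summed exon length {self.exonic_length}"
            )
        if self.flnc_count is not None and self.flnc_count < 0:
            raise ValueError(f"{self.transcript_id}: negative FLNC count")

    # -- basic geometry ---------------------------------------------------
    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def exonic_length(self) -> int:
        return sum(ex.length for ex in self.exons)

    def exons_in_transcription_order(self) -> list[GenomicInterval]:
        return list(self.exons) if self.strand == "+" else list(reversed(self.exons))

    def splice_junctions(self) -> tuple[Junction, ...]:
        """Exon-exon junctions in transcription (5'->3') order."""
        return _junctions_between(self.exons_in_transcription_order())

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the last transcribed base."""
        if self.strand == "+":
            return self.exons[-1].end - 1
        return self.exons[0].start

    # -- coordinate transforms -------------------------------------------
    def to_genomic_intervals(self, t_start: int, t_end: int) -> list[GenomicInterval]:
        """Map transcript coordinates [t_start, t_end) to genomic intervals.

        Returned intervals are in transcription order.
        """
        if not (0 <= t_start < t_end <= self.exonic_length):
            raise ValueError(
                f"{self.transcript_id}: transcript span [{t_start}, {t_end}) outside "
                f"[0, {self.exonic_length})"
            )
        out: list[GenomicInterval] = []
        pos = 0
        for ex in self.exons_in_transcription_order():
            lo = max(t_start, pos)
            hi = min(t_end, pos + ex.length)
            if lo < hi:
                off0, off1 = lo - pos, hi - pos
                if self.strand == "+":
                    out.append(
                        GenomicInterval(ex.chrom, ex.start + off0, ex.start + off1, "+")
                    )
                else:
                    out.append(
                        GenomicInterval(ex.chrom, ex.end - off1, ex.end - off0, "-")
                    )
            pos += ex.length
        return out

    def genomic_position(self, t_pos: int) -> int:
        """Genomic coordinate of transcript base ``t_pos``."""
        iv = self.to_genomic_intervals(t_pos, t_pos + 1)[0]
        return iv.start

    def with_cds_from_transcript_span(self, t_start: int, t_end: int) -> "TranscriptModel":
        """Return a copy with CDS set from a transcript-coordinate span."""
        cds = sorted(self.to_genomic_intervals(t_start, t_end), key=lambda iv: iv.start)
        return replace(self, cds=cds)


def _junctions_between(ordered: Sequence[GenomicInterval]) -> tuple[Junction, ...]:
    juncs = []
    for up, down in zip(ordered, ordered[1:]):
        if up.strand == "+":
            juncs.append(Junction(up.chrom, "+", up.end - 1, down.start))
        else:
            juncs.append(Junction(up.chrom, "-", up.start, down.end - 1))
    return tuple(juncs)


@dataclass(frozen=True)
class CdsElements:
    """The three comparable elements of a predicted protein isoform.

    ``start_site`` is the genomic coordinate of the first translated base
    (strand-aware 5' CDS boundary), ``stop_site`` the last translated base and
    ``junctions`` the CDS-internal splice junctions in transcription order.
    """

    chrom: str
    strand: str
    start_site: int
    junctions: tuple[Junction, ...]
    stop_site: int

    @property
    def chain_key(self) -> tuple:
        return (self.start_site, self.junctions, self.stop_site)


def extract_cds_elements(transcript: TranscriptModel) -> CdsElements:
    """Decompose a CDS-bearing transcript into N-terminus, junctions, C-terminus.

    Raises
    ------
    IntegrityError
        If the transcript carries no CDS or the CDS lies outside exonic space.
    """
    if not transcript.cds:
        raise IntegrityError(f"{transcript.transcript_id}: no CDS to extract")
    transcript.validate()
    ivs = (
        list(transcript.cds)
        if transcript.strand == "+"
        else list(reversed(transcript.cds))
    )
    if transcript.strand == "+":
        start_site = ivs[0].start
        stop_site = ivs[-1].end - 1
    else:
        start_site = ivs[0].end - 1
        stop_site = ivs[-1].start
    return CdsElements(
        chrom=transcript.chrom,
        strand=transcript.strand,
        start_site=start_site,
        junctions=_junctions_between(ivs),
        stop_site=stop_site,
    )


@dataclass(frozen=True)
class AbundanceRecord:
    """Per-transcript full-length read count and counts-per-million."""

    transcript_id: str
    flnc_count: int
    cpm: float


@dataclass
class CandidateORF:
    """One candidate open reading frame on a transcript.

    ``orf_start`` is the 0-based transcript position of the A of the ATG;
    ``orf_end`` the exclusive end of the stop codon (or the transcript end for
    3'-incomplete ORFs, flagged via ``has_stop``).
    """

    transcript_id: str
    orf_start: int
    orf_end: int
    aa_sequence: str
    has_stop: bool = True
    coding_score: float = float("nan")
    has_annotated_start: bool = False
    matches_reference_protein: bool = False
    upstream_atg_count: int = 0

    @property
    def length_nt(self) -> int:
        return self.orf_end - self.orf_start


@dataclass
class ProteinEntry:
    """A unique protein sequence entry of a database."""

    accession: str
    gene: str
    sequence: str
    cpm: float = 0.0
    pclass: Optional[str] = None
    members: tuple[str, ...] = ()
    cds_elements: Optional[CdsElements] = None
    genomic_model: Optional[TranscriptModel] = None
    cds_transcript_start: Optional[int] = None  # transcript coord of first coding base

    def __post_init__(self) -> None:
        if not self.members:
            self.members = (self.accession,)


@dataclass(frozen=True)
class ProteinClassification:
    accession: str
    pclass: str  # pFSM | pISM | pNIC | pNNC | other
    subclass: str
    novel_elements: tuple[str, ...] = ()


@dataclass(frozen=True)
class GeneCategory:
    """Sample-vs-reference relationship of one gene's isoform repertoire."""

    gene_id: str
    category: str  # Match | Subset | Superset | PartialOverlap | Distinct
    n_sample: int
    n_reference: int
    n_shared: int
    n_novel: int


@dataclass
class PeptideProteinMap:
    """Bipartite association between identified peptides and database entries."""

    edges: dict[str, frozenset[str]]
    unmapped: frozenset[str] = frozenset()

    def proteins_to_peptides(self) -> dict[str, frozenset[str]]:
        inv: dict[str, set[str]] = {}
        for pep, accs in self.edges.items():
            for acc in accs:
                inv.setdefault(acc, set()).add(pep)
        return {acc: frozenset(peps) for acc, peps in inv.items()}

    @property
    def peptides(self) -> frozenset[str]:
        return frozenset(self.edges)


@dataclass
class ProteinGroup:
    """A protein inference result group."""

    members: tuple[str, ...]
    peptides: frozenset[str]
    status: str  # retained | rescued_case1 | rescued_case2
    resolution: str = "unresolved"
    abundance_fractions: Mapping[str, float] = field(default_factory=dict)

    @property
    def accession(self) -> str:
        return self.members[0]
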