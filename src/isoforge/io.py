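"""Readers and writers for GTF, FASTA, BED12 and the tabular inputs.

GTF is parsed directly (exon/CDS features only) so that malformed lines can be
reported by line number, which the pipeline's error contract requires.  FASTA
goes through Biopython, tables through pandas.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    GenomicInterval,
    IntegrityError,
    ProteinEntry,
    TranscriptModel,
)

log = logging.getLogger(__name__)

__all__ = [
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "write_protein_fasta",
    "read_protein_fasta",
    "read_abundance_table",
    "write_abundance_table",
    "read_peptides",
    "write_peptides",
    "read_coding_scores",
    "write_bed_tracks",
    "isoform_bed_rows",
    "peptide_bed_rows",
]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Malformed GTF content, reported with the offending line number."""


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if "gene_id" not in attrs or "transcript_id" not in attrs:
        raise GtfParseError(
            f"line {lineno}: attribute column lacks gene_id/transcript_id: "
            f"{attr_field!r}"
        )
    return attrs


def read_gtf(
    path: str | Path, feature_filter: Optional[set[str]] = None
) -> list[TranscriptModel]:
    """Read exon (and CDS) features from a GTF file into transcript models.

    Coordinates are converted from GTF's 1-based inclusive convention to the
    internal 0-based half-open one.  Exons are grouped per transcript and
    sorted by genomic start; CDS intervals are attached when present.
    """
    wanted = feature_filter if feature_filter is not None else {"exon", "CDS"}
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields
            if feature not in wanted:
                continue
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: {exc}") from exc
            attrs = _parse_attributes(attr, lineno)
            tid = attrs["transcript_id"]
            if tid not in genes:
                genes[tid] = attrs["gene_id"]
                order.append(tid)
            bucket = exons if feature == "exon" else cds
            bucket.setdefault(tid, []).append(iv)

    out = []
    for tid in order:
        if tid not in exons:
            log.warning("transcript %s has CDS but no exon features; skipped", tid)
            continue
        exs = sorted(exons[tid], key=lambda iv: iv.start)
        if len({(iv.chrom, iv.strand) for iv in exs}) > 1:
            raise IntegrityError(f"{tid}: exons on mixed chromosome/strand")
        cds_ivs = sorted(cds[tid], key=lambda iv: iv.start) if tid in cds else None
        out.append(
            TranscriptModel(
                transcript_id=tid, gene_id=genes[tid], exons=exs, cds=cds_ivs
            )
        )
    return out


def write_gtf(
    transcripts: Iterable[TranscriptModel], path: str | Path, source: str = "isoforge"
) -> None:
    """Write exon and CDS features, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            for feature, ivs in (("exon", tx.exons), ("CDS", tx.cds or [])):
                for iv in ivs:
                    fh.write(
                        "\t".join(
                            [
                                iv.chrom,
                                source,
                                feature,
                                str(iv.start + 1),
                                str(iv.end),
                                ".",
                                iv.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase-sequence mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_protein_fasta(entries: Sequence[ProteinEntry], path: str | Path) -> None:
    """Write protein entries with ``<gene>|<accession>|<class>|<CPM>`` headers.

    CPM is printed with one decimal place and sequences wrap at 60 characters.
    """
    with open(path, "w") as fh:
        for entry in entries:
            if not entry.sequence:
                raise ValueError(f"{entry.accession}: empty protein sequence")
            header = f">{entry.gene}|{entry.accession}|{entry.pclass}|{entry.cpm:.1f}"
            fh.write(header + "\n")
            for i in range(0, len(entry.sequence), 60):
                fh.write(entry.sequence[i : i + 60] + "\n")


def read_protein_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read a protein FASTA written in the 4-field pipe-delimited dialect."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        if len(parts) != 4:
            raise ValueError(
                f"{rec.id}: expected 4 pipe-delimited header fields, got "
                f"{rec.description!r}"
            )
        gene, accession, pclass, cpm = parts
        entries.append(
            ProteinEntry(
                accession=accession,
                gene=gene,
                sequence=str(rec.seq),
                pclass=pclass,
                cpm=float(cpm),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_abundance_table(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    for col in ("transcript_id", "flnc_count"):
        if col not in df.columns:
            raise ValueError(f"abundance table lacks required column {col!r}")
    return dict(zip(df["transcript_id"], df["flnc_count"].astype(int)))


def write_abundance_table(counts: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"transcript_id": list(counts), "flnc_count": list(counts.values())}
    ).to_csv(path, sep="\t", index=False)


def read_polya_table(path: str | Path) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t")
    for col in ("transcript_id", "polya"):
        if col not in df.columns:
            raise ValueError(f"polyA table lacks required column {col!r}")
    truthy = {"true", "1", "yes"}
    return {
        tid: str(v).strip().lower() in truthy
        for tid, v in zip(df["transcript_id"], df["polya"])
    }


def write_polya_table(flags: Mapping[str, bool], path: str | Path) -> None:
    pd.DataFrame(
        {"transcript_id": list(flags), "polya": list(flags.values())}
    ).to_csv(path, sep="\t", index=False)


def read_peptides(path: str | Path) -> list[str]:
    """Read post-FDR peptide identifications (column ``sequence``).

    Modified and unmodified forms of a base sequence are distinct
    identifications; when a ``modifications`` column is present the peptide is
    keyed as ``sequence[modifications]``.
    """
    df = pd.read_csv(path, sep="\t")
    if "sequence" not in df.columns:
        raise ValueError("peptide table lacks required column 'sequence'")
    if "modifications" in df.columns:
        mods = df["modifications"].fillna("")
        return [
            s if not m else f"{s}[{m}]" for s, m in zip(df["sequence"], mods)
        ]
    return list(df["sequence"])


def write_peptides(peptides: Iterable[str], path: str | Path) -> None:
    pd.DataFrame({"sequence": list(peptides)}).to_csv(path, sep="\t", index=False)


def read_coding_scores(path: str | Path) -> dict[tuple[str, int], float]:
    """Read a CPAT-style coding-score table keyed by (transcript, orf_start)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("transcript_id", "orf_start", "coding_score"):
        if col not in df.columns:
            raise ValueError(f"coding score table lacks required column {col!r}")
    return {
        (tid, int(start)): float(score)
        for tid, start, score in zip(
            df["transcript_id"], df["orf_start"], df["coding_score"]
        )
    }


# ---------------------------------------------------------------------------
# BED12 genome-browser tracks
# ---------------------------------------------------------------------------

def _bed12_line(
    name: str,
    blocks: Sequence[GenomicInterval],
    thick: Optional[tuple[int, int]] = None,
) -> str:
    blocks = sorted(blocks, key=lambda iv: iv.start)
    chrom = blocks[0].chrom
    strand = blocks[0].strand
    chrom_start = blocks[0].start
    chrom_end = blocks[-1].end
    if thick is None:
        thick = (chrom_start, chrom_start)  # no thick region
    sizes = ",".join(str(iv.length) for iv in blocks)
    starts = ",".join(str(iv.start - chrom_start) for iv in blocks)
    return "\t".join(
        [
            chrom,
            str(chrom_start),
            str(chrom_end),
            name,
            "0",
            strand,
            str(thick[0]),
            str(thick[1]),
            "0",
            str(len(blocks)),
            sizes,
            starts,
        ]
    )


def isoform_bed_rows(entries: Sequence[ProteinEntry]) -> list[str]:
    """BED12 rows for database entries; thickStart/thickEnd mark the CDS."""
    rows = []
    for entry in entries:
        tx = entry.genomic_model
        if tx is None:
            log.warning("%s: no genomic model; skipped from BED track", entry.accession)
            continue
        thick = None
        if tx.cds:
            thick = (min(iv.start for iv in tx.cds), max(iv.end for iv in tx.cds))
        rows.append(_bed12_line(entry.accession, tx.exons, thick))
    return rows


def peptide_bed_rows(
    peptides: Iterable[str], entries: Sequence[ProteinEntry]
) -> list[str]:
    """BED12 rows mapping peptide AA spans back to genomic blocks."""
    rows = []
    by_acc = {e.accession: e for e in entries}
    for pep in peptides:
        for entry in by_acc.values():
            if entry.genomic_model is None or entry.cds_transcript_start is None:
                continue
            aa_pos = entry.sequence.find(pep)
            if aa_pos < 0:
                continue
            t0 = entry.cds_transcript_start + 3 * aa_pos
            t1 = t0 + 3 * len(pep)
            blocks = entry.genomic_model.to_genomic_intervals(t0, t1)
            rows.append(_bed12_line(f"{pep}|{entry.accession}", blocks))
    return rows


def write_bed_tracks(rows: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write(row + "\n")
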