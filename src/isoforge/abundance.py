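"""Transcript abundance (CPM) computation and transcript-level artifact filters."""

from __future__ import annotations

import logging
from typing import Mapping

from .config import FilterConfig
from .model import AbundanceRecord, TranscriptModel

log = logging.getLogger(__name__)

__all__ = ["compute_cpm", "filter_min_cpm", "intrapriming_flag"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def compute_cpm(counts: Mapping[str, int]) -> list[AbundanceRecord]:
    """Full-length counts per million over the whole input transcript table.

    cpm = flnc_count / total_reads * 1e6.  The denominator is the total FLNC
    read count of the (post-clustering) input table, before any filtering.
    """
    for tid, n in counts.items():
        if n < 0:
            raise ValueError(f"{tid}: negative FLNC count {n}")
    total = sum(counts.values())
    if total == 0:
        raise ZeroDivisionError(
            "cannot compute CPM: total FLNC read count is zero"
        )
    return [
        AbundanceRecord(tid, n, n / total * 1_000_000.0) for tid, n in counts.items()
    ]


def filter_min_cpm(
    records: list[AbundanceRecord], threshold: float = 1.0
) -> set[str]:
    """Transcripts retained for further analysis: strictly above ``threshold`` CPM."""
    if threshold < 0:
        raise ValueError(f"CPM threshold must be non-negative, got {threshold}")
    return {rec.transcript_id for rec in records if rec.cpm > threshold}


def intrapriming_flag(
    transcript: TranscriptModel,
    genome: Mapping[str, str],
    window: int = 20,
    frac: float = 0.95,
) -> bool:
    """Flag a suspected oligo-dT intrapriming artifact.

    True iff the adenosine fraction in the ``window`` nt of genome immediately
    downstream of the aligned 3' end is >= ``frac``.  On the minus strand the
    downstream window lies genomically leftward and genomic T is read as A.
    Windows truncated at a chromosome end are evaluated over the available
    bases (with a logged warning); an empty window never flags.
    """
    if transcript.chrom not in genome:
        raise KeyError(f"chromosome {transcript.chrom!r} absent from genome")
    chrom_seq = genome[transcript.chrom].upper()
    end = transcript.three_prime_end
    if transcript.strand == "+":
        lo, hi = end + 1, end + 1 + window
        seq = chrom_seq[lo : min(hi, len(chrom_seq))]
        target = "A"
    else:
        lo, hi = end - window, end
        seq = chrom_seq[max(lo, 0) : hi]
        target = "T"  # genomic complement of transcribed A
    if len(seq) < window:
        log.warning(
            "%s: intrapriming window truncated to %d nt at chromosome end",
            transcript.transcript_id,
            len(seq),
        )
    if not seq:
        return False
    return seq.count(target) / len(seq) >= frac
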