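"""ORF enumeration, ranking and selection for full-length transcripts.

Every ATG-initiated reading frame of at least ``min_orf_len_nt`` nucleotides is
a candidate; candidates ending without an in-frame stop are retained to the
transcript end and flagged 3'-incomplete.  Selection applies two rules:

1. Any candidate whose ATG matches a reference-annotated translation start of
   the gene is preferred in all cases; among several such candidates the
   upstream-most is taken.
2. Otherwise the candidate maximising
   ``coding_score * upstream_atg_penalty ** upstream_atg_count`` wins, which
   weights ORFs whose start codon sits closer to the transcript 5' end.  Ties
   break by upstream-most start, then longest ORF, then lexicographic protein
   sequence, so selection is total and deterministic.

Transcripts yielding identical proteins within a gene are collapsed into one
database entry whose base accession is the alphanumerically (byte-order)
smallest member and whose abundance is the summed member CPM.
"""

from __future__ import annotations

import bisect
import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .config import OrfCallConfig
from .model import CandidateORF, ProteinEntry, TranscriptModel

log = logging.getLogger(__name__)

__all__ = [
    "NoOrfError",
    "enumerate_candidate_orfs",
    "assign_fallback_coding_score",
    "annotate_candidates",
    "final_score",
    "call_best_orf",
    "call_orfs",
    "refine_orf_database",
]

_VALID_NT = set("ACGTN")
_STOPS = {"TAA", "TAG", "TGA"}


class NoOrfError(ValueError):
    """Signals a transcript with no candidate ORF (treated as non-coding)."""


def translate_orf(nt: str) -> str:
    """Translate from an ORF start, ending at the first in-frame stop (if any)."""
    aa = str(Seq(nt[: len(nt) // 3 * 3]).translate())
    return aa.split("*", 1)[0]


def enumerate_candidate_orfs(
    sequence: str,
    config: Optional[OrfCallConfig] = None,
    transcript_id: str = "",
) -> list[CandidateORF]:
    """All ATG-initiated candidate ORFs of a transcript sequence.

    Candidates end at the first in-frame stop (inclusive) or, lacking one, at
    the transcript end.  At most ``max_candidates`` are kept, ordered by
    descending length then 5'-most start.  ``upstream_atg_count`` counts ATG
    occurrences (any frame) strictly 5' of the candidate start.
    """
    config = config or OrfCallConfig()
    seq = sequence.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"sequence contains non-IUPAC characters: {sorted(bad)}")

    atg_positions: list[int] = []
    i = seq.find("ATG")
    while i != -1:
        atg_positions.append(i)
        i = seq.find("ATG", i + 1)

    stops_by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for p in range(len(seq) - 2):
        if seq[p : p + 3] in _STOPS:
            stops_by_frame[p % 3].append(p)

    candidates = []
    for idx, start in enumerate(atg_positions):
        stops = stops_by_frame[start % 3]
        j = bisect.bisect_left(stops, start)
        if j < len(stops):
            end = stops[j] + 3
            has_stop = True
        else:
            end = len(seq)
            has_stop = False
        if end - start < config.min_orf_len_nt:
            continue
        candidates.append(
            CandidateORF(
                transcript_id=transcript_id,
                orf_start=start,
                orf_end=end,
                aa_sequence=translate_orf(seq[start:end]),
                has_stop=has_stop,
                upstream_atg_count=idx,
            )
        )
    candidates.sort(key=lambda c: (-c.length_nt, c.orf_start))
    return candidates[: config.max_candidates]


def assign_fallback_coding_score(
    candidate: CandidateORF, transcript_length: int
) -> float:
    """Deterministic stand-in coding score used when no score table is given.

    A saturating function of the ORF's length fraction of the transcript:
    ``tanh(3 * fraction)``, which is 0 for a zero-length ORF, strictly
    increasing, and approaches 1 for an ORF spanning the whole transcript.
    """
    if transcript_length <= 0:
        raise ValueError("transcript length must be positive")
    frac = candidate.length_nt / transcript_length
    return math.tanh(3.0 * frac)


def annotate_candidates(
    candidates: Sequence[CandidateORF],
    transcript: TranscriptModel,
    known_starts: Optional[set[int]] = None,
    reference_proteins: Optional[set[str]] = None,
) -> None:
    """Fill genomic-annotation context on candidates, in place.

    ``has_annotated_start`` is true when the genomic position of the candidate
    ATG matches a reference-annotated translation start of the gene;
    ``matches_reference_protein`` when the translated product equals a
    reference protein of the gene.
    """
    for cand in candidates:
        if known_starts is not None:
            cand.has_annotated_start = (
                transcript.genomic_position(cand.orf_start) in known_starts
            )
        if reference_proteins is not None:
            cand.matches_reference_protein = cand.aa_sequence in reference_proteins


def final_score(candidate: CandidateORF, config: OrfCallConfig) -> float:
    return candidate.coding_score * config.upstream_atg_penalty ** candidate.upstream_atg_count


def call_best_orf(
    candidates: Sequence[CandidateORF], config: Optional[OrfCallConfig] = None
) -> CandidateORF:
    """Select the single most plausible ORF among the candidates."""
    config = config or OrfCallConfig()
    if not candidates:
        raise NoOrfError("no candidate ORFs: transcript is treated as non-coding")
    if config.annotated_start_override:
        annotated = [c for c in candidates if c.has_annotated_start]
        if annotated:
            return min(
                annotated,
                key=lambda c: (c.orf_start, -c.length_nt, c.aa_sequence),
            )
    return min(
        candidates,
        key=lambda c: (
            -final_score(c, config),
            c.orf_start,
            -c.length_nt,
            c.aa_sequence,
        ),
    )


def call_orfs(
    transcripts: Iterable[TranscriptModel],
    known_starts_by_gene: Optional[Mapping[str, set[int]]] = None,
    reference_proteins_by_gene: Optional[Mapping[str, set[str]]] = None,
    coding_scores: Optional[Mapping[tuple[str, int], float]] = None,
    config: Optional[OrfCallConfig] = None,
) -> dict[str, CandidateORF]:
    """Call one ORF per coding transcript; non-coding transcripts are omitted.

    External coding scores, when supplied, override the internal fallback per
    (transcript, orf_start).
    """
    config = config or OrfCallConfig()
    called: dict[str, CandidateORF] = {}
    for tx in transcripts:
        if tx.sequence is None:
            raise ValueError(f"{tx.transcript_id}: transcript sequence required")
        cands = enumerate_candidate_orfs(tx.sequence, config, tx.transcript_id)
        if not cands:
            log.info("%s: no candidate ORF; excluded as non-coding", tx.transcript_id)
            continue
        for cand in cands:
            external = None
            if coding_scores is not None:
                external = coding_scores.get((tx.transcript_id, cand.orf_start))
            cand.coding_score = (
                external
                if external is not None
                else assign_fallback_coding_score(cand, tx.exonic_length)
            )
        known_starts = (
            known_starts_by_gene.get(tx.gene_id) if known_starts_by_gene else None
        )
        ref_prot = (
            reference_proteins_by_gene.get(tx.gene_id)
            if reference_proteins_by_gene
            else None
        )
        annotate_candidates(cands, tx, known_starts, ref_prot)
        called[tx.transcript_id] = call_best_orf(cands, config)
    return called


def refine_orf_database(
    called: Mapping[str, tuple[str, float, str]],
    config: Optional[OrfCallConfig] = None,
) -> list[ProteinEntry]:
    """Collapse transcripts with identical protein products into unique entries.

    ``called`` maps transcript_id -> (aa_sequence, cpm, gene).  Grouping is
    within gene; the base accession is the smallest member transcript_id under
    plain lexicographic byte order (so ``PB.1.10 < PB.1.2``; a natural-order
    sort is available via ``config.natural_sort``), and the entry CPM is the
    sum over member CPMs.
    """
    config = config or OrfCallConfig()

    def sort_key(acc: str):
        if not config.natural_sort:
            return acc
        import re

        return tuple(
            int(part) if part.isdigit() else part
            for part in re.split(r"(\d+)", acc)
        )

    groups: dict[tuple[str, str], list[str]] = {}
    for tid, (aa, _cpm, gene) in called.items():
        groups.setdefault((gene, aa), []).append(tid)

    seq_genes: dict[str, set[str]] = {}
    for gene, aa in groups:
        seq_genes.setdefault(aa, set()).add(gene)
    for aa, genes in seq_genes.items():
        if len(genes) > 1:
            log.info(
                "identical protein sequence under multiple genes %s; kept as "
                "separate entries",
                sorted(genes),
            )

    entries = []
    for (gene, aa), members in groups.items():
        members = sorted(members, key=sort_key)
        entries.append(
            ProteinEntry(
                accession=members[0],
                gene=gene,
                sequence=aa,
                cpm=sum(called[m][1] for m in members),
                members=tuple(members),
            )
        )
    entries.sort(key=lambda e: e.accession)
    return entries
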