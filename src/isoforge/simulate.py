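"""Deterministic synthetic gene loci with known classification ground truth.

Each locus is a six-exon gene built in "locus space" (transcript orientation);
for minus-strand genes the genome holds the reverse complement and all
intervals are mirrored.  Sequence composition is constrained so that ORF
ground truth is unambiguous:

* UTRs and introns are drawn from {C, G, T}, so no adenosine — and hence no
  ATG and no stop codon — can occur outside the coding frame by accident.
* The coding body is built from {C, G, T} codons (amino acids P, R, L, A, G,
  V, S, C, W, F), which contain no stop and no ATG; translation-start codons
  are inserted deliberately at known positions (the primary start in exon 2,
  an annotated alternative start in exon 3, and a never-annotated internal
  start in exon 5), each preceded by an arginine codon so that suffix proteins
  digest to exact peptide subsets of the full protein.

Named perturbation recipes then force each sample isoform's transcript- and
protein-level class by construction (e.g. a novel donor forces NNC/pNNC; a
recombination of the annotated alternative start with the annotated exon-skip
junction forces pNIC; 5' truncation past all annotated starts forces pISM).

All randomness flows from a single seed, so repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import InferenceConfig
from .inference import digest
from .model import GenomicInterval, ProteinEntry, TranscriptModel
from .orfs import translate_orf

__all__ = [
    "SpecError",
    "LocusSpec",
    "TruthRecord",
    "SyntheticLocus",
    "generate_locus",
    "generate_abundances",
    "generate_peptide_observations",
    "build_case1_peptides",
    "build_case2_peptides",
    "build_case3_peptides",
    "RECIPES",
    "FILLER_TRANSCRIPT_ID",
]

_SAFE_NT = "CGT"
_SAFE_CODONS = [a + b + c for a in _SAFE_NT for b in _SAFE_NT for c in _SAFE_NT]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: background pseudo-transcript absorbing the rest of the sequencing library,
#: so that synthetic CPM values equal their intended targets exactly
FILLER_TRANSCRIPT_ID = "PB.0.0"

RECIPES = (
    "match",
    "skip-annotated",
    "alt-start",
    "utr-truncate",
    "skip-novel",
    "novel-donor",
    "retain-intron",
    "alt-start-skip",
    "truncate-5prime",
    "intraprime",
    "noncoding",
)


class SpecError(ValueError):
    """A locus spec or scenario that cannot be realised."""


@dataclass
class LocusSpec:
    """Parameters of one synthetic gene locus."""

    gene_id: str
    seed: int
    gene_index: int = 1  # numeric index used in PB.<gene>.<n> accessions
    chrom: str = "chr1"
    strand: str = "+"
    n_reference_isoforms: int = 3  # 1=full, 2=+exon-skip, 3=+alt-start
    sample_perturbations: tuple[str, ...] = ("match",)
    exon_codon_range: tuple[int, int] = (60, 90)  # codons per coding exon
    utr5_len_range: tuple[int, int] = (80, 140)
    utr3_len_range: tuple[int, int] = (30, 45)
    intron_codon_range: tuple[int, int] = (30, 50)
    flank_len: int = 200

    def __post_init__(self) -> None:
        if not 1 <= self.n_reference_isoforms <= 3:
            raise SpecError("n_reference_isoforms must be 1..3")
        unknown = set(self.sample_perturbations) - set(RECIPES)
        if unknown:
            raise SpecError(f"unknown perturbations: {sorted(unknown)}")
        needs_ref2 = {"skip-annotated", "alt-start-skip"}
        needs_ref3 = {"alt-start", "alt-start-skip"}
        if needs_ref2 & set(self.sample_perturbations) and self.n_reference_isoforms < 2:
            raise SpecError("exon-skip recipes need the skip reference isoform")
        if needs_ref3 & set(self.sample_perturbations) and self.n_reference_isoforms < 3:
            raise SpecError("alt-start recipes need the alt-start reference isoform")


@dataclass(frozen=True)
class TruthRecord:
    """Intended classes and outcomes for one generated isoform."""

    transcript_id: str
    gene_id: str
    recipe: str
    transcript_class: str
    protein_class: str
    aa_sequence: str  # "" for non-coding isoforms
    intraprime: bool = False


@dataclass
class SyntheticLocus:
    spec: LocusSpec
    chrom: str
    strand: str
    genome_sequence: str
    reference_transcripts: list[TranscriptModel]
    sample_transcripts: list[TranscriptModel]
    truth: dict[str, TruthRecord]
    reference_proteins: list[tuple[str, str, str]]  # (gene, accession, aa)


# ---------------------------------------------------------------------------
# locus construction
# ---------------------------------------------------------------------------


def _rand_seq(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _rand_codons(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_SAFE_CODONS, size=n))


@dataclass
class _Skeleton:
    """Locus-space layout shared by all isoforms of one gene."""

    exons: list[tuple[int, int]]  # six locus-space intervals
    locus_seq: str  # including flanks
    atg1: int  # primary annotated start (exon 2)
    atg2: int  # annotated alternative start (exon 3)
    atg3: int  # never-annotated internal start (exon 5)
    stop_start: int  # locus position of the stop codon
    intraprime_ext: int  # nt by which the intraprime recipe extends exon 6


def _build_skeleton(spec: LocusSpec, rng: np.random.Generator) -> _Skeleton:
    lo, hi = spec.exon_codon_range
    m = [int(rng.integers(lo, hi + 1)) for _ in range(5)]  # codons in exons 2..6
    u5 = int(rng.integers(*spec.utr5_len_range))
    u2 = int(rng.integers(9, 30))  # UTR stub at the 5' end of exon 2
    u3 = int(rng.integers(*spec.utr3_len_range))
    ilen = [3 * int(rng.integers(*spec.intron_codon_range)) for _ in range(5)]

    # codon-level layout of the coding body (exons 2..6)
    codons2 = ["ATG"] + _rand_codons(rng, m[0] - 1)
    codons3 = _rand_codons(rng, m[1])
    k3 = int(rng.integers(3, m[1] - 4))
    codons3[k3 - 1], codons3[k3] = "CGT", "ATG"  # R before the alt start
    codons4 = _rand_codons(rng, m[2])
    codons5 = _rand_codons(rng, m[3])
    k5 = int(rng.integers(4, m[3] - 5))
    codons5[k5 - 1], codons5[k5] = "CGT", "ATG"  # R before the internal start
    codons6 = _rand_codons(rng, m[4])

    exon_seqs = [
        _rand_seq(rng, _SAFE_NT, u5),
        _rand_seq(rng, _SAFE_NT, u2) + "".join(codons2),
        "".join(codons3),
        "".join(codons4),
        "".join(codons5),
        "".join(codons6) + "TAA" + "C" + _rand_seq(rng, _SAFE_NT, u3),
    ]
    introns = [_rand_seq(rng, _SAFE_NT, n) for n in ilen]
    flank5 = _rand_seq(rng, "ACGT", spec.flank_len)
    intraprime_ext = 30
    # 3' flank: a C-initiated spacer (so the normal 3' end never looks
    # intraprimed), then a 20 nt A-run placed right after the extended 3' end
    # used by the intraprime recipe.
    flank3 = (
        "C"
        + _rand_seq(rng, _SAFE_NT, intraprime_ext - 1)
        + "A" * 20
        + _rand_seq(rng, "ACGT", spec.flank_len - intraprime_ext - 20)
    )

    pieces = [flank5]
    exons: list[tuple[int, int]] = []
    pos = len(flank5)
    for i, seq in enumerate(exon_seqs):
        exons.append((pos, pos + len(seq)))
        pieces.append(seq)
        pos += len(seq)
        if i < 5:
            pieces.append(introns[i])
            pos += len(introns[i])
    pieces.append(flank3)
    locus_seq = "".join(pieces)

    atg1 = exons[1][0] + u2
    atg2 = exons[2][0] + 3 * k3
    atg3 = exons[4][0] + 3 * k5
    stop_start = exons[5][0] + 3 * m[4]
    return _Skeleton(exons, locus_seq, atg1, atg2, atg3, stop_start, intraprime_ext)


def _splice(locus_seq: str, intervals: Sequence[tuple[int, int]]) -> str:
    return "".join(locus_seq[s:e] for s, e in intervals)


def _locus_to_transcript_coord(
    intervals: Sequence[tuple[int, int]], locus_pos: int
) -> int:
    t = 0
    for s, e in intervals:
        if s <= locus_pos < e:
            return t + (locus_pos - s)
        t += e - s
    raise SpecError(f"locus position {locus_pos} not exonic")


def _reference_layouts(sk: _Skeleton, n: int) -> list[tuple[str, list[tuple[int, int]], int]]:
    """(name suffix, exon intervals, cds start locus pos) for reference isoforms."""
    E = sk.exons
    layouts = [("201", list(E), sk.atg1)]
    if n >= 2:
        layouts.append(("202", [E[0], E[1], E[2], E[4], E[5]], sk.atg1))
    if n >= 3:
        layouts.append(("203", [(sk.atg2, E[2][1]), E[3], E[4], E[5]], sk.atg2))
    return layouts


def _recipe_layout(
    recipe: str, sk: _Skeleton
) -> tuple[list[tuple[int, int]], str, str, Optional[int], bool]:
    """exons, transcript class, protein class, intended start, intraprime flag."""
    E = sk.exons
    if recipe == "match":
        return list(E), "FSM", "pFSM", sk.atg1, False
    if recipe == "skip-annotated":
        return [E[0], E[1], E[2], E[4], E[5]], "FSM", "pFSM", sk.atg1, False
    if recipe == "alt-start":
        return [(sk.atg2, E[2][1]), E[3], E[4], E[5]], "FSM", "pFSM", sk.atg2, False
    if recipe == "utr-truncate":
        return [E[1], E[2], E[3], E[4], E[5]], "ISM", "pFSM", sk.atg1, False
    if recipe == "skip-novel":
        return [E[0], E[1], E[2], E[3], E[5]], "NNC", "pNNC", sk.atg1, False
    if recipe == "novel-donor":
        ext = (E[1][0], E[1][1] + 6)  # donor pushed 6 nt into the intron
        return [E[0], ext, E[2], E[3], E[4], E[5]], "NNC", "pNNC", sk.atg1, False
    if recipe == "retain-intron":
        merged = (E[3][0], E[4][1])
        return [E[0], E[1], E[2], merged, E[5]], "NIC", "pNIC", sk.atg1, False
    if recipe == "alt-start-skip":
        return [(sk.atg2, E[2][1]), E[4], E[5]], "ISM", "pNIC", sk.atg2, False
    if recipe == "truncate-5prime":
        return [(sk.atg3 - 9, E[4][1]), E[5]], "ISM", "pISM", sk.atg3, False
    if recipe == "intraprime":
        ext = (E[5][0], E[5][1] + sk.intraprime_ext)
        return [E[0], E[1], E[2], E[3], E[4], ext], "FSM", "pFSM", sk.atg1, True
    if recipe == "noncoding":
        return [E[0]], "NIC", "other", None, False
    raise SpecError(f"unknown recipe {recipe!r}")


def _mirror_intervals(
    intervals: Sequence[tuple[int, int]], total_len: int
) -> list[tuple[int, int]]:
    return sorted((total_len - e, total_len - s) for s, e in intervals)


def _make_transcript(
    tid: str,
    gene: str,
    locus_exons: Sequence[tuple[int, int]],
    sk: _Skeleton,
    spec: LocusSpec,
    cds_span: Optional[tuple[int, int]] = None,
) -> TranscriptModel:
    seq = _splice(sk.locus_seq, locus_exons)
    L = len(sk.locus_seq)
    if spec.strand == "+":
        exon_ivs = [
            GenomicInterval(spec.chrom, s, e, "+") for s, e in locus_exons
        ]
    else:
        exon_ivs = [
            GenomicInterval(spec.chrom, s, e, "-")
            for s, e in _mirror_intervals(locus_exons, L)
        ]
    cds_ivs = None
    if cds_span is not None:
        s0, e0 = cds_span
        pieces = [
            (max(s, s0), min(e, e0))
            for s, e in locus_exons
            if max(s, s0) < min(e, e0)
        ]
        if spec.strand == "-":
            pieces = _mirror_intervals(pieces, L)
        cds_ivs = [GenomicInterval(spec.chrom, s, e, spec.strand) for s, e in pieces]
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, exons=exon_ivs, cds=cds_ivs, sequence=seq
    )


def generate_locus(spec: LocusSpec) -> SyntheticLocus:
    """Build one synthetic locus with reference and sample isoforms."""
    rng = np.random.default_rng(spec.seed)
    sk = _build_skeleton(spec, rng)
    L = len(sk.locus_seq)
    genome = (
        sk.locus_seq
        if spec.strand == "+"
        else sk.locus_seq.translate(_COMPLEMENT)[::-1]
    )

    reference_transcripts = []
    reference_proteins = []
    for suffix, exons, cds_start in _reference_layouts(
        sk, spec.n_reference_isoforms
    ):
        tid = f"{spec.gene_id}-{suffix}"
        tx = _make_transcript(
            tid, spec.gene_id, exons, sk, spec, cds_span=(cds_start, sk.stop_start + 3)
        )
        reference_transcripts.append(tx)
        t0 = _locus_to_transcript_coord(exons, cds_start)
        reference_proteins.append(
            (spec.gene_id, tid, translate_orf(tx.sequence[t0:]))
        )

    sample_transcripts = []
    truth: dict[str, TruthRecord] = {}
    for i, recipe in enumerate(spec.sample_perturbations, start=1):
        exons, tclass, pclass, start, intraprime = _recipe_layout(recipe, sk)
        tid = f"PB.{spec.gene_index}.{i}"
        tx = _make_transcript(tid, spec.gene_id, exons, sk, spec)
        if start is not None:
            t0 = _locus_to_transcript_coord(exons, start)
            aa = translate_orf(tx.sequence[t0:])
        else:
            aa = ""
        sample_transcripts.append(tx)
        truth[tid] = TruthRecord(
            transcript_id=tid,
            gene_id=spec.gene_id,
            recipe=recipe,
            transcript_class=tclass,
            protein_class=pclass,
            aa_sequence=aa,
            intraprime=intraprime,
        )
    return SyntheticLocus(
        spec=spec,
        chrom=spec.chrom,
        strand=spec.strand,
        genome_sequence=genome,
        reference_transcripts=reference_transcripts,
        sample_transcripts=sample_transcripts,
        truth=truth,
        reference_proteins=reference_proteins,
    )


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------


def generate_abundances(
    transcript_ids: Sequence[str],
    seed: int,
    forced_cpm: Optional[Mapping[str, float]] = None,
    total_reads: int = 1_000_000,
    cpm_log10_range: tuple[float, float] = (0.3, 2.7),
) -> dict[str, int]:
    """FLNC counts realising log-uniform CPM targets, plus a filler background.

    With the default library size of one million reads, a transcript's CPM
    equals its read count exactly; ``forced_cpm`` pins designated isoforms to
    chosen abundances (e.g. above/below the rescue threshold, or to exact
    within-group ratios for resolve scenarios).
    """
    rng = np.random.default_rng(seed)
    forced = dict(forced_cpm or {})
    counts: dict[str, int] = {}
    for tid in transcript_ids:
        target = forced.get(
            tid, float(10 ** rng.uniform(*cpm_log10_range))
        )
        counts[tid] = max(1, round(target * total_reads / 1_000_000))
    used = sum(counts.values())
    if used > total_reads:
        raise SpecError(
            f"CPM targets exceed the library size ({used} > {total_reads})"
        )
    counts[FILLER_TRANSCRIPT_ID] = total_reads - used
    return counts


# ---------------------------------------------------------------------------
# peptide observations
# ---------------------------------------------------------------------------


def generate_peptide_observations(
    entries: Sequence[ProteinEntry],
    detection_prob: float,
    seed: int,
    config: Optional[InferenceConfig] = None,
) -> list[str]:
    """Sample each digest peptide of the database independently."""
    config = config or InferenceConfig()
    rng = np.random.default_rng(seed)
    universe = sorted({p for e in entries for p in digest(e.sequence, config)})
    return [p for p in universe if rng.random() < detection_prob]


def build_case1_peptides(
    major: ProteinEntry, minor: ProteinEntry, config: Optional[InferenceConfig] = None
) -> list[str]:
    """Peptides making ``minor``'s mapped set a strict subset of ``major``'s."""
    config = config or InferenceConfig()
    d_major = digest(major.sequence, config)
    d_minor = digest(minor.sequence, config)
    shared = d_major & d_minor
    unique = d_major - d_minor
    if not shared or not unique:
        raise SpecError(
            "case 1 unsatisfiable: need shared peptides plus a peptide unique "
            "to the major isoform"
        )
    return sorted(shared | {min(unique)})


def build_case2_peptides(
    p1: ProteinEntry,
    p2: ProteinEntry,
    p3: ProteinEntry,
    config: Optional[InferenceConfig] = None,
) -> list[str]:
    """Peptides making ``p3`` subsumable by ``p1`` and ``p2``.

    Emits one peptide shared p3/p1 only, one shared p3/p2 only, and one unique
    to each of p1 and p2 (their additional evidence).
    """
    config = config or InferenceConfig()
    d1, d2, d3 = (digest(p.sequence, config) for p in (p1, p2, p3))
    pools = [d3 & d1 - d2, d3 & d2 - d1, d1 - d2 - d3, d2 - d1 - d3]
    if not all(pools):
        raise SpecError("case 2 unsatisfiable for these digest topologies")
    return sorted(min(pool) for pool in pools)


def build_case3_peptides(
    a: ProteinEntry, b: ProteinEntry, config: Optional[InferenceConfig] = None
) -> list[str]:
    """Peptides under which ``a`` and ``b`` are indistinguishable."""
    config = config or InferenceConfig()
    shared = digest(a.sequence, config) & digest(b.sequence, config)
    if not shared:
        raise SpecError("case 3 unsatisfiable: isoforms share no digest peptide")
    return sorted(shared)
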