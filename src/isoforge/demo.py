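"""The bundled three-gene demo scenario.

Three compact loci exercise every stage: classification classes on both
strands, identical-protein grouping, intrapriming and non-coding exclusion,
a case-1 rescue pair (full protein vs its alternative-start suffix), a case-3
ambiguous pair resolved 95:5, and a retained intron whose translation yields
peptides absent from the reference database.

Synthetic loci are compact (~0.25-1.7 kb isoforms), so the demo *config file*
scales the high-confidence length window down to 0.2-4.0 kb while every other
threshold keeps its library default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional

from . import io
from .config import InferenceConfig, PipelineConfig
from .model import ProteinEntry
from .simulate import (
    FILLER_TRANSCRIPT_ID,
    LocusSpec,
    SyntheticLocus,
    build_case1_peptides,
    build_case3_peptides,
    generate_abundances,
    generate_locus,
)
from .inference import digest

__all__ = ["demo_specs", "demo_forced_cpm", "demo_config", "write_demo_bundle"]

DEFAULT_DEMO_SEED = 7


def demo_specs(seed: int = DEFAULT_DEMO_SEED) -> list[LocusSpec]:
    common = dict(utr5_len_range=(210, 260))
    return [
        LocusSpec(
            gene_id="GENA",
            gene_index=1,
            seed=seed * 100 + 1,
            chrom="chr1",
            strand="+",
            n_reference_isoforms=2,
            sample_perturbations=(
                "match",
                "utr-truncate",
                "skip-novel",
                "retain-intron",
                "intraprime",
            ),
            **common,
        ),
        LocusSpec(
            gene_id="GENB",
            gene_index=2,
            seed=seed * 100 + 2,
            chrom="chr2",
            strand="-",
            n_reference_isoforms=3,
            sample_perturbations=(
                "match",
                "skip-annotated",
                "alt-start-skip",
                "truncate-5prime",
                "noncoding",
            ),
            **common,
        ),
        LocusSpec(
            gene_id="GENC",
            gene_index=3,
            seed=seed * 100 + 3,
            chrom="chr3",
            strand="+",
            n_reference_isoforms=3,
            sample_perturbations=("match", "alt-start", "skip-novel"),
            **common,
        ),
    ]


def demo_forced_cpm() -> dict[str, float]:
    """Designed abundances driving the rescue/resolve outcomes."""
    return {
        # GENA: abundant canonical pair, low-abundance novel skip, expressed
        # retained intron, intraprimed artifact
        "PB.1.1": 300.0,
        "PB.1.2": 40.0,
        "PB.1.3": 4.0,
        "PB.1.4": 80.0,
        "PB.1.5": 30.0,
        # GENB: 95:5 ambiguous pair (case 3), rescued alt-start-skip isoform,
        # degraded and non-coding isoforms
        "PB.2.1": 95.0,
        "PB.2.2": 5.0,
        "PB.2.3": 60.0,
        "PB.2.4": 10.0,
        "PB.2.5": 8.0,
        # GENC: canonical isoform, rescuable alt-start suffix, low novel skip
        "PB.3.1": 120.0,
        "PB.3.2": 50.0,
        "PB.3.3": 4.0,
    }


def demo_config() -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.high_confidence.min_len_kb = 0.2
    return cfg


def _truth_entry(locus: SyntheticLocus, recipe: str) -> ProteinEntry:
    for tid, rec in locus.truth.items():
        if rec.recipe == recipe:
            return ProteinEntry(
                accession=tid, gene=rec.gene_id, sequence=rec.aa_sequence
            )
    raise KeyError(recipe)


def demo_peptides(
    loci: Mapping[str, SyntheticLocus],
    config: Optional[InferenceConfig] = None,
) -> list[str]:
    """Deterministic peptide observations realising the demo scenarios."""
    config = config or InferenceConfig()
    gena, genb, genc = loci["GENA"], loci["GENB"], loci["GENC"]
    peptides: set[str] = set()
    # GENA: full coverage of the canonical protein and the retained-intron
    # protein -> both retained; intron-derived peptides are novel.
    peptides |= digest(_truth_entry(gena, "match").sequence, config)
    peptides |= digest(_truth_entry(gena, "retain-intron").sequence, config)
    # GENB: shared-only coverage makes the canonical and exon-skip proteins an
    # indistinguishable (case 3) pair; the alt-start-skip suffix is subsumed.
    peptides |= set(
        build_case3_peptides(
            _truth_entry(genb, "match"), _truth_entry(genb, "skip-annotated"), config
        )
    )
    # GENC: canonical protein fully covered; its alternative-start suffix
    # protein maps a strict peptide subset (case 1).
    peptides |= set(
        build_case1_peptides(
            _truth_entry(genc, "match"), _truth_entry(genc, "alt-start"), config
        )
    )
    return sorted(peptides)


def write_demo_bundle(out_dir: str | Path, seed: int = DEFAULT_DEMO_SEED) -> dict:
    """Generate the demo input bundle into ``out_dir``; returns a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    loci = {spec.gene_id: generate_locus(spec) for spec in demo_specs(seed)}

    genome = {locus.chrom: locus.genome_sequence for locus in loci.values()}
    io.write_fasta(genome, out_dir / "genome.fasta")

    reference = [tx for locus in loci.values() for tx in locus.reference_transcripts]
    io.write_gtf(reference, out_dir / "reference.gtf")

    sample = [tx for locus in loci.values() for tx in locus.sample_transcripts]
    io.write_gtf(sample, out_dir / "sample.gtf")
    io.write_fasta(
        {tx.transcript_id: tx.sequence for tx in sample},
        out_dir / "sample_transcripts.fasta",
    )

    tids = [tx.transcript_id for tx in sample]
    counts = generate_abundances(tids, seed=seed, forced_cpm=demo_forced_cpm())
    io.write_abundance_table(counts, out_dir / "abundance.tsv")
    io.write_polya_table({tid: True for tid in tids}, out_dir / "polya.tsv")

    peptides = demo_peptides(loci)
    io.write_peptides(peptides, out_dir / "peptides.tsv")

    truth_rows = []
    for locus in loci.values():
        for rec in locus.truth.values():
            truth_rows.append(
                "\t".join(
                    [
                        rec.transcript_id,
                        rec.gene_id,
                        rec.recipe,
                        rec.transcript_class,
                        rec.protein_class,
                        str(rec.intraprime),
                        rec.aa_sequence,
                    ]
                )
            )
    header = "transcript_id\tgene_id\trecipe\ttranscript_class\tprotein_class\tintraprime\taa_sequence"
    (out_dir / "truth.tsv").write_text(header + "\n" + "\n".join(truth_rows) + "\n")

    demo_config().to_yaml(out_dir / "config.yaml")
    return {
        "loci": loci,
        "n_sample_transcripts": len(sample),
        "n_peptides": len(peptides),
        "counts": counts,
    }
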