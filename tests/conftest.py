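from pathlib import Path

import pytest

from isoforge import io
from isoforge.config import PipelineConfig
from isoforge.demo import write_demo_bundle
from isoforge.model import GenomicInterval, TranscriptModel
from isoforge.pipeline import (
    reference_protein_sequences,
    run_build_db,
    run_classify,
    run_infer,
    run_orf_call,
)


def make_transcript(
    tid="T1",
    gene="G1",
    exons=((100, 200), (300, 400)),
    strand="+",
    chrom="chr1",
    cds=None,
    sequence=None,
):
    mk = lambda spans: [GenomicInterval(chrom, s, e, strand) for s, e in spans]
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        exons=mk(exons),
        cds=mk(cds) if cds else None,
        sequence=sequence,
    )


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("demo_bundle")
    write_demo_bundle(out, seed=7)
    return out


@pytest.fixture(scope="session")
def demo_results(demo_dir, tmp_path_factory):
    """Full pipeline run on the bundled demo scenario (shared across tests)."""
    out = tmp_path_factory.mktemp("demo_out")
    cfg = PipelineConfig.from_yaml(demo_dir / "config.yaml")
    orf = run_orf_call(
        demo_dir / "sample.gtf",
        demo_dir / "sample_transcripts.fasta",
        demo_dir / "abundance.tsv",
        reference_gtf=demo_dir / "reference.gtf",
        genome_fasta=demo_dir / "genome.fasta",
        config=cfg,
        out_dir=out,
    )
    cls = run_classify(
        orf.transcripts,
        io.read_gtf(demo_dir / "reference.gtf"),
        io.read_gtf(demo_dir / "sample.gtf"),
        out,
    )
    ref_proteins = reference_protein_sequences(
        io.read_gtf(demo_dir / "reference.gtf"), io.read_fasta(demo_dir / "genome.fasta")
    )
    polya = io.read_polya_table(demo_dir / "polya.tsv")
    db = run_build_db(orf, cls.protein_classes, polya, ref_proteins, cfg, out)
    inf = run_infer(
        io.read_peptides(demo_dir / "peptides.tsv"),
        db.hybrid,
        [db.reference_db],
        cfg,
        rescue_resolve=True,
        out_dir=out,
    )
    return {"orf": orf, "cls": cls, "db": db, "inf": inf, "out": out, "cfg": cfg}
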