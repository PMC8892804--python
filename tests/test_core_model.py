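"""Coordinate conventions, GTF/FASTA round-trips, CPM and artifact filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoforge import io
from isoforge.abundance import compute_cpm, filter_min_cpm, intrapriming_flag
from isoforge.model import (
    GenomicInterval,
    IntegrityError,
    Junction,
    ProteinEntry,
    extract_cds_elements,
)
from isoforge.simulate import LocusSpec, generate_locus

from conftest import make_transcript


class TestGtf:
    def test_coordinate_convention(self, tmp_path):
        """A 1-based inclusive GTF exon [101, 200] becomes [100, 200) internally."""
        gtf = tmp_path / "one.gtf"
        gtf.write_text(
            'chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        )
        (tx,) = io.read_gtf(gtf)
        assert (tx.exons[0].start, tx.exons[0].end) == (100, 200)
        assert (tx.gene_id, tx.transcript_id) == ("G", "T")

    def test_round_trip_on_generated_loci(self, tmp_path):
        """write_gtf(read_gtf(x)) preserves exons and CDS for synthetic loci."""
        for seed, strand in [(11, "+"), (12, "-"), (13, "+")]:
            spec = LocusSpec(
                gene_id=f"G{seed}",
                seed=seed,
                strand=strand,
                sample_perturbations=("match", "skip-novel", "truncate-5prime"),
            )
            locus = generate_locus(spec)
            txs = locus.reference_transcripts + locus.sample_transcripts
            path = tmp_path / f"{seed}.gtf"
            io.write_gtf(txs, path)
            back = {t.transcript_id: t for t in io.read_gtf(path)}
            assert len(back) == len(txs)
            for tx in txs:
                got = back[tx.transcript_id]
                assert got.exons == tx.exons
                assert got.cds == tx.cds
                assert got.gene_id == tx.gene_id

    def test_malformed_line_names_line_number(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text(
            'chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            "chr1\texon\t5\t9\n"
        )
        with pytest.raises(io.GtfParseError, match="line 2"):
            io.read_gtf(gtf)

    def test_missing_attributes_rejected(self, tmp_path):
        gtf = tmp_path / "noattr.gtf"
        gtf.write_text('chr1\t.\texon\t1\t10\t.\t+\t.\tfoo "bar";\n')
        with pytest.raises(io.GtfParseError, match="line 1"):
            io.read_gtf(gtf)

    def test_mixed_strand_transcript_rejected(self, tmp_path):
        gtf = tmp_path / "mixed.gtf"
        gtf.write_text(
            'chr1\t.\texon\t1\t10\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'chr1\t.\texon\t21\t30\t.\t-\t.\tgene_id "G"; transcript_id "T";\n'
        )
        with pytest.raises(IntegrityError):
            io.read_gtf(gtf)


class TestProteinFasta:
    def test_header_dialect(self, tmp_path):
        entry = ProteinEntry(
            accession="PB.100.1", gene="GAPDH", sequence="MKV", pclass="pFSM", cpm=12.5
        )
        path = tmp_path / "db.fasta"
        io.write_protein_fasta([entry], path)
        assert path.read_text().splitlines()[0] == ">GAPDH|PB.100.1|pFSM|12.5"

    def test_empty_entry_list(self, tmp_path):
        path = tmp_path / "empty.fasta"
        io.write_protein_fasta([], path)
        assert path.read_text() == ""

    def test_empty_sequence_rejected(self, tmp_path):
        bad = ProteinEntry(accession="A", gene="G", sequence="", pclass="pNIC")
        with pytest.raises(ValueError):
            io.write_protein_fasta([bad], tmp_path / "x.fasta")

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        entries = [
            ProteinEntry(
                accession=f"PB.{i}.1",
                gene=f"G{i}",
                sequence="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80)),
                pclass="pNNC",
                cpm=float(i) + 0.5,
            )
            for i in range(20)
        ]
        path = tmp_path / "db.fasta"
        io.write_protein_fasta(entries, path)
        back = io.read_protein_fasta(path)
        assert [(e.accession, e.gene, e.sequence, e.pclass, e.cpm) for e in back] == [
            (e.accession, e.gene, e.sequence, e.pclass, e.cpm) for e in entries
        ]


class TestCpm:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"T1": 5, "T2": 5}, {"T1": 500000.0, "T2": 500000.0}),
            ({"T1": 10}, {"T1": 1000000.0}),
            ({"T1": 3, "T2": 1}, {"T1": 750000.0, "T2": 250000.0}),
        ],
    )
    def test_direct_arithmetic(self, counts, expected):
        records = compute_cpm(counts)
        assert {r.transcript_id: r.cpm for r in records} == expected

    def test_zero_total_raises(self):
        with pytest.raises(ZeroDivisionError, match="total"):
            compute_cpm({"T1": 0})

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=10_000), min_size=1, max_size=40)
    )
    def test_cpm_conserves_a_million(self, counts):
        counts = {f"T{i}": c for i, c in enumerate(counts)}
        if sum(counts.values()) == 0:
            counts["T0"] = 1
        records = compute_cpm(counts)
        assert sum(r.cpm for r in records) == pytest.approx(1_000_000.0, rel=1e-6)

    def test_strict_threshold_excludes_boundary(self):
        # one transcript at exactly 1.0 CPM among a million reads
        counts = {"edge": 1, "bulk": 999_999}
        records = compute_cpm(counts)
        assert "edge" not in filter_min_cpm(records, 1.0)
        assert filter_min_cpm(records, 0.5) == {"edge", "bulk"}

    def test_filter_matches_brute_force(self):
        rng = np.random.default_rng(3)
        counts = {f"T{i}": int(rng.integers(0, 2000)) for i in range(200)}
        counts["T0"] = 1
        records = compute_cpm(counts)
        kept = filter_min_cpm(records, 1.0)
        total = sum(counts.values())
        expected = {t for t, c in counts.items() if c / total * 1e6 > 1.0}
        assert kept == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_min_cpm([], -1.0)


class TestIntrapriming:
    def _tx(self, strand="+"):
        if strand == "+":
            return make_transcript(exons=((10, 30),), strand="+", sequence=None)
        return make_transcript(exons=((40, 60),), strand="-", sequence=None)

    def test_downstream_a_run_flags(self):
        genome = {"chr1": "C" * 30 + "A" * 20 + "C" * 10}
        assert intrapriming_flag(self._tx(), genome) is True

    def test_exact_95_percent_flags(self):
        genome = {"chr1": "C" * 30 + "A" * 19 + "C" + "C" * 10}
        assert intrapriming_flag(self._tx(), genome) is True

    def test_90_percent_does_not_flag(self):
        genome = {"chr1": "C" * 30 + "A" * 18 + "CC" + "C" * 10}
        assert intrapriming_flag(self._tx(), genome) is False

    def test_minus_strand_reads_genomic_t(self):
        # downstream of a minus-strand 3' end (leftwards), transcribed A is genomic T
        genome = {"chr1": "G" * 20 + "T" * 20 + "G" * 30}
        assert intrapriming_flag(self._tx("-"), genome) is True

    def test_missing_chromosome_raises(self):
        with pytest.raises(KeyError):
            intrapriming_flag(self._tx(), {"chrX": "A" * 100})

    def test_monotone_in_a_content(self):
        # converting any non-A base to A never flips True -> False
        base = list("C" * 30 + "ACAACAAACAAAAACAAAAA" + "C" * 10)
        genome = {"chr1": "".join(base)}
        tx = self._tx()
        before = intrapriming_flag(tx, genome)
        for i in range(30, 50):
            if base[i] != "A":
                mutated = base.copy()
                mutated[i] = "A"
                after = intrapriming_flag(tx, {"chr1": "".join(mutated)})
                assert after >= before


class TestCdsElements:
    def test_mono_exonic(self):
        tx = make_transcript(exons=((100, 400),), cds=((100, 400),))
        el = extract_cds_elements(tx)
        assert (el.start_site, el.stop_site) == (100, 399)
        assert el.junctions == ()

    def test_two_exon_junction(self):
        tx = make_transcript(
            exons=((100, 200), (300, 400)), cds=((100, 200), (300, 400))
        )
        el = extract_cds_elements(tx)
        assert el.junctions == (Junction("chr1", "+", 199, 300),)

    def test_minus_strand_mirror(self):
        """Elements of a strand-mirrored transcript are coordinate mirrors."""
        plus = make_transcript(
            exons=((100, 200), (300, 400)), cds=((150, 200), (300, 350))
        )
        L = 500
        mirror = make_transcript(
            exons=((L - 400, L - 300), (L - 200, L - 100)),
            cds=((L - 350, L - 300), (L - 200, L - 150)),
            strand="-",
        )
        ep, em = extract_cds_elements(plus), extract_cds_elements(mirror)
        assert em.start_site == L - 1 - ep.start_site
        assert em.stop_site == L - 1 - ep.stop_site
        assert [(j.donor, j.acceptor) for j in em.junctions] == [
            (L - 1 - j.donor, L - 1 - j.acceptor) for j in ep.junctions
        ]

    def test_cds_outside_exons_rejected(self):
        with pytest.raises(IntegrityError):
            make_transcript(exons=((100, 200),), cds=((150, 250),))


class TestBedTracks:
    def _entry(self):
        tx = make_transcript(
            exons=((100, 200), (300, 400)), cds=((130, 200), (300, 360))
        )
        rng = np.random.default_rng(11)
        aa = "M" + "".join(rng.choice(list("ACDEFGHIKLNPQRSTVWY"), 42))
        # CDS starts at transcript coordinate 30; 43 AA = 129 nt + stop
        return ProteinEntry(
            accession="PB.1.1",
            gene="G1",
            sequence=aa,
            pclass="pNIC",
            genomic_model=tx,
            cds_transcript_start=30,
        )

    def test_isoform_line_blocks(self):
        (line,) = io.isoform_bed_rows([self._entry()])
        fields = line.split("\t")
        assert fields[0] == "chr1"
        assert int(fields[9]) == 2
        assert (fields[6], fields[7]) == ("130", "360")

    def test_peptide_within_one_exon(self):
        entry = self._entry()
        # AA 1..8 (0-based 1): nt 33..57, inside exon 1
        pep = entry.sequence[1:9]
        (line,) = io.peptide_bed_rows([pep], [entry])
        fields = line.split("\t")
        assert int(fields[9]) == 1
        assert int(fields[2]) - int(fields[1]) == 3 * len(pep)

    def test_peptide_spanning_junction_blocks_sum(self):
        entry = self._entry()
        # AA 20..30 -> nt 90..123 crosses the exon boundary at transcript nt 100
        pep = entry.sequence[20:30]
        (line,) = io.peptide_bed_rows([pep], [entry])
        fields = line.split("\t")
        assert int(fields[9]) == 2
        sizes = [int(x) for x in fields[10].split(",") if x]
        assert sum(sizes) == 3 * len(pep)

    def test_entry_without_model_skipped(self):
        naked = ProteinEntry(accession="X", gene="G", sequence="MAAA", pclass="pNNC")
        assert io.isoform_bed_rows([naked]) == []
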