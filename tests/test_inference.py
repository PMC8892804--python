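"""Digestion, peptide mapping, parsimony, rescue & resolve, permutation test."""

import numpy as np
import pytest
from scipy import stats

from isoforge.config import ConfigError, InferenceConfig
from isoforge.inference import (
    digest,
    find_novel_peptides,
    infer_parsimonious,
    map_peptides,
    rescue,
    resolve,
    validate_by_permutation,
)
from isoforge.model import PeptideProteinMap, ProteinEntry, ProteinGroup


def brute_force_tryptic(seq, missed, lo, hi):
    """Independent cleavage-site enumeration for trypsin (K/R not before P)."""
    sites = [0] + [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ] + [len(seq)]
    out = set()
    for i in range(len(sites) - 1):
        for j in range(i + 1, min(i + 2 + missed, len(sites))):
            pep = seq[sites[i] : sites[j]]
            if lo <= len(pep) <= hi:
                out.add(pep)
    return out


class TestDigest:
    def test_trypsin_cleaves_after_k_and_r(self):
        cfg = InferenceConfig(missed_cleavages=0, peptide_len_min=1, peptide_len_max=50)
        assert digest("AAAKGGGR", cfg) == {"AAAK", "GGGR"}

    def test_length_window_filters(self):
        cfg = InferenceConfig(missed_cleavages=0)
        assert digest("AAAKGGGR", cfg) == set()  # both peptides < 7 AA

    def test_proline_blocks_cleavage(self):
        cfg = InferenceConfig(missed_cleavages=0, peptide_len_min=1, peptide_len_max=50)
        assert digest("AAAKPGGG", cfg) == {"AAAKPGGG"}

    def test_unknown_enzyme_lists_supported(self):
        with pytest.raises(ConfigError, match="trypsin"):
            digest("MKV", InferenceConfig(protease="pepsinase"))

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            digest("AAAKBBBR")

    @pytest.mark.parametrize("missed", [0, 1, 2])
    def test_matches_brute_force_on_random_protein(self, missed):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 500))
        cfg = InferenceConfig(missed_cleavages=missed)
        assert digest(seq, cfg) == brute_force_tryptic(seq, missed, 7, 50)

    @pytest.mark.parametrize(
        "enzyme,site", [("lys-c", "K"), ("glu-c", "E"), ("arg-c", "R")]
    )
    def test_alternative_enzymes(self, enzyme, site):
        cfg = InferenceConfig(
            protease=enzyme, missed_cleavages=0, peptide_len_min=1, peptide_len_max=50
        )
        seq = f"AAA{site}GGGW"
        assert digest(seq, cfg) == {f"AAA{site}", "GGGW"}

    def test_asp_n_cleaves_before_d(self):
        cfg = InferenceConfig(
            protease="asp-n", missed_cleavages=0, peptide_len_min=1, peptide_len_max=50
        )
        assert digest("AAADGGG", cfg) == {"AAA", "DGGG"}


class TestMapPeptides:
    def _entries(self):
        return [
            ProteinEntry(accession="P1", gene="G", sequence="MAAAAAAKWWWWWWR"),
            ProteinEntry(accession="P2", gene="G", sequence="MAAAAAAKCCCCCCR"),
        ]

    def test_shared_and_unique_edges(self):
        cfg = InferenceConfig(missed_cleavages=0)
        pmap = map_peptides(["MAAAAAAK", "WWWWWWR"], self._entries(), cfg)
        assert pmap.edges["MAAAAAAK"] == frozenset({"P1", "P2"})
        assert pmap.edges["WWWWWWR"] == frozenset({"P1"})

    def test_unmapped_flagged(self):
        pmap = map_peptides(["DDDDDDDD"], self._entries())
        assert pmap.unmapped == frozenset({"DDDDDDDD"})
        assert pmap.edges == {}

    def test_il_distinct_by_default_with_switch(self):
        entries = [ProteinEntry(accession="P", gene="G", sequence="MIIIIIIKAAAA")]
        strict = map_peptides(["MLLLLLLK"], entries, InferenceConfig())
        assert "MLLLLLLK" in strict.unmapped
        loose = map_peptides(
            ["MLLLLLLK"], entries, InferenceConfig(equate_il=True)
        )
        assert loose.edges["MLLLLLLK"] == frozenset({"P"})

    def test_edges_match_inverted_index_oracle(self):
        rng = np.random.default_rng(6)
        entries = [
            ProteinEntry(
                accession=f"P{i}",
                gene="G",
                sequence="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200)),
            )
            for i in range(8)
        ]
        cfg = InferenceConfig()
        universe = sorted({p for e in entries for p in digest(e.sequence, cfg)})
        observed = [p for p in universe if rng.random() < 0.4]
        pmap = map_peptides(observed, entries, cfg)
        for pep in observed:
            expected = frozenset(
                e.accession for e in entries if pep in digest(e.sequence, cfg)
            )
            assert pmap.edges.get(pep, frozenset()) == expected


def _pmap(assignments):
    """Build a map from {protein: peptide-string-set}."""
    edges = {}
    for prot, peps in assignments.items():
        for pep in peps:
            edges.setdefault(pep, set()).add(prot)
    return PeptideProteinMap(
        edges={p: frozenset(a) for p, a in edges.items()}
    )


class TestParsimony:
    def test_strict_subset_is_case1(self):
        groups, eliminated = infer_parsimonious(
            _pmap({"P1": {"a", "b"}, "P2": {"a"}})
        )
        assert [g.members for g in groups] == [("P1",)]
        assert eliminated == [("P2", "case1")]

    def test_subsumable_is_case2(self):
        groups, eliminated = infer_parsimonious(
            _pmap({"P1": {"a", "b"}, "P2": {"c", "d"}, "P3": {"b", "c"}})
        )
        assert {g.members for g in groups} == {("P1",), ("P2",)}
        assert eliminated == [("P3", "case2")]

    def test_identical_sets_form_one_group(self):
        groups, eliminated = infer_parsimonious(
            _pmap({"P1": {"a", "b"}, "P2": {"a", "b"}})
        )
        assert [g.members for g in groups] == [("P1", "P2")]
        assert eliminated == []

    def test_empty_map(self):
        assert infer_parsimonious(PeptideProteinMap(edges={})) == ([], [])

    def test_random_instances_cover_and_no_retained_subset(self):
        rng = np.random.default_rng(17)
        for _ in range(150):
            n_prot = int(rng.integers(1, 9))
            n_pep = int(rng.integers(1, 13))
            peps = [f"p{j}" for j in range(n_pep)]
            assignments = {}
            for i in range(n_prot):
                k = int(rng.integers(1, n_pep + 1))
                assignments[f"P{i}"] = set(
                    rng.choice(peps, size=k, replace=False)
                )
            pmap = _pmap(assignments)
            groups, eliminated = infer_parsimonious(pmap)
            claimed = set().union(*(g.peptides for g in groups)) if groups else set()
            assert claimed == set(pmap.edges)  # full coverage
            for g in groups:
                for h in groups:
                    if g is not h:
                        assert not g.peptides < h.peptides  # no retained subset
            # labels match an independent case re-derivation
            retained_sets = [g.peptides for g in groups]
            observed_of = {}
            for prot, peps_ in assignments.items():
                observed_of[prot] = frozenset(peps_)
            for acc, case in eliminated:
                mine = observed_of[acc]
                covering = [r for r in retained_sets if r & mine]
                if any(r > mine for r in covering):
                    expected = "case1"
                elif (
                    len(covering) >= 2
                    and mine <= frozenset().union(*covering)
                    and all(r - mine for r in covering)
                ):
                    expected = "case2"
                else:
                    expected = "case_other"
                assert case == expected


class TestRescue:
    def _eliminated(self):
        return [("P1", "case1"), ("P2", "case2"), ("P3", "case_other")]

    def test_threshold_is_strict(self):
        cfg = InferenceConfig()
        assert rescue([("P1", "case1")], {"P1": 25.0}, cfg) == []
        (g,) = rescue([("P1", "case1")], {"P1": 25.0001}, cfg)
        assert g.status == "rescued_case1"

    def test_case_other_never_rescued(self):
        rescued = rescue(self._eliminated(), {"P1": 100, "P2": 100, "P3": 100})
        assert {g.members[0] for g in rescued} == {"P1", "P2"}
        assert {g.status for g in rescued} == {"rescued_case1", "rescued_case2"}

    def test_missing_abundance_treated_as_zero(self):
        assert rescue([("P1", "case1")], {}) == []

    def test_infinite_threshold_identity(self):
        cfg = InferenceConfig(rescue_cpm_threshold=float("inf"))
        assert rescue(self._eliminated(), {"P1": 1e9}, cfg) == []

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(23)
        eliminated = [(f"P{i}", "case1") for i in range(30)]
        cpm = {f"P{i}": float(rng.uniform(0, 100)) for i in range(30)}
        counts = [
            len(rescue(eliminated, cpm, InferenceConfig(rescue_cpm_threshold=t)))
            for t in [0.1, 5, 25, 50, 80, 1e9]
        ]
        assert counts == sorted(counts, reverse=True)


class TestResolve:
    def _group(self, members):
        return ProteinGroup(
            members=tuple(members), peptides=frozenset({"x"}), status="retained"
        )

    def test_dominant_isoform_resolves(self):
        (g,) = resolve([self._group(["P1", "P2"])], {"P1": 95.0, "P2": 5.0})
        assert g.resolution == "resolved_to:P1"
        assert g.abundance_fractions["P1"] == pytest.approx(0.95)

    def test_coexpressed_pair(self):
        (g,) = resolve(
            [self._group(["P1", "P2", "P3"])], {"P1": 40.0, "P2": 40.0, "P3": 20.0}
        )
        assert g.resolution == "coexpressed:P1,P2"

    def test_85_15_stays_unresolved(self):
        (g,) = resolve([self._group(["P1", "P2"])], {"P1": 85.0, "P2": 15.0})
        assert g.resolution == "unresolved"
        assert g.abundance_fractions == pytest.approx({"P1": 0.85, "P2": 0.15})

    def test_exact_90_is_not_dominant(self):
        (g,) = resolve([self._group(["P1", "P2"])], {"P1": 90.0, "P2": 10.0})
        assert g.resolution == "unresolved"

    def test_zero_total_left_unresolved(self):
        (g,) = resolve([self._group(["P1", "P2"])], {})
        assert g.resolution == "unresolved"
        assert g.abundance_fractions == {}

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(31)
        members = [f"P{i}" for i in range(5)]
        cpm = {m: float(rng.uniform(1, 50)) for m in members}
        (g,) = resolve([self._group(members)], cpm)
        assert sum(g.abundance_fractions.values()) == pytest.approx(1.0, abs=1e-9)
        if g.resolution.startswith("resolved_to:"):
            named = g.resolution.split(":")[1]
            assert g.abundance_fractions[named] == max(
                g.abundance_fractions.values()
            )


class TestNovelPeptides:
    def test_reference_membership(self):
        ref = [ProteinEntry(accession="R", gene="G", sequence="MAAAAAAKWWWWWWR")]
        cfg = InferenceConfig(missed_cleavages=0)
        novel = find_novel_peptides(["MAAAAAAK", "CCCCCCCK"], [ref], cfg)
        assert novel == {"CCCCCCCK"}

    def test_brute_force_scan(self):
        rng = np.random.default_rng(19)
        refs = [
            [
                ProteinEntry(
                    accession=f"R{i}",
                    gene="G",
                    sequence="".join(
                        rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 150)
                    ),
                )
                for i in range(4)
            ]
            for _ in range(2)
        ]
        cfg = InferenceConfig()
        all_ref = {
            p for db in refs for e in db for p in digest(e.sequence, cfg)
        }
        observed = sorted(all_ref)[:20] + ["WWWWWWWWWK"]
        assert find_novel_peptides(observed, refs, cfg) == {"WWWWWWWWWK"}


class TestPermutationValidation:
    def test_rate_endpoints(self):
        pool = [f"P{i}" for i in range(20)]
        obs, _, _ = validate_by_permutation(pool[:5], pool, set(pool[:5]), 10, seed=0)
        assert obs == 1.0
        obs, _, _ = validate_by_permutation(pool[:5], pool, set(pool[10:]), 10, seed=0)
        assert obs == 0.0

    def test_pool_smaller_than_tested_rejected(self):
        with pytest.raises(ValueError):
            validate_by_permutation(["a", "b"], ["a"], set(), 10)

    def test_seeded_rerun_bit_identical(self):
        pool = [f"P{i}" for i in range(50)]
        truth = set(pool[::3])
        r1 = validate_by_permutation(pool[:10], pool, truth, 200, seed=99)
        r2 = validate_by_permutation(pool[:10], pool, truth, 200, seed=99)
        assert r1[0] == r2[0] and r1[2] == r2[2]
        assert np.array_equal(r1[1], r2[1])

    def test_enriched_selection_gets_small_p(self):
        pool = [f"P{i}" for i in range(200)]
        truth = set(pool[:40])  # 20% base rate
        tested = pool[:25]  # 100% validated
        _, _, p = validate_by_permutation(tested, pool, truth, 999, seed=1)
        assert p < 0.01

    def test_null_p_values_not_stochastically_small(self):
        """Under selection independent of truth, p-values are >= uniform."""
        rng = np.random.default_rng(55)
        pool = [f"P{i}" for i in range(60)]
        pvals = []
        for run in range(200):
            truth = {p for p in pool if rng.random() < 0.3}
            tested = list(rng.choice(pool, size=12, replace=False))
            _, _, p = validate_by_permutation(
                tested, pool, truth, n_perm=99, seed=int(rng.integers(2**31))
            )
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform", alternative="greater")
        assert ks.pvalue > 0.01
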