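"""Peptide mapping, parsimonious protein grouping, and Rescue & Resolve.

Parsimonious inference follows Occam's razor: proteins indistinguishable by
their covering peptide set are merged into one group, and a greedy set cover
retains the fewest groups explaining every identified peptide.  Eliminated
proteins are labelled by why parsimony discarded them:

* **case1** — its peptides are a strict subset of one retained group's set;
* **case2** — its peptides are jointly explained by two or more retained
  groups, each of which has additional peptide evidence of its own;
* **case_other** — any other elimination pattern.

Rescue reinstates case1/case2 eliminations whose transcript abundance exceeds
a conservative CPM threshold, as singleton groups annotated with their case.
Resolve reduces ambiguous multi-member groups using relative transcript
abundance: a member above the dominant fraction resolves the group; two or
more members above the co-expression fraction flag genuine co-expression.

All threshold comparisons are strict (> 25 CPM, > 90%, > 30%).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from pyteomics import parser as _pyt_parser

from .config import ConfigError, InferenceConfig
from .model import PeptideProteinMap, ProteinEntry, ProteinGroup

log = logging.getLogger(__name__)

__all__ = [
    "ENZYME_RULES",
    "digest",
    "map_peptides",
    "infer_parsimonious",
    "rescue",
    "resolve",
    "find_novel_peptides",
    "validate_by_permutation",
]

# Cleavage specificity (regex consumed by pyteomics.parser.cleave; cleavage
# occurs after each match).  Trypsin and Arg-C honour the proline exception.
ENZYME_RULES = {
    "trypsin": r"[KR](?!P)",
    "lys-c": r"K",
    "arg-c": r"R(?!P)",
    "glu-c": r"E",
    "asp-n": r"\w(?=D)",  # cleaves N-terminally of D
    "chymotrypsin": r"([FYL](?=[^P]))|(W(?=[^MP]))",
}

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def digest(sequence: str, config: Optional[InferenceConfig] = None) -> set[str]:
    """In-silico proteolytic digest, filtered to the detectability window."""
    config = config or InferenceConfig()
    bad = set(sequence) - _AA
    if bad:
        raise ValueError(f"non-standard amino acids in sequence: {sorted(bad)}")
    rule = ENZYME_RULES.get(config.protease.lower())
    if rule is None:
        raise ConfigError(
            f"unknown protease {config.protease!r}; supported: "
            f"{sorted(ENZYME_RULES)}"
        )
    peptides = _pyt_parser.cleave(
        sequence, rule, missed_cleavages=config.missed_cleavages, min_length=1,
        regex=True,
    )
    return {
        p for p in peptides if config.peptide_len_min <= len(p) <= config.peptide_len_max
    }


def _canon(peptide: str, config: InferenceConfig) -> str:
    # strip any modification annotation for sequence matching; the annotated
    # form remains the identification key
    base = peptide.split("[", 1)[0]
    return base.replace("I", "L") if config.equate_il else base


def map_peptides(
    observed: Iterable[str],
    entries: Sequence[ProteinEntry],
    config: Optional[InferenceConfig] = None,
) -> PeptideProteinMap:
    """Link each observed peptide to every entry whose digest contains it.

    Isoleucine and leucine are distinct by default (``config.equate_il``
    switches the search-engine-style I/L equivalence on).  Peptides matching
    no entry are flagged unmapped.
    """
    config = config or InferenceConfig()
    index: dict[str, set[str]] = {}
    for entry in entries:
        for pep in digest(entry.sequence, config):
            index.setdefault(_canon(pep, config), set()).add(entry.accession)
    edges: dict[str, frozenset[str]] = {}
    unmapped = set()
    for pep in observed:
        accs = index.get(_canon(pep, config))
        if accs:
            edges[pep] = frozenset(accs)
        else:
            unmapped.add(pep)
    return PeptideProteinMap(edges=edges, unmapped=frozenset(unmapped))


def infer_parsimonious(
    pmap: PeptideProteinMap,
) -> tuple[list[ProteinGroup], list[tuple[str, str]]]:
    """Greedy minimal protein-group cover of the identified peptides.

    Returns the retained groups and the eliminated proteins as
    (accession, case) pairs.  Proteins with identical peptide sets are merged
    into indistinguishable groups first.  The greedy cover repeatedly retains
    the group explaining the most unclaimed peptides (ties: larger total
    peptide count, then lexicographically smallest member accession).
    """
    if not pmap.edges:
        return [], []
    prot2peps = pmap.proteins_to_peptides()

    merged: dict[frozenset[str], list[str]] = {}
    for acc, peps in prot2peps.items():
        merged.setdefault(peps, []).append(acc)
    pool = [
        (tuple(sorted(accs)), peps) for peps, accs in merged.items()
    ]
    pool.sort(key=lambda g: g[0][0])

    unclaimed = set(pmap.edges)
    retained: list[tuple[tuple[str, ...], frozenset[str]]] = []
    remaining = list(pool)
    while unclaimed:
        best = min(
            remaining,
            key=lambda g: (-len(g[1] & unclaimed), -len(g[1]), g[0][0]),
        )
        if not best[1] & unclaimed:  # unreachable peptides would loop forever
            break
        retained.append(best)
        remaining.remove(best)
        unclaimed -= best[1]

    eliminated: list[tuple[str, str]] = []
    for members, peps in remaining:
        covering = [r for r in retained if r[1] & peps]
        if any(r[1] > peps for r in covering):
            case = "case1"
        elif (
            len(covering) >= 2
            and peps <= frozenset().union(*(r[1] for r in covering))
            and all(r[1] - peps for r in covering)
        ):
            case = "case2"
        else:
            case = "case_other"
        eliminated.extend((acc, case) for acc in members)

    groups = [
        ProteinGroup(members=members, peptides=peps, status="retained")
        for members, peps in retained
    ]
    return groups, eliminated


def rescue(
    eliminated: Sequence[tuple[str, str]],
    abundances: Mapping[str, float],
    config: Optional[InferenceConfig] = None,
    pmap: Optional[PeptideProteinMap] = None,
) -> list[ProteinGroup]:
    """Reinstate case1/case2 eliminations with transcript abundance support.

    A protein is rescued iff its CPM is strictly greater than
    ``rescue_cpm_threshold``; rescued proteins are emitted as singleton groups
    annotated with their elimination case, leaving retained groups untouched.
    """
    config = config or InferenceConfig()
    prot2peps = pmap.proteins_to_peptides() if pmap is not None else {}
    rescued = []
    for acc, case in sorted(eliminated):
        if case not in ("case1", "case2"):
            continue
        if acc not in abundances:
            log.warning("%s: no abundance record; treated as 0 CPM", acc)
        if abundances.get(acc, 0.0) > config.rescue_cpm_threshold:
            rescued.append(
                ProteinGroup(
                    members=(acc,),
                    peptides=prot2peps.get(acc, frozenset()),
                    status=f"rescued_{case}",
                )
            )
    return rescued


def resolve(
    groups: Sequence[ProteinGroup],
    abundances: Mapping[str, float],
    config: Optional[InferenceConfig] = None,
) -> list[ProteinGroup]:
    """Attach abundance fractions and resolution status to ambiguous groups."""
    config = config or InferenceConfig()
    out = []
    for g in groups:
        cpms = {m: abundances.get(m, 0.0) for m in g.members}
        total = sum(cpms.values())
        if len(g.members) < 2:
            out.append(
                ProteinGroup(
                    g.members,
                    g.peptides,
                    g.status,
                    resolution="unresolved",
                    abundance_fractions={g.members[0]: 1.0} if total > 0 else {},
                )
            )
            continue
        if total == 0:
            log.info("group %s: zero total CPM; left unresolved", g.members)
            out.append(
                ProteinGroup(g.members, g.peptides, g.status, "unresolved", {})
            )
            continue
        fractions = {m: c / total for m, c in cpms.items()}
        top = max(fractions, key=lambda m: (fractions[m], m))
        coexpressed = sorted(
            m for m, f in fractions.items() if f > config.coexpression_fraction
        )
        if fractions[top] > config.dominant_fraction:
            resolution = f"resolved_to:{top}"
        elif len(coexpressed) >= 2:
            resolution = "coexpressed:" + ",".join(coexpressed)
        else:
            resolution = "unresolved"
        out.append(
            ProteinGroup(g.members, g.peptides, g.status, resolution, fractions)
        )
    return out


def find_novel_peptides(
    observed: Iterable[str],
    reference_databases: Sequence[Sequence[ProteinEntry]],
    config: Optional[InferenceConfig] = None,
) -> set[str]:
    """Observed peptides absent from every reference database digest."""
    config = config or InferenceConfig()
    reference_peptides: set[str] = set()
    for db in reference_databases:
        for entry in db:
            reference_peptides.update(
                _canon(p, config) for p in digest(entry.sequence, config)
            )
    return {p for p in observed if _canon(p, config) not in reference_peptides}


def validate_by_permutation(
    tested: Iterable[str],
    pool: Iterable[str],
    ground_truth: Iterable[str],
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> tuple[float, np.ndarray, float]:
    """Permutation test of a validation rate against random selection.

    ``observed = |tested ∩ truth| / |tested|``; each permutation draws
    ``|tested|`` proteins uniformly without replacement from the pool and
    computes the same rate.  The p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    tested = sorted(set(tested))
    pool_list = sorted(set(pool))
    truth = set(ground_truth)
    if not set(tested) <= set(pool_list):
        raise ValueError("tested set must be a subset of the pool")
    if len(pool_list) < len(tested):
        raise ValueError("pool smaller than tested set")
    if not tested:
        raise ValueError("tested set is empty")
    observed = sum(t in truth for t in tested) / len(tested)
    rng = np.random.default_rng(seed)
    truth_mask = np.array([p in truth for p in pool_list], dtype=bool)
    k = len(tested)
    null = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        idx = rng.choice(len(pool_list), size=k, replace=False)
        null[i] = truth_mask[idx].mean()
    p_value = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return observed, null, p_value
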