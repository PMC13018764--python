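"""Descendant-closure phenotype queries, source stratification, subtype
classification and term-frequency tabulations.

"Child code" means any proper descendant at any depth.  Frequency counts
are per participant: a term reported by both sources counts once in the
combined tally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .cohort_data import Cohort, term_set
from .errors import UnknownTermError, ValidationError
from .ontology import OntologyGraph

BOTH = "both"
PRD_ONLY = "PRD only"
CRD_ONLY = "CRD only"
ABSENT = "absent"


def has_phenotype(graph: OntologyGraph, terms: set[str], root_term: str) -> bool:
    """True iff any term equals root_term or descends from it."""
    if root_term not in graph.terms:
        raise UnknownTermError(root_term)
    return any(
        t == root_term or root_term in graph.ancestor_closure[t] for t in terms
    )


def stratify_by_source(
    cohort: Cohort, graph: OntologyGraph, root_term: str
) -> dict[str, str]:
    """Four-way presence label per participant with any data from both sources.

    Labels: both / PRD only / CRD only / absent, from evaluating the
    combined-scope term set of each source.
    """
    per_pid: dict[str, dict[str, set[str]]] = {}
    for r in cohort.records:
        per_pid.setdefault(r.participant_id, {}).setdefault(r.source, set()).add(
            r.term_id
        )
    out: dict[str, str] = {}
    for pid, by_source in per_pid.items():
        if set(by_source) != {"PRD", "CRD"}:
            continue
        in_prd = has_phenotype(graph, by_source["PRD"], root_term)
        in_crd = has_phenotype(graph, by_source["CRD"], root_term)
        if in_prd and in_crd:
            out[pid] = BOTH
        elif in_prd:
            out[pid] = PRD_ONLY
        elif in_crd:
            out[pid] = CRD_ONLY
        else:
            out[pid] = ABSENT
    return out


@dataclass(frozen=True)
class SubtypeResult:
    root_only: bool
    subtypes: frozenset[str]


def classify_subtype(
    graph: OntologyGraph, terms: set[str], root_term: str
) -> SubtypeResult:
    """Split a positive phenotype call into root-only vs subtyped.

    Returns the proper descendants of root_term present in ``terms``;
    root_only is True when only the root term itself appears.  Calling this
    on a term set without the phenotype is an error.
    """
    if not has_phenotype(graph, terms, root_term):
        raise ValidationError(f"phenotype {root_term} absent from term set")
    subtypes = frozenset(
        t for t in terms if t != root_term and root_term in graph.ancestor_closure[t]
    )
    return SubtypeResult(root_only=not subtypes, subtypes=subtypes)


def term_frequency(
    cohort: Cohort, source_filter: str = "combined"
) -> list[tuple[str, int]]:
    """Participant-level term counts, descending, ties broken by CURIE."""
    if source_filter not in ("PRD", "CRD", "combined"):
        raise ValueError("source_filter must be PRD, CRD or combined")
    carriers: dict[str, set[str]] = {}
    for r in cohort.records:
        if source_filter != "combined" and r.source != source_filter:
            continue
        carriers.setdefault(r.term_id, set()).add(r.participant_id)
    ranked = sorted(carriers.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [(term, len(pids)) for term, pids in ranked]


def unique_terms_by_system(cohort: Cohort) -> pd.DataFrame:
    """Per system, the number of vocabulary terms unique to each source."""
    vocab: dict[tuple[str, str], set[str]] = {}
    for r in cohort.records:
        vocab.setdefault((r.system, r.source), set()).add(r.term_id)
    systems = sorted({s for s, _ in vocab})
    rows = []
    for system in systems:
        prd = vocab.get((system, "PRD"), set())
        crd = vocab.get((system, "CRD"), set())
        rows.append({"system": system, "source": "PRD", "n_unique_to_source": len(prd - crd)})
        rows.append({"system": system, "source": "CRD", "n_unique_to_source": len(crd - prd)})
    return pd.DataFrame(rows, columns=["system", "source", "n_unique_to_source"])
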