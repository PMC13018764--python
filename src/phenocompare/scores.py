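"""Per-participant quantity, detail and set-similarity scores.

Quantity is the distinct-term count per source.  Detail credits the source
reporting the more specific (descendant) term, weighted by the minimal
number of ontology levels between the two terms, accumulated over all
qualifying cross-source term pairs.  Set similarity is the symmetric
best-match average of pairwise Lin similarities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .cohort_data import Cohort, paired_participants
from .ontology import OntologyGraph, ancestor_path_length, lin_similarity

PARENT_MORE = "Parent more"
DOCTOR_MORE = "Doctor more"
EQUAL_QUANTITY = "Equal quantity"
EQUAL = "Equal"

SCORE_COLUMNS = [
    "participant_id",
    "scope",
    "quantity_prd",
    "quantity_crd",
    "detail_prd",
    "detail_crd",
    "similarity",
    "quantity_category",
    "detail_category",
]


@dataclass(frozen=True)
class ScoreRow:
    participant_id: str
    scope: str
    quantity_prd: int
    quantity_crd: int
    detail_prd: int
    detail_crd: int
    similarity: Optional[float]
    quantity_category: str
    detail_category: str


def quantity_score(terms: set[str]) -> int:
    """Number of distinct terms provided."""
    return len(set(terms))


def detail_scores(
    graph: OntologyGraph,
    prd: set[str],
    crd: set[str],
    best_pair_only: bool = False,
) -> tuple[int, int]:
    """Detail totals (detail_prd, detail_crd) over all cross-source pairs.

    For each pair with one term a proper ancestor of the other, the source
    holding the descendant gains the minimal ancestor-path length.  Identical
    terms contribute nothing.  With ``best_pair_only`` each term keeps only
    its single largest increment (sensitivity analysis).
    """
    gains_prd: dict[str, int] = {}
    gains_crd: dict[str, int] = {}
    detail_prd = 0
    detail_crd = 0
    for p in prd:
        anc_p = graph.ancestor_closure[p]
        for c in crd:
            if p == c:
                continue
            d = ancestor_path_length(graph, p, c)
            if not d:
                continue
            if c in anc_p:  # crd term is the ancestor; prd is more specific
                if best_pair_only:
                    gains_prd[p] = max(gains_prd.get(p, 0), d)
                else:
                    detail_prd += d
            else:  # prd term is the ancestor; crd is more specific
                if best_pair_only:
                    gains_crd[c] = max(gains_crd.get(c, 0), d)
                else:
                    detail_crd += d
    if best_pair_only:
        detail_prd = sum(gains_prd.values())
        detail_crd = sum(gains_crd.values())
    return detail_prd, detail_crd


def set_similarity(graph: OntologyGraph, a: set[str], b: set[str]) -> Optional[float]:
    """Symmetric best-match-average Lin similarity between two term sets.

    Returns None when either set is empty (the participant is excluded from
    similarity analyses rather than scored 0).
    """
    if not a or not b:
        return None
    ab = sum(max(lin_similarity(graph, x, y) for y in b) for x in a) / len(a)
    ba = sum(max(lin_similarity(graph, x, y) for x in a) for y in b) / len(b)
    return (ab + ba) / 2.0


def _categorise(v_prd: float, v_crd: float, equal_label: str) -> str:
    if v_prd > v_crd:
        return PARENT_MORE
    if v_crd > v_prd:
        return DOCTOR_MORE
    return equal_label


def score_table(
    cohort: Cohort,
    graph: OntologyGraph,
    scopes: Iterable[str],
    combined_rule: str = "strict",
    best_pair_only: bool = False,
) -> list[ScoreRow]:
    """One ScoreRow per paired participant per scope."""
    index: dict[str, dict[str, dict[str, set[str]]]] = {}
    for r in cohort.records:
        index.setdefault(r.participant_id, {}).setdefault(r.source, {}).setdefault(
            r.system, set()
        ).add(r.term_id)

    def terms_for(pid: str, source: str, scope: str) -> set[str]:
        by_system = index.get(pid, {}).get(source, {})
        if scope == "combined":
            out: set[str] = set()
            for s in by_system.values():
                out |= s
            return out
        return set(by_system.get(scope, set()))

    rows: list[ScoreRow] = []
    for scope in scopes:
        for pid in sorted(paired_participants(cohort, scope, combined_rule)):
            prd = terms_for(pid, "PRD", scope)
            crd = terms_for(pid, "CRD", scope)
            qp, qc = quantity_score(prd), quantity_score(crd)
            dp, dc = detail_scores(graph, prd, crd, best_pair_only=best_pair_only)
            rows.append(
                ScoreRow(
                    participant_id=pid,
                    scope=scope,
                    quantity_prd=qp,
                    quantity_crd=qc,
                    detail_prd=dp,
                    detail_crd=dc,
                    similarity=set_similarity(graph, prd, crd),
                    quantity_category=_categorise(qp, qc, EQUAL_QUANTITY),
                    detail_category=_categorise(dp, dc, EQUAL),
                )
            )
    return rows


def lowest_similarity(rows: Iterable[ScoreRow], k: int, scope: str = "combined") -> list[ScoreRow]:
    """Bottom-k rows in a scope ranked by ascending similarity."""
    scoped = [r for r in rows if r.scope == scope and r.similarity is not None]
    return sorted(scoped, key=lambda r: (r.similarity, r.participant_id))[:k]


def scores_to_frame(rows: Iterable[ScoreRow]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in rows], columns=SCORE_COLUMNS)
    return df


def write_scores(rows: Iterable[ScoreRow], path: str | Path) -> None:
    scores_to_frame(rows).to_csv(path, sep="\t", index=False, na_rep="")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"participant_id": str, "scope": str})
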