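"""Comparison of per-participant term sets against a gene-to-phenotype
reference list, with Welch ANOVA across the PRD / CRD / combined sources
and Holm-adjusted pairwise follow-up."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from .cohort_data import Cohort, term_set
from .errors import DegenerateGroupError, UnknownTermError, ValidationError
from .ontology import OntologyGraph, resolve_term
from .scores import set_similarity
from .stats import TestResult, pairwise_welch_holm, welch_anova

logger = logging.getLogger(__name__)

REFERENCE_SOURCES = ("PRD", "CRD", "combined")


def read_reference(path: str | Path, graph: OntologyGraph) -> dict[str, set[str]]:
    """Load a gene -> HPO-term-set reference from TSV (gene, hpo_ids).

    ``hpo_ids`` is comma-separated; ids are resolved to primary terms and
    deduplicated; unresolvable ids are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "hpo_ids"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    ref: dict[str, set[str]] = {}
    dropped: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        terms: set[str] = set()
        for raw in str(row.hpo_ids).split(","):
            raw = raw.strip()
            if not raw:
                continue
            try:
                terms.add(resolve_term(graph, raw))
            except UnknownTermError:
                dropped.setdefault(row.gene, []).append(raw)
        if not terms:
            raise ValidationError(f"{path}: gene {row.gene!r} has no resolvable terms")
        ref.setdefault(row.gene, set()).update(terms)
    if dropped:
        logger.warning("reference terms dropped per gene: %s", dropped)
    for gene, terms in ref.items():
        logger.info("reference %s: %d terms", gene, len(terms))
    return ref


def _source_set(cohort: Cohort, pid: str, source: str) -> set[str]:
    if source == "combined":
        return term_set(cohort, pid, "PRD", "combined") | term_set(
            cohort, pid, "CRD", "combined"
        )
    return term_set(cohort, pid, source, "combined")


def reference_similarity(
    cohort: Cohort,
    graph: OntologyGraph,
    ref: dict[str, set[str]],
    gene: str,
    source: str,
) -> list[tuple[str, float]]:
    """Similarity of each gene-carrier's source set to the reference set.

    Participants with an empty source set are skipped (reported via log).
    """
    if gene not in ref:
        raise ValidationError(f"gene {gene!r} absent from reference")
    if source not in REFERENCE_SOURCES:
        raise ValueError(f"source must be one of {REFERENCE_SOURCES}")
    carriers = sorted(
        pid for pid, m in cohort.meta.items() if m.gene == gene
    )
    out: list[tuple[str, float]] = []
    skipped = 0
    for pid in carriers:
        sim = set_similarity(graph, _source_set(cohort, pid, source), ref[gene])
        if sim is None:
            skipped += 1
            continue
        out.append((pid, sim))
    if skipped:
        logger.info("%s/%s: skipped %d participant(s) with empty sets", gene, source, skipped)
    return out


def compare_sources_to_reference(
    cohort: Cohort,
    graph: OntologyGraph,
    ref: dict[str, set[str]],
    gene: str,
    alpha: float = 0.05,
) -> list[TestResult]:
    """Welch ANOVA across PRD/CRD/combined reference similarities for one
    gene; pairwise Welch t-tests with Holm follow significant ANOVAs."""
    family = f"reference:{gene}"
    groups = []
    for source in REFERENCE_SOURCES:
        sims = [s for _, s in reference_similarity(cohort, graph, ref, gene, source)]
        if len(sims) < 2:
            raise DegenerateGroupError(
                f"gene {gene!r}, source {source}: fewer than 2 observations"
            )
        groups.append(sims)
    try:
        f_stat, df1, df2, p = welch_anova(groups)
    except DegenerateGroupError as e:
        raise DegenerateGroupError(f"gene {gene!r}: {e}") from e
    results = [
        TestResult(
            family=family,
            scope="ANOVA",
            statistic=f_stat,
            p_raw=p,
            p_adjusted=p,
            method="Welch ANOVA",
            n=sum(len(g) for g in groups),
            extra={"df1": df1, "df2": df2},
        )
    ]
    if p < alpha:
        results.extend(
            pairwise_welch_holm(groups, labels=list(REFERENCE_SOURCES), family=family)
        )
    return results
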