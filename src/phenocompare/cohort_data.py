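"""Data model and I/O for paired-source phenotype cohorts.

Records are long-format (participant, source, system, term); per-participant
metadata carries the gene symbol and gene group.  Terms are resolved to
primary ontology ids at load time and duplicate tuples collapsed, with a
load report accounting for every dropped row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import UnknownTermError, ValidationError
from .ontology import OntologyGraph, resolve_term

logger = logging.getLogger(__name__)

SOURCES = ("PRD", "CRD")

DEFAULT_SYSTEMS = (
    "cardiac",
    "dental",
    "endocrine",
    "ENT",
    "gastroenterology",
    "immunology",
    "neurology",
    "renal",
    "respiratory",
    "vision",
)

RECORD_COLUMNS = ["participant_id", "source", "system", "term_id"]
META_COLUMNS = ["participant_id", "gene", "gene_group"]


@dataclass(frozen=True, order=True)
class PhenotypeRecord:
    participant_id: str
    source: str
    system: str
    term_id: str


@dataclass(frozen=True)
class ParticipantMeta:
    participant_id: str
    gene: str = ""
    gene_group: str = ""


@dataclass
class LoadReport:
    """Row-level accounting from read_cohort."""

    n_input: int = 0
    n_kept: int = 0
    n_duplicates: int = 0
    n_unknown_dropped: int = 0
    n_remapped: int = 0
    unknown_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class Cohort:
    records: list[PhenotypeRecord]
    meta: dict[str, ParticipantMeta] = field(default_factory=dict)
    systems: tuple[str, ...] = DEFAULT_SYSTEMS

    def participants(self) -> list[str]:
        return sorted({r.participant_id for r in self.records})

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.participant_id, r.source, r.system, r.term_id) for r in self.records],
            columns=RECORD_COLUMNS,
        )

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.participant_id, m.gene, m.gene_group) for m in self.meta.values()],
            columns=META_COLUMNS,
        )


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return df[columns].astype(str)


def read_cohort(
    records_path: str | Path,
    meta_path: Optional[str | Path],
    graph: OntologyGraph,
    on_unknown: str = "drop",
    systems: Iterable[str] = DEFAULT_SYSTEMS,
) -> tuple[Cohort, LoadReport]:
    """Load and validate a cohort from TSV/JSON.

    Term ids are resolved to primary ids (alt_id and replaced_by honoured);
    rows whose term cannot be resolved are dropped or fatal depending on
    ``on_unknown``; duplicate (participant, source, system, term) tuples are
    collapsed.
    """
    if on_unknown not in ("drop", "fail"):
        raise ValueError("on_unknown must be 'drop' or 'fail'")
    systems = tuple(systems)
    df = _read_table(records_path, RECORD_COLUMNS)
    report = LoadReport(n_input=len(df))

    seen: set[tuple[str, str, str, str]] = set()
    records: list[PhenotypeRecord] = []
    unknown: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pid, source, system, term = row
        if not pid or source not in SOURCES or not term:
            raise ValidationError(
                f"{records_path}: malformed row at line {i}: {tuple(row)!r}"
            )
        if system not in systems:
            raise ValidationError(
                f"{records_path}: line {i}: system {system!r} not in vocabulary"
            )
        try:
            primary = resolve_term(graph, term)
        except UnknownTermError:
            unknown.append(term)
            continue
        if primary != term:
            report.n_remapped += 1
        key = (pid, source, system, primary)
        if key in seen:
            report.n_duplicates += 1
            continue
        seen.add(key)
        records.append(PhenotypeRecord(pid, source, system, primary))

    report.unknown_ids = sorted(set(unknown))
    report.n_unknown_dropped = len(unknown)
    if unknown and on_unknown == "fail":
        raise UnknownTermError(set(unknown))
    report.n_kept = len(records)
    if unknown:
        logger.warning(
            "dropped %d record(s) with unknown term ids: %s",
            len(unknown),
            report.unknown_ids,
        )

    meta: dict[str, ParticipantMeta] = {}
    if meta_path is not None:
        mdf = _read_table(meta_path, META_COLUMNS)
        for i, row in enumerate(mdf.itertuples(index=False), start=2):
            pid, gene, group = row
            if pid in meta:
                raise ValidationError(f"{meta_path}: duplicate participant at line {i}")
            if gene and not group:
                raise ValidationError(
                    f"{meta_path}: line {i}: gene {gene!r} without a gene_group"
                )
            meta[pid] = ParticipantMeta(pid, gene, group)

    return Cohort(records=records, meta=meta, systems=systems), report


def write_cohort(cohort: Cohort, records_path: str | Path, meta_path: Optional[str | Path] = None) -> None:
    df = cohort.records_frame().sort_values(RECORD_COLUMNS)
    df.to_csv(records_path, sep="\t", index=False)
    if meta_path is not None:
        cohort.meta_frame().sort_values("participant_id").to_csv(
            meta_path, sep="\t", index=False
        )


def _systems_with_data(cohort: Cohort, pid: str) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for r in cohort.records:
        if r.participant_id == pid:
            out.setdefault(r.system, set()).add(r.source)
    return out


def paired_participants(
    cohort: Cohort, scope: str, combined_rule: str = "strict"
) -> set[str]:
    """Participants contributing both sources for the given scope.

    Single system: both sources present in that system.  ``combined``:
    under the default ``strict`` rule, both sources present in every system
    where either reported anything; under ``lenient``, both sources present
    anywhere in the cohort.
    """
    per_pid: dict[str, dict[str, set[str]]] = {}
    for r in cohort.records:
        per_pid.setdefault(r.participant_id, {}).setdefault(r.system, set()).add(
            r.source
        )
    out: set[str] = set()
    if scope == "combined":
        for pid, by_system in per_pid.items():
            if combined_rule == "strict":
                if all(srcs == set(SOURCES) for srcs in by_system.values()):
                    out.add(pid)
            elif combined_rule == "lenient":
                if set().union(*by_system.values()) == set(SOURCES):
                    out.add(pid)
            else:
                raise ValueError(f"unknown combined_rule {combined_rule!r}")
    else:
        for pid, by_system in per_pid.items():
            if by_system.get(scope) == set(SOURCES):
                out.add(pid)
    return out


def term_set(cohort: Cohort, participant: str, source: str, scope: str) -> set[str]:
    """Deduplicated term ids for a participant x source over a scope."""
    return {
        r.term_id
        for r in cohort.records
        if r.participant_id == participant
        and r.source == source
        and (scope == "combined" or r.system == scope)
    }
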