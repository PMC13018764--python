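from __future__ import annotations

import numpy as np
import pytest

from phenocompare import Cohort, ParticipantMeta, PhenotypeRecord, make_fixture_ontology


@pytest.fixture(scope="session")
def graph():
    return make_fixture_ontology()


def build_cohort(rows, meta=None, systems=None):
    """rows: iterable of (participant, source, system, term)."""
    records = [PhenotypeRecord(*r) for r in rows]
    meta_map = {}
    if meta:
        for pid, gene, group in meta:
            meta_map[pid] = ParticipantMeta(pid, gene, group)
    kwargs = {"systems": tuple(systems)} if systems else {}
    return Cohort(records=records, meta=meta_map, **kwargs)


def random_dag_obo(rng: np.random.Generator, n_terms: int) -> str:
    """OBO text for a random rooted DAG: term i draws 1-2 parents among 0..i-1."""
    lines = ["format-version: 1.2", ""]
    for i in range(n_terms):
        tid = f"TT:{i + 1:07d}"
        lines += ["[Term]", f"id: {tid}", f"name: term {i + 1}"]
        if i > 0:
            k = 1 if i == 1 else int(rng.integers(1, 3))
            parents = rng.choice(i, size=min(k, i), replace=False)
            for p in sorted(parents):
                lines.append(f"is_a: TT:{p + 1:07d}")
        lines.append("")
    return "\n".join(lines)
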