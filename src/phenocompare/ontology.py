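"""OBO-backed ontology DAG with ancestor queries, information content and
Lin term similarity.

Only ``is_a`` edges build the graph.  Obsolete terms are kept out of the DAG
and exposed solely through :func:`resolve_term` via their ``replaced_by``
targets.  Information content (IC) is computed either intrinsically from
descendant counts or from a corpus of term usages; Lin similarity is the
classic ``2*IC(MICA) / (IC(a) + IC(b))`` with the compared terms themselves
admitted as their own common ancestors.
"""

from __future__ import annotations

import math
import re
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

from .errors import CycleError, OntologyError, UnknownTermError

CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*:\d+$")


@dataclass
class Term:
    """One ontology term parsed from a ``[Term]`` stanza."""

    id: str
    name: str = ""
    parent_ids: set[str] = field(default_factory=set)
    alt_ids: set[str] = field(default_factory=set)
    obsolete: bool = False
    replaced_by: Optional[str] = None


@dataclass
class OntologyGraph:
    """Validated is_a DAG plus precomputed closures and IC table.

    ``ancestor_closure`` excludes the term itself; ``descendant_count``
    includes it.  ``ic`` is in nats and is 0 for the root.
    """

    terms: dict[str, Term]
    root_id: str
    ancestor_closure: dict[str, frozenset[str]]
    descendant_count: dict[str, int]
    ic: dict[str, float] = field(default_factory=dict)
    alt_map: dict[str, str] = field(default_factory=dict)
    replacement_map: dict[str, str] = field(default_factory=dict)
    _lin_cache: dict[tuple[str, str], float] = field(default_factory=dict, repr=False)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    @property
    def children(self) -> dict[str, set[str]]:
        kids: dict[str, set[str]] = {t: set() for t in self.terms}
        for tid, term in self.terms.items():
            for p in term.parent_ids:
                kids[p].add(tid)
        return kids

    def parents(self, term_id: str) -> set[str]:
        if term_id not in self.terms:
            raise UnknownTermError(term_id)
        return set(self.terms[term_id].parent_ids)

    def ancestors_or_self(self, term_id: str) -> frozenset[str]:
        if term_id not in self.terms:
            raise UnknownTermError(term_id)
        return self.ancestor_closure[term_id] | {term_id}

    def depth(self, term_id: str) -> int:
        """Minimum number of parent edges from term to root."""
        return ancestor_path_length(self, self.root_id, term_id)


def _parse_stanzas(text: str) -> list[dict[str, list[str]]]:
    stanzas: list[dict[str, list[str]]] = []
    current: Optional[dict[str, list[str]]] = None
    in_term = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("["):
            in_term = line == "[Term]"
            current = {} if in_term else None
            if in_term:
                stanzas.append(current)
            continue
        if current is None:
            continue
        if ":" not in line:
            continue
        key, _, value = line.partition(":")
        value = value.split("!")[0].strip()
        current.setdefault(key.strip(), []).append(value)
    return stanzas


def load_obo(path: str | Path, root: Optional[str] = None) -> OntologyGraph:
    """Parse an OBO flat file into a validated :class:`OntologyGraph`.

    Parameters
    ----------
    path
        OBO flat file; ``[Term]`` stanzas with id, name, is_a and optionally
        alt_id, is_obsolete and replaced_by are honoured, everything else is
        ignored.
    root
        Expected root CURIE.  When omitted, the unique term without parents
        is taken as root; ambiguity is fatal.

    Raises
    ------
    CycleError
        if the is_a relation is cyclic (the offending edges are attached).
    OntologyError
        for a missing/ambiguous root or is_a references to unknown ids.
    """
    text = Path(path).read_text(encoding="utf-8")
    terms: dict[str, Term] = {}
    replacement_map: dict[str, str] = {}
    alt_map: dict[str, str] = {}

    for stanza in _parse_stanzas(text):
        if "id" not in stanza:
            raise OntologyError("[Term] stanza without an id")
        tid = stanza["id"][0]
        if not CURIE_RE.match(tid):
            raise OntologyError(f"malformed term id: {tid!r}")
        obsolete = stanza.get("is_obsolete", ["false"])[0].lower() == "true"
        term = Term(
            id=tid,
            name=stanza.get("name", [""])[0],
            parent_ids=set() if obsolete else set(stanza.get("is_a", [])),
            alt_ids=set(stanza.get("alt_id", [])),
            obsolete=obsolete,
            replaced_by=stanza.get("replaced_by", [None])[0],
        )
        if obsolete:
            if term.replaced_by:
                replacement_map[tid] = term.replaced_by
            continue
        terms[tid] = term
        for alt in term.alt_ids:
            alt_map[alt] = tid

    if not terms:
        raise OntologyError("no non-obsolete [Term] stanzas found")

    unknown = sorted(
        p for t in terms.values() for p in t.parent_ids if p not in terms
    )
    if unknown:
        raise OntologyError(f"is_a references unknown ids: {unknown}")

    roots = [tid for tid, t in terms.items() if not t.parent_ids]
    if root is not None:
        if root not in terms:
            raise OntologyError(f"requested root {root} not present")
        root_id = root
    elif len(roots) == 1:
        root_id = roots[0]
    else:
        raise OntologyError(f"root is ambiguous or missing: parentless terms {roots}")

    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for tid, t in terms.items():
        for p in t.parent_ids:
            g.add_edge(tid, p)  # child -> parent
    if not nx.is_directed_acyclic_graph(g):
        raise CycleError([(u, v) for u, v in nx.find_cycle(g)])

    # every non-root term must reach the root via parent edges
    reachable = set(nx.ancestors(g, root_id)) | {root_id}  # edges run child -> parent
    stranded = sorted(set(terms) - reachable)
    if stranded:
        raise OntologyError(f"terms not reaching root {root_id}: {stranded}")

    closure: dict[str, frozenset[str]] = {}
    for tid in nx.topological_sort(g.reverse(copy=False)):
        anc: set[str] = set()
        for p in terms[tid].parent_ids:
            anc.add(p)
            anc |= closure[p]
        closure[tid] = frozenset(anc)

    desc_count = {tid: 1 for tid in terms}
    for tid in terms:
        for a in closure[tid]:
            desc_count[a] += 1

    graph = OntologyGraph(
        terms=terms,
        root_id=root_id,
        ancestor_closure=closure,
        descendant_count=desc_count,
        alt_map=alt_map,
        replacement_map=replacement_map,
    )
    return compute_ic(graph, mode="intrinsic")


def resolve_term(graph: OntologyGraph, term_id: str) -> str:
    """Map a CURIE to its primary id (identity, alt_id alias or replacement)."""
    if term_id in graph.terms:
        return term_id
    if term_id in graph.alt_map:
        return graph.alt_map[term_id]
    if term_id in graph.replacement_map:
        target = graph.replacement_map[term_id]
        return resolve_term(graph, target)
    raise UnknownTermError(term_id)


def ancestor_path_length(graph: OntologyGraph, a: str, b: str) -> Optional[int]:
    """Minimum number of parent edges between a term and its ancestor.

    Returns 0 when ``a == b``, the minimal edge count when one term is a
    proper ancestor of the other, and ``None`` when neither is.
    """
    for t in (a, b):
        if t not in graph.terms:
            raise UnknownTermError(t)
    if a == b:
        return 0
    if a in graph.ancestor_closure[b]:
        anc, desc = a, b
    elif b in graph.ancestor_closure[a]:
        anc, desc = b, a
    else:
        return None
    # BFS upward from the descendant
    frontier = deque([(desc, 0)])
    seen = {desc}
    while frontier:
        node, dist = frontier.popleft()
        for p in graph.terms[node].parent_ids:
            if p == anc:
                return dist + 1
            if p not in seen and anc in graph.ancestor_closure[p]:
                seen.add(p)
                frontier.append((p, dist + 1))
    raise OntologyError(f"closure inconsistency between {anc} and {desc}")


def compute_ic(
    graph: OntologyGraph,
    mode: str = "intrinsic",
    corpus: Optional[Iterable[str]] = None,
) -> OntologyGraph:
    """Populate ``graph.ic`` in place and return the graph.

    ``intrinsic``: IC(t) = -log(descendant_count(t) / descendant_count(root)).
    ``corpus``: usage counts propagated to all ancestors, then
    IC(t) = -log(freq(t) / freq(root)).  Corpus terms that do not resolve are
    dropped with a count kept on ``graph.ic_dropped``.
    """
    if mode == "intrinsic":
        n_root = graph.descendant_count[graph.root_id]
        graph.ic = {
            tid: -math.log(graph.descendant_count[tid] / n_root)
            for tid in graph.terms
        }
    elif mode == "corpus":
        if not corpus:
            raise ValueError("corpus mode requires a non-empty corpus")
        freq = {tid: 0 for tid in graph.terms}
        dropped = 0
        for raw in corpus:
            try:
                tid = resolve_term(graph, raw)
            except UnknownTermError:
                dropped += 1
                continue
            freq[tid] += 1
            for a in graph.ancestor_closure[tid]:
                freq[a] += 1
        total = freq[graph.root_id]
        if total == 0:
            raise ValueError("no corpus term resolved against the ontology")
        # unobserved terms get the maximum observed IC + 1 nat floor via
        # a pseudo-frequency of 1 to keep IC finite and monotone
        graph.ic = {}
        for tid in graph.terms:
            f = max(freq[tid], 1) if tid != graph.root_id else total
            graph.ic[tid] = -math.log(f / total)
        graph.ic_dropped = dropped  # type: ignore[attr-defined]
    else:
        raise ValueError(f"unknown IC mode: {mode!r}")
    graph.ic[graph.root_id] = 0.0
    graph._lin_cache.clear()
    return graph


def mica(graph: OntologyGraph, a: str, b: str) -> str:
    """Most informative common ancestor, terms themselves included."""
    common = graph.ancestors_or_self(a) & graph.ancestors_or_self(b)
    return max(common, key=lambda t: (graph.ic[t], t))


def lin_similarity(graph: OntologyGraph, a: str, b: str) -> float:
    """Lin similarity 2*IC(MICA)/(IC(a)+IC(b)), in [0, 1].

    Identical terms score exactly 1; a zero IC denominator (two root-like
    terms) scores 0.
    """
    if not graph.ic:
        raise OntologyError("information content not computed")
    if a == b:
        if a not in graph.terms:
            raise UnknownTermError(a)
        return 1.0
    key = (a, b) if a <= b else (b, a)
    cached = graph._lin_cache.get(key)
    if cached is not None:
        return cached
    denom = graph.ic[a] + graph.ic[b] if a in graph.terms and b in graph.terms else None
    if denom is None:
        raise UnknownTermError([t for t in (a, b) if t not in graph.terms])
    if denom == 0.0:
        sim = 0.0
    else:
        sim = min(1.0, 2.0 * graph.ic[mica(graph, a, b)] / denom)
    graph._lin_cache[key] = sim
    return sim
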