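"""Exception hierarchy shared across the package."""

from __future__ import annotations


class PhenocompareError(Exception):
    """Base class for all package errors."""


class OntologyError(PhenocompareError):
    """Structural problem in an ontology file or graph."""


class CycleError(OntologyError):
    """The is_a relation contains a cycle."""

    def __init__(self, edges: list[tuple[str, str]]):
        self.edges = edges
        super().__init__(f"cycle detected in is_a edges: {edges}")


class UnknownTermError(PhenocompareError):
    """A CURIE that cannot be resolved against the loaded ontology."""

    def __init__(self, ids):
        self.ids = sorted(ids) if not isinstance(ids, str) else [ids]
        super().__init__(f"unknown term id(s): {', '.join(self.ids)}")


class ValidationError(PhenocompareError):
    """Invalid input data (malformed rows, unresolvable records, ...)."""


class DegenerateGroupError(PhenocompareError):
    """A statistical group too small or with zero variance."""


class UndefinedTestError(PhenocompareError):
    """A test whose statistic is undefined for the given counts."""
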