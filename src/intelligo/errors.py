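"""Exception types shared across the package."""


class IntelligoError(Exception):
    """Base class for all package-specific errors."""


class UnknownTermError(IntelligoError, KeyError):
    """A term accession is not present in the ontology graph."""

    def __init__(self, term_id: str):
        super().__init__(term_id)
        self.term_id = term_id

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"unknown ontology term: {self.term_id!r}"


class GraphStructureError(IntelligoError, ValueError):
    """The graph violates a rooted-DAG invariant (cycle, orphan, bad root)."""


class NotAnAncestorError(IntelligoError, ValueError):
    """A path-length query was made against a term that is not an ancestor."""


class CacheStaleError(IntelligoError, ValueError):
    """A precomputed table was built from a different graph than the one loaded."""


class CacheIncompleteError(IntelligoError, KeyError):
    """A similarity computation needed a term pair absent from the cache."""


class ParseError(IntelligoError, ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ConfigError(IntelligoError, ValueError):
    """Invalid configuration, e.g. an evidence code missing from a weight list."""


class UndefinedICError(IntelligoError, KeyError):
    """Information content requested for a term never seen in the corpus."""


class UndefinedSimilarityError(IntelligoError, ValueError):
    """A similarity or benchmark statistic is undefined for the given inputs."""
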