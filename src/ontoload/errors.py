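"""Exception hierarchy."""


class OntoloadError(Exception):
    """Base class for all package errors."""


class IndexingError(OntoloadError):
    """Flat-file indexing failed (malformed entry structure)."""


class ParseError(OntoloadError):
    """A section of a GenBank entry could not be parsed."""


class LocationParseError(ParseError):
    """A feature location string does not follow the FTv8 grammar."""


class OntologyError(OntoloadError):
    """Ontology loading or closure computation failed."""


class StatementError(OntoloadError):
    """Statement generation or execution violated an internal contract."""


class JobStateError(OntoloadError):
    """Illegal job state transition."""


class QueryError(OntoloadError):
    """Ontological query could not be compiled or executed."""
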