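"""Exception hierarchy.

``ConfigError`` maps to exit code 2 in the CLI; everything else to 1.
"""


class GowmpnError(Exception):
    """Base class for all package errors."""


class ConfigError(GowmpnError):
    """Invalid or inconsistent configuration."""


class CorpusFormatError(GowmpnError):
    """Malformed on-disk corpus record; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class SchemaError(GowmpnError):
    """A label refers to a task or class absent from the schema."""


class EmptyDocumentError(GowmpnError):
    """Document tokenized to zero tokens; carries the doc_id."""

    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        super().__init__(f"document {doc_id!r} contains no tokens after tokenization")


class GraphStructureError(GowmpnError):
    """A document graph violates a structural requirement (e.g. an isolated node)."""


class CheckpointError(GowmpnError):
    """Unreadable or version-incompatible checkpoint."""


class TrainingDivergedError(GowmpnError):
    """Training produced a non-finite loss."""
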