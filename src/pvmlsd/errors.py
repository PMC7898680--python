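"""Exception hierarchy shared across the pipeline stages."""


class PvmlsdError(Exception):
    """Base class for all package errors."""


class FormatError(PvmlsdError):
    """A file does not conform to the declared table dialect."""


class IntegrityError(PvmlsdError):
    """Data violates a structural invariant (duplicates, empty sets, mismatched pairs)."""


class TermLookupError(PvmlsdError, KeyError):
    """A preferred term or drug code is absent from its dictionary/catalog."""


class DegenerateDataError(PvmlsdError):
    """Counts or labels are degenerate (empty margin, single-class labels)."""


class InestimableError(PvmlsdError):
    """A regression model cannot be estimated (constant outcome, empty arm)."""


class SeparationError(PvmlsdError):
    """Logistic regression failed to converge, typically complete separation."""


class ParameterError(PvmlsdError):
    """A user-supplied parameter is out of range for the data at hand."""


class SchemaError(PvmlsdError):
    """Encoded feature matrices disagree on their column schema."""
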