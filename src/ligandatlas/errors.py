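"""Exception hierarchy for the ligandatlas pipeline."""


class LigandAtlasError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LigandAtlasError):
    """A file does not conform to its documented layout (e.g. missing column)."""


class ValidationError(LigandAtlasError):
    """A value violates a domain constraint (alphabet, range, vocabulary)."""


class MissingReferenceError(LigandAtlasError):
    """An identifier refers to an entity absent from the referenced table."""


class FitError(LigandAtlasError):
    """A model fit failed to converge; carries diagnostics in the message."""
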