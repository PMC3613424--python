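"""Exception hierarchy shared across sapkit modules."""


class SapkitError(Exception):
    """Base class for all sapkit errors."""


class MalformedHeaderError(SapkitError):
    """A FASTA defline's first sub-header lacks a parseable ``gi|<digits>|`` prefix."""


class EmptyRecordError(SapkitError):
    """A FASTA record has an empty sequence body."""


class MalformedLineError(SapkitError):
    """A tabular alignment line does not have exactly 12 TAB-separated fields."""


class UnknownKoError(SapkitError):
    """A GI-to-KO row references a KO absent from the KO description table."""


class BackendError(SapkitError):
    """An external search tool failed or produced unparseable output."""


class BackendUnavailableError(BackendError):
    """The configured external search executable is not on PATH."""


class PipelineError(SapkitError):
    """A pipeline-stage contract was violated (empty sub-database, id mismatch...)."""
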