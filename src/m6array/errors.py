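"""Exception hierarchy for the m6array pipeline."""


class M6ArrayError(Exception):
    """Base class for all m6array errors."""


class ConfigError(M6ArrayError):
    """Invalid configuration; the message names the offending field."""


class ParseError(M6ArrayError):
    """Malformed on-disk input; the message locates the offending cell/line."""


class SelectionError(M6ArrayError):
    """Probe selection produced an unusable result (e.g. no probes pass)."""


class NormalizationError(M6ArrayError):
    """Spike-in normalization preconditions violated."""


class UniverseMismatchError(M6ArrayError):
    """Two tables that must share a transcript universe do not."""


class PipelineError(M6ArrayError):
    """A pipeline stage failed; wraps the stage name and the cause."""
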