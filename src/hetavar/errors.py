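"""Exception hierarchy shared across the toolkit."""


class HetavarError(Exception):
    """Base class for all toolkit errors."""


class FormatError(HetavarError):
    """Malformed on-disk input (FASTA, sample sheet, qPCR table, ...)."""


class ConfigurationError(HetavarError):
    """Invalid generator or analysis configuration."""


class AnalysisError(HetavarError):
    """A computation cannot proceed on the given data."""
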