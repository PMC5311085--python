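"""Exception hierarchy."""


class SnpPanelError(Exception):
    """Base class for all package errors."""


class FormatError(SnpPanelError, ValueError):
    """Malformed input file (VCF or dosage TSV)."""


class ConfigError(SnpPanelError, ValueError):
    """Invalid configuration or parameter value."""


class UnknownIdError(SnpPanelError, KeyError):
    """A requested variant or sample id is not present."""


class PipelineError(SnpPanelError, RuntimeError):
    """A pipeline stage produced an unusable result (e.g. empty panel)."""
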