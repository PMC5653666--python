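"""Exception hierarchy shared across the pipeline.

Exit-code mapping in the CLI: ConfigurationError -> 2, ParseError -> 3,
ConservationError -> 4.
"""


class AmpindelError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(AmpindelError):
    """Invalid reference, parameters, or run configuration."""


class ParseError(AmpindelError):
    """Malformed input file (FASTQ/FASTA/config/summary)."""


class ConservationError(AmpindelError):
    """A read-count conservation identity was violated; indicates a bug."""
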