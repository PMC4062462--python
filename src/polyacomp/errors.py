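"""Exception types shared across the pipeline stages."""


class PolyacompError(Exception):
    """Base class for package errors."""


class FastaFormatError(PolyacompError):
    """Malformed FASTA input; the message names the offending line."""


class DegenerateInputError(PolyacompError):
    """Input is syntactically valid but carries no usable signal."""


class IntegrityError(PolyacompError):
    """Cross-references between pipeline stages do not line up."""


class ConfigError(PolyacompError):
    """Invalid or infeasible configuration."""
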