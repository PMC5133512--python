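"""Exception hierarchy."""


class FamGxEError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FamGxEError):
    """Invalid simulation or analysis configuration."""


class PedigreeError(FamGxEError):
    """Structurally invalid pedigree (cycles, dangling parents, mixed founder links)."""


class DesignError(FamGxEError):
    """Rank-deficient or otherwise unusable fixed-effect design."""


class ParseError(FamGxEError):
    """Malformed input file."""


class EvaluationError(FamGxEError):
    """Summary requested on an empty or degenerate result set."""
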