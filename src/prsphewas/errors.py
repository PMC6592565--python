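"""Exception hierarchy used across the pipeline."""


class PrsPhewasError(Exception):
    """Base class for all package errors."""


class ConfigError(PrsPhewasError):
    """Invalid simulation or analysis configuration."""


class DegenerateSimulationError(PrsPhewasError):
    """A simulated trait collapsed to all-cases or all-controls."""


class ParseError(PrsPhewasError):
    """Malformed input row (alleles, mapping table, dates)."""


class EstimationError(PrsPhewasError):
    """A statistical estimate could not be computed (degenerate input)."""


class LdpredDivergenceError(EstimationError):
    """The point-normal Gibbs chain diverged (sampled heritability blew up)."""
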