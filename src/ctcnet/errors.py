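"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a cohort spec, run config, or model spec is invalid."""


class DataError(ValueError):
    """Raised when input data violate a precondition (missing covariate,
    zero-variance region, rank-deficient design, ...)."""
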