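"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Raised when a study configuration or sampling specification is invalid."""


class ContractError(RuntimeError):
    """Raised when an internal precondition is violated (e.g. grid mismatch)."""
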