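"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """Invalid configuration value (non-positive size, bad state count, ...)."""


class InputError(ValueError):
    """Malformed or inconsistent input data (intervals, tracks, gene sets)."""


class GenerationError(RuntimeError):
    """Synthetic-data request that cannot be satisfied (capacity exceeded)."""
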