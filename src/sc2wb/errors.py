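"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid layout, panel, scenario or run configuration."""


class DataError(ValueError):
    """Input data that cannot be processed (missing file, shape mismatch...)."""
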