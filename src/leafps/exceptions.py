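"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when rig / scene / solver configuration is physically invalid."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage is run without its prerequisites."""
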