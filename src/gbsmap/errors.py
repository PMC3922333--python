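class GbsmapError(Exception):
    """Base class for all gbsmap errors."""


class ConfigurationError(GbsmapError):
    """Invalid user-supplied configuration (motif, thresholds, barcode set ...)."""


class GenerationError(GbsmapError):
    """The synthetic-data generator cannot satisfy the requested configuration."""


class PipelineError(GbsmapError):
    """A pipeline stage failed; partial outputs are preserved."""
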