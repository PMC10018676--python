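class InvalidConfigError(ValueError):
    """A configuration value is structurally invalid for the requested operation."""


class ShapeError(ValueError):
    """An input array has a shape the operation cannot accept."""
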