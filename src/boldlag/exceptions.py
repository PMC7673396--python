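"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument violates an operation's precondition."""


class ConstructionError(ValueError):
    """Inconsistent geometry or masks when assembling a synthetic object."""
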