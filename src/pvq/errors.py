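"""Exception types shared across the toolkit."""


class InputError(ValueError):
    """Raised when an input recording, table, or parameter violates a precondition."""


class InsufficientVoicingError(InputError):
    """Raised when a recording contains too little voiced material to measure."""
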