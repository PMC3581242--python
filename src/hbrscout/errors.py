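class InputError(ValueError):
    """Invalid user-supplied input (malformed file, bad record, bad ids)."""


class GenerationError(RuntimeError):
    """Synthetic family generation could not satisfy the configuration."""
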