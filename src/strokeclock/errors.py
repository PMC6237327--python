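"""Exception types shared across the package."""


class StrokeclockError(Exception):
    """Base class for errors raised by this package."""


class UserInputError(StrokeclockError):
    """Invalid user-supplied data or parameters (CLI exit code 1)."""
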