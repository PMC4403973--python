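"""Exception types shared across the package."""


class PyrodenoiseError(Exception):
    """Base class for package errors."""


class FormatError(PyrodenoiseError):
    """A file does not conform to its declared on-disk format."""


class StageError(PyrodenoiseError):
    """A pipeline stage failed on otherwise well-formed input."""
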