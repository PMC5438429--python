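"""Exception hierarchy shared across the package."""


class AicMaxError(Exception):
    """Base class for all package errors."""


class DegenerateTaskError(AicMaxError):
    """A classification task with only one label class.

    Raised wherever a score would divide by a zero label entropy or a
    pair task ends up with fewer than two compounds in a class.
    """


class InputFormatError(AicMaxError):
    """Malformed input file or table (non-binary cell, duplicate id, ...)."""
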