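"""Exception hierarchy.

``ValidationError`` covers precondition violations on user input (CLI exit
code 1); ``FormatError``/``VersionError`` cover malformed or unsupported
on-disk files.
"""


class ErgkitError(Exception):
    """Base class for all package errors."""


class ValidationError(ErgkitError, ValueError):
    """Invalid argument, inconsistent data or violated precondition."""


class EmptySelectionError(ValidationError):
    """An operation selected zero trials or zero recordings."""


class FormatError(ErgkitError):
    """A file does not conform to the expected layout."""


class VersionError(FormatError):
    """A file declares an unsupported format version."""
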