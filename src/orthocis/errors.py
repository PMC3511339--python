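"""Exception hierarchy shared across the package."""


class OrthocisError(Exception):
    """Base class for all package errors."""


class FormatError(OrthocisError):
    """A file does not parse under the declared dialect."""


class ValidationError(OrthocisError):
    """An in-memory object or parameter violates its contract."""


class BandError(OrthocisError):
    """The alignment band is too narrow to admit any global path."""
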