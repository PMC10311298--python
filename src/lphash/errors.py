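"""Exception hierarchy shared across the package."""


class LphashError(Exception):
    """Base class for all package-specific errors."""


class InputError(LphashError, ValueError):
    """A caller-supplied value violates a precondition."""


class ValidationError(InputError):
    """An input file or string set fails the SPSS invariants."""


class FormatError(LphashError):
    """A serialized index/structure is corrupt or incompatible."""
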