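"""Exception hierarchy shared by all impingemap modules."""


class ImpingeMapError(Exception):
    """Base class for all errors raised by impingemap."""


class InputError(ImpingeMapError):
    """A file could not be read or parsed."""


class ValidationError(ImpingeMapError):
    """Input data violates a geometric or structural invariant."""


class ContractError(ImpingeMapError):
    """A function was called with arguments violating its preconditions."""
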