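"""Exception hierarchy shared across vmbench modules."""


class VmbenchError(Exception):
    """Base class for all vmbench errors."""


class InvalidParameterError(VmbenchError, ValueError):
    """A configuration or call parameter violates its contract."""


class DegenerateInputError(VmbenchError, ValueError):
    """The input is structurally valid but the quantity is undefined on it."""


class GenerationFailureError(VmbenchError, RuntimeError):
    """A rejection-sampling loop exhausted its attempt budget."""
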