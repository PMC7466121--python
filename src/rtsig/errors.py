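"""Exception hierarchy for the rtsig package."""


class RTSigError(Exception):
    """Base class for all rtsig errors."""


class FormatError(RTSigError, ValueError):
    """An external file violates its expected format."""


class ValidationError(RTSigError, ValueError):
    """An in-memory object violates a structural invariant."""


class EmptySelectionError(RTSigError, ValueError):
    """A statistical selection matched no positions (or no mismatching bases)."""
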