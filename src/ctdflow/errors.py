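"""Exception hierarchy shared across the toolkit.

All errors that report a problem with a specific parameter carry the
parameter's full dotted path so callers can point users at the offending
element.
"""


class CTDFlowError(Exception):
    """Base class for all toolkit errors."""


class CTDParseError(CTDFlowError):
    """A CTD document is malformed or violates a descriptor invariant."""


class DescriptorError(CTDFlowError):
    """A descriptor object violates its own invariants at construction."""


class BindingError(CTDFlowError):
    """A value binding references an unknown path or fails validation."""


class GraphError(CTDFlowError):
    """A workflow graph violates a structural invariant (cycle, dangling
    channel endpoint, direction mismatch, duplicate id)."""


class PetriNetError(CTDFlowError):
    """Illegal Petri-net operation, e.g. firing a disabled transition."""


class SourceParseError(CTDFlowError):
    """A source workflow directory is incomplete or malformed."""


class ConversionRejected(CTDFlowError):
    """A conversion was refused; carries the machine-readable report."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class ToolExecutionError(CTDFlowError):
    """A wrapped tool could not be executed or exited non-zero."""

    def __init__(self, message, exit_code=None, stderr=""):
        super().__init__(message)
        self.exit_code = exit_code
        self.stderr = stderr


class BundleError(CTDFlowError):
    """A gUSE-style bundle is missing members or internally inconsistent."""
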