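"""Exception hierarchy.

``InputError`` covers malformed or inconsistent user inputs (exit code 2 in
the CLI); ``ComputationError`` covers failures arising during a computation
on valid inputs (exit code 3).
"""


class Gd2fluxError(Exception):
    """Base class for all package-specific errors."""


class InputError(Gd2fluxError):
    """Malformed, missing, or inconsistent input data."""


class ComputationError(Gd2fluxError):
    """A computation could not be carried out on otherwise valid inputs."""


class GraphStructureError(InputError):
    """A pathway definition violates the metabolic-graph invariants."""


class GprParseError(InputError):
    """A gene-protein-reaction rule string could not be parsed."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)


class ConfigurationError(InputError):
    """Inputs are individually valid but mutually inconsistent."""


class CycleError(ComputationError):
    """A cycle was encountered where the algorithm requires an acyclic walk."""
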