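"""Exception hierarchy shared across modules."""


class HpfmdError(Exception):
    """Base class for all package errors."""


class ConfigParseError(HpfmdError):
    """Malformed configuration file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TopologyError(HpfmdError):
    """Connectivity violates a structural invariant (symmetry, range, molecule membership)."""


class ModelError(HpfmdError):
    """Invalid model/parameter file content (species, χ matrix, κ, bonded terms)."""


class PartitionError(HpfmdError):
    """Invalid molecule-to-rank assignment (overlap, empty rank, split molecule)."""


class ValidationError(HpfmdError):
    """A SystemConfig or field object violates its invariants."""


class SimulationError(HpfmdError):
    """Runtime integration failure (non-finite state, degenerate geometry)."""
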