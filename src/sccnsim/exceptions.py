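"""Exception hierarchy used across the simulator."""


class SccnsimError(Exception):
    """Base class for all package errors."""


class ParameterError(SccnsimError, ValueError):
    """A parameter is out of range or of the wrong type."""


class ConfigError(SccnsimError, ValueError):
    """Aggregated configuration validation failure.

    ``messages`` holds one entry per offending field so a user can fix
    everything in one pass.
    """

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.messages))


class InfeasibleSubcloneError(SccnsimError):
    """Raised when fewer disjoint clades exist than subclones requested."""

    def __init__(self, requested, achievable):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"requested {requested} disjoint subclone clades but at most "
            f"{achievable} are achievable on this tree"
        )


class ContractViolationError(SccnsimError):
    """An event references coordinates outside the current allele sequence."""
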