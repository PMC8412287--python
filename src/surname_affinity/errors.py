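"""Exception hierarchy shared across the pipeline stages."""


class SurnameAffinityError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SurnameAffinityError, ValueError):
    """A configuration or argument value violates its contract."""


class DegenerateInputError(SurnameAffinityError, ValueError):
    """Input is structurally valid but mathematically degenerate
    (e.g. constant vector passed to min-max normalization)."""


class DataIntegrityError(SurnameAffinityError, KeyError):
    """Cross-referenced records are inconsistent (missing occurrence
    counts, partition not covering the graph, ...)."""


class CapacityError(SurnameAffinityError, ValueError):
    """More items requested than the combinatorial space holds."""


class EmptyResultError(SurnameAffinityError, RuntimeError):
    """A filtering pipeline removed everything; carries stage diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class TrainingError(SurnameAffinityError, RuntimeError):
    """Optimization diverged; carries the epoch/batch diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
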