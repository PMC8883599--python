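"""Exception hierarchy shared across the package."""


class DairySwapError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DairySwapError):
    """A required column or config key is missing or malformed."""


class IntegrityError(DairySwapError):
    """A table-level integrity rule is violated (e.g. duplicate codes)."""


class ValidationError(DairySwapError, ValueError):
    """A value violates a documented precondition or invariant."""


class EstimationError(DairySwapError):
    """A regression / estimation problem is ill-posed."""


class SpecificationError(DairySwapError):
    """An optimisation problem cannot be built from the given inputs."""


class StateError(DairySwapError):
    """An operation was called on a result in the wrong state."""


class SizeError(DairySwapError):
    """A problem exceeds the size limits of an exact method."""


class GenerationError(DairySwapError):
    """A synthetic instance could not be constructed."""


class ScenarioError(DairySwapError):
    """A scenario run failed; carries the scenario label."""

    def __init__(self, label: str, message: str):
        super().__init__(f"[{label}] {message}")
        self.label = label
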