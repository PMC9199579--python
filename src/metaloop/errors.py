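"""Exception hierarchy shared across the framework."""


class MetaloopError(Exception):
    """Base class for all framework errors."""


class ConfigurationError(MetaloopError):
    """A run/optimizee/optimizer configuration is invalid or incomplete."""


class ContractError(MetaloopError):
    """An optimizee or optimizer violated the inner/outer-loop contract."""


class EvaluationError(MetaloopError):
    """A single simulation (inner-loop evaluation) failed."""


class TrajectoryLoadError(MetaloopError):
    """A persisted trajectory could not be read back.

    ``generation`` names the first generation whose record failed to load,
    or ``None`` when the file header itself is unreadable.
    """

    def __init__(self, message: str, generation: int | None = None):
        self.generation = generation
        if generation is not None:
            message = f"{message} (generation {generation})"
        super().__init__(message)
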