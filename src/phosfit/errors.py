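"""Exception hierarchy.

All user-facing failures derive from :class:`PhosfitError` so the CLI can map
them to exit code 1; anything else is an internal error (exit code 2).
"""


class PhosfitError(Exception):
    """Base class for all phosfit errors."""


class ParameterError(PhosfitError, ValueError):
    """An argument violates a documented precondition."""


class DomainError(PhosfitError, ValueError):
    """A physical quantity lies outside the valid domain of a formula."""


class SpectralWindowError(PhosfitError, ValueError):
    """A resonance or analysis window falls outside the acquired bandwidth."""


class FitError(PhosfitError, RuntimeError):
    """Spectral fitting could not be set up or is degenerate."""


class PipelineError(PhosfitError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str, replay: str | None = None):
        self.stage = stage
        self.replay = replay
        hint = f" (replay: {replay})" if replay else ""
        super().__init__(f"stage '{stage}' failed: {message}{hint}")
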