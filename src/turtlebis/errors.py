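"""Exception hierarchy shared across the pipeline stages."""


class TurtleBISError(Exception):
    """Base class for all package errors."""


class ArgumentError(TurtleBISError, ValueError):
    """Invalid argument or precondition violation."""


class GenerationError(TurtleBISError, RuntimeError):
    """Synthetic cohort or phantom generation failed (e.g. infeasible target)."""


class FitError(TurtleBISError, RuntimeError):
    """Regression fit failed (e.g. rank-deficient design)."""


class ConsistencyError(TurtleBISError, RuntimeError):
    """Masks or derived quantities violate a structural invariant."""


class ConvergenceError(TurtleBISError, RuntimeError):
    """A numeric solver failed to converge below its cap."""


class PipelineError(TurtleBISError, RuntimeError):
    """A pipeline stage aborted; message carries the stage name."""
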