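"""Exception types shared across the package."""


class HetrwrError(Exception):
    """Base class for all package-specific errors."""


class UnknownTermError(HetrwrError, KeyError):
    """A term/entity identifier is absent from the ontology or registry."""


class ParameterError(HetrwrError, ValueError):
    """A model parameter violates its documented constraint."""


class DegenerateKernelError(HetrwrError, ValueError):
    """All interaction profiles along an axis are zero; the GIP bandwidth is undefined."""


class ConvergenceError(HetrwrError, RuntimeError):
    """The restart walk failed to reach the L1 tolerance within max_iter."""

    def __init__(self, iterations: int, residual: float, tol: float):
        self.iterations = iterations
        self.residual = residual
        self.tol = tol
        super().__init__(
            f"walk did not converge: residual {residual:.3e} > tol {tol:.3e} "
            f"after {iterations} iterations"
        )


class InputFormatError(HetrwrError, ValueError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(f"{loc}{message}")
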