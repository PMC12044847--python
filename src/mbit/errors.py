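"""Exception hierarchy."""


class MbitError(Exception):
    """Base class for all package errors."""


class InvalidCellError(MbitError):
    pass


class SymmetryError(MbitError):
    pass


class ConfigurationError(MbitError):
    pass


class DataError(MbitError):
    pass


class ReflectionSetTooLarge(MbitError):
    pass


class RefinementError(MbitError):
    pass


class NonConvergenceError(RefinementError):
    pass


class TmmpError(RefinementError):
    """Failure inside the staged theoretical-multipole-parameter fit."""

    def __init__(self, stage: int, message: str):
        self.stage = stage
        super().__init__(f"tMMP stage {stage}: {message}")


class LoopError(MbitError):
    """Failure inside the iterative refinement loop."""

    def __init__(self, cycle: int, message: str):
        self.cycle = cycle
        super().__init__(f"cycle {cycle}: {message}")


class CriticalPointError(MbitError):
    pass


class ParseError(MbitError):
    pass
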