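"""Exception types shared across the package."""


class GjpropError(Exception):
    """Base class for package errors."""


class IntegrationDivergenceError(GjpropError):
    """Membrane-potential integration produced a non-finite value."""

    def __init__(self, time_ms: float, cell: int | None = None):
        self.time_ms = time_ms
        self.cell = cell
        where = f" (cell {cell})" if cell is not None else ""
        super().__init__(f"integration diverged at t = {time_ms:.3f} ms{where}")


class NoPropagationError(GjpropError):
    """No cell outside the stimulated zone was recruited."""


class DegenerateWaveError(GjpropError):
    """Propagation timing is degenerate (non-positive latency difference)."""


class NoPeakError(GjpropError):
    """No qualifying peak found in a peristimulus histogram."""


class FitFailureError(GjpropError):
    """A curve fit could not be performed on degenerate data."""


class FeatureUndefinedError(GjpropError):
    """A waveform snippet lacks the valley/peak structure required."""


class UndefinedResultError(GjpropError):
    """A statistic is undefined on the given input (e.g. empty segment)."""
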