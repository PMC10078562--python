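"""Core domain containers and error hierarchy.

Coordinate convention, used everywhere in this package: ``x`` is the
medio-lateral (ML, side-to-side) COP coordinate and ``y`` the
anterior-posterior (AP, front-to-back) coordinate, both in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ML = "ML"
AP = "AP"


class DataError(ValueError):
    """Input data violates a validity invariant (non-finite, too short...)."""


class FormatError(ValueError):
    """A file does not conform to the package's on-disk formats."""


class DesignError(ValueError):
    """A label or cell is not part of the declared study design."""


class DegenerateInputError(ValueError):
    """The computation is undefined for this input (constant series, ...)."""


@dataclass(frozen=True)
class CopTrial:
    """One quiet-standing centre-of-pressure recording with design labels."""

    subject: str
    inhalation_type: str
    timepoint: str
    rep: int
    sampling_rate: float
    x: np.ndarray  # medio-lateral, mm
    y: np.ndarray  # anterior-posterior, mm

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise DataError("x and y must be 1-D series of equal length")
        if len(x) < 2:
            raise DataError("a COP trial needs at least 2 samples")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise DataError("COP coordinates must be finite")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def coordinate(self, direction: str) -> np.ndarray:
        """Return the series for a sway direction (``ML`` or ``AP``)."""
        if direction == ML:
            return self.x
        if direction == AP:
            return self.y
        raise DesignError(f"unknown sway direction {direction!r}")


@dataclass(frozen=True)
class RespSignal:
    """A respiration transducer trace (arbitrary voltage units)."""

    samples: np.ndarray
    sampling_rate: float
    condition: str = ""
    phase: str = ""
    window_bounds: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 1 or len(s) == 0:
            raise DataError("samples must be a non-empty 1-D series")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        dur = len(s) / self.sampling_rate
        for start, end in self.window_bounds:
            if not (0 <= start < end <= dur + 1e-9):
                raise DataError(
                    f"window ({start}, {end}) s outside record of {dur:.3f} s"
                )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass(frozen=True)
class SwayMetrics:
    """Sway path lengths of one trial, in millimetres."""

    ml_path: float
    ap_path: float
    total_path: float
    n_increments: int

    def __post_init__(self) -> None:
        eps = 1e-9 * max(1.0, self.total_path)
        if min(self.ml_path, self.ap_path, self.total_path) < 0:
            raise DataError("path lengths must be non-negative")
        if self.total_path + eps < max(self.ml_path, self.ap_path):
            raise DataError("total path below a per-axis path")
        if self.total_path > self.ml_path + self.ap_path + eps:
            raise DataError("total path above the sum of per-axis paths")


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters for one sway direction."""

    delay: int
    dimension: int
    direction: str = ""

    def __post_init__(self) -> None:
        if self.delay < 1 or self.dimension < 1:
            raise DataError("delay and dimension must be >= 1")


@dataclass(frozen=True)
class DivergenceCurve:
    """Mean log nearest-neighbour divergence versus time, with its slope.

    ``slope`` is the largest Lyapunov exponent estimate (1/s), the
    least-squares slope of ``mean_log_divergence`` against ``times`` over
    ``fit_window``.  Larger slope = faster divergence = lower local
    dynamic stability.
    """

    times: np.ndarray  # s, starting at 0
    mean_log_divergence: np.ndarray
    n_pairs: np.ndarray
    fit_window: tuple[float, float]
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise DataError("times must increase strictly from 0")
        if np.any(np.diff(np.asarray(self.n_pairs)) > 0):
            raise DataError("n_pairs must be non-increasing in time")
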