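"""Pattern quantification: amplitude, covariance, structure factor, length scale.

The dominant length scale is read off the peak of the structure factor of the
mean-subtracted field (radially averaged in 2D); a peak counts as significant
only if it exceeds ``peak_significance`` times the spectral median, so
noise-dominated spectra yield "no defined length" rather than a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .simulator import FieldState

__all__ = [
    "StructureFactor",
    "PatternMetrics",
    "NoSignificantPeakError",
    "amplitude",
    "covariance",
    "structure_factor",
    "dominant_length",
    "try_dominant_length",
    "pattern_metrics",
    "pattern_metrics_triple",
    "scaling_exponent",
]

#: peak must exceed this multiple of the spectral median to define a length
PEAK_SIGNIFICANCE = 10.0


class NoSignificantPeakError(RuntimeError):
    """The structure factor has no significant nonzero-q peak."""


@dataclass
class StructureFactor:
    """Spectral power of a mean-subtracted field over nonzero wavenumber bins."""

    q: np.ndarray
    S: np.ndarray

    def to_csv(self, path: Union[str, Path]) -> None:
        np.savetxt(path, np.column_stack([self.q, self.S]), delimiter=",", header="q,S", comments="")


@dataclass
class PatternMetrics:
    """Summary of a stationary pattern; ``length`` is None when undefined."""

    amplitude: float
    covariance: float
    length: Optional[float]


def amplitude(field: np.ndarray) -> float:
    """Half the peak-to-peak range of the field."""
    field = np.asarray(field)
    if field.size == 0:
        raise ValueError("field must be nonempty")
    return 0.5 * float(field.max() - field.min())


def covariance(a, b=None) -> float:
    """Spatial covariance ``<a b> - <a><b>``; accepts a FieldState or two fields."""
    if b is None:
        if not isinstance(a, FieldState):
            raise TypeError("single-argument form requires a FieldState")
        a, b = a.phiA, a.phiI
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fields must share a grid")
    return float(np.mean(a * b) - np.mean(a) * np.mean(b))


def structure_factor(field: np.ndarray, dx: float = 1.0) -> StructureFactor:
    """Discrete Fourier power of the mean-subtracted field, q=0 excluded.

    Power is normalized by the number of cells.  In 2D the power is averaged
    over annular bins of width ``2 pi / L`` anchored at ``q = 2 pi / L``
    (one Fourier shell per bin on a square box).
    """
    field = np.asarray(field, dtype=float)
    if any(s < 8 for s in field.shape):
        raise ValueError("field needs at least 8 points per axis")
    delta = field - field.mean()
    n_cells = field.size
    if field.ndim == 1:
        N = field.shape[0]
        F = np.fft.rfft(delta)
        S = np.abs(F) ** 2 / n_cells
        q = 2.0 * np.pi * np.arange(len(F)) / (N * dx)
        return StructureFactor(q=q[1:], S=S[1:])
    if field.ndim == 2:
        if field.shape[0] != field.shape[1]:
            raise ValueError("2D structure factor requires a square box")
        N = field.shape[0]
        F = np.fft.fft2(delta)
        P = np.abs(F) ** 2 / n_cells
        m = np.fft.fftfreq(N, d=1.0 / N)  # integer mode numbers
        mm = np.sqrt(m[:, None] ** 2 + m[None, :] ** 2)
        ring = np.rint(mm).astype(int)
        n_bins = N // 2
        S = np.zeros(n_bins)
        for r in range(1, n_bins + 1):
            mask = ring == r
            S[r - 1] = P[mask].mean() if np.any(mask) else 0.0
        q = 2.0 * np.pi * np.arange(1, n_bins + 1) / (N * dx)
        return StructureFactor(q=q, S=S)
    raise ValueError("only 1D and 2D fields are supported")


def dominant_length(
    field: np.ndarray,
    dx: float = 1.0,
    peak_significance: float = PEAK_SIGNIFICANCE,
    refine: bool = False,
) -> float:
    """Dominant pattern wavelength ``2 pi / q_peak`` from the structure factor.

    ``q_peak`` is the discrete argmax bin (ties resolve to the smallest q).
    With ``refine=True`` a 3-point log-parabolic interpolation around the
    peak is applied.  Raises :class:`NoSignificantPeakError` when the peak
    does not stand out from the spectral median.
    """
    sf = structure_factor(field, dx)
    i = int(np.argmax(sf.S))  # argmax returns the first (smallest-q) maximum
    med = float(np.median(sf.S))
    if sf.S[i] <= peak_significance * med or sf.S[i] <= 0.0:
        raise NoSignificantPeakError(
            f"no significant spectral peak (max {sf.S[i]:.3e} vs median {med:.3e})"
        )
    q_peak = sf.q[i]
    if refine and 0 < i < len(sf.S) - 1 and sf.S[i - 1] > 0 and sf.S[i + 1] > 0:
        lm, l0, lp = np.log(sf.S[i - 1]), np.log(sf.S[i]), np.log(sf.S[i + 1])
        denom = lm - 2.0 * l0 + lp
        if denom < 0.0:
            shift = 0.5 * (lm - lp) / denom
            q_peak = sf.q[i] + shift * (sf.q[min(i + 1, len(sf.q) - 1)] - sf.q[i])
    return 2.0 * np.pi / float(q_peak)


def try_dominant_length(field: np.ndarray, dx: float = 1.0, **kwargs) -> Optional[float]:
    """Like :func:`dominant_length`, returning None when undefined."""
    try:
        return dominant_length(field, dx, **kwargs)
    except NoSignificantPeakError:
        return None


def pattern_metrics(state: FieldState) -> PatternMetrics:
    """Amplitude, covariance and dominant length of a state (length may be None)."""
    return PatternMetrics(
        amplitude=amplitude(state.phiA),
        covariance=covariance(state),
        length=try_dominant_length(state.phiA, state.grid.dx),
    )


def pattern_metrics_triple(state: FieldState) -> tuple:
    """(amplitude, covariance, length-or-nan) tuple for stationarity checks."""
    m = pattern_metrics(state)
    return (m.amplitude, m.covariance, m.length if m.length is not None else np.nan)


def scaling_exponent(pairs: Sequence[tuple]) -> tuple[float, float]:
    """Least-squares slope of log(l) vs log(k), with its standard error.

    ``pairs`` is a sequence of ``(k, l)`` with strictly positive entries;
    at least 3 pairs are required.
    """
    pairs = [(float(k), float(l)) for k, l in pairs]
    if len(pairs) < 3:
        raise ValueError("need at least 3 (k, length) pairs")
    k, l = np.asarray(pairs).T
    if np.any(k <= 0) or np.any(l <= 0):
        raise ValueError("all values must be positive")
    res = stats.linregress(np.log(k), np.log(l))
    return float(res.slope), float(res.stderr)
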