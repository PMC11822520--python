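"""Per-spectrum figure-of-merit quality index (Q_i).

For each configured peak, the index takes the mean intensity in a small
window about the peak position p and subtracts the mean of the two baseline
windows b1 and b2 (each window spanning +/- n grid points).  With t peaks,
the per-peak baseline-subtracted means are combined as a geometric mean
(their product raised to 1/t); any nonpositive factor clips the whole index
to 0, so Q_i >= 0 always.  With the default single peak (p = 792 cm^-1,
b1 = b2 = 723 cm^-1) this reduces to the baseline-subtracted 792 cm^-1
window mean, clipped at zero.

Q_i is a background-robust surrogate for analyte signal strength: adding a
constant offset to a spectrum leaves it unchanged, and for t = 1 scaling
the spectrum scales Q_i proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .spectra import SpectralMap, Spectrum, nearest_index

__all__ = ["QiConfig", "window_mean", "compute_qi", "compute_qi_map"]


@dataclass(frozen=True)
class QiConfig:
    """Peak/baseline positions (cm^-1) and averaging half-window (grid points).

    ``peaks`` is a list of (p, b1, b2) triples; ``half_window`` is n, the
    number of neighbors averaged on each side of a position (windows are
    clipped at the axis edges).
    """

    peaks: tuple[tuple[float, float, float], ...] = ((792.0, 723.0, 723.0),)
    half_window: int = 2

    def __post_init__(self) -> None:
        if len(self.peaks) < 1:
            raise ConfigurationError("at least one peak definition is required")
        if self.half_window < 0:
            raise ConfigurationError("half_window must be nonnegative")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def _window_bounds(wavenumbers: np.ndarray, center: float, n: int) -> tuple[int, int]:
    i = nearest_index(wavenumbers, center)
    return max(0, i - n), min(wavenumbers.size, i + n + 1)


def window_mean(spectrum: Spectrum, center: float, n: int) -> float:
    """Mean intensity over the nearest grid point to ``center`` +/- n points."""
    lo, hi = _window_bounds(spectrum.wavenumbers, center, n)
    return float(spectrum.intensities[lo:hi].mean())


def compute_qi(spectrum: Spectrum, cfg: QiConfig = QiConfig()) -> float:
    """Quality index of one spectrum (always >= 0)."""
    factors = []
    for p, b1, b2 in cfg.peaks:
        s = window_mean(spectrum, p, cfg.half_window) - 0.5 * (
            window_mean(spectrum, b1, cfg.half_window)
            + window_mean(spectrum, b2, cfg.half_window)
        )
        if s <= 0:
            return 0.0
        factors.append(s)
    return float(np.prod(factors) ** (1.0 / cfg.n_peaks))


def compute_qi_map(smap: SpectralMap, cfg: QiConfig = QiConfig()) -> np.ndarray:
    """Quality index of every spectrum in a map, in raster order.

    Vectorized over spectra; exactly equivalent to calling
    :func:`compute_qi` row by row.
    """
    w = smap.wavenumbers
    y = smap.intensities
    factors = np.empty((cfg.n_peaks, smap.n_spectra))
    for k, (p, b1, b2) in enumerate(cfg.peaks):
        plo, phi = _window_bounds(w, p, cfg.half_window)
        b1lo, b1hi = _window_bounds(w, b1, cfg.half_window)
        b2lo, b2hi = _window_bounds(w, b2, cfg.half_window)
        factors[k] = y[:, plo:phi].mean(axis=1) - 0.5 * (
            y[:, b1lo:b1hi].mean(axis=1) + y[:, b2lo:b2hi].mean(axis=1)
        )
    positive = np.all(factors > 0, axis=0)
    qi = np.zeros(smap.n_spectra)
    if positive.any():
        qi[positive] = np.prod(factors[:, positive], axis=0) ** (1.0 / cfg.n_peaks)
    return qi
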