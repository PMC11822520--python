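"""Core in-memory containers for spectral-map experiments.

A :class:`Spectrum` is the atomic measurement: a strictly ascending
wavenumber axis (cm^-1) and one intensity vector (detector counts).  A
:class:`SpectralMap` holds all spectra acquired from one well of the plate,
row-stacked on a single shared axis together with their raster coordinates.
A :class:`PlateDesign` records how wells map onto samples (analyte
concentrations in ng/mL, plus a matrix blank), and a :class:`Plate` bundles
a design with its per-well maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from string import ascii_uppercase
from typing import Iterator, Mapping

import numpy as np

from .errors import ConsistencyError, SpectralRangeError

__all__ = [
    "Spectrum",
    "SpectralMap",
    "Sample",
    "PlateDesign",
    "Plate",
    "nearest_index",
    "well_name",
]


def nearest_index(wavenumbers: np.ndarray, center: float) -> int:
    """Index of the grid point nearest ``center``; ties go to the lower wavenumber.

    Raises :class:`SpectralRangeError` if ``center`` lies outside the axis.
    """
    w = np.asarray(wavenumbers)
    if center < w[0] or center > w[-1]:
        raise SpectralRangeError(
            f"position {center} cm^-1 outside axis range [{w[0]}, {w[-1]}]"
        )
    j = int(np.searchsorted(w, center))
    if j == 0:
        return 0
    if j == len(w):
        return len(w) - 1
    # tie (equidistant) breaks toward the lower wavenumber
    return j - 1 if center - w[j - 1] <= w[j] - center else j


@dataclass(frozen=True, eq=False)
class Spectrum:
    """One wavenumber axis + intensity vector."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if w.shape != y.shape:
            raise ValueError(
                f"axis length {w.shape[0]} != intensity length {y.shape[0]}"
            )
        if w.size == 0:
            raise ValueError("spectrum must contain at least one point")
        if w.size > 1 and not np.all(np.diff(w) > 0):
            raise ValueError("wavenumber axis must be strictly ascending")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(y)):
            raise ValueError("spectrum values must be finite")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavenumbers, intensities)


@dataclass(eq=False)
class SpectralMap:
    """All spectra of one well, sharing a single wavenumber axis.

    ``intensities`` has shape ``(n_spectra, n_points)``; ``coordinates``
    has shape ``(n_spectra, 2)`` with integer (line, position) raster indices.
    """

    well_id: str
    wavenumbers: np.ndarray
    intensities: np.ndarray
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        c = np.asarray(self.coordinates, dtype=int)
        if w.ndim != 1 or y.ndim != 2 or c.ndim != 2 or c.shape[1] != 2:
            raise ValueError("bad array shapes for SpectralMap")
        if y.shape[1] != w.size:
            raise ValueError("intensity rows must match axis length")
        if y.shape[0] != c.shape[0]:
            raise ValueError("one coordinate pair required per spectrum")
        if w.size > 1 and not np.all(np.diff(w) > 0):
            raise ValueError("wavenumber axis must be strictly ascending")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        self.wavenumbers = w
        self.intensities = y
        self.coordinates = c

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.intensities[i])

    def spectra(self) -> Iterator[Spectrum]:
        for i in range(self.n_spectra):
            yield self.spectrum(i)

    def subset(self, indices: np.ndarray) -> "SpectralMap":
        idx = np.asarray(indices, dtype=int)
        return SpectralMap(
            self.well_id,
            self.wavenumbers,
            self.intensities[idx],
            self.coordinates[idx],
        )


def well_name(row: int, col: int) -> str:
    """Canonical well id, e.g. row 0 / col 0 -> ``A1``."""
    if row >= len(ascii_uppercase):
        raise ValueError("plate rows beyond Z are not supported")
    return f"{ascii_uppercase[row]}{col + 1}"


@dataclass(frozen=True)
class Sample:
    """A plate sample: a spiked concentration (ng/mL) or the matrix blank.

    ``index`` is the concentration index n: 0 for the highest concentration,
    increasing toward the blank (which carries the last index and
    concentration 0).
    """

    label: str
    concentration: float
    index: int

    @property
    def is_blank(self) -> bool:
        return self.concentration == 0.0


@dataclass
class PlateDesign:
    """Well -> sample assignment for an ``rows x cols`` plate."""

    rows: int
    cols: int
    samples: tuple[Sample, ...]
    well_to_sample: dict[str, int]
    replicate_wells_per_sample: int

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("plate must have positive dimensions")
        counts = {s.index: 0 for s in self.samples}
        for sample_idx in self.well_to_sample.values():
            if sample_idx not in counts:
                raise ConsistencyError(f"well assigned to unknown sample {sample_idx}")
            counts[sample_idx] += 1
        for idx, n in counts.items():
            if n != self.replicate_wells_per_sample:
                raise ConsistencyError(
                    f"sample index {idx} has {n} wells, expected "
                    f"{self.replicate_wells_per_sample}"
                )
        indices = sorted(s.index for s in self.samples)
        if indices != list(range(len(self.samples))):
            raise ConsistencyError("sample indices must be contiguous from 0")

    @property
    def well_ids(self) -> list[str]:
        return list(self.well_to_sample)

    @property
    def n_wells(self) -> int:
        return len(self.well_to_sample)

    def sample(self, index: int) -> Sample:
        for s in self.samples:
            if s.index == index:
                return s
        raise KeyError(index)

    def sample_of(self, well_id: str) -> Sample:
        return self.sample(self.well_to_sample[well_id])

    def wells_for(self, sample_index: int) -> list[str]:
        return [w for w, s in self.well_to_sample.items() if s == sample_index]

    @property
    def blank_sample(self) -> Sample | None:
        for s in self.samples:
            if s.is_blank:
                return s
        return None

    @property
    def nonblank_samples(self) -> list[Sample]:
        return sorted((s for s in self.samples if not s.is_blank), key=lambda s: s.index)


@dataclass
class Plate:
    """A design plus the spectral map of every well."""

    design: PlateDesign
    maps: dict[str, SpectralMap] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [w for w in self.design.well_ids if w not in self.maps]
        extra = [w for w in self.maps if w not in self.design.well_to_sample]
        if missing or extra:
            raise ConsistencyError(
                f"design/map well mismatch (missing={missing}, extra={extra})"
            )

    @property
    def n_spectra(self) -> int:
        return sum(m.n_spectra for m in self.maps.values())

    def maps_for(self, sample_index: int) -> list[SpectralMap]:
        return [self.maps[w] for w in self.design.wells_for(sample_index)]
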