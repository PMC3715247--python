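"""Wavelength grids and sampled spectra.

Two grids recur throughout the pipeline: the 25-band reconstruction grid
(450-690 nm, 10 nm step) on which full reflectance spectra are recovered
from RGB, and the 6-band estimation grid (500-600 nm, 20 nm step) on which
chromophore regression operates.  The estimation grid is an exact subset of
the reconstruction grid, so band extraction is index selection, never
interpolation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = ["SpectralGrid", "Spectrum"]


@dataclass(frozen=True)
class SpectralGrid:
    """A strictly increasing, uniformly spaced wavelength axis in nm."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("grid needs at least two wavelengths")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("wavelength step must be uniform")
        object.__setattr__(self, "wavelengths", wl)

    @classmethod
    def reconstruction(cls) -> "SpectralGrid":
        """450-690 nm at 10 nm: the 25 bands recovered by Wiener estimation."""
        return cls(np.arange(450.0, 691.0, 10.0))

    @classmethod
    def estimation(cls) -> "SpectralGrid":
        """500-600 nm at 20 nm: the 6 bands used for chromophore regression."""
        return cls(np.arange(500.0, 601.0, 20.0))

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return (
            self.wavelengths.shape == other.wavelengths.shape
            and bool(np.allclose(self.wavelengths, other.wavelengths, rtol=0, atol=1e-9))
        )

    def __hash__(self) -> int:
        return hash((self.wavelengths.size, self.wavelengths[0], self.wavelengths[-1]))

    def index_of(self, wavelength: float) -> int:
        """Index of an exactly matching wavelength (to 1e-6 nm)."""
        hits = np.nonzero(np.isclose(self.wavelengths, wavelength, rtol=0, atol=1e-6))[0]
        if hits.size == 0:
            raise KeyError(f"{wavelength} nm not on grid")
        return int(hits[0])

    def indices_in(self, sub: "SpectralGrid") -> np.ndarray:
        """Indices selecting every wavelength of `sub` out of this grid."""
        return np.array([self.index_of(w) for w in sub.wavelengths])


@dataclass
class Spectrum:
    """Reflectance values sampled on a :class:`SpectralGrid`.

    Values are dimensionless reflectances normalized to a white standard.
    Negative values are tolerated because linear reconstruction can
    undershoot; downstream absorbance computation guards against them.
    """

    grid: SpectralGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != len(self.grid):
            raise ValueError(
                f"spectrum length {v.size} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        self.values = v

    def __len__(self) -> int:
        return int(self.values.size)

    def subsample(self, sub: SpectralGrid) -> "Spectrum":
        """Restrict to a coarser grid whose wavelengths lie on this grid."""
        return Spectrum(sub, self.values[self.grid.indices_in(sub)])


def as_values(r: "Spectrum | Iterable[float] | np.ndarray") -> np.ndarray:
    if isinstance(r, Spectrum):
        return r.values
    return np.asarray(r, dtype=float)
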