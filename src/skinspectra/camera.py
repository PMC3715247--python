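"""RGB camera forward model.

A trichromatic camera observing a reflectance spectrum r(lambda) under an
illuminant E(lambda) with sensor sensitivity S(lambda) and channel filter
transmittances u_i(lambda) produces linear responses

    v_i = sum_lambda u_i(lambda) E(lambda) S(lambda) r(lambda),

i.e. v = F r with the 3 x k system matrix F whose row i is the elementwise
product u_i * E * S on the discrete grid.  The discrete sum carries no
delta-lambda factor: the constant is absorbed into the Wiener training and
cancels through the pipeline.

Camera responses are treated as linear after white-standard normalization
(each channel divided by the white-diffuser response).  Gamma decoding, if a
source image needs it, is a pre-processing option (`decode_gamma`), off by
default.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import SpectralGrid, Spectrum, as_values

__all__ = [
    "CameraSystem",
    "build_system_matrix",
    "simulate_camera_response",
    "decode_gamma",
]


@dataclass
class CameraSystem:
    """Spectral description of illumination and sensing.

    ``filter_transmittances`` has shape (3, k) with rows ordered R, G, B
    (channel index i = 1, 2, 3 of the forward model).
    """

    grid: SpectralGrid
    filter_transmittances: np.ndarray = field(repr=False)
    illuminant: np.ndarray = field(repr=False)
    sensitivity: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        k = len(self.grid)
        u = np.asarray(self.filter_transmittances, dtype=float)
        e = np.asarray(self.illuminant, dtype=float)
        s = np.asarray(self.sensitivity, dtype=float)
        if u.shape != (3, k):
            raise ValueError(f"filter transmittances must be (3, {k}), got {u.shape}")
        if e.shape != (k,) or s.shape != (k,):
            raise ValueError("illuminant and sensitivity must match the grid length")
        for name, arr in (("filters", u), ("illuminant", e), ("sensitivity", s)):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and nonnegative")
        self.filter_transmittances = u
        self.illuminant = e
        self.sensitivity = s

    # -- CSV profile format: wavelength_nm, filter_r, filter_g, filter_b,
    #    illuminant, sensitivity (header required) --
    @classmethod
    def from_csv(cls, path: str | Path) -> "CameraSystem":
        df = pd.read_csv(path, comment="#")
        grid = SpectralGrid(df["wavelength_nm"].to_numpy(dtype=float))
        u = df[["filter_r", "filter_g", "filter_b"]].to_numpy(dtype=float).T
        return cls(
            grid=grid,
            filter_transmittances=u,
            illuminant=df["illuminant"].to_numpy(dtype=float),
            sensitivity=df["sensitivity"].to_numpy(dtype=float),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "wavelength_nm": self.grid.wavelengths,
                "filter_r": self.filter_transmittances[0],
                "filter_g": self.filter_transmittances[1],
                "filter_b": self.filter_transmittances[2],
                "illuminant": self.illuminant,
                "sensitivity": self.sensitivity,
            }
        )
        df.to_csv(path, index=False)

    def system_matrix(self) -> np.ndarray:
        return build_system_matrix(self)


def build_system_matrix(camera: CameraSystem) -> np.ndarray:
    """3 x k system matrix F: row i = u_i * E * S elementwise."""
    return camera.filter_transmittances * camera.illuminant * camera.sensitivity


def simulate_camera_response(F: np.ndarray, r: Spectrum | np.ndarray) -> np.ndarray:
    """Linear camera response v = F r (length 3)."""
    F = np.asarray(F, dtype=float)
    values = as_values(r)
    if F.ndim != 2 or F.shape[0] != 3:
        raise ValueError(f"system matrix must be 3 x k, got {F.shape}")
    if values.shape != (F.shape[1],):
        raise ValueError(
            f"spectrum length {values.shape} does not match system matrix columns {F.shape[1]}"
        )
    return F @ values


def decode_gamma(image: np.ndarray, gamma: float = 2.2) -> np.ndarray:
    """Invert a power-law encoding on an image already scaled to [0, 1]."""
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("gamma decoding expects nonnegative values")
    return image ** gamma
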