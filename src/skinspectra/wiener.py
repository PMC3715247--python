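"""Wiener estimation of reflectance spectra from RGB responses.

The Wiener matrix is the linear minimum-mean-squared-error reconstructor

    W = <r r^T> F^T (F <r r^T> F^T)^{-1}

built from the ensemble autocorrelation matrix <r r^T> of plausible skin
spectra (a second-order prior) and the camera system matrix F.  Applying
r_est = W v per pixel turns one RGB frame into a k-band reflectance stack.

Reconstruction quality is scored with the goodness-of-fit coefficient
(GFC), the normalized inner product of measured and estimated spectra;
GFC > 0.995 is the conventional colorimetric-accuracy bound and
GFC >= 0.999 an excellent fit.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .camera import CameraSystem, build_system_matrix, simulate_camera_response
from .grids import SpectralGrid, Spectrum, as_values

__all__ = [
    "WienerModel",
    "compute_autocorrelation",
    "compute_wiener_matrix",
    "reconstruct_spectrum",
    "reconstruct_image",
    "gfc",
    "load_ensemble_csv",
    "save_ensemble_csv",
    "write_spectral_stack",
]

#: condition number of the 3x3 Gram matrix above which the direct solve is
#: abandoned for a Moore-Penrose pseudo-inverse
GRAM_CONDITION_LIMIT = 1e12


def _ensemble_matrix(ensemble: "Sequence[Spectrum] | np.ndarray") -> tuple[np.ndarray, SpectralGrid | None]:
    if isinstance(ensemble, np.ndarray):
        X = np.asarray(ensemble, dtype=float)
        if X.ndim != 2:
            raise ValueError("ensemble array must be 2-D (samples x wavelengths)")
        return X, None
    spectra = list(ensemble)
    if not spectra:
        raise ValueError("ensemble is empty")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise ValueError("ensemble spectra are on mixed grids")
    return np.stack([s.values for s in spectra]), grid


def compute_autocorrelation(ensemble: "Sequence[Spectrum] | np.ndarray") -> np.ndarray:
    """Ensemble-average outer product (1/N) sum_j r_j r_j^T (k x k).

    A plain mean over samples, not a covariance: the prior is the second
    moment of the raw white-normalized reflectances.
    """
    X, _ = _ensemble_matrix(ensemble)
    if X.shape[0] == 0:
        raise ValueError("ensemble is empty")
    if not np.all(np.isfinite(X)):
        raise ValueError("ensemble contains non-finite values")
    R = X.T @ X / X.shape[0]
    return (R + R.T) / 2.0  # symmetrize away roundoff


def compute_wiener_matrix(
    autocorrelation: np.ndarray,
    F: np.ndarray,
    noise_variance: float = 0.0,
) -> np.ndarray:
    """k x 3 Wiener matrix W = R F^T (F R F^T + sigma^2 I)^{-1}.

    ``noise_variance`` adds a scalar ridge to the Gram matrix diagonal for
    noisy-camera regularization; the default 0 reproduces the noise-free
    estimator.  A Gram matrix conditioned worse than
    :data:`GRAM_CONDITION_LIMIT` falls back to a pseudo-inverse with a
    warning.
    """
    R = np.asarray(autocorrelation, dtype=float)
    F = np.asarray(F, dtype=float)
    if not (np.all(np.isfinite(R)) and np.all(np.isfinite(F))):
        raise ValueError("autocorrelation and system matrix must be finite")
    if R.shape[0] != R.shape[1] or F.shape != (3, R.shape[0]):
        raise ValueError(
            f"shapes not conformable: autocorrelation {R.shape}, system matrix {F.shape}"
        )
    RFt = R @ F.T
    gram = F @ RFt
    if noise_variance:
        gram = gram + noise_variance * np.eye(3)
    if np.linalg.cond(gram) > GRAM_CONDITION_LIMIT:
        warnings.warn(
            "camera Gram matrix is near singular; using pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        return RFt @ np.linalg.pinv(gram, rcond=1e-12)
    return np.linalg.solve(gram.T, RFt.T).T


@dataclass
class WienerModel:
    """Trained Wiener reconstructor: prior, camera and estimation matrix."""

    grid: SpectralGrid
    autocorrelation: np.ndarray = field(repr=False)
    system_matrix: np.ndarray = field(repr=False)
    W: np.ndarray = field(repr=False)

    @classmethod
    def train(
        cls,
        ensemble: "Sequence[Spectrum] | np.ndarray",
        camera: CameraSystem,
        noise_variance: float = 0.0,
    ) -> "WienerModel":
        X, grid = _ensemble_matrix(ensemble)
        grid = grid or camera.grid
        if X.shape[1] != len(camera.grid):
            raise ValueError("ensemble and camera grids differ in length")
        R = compute_autocorrelation(X)
        F = build_system_matrix(camera)
        W = compute_wiener_matrix(R, F, noise_variance=noise_variance)
        return cls(grid=grid, autocorrelation=R, system_matrix=F, W=W)

    def reconstruct_spectrum(self, v: np.ndarray, clip_negative: bool = False) -> Spectrum:
        return reconstruct_spectrum(self, v, clip_negative=clip_negative)

    def reconstruct_image(self, rgb: np.ndarray, clip_negative: bool = False) -> np.ndarray:
        return reconstruct_image(self, rgb, clip_negative=clip_negative)

    # single columnar text file: one row per wavelength holding W, F^T and
    # the autocorrelation row for that wavelength
    def save(self, path: str | Path) -> None:
        k = len(self.grid)
        cols: dict[str, np.ndarray] = {"wavelength_nm": self.grid.wavelengths}
        for i, ch in enumerate("rgb"):
            cols[f"W_{ch}"] = self.W[:, i]
        for i, ch in enumerate("rgb"):
            cols[f"F_{ch}"] = self.system_matrix[i, :]
        for j in range(k):
            cols[f"acf_{int(round(self.grid.wavelengths[j]))}"] = self.autocorrelation[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "WienerModel":
        df = pd.read_csv(path)
        grid = SpectralGrid(df["wavelength_nm"].to_numpy(dtype=float))
        W = df[["W_r", "W_g", "W_b"]].to_numpy(dtype=float)
        F = df[["F_r", "F_g", "F_b"]].to_numpy(dtype=float).T
        acf_cols = [c for c in df.columns if c.startswith("acf_")]
        R = df[acf_cols].to_numpy(dtype=float)
        return cls(grid=grid, autocorrelation=R, system_matrix=F, W=W)


def reconstruct_spectrum(
    model: WienerModel, v: np.ndarray, clip_negative: bool = False
) -> Spectrum:
    """r_est = W v.  Negative reflectances are kept unless ``clip_negative``:
    silently clipping would bias the downstream absorbance regression."""
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"RGB response must have 3 elements, got shape {v.shape}")
    r = model.W @ v
    if clip_negative:
        r = np.maximum(r, 0.0)
    return Spectrum(model.grid, r)


def reconstruct_image(
    model: WienerModel, rgb: np.ndarray, clip_negative: bool = False
) -> np.ndarray:
    """Per-pixel Wiener reconstruction of an H x W x 3 image.

    Returns a stack of shape (k, H, W), planes in ascending wavelength.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {rgb.shape}")
    stack = np.einsum("kc,hwc->khw", model.W, rgb)
    if clip_negative:
        stack = np.maximum(stack, 0.0)
    return stack


def gfc(measured: Spectrum | np.ndarray, estimated: Spectrum | np.ndarray) -> float:
    """Goodness-of-fit coefficient |<r_mes, r_est>| / (||r_mes|| ||r_est||).

    Bounded in [0, 1] by the Cauchy-Schwarz inequality and invariant to
    positive rescaling of either spectrum; 1 means identical shape.
    """
    a = as_values(measured)
    b = as_values(estimated)
    if a.shape != b.shape:
        raise ValueError("spectra must share a grid")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("GFC is undefined for an all-zero spectrum")
    return float(min(abs(float(a @ b)) / (na * nb), 1.0))


# -- ensemble and stack I/O ----------------------------------------------

def load_ensemble_csv(path: str | Path) -> np.ndarray:
    """Spectral ensemble CSV: one row per sample, one column per wavelength
    (header row gives the nm values).  Returns (N, k) array."""
    df = pd.read_csv(path, comment="#")
    return df.to_numpy(dtype=float)


def save_ensemble_csv(path: str | Path, ensemble: "Sequence[Spectrum] | np.ndarray",
                      grid: SpectralGrid | None = None) -> None:
    X, g = _ensemble_matrix(ensemble)
    g = g or grid
    if g is None:
        raise ValueError("grid required when saving a bare array ensemble")
    pd.DataFrame(X, columns=[f"{w:g}" for w in g.wavelengths]).to_csv(path, index=False)


def write_spectral_stack(path: str | Path, stack: np.ndarray, grid: SpectralGrid) -> None:
    """Multi-page float32 TIFF, one page per wavelength in ascending order,
    plus a sidecar CSV ``<path>.wavelengths.csv`` listing the nm values."""
    stack = np.asarray(stack, dtype=np.float32)
    if stack.shape[0] != len(grid):
        raise ValueError("stack plane count does not match grid")
    tifffile.imwrite(path, stack, photometric="minisblack")
    side = Path(str(path) + ".wavelengths.csv")
    pd.DataFrame({"page": np.arange(len(grid)), "wavelength_nm": grid.wavelengths}).to_csv(
        side, index=False
    )
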