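"""Per-pixel chromophore mapping and ROI time-course analysis.

The imaging chain per pixel: Wiener-reconstruct the 25-band reflectance
spectrum from the white-normalized linear RGB triple, extract the 6
estimation bands by exact index, take absorbance, run the first-stage
regression (MRA1), read off StO2 from the oxy/deoxy coefficient ratio, and
convert (a_m, a_tb, a_0) to C_m and C_tb with the trained conversion
vectors.  Pixels whose reflectance needed flooring or whose blood total
vanished are flagged in a quality mask and excluded from ROI statistics
rather than imputed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .grids import SpectralGrid, Spectrum
from .montecarlo import ExtinctionTable, TrainingRecord
from .regression import (
    ConversionModel,
    absorbance,
    basis_expand_arrays,
    fit_conversion_vectors,
    mra1,
    mra1_batch,
    REFLECTANCE_FLOOR,
)
from .wiener import WienerModel, reconstruct_image

logger = logging.getLogger("skinspectra")

__all__ = [
    "ChromophoreMaps",
    "ROI",
    "ROITimecourse",
    "estimate_maps",
    "estimate_sequence",
    "roi_timecourse",
    "train_conversion_model",
    "read_rgb",
    "save_maps",
]


@dataclass
class ChromophoreMaps:
    """Estimated chromophore images in % units.

    ``sto2`` is clipped to [0, 100] with NaN where undefined; raw
    (unclipped) companions preserve under/overshoot for analysis.
    ``quality_mask`` is True where a pixel was flagged.
    """

    c_m: np.ndarray
    c_tb: np.ndarray
    sto2: np.ndarray
    quality_mask: np.ndarray
    c_m_raw: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    c_tb_raw: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    sto2_raw: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = self.c_m.shape
        if self.c_m_raw is None:
            self.c_m_raw = self.c_m.copy()
        if self.c_tb_raw is None:
            self.c_tb_raw = self.c_tb.copy()
        if self.sto2_raw is None:
            self.sto2_raw = self.sto2.copy()
        for name in ("c_tb", "sto2", "quality_mask", "c_m_raw", "c_tb_raw", "sto2_raw"):
            if getattr(self, name).shape != shape:
                raise ValueError("all maps must share one spatial shape")
        finite = self.sto2[np.isfinite(self.sto2)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("sto2 map must lie in [0, 100] where defined")

    @property
    def shape(self) -> tuple[int, int]:
        return self.c_m.shape  # type: ignore[return-value]


def train_conversion_model(
    records: Sequence[TrainingRecord],
    table: ExtinctionTable,
    basis: Sequence[tuple[int, int, int]] | None = None,
) -> ConversionModel:
    """Run MRA1 over a reflectance training grid and fit conversion vectors."""
    training = []
    for rec in records:
        coeffs = mra1(absorbance(rec.spectrum), table)
        training.append((rec.state, coeffs))
    return fit_conversion_vectors(training, basis)


def estimate_maps(
    rgb: np.ndarray,
    wiener: WienerModel,
    table: ExtinctionTable,
    conv: ConversionModel,
    estimation_grid: SpectralGrid | None = None,
    floor: float = REFLECTANCE_FLOOR,
) -> ChromophoreMaps:
    """Estimate C_m, C_tb and StO2 maps from one linear RGB image.

    ``rgb`` must already be white-standard normalized (H, W, 3).  The
    estimation bands are taken from the reconstruction by exact index; the
    Wiener grid must therefore contain them.
    """
    if wiener.W is None:
        raise ValueError("Wiener model is not trained")
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got {rgb.shape}")
    est_grid = estimation_grid or SpectralGrid.estimation()
    sub_idx = wiener.grid.indices_in(est_grid)

    stack = reconstruct_image(wiener, rgb)  # (k, H, W)
    sub = stack[sub_idx]  # (6, H, W)
    h, w = rgb.shape[:2]
    flat = sub.reshape(len(est_grid), -1)

    bad = flat <= 0
    floored = bad.any(axis=0)
    A = -np.log10(np.where(bad, floor, flat))

    coefs = mra1_batch(A, est_grid, table)  # (4, P): a_m, a_ob, a_db, a_0
    a_m, a_ob, a_db, a_0 = coefs
    a_tb = a_ob + a_db

    tb_zero = a_tb == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        sto2_raw = np.where(tb_zero, np.nan, 100.0 * a_ob / np.where(tb_zero, 1.0, a_tb))
    sto2 = np.clip(sto2_raw, 0.0, 100.0)

    feats = basis_expand_arrays(a_m, a_tb, a_0, conv.basis)  # (z, P)
    cm_raw = conv.b_m @ feats
    ctb_raw = conv.b_tb @ feats

    mask = floored | tb_zero
    logger.info(
        "estimate_maps: %dx%d image, %d flagged pixels (%d floored, %d zero blood total)",
        h, w, int(mask.sum()), int(floored.sum()), int(tb_zero.sum()),
    )
    shape = (h, w)
    return ChromophoreMaps(
        c_m=np.maximum(cm_raw, 0.0).reshape(shape),
        c_tb=np.maximum(ctb_raw, 0.0).reshape(shape),
        sto2=sto2.reshape(shape),
        quality_mask=mask.reshape(shape),
        c_m_raw=cm_raw.reshape(shape),
        c_tb_raw=ctb_raw.reshape(shape),
        sto2_raw=sto2_raw.reshape(shape),
    )


def estimate_maps_pixelwise(
    rgb: np.ndarray,
    wiener: WienerModel,
    table: ExtinctionTable,
    conv: ConversionModel,
    estimation_grid: SpectralGrid | None = None,
) -> ChromophoreMaps:
    """Reference loop implementation of :func:`estimate_maps`.

    Chains the scalar operations pixel by pixel; used to validate the
    vectorized path, and kept as executable documentation of the chain.
    """
    from .regression import compute_sto2, predict_concentrations

    rgb = np.asarray(rgb, dtype=float)
    est_grid = estimation_grid or SpectralGrid.estimation()
    h, w = rgb.shape[:2]
    out = {k: np.zeros((h, w)) for k in ("c_m", "c_tb", "sto2", "c_m_raw", "c_tb_raw", "sto2_raw")}
    mask = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            r25 = wiener.reconstruct_spectrum(rgb[i, j])
            r6 = r25.subsample(est_grid)
            A = absorbance(r6)
            coeffs = mra1(A, table)
            sto2, sto2_raw = compute_sto2(coeffs)
            cm, ctb, cm_raw, ctb_raw = predict_concentrations(coeffs, conv)
            out["c_m"][i, j] = cm
            out["c_tb"][i, j] = ctb
            out["sto2"][i, j] = sto2
            out["c_m_raw"][i, j] = cm_raw
            out["c_tb_raw"][i, j] = ctb_raw
            out["sto2_raw"][i, j] = sto2_raw
            mask[i, j] = A.flagged or coeffs.a_tb == 0.0
    return ChromophoreMaps(
        c_m=out["c_m"], c_tb=out["c_tb"], sto2=out["sto2"], quality_mask=mask,
        c_m_raw=out["c_m_raw"], c_tb_raw=out["c_tb_raw"], sto2_raw=out["sto2_raw"],
    )


@dataclass(frozen=True)
class ROI:
    """Rectangle in pixel coordinates, origin top-left, 0-based, half-open."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if not (self.row_start < self.row_stop and self.col_start < self.col_stop):
            raise ValueError("ROI must be non-empty")
        if min(self.row_start, self.col_start) < 0:
            raise ValueError("ROI coordinates must be nonnegative")

    def check_within(self, shape: tuple[int, int]) -> None:
        if self.row_stop > shape[0] or self.col_stop > shape[1]:
            raise ValueError(f"ROI {self} exceeds image shape {shape}")


@dataclass
class ROITimecourse:
    """Mean and SD of each chromophore over an ROI, per frame."""

    times: np.ndarray
    c_m_mean: np.ndarray
    c_m_sd: np.ndarray
    c_tb_mean: np.ndarray
    c_tb_sd: np.ndarray
    sto2_mean: np.ndarray
    sto2_sd: np.ndarray

    def __post_init__(self) -> None:
        n = self.times.size
        for name in ("c_m_mean", "c_m_sd", "c_tb_mean", "c_tb_sd", "sto2_mean", "sto2_sd"):
            if getattr(self, name).shape != (n,):
                raise ValueError("all time-course arrays must share one length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "C_m_mean": self.c_m_mean,
                "C_m_sd": self.c_m_sd,
                "C_tb_mean": self.c_tb_mean,
                "C_tb_sd": self.c_tb_sd,
                "StO2_mean": self.sto2_mean,
                "StO2_sd": self.sto2_sd,
            }
        )


def estimate_sequence(
    frames: Sequence[np.ndarray],
    wiener: WienerModel,
    table: ExtinctionTable,
    conv: ConversionModel,
) -> list[ChromophoreMaps]:
    return [estimate_maps(f, wiener, table, conv) for f in frames]


def roi_timecourse(
    maps_sequence: Sequence[ChromophoreMaps],
    roi: ROI,
    interval_s: float,
) -> ROITimecourse:
    """ROI statistics per frame; times are frame_index * interval_s.

    Flagged pixels are excluded; a fully flagged ROI yields NaN for that
    frame.  SDs are population SDs (ddof = 0) over the unflagged pixels.
    """
    if not maps_sequence:
        raise ValueError("empty image sequence")
    shape = maps_sequence[0].shape
    roi.check_within(shape)
    n = len(maps_sequence)
    cols = {k: np.full(n, np.nan) for k in
            ("c_m_mean", "c_m_sd", "c_tb_mean", "c_tb_sd", "sto2_mean", "sto2_sd")}
    for t, maps in enumerate(maps_sequence):
        if maps.shape != shape:
            raise ValueError("frames must share one shape")
        sl = (slice(roi.row_start, roi.row_stop), slice(roi.col_start, roi.col_stop))
        ok = ~maps.quality_mask[sl]
        if not ok.any():
            continue
        for key, img in (("c_m", maps.c_m), ("c_tb", maps.c_tb), ("sto2", maps.sto2)):
            vals = img[sl][ok]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                cols[f"{key}_mean"][t] = vals.mean()
                cols[f"{key}_sd"][t] = vals.std()
    times = np.arange(n, dtype=float) * interval_s
    return ROITimecourse(times=times, **cols)


# -- I/O -----------------------------------------------------------------

def read_rgb(
    path: str | Path,
    white: "np.ndarray | Sequence[float] | None" = None,
) -> np.ndarray:
    """Read an 8- or 16-bit PNG/TIFF as float RGB in [0, 1].

    ``white`` (a per-channel white-standard response, same scale as the
    image) divides the result channelwise, completing the normalization.
    """
    raw = np.asarray(iio.imread(path))
    if raw.ndim != 3 or raw.shape[2] < 3:
        raise ValueError(f"expected an RGB image, got shape {raw.shape}")
    img = raw[:, :, :3].astype(float)
    if np.issubdtype(raw.dtype, np.integer):
        scale = float(np.iinfo(raw.dtype).max)
        img = img / scale
    else:
        scale = 1.0
    if white is not None:
        w = np.asarray(white, dtype=float).reshape(1, 1, 3)
        if np.any(w <= 0):
            raise ValueError("white reference must be positive")
        img = img / (w / scale if w.max() > 1.0 else w)
    return img


def save_maps(maps: ChromophoreMaps, directory: str | Path, prefix: str = "maps") -> None:
    """Write one float32 TIFF per quantity plus a CSV of whole-image stats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, img in (("C_m", maps.c_m), ("C_tb", maps.c_tb), ("StO2", maps.sto2)):
        tifffile.imwrite(directory / f"{prefix}_{name}.tif", img.astype(np.float32))
    tifffile.imwrite(
        directory / f"{prefix}_quality_mask.tif", maps.quality_mask.astype(np.uint8)
    )
    ok = ~maps.quality_mask
    rows = []
    for name, img in (("C_m", maps.c_m), ("C_tb", maps.c_tb), ("StO2", maps.sto2)):
        vals = img[ok]
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "quantity": name,
                "mean": vals.mean() if vals.size else np.nan,
                "sd": vals.std() if vals.size else np.nan,
                "n_pixels": int(vals.size),
                "n_flagged": int(maps.quality_mask.sum()),
            }
        )
    pd.DataFrame(rows).to_csv(directory / f"{prefix}_summary.csv", index=False)
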