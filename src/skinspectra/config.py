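"""Unified pipeline configuration.

One YAML file can drive the whole chain; each section is optional and
falls back to the package defaults.  Sections:

* ``camera`` — ``profile_csv`` (path) or ``seed`` for the synthetic profile.
* ``wiener`` — ``noise_variance`` (Gram-matrix ridge), ``clip_negative``.
* ``montecarlo`` — the layer/photon settings of :class:`MCConfig`.
* ``regression`` — ``reflectance_floor`` and an optional explicit ``basis``
  (list of exponent triples).
* ``pipeline`` — ``estimation_wavelengths`` (defaults to 500-600/20 nm) and
  ``frame_interval_s``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .camera import CameraSystem
from .grids import SpectralGrid
from .montecarlo import MCConfig
from .regression import REFLECTANCE_FLOOR, default_basis

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    camera_profile_csv: Path | None = None
    camera_seed: int = 0
    wiener_noise_variance: float = 0.0
    wiener_clip_negative: bool = False
    montecarlo: MCConfig = field(default_factory=MCConfig.default)
    reflectance_floor: float = REFLECTANCE_FLOOR
    basis: tuple[tuple[int, int, int], ...] = field(default_factory=default_basis)
    estimation_wavelengths: np.ndarray = field(
        default_factory=lambda: SpectralGrid.estimation().wavelengths
    )
    frame_interval_s: float = 5.0

    @property
    def estimation_grid(self) -> SpectralGrid:
        return SpectralGrid(self.estimation_wavelengths)

    def camera(self) -> CameraSystem:
        if self.camera_profile_csv is not None:
            return CameraSystem.from_csv(self.camera_profile_csv)
        from .fixtures import make_camera_profiles

        return make_camera_profiles(seed=self.camera_seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cam = raw.get("camera", {})
        wie = raw.get("wiener", {})
        reg = raw.get("regression", {})
        pipe = raw.get("pipeline", {})
        kwargs: dict = {}
        if "profile_csv" in cam:
            kwargs["camera_profile_csv"] = Path(cam["profile_csv"])
        if "seed" in cam:
            kwargs["camera_seed"] = int(cam["seed"])
        if "noise_variance" in wie:
            kwargs["wiener_noise_variance"] = float(wie["noise_variance"])
        if "clip_negative" in wie:
            kwargs["wiener_clip_negative"] = bool(wie["clip_negative"])
        if "montecarlo" in raw:
            kwargs["montecarlo"] = MCConfig.from_dict(raw["montecarlo"])
        if "reflectance_floor" in reg:
            kwargs["reflectance_floor"] = float(reg["reflectance_floor"])
        if "basis" in reg:
            kwargs["basis"] = tuple(tuple(int(e) for e in t) for t in reg["basis"])
        if "estimation_wavelengths" in pipe:
            kwargs["estimation_wavelengths"] = np.asarray(
                pipe["estimation_wavelengths"], dtype=float
            )
        if "frame_interval_s" in pipe:
            kwargs["frame_interval_s"] = float(pipe["frame_interval_s"])
        return cls(**kwargs)
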