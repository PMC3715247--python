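"""Synthetic inputs: camera profiles, skin spectra, phantom scenes.

Everything the pipeline consumes can be generated here deterministically
from a seed, standing in for laboratory inputs: smooth trichromatic camera
profiles (for the untabulated vendor curves), ensembles of skin-like
reflectance spectra (for the spectrometer training set), flat phantom-like
scenes with known chromophore patches (for the agar-phantom experiment),
and occlusion-shaped image sequences (for the arm-cuff protocol).

Two forward models turn a chromophore state into a reflectance spectrum:

* ``"surrogate"`` — a modified Beer-Lambert two-layer closed form
  R(lambda) = R0(lambda) exp(-mu_a,epi l_e - mu_a,derm l_d) with fixed
  effective path lengths per layer.  It is smooth, instantaneous, and shares
  the monotone structure of the physics, so it backs the fast test paths.
* ``"mc"`` — the full Monte Carlo simulator (slow, stochastic, physical).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .camera import CameraSystem, build_system_matrix
from .grids import SpectralGrid, Spectrum
from .montecarlo import (
    ChromophoreState,
    ExtinctionTable,
    MCConfig,
    SkinModel,
    chromophore_to_absorption,
    simulate_reflectance,
)

__all__ = [
    "SceneSpec",
    "Patch",
    "make_camera_profiles",
    "beer_lambert_reflectance",
    "make_skin_ensemble",
    "render_scene",
    "render_occlusion_sequence",
    "default_occlusion_schedule",
    "surrogate_training_records",
]

#: effective double-pass path lengths of the surrogate forward model (mm)
SURROGATE_PATH_EPIDERMIS = 0.12
SURROGATE_PATH_DERMIS = 1.2

#: default sampling ranges for random chromophore states (%)
DEFAULT_PARAMETER_RANGES = {
    "C_m": (1.0, 10.0),
    "C_tb": (0.2, 1.0),
    "StO2": (0.0, 100.0),
}


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def make_camera_profiles(seed: int = 0, grid: SpectralGrid | None = None) -> CameraSystem:
    """Smooth synthetic camera: Gaussian R/G/B passbands, LED-like illuminant.

    Filter peaks are jittered a few nm by the seed but always ordered
    B < G < R in wavelength; the resulting system matrix has rank 3.
    """
    grid = grid or SpectralGrid.reconstruction()
    wl = grid.wavelengths
    rng = np.random.default_rng(seed)
    centers = np.array([610.0, 540.0, 460.0]) + rng.uniform(-5.0, 5.0, size=3)
    widths = np.array([32.0, 35.0, 30.0]) * rng.uniform(0.95, 1.05, size=3)
    filters = np.stack([_gaussian(wl, c, w) for c, w in zip(centers, widths)])
    # white-LED shape: blue pump plus a broad phosphor hump
    illuminant = 0.55 * _gaussian(wl, 455.0, 18.0) + _gaussian(wl, 565.0, 75.0) + 0.05
    sensitivity = 1.0 - 0.0008 * (wl - 550.0)  # gentle slope, positive on-grid
    return CameraSystem(
        grid=grid,
        filter_transmittances=filters,
        illuminant=illuminant,
        sensitivity=sensitivity,
    )


def beer_lambert_reflectance(
    state: ChromophoreState,
    table: ExtinctionTable,
    grid: SpectralGrid | None = None,
    baseline_scale: float = 1.0,
) -> Spectrum:
    """Closed-form two-layer surrogate reflectance.

    R0(lambda) is a gently sloped scattering baseline (~0.55 at 550 nm);
    ``baseline_scale`` lets ensemble generation vary it between samples.
    """
    grid = grid or SpectralGrid.reconstruction()
    wl = grid.wavelengths
    mu_a_epi, mu_a_derm = chromophore_to_absorption(state, table, grid)
    tau = mu_a_epi * SURROGATE_PATH_EPIDERMIS + mu_a_derm * SURROGATE_PATH_DERMIS
    r0 = baseline_scale * (0.55 + 0.0004 * (wl - 550.0))
    return Spectrum(grid, r0 * np.exp(-tau))


ForwardName = Literal["surrogate", "mc"]


def _forward_fn(
    forward: ForwardName,
    table: ExtinctionTable,
    grid: SpectralGrid,
    mc_config: MCConfig | None = None,
    mc_photons: int = 10_000,
    mc_seed: int = 0,
) -> Callable[[ChromophoreState, float], Spectrum]:
    if forward == "surrogate":
        return lambda state, scale=1.0: beer_lambert_reflectance(state, table, grid, scale)
    if forward == "mc":
        config = mc_config or MCConfig.default()

        def run(state: ChromophoreState, scale: float = 1.0) -> Spectrum:
            model = SkinModel.from_state(state, table, config, grid)
            spec = simulate_reflectance(model, mc_photons, mc_seed, config.ambient_n)
            return Spectrum(grid, scale * spec.values)

        return run
    raise ValueError(f"unknown forward model {forward!r}")


def make_skin_ensemble(
    n: int,
    parameter_ranges: dict[str, tuple[float, float]] | None = None,
    forward: ForwardName = "surrogate",
    seed: int = 0,
    grid: SpectralGrid | None = None,
    table: ExtinctionTable | None = None,
    mc_photons: int = 10_000,
) -> list[Spectrum]:
    """Draw n skin-like reflectance spectra from random chromophore states.

    States are sampled uniformly in ``parameter_ranges``; a +/-10%
    multiplicative jitter on the scattering baseline emulates
    subject-to-subject variation, so the ensemble is richer than the bare
    three-parameter family.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = grid or SpectralGrid.reconstruction()
    table = table or ExtinctionTable.default()
    ranges = dict(DEFAULT_PARAMETER_RANGES)
    if parameter_ranges:
        ranges.update(parameter_ranges)
    rng = np.random.default_rng(seed)
    fwd = _forward_fn(forward, table, grid, mc_photons=mc_photons, mc_seed=seed)
    out = []
    for _ in range(n):
        state = ChromophoreState(
            C_m=rng.uniform(*ranges["C_m"]),
            C_tb=rng.uniform(*ranges["C_tb"]),
            StO2=rng.uniform(*ranges["StO2"]),
        )
        scale = rng.uniform(0.9, 1.1)
        out.append(fwd(state, scale))
    return out


# -- scenes --------------------------------------------------------------

Rect = tuple[int, int, int, int]  # (row_start, row_stop, col_start, col_stop), half-open


@dataclass(frozen=True)
class Patch:
    rect: Rect
    state: ChromophoreState


@dataclass
class SceneSpec:
    """A flat multi-patch scene with ground-truth chromophore states.

    Patches must tile the image exactly: overlap or uncovered pixels are
    errors.  ``noise_sd`` is the relative SD of multiplicative Gaussian
    RGB noise (0 disables it).
    """

    width: int
    height: int
    patches: Sequence[Patch] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("scene must be at least 1 x 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def patch_index_map(self) -> np.ndarray:
        """H x W map of patch indices; validates exact tiling."""
        idx = np.full((self.height, self.width), -1, dtype=int)
        for i, patch in enumerate(self.patches):
            r0, r1, c0, c1 = patch.rect
            if not (0 <= r0 < r1 <= self.height and 0 <= c0 < c1 <= self.width):
                raise ValueError(f"patch {i} rectangle {patch.rect} out of bounds")
            block = idx[r0:r1, c0:c1]
            if np.any(block != -1):
                raise ValueError(f"patch {i} overlaps a previous patch")
            block[...] = i
        if np.any(idx == -1):
            raise ValueError("patches do not cover the image")
        return idx


def render_scene(
    spec: SceneSpec,
    camera: CameraSystem,
    forward: ForwardName = "surrogate",
    table: ExtinctionTable | None = None,
    mc_photons: int = 10_000,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render a scene to a linear RGB image plus ground-truth maps.

    Returns ``(rgb, truth)`` where rgb is (H, W, 3) float and truth holds
    per-pixel ``C_m``, ``C_tb`` and ``StO2`` arrays.
    """
    table = table or ExtinctionTable.default()
    idx = spec.patch_index_map()
    F = build_system_matrix(camera)
    fwd = _forward_fn(forward, table, camera.grid, mc_photons=mc_photons, mc_seed=spec.seed)
    rgb = np.zeros((spec.height, spec.width, 3))
    truth = {
        name: np.zeros((spec.height, spec.width)) for name in ("C_m", "C_tb", "StO2")
    }
    for i, patch in enumerate(spec.patches):
        r = fwd(patch.state)
        v = F @ r.values
        mask = idx == i
        rgb[mask] = v
        truth["C_m"][mask] = patch.state.C_m
        truth["C_tb"][mask] = patch.state.C_tb
        truth["StO2"][mask] = patch.state.StO2
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        rgb = rgb * (1.0 + spec.noise_sd * rng.standard_normal(rgb.shape))
        rgb = np.maximum(rgb, 0.0)
    return rgb, truth


ScheduleEntry = tuple[float, float, float]  # (time_s, C_tb %, StO2 %)


def default_occlusion_schedule(
    n_frames: int = 129,
    interval_s: float = 5.0,
    baseline_ctb: float = 0.8,
    baseline_sto2: float = 70.0,
    occlusion_start_s: float = 40.0,
    occlusion_end_s: float = 340.0,
) -> list[ScheduleEntry]:
    """Arm-cuff-shaped schedule: baseline, occlusion (StO2 decays
    exponentially, C_tb creeps up), then release with a brief reactive
    hyperemia overshoot and recovery.  129 frames at 5 s span 640 s.
    """
    entries = []
    for i in range(n_frames):
        t = i * interval_s
        if t < occlusion_start_s:
            ctb, sto2 = baseline_ctb, baseline_sto2
        elif t < occlusion_end_s:
            dt = t - occlusion_start_s
            sto2 = baseline_sto2 * np.exp(-dt / 150.0)
            ctb = baseline_ctb * (1.0 + 0.1 * dt / (occlusion_end_s - occlusion_start_s))
        else:
            # release: StO2 rises from the occlusion-end value toward a
            # hyperemic plateau; C_tb overshoots then settles back
            dt = t - occlusion_end_s
            ctb = baseline_ctb * (1.0 + 0.3 * np.exp(-dt / 60.0))
            sto2_end = baseline_sto2 * np.exp(
                -(occlusion_end_s - occlusion_start_s) / 150.0
            )
            sto2 = min(95.0 + (sto2_end - 95.0) * np.exp(-dt / 25.0), 100.0)
        entries.append((t, float(ctb), float(sto2)))
    return entries


def render_occlusion_sequence(
    base: SceneSpec,
    schedule: Sequence[ScheduleEntry],
    camera: CameraSystem,
    forward: ForwardName = "surrogate",
    table: ExtinctionTable | None = None,
) -> tuple[list[np.ndarray], dict[str, np.ndarray]]:
    """One frame per schedule entry, overriding every patch's blood state.

    Melanin is held at each patch's own C_m (occlusion does not move it).
    Returns the frames and ground-truth time series arrays keyed
    ``times``, ``C_tb``, ``StO2``.
    """
    times = np.array([t for t, _, _ in schedule], dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("schedule times must be strictly increasing")
    frames = []
    for j, (_, ctb, sto2) in enumerate(schedule):
        patches = [
            Patch(p.rect, ChromophoreState(p.state.C_m, ctb, sto2)) for p in base.patches
        ]
        frame_spec = SceneSpec(
            width=base.width,
            height=base.height,
            patches=patches,
            noise_sd=base.noise_sd,
            seed=base.seed + j,
        )
        rgb, _ = render_scene(frame_spec, camera, forward=forward, table=table)
        frames.append(rgb)
    truth = {
        "times": times,
        "C_tb": np.array([c for _, c, _ in schedule]),
        "StO2": np.array([s for _, _, s in schedule]),
    }
    return frames, truth


def surrogate_training_records(
    table: ExtinctionTable | None = None,
    grid: SpectralGrid | None = None,
    states: "Sequence[ChromophoreState] | None" = None,
    baseline_jitter: float = 0.05,
    seed: int = 0,
):
    """Training records over the standard chromophore grid using the fast
    surrogate forward model — a drop-in stand-in for the Monte Carlo grid
    when speed matters more than physics.

    A small multiplicative jitter on the scattering baseline varies the
    regression intercept across records; without it the surrogate grid's
    intercept is constant and the 14-term conversion basis would be
    degenerate on it.
    """
    from .montecarlo import TrainingRecord, default_chromophore_grid

    table = table or ExtinctionTable.default()
    grid = grid or SpectralGrid.estimation()
    states = list(states) if states is not None else default_chromophore_grid()
    rng = np.random.default_rng(seed)
    scales = 1.0 + baseline_jitter * rng.uniform(-1.0, 1.0, size=len(states))
    return [
        TrainingRecord(s, beer_lambert_reflectance(s, table, grid, scale))
        for s, scale in zip(states, scales)
    ]
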