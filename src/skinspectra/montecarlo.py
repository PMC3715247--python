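"""Photon-packet Monte Carlo transport in layered skin.

A standard multi-layer photon-packet simulator in the MCML tradition:
packets launch normally onto the surface, lose the specular fraction at the
ambient/epidermis interface, take exponentially sampled steps
s = -ln(xi)/(mu_a + mu_s), deposit weight by implicit capture
(w -> w * mu_s / (mu_a + mu_s)), scatter by the Henyey-Greenstein phase
function, undergo Fresnel reflection/refraction at layer boundaries, and
terminate by Russian roulette.  Packet weight escaping through the top
surface is tallied as diffuse reflectance; the specular fraction is kept
out of that tally, matching a crossed-polarizer acquisition geometry that
rejects specular light.

The default skin model is two layers: a thin melanin-bearing epidermis over
a blood-bearing dermis.  Chromophore concentrations (melanin volume
fraction C_m in the epidermis; total blood fraction C_tb and oxygen
saturation StO2 in the dermis) map linearly onto absorption coefficients
through an extinction table, and the simulator turns each concentration
triple into a diffuse reflectance spectrum.  A grid of such simulations is
the training set for the concentration conversion regression.

RNG: numba's internal MT19937-compatible generator, seeded per run; a fixed
seed reproduces results bit for bit.
"""
from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from numba import njit

from .grids import SpectralGrid, Spectrum

__all__ = [
    "ChromophoreState",
    "ExtinctionTable",
    "LayerOptics",
    "SkinModel",
    "LayerSpec",
    "MCConfig",
    "TransportResult",
    "TrainingRecord",
    "chromophore_to_absorption",
    "transport",
    "simulate_reflectance",
    "default_chromophore_grid",
    "generate_training_grid",
    "training_grid_to_frame",
    "training_grid_from_frame",
]

_SEED_MOD = 2**31

#: Russian-roulette trigger weight and survival probability.  Roulette is
#: unbiased for any trigger; 1e-3 trades a little low-weight variance for
#: substantially shorter packet histories in weakly absorbing layers.
WEIGHT_THRESHOLD = 1e-3
ROULETTE_SURVIVAL = 0.1


@dataclass(frozen=True)
class ChromophoreState:
    """Concentration triple driving the two-layer model.

    C_m: melanin volume concentration in the epidermis (%).
    C_tb: total blood volume concentration in the dermis (%).
    StO2: oxygen saturation of that blood (%), the oxygenated fraction.
    """

    C_m: float
    C_tb: float
    StO2: float

    def __post_init__(self) -> None:
        for name in ("C_m", "C_tb", "StO2"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100] %, got {v}")


@dataclass
class ExtinctionTable:
    """Absorption basis spectra (mm^-1 at 100% concentration).

    eps_melanin applies to the epidermal melanin fraction; eps_oxy and
    eps_deoxy apply to oxygenated/deoxygenated whole blood in the dermis.
    """

    grid: SpectralGrid
    eps_melanin: np.ndarray = field(repr=False)
    eps_oxy: np.ndarray = field(repr=False)
    eps_deoxy: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        k = len(self.grid)
        for name in ("eps_melanin", "eps_oxy", "eps_deoxy"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k,):
                raise ValueError(f"{name} must match the grid length {k}")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and nonnegative")
            setattr(self, name, arr)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExtinctionTable":
        df = pd.read_csv(path, comment="#")
        return cls(
            grid=SpectralGrid(df["wavelength_nm"].to_numpy(dtype=float)),
            eps_melanin=df["eps_melanin"].to_numpy(dtype=float),
            eps_oxy=df["eps_oxy"].to_numpy(dtype=float),
            eps_deoxy=df["eps_deoxy"].to_numpy(dtype=float),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "wavelength_nm": self.grid.wavelengths,
                "eps_melanin": self.eps_melanin,
                "eps_oxy": self.eps_oxy,
                "eps_deoxy": self.eps_deoxy,
            }
        ).to_csv(path, index=False)

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """Bundled synthetic table covering 450-700 nm (see its header)."""
        ref = importlib.resources.files("skinspectra.data") / "extinction_skin_synthetic.csv"
        with importlib.resources.as_file(ref) as p:
            return cls.from_csv(p)

    def on_grid(self, grid: SpectralGrid) -> "ExtinctionTable":
        """Linear interpolation onto another grid inside the covered range."""
        wl = grid.wavelengths
        lo, hi = self.grid.wavelengths[0], self.grid.wavelengths[-1]
        if wl[0] < lo - 1e-9 or wl[-1] > hi + 1e-9:
            raise ValueError(
                f"extinction table covers {lo}-{hi} nm, requested {wl[0]}-{wl[-1]} nm"
            )
        src = self.grid.wavelengths
        return ExtinctionTable(
            grid=grid,
            eps_melanin=np.interp(wl, src, self.eps_melanin),
            eps_oxy=np.interp(wl, src, self.eps_oxy),
            eps_deoxy=np.interp(wl, src, self.eps_deoxy),
        )


@dataclass
class LayerOptics:
    """Per-wavelength optical properties of one slab."""

    mu_a: np.ndarray  # absorption, mm^-1
    mu_s: np.ndarray  # scattering, mm^-1
    g: np.ndarray  # Henyey-Greenstein anisotropy, in (-1, 1)
    n: float  # refractive index
    thickness: float  # mm

    def __post_init__(self) -> None:
        self.mu_a = np.atleast_1d(np.asarray(self.mu_a, dtype=float))
        self.mu_s = np.atleast_1d(np.asarray(self.mu_s, dtype=float))
        self.g = np.atleast_1d(np.asarray(self.g, dtype=float))
        if not (self.mu_a.shape == self.mu_s.shape == self.g.shape):
            raise ValueError("mu_a, mu_s and g must share a wavelength grid")
        if np.any(self.mu_a < 0):
            raise ValueError("mu_a must be nonnegative")
        if np.any(self.mu_s <= 0):
            raise ValueError("mu_s must be positive")
        if np.any(np.abs(self.g) >= 1):
            raise ValueError("g must lie in (-1, 1)")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


@dataclass
class SkinModel:
    """Two-layer skin: epidermis over dermis, on a shared wavelength grid."""

    grid: SpectralGrid
    epidermis: LayerOptics
    dermis: LayerOptics

    def __post_init__(self) -> None:
        k = len(self.grid)
        for layer in (self.epidermis, self.dermis):
            if layer.mu_a.shape != (k,):
                raise ValueError("layer optics must match the model grid")

    @classmethod
    def from_state(
        cls,
        state: ChromophoreState,
        table: ExtinctionTable,
        config: "MCConfig | None" = None,
        grid: SpectralGrid | None = None,
    ) -> "SkinModel":
        config = config or MCConfig.default()
        grid = grid or SpectralGrid.estimation()
        mu_a_epi, mu_a_derm = chromophore_to_absorption(state, table, grid)
        wl = grid.wavelengths
        epi, derm = config.epidermis, config.dermis
        return cls(
            grid=grid,
            epidermis=LayerOptics(
                mu_a=mu_a_epi,
                mu_s=epi.mu_s_550 * (550.0 / wl) ** epi.mu_s_exponent,
                g=np.full(len(grid), epi.g),
                n=epi.n,
                thickness=epi.thickness_mm,
            ),
            dermis=LayerOptics(
                mu_a=mu_a_derm,
                mu_s=derm.mu_s_550 * (550.0 / wl) ** derm.mu_s_exponent,
                g=np.full(len(grid), derm.g),
                n=derm.n,
                thickness=derm.thickness_mm,
            ),
        )


@dataclass(frozen=True)
class LayerSpec:
    """Wavelength-parametric optics of one layer: mu_s power law plus constants."""

    mu_s_550: float
    mu_s_exponent: float
    g: float
    n: float
    thickness_mm: float


@dataclass(frozen=True)
class MCConfig:
    """Simulation configuration: layer specs, ambient index, photon budget."""

    epidermis: LayerSpec
    dermis: LayerSpec
    ambient_n: float = 1.0
    photons: int = 100_000
    seed: int = 1234

    @classmethod
    def from_dict(cls, d: dict) -> "MCConfig":
        return cls(
            epidermis=LayerSpec(**d["epidermis"]),
            dermis=LayerSpec(**d["dermis"]),
            ambient_n=float(d.get("ambient_n", 1.0)),
            photons=int(d.get("photons", 100_000)),
            seed=int(d.get("seed", 1234)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MCConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "MCConfig":
        ref = importlib.resources.files("skinspectra.data") / "mc_defaults.yaml"
        with importlib.resources.as_file(ref) as p:
            return cls.from_yaml(p)


def chromophore_to_absorption(
    state: ChromophoreState,
    table: ExtinctionTable,
    grid: SpectralGrid | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Map a concentration triple to per-layer absorption spectra (mm^-1).

    Epidermis: mu_a = (C_m/100) * eps_melanin.  Dermis: the total-blood
    absorption splits between oxygenated and deoxygenated blood by StO2,
    mu_a = (C_tb/100) * [(StO2/100) eps_oxy + (1 - StO2/100) eps_deoxy].
    Both are linear in their concentrations.
    """
    t = table if grid is None else table.on_grid(grid)
    f_ox = state.StO2 / 100.0
    mu_a_epi = (state.C_m / 100.0) * t.eps_melanin
    mu_a_derm = (state.C_tb / 100.0) * (f_ox * t.eps_oxy + (1.0 - f_ox) * t.eps_deoxy)
    return mu_a_epi, mu_a_derm


# -- transport kernel ----------------------------------------------------

@njit(cache=True, fastmath=True)
def _transport_kernel(
    mu_a, mu_s, g, n, thick, n_above, n_below, n_photons, seed, w_threshold, p_survive
):  # pragma: no cover - exercised through `transport`
    np.random.seed(seed)
    L = mu_a.shape[0]
    zb = np.empty(L + 1)
    zb[0] = 0.0
    for i in range(L):
        zb[i + 1] = zb[i] + thick[i]
    inv_mut = np.empty(L)
    albedo = np.empty(L)
    for i in range(L):
        inv_mut[i] = 1.0 / (mu_a[i] + mu_s[i])
        albedo[i] = mu_s[i] * inv_mut[i]
    refl = 0.0
    trans = 0.0
    absorbed = 0.0
    spec = 0.0
    r_kill = 0.0
    r_gain = 0.0
    for _ in range(n_photons):
        w = 1.0
        if n_above != n[0]:
            rs = ((n_above - n[0]) / (n_above + n[0])) ** 2
            spec += rs
            w -= rs
        layer = 0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        s_left = 0.0
        alive = True
        while alive:
            if s_left == 0.0:
                xi = np.random.random()
                while xi <= 0.0:
                    xi = np.random.random()
                s_left = -np.log(xi)
            step = s_left * inv_mut[layer]
            if uz > 0.0:
                db = (zb[layer + 1] - z) / uz
            elif uz < 0.0:
                db = (zb[layer] - z) / uz
            else:
                db = 1e30
            if db < step:
                # hit a boundary before the interaction point
                s_left -= db / inv_mut[layer]
                going_down = uz > 0.0
                n1 = n[layer]
                if going_down:
                    z = zb[layer + 1]
                    n2 = n[layer + 1] if layer + 1 < L else n_below
                else:
                    z = zb[layer]
                    n2 = n[layer - 1] if layer > 0 else n_above
                ci = abs(uz)
                if n1 == n2:
                    # index-matched: no Fresnel event, no RNG draw
                    crossed = True
                    ct = ci
                else:
                    si = np.sqrt(max(0.0, 1.0 - ci * ci))
                    st = n1 / n2 * si
                    if st >= 1.0:
                        crossed = False  # total internal reflection
                        ct = ci
                    else:
                        ct = np.sqrt(1.0 - st * st)
                        if ci > 0.9999999:
                            R = ((n1 - n2) / (n1 + n2)) ** 2
                        else:
                            rs_ = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
                            rp_ = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
                            R = 0.5 * (rs_ * rs_ + rp_ * rp_)
                        crossed = np.random.random() > R
                if crossed:
                    if going_down and layer == L - 1:
                        trans += w
                        alive = False
                    elif (not going_down) and layer == 0:
                        refl += w
                        alive = False
                    else:
                        ratio = n1 / n2
                        ux *= ratio
                        uy *= ratio
                        uz = ct if going_down else -ct
                        layer = layer + 1 if going_down else layer - 1
                else:
                    uz = -uz
            else:
                # interaction inside the layer
                z += uz * step
                s_left = 0.0
                wn = w * albedo[layer]
                absorbed += w - wn
                w = wn
                gg = g[layer]
                xi = np.random.random()
                if gg == 0.0:
                    ct = 2.0 * xi - 1.0
                else:
                    tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * xi)
                    ct = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                    if ct < -1.0:
                        ct = -1.0
                    elif ct > 1.0:
                        ct = 1.0
                st = np.sqrt(1.0 - ct * ct)
                # azimuth by rejection sampling of a unit disc point
                # (avoids cos/sin evaluations)
                while True:
                    vx = 2.0 * np.random.random() - 1.0
                    vy = 2.0 * np.random.random() - 1.0
                    rsq = vx * vx + vy * vy
                    if 0.0 < rsq < 1.0:
                        break
                inv_r = 1.0 / np.sqrt(rsq)
                cp = vx * inv_r
                sp = vy * inv_r
                if abs(uz) > 0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct if uz >= 0.0 else -ct
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    ux_n = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    uy_n = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    uz_n = -st * cp * den + uz * ct
                    ux = ux_n
                    uy = uy_n
                    uz = uz_n
                if w < w_threshold:
                    if np.random.random() < p_survive:
                        r_gain += w * (1.0 / p_survive - 1.0)
                        w /= p_survive
                    else:
                        r_kill += w
                        alive = False
    return refl, trans, absorbed, spec, r_kill, r_gain


@dataclass(frozen=True)
class TransportResult:
    """Per-launch-normalized tallies of one transport run.

    ``balance`` is the full energy book: diffuse reflectance +
    transmittance + absorbed + specular + roulette-killed weight minus
    roulette-gained weight.  It equals 1 up to floating accumulation.
    """

    reflectance: float
    transmittance: float
    absorbed: float
    specular: float
    roulette_killed: float
    roulette_gained: float

    @property
    def balance(self) -> float:
        return (
            self.reflectance
            + self.transmittance
            + self.absorbed
            + self.specular
            + self.roulette_killed
            - self.roulette_gained
        )


def transport(
    layers: Sequence[tuple[float, float, float, float, float]],
    n_photons: int,
    seed: int,
    n_above: float = 1.0,
    n_below: float | None = None,
) -> TransportResult:
    """Run photon transport at a single wavelength.

    ``layers`` is a top-to-bottom sequence of (mu_a, mu_s, g, n, thickness)
    tuples.  ``n_below`` defaults to the bottom layer's index (matched
    boundary).  Returns per-photon-normalized tallies.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    arr = np.asarray([list(t) for t in layers], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 5:
        raise ValueError("each layer is (mu_a, mu_s, g, n, thickness)")
    mu_a, mu_s, g, n, thick = (np.ascontiguousarray(arr[:, i]) for i in range(5))
    if np.any(mu_a < 0) or np.any(mu_s <= 0) or np.any(thick <= 0):
        raise ValueError("nonphysical optics: need mu_a >= 0, mu_s > 0, thickness > 0")
    if n_below is None:
        n_below = float(n[-1])
    out = _transport_kernel(
        mu_a,
        mu_s,
        g,
        n,
        thick,
        float(n_above),
        float(n_below),
        int(n_photons),
        int(seed) % _SEED_MOD,
        WEIGHT_THRESHOLD,
        ROULETTE_SURVIVAL,
    )
    return TransportResult(*(v / n_photons for v in out))


def simulate_reflectance(
    model: SkinModel,
    n_photons: int,
    seed: int,
    ambient_n: float = 1.0,
) -> Spectrum:
    """Diffuse reflectance spectrum of a two-layer model.

    One independent transport run per wavelength, seeded ``seed + j`` for
    wavelength index j; fixed ``seed`` gives bit-identical output.
    """
    values = np.empty(len(model.grid))
    for j in range(len(model.grid)):
        res = transport(
            [
                (
                    model.epidermis.mu_a[j],
                    model.epidermis.mu_s[j],
                    model.epidermis.g[j],
                    model.epidermis.n,
                    model.epidermis.thickness,
                ),
                (
                    model.dermis.mu_a[j],
                    model.dermis.mu_s[j],
                    model.dermis.g[j],
                    model.dermis.n,
                    model.dermis.thickness,
                ),
            ],
            n_photons=n_photons,
            seed=(seed + j) % _SEED_MOD,
            n_above=ambient_n,
        )
        values[j] = res.reflectance
    return Spectrum(model.grid, values)


# -- training grid -------------------------------------------------------

DEFAULT_CM_VALUES = tuple(float(v) for v in range(1, 11))  # 1..10 %
DEFAULT_CTB_VALUES = (0.2, 0.4, 0.6, 0.8, 1.0)  # %
DEFAULT_STO2_VALUES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)  # %


def default_chromophore_grid(
    cm_values: Sequence[float] = DEFAULT_CM_VALUES,
    ctb_values: Sequence[float] = DEFAULT_CTB_VALUES,
    sto2_values: Sequence[float] = DEFAULT_STO2_VALUES,
) -> list[ChromophoreState]:
    """Cartesian grid of training states, lexicographic in (C_m, C_tb, StO2).

    The defaults enumerate 10 x 5 x 6 = 300 states.
    """
    return [
        ChromophoreState(cm, ctb, s)
        for cm, ctb, s in itertools.product(cm_values, ctb_values, sto2_values)
    ]


@dataclass(frozen=True)
class TrainingRecord:
    state: ChromophoreState
    spectrum: Spectrum


def generate_training_grid(
    table: ExtinctionTable | None = None,
    config: MCConfig | None = None,
    grid: SpectralGrid | None = None,
    states: Sequence[ChromophoreState] | None = None,
    n_photons: int | None = None,
    seed: int | None = None,
) -> list[TrainingRecord]:
    """Simulate the reflectance training grid.

    Defaults: the 300-state chromophore grid, the 6-band estimation grid,
    and the bundled optics.  Each record's transport runs are seeded
    deterministically from the base seed and the record index, so the grid
    is reproducible and order-stable.
    """
    table = table or ExtinctionTable.default()
    config = config or MCConfig.default()
    grid = grid or SpectralGrid.estimation()
    states = list(states) if states is not None else default_chromophore_grid()
    n_photons = n_photons if n_photons is not None else config.photons
    base_seed = seed if seed is not None else config.seed
    records = []
    for i, state in enumerate(states):
        model = SkinModel.from_state(state, table, config, grid)
        spec = simulate_reflectance(
            model,
            n_photons=n_photons,
            seed=(base_seed + i * len(grid)) % _SEED_MOD,
            ambient_n=config.ambient_n,
        )
        records.append(TrainingRecord(state, spec))
    return records


def training_grid_to_frame(records: Sequence[TrainingRecord]) -> pd.DataFrame:
    """Columns C_m, C_tb, StO2, then one reflectance column per wavelength."""
    if not records:
        raise ValueError("no training records")
    grid = records[0].spectrum.grid
    rows = []
    for rec in records:
        if rec.spectrum.grid != grid:
            raise ValueError("training records are on mixed grids")
        row = {"C_m": rec.state.C_m, "C_tb": rec.state.C_tb, "StO2": rec.state.StO2}
        for w, v in zip(grid.wavelengths, rec.spectrum.values):
            row[f"R_{int(round(w))}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def training_grid_from_frame(df: pd.DataFrame) -> list[TrainingRecord]:
    r_cols = [c for c in df.columns if c.startswith("R_")]
    grid = SpectralGrid(np.array([float(c[2:]) for c in r_cols]))
    return [
        TrainingRecord(
            ChromophoreState(row["C_m"], row["C_tb"], row["StO2"]),
            Spectrum(grid, row[r_cols].to_numpy(dtype=float)),
        )
        for _, row in df.iterrows()
    ]
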