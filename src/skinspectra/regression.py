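"""Chromophore quantification by two-stage multiple regression.

Stage one (MRA1) regresses the absorbance spectrum A(lambda) = -log10
r(lambda) onto the extinction spectra of melanin, oxygenated blood and
deoxygenated blood plus an intercept:

    A(lambda) = a_m eps_m + a_ob eps_ob + a_db eps_db + a_0.

The coefficients absorb the unknown mean optical path lengths and the
scattering attenuation, so they are proportional to — but not equal to —
the concentrations.  Oxygen saturation follows directly,
StO2 = 100 a_ob / (a_ob + a_db), because the path-length factor cancels in
the ratio.

Stage two (MRA2) converts (a_m, a_tb, a_0), with a_tb = a_ob + a_db, into
concentrations via conversion vectors b_m, b_tb trained on a Monte Carlo
grid of known concentrations: expand the coefficients into z = 14 monomial
terms a = (1, a_m, a_tb, a_0, a_m a_tb, a_m a_0, ...) and fit
C_m = b_m . a and C_tb = b_tb . a by ordinary least squares, one fit per
response.  At prediction time the dot products replace any further
simulation, so the whole chain is closed-form per pixel.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .grids import SpectralGrid, Spectrum
from .montecarlo import ChromophoreState, ExtinctionTable

__all__ = [
    "AbsorbanceSpectrum",
    "MRA1Coefficients",
    "ConversionModel",
    "absorbance",
    "mra1",
    "compute_sto2",
    "default_basis",
    "basis_expand",
    "fit_conversion_vectors",
    "predict_concentrations",
]

#: reflectance floor substituted for nonpositive values before the log
REFLECTANCE_FLOOR = 1e-4


@dataclass
class AbsorbanceSpectrum:
    """A(lambda) = -log10 r(lambda); ``floored`` marks guarded wavelengths."""

    grid: SpectralGrid
    values: np.ndarray = field(repr=False)
    floored: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        f = np.asarray(self.floored, dtype=bool)
        if v.shape != (len(self.grid),) or f.shape != v.shape:
            raise ValueError("absorbance values/flags must match the grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("absorbance must be finite")
        self.values = v
        self.floored = f

    @property
    def flagged(self) -> bool:
        return bool(self.floored.any())


def absorbance(r: Spectrum, floor: float = REFLECTANCE_FLOOR) -> AbsorbanceSpectrum:
    """Elementwise -log10 of reflectance.

    Nonpositive reflectances (possible after linear reconstruction) are
    replaced by ``floor`` and flagged so downstream maps can mask the pixel.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    vals = r.values
    bad = vals <= 0
    safe = np.where(bad, floor, vals)
    return AbsorbanceSpectrum(r.grid, -np.log10(safe), bad)


@dataclass(frozen=True)
class MRA1Coefficients:
    """First-stage regression coefficients; a_tb is the blood total."""

    a_m: float
    a_ob: float
    a_db: float
    a_0: float

    @property
    def a_tb(self) -> float:
        return self.a_ob + self.a_db


def _design_matrix(table: ExtinctionTable) -> np.ndarray:
    k = len(table.grid)
    return np.column_stack([table.eps_melanin, table.eps_oxy, table.eps_deoxy, np.ones(k)])


def _check_design_rank(X: np.ndarray, table: ExtinctionTable) -> None:
    if np.linalg.matrix_rank(X, tol=1e-10 * np.linalg.norm(X)) >= 4:
        return
    names = ["eps_melanin", "eps_oxy", "eps_deoxy", "intercept"]
    norms = np.linalg.norm(X, axis=0)
    best = None
    for i, j in combinations(range(4), 2):
        c = abs(float(X[:, i] @ X[:, j])) / (norms[i] * norms[j] + 1e-300)
        if best is None or c > best[0]:
            best = (c, names[i], names[j])
    raise ValueError(
        "extinction design matrix is rank deficient on this grid; "
        f"most collinear pair: {best[1]} and {best[2]} (|cos| = {best[0]:.6f})"
    )


def mra1(A: AbsorbanceSpectrum, table: ExtinctionTable) -> MRA1Coefficients:
    """OLS fit of absorbance onto [eps_m, eps_ob, eps_db, 1]."""
    if len(A.grid) < 4:
        raise ValueError("MRA1 needs at least 4 wavelengths")
    t = table.on_grid(A.grid)
    X = _design_matrix(t)
    _check_design_rank(X, t)
    coef, *_ = np.linalg.lstsq(X, A.values, rcond=None)
    return MRA1Coefficients(*(float(c) for c in coef))


def mra1_batch(A_values: np.ndarray, grid: SpectralGrid, table: ExtinctionTable) -> np.ndarray:
    """Vectorized MRA1: ``A_values`` is (k, P); returns (4, P) coefficients
    in the order a_m, a_ob, a_db, a_0."""
    if len(grid) < 4:
        raise ValueError("MRA1 needs at least 4 wavelengths")
    t = table.on_grid(grid)
    X = _design_matrix(t)
    _check_design_rank(X, t)
    return np.linalg.pinv(X) @ A_values


def compute_sto2(c: MRA1Coefficients) -> tuple[float, float]:
    """StO2 % = 100 a_ob / (a_ob + a_db).

    Returns ``(clipped, raw)``; the clipped value lies in [0, 100].  A zero
    blood total leaves the ratio undefined: both values are NaN and the
    caller should flag the pixel.  The ratio is invariant to a common
    positive rescaling of a_ob and a_db.
    """
    if c.a_tb == 0.0:
        return float("nan"), float("nan")
    raw = 100.0 * c.a_ob / c.a_tb
    return float(np.clip(raw, 0.0, 100.0)), float(raw)


# -- MRA2: basis expansion and conversion vectors ------------------------

def default_basis() -> tuple[tuple[int, int, int], ...]:
    """Exponent triples (p, q, s) meaning a_m^p a_tb^q a_0^s; z = 14 terms.

    All monomials of total degree <= 2 in (a_m, a_tb, a_0), then the three
    pure cubes and the triple product, ordered so the expansion begins
    (1, a_m, a_tb, a_0, a_m a_tb, a_m a_0, ...).
    """
    return (
        (0, 0, 0),
        (1, 0, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 1, 0),
        (1, 0, 1),
        (0, 1, 1),
        (2, 0, 0),
        (0, 2, 0),
        (0, 0, 2),
        (3, 0, 0),
        (0, 3, 0),
        (0, 0, 3),
        (1, 1, 1),
    )


def _validate_basis(spec: Sequence[tuple[int, int, int]]) -> tuple[tuple[int, int, int], ...]:
    spec = tuple(tuple(int(e) for e in t) for t in spec)
    if not spec or spec[0] != (0, 0, 0):
        raise ValueError("basis must start with the constant term (0, 0, 0)")
    if any(len(t) != 3 or min(t) < 0 for t in spec):
        raise ValueError("basis terms are nonnegative exponent triples")
    if len(set(spec)) != len(spec):
        raise ValueError("basis terms must be distinct")
    return spec


def basis_expand(
    c: MRA1Coefficients,
    spec: Sequence[tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """Monomial feature vector a with a[j] = a_m^p a_tb^q a_0^s."""
    spec = _validate_basis(spec or default_basis())
    return basis_expand_arrays(
        np.asarray(c.a_m), np.asarray(c.a_tb), np.asarray(c.a_0), spec
    )


def basis_expand_arrays(
    a_m: np.ndarray,
    a_tb: np.ndarray,
    a_0: np.ndarray,
    spec: Sequence[tuple[int, int, int]],
) -> np.ndarray:
    """Vectorized expansion: output shape (z, ...) over broadcast inputs."""
    a_m, a_tb, a_0 = np.broadcast_arrays(a_m, a_tb, a_0)
    out = np.empty((len(spec),) + a_m.shape)
    for j, (p, q, s) in enumerate(spec):
        out[j] = (a_m ** p) * (a_tb ** q) * (a_0 ** s)
    return out


@dataclass
class ConversionModel:
    """Trained MRA2 conversion vectors over a monomial basis."""

    basis: tuple[tuple[int, int, int], ...]
    b_m: np.ndarray = field(repr=False)
    b_tb: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.basis = _validate_basis(self.basis)
        z = len(self.basis)
        self.b_m = np.asarray(self.b_m, dtype=float)
        self.b_tb = np.asarray(self.b_tb, dtype=float)
        if self.b_m.shape != (z,) or self.b_tb.shape != (z,):
            raise ValueError("conversion vectors must match the basis length")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "basis": [list(t) for t in self.basis],
            "b_m": self.b_m.tolist(),
            "b_tb": self.b_tb.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConversionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            basis=tuple(tuple(t) for t in d["basis"]),
            b_m=np.array(d["b_m"], dtype=float),
            b_tb=np.array(d["b_tb"], dtype=float),
        )


def fit_conversion_vectors(
    training: Sequence[tuple[ChromophoreState, MRA1Coefficients]],
    spec: Sequence[tuple[int, int, int]] | None = None,
) -> ConversionModel:
    """Two separate OLS fits of known C_m and C_tb onto the expanded basis."""
    spec = _validate_basis(spec or default_basis())
    z = len(spec)
    if len(training) <= z:
        raise ValueError(f"need more than z = {z} training records, got {len(training)}")
    a_m = np.array([c.a_m for _, c in training])
    a_tb = np.array([c.a_tb for _, c in training])
    a_0 = np.array([c.a_0 for _, c in training])
    X = basis_expand_arrays(a_m, a_tb, a_0, spec).T  # (N, z)
    if np.linalg.matrix_rank(X, tol=1e-10 * np.linalg.norm(X)) < z:
        raise ValueError(
            "MRA2 design matrix is rank deficient; the training grid does not "
            "span the basis — use a smaller basis or a richer grid"
        )
    y_m = np.array([s.C_m for s, _ in training])
    y_tb = np.array([s.C_tb for s, _ in training])
    b_m, *_ = np.linalg.lstsq(X, y_m, rcond=None)
    b_tb, *_ = np.linalg.lstsq(X, y_tb, rcond=None)
    return ConversionModel(basis=spec, b_m=b_m, b_tb=b_tb)


def predict_concentrations(
    c: MRA1Coefficients, model: ConversionModel
) -> tuple[float, float, float, float]:
    """Predict concentrations from first-stage coefficients.

    Returns ``(C_m, C_tb, C_m_raw, C_tb_raw)`` where the first two are
    clipped at 0 for reporting and the raw values preserve any
    undershoot for analysis.
    """
    a = basis_expand(c, model.basis)
    cm_raw = float(model.b_m @ a)
    ctb_raw = float(model.b_tb @ a)
    return max(cm_raw, 0.0), max(ctb_raw, 0.0), cm_raw, ctb_raw
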