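"""Pseudoatom electron density in the Hansen-Coppens multipole model.

rho(r) = rho_core(r)
       + Pval * kappa^3 * rho_val(kappa * r)
       + sum_l kappa'^3 * R_l(kappa' * r) * sum_m P_lm * d_lm(theta, phi)

Core and spherical-valence densities are normalized single-zeta Slater
shells; the deformation radial functions are normalized Slater functions
r^{n_l} exp(-zeta_l r).  All populations are in electrons, lengths in
angstrom, densities in e/A^3.  The per-element exponents shipped here are an
internally consistent package choice: every statistical operation in this
package acts on the parameters themselves, and the density evaluator exists
as the geometric oracle for frame rotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bank import MultipoleParameterSet
from .harmonics import lm_indices, real_sh_many

#: evaluation points are kept this far (angstrom) from the nucleus
NUCLEUS_CAP = 1e-4

BOHR = 0.529177210903  # angstrom


class DensityConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RadialModel:
    """Single-zeta Slater radial parts of one element's pseudoatom.

    ``deformation`` maps degree l to (n_l, zeta_l) with zeta in 1/angstrom
    and n_l >= l; ``core_electrons`` may be zero (hydrogen).
    """

    element: str
    core_electrons: float
    core_n: int
    core_zeta: float          # 1/angstrom, density exponent
    valence_n: int
    valence_zeta: float
    deformation: dict[int, tuple[int, float]]

    def validate(self) -> None:
        if self.core_electrons and self.core_zeta <= 0:
            raise DensityConfigError("core exponent must be positive")
        if self.valence_zeta <= 0:
            raise DensityConfigError("valence exponent must be positive")
        for l, (n_l, zeta_l) in self.deformation.items():
            if zeta_l <= 0 or n_l < l:
                raise DensityConfigError(
                    f"deformation shell l={l}: need zeta>0 and n_l>=l")


def _slater_norm(n: int, zeta: float) -> float:
    """Prefactor making int_0^inf r^n e^(-zeta r) r^2 dr = 1."""
    return zeta ** (n + 3) / math.factorial(n + 2)


def slater_radial(r, n: int, zeta: float):
    """Normalized radial function R(r) = N r^n e^(-zeta r)."""
    return _slater_norm(n, zeta) * np.power(r, n) * np.exp(-zeta * r)


def spherical_slater_density(r, n: int, zeta: float):
    """Spherical density with unit electron count: R(r) / (4 pi)."""
    return slater_radial(r, n, zeta) / (4.0 * math.pi)


# Orbital exponents (bohr^-1) in the spirit of single-zeta atomic fits;
# density exponents are twice these, converted to 1/angstrom.
_VALENCE_ORBITAL_ZETA = {
    "H": 1.24, "B": 1.30, "C": 1.72, "N": 1.95, "O": 2.25, "F": 2.55,
    "Si": 1.60, "P": 1.80, "S": 2.05, "Cl": 2.10, "Br": 2.20, "I": 2.00,
}
_CORE_ORBITAL_ZETA = {
    "B": 4.68, "C": 5.67, "N": 6.66, "O": 7.66, "F": 8.65,
    "Si": 13.6, "P": 14.6, "S": 15.5, "Cl": 16.4, "Br": 34.0, "I": 52.0,
}
_CORE_ELECTRONS = {
    "H": 0, "B": 2, "C": 2, "N": 2, "O": 2, "F": 2,
    "Si": 10, "P": 10, "S": 10, "Cl": 10, "Br": 28, "I": 46,
}
_VALENCE_POWER = {"H": 0, "B": 2, "C": 2, "N": 2, "O": 2, "F": 2,
                  "Si": 4, "P": 4, "S": 4, "Cl": 4, "Br": 6, "I": 8}


def default_radial_model(element: str) -> RadialModel:
    if element not in _VALENCE_ORBITAL_ZETA:
        raise DensityConfigError(f"no radial model for element {element!r}")
    zv = 2.0 * _VALENCE_ORBITAL_ZETA[element] / BOHR
    zc = 2.0 * _CORE_ORBITAL_ZETA.get(element, 1.0) / BOHR
    n_val = _VALENCE_POWER[element]
    # common multipole-model choice for first-row-like shells: n_l grows
    # with l so the radial node structure can follow the angular one
    n_l = {1: max(n_val, 1), 2: max(n_val, 2), 3: max(n_val, 3),
           4: max(n_val, 4)}
    deformation = {0: (n_val, zv)} | {l: (n_l[l], zv) for l in (1, 2, 3, 4)}
    return RadialModel(
        element=element, core_electrons=_CORE_ELECTRONS[element],
        core_n=0, core_zeta=zc, valence_n=n_val, valence_zeta=zv,
        deformation=deformation)


@dataclass
class DensityGrid:
    origin: np.ndarray
    spacing: float
    values: np.ndarray        # shape (nx, ny, nz), e/A^3

    def validate(self) -> None:
        if self.spacing <= 0:
            raise DensityConfigError("grid spacing must be positive")
        if not np.isfinite(self.values).all():
            raise DensityConfigError("grid contains non-finite values")

    def points(self) -> np.ndarray:
        nx, ny, nz = self.values.shape
        ax = [self.origin[i] + self.spacing * np.arange(n)
              for i, n in enumerate((nx, ny, nz))]
        grid = np.meshgrid(*ax, indexing="ij")
        return np.stack([g.ravel() for g in grid], axis=1)

    def integral(self) -> float:
        return float(self.values.sum() * self.spacing ** 3)

    def to_csv(self) -> str:
        pts = self.points()
        rows = ["x,y,z,rho"]
        for (x, y, z), v in zip(pts, self.values.ravel()):
            rows.append(f"{x:.4f},{y:.4f},{z:.4f},{v:.8e}")
        return "\n".join(rows) + "\n"


def pseudoatom_density(params: MultipoleParameterSet, radial: RadialModel,
                       point) -> float | np.ndarray:
    """Electron density (e/A^3) at position(s) relative to the nucleus."""
    radial.validate()
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    r = np.maximum(np.linalg.norm(pts, axis=1), NUCLEUS_CAP)
    u = pts / r[:, None]

    rho = np.zeros_like(r)
    if radial.core_electrons:
        rho += radial.core_electrons * spherical_slater_density(
            r, radial.core_n, radial.core_zeta)
    k = params.kappa
    rho += params.p_val * k ** 3 * spherical_slater_density(
        k * r, radial.valence_n, radial.valence_zeta)

    if params.p_lm:
        kp = params.kappa_prime
        lmax = max(l for l, _ in params.p_lm)
        ang = real_sh_many(u, lmax)           # (n_lm, n_points)
        order = lm_indices(lmax)
        by_l: dict[int, np.ndarray] = {}
        for (l, m), row in zip(order, ang):
            v = params.p_lm.get((l, m), 0.0)
            if v:
                by_l[l] = by_l.get(l, 0.0) + v * row
        for l, angular in by_l.items():
            n_l, zeta_l = radial.deformation[l]
            rho += kp ** 3 * slater_radial(kp * r, n_l, zeta_l) * angular
    return float(rho[0]) if np.ndim(point) == 1 else rho


def density_on_grid(params: MultipoleParameterSet, radial: RadialModel,
                    origin, spacing: float, shape) -> DensityGrid:
    """Evaluate the pseudoatom on a regular grid (deterministic)."""
    grid = DensityGrid(origin=np.asarray(origin, dtype=float),
                       spacing=float(spacing),
                       values=np.zeros(tuple(shape)))
    grid.validate()
    pts = grid.points()
    grid.values = pseudoatom_density(params, radial, pts).reshape(tuple(shape))
    grid.validate()
    return grid
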