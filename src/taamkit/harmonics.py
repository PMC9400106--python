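"""Density-normalized real spherical harmonics d_lm and their rotation.

The deformation-valence term of a multipolar pseudoatom is expanded on real
spherical harmonics in the *density* normalization: the monopole is the
constant ``d00 = 1/(4*pi)`` and every higher function satisfies
``integral |d_lm| dOmega = 2``, so that a population ``P_lm = 1`` transfers
one electron from the negative to the positive lobes of the function.

Angular parts use associated Legendre functions as returned by
:func:`scipy.special.lpmv`, i.e. with the Condon-Shortley phase.  With this
sign choice a bond-directed sp2 deformation produces a positive ``P33`` in a
frame whose X axis bisects two bonds, and a bond-directed sp3 deformation a
negative ``P32`` in a frame whose Z axis bisects two bonds, matching the
signs conventionally reported for transferable pseudoatom banks.

Rotation matrices for the real harmonics are obtained by numerically exact
quadrature projection (Gauss-Legendre x uniform azimuth, sized so that all
integrands of degree <= 2*l_max are integrated exactly), which keeps the
implementation independent of any recursion bookkeeping and is validated
against a density-grid oracle in the test-suite.
"""

from __future__ import annotations

import functools
import math

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.integrate import quad
from scipy.special import lpmv

LMAX = 4

__all__ = [
    "LMAX",
    "lm_indices",
    "real_sh",
    "real_sh_many",
    "density_norm_constant",
    "plm_dict_to_vector",
    "vector_to_plm_dict",
    "yreal_rotation_blocks",
    "dlm_rotation_blocks",
    "dlm_operator_blocks",
]


def lm_indices(lmax: int = LMAX) -> list[tuple[int, int]]:
    """(l, m) pairs in canonical order: l ascending, m from -l to +l."""
    return [(l, m) for l in range(lmax + 1) for m in range(-l, l + 1)]


def _check_lm(l: int, m: int) -> None:
    if not (0 <= l <= LMAX):
        raise ValueError(f"degree l={l} outside supported range 0..{LMAX}")
    if abs(m) > l:
        raise ValueError(f"order m={m} invalid for l={l}")


def _legendre_abs_integral(l: int, m: int) -> float:
    """integral_{-1}^{1} |lpmv(m, l, x)| dx, with breakpoints at the zeros."""
    # zeros of d^m/dx^m P_l(x) inside (-1, 1)
    coeffs = npleg.leg2poly(npleg.legder([0.0] * l + [1.0], m) if m else
                            [0.0] * l + [1.0])
    roots = np.polynomial.polynomial.polyroots(coeffs)
    pts = sorted(float(r.real) for r in roots
                 if abs(r.imag) < 1e-12 and -1 < r.real < 1)
    val, _ = quad(lambda x: abs(lpmv(m, l, x)), -1.0, 1.0,
                  points=pts or None, limit=200, epsabs=1e-13, epsrel=1e-13)
    return val


@functools.lru_cache(maxsize=None)
def density_norm_constant(l: int, m: int) -> float:
    """Prefactor L_lm with d_lm = L_lm * lpmv(|m|, l, cos th) * trig(m phi)."""
    _check_lm(l, m)
    if l == 0:
        return 1.0 / (4.0 * math.pi)
    i_phi = 2.0 * math.pi if m == 0 else 4.0  # int |cos m phi| = int |sin m phi| = 4
    return 2.0 / (_legendre_abs_integral(l, abs(m)) * i_phi)


@functools.lru_cache(maxsize=None)
def _ortho_norm_constant(l: int, m: int) -> float:
    """Prefactor of the orthonormal real harmonic built on the same lpmv."""
    am = abs(m)
    n = math.sqrt((2 * l + 1) / (4.0 * math.pi)
                  * math.factorial(l - am) / math.factorial(l + am))
    return n * (math.sqrt(2.0) if m != 0 else 1.0)


@functools.lru_cache(maxsize=None)
def _d_over_y(l: int, m: int) -> float:
    """Diagonal scaling c_lm with d_lm = c_lm * Y_lm (orthonormal real)."""
    if l == 0:
        return 1.0 / math.sqrt(4.0 * math.pi)
    return density_norm_constant(l, m) / _ortho_norm_constant(l, m)


def _angular(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x, y, z = points[..., 0], points[..., 1], points[..., 2]
    z = np.clip(z, -1.0, 1.0)
    # a point that reaches the pole only up to roundoff must evaluate as the
    # exact pole: sqrt(1-z^2) would amplify the 1e-16 error to 1e-8
    z = np.where(1.0 - np.abs(z) < 1e-15, np.sign(z), z)
    return z, np.arctan2(y, x)


def _eval(l: int, m: int, cos_theta, phi, norm: float):
    leg = lpmv(abs(m), l, cos_theta)
    if m > 0:
        return norm * leg * np.cos(m * phi)
    if m < 0:
        return norm * leg * np.sin(-m * phi)
    return norm * leg


def real_sh(l: int, m: int, direction) -> float | np.ndarray:
    """Density-normalized real spherical harmonic d_lm at unit direction(s)."""
    _check_lm(l, m)
    u = np.asarray(direction, dtype=float)
    norms = np.linalg.norm(u, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("direction must be a unit vector (|u| = 1 within 1e-8)")
    ct, phi = _angular(u)
    out = _eval(l, m, ct, phi, density_norm_constant(l, m))
    return float(out) if np.ndim(out) == 0 else out


def real_sh_many(points: np.ndarray, lmax: int = LMAX,
                 normalization: str = "density") -> np.ndarray:
    """Evaluate all harmonics up to lmax; returns array (n_lm, n_points)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ct, phi = _angular(pts)
    rows = []
    for l, m in lm_indices(lmax):
        if normalization == "density":
            norm = density_norm_constant(l, m)
        elif normalization == "orthonormal":
            norm = _ortho_norm_constant(l, m)
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        rows.append(_eval(l, m, ct, phi, norm))
    return np.asarray(rows)


def plm_dict_to_vector(p_lm: dict, lmax: int = LMAX) -> np.ndarray:
    vec = np.zeros(len(lm_indices(lmax)))
    order = {lm: i for i, lm in enumerate(lm_indices(lmax))}
    for (l, m), v in p_lm.items():
        _check_lm(l, m)
        if l > lmax:
            raise ValueError(f"(l={l}, m={m}) exceeds lmax={lmax}")
        vec[order[(l, m)]] = v
    return vec


def vector_to_plm_dict(vec: np.ndarray, lmax: int = LMAX,
                       drop_tol: float = 0.0) -> dict:
    out = {}
    for (l, m), v in zip(lm_indices(lmax), vec):
        if abs(v) > drop_tol:
            out[(l, m)] = float(v)
    return out


# Quadrature grid sized for exact integration of degree <= 2*LMAX products.
@functools.lru_cache(maxsize=None)
def _projection_grid(lmax: int):
    # even node count keeps theta = 90 deg off the grid, so symmetry
    # operations cannot map grid points onto the poles
    n_theta = lmax + 2 + (lmax % 2)
    n_phi = 4 * lmax + 4
    x, wx = np.polynomial.legendre.leggauss(n_theta)
    phi = np.arange(n_phi) * (2.0 * math.pi / n_phi)
    ct = np.repeat(x, n_phi)
    st = np.sqrt(1.0 - ct**2)
    ph = np.tile(phi, n_theta)
    pts = np.stack([st * np.cos(ph), st * np.sin(ph), ct], axis=1)
    w = np.repeat(wx, n_phi) * (2.0 * math.pi / n_phi)
    return pts, w


def yreal_rotation_blocks(rotation: np.ndarray, lmax: int = LMAX) -> list[np.ndarray]:
    """Per-l rotation matrices in the orthonormal real harmonic basis.

    ``blocks[l] @ q`` gives the coefficients of the actively rotated function
    f'(u) = f(R^T u) for a proper rotation R.
    """
    rot = np.asarray(rotation, dtype=float)
    if rot.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(rot) < 0:
        raise ValueError("improper operation (det = -1) is not a rotation")
    pts, w = _projection_grid(lmax)
    yu = real_sh_many(pts, lmax, normalization="orthonormal")
    yv = real_sh_many(pts @ rot, lmax, normalization="orthonormal")  # R^T u
    gram = (yu * w) @ yv.T
    blocks, off = [], 0
    for l in range(lmax + 1):
        dim = 2 * l + 1
        blocks.append(gram[off:off + dim, off:off + dim].copy())
        off += dim
    return blocks


def dlm_rotation_blocks(rotation: np.ndarray, lmax: int = LMAX) -> list[np.ndarray]:
    """Per-l rotation matrices acting on populations in the d_lm basis."""
    blocks = yreal_rotation_blocks(rotation, lmax)
    out = []
    for l, b in enumerate(blocks):
        # populations p relate to orthonormal coefficients q via q = c * p,
        # so p transforms with C^-1 D C
        c = np.array([_d_over_y(l, m) for m in range(-l, l + 1)])
        out.append(b * (c[None, :] / c[:, None]) if l else b.copy())
    return out


def plm_l_norms(p_lm: dict, lmax: int | None = None) -> dict[int, float]:
    """Rotation-invariant L2 norm of each degree-l component.

    Density-normalized harmonics are not orthonormal (their constants differ
    with |m| by a few percent), so the plain Euclidean norm of raw
    populations is not conserved by frame changes; the function-space norm
    ``sqrt(sum_m (c_lm P_lm)^2)`` is, to machine precision.
    """
    if lmax is None:
        lmax = max((l for l, _ in p_lm), default=0)
    out: dict[int, float] = {}
    for l in range(lmax + 1):
        out[l] = math.sqrt(sum(
            (_d_over_y(l, m) * p_lm.get((l, m), 0.0)) ** 2
            for m in range(-l, l + 1)))
    return out


def dlm_operator_blocks(op: np.ndarray, lmax: int = LMAX) -> list[np.ndarray]:
    """Action of a (possibly improper) orthogonal operation on d_lm populations.

    Improper operations factor as inversion times a proper rotation; inversion
    multiplies the degree-l block by (-1)^l.
    """
    op = np.asarray(op, dtype=float)
    det = np.linalg.det(op)
    if det > 0:
        return dlm_rotation_blocks(op, lmax)
    blocks = dlm_rotation_blocks(-op, lmax)
    return [((-1.0) ** l) * b for l, b in enumerate(blocks)]
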