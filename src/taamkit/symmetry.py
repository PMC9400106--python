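"""Site-symmetry selection rules for multipole populations.

Which P_lm may be nonzero in a properly oriented local frame is dictated by
the point group of the atomic site.  Instead of a lookup table, the allowed
index sets are derived here by symmetry projection: the group is generated
from its generator matrices, each element's action on the d_lm basis is
built (improper operations factor through the parity (-1)^l), and an index
is allowed exactly when the group-averaged projector does not annihilate it.

Orientation conventions match the frames that reveal each symmetry:

* ``m``      - mirror is the local XZ plane
* ``mm2``    - two-fold along Z, mirrors XZ and YZ
* ``3m``     - three-fold along Z, one mirror containing Z and X
* ``-6m2``   - 3m plus the horizontal mirror (planar trigonal sites, XabYa)
* ``-43m``   - tetrahedral group oriented as realized by a ZabXc frame
               (Z bisecting two bonds, X toward a third)
* ``cylindrical`` - continuous C_inf_v about Z, handled analytically
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .harmonics import LMAX, dlm_operator_blocks, lm_indices

__all__ = ["PointGroupSpec", "POINT_GROUPS", "point_group", "group_elements",
           "allowed_indices", "project_plm", "detect_symmetry",
           "SymmetryError"]


class SymmetryError(ValueError):
    pass


@dataclass(frozen=True)
class PointGroupSpec:
    name: str
    generators: tuple          # tuple of 3x3 orthogonal matrices
    order: int                 # group order; 0 encodes the continuous group


def _rz(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_MIRROR_XZ = np.diag([1.0, -1.0, 1.0])
_MIRROR_YZ = np.diag([-1.0, 1.0, 1.0])
_MIRROR_XY = np.diag([1.0, 1.0, -1.0])

# Tetrahedral group in its standard orientation (two-fold axes along x,y,z),
# then conjugated into the ZabXc realization: with bonds along the cube
# diagonals, Z bisects bonds a,b -> the standard x axis; X points toward
# bond c projected -> (0,1,-1)/sqrt(2).
_C3_111 = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
_S4_Z = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, -1.0]])
_B_ZABXC = np.array([
    [0.0, 1.0, -1.0],
    [0.0, 1.0, 1.0],
    [math.sqrt(2.0), 0.0, 0.0],
]) / math.sqrt(2.0)          # rows = local X, Y, Z in standard coordinates


def _conj(b: np.ndarray, g: np.ndarray) -> np.ndarray:
    return b @ g @ b.T


POINT_GROUPS: dict[str, PointGroupSpec] = {
    "1": PointGroupSpec("1", (), 1),
    "m": PointGroupSpec("m", (_MIRROR_XZ,), 2),
    "mm2": PointGroupSpec("mm2", (_MIRROR_XZ, _MIRROR_YZ), 4),
    "3m": PointGroupSpec("3m", (_rz(120.0), _MIRROR_XZ), 6),
    "-6m2": PointGroupSpec("-6m2", (_rz(120.0), _MIRROR_XZ, _MIRROR_XY), 12),
    "-43m": PointGroupSpec(
        "-43m", (_conj(_B_ZABXC, _C3_111), _conj(_B_ZABXC, _S4_Z)), 24),
    "cylindrical": PointGroupSpec("cylindrical", (), 0),
}

#: fixed precedence for symmetry detection ties (most to least symmetric)
DETECTION_PRECEDENCE = ("cylindrical", "-43m", "-6m2", "3m", "mm2", "m", "1")


def point_group(name: str) -> PointGroupSpec:
    try:
        return POINT_GROUPS[name]
    except KeyError:
        raise SymmetryError(f"unknown point group {name!r}") from None


def group_elements(group: PointGroupSpec) -> list[np.ndarray]:
    """Close the generator set under multiplication (finite groups only)."""
    if group.order == 0:
        raise SymmetryError(
            "the cylindrical group is continuous; use its analytic rule")
    elements = [np.eye(3)]

    def seen(mat):
        return any(np.allclose(mat, e, atol=1e-9) for e in elements)

    frontier = [np.asarray(g, dtype=float) for g in group.generators]
    for g in frontier:
        if not np.allclose(g @ g.T, np.eye(3), atol=1e-9):
            raise SymmetryError(f"{group.name}: generator not orthogonal")
        if not seen(g):
            elements.append(g)
    changed = True
    while changed:
        changed = False
        for a in list(elements):
            for b in list(elements):
                prod = a @ b
                if not seen(prod):
                    elements.append(prod)
                    changed = True
                    if len(elements) > 48:
                        raise SymmetryError(
                            f"{group.name}: generators do not close")
    if group.order and len(elements) != group.order:
        raise SymmetryError(
            f"{group.name}: closure has {len(elements)} elements, "
            f"expected {group.order}")
    return elements


def _projector_blocks(group: PointGroupSpec, lmax: int) -> list[np.ndarray]:
    elements = group_elements(group)
    blocks = [np.zeros((2 * l + 1, 2 * l + 1)) for l in range(lmax + 1)]
    for g in elements:
        for l, b in enumerate(dlm_operator_blocks(g, lmax)):
            blocks[l] += b
    return [b / len(elements) for b in blocks]


def allowed_indices(group: PointGroupSpec | str, l_max: int = LMAX,
                    tol: float = 1e-10) -> set[tuple[int, int]]:
    """Symmetry-allowed (l, m) index set, derived by group averaging.

    An index is allowed iff the symmetry projector does not annihilate its
    basis function, i.e. the projector's diagonal element is nonzero.
    """
    if isinstance(group, str):
        group = point_group(group)
    if not (0 <= l_max <= LMAX):
        raise SymmetryError(f"l_max={l_max} outside 0..{LMAX}")
    if group.order == 0:   # continuous rotations about Z kill every m != 0
        return {(l, 0) for l in range(l_max + 1)}
    blocks = _projector_blocks(group, l_max)
    allowed = set()
    for l in range(l_max + 1):
        diag = np.diag(blocks[l])
        for m, d in zip(range(-l, l + 1), diag):
            if abs(d) > tol:
                allowed.add((l, m))
    return allowed


def project_plm(p_lm: dict, group: PointGroupSpec | str,
                l_max: int | None = None) -> dict:
    """Group-average a population vector; zeroes exactly the disallowed
    indices and leaves an invariant vector untouched."""
    if isinstance(group, str):
        group = point_group(group)
    if l_max is None:
        l_max = max((l for l, _ in p_lm), default=0)
    if group.order == 0:
        return {(l, m): (v if m == 0 else 0.0) for (l, m), v in p_lm.items()}
    from .harmonics import plm_dict_to_vector
    vec = plm_dict_to_vector(p_lm, l_max)
    blocks = _projector_blocks(group, l_max)
    out, off = np.empty_like(vec), 0
    for l in range(l_max + 1):
        dim = 2 * l + 1
        out[off:off + dim] = blocks[l] @ vec[off:off + dim]
        off += dim
    return dict(zip(lm_indices(l_max), map(float, out)))


def detect_symmetry(p_lm: dict, candidate_groups=None,
                    tolerance_e: float = 0.005) -> str:
    """Highest point group compatible with a population vector.

    A candidate is compatible when every disallowed index carries at most
    ``tolerance_e`` electrons; among compatible candidates the largest group
    order wins, ties broken by a fixed precedence list.
    """
    if tolerance_e <= 0:
        raise SymmetryError("tolerance must be positive")
    if candidate_groups is None:
        candidate_groups = list(DETECTION_PRECEDENCE)
    if not candidate_groups:
        raise SymmetryError("empty candidate list")
    l_max = min(max((l for l, _ in p_lm), default=0), LMAX)
    ranked = sorted(
        candidate_groups,
        key=lambda n: (-(point_group(n).order or 10 ** 6),
                       DETECTION_PRECEDENCE.index(n)
                       if n in DETECTION_PRECEDENCE else len(DETECTION_PRECEDENCE)))
    for name in ranked:
        allowed = allowed_indices(name, l_max)
        if all(abs(v) <= tolerance_e
               for lm, v in p_lm.items() if lm not in allowed):
            return name
    return "1"


def allowed_indices_csv(l_max: int = LMAX) -> str:
    rows = ["group,l,m,allowed"]
    for name in POINT_GROUPS:
        allowed = allowed_indices(name, l_max)
        for l, m in lm_indices(l_max):
            rows.append(f"{name},{l},{m},{int((l, m) in allowed)}")
    return "\n".join(rows) + "\n"
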