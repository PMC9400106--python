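"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import math

import numpy as np


def brute_force_dbscan(x: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Textbook O(n^2) DBSCAN: core points have >= min_pts neighbors
    (self included) within eps; clusters are connected components of core
    points plus their border points; everything else is noise (-1)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        stack.append(k)
        cluster += 1
    return labels


def labels_equivalent(a, b) -> bool:
    """Label-permutation equality with -1 fixed."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    if ((a == -1) != (b == -1)).any():
        return False
    mapping: dict[int, int] = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(int(x), int(y)) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


# Hand-coded Cartesian forms of the density-normalized harmonics for l <= 2
# (associated Legendre with Condon-Shortley phase; normalization constants
# from the closed-form |P| integrals).
def dlm_cartesian(l: int, m: int, u) -> float:
    x, y, z = u
    if (l, m) == (0, 0):
        return 1.0 / (4.0 * math.pi)
    if l == 1:
        c = 1.0 / math.pi                       # 2 / (int|P1|=1 * 4) = 1/2? no:
        # int_{-1}^{1} |x| dx = 1, azimuthal: 2pi for m=0 -> L10 = 2/(1*2pi)
        if m == 0:
            return (1.0 / math.pi) * z
        # lpmv(1,1,ct) = -sin(theta); L11 = 2 / (pi/2 * 4) = 4/pi... see below
        L11 = 2.0 / ((math.pi / 2.0) * 4.0)     # int|P_1^1| = pi/2
        if m == 1:
            return -L11 * x
        return -L11 * y
    if l == 2:
        if m == 0:
            # int_{-1}^{1} |3x^2-1|/2 dx = 4/(3*sqrt(3))
            L20 = 2.0 / ((4.0 / (3.0 * math.sqrt(3.0))) * 2.0 * math.pi)
            return L20 * 0.5 * (3.0 * z * z - 1.0)
        # int_{-1}^{1} 3|x|(1-x^2)^{1/2} dx = 2 ; P_2^1 = -3 x sqrt(1-x^2)
        L21 = 2.0 / (2.0 * 4.0)
        if m == 1:
            return -L21 * 3.0 * z * x
        if m == -1:
            return -L21 * 3.0 * z * y
        # int_{-1}^{1} 3(1-x^2) dx = 4 ; P_2^2 = 3(1-x^2)
        L22 = 2.0 / (4.0 * 4.0)
        if m == 2:
            return L22 * 3.0 * (x * x - y * y)
        return L22 * 6.0 * x * y
    raise ValueError("hand-coded forms cover l <= 2 only")


def two_pass_subtract_normalize(features: np.ndarray, valence: np.ndarray
                                ) -> np.ndarray:
    """Independent column-by-column subtract+normalize (kappa, Pval, kappa'
    in the first three columns)."""
    out = features.astype(float).copy()
    out[:, 0] -= 1.0
    out[:, 1] -= valence
    out[:, 2] -= 1.0
    for j in range(out.shape[1]):
        norm = math.sqrt(float((out[:, j] ** 2).sum()))
        if norm > 0:
            out[:, j] /= norm
    return out
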