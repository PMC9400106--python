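"""Local coordinate systems of multipolar atom types.

A local coordinate system (LCS) anchors the multipole expansion to neighbor
geometry: two axes are specified from bond directions (one neighbor, or the
average direction of two or three neighbors), the third follows from the
right-hand rule.  A frame name encodes group, rotation number and axis
construction, e.g. ``4n_62-ZabdXa``: rotation 62 of the 4n group, Z along the
average of neighbors a, b, d and X toward neighbor a.

Rotation numbers are banded by system family: 1-12 ZaXb (with the ZaXx and
ZaXany variants for single-neighbor and collinear types), 21-32 XabYa,
41-52 ZabXc, 61-64 ZabcXa, 71-72 ZabYa.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import math
import re
from dataclasses import dataclass

import numpy as np

from .harmonics import (LMAX, dlm_rotation_blocks, lm_indices,
                        plm_dict_to_vector)

logger = logging.getLogger(__name__)

FAMILY_BANDS = {"ZaXb": 1, "XabYa": 21, "ZabXc": 41, "ZabcXa": 61, "ZabYa": 71}

#: frame counts per group as fixed by the enumeration rules
GROUP_FRAME_COUNTS = {"1x": 1, "1p": 1, "2x": 2, "2p": 6,
                      "3p": 12, "3n": 16, "4n": 40, "6n": 1}


class FrameError(ValueError):
    """Unrealizable or inconsistently specified local coordinate system."""


@dataclass(frozen=True)
class AxisSpec:
    """How one axis is pointed: at a neighbor, at an average direction of
    several, at the nearest non-collinear distant neighbor ('x'), or at a
    deterministic direction orthogonal to the other axis."""

    kind: str                 # neighbor | mean | distant | any_orthogonal
    labels: tuple[str, ...] = ()

    def token(self) -> str:
        if self.kind == "neighbor" or self.kind == "mean":
            return "".join(self.labels)
        return {"distant": "x", "any_orthogonal": "any"}[self.kind]


@dataclass(frozen=True)
class LocalFrame:
    group: str
    number: int
    primary: tuple[str, AxisSpec]     # (axis letter, direction spec)
    secondary: tuple[str, AxisSpec]

    @property
    def name(self) -> str:
        p_letter, p_spec = self.primary
        s_letter, s_spec = self.secondary
        return (f"{self.group}_{self.number}-"
                f"{p_letter}{p_spec.token()}{s_letter}{s_spec.token()}")

    @property
    def family(self) -> str:
        """Generic system name: ZaXb (incl. ZaXx/ZaXany variants), XabYa,
        ZabXc, ZabcXa or ZabYa."""
        p_letter, p_spec = self.primary
        s_letter, _ = self.secondary
        if p_spec.kind == "neighbor":
            return "ZaXb"
        if len(p_spec.labels) == 3:
            return "ZabcXa"
        if p_letter == "X":
            return "XabYa"
        return "ZabXc" if s_letter == "X" else "ZabYa"

    @property
    def required_labels(self) -> frozenset[str]:
        labels = set(self.primary[1].labels) | set(self.secondary[1].labels)
        return frozenset(labels)


_NAME_RE = re.compile(
    r"^(?P<group>[1-6][xpn])_(?P<num>\d+)-"
    r"(?P<l1>[ZXY])(?P<d1>any|x|[a-f]+)(?P<l2>[ZXY])(?P<d2>any|x|[a-f]+)$")


def _spec_from_token(token: str) -> AxisSpec:
    if token == "any":
        return AxisSpec("any_orthogonal")
    if token == "x":
        return AxisSpec("distant")
    if len(token) == 1:
        return AxisSpec("neighbor", tuple(token))
    return AxisSpec("mean", tuple(token))


def parse_frame_name(name: str) -> LocalFrame:
    m = _NAME_RE.match(name)
    if not m:
        raise FrameError(f"cannot parse frame name {name!r}")
    frame = LocalFrame(
        group=m.group("group"), number=int(m.group("num")),
        primary=(m.group("l1"), _spec_from_token(m.group("d1"))),
        secondary=(m.group("l2"), _spec_from_token(m.group("d2"))))
    if frame.primary[0] == frame.secondary[0]:
        raise FrameError(f"{name}: primary and secondary axis letters equal")
    return frame


def enumerate_frames(group_label: str,
                     n_first_neighbors: int | None = None) -> list[LocalFrame]:
    """All local coordinate systems considered for a group.

    Counts: 1x and 1p one frame each, 2x two, 2p six (ZaXb, XabYa, ZabYa,
    two each), 3p twelve (6 ZaXb + 6 XabYa), 3n sixteen (+3 ZabXc +1 ZabcXa),
    4n forty (12+12+12+4) and 6n one.
    """
    from .bank import GROUP_NEIGHBOR_COUNT
    if group_label not in GROUP_NEIGHBOR_COUNT:
        raise FrameError(f"unknown group label {group_label!r}")
    n = GROUP_NEIGHBOR_COUNT[group_label]
    if n_first_neighbors is not None and n_first_neighbors != n:
        raise FrameError(
            f"group {group_label} implies {n} first neighbors, "
            f"got {n_first_neighbors}")
    labels = "abcdef"[:n]
    frames: list[LocalFrame] = []

    def add(number, primary, secondary):
        frames.append(LocalFrame(group_label, number, primary, secondary))

    if group_label == "1x":
        add(1, ("Z", AxisSpec("neighbor", ("a",))), ("X", AxisSpec("any_orthogonal")))
        return frames
    if group_label == "1p":
        add(1, ("Z", AxisSpec("neighbor", ("a",))), ("X", AxisSpec("distant")))
        return frames
    if group_label == "2x":
        for i, lab in enumerate(labels):
            add(i + 1, ("Z", AxisSpec("neighbor", (lab,))),
                ("X", AxisSpec("any_orthogonal")))
        return frames
    if group_label == "6n":
        add(1, ("Z", AxisSpec("neighbor", ("a",))), ("X", AxisSpec("neighbor", ("b",))))
        return frames

    # ZaXb: all ordered pairs of distinct neighbors, band 1-12
    num = FAMILY_BANDS["ZaXb"]
    for i, j in itertools.permutations(labels, 2):
        add(num, ("Z", AxisSpec("neighbor", (i,))), ("X", AxisSpec("neighbor", (j,))))
        num += 1

    # XabYa: unordered pairs, Y toward either member, band 21-32
    num = FAMILY_BANDS["XabYa"]
    for pair in itertools.combinations(labels, 2):
        for y in pair:
            add(num, ("X", AxisSpec("mean", pair)), ("Y", AxisSpec("neighbor", (y,))))
            num += 1

    if group_label == "2p":
        # ZabYa: the bisector frame of bent two-neighbor types, band 71-72
        num = FAMILY_BANDS["ZabYa"]
        for y in labels:
            add(num, ("Z", AxisSpec("mean", tuple(labels))),
                ("Y", AxisSpec("neighbor", (y,))))
            num += 1
        return frames
    if group_label == "3p":
        # planar groups use no pair-bisector or triple frames
        return frames

    # ZabXc: Z bisects a pair, X toward one remaining neighbor, band 41-52
    num = FAMILY_BANDS["ZabXc"]
    for pair in itertools.combinations(labels, 2):
        for rest in (lab for lab in labels if lab not in pair):
            add(num, ("Z", AxisSpec("mean", pair)), ("X", AxisSpec("neighbor", (rest,))))
            num += 1

    # ZabcXa: Z along the average of a triple, X toward its first member,
    # band 61-64 in the printed order ZabcXa, ZabdXa, ZbcdXb, ZacdXa.
    num = FAMILY_BANDS["ZabcXa"]
    triples = list(itertools.combinations(labels, 3))
    if len(triples) == 4:
        triples = [triples[0], triples[1], triples[3], triples[2]]
    for triple in triples:
        add(num, ("Z", AxisSpec("mean", triple)), ("X", AxisSpec("neighbor", (triple[0],))))
        num += 1
    return frames


@dataclass(frozen=True)
class FrameRealization:
    rotation: np.ndarray     # rows = local x,y,z axes; maps global -> local
    frame_name: str
    geometry_hash: str

    def validate(self) -> None:
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise FrameError(f"{self.frame_name}: axes not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-9:
            raise FrameError(f"{self.frame_name}: left-handed frame")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise FrameError("zero-length axis direction")
    return v / n


def _any_orthogonal(axis: np.ndarray) -> np.ndarray:
    """Deterministic perpendicular: the coordinate axis least parallel to
    ``axis``, Gram-Schmidt orthogonalized."""
    k = int(np.argmin(np.abs(axis)))
    e = np.zeros(3)
    e[k] = 1.0
    return _unit(e - np.dot(e, axis) * axis)


def realize_frame(frame: LocalFrame, central, neighbor_positions: dict,
                  distant_positions=None, *,
                  collinear_tol_deg: float = 5.0) -> FrameRealization:
    """Turn a frame definition plus geometry into a 3x3 rotation matrix.

    The primary axis lies exactly along its direction spec; the secondary is
    orthogonalized against it; the third axis completes a right-handed set.
    """
    center = np.asarray(central, dtype=float)
    missing = [lab for lab in frame.required_labels
               if lab not in neighbor_positions]
    if missing:
        raise FrameError(f"{frame.name}: missing neighbor(s) {missing}")

    def direction(spec: AxisSpec, primary_dir=None):
        if spec.kind == "neighbor":
            return _unit(np.asarray(neighbor_positions[spec.labels[0]], float)
                         - center)
        if spec.kind == "mean":
            units = [_unit(np.asarray(neighbor_positions[lab], float) - center)
                     for lab in spec.labels]
            return _unit(np.sum(units, axis=0))
        if spec.kind == "any_orthogonal":
            return _any_orthogonal(primary_dir)
        if spec.kind == "distant":
            if not distant_positions:
                raise FrameError(
                    f"{frame.name}: ZaXx needs second-or-further neighbors")
            cands = sorted(np.asarray(distant_positions, float).reshape(-1, 3),
                           key=lambda p: float(np.linalg.norm(p - center)))
            min_sin = math.sin(math.radians(collinear_tol_deg))
            for p in cands:
                d = _unit(p - center)
                if np.linalg.norm(np.cross(d, primary_dir)) > min_sin:
                    return d
            raise FrameError(
                f"{frame.name}: all distant neighbors collinear with Z")
        raise FrameError(f"unknown axis spec kind {spec.kind!r}")

    p_letter, p_spec = frame.primary
    s_letter, s_spec = frame.secondary
    p_dir = direction(p_spec)
    s_raw = direction(s_spec, primary_dir=p_dir)
    s_orth = s_raw - np.dot(s_raw, p_dir) * p_dir
    if np.linalg.norm(s_orth) < 1e-8:
        raise FrameError(f"{frame.name}: degenerate (collinear) axis specs")
    s_dir = _unit(s_orth)

    axes = {p_letter: p_dir, s_letter: s_dir}
    if "X" in axes and "Y" in axes:
        axes["Z"] = np.cross(axes["X"], axes["Y"])
    elif "Z" in axes and "X" in axes:
        axes["Y"] = np.cross(axes["Z"], axes["X"])
    else:
        axes["X"] = np.cross(axes["Y"], axes["Z"])
    rotation = np.vstack([axes["X"], axes["Y"], axes["Z"]])

    digest = hashlib.sha256()
    digest.update(np.round(center, 9).tobytes())
    for lab in sorted(neighbor_positions):
        digest.update(lab.encode())
        digest.update(np.round(np.asarray(neighbor_positions[lab], float), 9)
                      .tobytes())
    real = FrameRealization(rotation=rotation, frame_name=frame.name,
                            geometry_hash=digest.hexdigest()[:16])
    real.validate()
    return real


def rotate_plm(p_lm: dict, rotation: np.ndarray, lmax: int | None = None) -> dict:
    """Re-express deformation populations after rotating the coordinate
    system: the returned map describes the same physical density in the
    frame whose axes are the rows of ``rotation``.

    Block-diagonal per degree l; the monopole is invariant and the Euclidean
    norm within each l is preserved.  Improper operations are rejected.
    """
    rot = np.asarray(rotation, dtype=float)
    if np.linalg.det(rot) < 0:
        raise FrameError("improper operation passed to rotate_plm; mirror "
                         "symmetry is handled analytically in taamkit.symmetry")
    if lmax is None:
        lmax = max((l for l, _ in p_lm), default=0)
    if lmax > LMAX:
        raise FrameError(f"lmax={lmax} exceeds supported {LMAX}")
    if np.array_equal(rot, np.eye(3)):
        return dict(p_lm)
    vec = plm_dict_to_vector(p_lm, lmax)
    blocks = dlm_rotation_blocks(rot, lmax)
    out, off = np.empty_like(vec), 0
    for l in range(lmax + 1):
        dim = 2 * l + 1
        out[off:off + dim] = blocks[l] @ vec[off:off + dim]
        off += dim
    return {lm: float(v) for lm, v in zip(lm_indices(lmax), out)}


def rotate_plm_sd(sd_p_lm: dict, rotation: np.ndarray,
                  lmax: int | None = None) -> dict:
    """Propagate per-population sds through a frame change assuming
    independent member scatter: sd'^2 = (B*B) sd^2 per l block."""
    rot = np.asarray(rotation, dtype=float)
    if lmax is None:
        lmax = max((l for l, _ in sd_p_lm), default=0)
    var = plm_dict_to_vector(sd_p_lm, lmax) ** 2
    blocks = dlm_rotation_blocks(rot, lmax)
    out, off = np.empty_like(var), 0
    for l in range(lmax + 1):
        dim = 2 * l + 1
        out[off:off + dim] = (blocks[l] ** 2) @ var[off:off + dim]
        off += dim
    return {lm: float(math.sqrt(max(v, 0.0)))
            for lm, v in zip(lm_indices(lmax), out)}


@dataclass
class MemberAtom:
    """One atom contributing to a type: geometry plus its deformation
    populations expressed in the global (laboratory) frame."""

    central: np.ndarray
    neighbors: dict[str, np.ndarray]     # first-shell label -> position
    p_lm: dict[tuple[int, int], float]
    distant: list | None = None          # second-or-further neighbor positions


@dataclass
class FrameStats:
    frame_name: str
    mean_p_lm: dict
    sd_p_lm: dict
    inconsistent: bool
    n_members: int


def recompute_type_in_frames(member_atoms: list[MemberAtom], target_frames,
                             sd_threshold: float = 0.05,
                             lmax: int = LMAX) -> dict[str, FrameStats]:
    """Average member populations per target frame (unweighted sample sd,
    no symmetry filtering); a frame is flagged inconsistent when any Plm sd
    exceeds ``sd_threshold`` (electrons).  Members whose geometry cannot
    realize a frame are skipped with a logged warning."""
    if len(member_atoms) < 2:
        raise FrameError("need at least two member atoms to average")
    order = lm_indices(lmax)
    out: dict[str, FrameStats] = {}
    for frame in target_frames:
        rows = []
        for idx, member in enumerate(member_atoms):
            try:
                real = realize_frame(frame, member.central, member.neighbors,
                                     member.distant)
            except FrameError as exc:
                logger.warning("member %d skipped for frame %s: %s",
                               idx, frame.name, exc)
                continue
            rotated = rotate_plm(member.p_lm, real.rotation, lmax)
            rows.append(plm_dict_to_vector(rotated, lmax))
        if len(rows) < 2:
            logger.warning("frame %s realizable for %d member(s); skipped",
                           frame.name, len(rows))
            continue
        arr = np.asarray(rows)
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1)
        out[frame.name] = FrameStats(
            frame_name=frame.name,
            mean_p_lm=dict(zip(order, map(float, mean))),
            sd_p_lm=dict(zip(order, map(float, sd))),
            inconsistent=bool((sd > sd_threshold).any()),
            n_members=len(rows))
    return out


def frames_to_csv(frames) -> str:
    rows = ["name,group,number,family,primary,secondary"]
    for f in frames:
        rows.append(",".join([
            f.name, f.group, str(f.number), f.family,
            f"{f.primary[0]}:{f.primary[1].kind}:{'|'.join(f.primary[1].labels)}",
            f"{f.secondary[0]}:{f.secondary[1].kind}:{'|'.join(f.secondary[1].labels)}",
        ]))
    return "\n".join(rows) + "\n"
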