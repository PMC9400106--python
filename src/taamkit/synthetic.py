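"""Seeded synthetic atom-type bank with planted ground truth.

The generator emulates the statistical structure of a multipolar pseudoatom
databank: per-element Pval near the formal valence-electron count, kappa and
kappa' near 1, and deformation populations that follow a planted
hybridization (sp1/sp2/sp3) and site symmetry in a stated local frame.
Member-atom geometries are idealized neighbor arrangements (linear, bent,
trigonal planar, pyramidal, tetrahedral, octahedral) with small angular
jitter, and every parameter carries independent Gaussian noise.

Deformation patterns are *bond directed*: the planted P_lm vector is the
degree-limited expansion of a sum of lobes pointing along bonds and lone
pairs, which automatically respects the planted point group and reproduces
the characteristic dominant multipoles (e.g. negative P32 for tetrahedral
types in a ZabXc frame, positive P33 for trigonal planar types in XabYa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .bank import (AtomTypeEntry, AtomTypeTopology,
                   MultipoleParameterSet, NeighborRecord,
                   filter_stored_plm)
from .frames import (LocalFrame, MemberAtom, enumerate_frames, realize_frame,
                     recompute_type_in_frames, rotate_plm)
from .harmonics import lm_indices, real_sh_many
from .symmetry import allowed_indices

PATTERN_LMAX = 3


class SyntheticSpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# idealized neighbor arrangements
# ---------------------------------------------------------------------------

_T = 109.47122063449069  # tetrahedral angle, degrees


def _sph(theta_deg: float, phi_deg: float) -> np.ndarray:
    t, p = math.radians(theta_deg), math.radians(phi_deg)
    return np.array([math.sin(t) * math.cos(p),
                     math.sin(t) * math.sin(p), math.cos(t)])


@dataclass(frozen=True)
class IdealGeometry:
    bonds: tuple            # unit vectors toward first neighbors a, b, ...
    lone_pairs: tuple = ()  # unit vectors of lone-pair lobes
    distants: tuple = ()    # positions (angstrom) of second-shell atoms


def ideal_geometry(group_label: str, hybridization: str) -> IdealGeometry:
    """Idealized unit bond directions and lone-pair lobes for a group."""
    key = (group_label, hybridization)
    if group_label == "1x":
        return IdealGeometry(bonds=(_sph(0, 0),))
    if group_label == "1p":
        # sp2-like terminal atom: one bond, two in-plane lone pairs, and a
        # non-collinear second-shell atom for the ZaXx frame
        return IdealGeometry(
            bonds=(_sph(0, 0),),
            lone_pairs=(_sph(120, 0), _sph(120, 180)),
            distants=(np.array([1.2, 0.0, 1.9]),))
    if group_label == "2x":
        return IdealGeometry(bonds=(_sph(0, 0), _sph(180, 0)))
    if group_label == "2p":
        # bent, water-like: bonds in the YZ plane about +Z, lone pairs in XZ
        half = 104.5 / 2.0
        return IdealGeometry(
            bonds=(_sph(half, 90), _sph(half, -90)),
            lone_pairs=(_sph(125, 0), _sph(125, 180)))
    if group_label == "3p":
        if hybridization == "sp2":
            # trigonal planar in XY, a/b bisected by +X, pi lobes along +-Z
            return IdealGeometry(
                bonds=(_sph(90, 60), _sph(90, -60), _sph(90, 180)),
                lone_pairs=(_sph(0, 0), _sph(180, 0)))
        raise SyntheticSpecError(f"unsupported combination {key}")
    if group_label == "3n":
        # pyramidal: bonds around +Z, lone pair along -Z
        return IdealGeometry(
            bonds=(_sph(_T - 40, 0), _sph(_T - 40, 120), _sph(_T - 40, 240)),
            lone_pairs=(_sph(180, 0),))
    if group_label == "4n":
        return IdealGeometry(bonds=(
            _sph(0, 0), _sph(_T, 0), _sph(_T, 120), _sph(_T, 240)))
    if group_label == "6n":
        return IdealGeometry(bonds=(
            _sph(0, 0), _sph(180, 0), _sph(90, 0), _sph(90, 90),
            _sph(90, 180), _sph(90, 270)))
    raise SyntheticSpecError(f"no idealized geometry for group {group_label}")


def bond_directed_pattern(bond_dirs, lone_pair_dirs=(), *, scale: float,
                          lone_pair_weight: float = 1.3,
                          lmax: int = PATTERN_LMAX) -> dict:
    """Degree-limited population vector of lobes along the given directions.

    The expansion of a sum of zonal kernels centered on the directions is
    taken in the orthonormal basis and converted to density-normalized
    populations, then rescaled so the largest |P_lm| equals ``scale``
    (electrons).  The result inherits the point symmetry of the direction
    set exactly.
    """
    from .harmonics import _d_over_y  # diagonal d_lm <-> orthonormal scaling
    dirs = [(np.asarray(d, float), 1.0) for d in bond_dirs]
    dirs += [(np.asarray(d, float), lone_pair_weight) for d in lone_pair_dirs]
    if not dirs:
        raise SyntheticSpecError("pattern needs at least one direction")
    coeff = np.zeros(len(lm_indices(lmax)))
    for d, w in dirs:
        coeff += w * real_sh_many(d / np.linalg.norm(d), lmax,
                                  normalization="orthonormal").ravel()
    pattern = {}
    for (l, m), q in zip(lm_indices(lmax), coeff):
        if l == 0:
            continue
        pattern[(l, m)] = q / _d_over_y(l, m)
    peak = max(abs(v) for v in pattern.values())
    if peak == 0.0:
        raise SyntheticSpecError("directions produced a null pattern")
    out = {lm: v * scale / peak for lm, v in pattern.items()}
    return {lm: v for lm, v in out.items() if abs(v) > 1e-12}


# ---------------------------------------------------------------------------
# planted specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedClusterSpec:
    cluster_id: int
    element: str
    group_label: str
    hybridization: str            # sp1 | sp2 | sp3
    point_group: str
    frame_family: str             # system family of the reference frame
    neighbor_elements: tuple      # first-shell elements, labeled a, b, ...
    mean_kappa: float
    mean_p_val: float
    mean_kappa_prime: float
    pattern_scale: float          # electrons, largest |P_lm| of the pattern
    second_neighbors: tuple = ()  # (attach label, element) pairs
    lone_pair_weight: float = 1.3
    n_types: int = 6
    n_member_atoms: int = 16
    noise_plm: float = 0.02       # electrons, member-to-member scatter
    type_spread_plm: float = 0.002  # electrons, type-to-type scatter in a cluster
    noise_kappa: float = 0.003
    noise_p_val: float = 0.005
    angle_jitter_deg: float = 2.0
    bond_length: float = 1.5
    # explicit P_lm means in the reference frame; None -> bond-directed
    pattern_override: tuple = ()  # ((l, m, value), ...)

    def reference_frame(self) -> LocalFrame:
        for frame in enumerate_frames(self.group_label):
            if frame.family == self.frame_family:
                return frame
        raise SyntheticSpecError(
            f"group {self.group_label} has no {self.frame_family} frame")

    def pattern(self) -> dict:
        """Planted P_lm means in the reference frame; validated against the
        planted point group."""
        if self.pattern_override:
            pattern = {(l, m): v for l, m, v in self.pattern_override}
        else:
            geo = ideal_geometry(self.group_label, self.hybridization)
            frame = self.reference_frame()
            positions = {lab: self.bond_length * b
                         for lab, b in zip("abcdef", geo.bonds)}
            rot = realize_frame(frame, np.zeros(3), positions,
                                list(geo.distants) or None).rotation
            pattern = bond_directed_pattern(
                [rot @ b for b in geo.bonds],
                [rot @ lp for lp in geo.lone_pairs],
                scale=self.pattern_scale,
                lone_pair_weight=self.lone_pair_weight)
        allowed = allowed_indices(self.point_group, PATTERN_LMAX)
        bad = {lm: v for lm, v in pattern.items()
               if lm not in allowed and abs(v) > 1e-8}
        if bad:
            raise SyntheticSpecError(
                f"cluster {self.cluster_id}: pattern violates point group "
                f"{self.point_group}: {bad}")
        return {lm: v for lm, v in pattern.items() if lm in allowed}

    def validate(self) -> None:
        if self.noise_plm < 0 or self.noise_kappa < 0 or self.noise_p_val < 0:
            raise SyntheticSpecError("noise sds must be non-negative")
        if self.n_types < 1 or self.n_member_atoms < 2:
            raise SyntheticSpecError("need >=1 types and >=2 members")
        if len(self.neighbor_elements) != len(
                ideal_geometry(self.group_label, self.hybridization).bonds):
            raise SyntheticSpecError("neighbor elements do not match group")
        self.pattern()   # raises if inconsistent with the point group


@dataclass
class GroundTruth:
    """Planted provenance of every generated entry."""

    cluster_id: dict[str, int]
    point_group: dict[str, str]
    reference_frame: dict[str, str]

    def row_label(self, entry_name: str, frame: LocalFrame) -> str:
        """Expected leaf identity of one (entry, frame) row: rotations of a
        planted cluster coincide exactly within one system family."""
        return f"{self.cluster_id[entry_name]}|{frame.family}"

    def to_csv(self) -> str:
        rows = ["entry,cluster_id,point_group,reference_frame"]
        for name in sorted(self.cluster_id):
            rows.append(f"{name},{self.cluster_id[name]},"
                        f"{self.point_group[name]},{self.reference_frame[name]}")
        return "\n".join(rows) + "\n"


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _jitter_direction(d: np.ndarray, sd_deg: float,
                      rng: np.random.Generator) -> np.ndarray:
    if sd_deg <= 0:
        return d
    perturbed = d + rng.normal(scale=math.radians(sd_deg), size=3)
    return perturbed / np.linalg.norm(perturbed)


def _topology_for(spec: PlantedClusterSpec) -> AtomTypeTopology:
    neighbors = [NeighborRecord(shell=1, label=lab, element=el,
                                planar=spec.hybridization == "sp2")
                 for lab, el in zip("abcdef", spec.neighbor_elements)]
    for i, (attach, el) in enumerate(spec.second_neighbors):
        neighbors.append(NeighborRecord(
            shell=2, label=f"{attach}{i + 1}", element=el, attached_to=attach))
    return AtomTypeTopology(central_element=spec.element,
                            neighbors=tuple(neighbors),
                            group_label=spec.group_label)


def generate_bank(specs, seed: int):
    """Generate entries, their member atoms, and the planted ground truth.

    Returns ``(entries, members_by_name, truth)``; reproducible for a fixed
    seed.  Member populations are expressed in the global frame so that any
    frame recomputation must genuinely rotate them back.
    """
    if not specs:
        raise SyntheticSpecError("no planted cluster specs given")
    rng = np.random.default_rng(seed)
    entries: list[AtomTypeEntry] = []
    members_by_name: dict[str, list[MemberAtom]] = {}
    truth = GroundTruth({}, {}, {})
    feature_lms = [lm for lm in lm_indices(PATTERN_LMAX) if lm[0] > 0]

    for spec in specs:
        spec.validate()
        geo = ideal_geometry(spec.group_label, spec.hybridization)
        frame = spec.reference_frame()
        pattern = spec.pattern()
        for t in range(spec.n_types):
            name = f"{spec.element}{spec.cluster_id}{t:02d}"
            type_plm = {lm: pattern.get(lm, 0.0)
                        + rng.normal(scale=spec.type_spread_plm)
                        for lm in feature_lms}
            kappa = spec.mean_kappa + rng.normal(scale=spec.noise_kappa)
            kappa_p = spec.mean_kappa_prime + rng.normal(scale=spec.noise_kappa)
            p_val = spec.mean_p_val + rng.normal(scale=spec.noise_p_val)

            members: list[MemberAtom] = []
            for _ in range(spec.n_member_atoms):
                g_rot = _random_rotation(rng)
                positions = {
                    lab: spec.bond_length
                    * (g_rot @ _jitter_direction(b, spec.angle_jitter_deg, rng))
                    for lab, b in zip("abcdef", geo.bonds)}
                distant = ([g_rot @ d for d in geo.distants]
                           if geo.distants else None)
                local = realize_frame(frame, np.zeros(3), positions,
                                      distant).rotation
                member_local = {lm: v + rng.normal(scale=spec.noise_plm)
                                for lm, v in type_plm.items()}
                member_global = rotate_plm(member_local, local.T)
                members.append(MemberAtom(central=np.zeros(3),
                                          neighbors=positions,
                                          p_lm=member_global,
                                          distant=distant))

            stats = recompute_type_in_frames(members, [frame],
                                             lmax=PATTERN_LMAX)[frame.name]
            allowed = allowed_indices(spec.point_group, PATTERN_LMAX)
            params = MultipoleParameterSet(
                kappa=kappa, p_val=p_val, kappa_prime=kappa_p,
                p_lm=filter_stored_plm(stats.mean_p_lm, stats.sd_p_lm,
                                       allowed),
                sd_p_lm=dict(stats.sd_p_lm),
                sd_kappa=spec.noise_kappa, sd_p_val=spec.noise_p_val,
                sd_kappa_prime=spec.noise_kappa)
            entry = AtomTypeEntry(
                name=name, topology=_topology_for(spec), frame=frame.name,
                params=params, inconsistent=stats.inconsistent)
            entry.validate()
            entries.append(entry)
            members_by_name[name] = members
            truth.cluster_id[name] = spec.cluster_id
            truth.point_group[name] = spec.point_group
            truth.reference_frame[name] = frame.name
    return entries, members_by_name, truth


def default_paper_like_spec() -> list[PlantedClusterSpec]:
    """Nine planted clusters spanning H/C/N/O/S across the 1x, 1p, 2x, 2p,
    3p, 3n and 4n groups: polar vs nonpolar hydrogen, sp1/sp2/sp3 carbon,
    pyramidal nitrogen, water-like and terminal sp2 oxygen, and a sulfur
    analogue with larger deformation populations."""
    return [
        PlantedClusterSpec(0, "H", "1x", "sp1", "cylindrical", "ZaXb",
                           ("O",), mean_kappa=1.15, mean_p_val=0.85,
                           mean_kappa_prime=1.20, pattern_scale=0.28,
                           second_neighbors=(("a", "X"),), n_types=5,
                           pattern_override=((1, 0, 0.28), (2, 0, 0.10))),
        PlantedClusterSpec(1, "H", "1x", "sp1", "cylindrical", "ZaXb",
                           ("C",), mean_kappa=1.05, mean_p_val=1.05,
                           mean_kappa_prime=1.10, pattern_scale=0.12,
                           second_neighbors=(("a", "X"),), n_types=5,
                           pattern_override=((1, 0, 0.12), (2, 0, 0.04))),
        PlantedClusterSpec(2, "C", "4n", "sp3", "-43m", "ZabXc",
                           ("C", "C", "C", "C"), mean_kappa=0.99,
                           mean_p_val=4.05, mean_kappa_prime=0.86,
                           pattern_scale=0.25,
                           second_neighbors=(("a", "X"), ("b", "X"))),
        PlantedClusterSpec(3, "C", "3p", "sp2", "-6m2", "XabYa",
                           ("C", "C", "C"), mean_kappa=0.99,
                           mean_p_val=4.00, mean_kappa_prime=0.92,
                           pattern_scale=0.30, lone_pair_weight=0.8,
                           second_neighbors=(("a", "X"),)),
        PlantedClusterSpec(4, "C", "2x", "sp1", "cylindrical", "ZaXb",
                           ("C", "N"), mean_kappa=1.00, mean_p_val=3.95,
                           mean_kappa_prime=0.95, pattern_scale=0.20,
                           second_neighbors=(("a", "X"),)),
        PlantedClusterSpec(5, "N", "3n", "sp3", "3m", "ZabcXa",
                           ("C", "C", "C"), mean_kappa=1.00,
                           mean_p_val=5.05, mean_kappa_prime=0.90,
                           pattern_scale=0.22,
                           second_neighbors=(("a", "X"),)),
        PlantedClusterSpec(6, "O", "2p", "sp3", "mm2", "ZabYa",
                           ("H", "H"), mean_kappa=0.98, mean_p_val=6.10,
                           mean_kappa_prime=0.95, pattern_scale=0.12),
        PlantedClusterSpec(7, "O", "1p", "sp2", "m", "ZaXb",
                           ("C",), mean_kappa=0.98, mean_p_val=6.05,
                           mean_kappa_prime=0.97, pattern_scale=0.15,
                           second_neighbors=(("a", "X"), ("a", "X"))),
        PlantedClusterSpec(8, "S", "2p", "sp3", "mm2", "ZabYa",
                           ("C", "C"), mean_kappa=0.99, mean_p_val=5.90,
                           mean_kappa_prime=0.85, pattern_scale=0.35,
                           second_neighbors=(("a", "X"), ("b", "X"))),
        # two deliberately unique types: far from every other cluster, they
        # form singleton clusters per frame family (overlay category
        # "unique") and anchor the upper end of the k-distance curve
        PlantedClusterSpec(9, "N", "2p", "sp3", "mm2", "ZabYa",
                           ("O", "O"), mean_kappa=1.05, mean_p_val=4.55,
                           mean_kappa_prime=1.10, pattern_scale=0.55,
                           second_neighbors=(("a", "X"),), n_types=1),
        PlantedClusterSpec(10, "C", "3p", "sp2", "-6m2", "XabYa",
                           ("N", "N", "N"), mean_kappa=1.08,
                           mean_p_val=3.45, mean_kappa_prime=1.15,
                           pattern_scale=0.60, lone_pair_weight=0.8,
                           second_neighbors=(("a", "X"),), n_types=1),
    ]


def hard_noise_preset(specs=None) -> list[PlantedClusterSpec]:
    """Same planted structure with member noise above the 0.05 e
    inconsistency threshold, to exercise the flag."""
    specs = specs if specs is not None else default_paper_like_spec()
    return [replace(s, noise_plm=0.08) for s in specs]
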