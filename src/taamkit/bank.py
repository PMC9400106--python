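"""Atom-type bank records and a plain-text bank dialect.

An atom type is an equivalence class of atoms sharing the same local chemical
topology (central element, first/second neighbor shells, planarity and ring
flags) and a set of averaged multipole-model parameters (kappa, Pval, kappa',
Plm with sample standard deviations) expressed in a named local coordinate
system.

The on-disk dialect is deliberately simple: one ``entry .. end`` block per
type made of key-value lines (formal grammar in ``docs/bank_format.md``).
``write_bank(parse_bank(text)) == text`` holds for canonically formatted
documents.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .harmonics import LMAX

# Elements that may appear in a bank plus the any-element wildcard.
KNOWN_ELEMENTS = {
    "H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I",
}
WILDCARD = "X"

ATOMIC_NUMBER = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Br": 35, "I": 53, WILDCARD: 0,
}

#: formal valence electron counts used by the Pval subtraction transform
VALENCE_ELECTRONS = {
    "H": 1, "B": 3, "C": 4, "N": 5, "O": 6, "F": 7, "Si": 4, "P": 5,
    "S": 6, "Cl": 7, "Br": 7, "I": 7,
}

GROUP_LABELS = ("1x", "1p", "2x", "2p", "3p", "3n", "4n", "6n")
GROUP_NEIGHBOR_COUNT = {"1x": 1, "1p": 1, "2x": 2, "2p": 2,
                        "3p": 3, "3n": 3, "4n": 4, "6n": 6}

#: sample-standard-deviation threshold (electrons) for the inconsistent flag
INCONSISTENT_SD = 0.05
#: smallest |Plm| (electrons) kept by the bank storage filter
PLM_STORAGE_FLOOR = 0.002


class BankError(ValueError):
    """Malformed or invalid bank content."""


@dataclass(frozen=True)
class NeighborRecord:
    """One atom on the connectivity list of an atom type."""

    shell: int                      # 1 = bonded to the center, 2 = next shell
    label: str                      # a, b, c ... within its shell
    element: str                    # element symbol or the wildcard "X"
    planar: bool = False            # member of a planar group
    rings: frozenset[int] = frozenset()   # {3,4} rings and planar {5,6,7} rings
    attached_to: str | None = None  # first-shell label a second neighbor hangs on

    def validate(self) -> None:
        if self.shell not in (1, 2, 3):
            raise BankError(f"unsupported neighbor shell {self.shell}")
        if self.element != WILDCARD and self.element not in KNOWN_ELEMENTS:
            raise BankError(f"unknown element symbol {self.element!r}")
        if not self.rings <= {3, 4, 5, 6, 7}:
            raise BankError(f"unsupported ring sizes {sorted(self.rings)}")
        if self.shell >= 2 and self.attached_to is None:
            raise BankError(
                f"neighbor {self.label} in shell {self.shell} lacks attachment")


@dataclass(frozen=True)
class AtomTypeTopology:
    central_element: str
    neighbors: tuple[NeighborRecord, ...]
    group_label: str

    @property
    def first_shell(self) -> tuple[NeighborRecord, ...]:
        return tuple(n for n in self.neighbors if n.shell == 1)

    @property
    def second_shell(self) -> tuple[NeighborRecord, ...]:
        return tuple(n for n in self.neighbors if n.shell >= 2)

    def validate(self) -> None:
        if self.central_element not in KNOWN_ELEMENTS:
            raise BankError(f"unknown element {self.central_element!r}")
        if self.group_label not in GROUP_LABELS:
            raise BankError(f"unknown group label {self.group_label!r}")
        first = self.first_shell
        if not first:
            raise BankError("atom type needs at least one first neighbor")
        expected = GROUP_NEIGHBOR_COUNT[self.group_label]
        if len(first) != expected:
            raise BankError(
                f"group {self.group_label} requires {expected} first "
                f"neighbors, got {len(first)}")
        first_labels = {n.label for n in first}
        if len(first_labels) != len(first):
            raise BankError("duplicate first-neighbor labels")
        for n in self.neighbors:
            n.validate()
            if n.shell >= 2 and n.attached_to not in first_labels:
                raise BankError(
                    f"second neighbor {n.label} attaches to undeclared "
                    f"first neighbor {n.attached_to!r}")


@dataclass
class MultipoleParameterSet:
    """kappa, Pval, kappa' and the deformation populations Plm (electrons)."""

    kappa: float
    p_val: float
    kappa_prime: float
    p_lm: dict[tuple[int, int], float] = field(default_factory=dict)
    sd_p_lm: dict[tuple[int, int], float] = field(default_factory=dict)
    sd_kappa: float = 0.0
    sd_p_val: float = 0.0
    sd_kappa_prime: float = 0.0

    def validate(self) -> None:
        if self.kappa <= 0 or self.kappa_prime <= 0:
            raise BankError("kappa and kappa' must be positive")
        if self.p_val <= 0:
            raise BankError("Pval must be positive")
        for (l, m) in self.p_lm:
            if not (0 <= l <= LMAX and abs(m) <= l):
                raise BankError(f"Plm index (l={l}, m={m}) out of range")
            if (l, m) not in self.sd_p_lm:
                raise BankError(f"Plm ({l},{m}) lacks a standard deviation")

    def max_plm_sd(self) -> float:
        return max(self.sd_p_lm.values(), default=0.0)


@dataclass
class AtomTypeEntry:
    name: str
    topology: AtomTypeTopology
    frame: str                       # local-coordinate-system name
    params: MultipoleParameterSet
    inconsistent: bool = False

    def validate(self) -> None:
        self.topology.validate()
        self.params.validate()
        flag = self.params.max_plm_sd() > INCONSISTENT_SD
        if self.inconsistent != flag:
            raise BankError(
                f"{self.name}: inconsistent flag {self.inconsistent} does not "
                f"match Plm sd data (max sd {self.params.max_plm_sd():.4f} e)")


def filter_stored_plm(p_lm: dict, sd: dict, allowed: set) -> dict:
    """Apply the bank storage filter to a Plm map.

    A population is kept iff |Plm| > 0.002 e, |Plm| exceeds one sample
    standard deviation, and its index is symmetry-allowed.  Total function;
    idempotent; output is a subset of the input.
    """
    out = {}
    for lm, value in p_lm.items():
        if lm not in allowed:
            continue
        if abs(value) <= PLM_STORAGE_FLOOR:
            continue
        if abs(value) <= sd.get(lm, math.inf):
            continue
        out[lm] = value
    return out


def assign_group(first_neighbor_coords, central_coord,
                 second_neighbor_coords=(), *,
                 collinear_tol_deg: float = 5.0,
                 planarity_tol: float = 0.1) -> str:
    """Classify a neighbor geometry into one of the eight frame groups.

    One neighbor: 1x when every second neighbor is collinear with the
    center-neighbor axis (cylindrical environment), otherwise 1p.  Two
    neighbors: 2x when collinear within ``collinear_tol_deg`` of 180 deg,
    else 2p.  Three: 3p when the center lies within ``planarity_tol``
    angstrom of the neighbor plane, else 3n.  Four -> 4n, six -> 6n.
    """
    center = np.asarray(central_coord, dtype=float)
    first = np.asarray(first_neighbor_coords, dtype=float).reshape(-1, 3)
    n = len(first)

    def _angle(u, v):
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))

    if n == 1:
        axis = first[0] - center
        seconds = np.asarray(second_neighbor_coords, dtype=float).reshape(-1, 3)
        if len(seconds) == 0:
            return "1x"
        angs = [_angle(axis, s - center) for s in seconds]
        collinear = all(a > 180.0 - collinear_tol_deg or
                        a < collinear_tol_deg for a in angs)
        return "1x" if collinear else "1p"
    if n == 2:
        ang = _angle(first[0] - center, first[1] - center)
        return "2x" if ang > 180.0 - collinear_tol_deg else "2p"
    if n == 3:
        # distance of the center from the plane through the three neighbors
        v1, v2 = first[1] - first[0], first[2] - first[0]
        normal = np.cross(v1, v2)
        nn = np.linalg.norm(normal)
        if nn < 1e-12:
            raise BankError("degenerate (collinear) three-neighbor geometry")
        dist = abs(np.dot(center - first[0], normal / nn))
        return "3p" if dist <= planarity_tol else "3n"
    if n == 4:
        return "4n"
    if n == 6:
        return "6n"
    raise BankError(f"unsupported first-neighbor count {n}")


# ---------------------------------------------------------------------------
# text format
# ---------------------------------------------------------------------------

_HEADER = "# taamkit bank 1"
_FMT = "{:.6f}"


def _fmt_rings(rings: frozenset[int]) -> str:
    return ",".join(str(r) for r in sorted(rings))


def write_bank(entries) -> str:
    """Serialize entries in the canonical dialect (round-trips bit-exactly)."""
    buf = io.StringIO()
    buf.write(_HEADER + "\n")
    for e in entries:
        buf.write(f"entry {e.name}\n")
        buf.write(f"element {e.topology.central_element}\n")
        buf.write(f"group {e.topology.group_label}\n")
        buf.write(f"frame {e.frame}\n")
        buf.write(f"inconsistent {'yes' if e.inconsistent else 'no'}\n")
        for n in e.topology.neighbors:
            parts = [f"neighbor {n.shell} {n.label} {n.element}"]
            if n.planar:
                parts.append("planar")
            if n.rings:
                parts.append(f"rings={_fmt_rings(n.rings)}")
            if n.attached_to is not None:
                parts.append(f"attach={n.attached_to}")
            buf.write(" ".join(parts) + "\n")
        p = e.params
        buf.write(f"kappa {_FMT.format(p.kappa)} {_FMT.format(p.sd_kappa)}\n")
        buf.write(f"pval {_FMT.format(p.p_val)} {_FMT.format(p.sd_p_val)}\n")
        buf.write("kappa_prime "
                  f"{_FMT.format(p.kappa_prime)} {_FMT.format(p.sd_kappa_prime)}\n")
        for (l, m) in sorted(p.p_lm):
            buf.write(f"plm {l} {m} {_FMT.format(p.p_lm[(l, m)])} "
                      f"{_FMT.format(p.sd_p_lm[(l, m)])}\n")
        buf.write("end\n")
    return buf.getvalue()


def parse_bank(text: str) -> list[AtomTypeEntry]:
    """Parse a bank document; entries are validated against type invariants."""
    entries: list[AtomTypeEntry] = []
    state: dict | None = None
    lines = text.splitlines()
    if not lines or lines[0].strip() != _HEADER:
        raise BankError(f"missing bank header line {_HEADER!r}")

    def err(lineno, msg):
        name = state["name"] if state else "?"
        return BankError(f"line {lineno} (entry {name}): {msg}")

    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        key = tokens[0]
        if key == "entry":
            if state is not None:
                raise err(lineno, "nested 'entry' block")
            if len(tokens) != 2:
                raise err(lineno, "'entry' needs exactly one name")
            state = {"name": tokens[1], "neighbors": [], "p_lm": {},
                     "sd_p_lm": {}}
            continue
        if state is None:
            raise BankError(f"line {lineno}: content outside an entry block")
        try:
            if key == "element":
                state["element"] = tokens[1]
            elif key == "group":
                state["group"] = tokens[1]
            elif key == "frame":
                state["frame"] = tokens[1]
            elif key == "inconsistent":
                state["inconsistent"] = tokens[1] == "yes"
            elif key == "neighbor":
                shell, label, element = int(tokens[1]), tokens[2], tokens[3]
                planar, rings, attach = False, frozenset(), None
                for opt in tokens[4:]:
                    if opt == "planar":
                        planar = True
                    elif opt.startswith("rings="):
                        rings = frozenset(int(r)
                                          for r in opt[6:].split(",") if r)
                    elif opt.startswith("attach="):
                        attach = opt[7:]
                    else:
                        raise err(lineno, f"unknown neighbor option {opt!r}")
                state["neighbors"].append(NeighborRecord(
                    shell=shell, label=label, element=element, planar=planar,
                    rings=rings, attached_to=attach))
            elif key in ("kappa", "pval", "kappa_prime"):
                state[key] = float(tokens[1])
                state["sd_" + key] = float(tokens[2])
            elif key == "plm":
                l, m = int(tokens[1]), int(tokens[2])
                if not (0 <= l <= LMAX and abs(m) <= l):
                    raise err(lineno, f"Plm index (l={l}, m={m}) out of range")
                state["p_lm"][(l, m)] = float(tokens[3])
                state["sd_p_lm"][(l, m)] = float(tokens[4])
            elif key == "end":
                for req in ("element", "group", "frame",
                            "kappa", "pval", "kappa_prime"):
                    if req not in state:
                        raise err(lineno, f"missing '{req}' before 'end'")
                topo = AtomTypeTopology(
                    central_element=state["element"],
                    neighbors=tuple(state["neighbors"]),
                    group_label=state["group"])
                params = MultipoleParameterSet(
                    kappa=state["kappa"], p_val=state["pval"],
                    kappa_prime=state["kappa_prime"],
                    p_lm=state["p_lm"], sd_p_lm=state["sd_p_lm"],
                    sd_kappa=state["sd_kappa"], sd_p_val=state["sd_pval"],
                    sd_kappa_prime=state["sd_kappa_prime"])
                entry = AtomTypeEntry(
                    name=state["name"], topology=topo, frame=state["frame"],
                    params=params,
                    inconsistent=state.get("inconsistent", False))
                entry.validate()
                entries.append(entry)
                state = None
            else:
                raise err(lineno, f"unknown key {key!r}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, BankError):
                raise
            raise err(lineno, f"malformed line {line!r}: {exc}") from exc
    if state is not None:
        raise BankError(f"entry {state['name']} not closed with 'end'")
    return entries


def entries_to_csv(entries, lmax: int = LMAX) -> str:
    """One row per type: name, element, group, frame, kappa, Pval, kappa',
    then Plm columns P1-1 ... in canonical order."""
    from .harmonics import lm_indices
    cols = [lm for lm in lm_indices(lmax) if lm[0] > 0]
    header = (["name", "element", "group", "frame",
               "kappa", "pval", "kappa_prime"]
              + [f"P{l}{m}" for l, m in cols])
    rows = [",".join(header)]
    for e in entries:
        vals = [e.name, e.topology.central_element, e.topology.group_label,
                e.frame, _FMT.format(e.params.kappa),
                _FMT.format(e.params.p_val),
                _FMT.format(e.params.kappa_prime)]
        vals += [_FMT.format(e.params.p_lm.get(lm, 0.0)) for lm in cols]
        rows.append(",".join(vals))
    return "\n".join(rows) + "\n"


def neighbor_order_key(record: NeighborRecord, position: int):
    """Label-assignment order: descending atomic number, ties by input order."""
    return (-ATOMIC_NUMBER.get(record.element, 0), position)
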