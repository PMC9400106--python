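import pathlib

import numpy as np
import pytest

from taamkit.bank import (AtomTypeEntry, AtomTypeTopology,
                          MultipoleParameterSet, NeighborRecord)
from taamkit.clustering import ClusteringConfig
from taamkit.pipeline import rotate_bank
from taamkit.synthetic import default_paper_like_spec, generate_bank

DATA_DIR = pathlib.Path(__file__).parent / "data"

#: single seed used by every seeded fixture in the suite
SUITE_SEED = 17


def make_entry(name, element, group, first, second=(), frame=None,
               p_lm=None, sd=None, kappa=1.0, p_val=None, kappa_prime=1.0,
               inconsistent=False):
    """Small helper to assemble a valid bank entry for tests.

    ``first`` is a list of (element, planar, rings) or plain element
    symbols; ``second`` a list of (attach label, element).
    """
    neighbors = []
    for lab, item in zip("abcdef", first):
        if isinstance(item, str):
            item = (item, False, ())
        el, planar, rings = item
        neighbors.append(NeighborRecord(shell=1, label=lab, element=el,
                                        planar=planar,
                                        rings=frozenset(rings)))
    for i, (attach, el) in enumerate(second):
        neighbors.append(NeighborRecord(shell=2, label=f"{attach}{i+1}",
                                        element=el, attached_to=attach))
    topo = AtomTypeTopology(central_element=element,
                            neighbors=tuple(neighbors), group_label=group)
    p_lm = dict(p_lm or {})
    sd = dict(sd if sd is not None else {lm: 0.01 for lm in p_lm})
    from taamkit.bank import VALENCE_ELECTRONS
    params = MultipoleParameterSet(
        kappa=kappa, p_val=p_val if p_val is not None
        else float(VALENCE_ELECTRONS[element]),
        kappa_prime=kappa_prime, p_lm=p_lm, sd_p_lm=sd)
    from taamkit.frames import enumerate_frames
    entry = AtomTypeEntry(
        name=name, topology=topo,
        frame=frame or enumerate_frames(group)[0].name,
        params=params, inconsistent=inconsistent)
    entry.validate()
    return entry


@pytest.fixture(scope="session")
def default_bank():
    """Default synthetic bank: entries, member atoms, planted truth."""
    return generate_bank(default_paper_like_spec(), seed=SUITE_SEED)


@pytest.fixture(scope="session")
def rotated_table(default_bank):
    entries, members, _ = default_bank
    return rotate_bank(entries, members)


@pytest.fixture(scope="session")
def clustered(rotated_table):
    from taamkit.pipeline import cluster_rotated
    return cluster_rotated(rotated_table, ClusteringConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(SUITE_SEED)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture
def topology_fixture_entries():
    """Twelve entries whose extended tree has exactly nine terminal
    clusters, enumerated by hand:

    1. C/3/(C,C,H)/4/XXXX  x3  -> one 3-element cluster
    2. C/3/(C,N,O)/4/XXXX  x2  -> one 2-element cluster
    3-9. seven entries with pairwise distinct signatures -> singletons
    """
    shared1 = dict(element="C", group="3p",
                   first=["C", "C", "H"],
                   second=[("a", "X"), ("a", "X"), ("b", "X"), ("b", "X")])
    shared2 = dict(element="C", group="3p",
                   first=["C", "N", "O"],
                   second=[("a", "X"), ("a", "X"), ("b", "X"), ("b", "X")])
    entries = [make_entry(f"C10{i}", **shared1) for i in range(3)]
    entries += [make_entry(f"C20{i}", **shared2) for i in range(2)]
    entries.append(make_entry("C301", "C", "3p", ["C", "C", "C"],
                              [("a", "X")]))
    entries.append(make_entry("C302", "C", "4n", ["C", "C", "H", "H"],
                              [("a", "X")]))
    entries.append(make_entry("N401", "N", "3n", ["C", "C", "C"],
                              [("a", "X")]))
    entries.append(make_entry("O501", "O", "2p", ["H", "H"]))
    entries.append(make_entry("O502", "O", "1p", ["C"], [("a", "X")]))
    entries.append(make_entry("H601", "H", "1x", ["O"], [("a", "X")]))
    entries.append(make_entry("S701", "S", "2p", ["C", "C"],
                              [("a", "X"), ("b", "X")]))
    return entries
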