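"""Local coordinate systems: enumeration, realization, Plm rotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taamkit.frames import (FrameError, GROUP_FRAME_COUNTS, enumerate_frames,
                            MemberAtom, parse_frame_name, realize_frame,
                            recompute_type_in_frames, rotate_plm)
from taamkit.harmonics import lm_indices, plm_l_norms
from .conftest import random_rotation

TETRA = {
    "a": np.array([1.0, 1.0, 1.0]),
    "b": np.array([1.0, -1.0, -1.0]),
    "c": np.array([-1.0, 1.0, -1.0]),
    "d": np.array([-1.0, -1.0, 1.0]),
}


class TestEnumeration:
    @pytest.mark.parametrize("group,count", sorted(GROUP_FRAME_COUNTS.items()))
    def test_frame_counts_per_group(self, group, count):
        frames = enumerate_frames(group)
        assert len(frames) == count
        assert len({f.name for f in frames}) == count

    def test_names_parse_back_to_their_specs(self):
        for group in GROUP_FRAME_COUNTS:
            for frame in enumerate_frames(group):
                assert parse_frame_name(frame.name) == frame

    def test_rotation_number_bands(self):
        for frame in enumerate_frames("4n"):
            band = {"ZaXb": range(1, 13), "XabYa": range(21, 33),
                    "ZabXc": range(41, 53), "ZabcXa": range(61, 65)}
            assert frame.number in band[frame.family]

    def test_printed_triple_frame_quartet(self):
        names = [f.name for f in enumerate_frames("4n") if f.number >= 61]
        assert names == ["4n_61-ZabcXa", "4n_62-ZabdXa",
                         "4n_63-ZbcdXb", "4n_64-ZacdXa"]

    def test_single_neighbor_frames(self):
        assert enumerate_frames("1x")[0].name == "1x_1-ZaXany"
        assert enumerate_frames("1p")[0].name == "1p_1-ZaXx"

    def test_group_neighbor_mismatch(self):
        with pytest.raises(FrameError):
            enumerate_frames("4n", n_first_neighbors=3)


class TestRealization:
    def test_axis_aligned_zaxb_is_identity(self):
        frame = enumerate_frames("2p")[0]     # 2p_1-ZaXb
        real = realize_frame(frame, [0, 0, 0],
                             {"a": [0, 0, 1.0], "b": [1.0, 0, 1.0]})
        np.testing.assert_allclose(real.rotation, np.eye(3), atol=1e-12)

    def test_zabxc_on_tetrahedron_is_proper_orthonormal(self):
        frame = [f for f in enumerate_frames("4n")
                 if f.name == "4n_41-ZabXc"][0]
        real = realize_frame(frame, np.zeros(3), TETRA)
        r = real.rotation
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)
        # Z bisects bonds a and b
        z_expected = (TETRA["a"] + TETRA["b"])
        z_expected = z_expected / np.linalg.norm(z_expected)
        np.testing.assert_allclose(r[2], z_expected, atol=1e-12)

    def test_swapping_pair_members_flips_y_keeps_x(self):
        frames = {f.name: f for f in enumerate_frames("3p")}
        ya = frames["3p_21-XabYa"]
        yb = frames["3p_22-XabYb"]
        pos = {"a": np.array([0.5, 0.87, 0.0]),
               "b": np.array([0.5, -0.87, 0.0]),
               "c": np.array([-1.0, 0.0, 0.0])}
        ra = realize_frame(ya, np.zeros(3), pos).rotation
        rb = realize_frame(yb, np.zeros(3), pos).rotation
        np.testing.assert_allclose(ra[0], rb[0], atol=1e-12)   # X shared
        np.testing.assert_allclose(ra[1], -rb[1], atol=1e-12)  # Y flipped

    def test_collinear_specs_raise(self):
        frame = enumerate_frames("2p")[0]
        with pytest.raises(FrameError, match="degenerate"):
            realize_frame(frame, [0, 0, 0],
                          {"a": [0, 0, 1.0], "b": [0, 0, 2.0]})

    def test_missing_neighbor_raises(self):
        frame = enumerate_frames("2p")[0]
        with pytest.raises(FrameError, match="missing"):
            realize_frame(frame, [0, 0, 0], {"a": [0, 0, 1.0]})

    def test_zaxx_uses_nearest_noncollinear_distant(self):
        frame = enumerate_frames("1p")[0]
        real = realize_frame(frame, np.zeros(3), {"a": [0, 0, 1.2]},
                             distant_positions=[[0, 0, 2.4], [1.0, 0, 1.8]])
        np.testing.assert_allclose(real.rotation[2], [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(real.rotation[0], [1, 0, 0], atol=1e-12)


class TestRotatePlm:
    def test_identity_is_exact(self):
        p = {(1, 0): 0.2, (3, 3): -0.1}
        assert rotate_plm(p, np.eye(3)) == p

    def test_90deg_about_y_moves_dipole_to_x(self):
        ry = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
        out = rotate_plm({(1, 0): 1.0}, ry)
        assert out[(1, 0)] == pytest.approx(0.0, abs=1e-12)
        assert abs(out[(1, 1)]) == pytest.approx(1.0, abs=1e-12)

    def test_improper_rejected(self):
        with pytest.raises(FrameError, match="improper"):
            rotate_plm({(1, 0): 1.0}, np.diag([1.0, 1.0, -1.0]))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_invariant_norm_and_composition(self, seed):
        rng = np.random.default_rng(seed)
        p = {lm: float(v) for lm, v in
             zip(lm_indices(4), rng.normal(size=25))}
        r1, r2 = random_rotation(rng), random_rotation(rng)
        once = rotate_plm(rotate_plm(p, r1), r2)
        combined = rotate_plm(p, r2 @ r1)
        for lm in lm_indices(4):
            assert once[lm] == pytest.approx(combined[lm], abs=1e-10)
        n0 = plm_l_norms(p, 4)
        n1 = plm_l_norms(combined, 4)
        for l in range(5):
            assert n1[l] == pytest.approx(n0[l], abs=1e-9)


class TestRecompute:
    def _members(self, p_lm, n=3, jitter=None, seed=0):
        rng = np.random.default_rng(seed)
        members = []
        for _ in range(n):
            pos = {k: v.copy() for k, v in TETRA.items()}
            if jitter:
                for k in pos:
                    pos[k] = pos[k] + rng.normal(scale=jitter, size=3)
            members.append(MemberAtom(central=np.zeros(3), neighbors=pos,
                                      p_lm=dict(p_lm)))
        return members

    def test_identical_members_have_zero_sd(self):
        frames = enumerate_frames("4n")[:3]
        stats = recompute_type_in_frames(
            self._members({(3, 2): -0.3, (1, 0): 0.05}), frames)
        for st_ in stats.values():
            assert max(st_.sd_p_lm.values()) == pytest.approx(0.0, abs=1e-12)
            assert not st_.inconsistent

    def test_two_point_sample_sd(self):
        # members differing by 0.2 e in P20: sd = 0.2/sqrt(2) ~ 0.141 > 0.05
        # (geometry chosen so the frame realizes as the identity and the
        # difference stays on P20)
        frame = enumerate_frames("2p")[0]     # 2p_1-ZaXb
        pos = {"a": np.array([0.0, 0.0, 1.0]),
               "b": np.array([1.0, 0.0, 1.0])}
        members = [
            MemberAtom(np.zeros(3), dict(pos), {(2, 0): 0.1}),
            MemberAtom(np.zeros(3), dict(pos), {(2, 0): 0.3}),
        ]
        stats = recompute_type_in_frames(members, [frame])[frame.name]
        assert stats.sd_p_lm[(2, 0)] == pytest.approx(0.2 / np.sqrt(2),
                                                      abs=1e-9)
        assert stats.inconsistent

    def test_fewer_than_two_members_rejected(self):
        with pytest.raises(FrameError):
            recompute_type_in_frames(
                self._members({(1, 0): 0.1}, n=1), enumerate_frames("4n")[:1])

    def test_misaligned_frame_inflates_sd(self, default_bank):
        """sp3 carbon members averaged in their own (ZabXc-family) frame show
        the planted pattern with small sd; a ZaXb frame mixes rotations of
        the jittered geometry and inflates the sd."""
        entries, members_by_name, truth = default_bank
        name = next(n for n, cid in truth.cluster_id.items() if cid == 2)
        members = members_by_name[name]
        frames = {f.name: f for f in enumerate_frames("4n")}
        aligned = truth.reference_frame[name]
        stats = recompute_type_in_frames(
            members, [frames[aligned], frames["4n_1-ZaXb"]])
        sd_aligned = max(stats[aligned].sd_p_lm.values())
        sd_misaligned = max(stats["4n_1-ZaXb"].sd_p_lm.values())
        assert sd_misaligned > sd_aligned
        # dominant multipole in the bisector frame is a negative P32
        mean = stats[aligned].mean_p_lm
        dominant = max(mean, key=lambda lm: abs(mean[lm]))
        assert dominant == (3, 2)
        assert mean[dominant] < 0


def test_kappa_pval_untouched_by_frame_changes(rotated_table, default_bank):
    entries, _, _ = default_bank
    by_name = {e.name: e for e in entries}
    for name, sub in rotated_table.groupby("entry"):
        assert (sub["kappa"] == by_name[name].params.kappa).all()
        assert (sub["p_val"] == by_name[name].params.p_val).all()
        assert (sub["kappa_prime"] == by_name[name].params.kappa_prime).all()
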