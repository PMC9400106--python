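"""Feature transforms, knee Eps, DBSCAN and the multi-level protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from taamkit.clustering import (ClusteringConfig, ClusteringError,
                                ClusterLabelPath, DegenerateEpsError,
                                FEATURE_COLUMNS, dbscan,
                                estimate_eps, multilevel_cluster, transform)
from ._reference import (brute_force_dbscan, labels_equivalent,
                         two_pass_subtract_normalize)


def frame_from_array(x, elements=None):
    df = pd.DataFrame(x, columns=FEATURE_COLUMNS)
    if elements is not None:
        df["element"] = elements
    return df


def synthetic_features(rng, n):
    x = np.zeros((n, 18))
    x[:, 0] = 1.0 + 0.05 * rng.normal(size=n)    # kappa
    x[:, 1] = 4.0 + 0.2 * rng.normal(size=n)     # p_val
    x[:, 2] = 0.9 + 0.05 * rng.normal(size=n)    # kappa'
    x[:, 3:] = 0.1 * rng.normal(size=(n, 15))
    return x


class TestTransform:
    def test_carbon_subtraction_rule(self):
        x = np.zeros((1, 18))
        x[0, :3] = [1.05, 4.2, 0.9]
        out = transform(frame_from_array(x, ["C"]), "subtract")
        assert out.iloc[0, 0] == pytest.approx(0.05)
        assert out.iloc[0, 1] == pytest.approx(0.2)
        assert out.iloc[0, 2] == pytest.approx(-0.1)

    def test_constant_column_normalizes_to_inverse_sqrt_n(self):
        n = 16
        x = np.ones((n, 18)) * 3.0
        out = transform(frame_from_array(x), "normalize")
        np.testing.assert_allclose(out.to_numpy(), 1.0 / np.sqrt(n),
                                   atol=1e-14)

    def test_matches_two_pass_oracle(self, rng):
        x = synthetic_features(rng, 40)
        elements = ["C"] * 20 + ["N"] * 10 + ["O"] * 10
        ours = transform(frame_from_array(x, elements),
                         "subtract_normalize").to_numpy()
        valence = np.array([{"C": 4, "N": 5, "O": 6}[e] for e in elements],
                           float)
        oracle = two_pass_subtract_normalize(x, valence)
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_zero_norm_column_left_alone(self, rng):
        x = synthetic_features(rng, 10)
        x[:, 5] = 0.0
        out = transform(frame_from_array(x), "normalize")
        assert (out.iloc[:, 5] == 0.0).all()

    def test_scale_applied_last(self, rng):
        x = synthetic_features(rng, 10)
        base = transform(frame_from_array(x), "normalize")
        scaled = transform(frame_from_array(x), "normalize", scale=11064.0)
        np.testing.assert_allclose(scaled.to_numpy(),
                                   11064.0 * base.to_numpy())


class TestEstimateEps:
    def test_two_tight_blobs(self, rng):
        """Two tight 18-D blobs (per-dimension spread 0.01, separation 1.0):
        the knee lands above the intra-blob scale and far below the
        separation; verified against an inline chord-distance oracle."""
        a = rng.normal(scale=0.01, size=(6, 18))
        b = rng.normal(scale=0.01, size=(6, 18))
        b[:, 1] += 1.0
        x = np.vstack([a, b])
        eps = estimate_eps(x, k=2)
        assert 0.05 < eps < 0.9
        # independent knee computation on the explicit k-distance curve
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        kdist = np.sort(np.sort(d, axis=1)[:, 2])   # 2nd non-self neighbor
        t = np.arange(len(kdist), dtype=float)
        chord = np.array([t[-1], kdist[-1] - kdist[0]])
        chord = chord / np.linalg.norm(chord)
        perp = np.abs(t * chord[1] - (kdist - kdist[0]) * chord[0])
        assert eps == pytest.approx(kdist[np.argmax(perp)])

    def test_uniform_grid_knee_near_spacing(self):
        g = np.stack(np.meshgrid(*[np.arange(5.0)] * 2),
                     axis=-1).reshape(-1, 2)
        eps = estimate_eps(g, k=2)
        # k=2 distance on a square lattice is the spacing (1.0)
        assert eps == pytest.approx(1.0, rel=0.2)

    def test_duplicates_do_not_change_the_estimate(self, rng):
        x = rng.normal(size=(40, 4))
        assert estimate_eps(np.vstack([x, x]), k=2) == \
            pytest.approx(estimate_eps(x, k=2))

    def test_all_identical_points_degenerate(self):
        x = np.ones((10, 3))
        with pytest.raises(DegenerateEpsError):
            estimate_eps(x, k=2)

    def test_too_few_distinct_points_degenerate(self):
        with pytest.raises(DegenerateEpsError):
            estimate_eps(np.array([[0.0, 0], [1, 1]]), k=2)


class TestDbscan:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(scale=0.02, size=(12, 5))
        b = rng.normal(scale=0.02, size=(12, 5)) + 1.0
        labels = dbscan(np.vstack([a, b]), eps=0.2, min_pts=2)
        assert set(labels) == {0, 1}
        assert (labels[:12] == 0).all() and (labels[12:] == 1).all()

    def test_isolated_point_is_noise(self, rng):
        x = np.vstack([rng.normal(scale=0.02, size=(10, 3)),
                       [[5.0, 5.0, 5.0]]])
        labels = dbscan(x, eps=0.2, min_pts=2)
        assert labels[-1] == -1

    def test_translation_invariance(self, rng):
        x = rng.normal(size=(50, 4))
        l1 = dbscan(x, eps=0.8, min_pts=3)
        l2 = dbscan(x + 100.0, eps=0.8, min_pts=3)
        assert (l1 == l2).all()

    def test_label_numbering_follows_row_order(self, rng):
        a = rng.normal(scale=0.02, size=(5, 2)) + 10.0
        b = rng.normal(scale=0.02, size=(5, 2))
        labels = dbscan(np.vstack([a, b]), eps=0.2, min_pts=2)
        assert labels[0] == 0 and labels[5] == 1

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(derandomize=True, max_examples=15, deadline=None)
    def test_agrees_with_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        centers = rng.uniform(-3, 3, size=(4, 6))
        x = np.vstack([c + rng.normal(scale=0.3, size=(n // 4, 6))
                       for c in centers])
        eps = float(rng.uniform(0.3, 1.2))
        min_pts = int(rng.integers(2, 5))
        assert labels_equivalent(dbscan(x, eps, min_pts),
                                 brute_force_dbscan(x, eps, min_pts))


class TestLabelPath:
    def test_string_round_trip(self):
        p = ClusterLabelPath((10, 0, 16, 3))
        assert str(p) == "10_0_16_3"
        assert ClusterLabelPath.parse("10_0_16_3") == p

    def test_outlier_terminates_path(self):
        assert ClusterLabelPath((2, -1)).is_outlier
        with pytest.raises(ClusteringError):
            ClusterLabelPath((-1, 2))


class TestMultilevel:
    def _hierarchical_data(self, rng):
        """Two super-blobs, each of three tight sub-blobs whose combined Plm
        spread at level 1 exceeds 0.05 e, plus one stray row per super-blob
        (an atom type unlike any other, as real banks contain) whose large
        k-distance anchors the tail of the level-2 knee curve."""
        rows, truth = [], []
        for sup in range(2):
            base = np.zeros(18)
            base[0], base[2] = 1.0, 0.9
            base[1] = 4.0 + 3.0 * sup           # Pval separates super-blobs
            for sub in range(3):
                center = base.copy()
                # close enough to chain at the level-1 Eps, far enough to
                # split at the level-2 Eps
                center[3 + sub] = 0.25 * (sub + 1) * (-1) ** sub
                for _ in range(8):
                    rows.append(center + np.concatenate(
                        [[0, 0, 0], rng.normal(scale=0.003, size=15)]))
                    truth.append(sup * 3 + sub)
            stray = base.copy()
            stray[12] += 0.5
            rows.append(stray)
            truth.append(6 + sup)
        return frame_from_array(np.array(rows)), np.array(truth)

    def test_planted_hierarchy_recovered_within_two_levels(self, rng):
        df, truth = self._hierarchical_data(rng)
        labels, eps_log = multilevel_cluster(df, ClusteringConfig(eps=1.0))
        assert adjusted_rand_score(truth, [str(l) for l in labels]) >= 0.9
        assert max(len(l.levels) for l in labels) == 2
        leaf = {str(l) for l in labels if not l.is_outlier}
        assert len(leaf) == 6
        # the strays drop out as noise within their super-cluster
        assert {str(l) for l in labels} - leaf <= {"0_-1", "1_-1"}

    def test_tight_blob_stays_single_cluster(self, rng):
        x = np.tile(synthetic_features(rng, 1), (20, 1))
        x[:, 3:] += rng.normal(scale=0.005, size=(20, 15))
        x += rng.normal(scale=1e-4, size=x.shape)
        labels, _ = multilevel_cluster(frame_from_array(x),
                                       ClusteringConfig(eps=0.5))
        assert {str(l) for l in labels} == {"0"}
        assert all(len(l.levels) == 1 for l in labels)

    def test_max_levels_one_gives_flat_labels(self, rng):
        df, _ = self._hierarchical_data(rng)
        labels, _ = multilevel_cluster(df, ClusteringConfig(eps=1.0,
                                                            max_levels=1))
        assert all(len(l.levels) == 1 for l in labels)

    def test_schedule_replay_is_deterministic(self, rng):
        df, _ = self._hierarchical_data(rng)
        schedule = {"": 1.0, "0": 0.3, "1": 0.3}
        cfg = ClusteringConfig(eps_schedule=schedule)
        l1, log1 = multilevel_cluster(df, cfg)
        l2, log2 = multilevel_cluster(df, cfg)
        assert [str(a) for a in l1] == [str(b) for b in l2]
        assert [(r.path, r.eps) for r in log1] == \
            [(r.path, r.eps) for r in log2]
        assert all(r.source == "schedule" for r in log1)
        # Eps values along any path are non-increasing
        assert schedule["0"] <= schedule[""]

    def test_outliers_never_subdivided(self, rng):
        df, _ = self._hierarchical_data(rng)
        iso = df.iloc[[0]].copy()
        iso.iloc[0, 1] = 40.0
        df2 = pd.concat([df, iso], ignore_index=True)
        labels, _ = multilevel_cluster(df2, ClusteringConfig(eps=1.0))
        assert labels[-1].levels == (-1,)

    def test_partition_at_every_level(self, clustered, rotated_table):
        labels, _, _, _ = clustered
        assert len(labels) == len(rotated_table)
        # every row has exactly one label; prefixes nest consistently
        for lab in labels:
            assert len(lab.levels) <= 4


class TestReport:
    def test_identical_rows_have_zero_sd_and_dominant(self, rng):
        from taamkit.clustering import cluster_report
        x = np.tile(synthetic_features(rng, 1), (5, 1))
        x[:, 10] = 0.5                    # P21 dominates
        df = frame_from_array(x)
        report = cluster_report(df, [ClusterLabelPath((0,))] * 5)
        row = report.iloc[0]
        assert row["n"] == 5
        assert row["dominant_multipole"] == FEATURE_COLUMNS[10]
        assert row["max_plm_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_sp3_and_sp2_dominant_multipoles(self, clustered, rotated_table,
                                             default_bank):
        """Cluster means reproduce the hallmark dominant multipoles:
        negative P32 for tetrahedral types in their pair-bisector (ZabXc)
        frame, positive P33 for trigonal planar types in XabYa."""
        _, _, _, report = clustered
        entries, _, truth = default_bank
        labels = clustered[0]
        table = rotated_table.copy()
        table["label"] = [str(l) for l in labels]
        table["cid"] = [truth.cluster_id[e] for e in table["entry"]]

        sp3 = table[(table.cid == 2) & (table.family == "ZabXc")]
        lab = sp3.label.mode()[0]
        row = report[report.cluster == lab].iloc[0]
        assert row.dominant_multipole == "P32"
        assert row.dominant_value < 0

        sp2 = table[(table.cid == 3) & (table.family == "XabYa")]
        lab = sp2.label.mode()[0]
        row = report[report.cluster == lab].iloc[0]
        assert row.dominant_multipole == "P33"
        assert row.dominant_value > 0
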