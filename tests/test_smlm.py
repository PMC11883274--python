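import io

import numpy as np
import pandas as pd
import pytest

from chromopws.smlm import (NanodomainCaller, cluster_localizations,
                            domain_geometry, filter_domains,
                            read_thunderstorm_csv, summarize_domains_by_region,
                            write_thunderstorm_csv)
from conftest import brute_force_dbscan


def locs_frame(xy, uncertainty=25.0):
    xy = np.asarray(xy, float)
    return pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1],
                         "uncertainty": np.full(len(xy), uncertainty),
                         "frame": np.arange(1, len(xy) + 1)})


def canonical(labels):
    """Relabel clusters by first appearance so labelings compare up to
    permutation."""
    out = np.full(len(labels), -1)
    mapping = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


class TestClustering:
    def test_two_isolated_points_are_noise(self):
        labels = cluster_localizations(locs_frame([[0, 0], [500, 0]]))
        np.testing.assert_array_equal(labels, [-1, -1])

    def test_three_collinear_points_single_cluster(self):
        # middle point has all 3 within eps=50 (self-inclusive): it is core
        labels = cluster_localizations(locs_frame([[0, 0], [40, 0], [80, 0]]))
        assert set(labels) == {0}
        ref = brute_force_dbscan(np.array([[0., 0], [40, 0], [80, 0]]), 50, 3)
        np.testing.assert_array_equal(canonical(labels), canonical(ref))

    def test_two_separated_gaussian_clusters(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            a = rng.normal([0, 0], 20, (50, 2))
            b = rng.normal([1000, 0], 20, (50, 2))
            labels = cluster_localizations(locs_frame(np.vstack([a, b])))
            n_clusters = len(set(labels) - {-1})
            n_noise = int((labels == -1).sum())
            if n_clusters == 2 and n_noise <= 2:
                # no merging: the two halves never share a label
                assert len(set(labels[:50]) & set(labels[50:]) - {-1}) == 0
                hits += 1
        assert hits >= 0.95 * 40

    def test_matches_brute_force_oracle(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = rng.integers(5, 200)
            xy = rng.uniform(0, 600, (n, 2))
            ours = cluster_localizations(locs_frame(xy))
            ref = brute_force_dbscan(xy, 50.0, 3)
            np.testing.assert_array_equal(canonical(ours), canonical(ref))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 500, (120, 2))
        base = canonical(cluster_localizations(locs_frame(xy)))
        for k in range(5):
            th = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(th), -np.sin(th)],
                            [np.sin(th), np.cos(th)]])
            moved = xy @ rot.T + rng.uniform(-1e4, 1e4, 2)
            got = canonical(cluster_localizations(locs_frame(moved)))
            np.testing.assert_array_equal(got, base)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            cluster_localizations(locs_frame([[0, 0]]), eps=0)
        with pytest.raises(ValueError):
            cluster_localizations(locs_frame([[0, 0]]), min_pts=0)
        with pytest.raises(ValueError):
            cluster_localizations(locs_frame(np.empty((0, 2))))


class TestGeometry:
    def test_unit_square_hull(self):
        square = [[0, 0], [100, 0], [100, 100], [0, 100]]
        dom = domain_geometry(np.array(square, float))
        assert dom.hull_area == pytest.approx(1e4)
        assert dom.eq_diameter == pytest.approx(2 * np.sqrt(1e4 / np.pi))
        assert dom.eq_diameter == pytest.approx(112.8, abs=0.1)

    def test_collinear_degenerate_fallback(self):
        dom = domain_geometry(np.array([[0., 0], [40, 0], [80, 0]]))
        assert dom.degenerate and dom.hull_area == 0.0
        assert dom.size_nm == pytest.approx(80.0)

    def test_rotation_invariant_area(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 300, (40, 2))
        base = domain_geometry(pts).hull_area
        for _ in range(10):
            th = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(th), -np.sin(th)],
                            [np.sin(th), np.cos(th)]])
            got = domain_geometry(pts @ rot.T).hull_area
            assert got == pytest.approx(base, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            domain_geometry(np.array([[0., 0], [1, 1]]))


def synthetic_cluster(center, size_nm, n, rng):
    """Points whose hull has (approximately) the requested equivalent
    diameter: uniform on a disk of that diameter."""
    theta = rng.uniform(0, 2 * np.pi, n)
    r = (size_nm / 2) * np.sqrt(rng.uniform(0, 1, n))
    return np.column_stack([center[0] + r * np.cos(theta),
                            center[1] + r * np.sin(theta)])


class TestFiltering:
    def _clusters_of_sizes(self, sizes):
        out = []
        for i, s in enumerate(sizes):
            # build an exact square hull with the requested eq_diameter
            side = s * np.sqrt(np.pi) / 2.0
            pts = np.array([[0, 0], [side, 0], [side, side], [0, side]],
                           float) + i * 5000.0
            out.append(domain_geometry(pts))
            assert out[-1].eq_diameter == pytest.approx(s)
        return out

    def test_oversized_cluster_removed(self):
        clusters = self._clusters_of_sizes([900.0])
        locs = locs_frame(np.random.default_rng(0).uniform(0, 100, (5, 2)))
        assert filter_domains(clusters, locs) == []

    def test_undersized_cluster_removed(self):
        clusters = self._clusters_of_sizes([40.0])
        locs = locs_frame(np.zeros((5, 2)), uncertainty=25.0)
        assert filter_domains(clusters, locs) == []

    def test_window_fixture_exact_retention(self):
        sizes = [30.0, 60.0, 200.0, 790.0, 900.0]
        clusters = self._clusters_of_sizes(sizes)
        locs = locs_frame(np.zeros((10, 2)), uncertainty=25.0)
        kept = filter_domains(clusters, locs)
        assert sorted(round(c.eq_diameter) for c in kept) == [60, 200, 790]

    def test_idempotent_and_monotone_in_lower_bound(self):
        sizes = [30.0, 60.0, 200.0, 790.0, 900.0]
        clusters = self._clusters_of_sizes(sizes)
        locs = locs_frame(np.zeros((10, 2)), uncertainty=25.0)
        once = filter_domains(clusters, locs)
        twice = filter_domains(once, locs)
        assert [c.label for c in once] == [c.label for c in twice]
        sizes_kept = [len(filter_domains(clusters, locs, lower_bound_nm=b))
                      for b in (10, 50, 100, 500)]
        assert sizes_kept == sorted(sizes_kept, reverse=True)

    def test_missing_uncertainty_column_named(self):
        clusters = self._clusters_of_sizes([100.0])
        locs = pd.DataFrame({"x": [0.0], "y": [0.0]})
        with pytest.raises(ValueError, match="uncertainty"):
            filter_domains(clusters, locs)

    def test_known_structure_size_recovery(self):
        rng = np.random.default_rng(4)
        for r in (50.0, 120.0):
            for seed in range(5):
                pts = synthetic_cluster((0, 0), 2 * r, 30, rng)
                pts += rng.normal(0, 10, pts.shape)
                dom = domain_geometry(pts)
                assert 1.2 * r <= dom.eq_diameter <= 2.4 * r


class TestRegionSummary:
    def test_counts_by_centroid(self, small_scene):
        px_nm = small_scene.pixel_size * 1000.0
        rng = np.random.default_rng(0)
        clusters = []
        # three clusters centered inside the bleb
        ci, cj = np.argwhere(small_scene.bleb_mask).mean(axis=0)
        for k in range(3):
            pts = synthetic_cluster(((cj + 0.5) * px_nm, (ci + 0.5) * px_nm),
                                    80, 20, rng)
            clusters.append(domain_geometry(pts))
        table = summarize_domains_by_region(clusters, small_scene)
        assert (table.region == "bleb").sum() == 3

    def test_empty_bleb_histogram_still_emitted(self, small_scene):
        table = summarize_domains_by_region([], small_scene)
        assert list(table.columns)[:3] == ["cell_id", "condition", "region"]
        assert len(table) == 0

    def test_outside_bucket_never_dropped(self, small_scene):
        rng = np.random.default_rng(1)
        pts = synthetic_cluster((1e6, 1e6), 100, 10, rng)  # far off-scene
        table = summarize_domains_by_region([domain_geometry(pts)],
                                            small_scene)
        assert list(table.region) == ["outside"]


class TestIo:
    def test_thunderstorm_round_trip(self, tmp_path):
        df = locs_frame(np.random.default_rng(0).uniform(0, 1e4, (20, 2)))
        path = tmp_path / "locs.csv"
        write_thunderstorm_csv(df, path)
        back = read_thunderstorm_csv(path)
        np.testing.assert_allclose(back["x"], df["x"])
        assert "uncertainty" in back.columns

    def test_semicolon_delimiter_accepted(self):
        text = 'x [nm];y [nm];uncertainty [nm];frame\n10;20;25;1\n30;40;25;2\n'
        back = read_thunderstorm_csv(io.StringIO(text))
        assert list(back["x"]) == [10, 30]

    def test_missing_coordinates_rejected(self):
        with pytest.raises(ValueError, match="x"):
            read_thunderstorm_csv(io.StringIO("a,b\n1,2\n"))


class TestCaller:
    def test_caller_outputs_consistent(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([synthetic_cluster((c * 2000, 0), 150, 30, rng)
                         for c in range(4)])
        locs = locs_frame(pts)
        caller = NanodomainCaller().fit(locs)
        assert len(caller.clusters_) >= 4
        assert caller.size_bounds_ == (50.0, 800.0)
        labels = caller.fit_predict(locs)
        assert labels.shape == (len(locs),)
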