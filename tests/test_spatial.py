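"""Thiessen polygons, interpolation, contour extraction and transects."""

import numpy as np
import pytest

from hzfootprint.core import LocalityTable
from hzfootprint.markers import HybridIndexTable
from hzfootprint.spatial import (
    GriddedField,
    build_thiessen,
    extract_half_contour,
    interpolate_surface,
    signed_transect,
)


def _table(points):
    ids = tuple(f"p{i}" for i in range(len(points)))
    return LocalityTable(
        ids,
        tuple(float(x) for x, _ in points),
        tuple(float(y) for _, y in points),
        {i: (f"{i}_i1",) for i in ids},
    )


class TestThiessen:
    def test_two_points_half_planes(self):
        t = _table([(0, 0), (2, 0)])
        tm = build_thiessen(t)
        assert tm.adjacency == {"p0": ("p1",), "p1": ("p0",)}
        assert tm.polygons["p0"].area == pytest.approx(tm.polygons["p1"].area)
        assert tm.area() == pytest.approx(tm.bounding_region.area)

    def test_unit_square_plus_centre(self):
        t = _table([(0, 0), (1, 0), (0, 1), (1, 1), (0.5, 0.5)])
        tm = build_thiessen(t)
        assert set(tm.adjacency["p4"]) == {"p0", "p1", "p2", "p3"}
        assert "p3" not in tm.adjacency["p0"]  # opposite corners meet only at a point

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="duplicate coordinates.*p0.*p2"):
            build_thiessen(_table([(0, 0), (1, 1), (0, 0)]))

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        t = _table([tuple(p) for p in rng.uniform(0, 100, size=(12, 2))])
        tm = build_thiessen(t)
        assert tm.area() == pytest.approx(tm.bounding_region.area, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_adjacency_matches_bruteforce_nearest_site(self, seed):
        """Oracle: classify a dense grid by nearest site; two sites are
        adjacent iff their grid regions touch over more than a corner."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, size=(rng.integers(4, 10), 2))
        t = _table([tuple(p) for p in pts])
        tm = build_thiessen(t, margin=0.1)
        minx, miny, maxx, maxy = tm.bounding_region.bounds
        n = 400
        xs = np.linspace(minx, maxx, n)
        ys = np.linspace(miny, maxy, n)
        XX, YY = np.meshgrid(xs, ys)
        d2 = (XX[..., None] - pts[:, 0]) ** 2 + (YY[..., None] - pts[:, 1]) ** 2
        lab = d2.argmin(axis=2)
        oracle = {i: set() for i in range(len(pts))}
        h_pairs = np.stack([lab[:, :-1].ravel(), lab[:, 1:].ravel()])
        v_pairs = np.stack([lab[:-1, :].ravel(), lab[1:, :].ravel()])
        pairs = np.concatenate([h_pairs, v_pairs], axis=1)
        diff = pairs[:, pairs[0] != pairs[1]]
        cnt = {}
        for a, b in zip(*diff):
            key = (min(a, b), max(a, b))
            cnt[key] = cnt.get(key, 0) + 1
        for (a, b), c in cnt.items():
            if c >= 3:  # more than a corner touch on the fine grid
                oracle[a].add(b)
                oracle[b].add(a)
        got = {
            int(l[1:]): {int(n_[1:]) for n_ in tm.adjacency[l]}
            for l in t.locality_ids
        }
        assert got == oracle


class TestInterpolation:
    def test_constant_field(self):
        t = _table([(0, 0), (10, 0), (0, 10), (10, 10)])
        f = interpolate_surface(t, {l: 0.6 for l in t.locality_ids}, resolution=20)
        assert np.nanmax(np.abs(f.values - 0.6)) < 1e-12

    def test_linear_reproduction(self):
        rng = np.random.default_rng(0)
        pts = [(0, 0), (100, 0), (0, 100), (100, 100)] + [
            tuple(p) for p in rng.uniform(0, 100, size=(10, 2))
        ]
        t = _table(pts)
        vals = {l: t.position(l)[0] / 100.0 for l in t.locality_ids}
        f = interpolate_surface(t, vals, resolution=50, max_triangle_edge=np.inf)
        XX = np.meshgrid(f.xs, f.ys)[0]
        ok = np.isfinite(f.values)
        assert np.abs(f.values[ok] - XX[ok] / 100.0).max() < 1e-9

    def test_node_values_exact(self):
        t = _table([(0, 0), (4, 0), (0, 4), (4, 4), (2, 2)])
        vals = {l: i / 10 for i, l in enumerate(t.locality_ids)}
        f = interpolate_surface(t, vals, resolution=5)  # nodes land on localities
        assert f.values[2, 2] == pytest.approx(vals["p4"])

    def test_collinear_rejected(self):
        t = _table([(0, 0), (1, 1), (2, 2), (3, 3)])
        with pytest.raises(ValueError, match="collinear"):
            interpolate_surface(t, {l: 0.5 for l in t.locality_ids})


def _linear_field(resolution=101):
    xs = np.linspace(0, 100, resolution)
    ys = np.linspace(0, 100, resolution)
    return GriddedField(xs, ys, np.tile(xs / 100.0, (resolution, 1)))


class TestContour:
    def test_flat_field_has_no_contour(self):
        f = GriddedField(np.arange(5.0), np.arange(5.0), np.full((5, 5), 0.6))
        assert extract_half_contour(f).empty

    def test_linear_field_contour_near_fifty(self):
        cs = extract_half_contour(_linear_field())
        assert len(cs.polylines) == 1
        xs = np.asarray(cs.polylines[0].xy[0])
        assert np.abs(xs - 50.0).max() < 1.0  # within one grid cell

    def test_enclave_bubble_gives_two_polylines(self):
        f = _linear_field()
        XX, YY = np.meshgrid(f.xs, f.ys)
        bubble = (XX - 20) ** 2 + (YY - 50) ** 2 < 10**2
        f.values[bubble] = 0.9
        cs = extract_half_contour(f)
        assert len(cs.polylines) >= 2


class TestTransect:
    def _dominant(self, t, split=50.0):
        return {
            l: ("focal" if t.position(l)[0] >= split else "other")
            for l in t.locality_ids
        }

    def test_locality_on_contour_zero(self):
        cs = extract_half_contour(_linear_field())
        t = _table([(50, 50), (75, 20), (20, 80)])
        pts = signed_transect(t, cs, self._dominant(t), "focal")
        by_id = {p.locality_id: p for p in pts}
        assert abs(by_id["p0"].distance) < 1.0
        assert by_id["p1"].distance == pytest.approx(25.0, abs=1.0)
        assert by_id["p2"].distance == pytest.approx(-30.0, abs=1.0)

    def test_reflection_flips_signs_only(self):
        cs = extract_half_contour(_linear_field())
        t = _table([(70, 30), (35, 60)])
        fwd = signed_transect(t, cs, self._dominant(t), "focal")
        mirrored = _table([(100 - 70, 30), (100 - 35, 60)])
        bwd = signed_transect(mirrored, cs, self._dominant(mirrored), "focal")
        for a, b in zip(fwd, bwd):
            assert a.distance == pytest.approx(-b.distance, abs=1e-6)

    def test_rigid_motion_invariance(self):
        """Translating and rotating the whole map leaves |distance| unchanged."""
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, size=(12, 2))
        t = _table([tuple(p) for p in pts])
        vals = {l: t.position(l)[0] / 100.0 for l in t.locality_ids}
        f = interpolate_surface(t, vals, resolution=80, max_triangle_edge=np.inf)
        cs = extract_half_contour(f)
        dom = self._dominant(t)
        base = signed_transect(t, cs, dom, "focal")

        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ R.T + np.array([13.0, -7.0])
        t2 = LocalityTable(t.locality_ids, tuple(moved[:, 0]), tuple(moved[:, 1]),
                           t.individuals)
        f2 = interpolate_surface(t2, vals, resolution=80, max_triangle_edge=np.inf)
        cs2 = extract_half_contour(f2)
        moved_pts = signed_transect(t2, cs2, dom, "focal")
        for a, b in zip(base, moved_pts):
            assert a.distance == pytest.approx(b.distance, abs=1.5)

    def test_missing_dominant_label_rejected(self):
        cs = extract_half_contour(_linear_field())
        t = _table([(10, 10)])
        with pytest.raises(ValueError, match="dominant"):
            signed_transect(t, cs, {}, "focal")

    def test_hybrid_table_fills_h_and_n(self):
        cs = extract_half_contour(_linear_field())
        t = _table([(80, 50)])
        hyb = HybridIndexTable("focal", {"p0": 0.9}, {"p0": 46}, {"p0": 92})
        pts = signed_transect(t, cs, {"p0": "focal"}, "focal", hybrid=hyb)
        assert pts[0].h == 0.9 and pts[0].n_genotypes == 46


def test_geojson_exports(tmp_path):
    import json

    from hzfootprint.spatial import contours_to_geojson, thiessen_to_geojson

    t = _table([(0, 0), (4, 0), (0, 4)])
    tm = build_thiessen(t)
    p = tmp_path / "thiessen.geojson"
    thiessen_to_geojson(tm, p)
    gj = json.loads(p.read_text())
    assert len(gj["features"]) == 3
    assert {f["properties"]["locality_id"] for f in gj["features"]} == set(t.locality_ids)

    cs = extract_half_contour(_linear_field())
    pc = tmp_path / "contour.geojson"
    contours_to_geojson(cs, pc)
    gj = json.loads(pc.read_text())
    assert gj["features"][0]["geometry"]["type"] == "LineString"
    assert gj["features"][0]["properties"]["level"] == 0.5
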