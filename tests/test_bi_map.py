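import numpy as np
import pytest

import impingemap as im
from impingemap.bi_map import (MODE_BTBI, MODE_ITBI, Cluster, ImpingementMap,
                               _category_of)

from conftest import icosphere_mesh, red_bump_spec


class TestCategories:
    def test_thresholds_are_fractions_of_the_cca(self):
        cats = im.CCACategories()
        assert im.categorize(20.0, cats) == pytest.approx([5, 10, 15, 20])

    def test_zero_cca_collapses_all_thresholds(self):
        assert im.categorize(0.0, im.CCACategories()) == [0, 0, 0, 0]

    def test_negative_cca_rejected(self):
        with pytest.raises(im.ContractError):
            im.categorize(-1.0, im.CCACategories())

    @pytest.mark.parametrize("fractions,colors", [
        ((0.5, 0.25, 1.0), ("red", "yellow", "blue")),   # not increasing
        ((0.5, 1.5), ("red", "blue")),                   # above 1
        ((0.25, 0.5), ("red", "yellow", "blue")),        # length mismatch
        ((-0.1, 1.0), ("red", "blue")),                  # non-positive
    ])
    def test_invalid_category_specs_rejected(self, fractions, colors):
        with pytest.raises(im.ContractError):
            im.CCACategories(fractions, colors)

    def test_category_of_picks_first_band(self):
        thr = [5.0, 10.0, 15.0, 20.0]
        assert _category_of(0.0, thr) == 0
        assert _category_of(5.0, thr) == 0
        assert _category_of(5.1, thr) == 1
        assert _category_of(20.0, thr) == 3
        with pytest.raises(im.ContractError):
            _category_of(21.0, thr)


class TestRegionGrow:
    def test_unmarked_closed_mesh_is_one_cluster(self):
        mesh = icosphere_mesh(radius=5, subdivisions=2)
        clusters = im.region_grow(mesh, set())
        assert len(clusters) == 1
        assert clusters[0].faces == frozenset(range(mesh.n_faces))

    def test_equatorial_belt_splits_a_sphere_in_two(self):
        mesh = icosphere_mesh(radius=5, subdivisions=3)
        belt = {i for i, v in enumerate(mesh.vertices) if abs(v[2]) < 0.35}
        clusters = im.region_grow(mesh, belt)
        big = sorted(clusters, key=lambda c: len(c.faces), reverse=True)[:2]
        assert len(clusters) >= 2
        # the two hemispheres sit on opposite sides of the belt
        signs = []
        for c in big:
            ids = np.fromiter(c.faces, dtype=np.int64)
            signs.append(np.sign(mesh.face_centroids[ids][:, 2]))
        assert (signs[0] == signs[0][0]).all() and (signs[1] == signs[1][0]).all()
        assert signs[0][0] != signs[1][0]

    def test_faces_touching_a_crossed_vertex_are_in_no_cluster(self):
        mesh = icosphere_mesh(radius=5, subdivisions=2)
        crossed = {0, 7}
        clusters = im.region_grow(mesh, crossed)
        touched = {i for i, f in enumerate(mesh.faces)
                   if set(f.tolist()) & crossed}
        for c in clusters:
            assert not (c.faces & touched)

    def test_out_of_range_vertex_id_is_contract_error(self):
        mesh = icosphere_mesh(radius=5, subdivisions=1)
        with pytest.raises(im.ContractError):
            im.region_grow(mesh, {mesh.n_vertices})

    def test_matches_networkx_connected_components(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(11)
        mesh = icosphere_mesh(radius=5, subdivisions=3)
        for _ in range(10):
            n_marked = int(rng.integers(0, mesh.n_vertices // 3))
            crossed = set(rng.choice(mesh.n_vertices, n_marked,
                                     replace=False).tolist())
            clusters = im.region_grow(mesh, crossed)
            seed = [i for i, f in enumerate(mesh.faces)
                    if not (set(f.tolist()) & crossed)]
            g = nx.Graph()
            g.add_nodes_from(seed)
            seed_set = set(seed)
            for a, b in mesh.face_adjacency:
                if a in seed_set and b in seed_set:
                    g.add_edge(int(a), int(b))
            expected = {frozenset(c) for c in nx.connected_components(g)}
            assert {c.faces for c in clusters} == expected


class TestSelectImpinged:
    def test_selects_the_cluster_inside_a_closed_opposing_mesh(self):
        a = icosphere_mesh(radius=2.0, subdivisions=3)
        b = icosphere_mesh(radius=2.0, subdivisions=3, center=(3.2, 0, 0))
        res = im.mesh_intersect(a, np.eye(4), b)
        assert res.intersects
        clusters = im.region_grow(a, res.crossed_vertices_a)
        picked = im.select_impinged(clusters, a, b, np.eye(4))
        assert picked
        ids = np.fromiter(picked, dtype=np.int64)
        # picked faces bulge into b; the rest stay outside it
        assert (np.linalg.norm(a.face_centroids[ids] - [3.2, 0, 0], axis=1)
                < 2.0).all()
        rest = [c for c in clusters if not (c.faces & picked)]
        for c in rest:
            rid = np.fromiter(c.faces, dtype=np.int64)
            assert (np.linalg.norm(a.face_centroids[rid] - [3.2, 0, 0], axis=1)
                    > 2.0).all()

    def test_without_a_crossing_it_is_a_contract_error(self):
        a = icosphere_mesh(radius=1.0, subdivisions=1)
        b = icosphere_mesh(radius=1.0, subdivisions=1, center=(5, 0, 0))
        clusters = im.region_grow(a, set())
        with pytest.raises(im.ContractError):
            im.select_impinged(clusters, a, b, np.eye(4))

    def test_open_opposing_mesh_uses_area_heuristic_with_warning(self, caplog):
        a = icosphere_mesh(radius=2.0, subdivisions=3)
        b = icosphere_mesh(radius=2.0, subdivisions=3, center=(3.5, 0, 0))
        res = im.mesh_intersect(a, np.eye(4), b)
        clusters = im.region_grow(a, res.crossed_vertices_a)
        # strip one face from b so it is no longer watertight
        b_open = im.TriMesh(b.vertices, b.faces[1:])
        assert not b_open.is_watertight
        with caplog.at_level("WARNING", logger="impingemap.bi_map"):
            picked = im.select_impinged(clusters, a, b_open, np.eye(4))
        assert "not closed" in caplog.text
        exact = im.select_impinged(clusters, a, b, np.eye(4))
        assert picked == exact


class TestMapBI:
    def test_modes_determine_which_bones_are_mapped(self, band_maps):
        assert set(band_maps) == {"pelvis", "femur"}
        for bone, imap in band_maps.items():
            assert imap.mode == MODE_BTBI
            assert imap.bone == bone

    def test_bump_in_top_band_colours_only_the_last_category(
            self, band_spec, band_model, band_maps):
        pmap = band_maps["pelvis"]
        assert pmap.itf, "expected bone-to-bone impingement on the bump"
        assert set(pmap.itf.values()) == {3}
        # every flagged face lies on the bump sphere, not on the plate
        c = band_spec.bump.center()
        ids = np.fromiter(pmap.itf, dtype=np.int64)
        d = np.linalg.norm(band_model.pelvis.face_centroids[ids] - c, axis=1)
        assert d.max() < band_spec.bump.radius * 1.5
        fmap = band_maps["femur"]
        assert fmap.itf and set(fmap.itf.values()) == {3}

    def test_provenance_records_the_flagging_posture(self, band_maps):
        pmap = band_maps["pelvis"]
        for fid, cat in pmap.itf.items():
            assert ("neutral", 0) in pmap.provenance[fid]

    def test_contact_at_zero_aperture_is_most_severe(self):
        spec = red_bump_spec()
        model = im.make_hip_fixture(spec)
        params = im.SweepParams(dt_alpha=2.0, n_alpha=16, dt_con=45.0)
        cca, _ = im.compute_cca(model, im.Posture(), params)
        prof = im.CCAProfile("neutral", [im.Posture()], [cca], [False])
        maps = im.map_bi(model, [prof], im.CCACategories(), params, MODE_BTBI)
        pmap = maps["pelvis"]
        assert pmap.itf
        assert 0 in set(pmap.itf.values())
        # the per-face category is the smallest flagged fraction, so the
        # category-0 set is nested inside every later pre-collapse set
        for j in range(3):
            assert pmap.itf_at_category(j) <= pmap.itf_at_category(j + 1)

    def test_itbi_maps_the_pelvis_only(self, band_model, band_profile):
        profile, params = band_profile
        maps = im.map_bi(band_model, [profile], im.CCACategories(), params,
                         MODE_ITBI)
        assert set(maps) == {"pelvis"}
        assert maps["pelvis"].mode == MODE_ITBI

    def test_unknown_mode_rejected(self, band_model, band_profile):
        profile, params = band_profile
        with pytest.raises(im.ContractError):
            im.map_bi(band_model, [profile], im.CCACategories(), params, "PI")

    def test_deterministic(self, band_model, band_profile, band_maps):
        profile, params = band_profile
        again = im.map_bi(band_model, [profile], im.CCACategories(), params,
                          MODE_BTBI)
        assert again["pelvis"].itf == band_maps["pelvis"].itf
        assert again["femur"].itf == band_maps["femur"].itf


class TestMapAlgebra:
    @staticmethod
    def _m(bone, mode, itf):
        m = ImpingementMap(bone, mode, itf=dict(itf),
                           provenance={f: {("a", 0)} for f in itf})
        return m

    def test_filter_itbi_removes_exactly_the_common_faces(self):
        itbi = self._m("pelvis", MODE_ITBI, {1: 0, 2: 1, 3: 2})
        btbi = self._m("pelvis", MODE_BTBI, {2: 3, 3: 0, 9: 1})
        out = im.filter_itbi(itbi, btbi)
        assert set(out.itf) == {1}
        assert out.itf[1] == 0
        assert set(out.provenance) == {1}
        # inputs untouched
        assert set(itbi.itf) == {1, 2, 3} and set(btbi.itf) == {2, 3, 9}

    def test_filter_itbi_requires_matching_bones(self):
        with pytest.raises(im.ContractError):
            im.filter_itbi(self._m("pelvis", MODE_ITBI, {}),
                           self._m("femur", MODE_BTBI, {}))

    def test_combine_keeps_the_more_severe_category(self):
        a = self._m("pelvis", MODE_ITBI, {1: 2, 2: 0})
        b = self._m("pelvis", MODE_BTBI, {1: 1, 3: 3})
        out = im.combine_maps(a, b)
        assert out.itf == {1: 1, 2: 0, 3: 3}
        assert out.mode == "combined"
        assert out.provenance[1] == {("a", 0)}

    def test_itf_nesting_across_categories(self):
        m = self._m("pelvis", MODE_BTBI, {1: 0, 2: 1, 3: 1, 4: 3})
        sets = [m.itf_at_category(j) for j in range(4)]
        assert sets == [{1}, {1, 2, 3}, {1, 2, 3}, {1, 2, 3, 4}]
        for small, big in zip(sets, sets[1:]):
            assert small <= big
        assert m.faces_with_category(1) == {2, 3}
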