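"""Mesh generation: area conservation, sizing contracts, determinism."""

import numpy as np
import pytest

from bifurcbench.geometry import Strut, StrutSpec, StentLayout, build_bifurcation, make_channel, place_struts
from bifurcbench.meshing import Mesh, MeshConfig, MeshingError, generate_mesh, convergence_study


def _unique_edges(mesh):
    e = np.concatenate(
        [mesh.triangles[:, [0, 1]], mesh.triangles[:, [1, 2]], mesh.triangles[:, [2, 0]]]
    )
    return np.unique(np.sort(e, axis=1), axis=0)


class TestChannelMeshes:
    def test_area_conservation_straight_channel(self):
        mesh = generate_mesh(make_channel(5.5, 15.0), None,
                             MeshConfig(h_max=0.3, near_wall_factor=1.0))
        assert mesh.element_areas().sum() == pytest.approx(82.5, rel=1e-6)

    def test_halving_h_quadruples_element_count(self):
        coarse = generate_mesh(make_channel(5.5, 15.0), None,
                               MeshConfig(h_max=0.3, near_wall_factor=1.0))
        fine = generate_mesh(make_channel(5.5, 15.0), None,
                             MeshConfig(h_max=0.15, near_wall_factor=1.0))
        ratio = len(fine.triangles) / len(coarse.triangles)
        assert 3.5 <= ratio <= 4.5

    def test_too_coarse_h_rejected(self):
        with pytest.raises(MeshingError):
            generate_mesh(make_channel(5.5, 15.0), None, MeshConfig(h_max=0.6))


@pytest.fixture(scope="module")
def kio_mesh():
    geom = build_bifurcation()
    layout = place_struts(geom, "KIO", mix=(0.79, 0.05, 0.16), seed=1)
    cfg = MeshConfig(h_max=0.34, near_wall_factor=0.5, h_strut=0.045)
    return geom, layout, cfg, generate_mesh(geom, layout, cfg)


class TestStentedMeshes:
    def test_positive_areas_and_conformity(self, kio_mesh):
        geom, layout, cfg, mesh = kio_mesh
        areas = mesh.element_areas()
        assert (areas > 0).all()
        # conformity: every boundary edge is used by exactly one element and
        # carries exactly one tag
        uniq = _unique_edges(mesh)
        tagged = {tuple(sorted((i, j))) for i, j, _ in mesh.boundary_edges}
        assert len(tagged) == len(mesh.boundary_edges)
        assert tagged <= {tuple(e) for e in uniq.tolist()}

    def test_area_equals_lumen_minus_struts(self, kio_mesh):
        geom, layout, cfg, mesh = kio_mesh
        import shapely
        from shapely.geometry import Polygon

        fluid = geom.polygon().difference(
            shapely.union_all([Polygon(s.square()) for s in layout.struts])
        )
        assert mesh.element_areas().sum() == pytest.approx(fluid.area, rel=1e-6)

    def test_edge_length_contracts(self, kio_mesh):
        geom, layout, cfg, mesh = kio_mesh
        uniq = _unique_edges(mesh)
        elen = np.linalg.norm(mesh.points[uniq[:, 0]] - mesh.points[uniq[:, 1]], axis=1)
        assert elen.max() <= cfg.h_max * (1 + 1e-9)
        # elements owning a wall/strut boundary edge obey the refined limit
        wall_edges = {tuple(sorted((i, j))) for i, j, t in mesh.boundary_edges
                      if t in ("wall", "strut")}
        limit = cfg.near_wall_factor * cfg.h_max * (1 + 1e-9)
        tri_sorted = [
            [tuple(sorted(t[[0, 1]])), tuple(sorted(t[[1, 2]])), tuple(sorted(t[[2, 0]]))]
            for t in mesh.triangles
        ]
        for tri in tri_sorted:
            if any(e in wall_edges for e in tri):
                for a, b in tri:
                    d = np.linalg.norm(mesh.points[a] - mesh.points[b])
                    assert d <= limit

    def test_boundary_tags_cover_all_boundary_types(self, kio_mesh):
        *_, mesh = kio_mesh
        tags = {t for _, _, t in mesh.boundary_edges}
        assert tags == {"inlet", "outlet_mb", "outlet_sb", "wall", "strut"}

    def test_mesh_generation_deterministic(self, kio_mesh):
        geom, layout, cfg, mesh = kio_mesh
        again = generate_mesh(geom, layout, cfg)
        assert mesh.to_json() == again.to_json()

    def test_reference_mesh_element_count_order_of_magnitude(self):
        # the full model at the reference sizing (0.1 mm, refined boundaries)
        # lands near the reported ~95k elements
        geom = build_bifurcation()
        layout = place_struts(geom, "KIO", mix=(0.79, 0.05, 0.16), seed=1)
        mesh = generate_mesh(geom, layout, MeshConfig(h_max=0.1, near_wall_factor=0.25))
        assert 5e4 <= len(mesh.triangles) <= 2e5

    def test_sliver_strut_reported_with_id(self):
        geom = build_bifurcation()
        spec = StrutSpec()
        t = spec.thickness_mm
        # a malapposed-labelled strut hovering 5 um off the lower wall
        gap = 0.005
        strut = Strut(center=(-8.0, -2.75 + gap + t / 2), side="lower_wall",
                      wall_gap_um=90.0, apposition="MA", thickness_um=spec.thickness_um)
        layout = StentLayout("KIO", [strut], spec, 0, (0.0, 1.0, 0.0))
        with pytest.raises(MeshingError, match="strut 0"):
            generate_mesh(geom, layout, MeshConfig(h_max=0.3, near_wall_factor=0.6))

    def test_vtk_and_json_round_trip(self, kio_mesh, tmp_path):
        *_, mesh = kio_mesh
        back = Mesh.from_dict(__import__("json").loads(mesh.to_json()))
        assert np.allclose(back.points, mesh.points)
        path = tmp_path / "mesh.vtk"
        mesh.to_vtk(str(path))
        text = path.read_text()
        assert text.startswith("# vtk DataFile")
        assert f"CELLS {len(mesh.triangles)}" in text


class TestConvergenceStudy:
    def test_single_level_rejected(self):
        geom = make_channel(5.5, 15.0)
        with pytest.raises(ValueError):
            convergence_study(geom, None, MeshConfig(h_max=0.4), levels=1)

    def test_poiseuille_centerline_converges(self):
        geom = make_channel(5.5, 15.0)
        df = convergence_study(
            geom, None, MeshConfig(h_max=0.45, near_wall_factor=0.6), levels=3,
            refine_ratio=0.7, probe_point=np.array([7.5, 0.0]),
        )
        # analytic limit: 1.5 * U_mean at the channel centreline
        assert df["probe_speed"].iloc[-1] == pytest.approx(0.21, rel=0.01)
        assert df["rel_change_probe_speed"].iloc[-1] < 0.01

    def test_identical_levels_report_zero_change(self):
        geom = make_channel(5.5, 15.0)
        df = convergence_study(
            geom, None, MeshConfig(h_max=0.45, near_wall_factor=0.6), levels=2,
            refine_ratio=1.0, probe_point=np.array([7.5, 0.0]),
        )
        assert df["rel_change_probe_speed"].iloc[-1] == pytest.approx(0.0, abs=1e-12)
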