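"""Graded triangular meshing of the stented-lumen flow domain.

The fluid domain is the lumen polygon minus the strut squares.  Meshing is
Delaunay-based: tagged boundary polylines are sampled at the local target
size, the interior is filled with nested hexagonal lattices following a
size field (coarse in the bulk, ``near_wall_factor * h_max`` in a band along
walls and struts, optionally finer still at strut surfaces), the point cloud
is triangulated with scipy's Delaunay and triangles outside the fluid domain
are discarded.  A midpoint-insertion loop then enforces the two sizing
contracts: no edge longer than ``h_max`` anywhere, and no edge longer than
``near_wall_factor * h_max`` on elements touching a wall or strut boundary.

Element shape is triangular throughout; the sizing/refinement contract, not
the element polygon, is what the downstream shear recovery relies on.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon as ShapelyPolygon

from .geometry import BifurcationGeometry2D, StentLayout

__all__ = ["MeshConfig", "Mesh", "MeshingError", "generate_mesh", "convergence_study"]

_GEOM_TOL = 1e-7


class MeshingError(RuntimeError):
    pass


@dataclass(frozen=True)
class MeshConfig:
    """Mesh sizing parameters (mm).

    ``h_max`` 0.1 mm with boundary refinement reproduces the reference element
    count (~95k for the full model); ``h_strut`` caps the element size on strut
    surfaces independently of ``h_max`` so coarse bulk meshes still resolve the
    ~80 um squares (defaults to ``near_wall_factor * h_max`` when None).
    """

    h_max: float = 0.1
    near_wall_factor: float = 0.25
    h_strut: float | None = None
    target_element_count_hint: int = 95_000

    def validate(self) -> None:
        if self.h_max <= 0:
            raise MeshingError("h_max must be positive")
        if not 0 < self.near_wall_factor <= 1:
            raise MeshingError("near_wall_factor must lie in (0, 1]")
        if self.h_strut is not None and self.h_strut <= 0:
            raise MeshingError("h_strut must be positive")

    @property
    def h_wall(self) -> float:
        return self.near_wall_factor * self.h_max

    def strut_size(self) -> float:
        return self.h_strut if self.h_strut is not None else self.h_wall


@dataclass
class Mesh:
    """Conforming triangle mesh with tagged boundary edges (mm)."""

    points: np.ndarray  # (n, 2)
    triangles: np.ndarray  # (m, 3) CCW
    boundary_edges: list[tuple[int, int, str]]  # (i, j, tag); fluid on the left
    config: MeshConfig | None = None

    def element_areas(self) -> np.ndarray:
        p = self.points
        t = self.triangles
        d1 = p[t[:, 1]] - p[t[:, 0]]
        d2 = p[t[:, 2]] - p[t[:, 0]]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def element_centroids(self) -> np.ndarray:
        return self.points[self.triangles].mean(axis=1)

    def boundary_nodes(self, tags: set[str]) -> np.ndarray:
        idx = set()
        for i, j, t in self.boundary_edges:
            if t in tags:
                idx.add(i)
                idx.add(j)
        return np.array(sorted(idx), dtype=np.int64)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "points": self.points.tolist(),
            "triangles": self.triangles.tolist(),
            "boundary_edges": [[int(i), int(j), t] for i, j, t in self.boundary_edges],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "Mesh":
        return cls(
            np.asarray(d["points"], float),
            np.asarray(d["triangles"], np.int64),
            [(int(i), int(j), str(t)) for i, j, t in d["boundary_edges"]],
        )

    def to_vtk(self, path: str, cell_data: dict[str, np.ndarray] | None = None) -> None:
        """Legacy ASCII VTK unstructured grid."""
        n, m = len(self.points), len(self.triangles)
        with open(path, "w") as f:
            f.write("# vtk DataFile Version 3.0\nbifurcbench mesh\nASCII\n")
            f.write("DATASET UNSTRUCTURED_GRID\n")
            f.write(f"POINTS {n} double\n")
            for x, y in self.points:
                f.write(f"{x:.9g} {y:.9g} 0\n")
            f.write(f"CELLS {m} {4 * m}\n")
            for a, b, c in self.triangles:
                f.write(f"3 {a} {b} {c}\n")
            f.write(f"CELL_TYPES {m}\n")
            f.write("5\n" * m)
            if cell_data:
                f.write(f"CELL_DATA {m}\n")
                for name, arr in cell_data.items():
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in np.asarray(arr, float):
                        f.write(f"{v:.9g}\n")


# ----------------------------------------------------------------------
# size field
# ----------------------------------------------------------------------

def _point_segment_distance(pts: np.ndarray, segs: np.ndarray,
                            chunk: int = 20_000) -> np.ndarray:
    """Min distance from each point to a set of segments ((S,2,2))."""
    if len(segs) == 0:
        return np.full(len(pts), np.inf)
    a = segs[:, 0]
    ab = segs[:, 1] - segs[:, 0]
    ab2 = np.maximum((ab ** 2).sum(axis=1), 1e-30)
    out = np.empty(len(pts))
    for lo in range(0, len(pts), chunk):
        p = pts[lo:lo + chunk]
        ap = p[:, None, :] - a[None, :, :]
        t = np.clip((ap * ab[None]).sum(-1) / ab2[None], 0.0, 1.0)
        close = a[None] + t[..., None] * ab[None]
        d = np.linalg.norm(p[:, None, :] - close, axis=-1)
        out[lo:lo + chunk] = d.min(axis=1)
    return out


def _densify(segs: np.ndarray, step: float) -> np.ndarray:
    """Points sampled every ``step`` along each segment (distance proxy)."""
    out = []
    for a, b in segs:
        n = max(1, int(math.ceil(np.linalg.norm(b - a) / step)))
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        out.append(a + t * (b - a))
    return np.concatenate(out, axis=0)


class SizeField:
    """Local target edge length h(x) for the graded mesh.

    Distances to walls and struts are evaluated against KD-trees of densely
    sampled boundary points; the sampling step biases distances upward by at
    most step/2, which is folded in conservatively (toward refinement).
    """

    def __init__(self, wall_segs: np.ndarray, strut_segs: np.ndarray, cfg: MeshConfig):
        self.cfg = cfg
        self.h_wall = cfg.h_wall
        self.h_strut = min(cfg.strut_size(), cfg.h_wall)
        self._dw_step = self.h_wall / 3.0
        self._wall_tree = cKDTree(_densify(wall_segs, self._dw_step))
        if len(strut_segs):
            self._ds_step = self.h_strut / 3.0
            self._strut_tree = cKDTree(_densify(strut_segs, self._ds_step))
        else:
            self._strut_tree = None

    def dist_wall(self, pts: np.ndarray) -> np.ndarray:
        d, _ = self._wall_tree.query(pts)
        return np.maximum(d - self._dw_step / 2.0, 0.0)

    def dist_strut(self, pts: np.ndarray) -> np.ndarray:
        if self._strut_tree is None:
            return np.full(len(pts), np.inf)
        d, _ = self._strut_tree.query(pts)
        return np.maximum(d - self._ds_step / 2.0, 0.0)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        H = self.cfg.h_max
        h = np.full(len(pts), H)
        dw = self.dist_wall(pts)
        ramp = np.clip((dw - H) / (1.5 * H), 0.0, 1.0)
        h = np.minimum(h, self.h_wall + (H - self.h_wall) * ramp)
        if self._strut_tree is not None:
            ds = self.dist_strut(pts)
            band = 2.0 * self.h_strut
            ramp_s = np.clip((ds - band) / (0.8 * H), 0.0, 1.0)
            h = np.minimum(h, self.h_strut + (H - self.h_strut) * ramp_s)
        return h


# ----------------------------------------------------------------------
# point generation
# ----------------------------------------------------------------------

def _sample_polyline(p0: np.ndarray, p1: np.ndarray, size: SizeField) -> np.ndarray:
    """Points along segment p0-p1 spaced at ~0.9 * local h, endpoints included."""
    L = float(np.linalg.norm(p1 - p0))
    probes = np.linspace(0.0, 1.0, 9)[:, None]
    h_probe = size(p0 + probes * (p1 - p0))
    n_probe = min(4000, max(9, int(math.ceil(4 * L / h_probe.min()))))
    s = np.linspace(0.0, 1.0, n_probe)
    h = size(p0 + s[:, None] * (p1 - p0))
    dens = 1.0 / (0.9 * h)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(s) * L)])
    n = max(1, int(round(cum[-1])))
    targets = np.linspace(0.0, cum[-1], n + 1)
    s_pts = np.interp(targets, cum, s)
    return p0 + s_pts[:, None] * (p1 - p0)


def _hex_lattice(bbox, a: float) -> np.ndarray:
    """Hexagonal lattice of spacing ``a``, mirror-symmetric about y = 0."""
    x0, y0, x1, y1 = bbox
    dy = a * math.sqrt(3) / 2.0
    n_rows = int(math.ceil(max(abs(y0), abs(y1)) / dy)) + 1
    xs0 = np.arange(x0 - a, x1 + a, a)
    rows = []
    for j in range(n_rows):
        y = (j + 0.5) * dy
        xs = xs0 + (j % 2) * a / 2.0
        if y <= y1 + dy:
            rows.append(np.stack([xs, np.full_like(xs, y)], axis=1))
        if -y >= y0 - dy:
            rows.append(np.stack([xs, np.full_like(xs, -y)], axis=1))
    return np.concatenate(rows, axis=0) if rows else np.empty((0, 2))


# ----------------------------------------------------------------------
# mesh generation
# ----------------------------------------------------------------------

def _collect_boundary(geom: BifurcationGeometry2D, layout: StentLayout | None):
    """Tagged boundary segments of the fluid domain."""
    segs, tags = [], []
    for i, j, tag in geom.edges:
        segs.append([geom.vertices[i], geom.vertices[j]])
        tags.append(tag)
    strut_segs = []
    if layout is not None:
        for s in layout.struts:
            sq = s.square()
            for k in range(4):
                strut_segs.append([sq[k], sq[(k + 1) % 4]])
    return np.asarray(segs), tags, np.asarray(strut_segs).reshape(-1, 2, 2)


def _sliver_check(geom, layout, cfg):
    """A strut hovering a hair off a wall makes an unmeshable sliver."""
    if layout is None:
        return
    wall_segs = geom.wall_segments
    for k, s in enumerate(layout.struts):
        sq = shapely.polygons(s.square())
        d = min(
            shapely.distance(sq, shapely.linestrings(seg)) for seg in wall_segs
        )
        if 1e-9 < d < cfg.h_max / 10.0:
            raise MeshingError(
                f"strut {k} sits {d * 1e3:.1f} um off a wall (< h_max/10): "
                "degenerate sliver, refine h_max or re-seat the strut"
            )


def _fluid_polygon(geom, layout):
    poly = geom.polygon()
    if layout is not None:
        squares = [ShapelyPolygon(s.square()) for s in layout.struts]
        poly = poly.difference(shapely.union_all(squares))
    return poly


def _triangulate(points: np.ndarray, fluid_buffered) -> np.ndarray:
    tri = Delaunay(points)
    simplices = tri.simplices
    pts_t = points[simplices]
    cent = pts_t.mean(axis=1)
    keep = shapely.contains_xy(fluid_buffered, cent[:, 0], cent[:, 1])
    mids = 0.5 * (pts_t + np.roll(pts_t, -1, axis=1))  # (m,3,2) edge midpoints
    for k in range(3):
        keep &= shapely.contains_xy(fluid_buffered, mids[:, k, 0], mids[:, k, 1])
    simplices = simplices[keep]
    # orient CCW and drop degenerate slivers of (near) zero area
    d1 = points[simplices[:, 1]] - points[simplices[:, 0]]
    d2 = points[simplices[:, 2]] - points[simplices[:, 0]]
    areas = 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    flip = areas < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]
    return simplices[np.abs(areas) > 1e-14]


def _edge_arrays(simplices: np.ndarray):
    e = np.concatenate(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [2, 0]]], axis=0
    )
    es = np.sort(e, axis=1)
    uniq, inv, counts = np.unique(es, axis=0, return_inverse=True, return_counts=True)
    return e, uniq, inv, counts


def generate_mesh(
    geom: BifurcationGeometry2D,
    layout: StentLayout | None = None,
    cfg: MeshConfig | None = None,
    max_refine_passes: int = 12,
) -> Mesh:
    """Mesh the lumen-minus-struts domain with boundary-refined triangles."""
    cfg = cfg or MeshConfig()
    cfg.validate()
    geom.validate()
    if geom.params is not None:
        wmin = min(geom.params.D_prox, geom.params.D_mb, geom.params.D_sb)
    else:
        v = geom.vertices
        wmin = min(np.ptp(v[:, 0]), np.ptp(v[:, 1]))
    if cfg.h_max >= wmin / 10.0:
        raise MeshingError(
            f"h_max={cfg.h_max} too coarse for minimum channel width {wmin}"
        )
    _sliver_check(geom, layout, cfg)

    segs, tags, strut_segs = _collect_boundary(geom, layout)
    wall_segs = np.asarray(
        [s for s, t in zip(segs, tags) if t == "wall"]
    ).reshape(-1, 2, 2)
    size = SizeField(wall_segs, strut_segs, cfg)

    # boundary points: sample the rings of the actual fluid polygon (lumen
    # minus strut squares), so notch corners of wall-seated struts are honoured
    fluid = _fluid_polygon(geom, layout)
    if fluid.geom_type != "Polygon":
        raise MeshingError("strut layout disconnects the fluid domain")
    shapely.prepare(fluid)
    rings = [np.asarray(fluid.exterior.coords)] + [
        np.asarray(r.coords) for r in fluid.interiors
    ]
    ring_segs = []
    bpts = [np.empty((0, 2))]
    for ring in rings:
        for k in range(len(ring) - 1):
            ring_segs.append([ring[k], ring[k + 1]])
            bpts.append(_sample_polyline(ring[k], ring[k + 1], size))
    ring_segs = np.asarray(ring_segs)
    boundary_points = np.concatenate(bpts, axis=0)

    # interior lattices, finest levels restricted to their refinement bands
    v = geom.vertices
    bbox = (v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max())
    h_min = min(size.h_wall, size.h_strut)
    levels = [cfg.h_max]
    while levels[-1] > h_min * 1.01:
        levels.append(levels[-1] * 0.55)
    levels[-1] = h_min
    all_bound_segs = ring_segs
    clearance_step = max(h_min / 2.0, 0.01)
    bound_tree = cKDTree(_densify(all_bound_segs, clearance_step))
    interior = []
    for li, s_lvl in enumerate(levels):
        cand = _hex_lattice(bbox, 0.85 * s_lvl)
        if li > 0:  # fine lattices only needed near walls / struts
            d_near = np.minimum(size.dist_wall(cand), size.dist_strut(cand))
            cand = cand[d_near < 3.2 * cfg.h_max]
        if not len(cand):
            continue
        inside = shapely.contains_xy(fluid, cand[:, 0], cand[:, 1])
        cand = cand[inside]
        if not len(cand):
            continue
        h_loc = size(cand)
        lo = 0.0 if li == len(levels) - 1 else 0.74 * s_lvl
        hi = np.inf if li == 0 else 1.346 * s_lvl
        sel = (h_loc >= lo) & (h_loc < hi)
        cand, h_loc = cand[sel], h_loc[sel]
        if not len(cand):
            continue
        d_bound, _ = bound_tree.query(cand)
        cand = cand[np.maximum(d_bound - clearance_step / 2.0, 0.0) > 0.6 * h_loc]
        interior.append(cand)

    pts = np.concatenate([boundary_points] + interior, axis=0)
    pts = np.unique(np.round(pts / 1e-9) * 1e-9, axis=0)

    fluid_buf = fluid.buffer(1e-9)
    shapely.prepare(fluid_buf)

    simplices = _triangulate(pts, fluid_buf)

    # enforce the edge-length contracts by midpoint insertion
    for _ in range(max_refine_passes):
        e, uniq, inv, counts = _edge_arrays(simplices)
        elen = np.linalg.norm(pts[uniq[:, 0]] - pts[uniq[:, 1]], axis=1)
        bad = elen > 0.995 * cfg.h_max
        # wall/strut-adjacent elements: any element owning a boundary edge
        # that lies on a wall or strut
        bedge = counts[inv] == 1  # per (3m) edge slot
        mid_all = 0.5 * (pts[uniq[:, 0]] + pts[uniq[:, 1]])
        on_wall = np.zeros(len(uniq), dtype=bool)
        buniq = np.unique(inv[bedge])
        if len(buniq):
            dw = _point_segment_distance(mid_all[buniq], wall_segs)
            if len(strut_segs):
                dw = np.minimum(dw, _point_segment_distance(mid_all[buniq], strut_segs))
            on_wall[buniq[dw < _GEOM_TOL]] = True
        tri_inv = inv.reshape(3, -1).T  # (m,3) unique-edge id per element edge
        tri_on_wall = on_wall[tri_inv].any(axis=1)
        limit = 0.995 * cfg.h_wall
        for k in range(3):
            sel = tri_on_wall & (elen[tri_inv[:, k]] > limit)
            bad[tri_inv[sel, k]] = True
        # boundary edges not lying on the domain boundary signal an orphaned
        # sliver (a crossing triangle was filtered out): split to recover it
        if len(buniq):
            d_any = _point_segment_distance(mid_all[buniq], all_bound_segs)
            bad[buniq[d_any > _GEOM_TOL]] = True
        if not bad.any():
            break
        new_pts = mid_all[bad]
        keep_new = shapely.contains_xy(fluid_buf, new_pts[:, 0], new_pts[:, 1])
        new_pts = new_pts[keep_new]
        if not len(new_pts):
            break
        pts = np.unique(np.round(np.concatenate([pts, new_pts]) / 1e-9) * 1e-9, axis=0)
        simplices = _triangulate(pts, fluid_buf)

    # compact unused points
    used = np.unique(simplices)
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    pts = pts[used]
    simplices = remap[simplices]

    mesh = _build_tagged_mesh(pts, simplices, segs, tags, strut_segs, cfg)
    _validate_mesh(mesh, fluid)
    return mesh


def _build_tagged_mesh(pts, simplices, segs, tags, strut_segs, cfg) -> Mesh:
    e, uniq, inv, counts = _edge_arrays(simplices)
    # boundary edges appear once; recover orientation (fluid on the left)
    once = counts == 1
    bound_ids = np.nonzero(once)[0]
    # map unique edge -> oriented edge as it appears in its element (CCW order
    # means the fluid is on the left already)
    _, first_slot = np.unique(inv, return_index=True)
    slot_of = {int(eid): int(first_slot[eid]) for eid in bound_ids}
    groups = {}
    for t in set(tags):
        groups[t] = np.asarray([s for s, tg in zip(segs, tags) if tg == t]).reshape(-1, 2, 2)
    boundary_edges = []
    mids = []
    oriented = []
    for eid in bound_ids:
        i, j = e[slot_of[eid]]
        oriented.append((int(i), int(j)))
        mids.append(0.5 * (pts[i] + pts[j]))
    mids = np.asarray(mids).reshape(-1, 2)
    dist_by_tag = {}
    for t, g in groups.items():
        dist_by_tag[t] = _point_segment_distance(mids, g) if len(g) else np.full(len(mids), np.inf)
    d_strut = (
        _point_segment_distance(mids, strut_segs)
        if len(strut_segs)
        else np.full(len(mids), np.inf)
    )
    tag_names = list(dist_by_tag)
    dist_mat = np.stack([dist_by_tag[t] for t in tag_names] + [d_strut], axis=1)
    best = np.argmin(dist_mat, axis=1)
    best_d = dist_mat[np.arange(len(mids)), best]
    if np.any(best_d > _GEOM_TOL):
        k = int(np.argmax(best_d))
        raise MeshingError(
            f"non-conforming boundary edge at {mids[k]} (distance {best_d[k]:.2e} mm)"
        )
    for n, (i, j) in enumerate(oriented):
        t = "strut" if best[n] == len(tag_names) else tag_names[best[n]]
        boundary_edges.append((i, j, t))
    return Mesh(pts, simplices, boundary_edges, cfg)


def _validate_mesh(mesh: Mesh, fluid) -> None:
    areas = mesh.element_areas()
    if np.any(areas <= 0):
        raise MeshingError("mesh contains non-positive element areas")
    rel = abs(areas.sum() - fluid.area) / fluid.area
    if rel > 1e-6:
        raise MeshingError(
            f"mesh area mismatch: sum {areas.sum():.9g} vs domain {fluid.area:.9g} "
            f"(relative {rel:.2e})"
        )


# ----------------------------------------------------------------------
# convergence study
# ----------------------------------------------------------------------

def convergence_study(
    geom: BifurcationGeometry2D,
    layout: StentLayout | None,
    cfg: MeshConfig,
    levels: int,
    refine_ratio: float = 0.7,
    probe_point: np.ndarray | None = None,
    fluid=None,
    conditions=None,
    threshold: float = 1000.0,
    roi="ostium",
):
    """Refine h_max geometrically and monitor centreline velocity and A_high.

    Returns a DataFrame with one row per level: h, element count, probe
    velocity magnitude, high-shear area, and the successive relative changes
    of the two monitored quantities.
    """
    import pandas as pd

    from . import flow as _flow
    from . import metrics as _metrics

    if levels < 2:
        raise ValueError("a convergence study needs at least 2 refinement levels")
    if probe_point is None:
        v = geom.vertices
        if geom.ostium_segment is not None:
            x_in = v[:, 0].min()
            probe_point = np.array([(x_in + geom.ostium_segment[0, 0]) / 2.0, 0.0])
        else:
            probe_point = v.mean(axis=0)
    rows = []
    for k in range(levels):
        r = refine_ratio ** k
        cfg_k = MeshConfig(
            h_max=cfg.h_max * r,
            near_wall_factor=cfg.near_wall_factor,
            h_strut=None if cfg.h_strut is None else cfg.h_strut * r,
            target_element_count_hint=cfg.target_element_count_hint,
        )
        mesh = generate_mesh(geom, layout, cfg_k)
        field = _flow.solve_steady_flow(mesh, fluid, conditions)
        u = field.velocity_at(np.atleast_2d(probe_point))[0]
        shear = _flow.compute_shear_rate_field(field)
        if geom.ostium_segment is not None and roi == "ostium":
            roi_geom = _metrics.ostium_roi(geom)
        else:
            roi_geom = None
        m = _metrics.compute_shear_metrics(shear, threshold=threshold, roi=roi_geom)
        rows.append(
            {
                "level": k,
                "h_max": cfg_k.h_max,
                "n_elements": len(mesh.triangles),
                "probe_speed": float(np.linalg.norm(u)),
                "A_high_mm2": m.A_high,
                "shear_max": m.shear_max,
            }
        )
    df = pd.DataFrame(rows)
    for col in ("probe_speed", "A_high_mm2"):
        prev = df[col].shift(1)
        denom = np.where(np.abs(prev) > 0, np.abs(prev), np.inf)
        df[f"rel_change_{col}"] = np.abs(df[col] - prev) / denom
    return df
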