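"""Parametric 2D longitudinal geometry of a stented coronary bifurcation.

The model is the sagittal (y-up) cut through a Y-shaped left-main bifurcation:
a proximal channel of width ``D_prox`` running along the +x axis that splits at
the carina (origin) into a main branch (MB, opening upward) and a side branch
(SB, opening downward from the lower wall).  Channel widths are measured normal
to each segment axis.  Stent struts appear in this cut as small axis-aligned
squares of side equal to the strut thickness, lying on a wall (well-apposed or
malapposed) or suspended across the SB ostium (floating).

All lengths are millimetres unless noted; strut thicknesses are carried in
micrometres, as they are quoted clinically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon

__all__ = [
    "BifurcationParams",
    "BifurcationGeometry2D",
    "StrutSpec",
    "Strut",
    "StentLayout",
    "build_bifurcation",
    "make_channel",
    "place_struts",
    "inlet_velocity_from_flow",
    "largest_remainder",
    "GeometryError",
]

UM_PER_MM = 1000.0

Strategy = Literal["KIO", "KBI", "BD-DES"]
STRATEGIES = ("KIO", "KBI", "BD-DES")


class GeometryError(ValueError):
    """Invalid geometric parameters or an infeasible strut layout."""


@dataclass(frozen=True)
class BifurcationParams:
    """Dimensions and angles of the bifurcation lumen.

    Defaults are the bench model's printed dimensions: proximal diameter
    5.5 mm, distal MB and SB diameters 3.5 mm, 90 deg between MB and SB and
    135 deg between each branch and the proximal segment.  Segment lengths are
    not printed for the model; 15 mm per segment comfortably hosts a 24-25 mm
    device across the junction.
    """

    D_prox: float = 5.5
    D_mb: float = 3.5
    D_sb: float = 3.5
    angle_mb_sb: float = 90.0
    angle_branch_prox: float = 135.0
    L_prox: float = 15.0
    L_mb: float = 15.0
    L_sb: float = 15.0
    ostium_width: float | None = None  # None -> exact geometric chord
    carina_fillet: float = 0.3

    def validate(self) -> None:
        if min(self.D_prox, self.D_mb, self.D_sb) <= 0:
            raise GeometryError("all diameters must be positive")
        if min(self.L_prox, self.L_mb, self.L_sb) <= 0:
            raise GeometryError("all segment lengths must be positive")
        if self.D_prox <= self.D_mb or self.D_prox <= self.D_sb:
            raise GeometryError("proximal diameter must exceed both branch diameters")
        if not 0.0 < self.angle_mb_sb < 180.0:
            raise GeometryError("MB-SB angle must lie strictly between 0 and 180 deg")
        if not 90.0 < self.angle_branch_prox < 180.0:
            raise GeometryError("branch-to-proximal angle must lie in (90, 180) deg")
        if self.ostium_width is not None and self.ostium_width <= 0:
            raise GeometryError("ostium_width must be positive")
        if self.carina_fillet < 0:
            raise GeometryError("carina_fillet must be non-negative")


@dataclass
class BifurcationGeometry2D:
    """Closed lumen polygon with tagged boundary edges.

    ``vertices`` is a CCW (N, 2) array in mm; ``edges`` maps each consecutive
    vertex pair to a boundary tag in {inlet, outlet_mb, outlet_sb, wall}.
    ``ostium_segment`` is the chord spanning the SB opening in the lower wall
    (None for plain channels).
    """

    vertices: np.ndarray
    edges: list[tuple[int, int, str]]
    ostium_segment: np.ndarray | None
    params: BifurcationParams | None = None

    def polygon(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.vertices)

    def tagged_segments(self, tag: str) -> np.ndarray:
        """(k, 2, 2) array of boundary segments carrying ``tag``."""
        segs = [
            (self.vertices[i], self.vertices[j])
            for i, j, t in self.edges
            if t == tag
        ]
        return np.asarray(segs, dtype=float).reshape(-1, 2, 2)

    @property
    def wall_segments(self) -> np.ndarray:
        return self.tagged_segments("wall")

    def validate(self) -> None:
        poly = self.polygon()
        if not poly.is_valid or not poly.is_simple:
            raise GeometryError("lumen polygon is self-intersecting")
        tags = [t for _, _, t in self.edges]
        if tags.count("inlet") != 1:
            raise GeometryError("exactly one inlet edge required")
        n_out = sum(1 for t in tags if t.startswith("outlet"))
        if n_out not in (1, 2):
            raise GeometryError("one or two outlet edges required")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "vertices": self.vertices.tolist(),
            "edges": [[i, j, t] for i, j, t in self.edges],
            "ostium_segment": None
            if self.ostium_segment is None
            else self.ostium_segment.tolist(),
            "params": None if self.params is None else asdict(self.params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BifurcationGeometry2D":
        params = None if d.get("params") is None else BifurcationParams(**d["params"])
        ost = d.get("ostium_segment")
        return cls(
            vertices=np.asarray(d["vertices"], dtype=float),
            edges=[(int(i), int(j), str(t)) for i, j, t in d["edges"]],
            ostium_segment=None if ost is None else np.asarray(ost, dtype=float),
            params=params,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def to_wkt(self) -> str:
        return self.polygon().wkt


@dataclass(frozen=True)
class StrutSpec:
    """Cross-sectional strut parameters of the deployed device.

    81 um is the conventional Co-Cr DES strut thickness, 70 um the
    bifurcation-dedicated platform; the BD-DES carries two connector struts in
    a 2.0-2.4 mm ostial zone and a proximal/distal diameter step of 1.15-1.3.
    """

    thickness_um: float = 81.0
    ring_spacing: float = 1.0
    connector_zone: tuple[float, float] = (2.0, 2.4)
    prox_to_dist_ratio_range: tuple[float, float] = (1.15, 1.3)

    def validate(self) -> None:
        if self.thickness_um <= 0:
            raise GeometryError("strut thickness must be positive")
        if self.ring_spacing * UM_PER_MM <= self.thickness_um:
            raise GeometryError("ring spacing must exceed strut thickness")

    @property
    def thickness_mm(self) -> float:
        return self.thickness_um / UM_PER_MM


@dataclass
class Strut:
    """One strut cross-section.

    ``wall_gap_um`` is the distance from the square to the nearest wall
    (0 for well-apposed, >thickness for malapposed, NaN for floating struts,
    which span the ostium and have no wall behind them).
    """

    center: tuple[float, float]
    side: Literal["upper_wall", "lower_wall", "ostium"]
    wall_gap_um: float
    apposition: Literal["WA", "MA", "FLOATING"]
    thickness_um: float
    is_connector: bool = False

    def square(self) -> np.ndarray:
        """Axis-aligned square outline, (4, 2) mm, CCW."""
        h = 0.5 * self.thickness_um / UM_PER_MM
        cx, cy = self.center
        return np.array(
            [[cx - h, cy - h], [cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h]]
        )

    def expected_apposition(self) -> str:
        if self.side == "ostium":
            return "FLOATING"
        return "MA" if self.wall_gap_um > self.thickness_um else "WA"


@dataclass
class StentLayout:
    strategy: Strategy
    struts: list[Strut]
    spec: StrutSpec
    seed: int
    mix: tuple[float, float, float]  # (WA, MA, floating) requested fractions

    def counts(self) -> tuple[int, int, int]:
        n_wa = sum(1 for s in self.struts if s.apposition == "WA")
        n_ma = sum(1 for s in self.struts if s.apposition == "MA")
        n_fl = sum(1 for s in self.struts if s.apposition == "FLOATING")
        return n_wa, n_ma, n_fl

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "seed": self.seed,
            "mix": list(self.mix),
            "spec": asdict(self.spec),
            "struts": [
                {
                    "center": list(s.center),
                    "side": s.side,
                    "wall_gap_um": s.wall_gap_um,
                    "apposition": s.apposition,
                    "thickness_um": s.thickness_um,
                    "is_connector": s.is_connector,
                }
                for s in self.struts
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StentLayout":
        spec_d = dict(d["spec"])
        spec_d["connector_zone"] = tuple(spec_d["connector_zone"])
        spec_d["prox_to_dist_ratio_range"] = tuple(spec_d["prox_to_dist_ratio_range"])
        return cls(
            strategy=d["strategy"],
            seed=int(d["seed"]),
            mix=tuple(d["mix"]),
            spec=StrutSpec(**spec_d),
            struts=[
                Strut(
                    center=tuple(s["center"]),
                    side=s["side"],
                    wall_gap_um=float(s["wall_gap_um"]),
                    apposition=s["apposition"],
                    thickness_um=float(s["thickness_um"]),
                    is_connector=bool(s.get("is_connector", False)),
                )
                for s in d["struts"]
            ],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


# ----------------------------------------------------------------------
# lumen construction
# ----------------------------------------------------------------------

def _rot90(v: np.ndarray) -> np.ndarray:
    return np.array([-v[1], v[0]])


def build_bifurcation(params: BifurcationParams | None = None) -> BifurcationGeometry2D:
    """Build the Y-shaped lumen polygon with tagged boundaries.

    The carina (flow-divider tip) sits at the origin; the MB axis rises at
    ``180 - angle_branch_prox`` degrees above +x and the SB axis is placed so
    that the MB-SB angle equals ``angle_mb_sb``.  A small circular fillet
    (``carina_fillet``) rounds the divider tip, as in a cast silicone model;
    without it the tip is a reflex corner with a singular velocity gradient.
    """
    params = params or BifurcationParams()
    params.validate()

    alpha = math.radians(180.0 - params.angle_branch_prox)  # MB elevation
    beta = alpha - math.radians(params.angle_mb_sb)  # SB elevation
    if beta >= 0 or beta <= -math.pi / 2:
        raise GeometryError(
            "angles place the side branch outside the lower half-plane "
            "(degenerate or self-intersecting lumen)"
        )

    u_mb = np.array([math.cos(alpha), math.sin(alpha)])
    n_mb = _rot90(u_mb)  # away from the SB, toward the upper wall
    u_sb = np.array([math.cos(beta), math.sin(beta)])
    n_sb = -_rot90(u_sb)  # toward the lower wall

    C = np.zeros(2)  # carina
    half_prox = params.D_prox / 2.0

    # MB outer wall: through C + D_mb*n_mb along u_mb; meets y = +D_prox/2
    t1 = (half_prox - params.D_mb * n_mb[1]) / u_mb[1]
    if t1 <= 0:
        raise GeometryError("MB outer wall cannot reach the proximal upper wall")
    P1 = C + params.D_mb * n_mb + t1 * u_mb
    # SB outer wall meets y = -D_prox/2
    t2 = (-half_prox - params.D_sb * n_sb[1]) / u_sb[1]
    if t2 <= 0:
        raise GeometryError("SB outer wall cannot reach the proximal lower wall")
    P2 = C + params.D_sb * n_sb + t2 * u_sb

    x_in = min(P1[0], P2[0]) - params.L_prox

    # carina fillet: tangent to both inner walls, replacing the tip vertex
    gamma = math.radians(params.angle_mb_sb) / 2.0  # solid wedge half-angle
    r_f = params.carina_fillet
    if r_f > 0:
        bisector = (u_mb + u_sb) / np.linalg.norm(u_mb + u_sb)
        O = C + (r_f / math.sin(gamma)) * bisector
        tang = r_f / math.tan(gamma)
        T_mb = C + tang * u_mb
        T_sb = C + tang * u_sb
        if tang >= min(params.L_mb, params.L_sb) / 2:
            raise GeometryError("carina fillet too large for the branch lengths")
        a_sb = math.atan2(*(T_sb - O)[::-1])
        a_mb = math.atan2(*(T_mb - O)[::-1])
        # sweep through the upstream side (passing nearest the original tip C)
        a_c = math.atan2(*(C - O)[::-1])
        # go from a_sb to a_mb the way that passes a_c
        def _unwrap(a, ref):
            while a < ref - math.pi:
                a += 2 * math.pi
            while a > ref + math.pi:
                a -= 2 * math.pi
            return a

        a_c = _unwrap(a_c, a_sb)
        a_mb_u = _unwrap(a_mb, a_c)
        angles = np.linspace(a_sb, a_mb_u, 9)
        arc = np.stack([O[0] + r_f * np.cos(angles), O[1] + r_f * np.sin(angles)], axis=1)
    else:
        T_mb = T_sb = C
        arc = C[None, :]

    Q2o = C + params.D_sb * n_sb + params.L_sb * u_sb  # SB outlet, outer corner
    Q2i = C + params.L_sb * u_sb  # SB outlet, inner corner
    Q1i = C + params.L_mb * u_mb
    Q1o = C + params.D_mb * n_mb + params.L_mb * u_mb

    verts: list[np.ndarray] = [np.array([x_in, -half_prox]), P2, Q2o, Q2i]
    tags: list[str] = ["wall", "wall", "outlet_sb", "wall"]  # tag of edge leaving vertex
    for p in arc:
        verts.append(p)
        tags.append("wall")
    verts += [Q1i, Q1o, P1, np.array([x_in, half_prox])]
    tags += ["outlet_mb", "wall", "wall", "inlet"]

    vertices = np.asarray(verts, dtype=float)
    edges = [(i, (i + 1) % len(verts), tags[i]) for i in range(len(verts))]

    ostium = np.array([P2, T_sb])
    if params.ostium_width is not None:
        mid = ostium.mean(axis=0)
        d = ostium[1] - ostium[0]
        d /= np.linalg.norm(d)
        half = params.ostium_width / 2.0
        ostium = np.array([mid - half * d, mid + half * d])

    geom = BifurcationGeometry2D(vertices, edges, ostium, params)
    geom.validate()
    return geom


def make_channel(width: float, length: float) -> BifurcationGeometry2D:
    """Straight 2D channel (inlet left, outlet right) used as a benchmark."""
    if width <= 0 or length <= 0:
        raise GeometryError("channel width and length must be positive")
    h = width / 2.0
    vertices = np.array([[0.0, -h], [length, -h], [length, h], [0.0, h]])
    edges = [(0, 1, "wall"), (1, 2, "outlet_mb"), (2, 3, "wall"), (3, 0, "inlet")]
    return BifurcationGeometry2D(vertices, edges, None, None)


# ----------------------------------------------------------------------
# strut placement
# ----------------------------------------------------------------------

def largest_remainder(fractions: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` integer counts to ``fractions`` (sum 1) by the
    largest-remainder rule; ties broken by ascending index."""
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr < -1e-12) or np.any(fr > 1 + 1e-12):
        raise GeometryError("fractions must lie in [0, 1]")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise GeometryError("fractions must sum to 1")
    raw = fr * total
    base = np.floor(raw + 1e-12).astype(int)
    rem = raw - base
    short = total - int(base.sum())
    order = np.argsort(-rem, kind="stable")
    for k in range(short):
        base[order[k]] += 1
    return base.tolist()


def _support_offset(normal: np.ndarray, side_mm: float) -> float:
    """Distance from square centre to its closest point along -normal."""
    return 0.5 * side_mm * (abs(normal[0]) + abs(normal[1]))


def _chain_slots(points: np.ndarray, normals: np.ndarray, spacing: float):
    """Equally spaced (point, inward normal) slots along a polyline."""
    seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = seglen.sum()
    n = max(1, int(math.floor(total / spacing)))
    s_values = (np.arange(n) + 0.5) * (total / n)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    slots = []
    for s in s_values:
        k = min(np.searchsorted(cum, s) - 1, len(seglen) - 1)
        k = max(k, 0)
        frac = (s - cum[k]) / seglen[k]
        p = points[k] + frac * (points[k + 1] - points[k])
        slots.append((p, normals[k]))
    return slots


def _inward_normal(a: np.ndarray, b: np.ndarray, poly: ShapelyPolygon) -> np.ndarray:
    d = b - a
    d = d / np.linalg.norm(d)
    n = _rot90(d)
    mid = (a + b) / 2.0
    probe = mid + 1e-4 * n
    if not poly.contains(shapely.points(probe[0], probe[1])):
        n = -n
    return n


def place_struts(
    geom: BifurcationGeometry2D,
    strategy: Strategy,
    spec: StrutSpec | None = None,
    mix: Sequence[float] = (0.79, 0.05, 0.16),
    seed: int = 0,
    n_struts: int = 40,
    stent_length: float | None = None,
    prox_coverage: float = 9.0,
) -> StentLayout:
    """Place strut squares for a deployment strategy.

    ``mix`` is the requested (WA, MA, floating) fraction triple; realized
    counts follow largest-remainder rounding.  Wall struts sit at
    ``ring_spacing`` intervals along the upper wall chain (proximal upper wall
    + MB outer wall) and the lower wall chain (proximal lower wall + MB inner
    wall); floating struts are spread evenly across the ostium chord.  BD-DES
    places exactly two connector struts in the ostial connector zone.

    Deterministic: a pure function of (geom, strategy, spec, mix, seed).
    """
    if strategy not in STRATEGIES:
        raise GeometryError(f"unknown strategy {strategy!r}")
    if spec is None:
        spec = StrutSpec(thickness_um=70.0 if strategy == "BD-DES" else 81.0)
    spec.validate()
    mix = tuple(float(m) for m in mix)
    if len(mix) != 3:
        raise GeometryError("mix must be a (WA, MA, floating) triple")
    n_wa, n_ma, n_fl = largest_remainder(mix, n_struts)
    if geom.ostium_segment is None and n_fl > 0:
        raise GeometryError("geometry has no ostium: floating fraction must be 0")

    rng = np.random.default_rng(seed)
    poly = geom.polygon()
    t_mm = spec.thickness_mm
    if stent_length is None:
        stent_length = 25.0 if strategy == "BD-DES" else 24.0

    params = geom.params or BifurcationParams()
    inlet = geom.tagged_segments("inlet")[0]
    x_in = inlet[:, 0].min()

    # wall chains rebuilt from the construction geometry (ordered, exact)
    if params is not None and geom.ostium_segment is not None:
        alpha = math.radians(180.0 - params.angle_branch_prox)
        u_mb = np.array([math.cos(alpha), math.sin(alpha)])
        n_mb = _rot90(u_mb)
        half_prox = params.D_prox / 2.0
        t1 = (half_prox - params.D_mb * n_mb[1]) / u_mb[1]
        P1 = params.D_mb * n_mb + t1 * u_mb
        Q1o = params.D_mb * n_mb + params.L_mb * u_mb
        Q1i = params.L_mb * u_mb
        T_sb = geom.ostium_segment[1]
        P2 = geom.ostium_segment[0]
        gamma = math.radians(params.angle_mb_sb) / 2.0
        tang = params.carina_fillet / math.tan(gamma) if params.carina_fillet > 0 else 0.0
        T_mb = tang * u_mb  # fillet tangent point on the MB inner wall
        upper_chain = np.array([[x_in, half_prox], P1, Q1o])
        upper_normals = np.array([[0.0, -1.0], -n_mb])
        lower_prox = np.array([[x_in, -half_prox], P2])
        lower_prox_normals = np.array([[0.0, 1.0]])
        mb_inner = np.array([T_mb, Q1i])
        mb_inner_normals = np.array([n_mb])
    else:
        raise GeometryError("place_struts requires a bifurcation geometry")

    # stent span: from prox_coverage upstream of the junction, stent_length long,
    # measured along the upper chain.
    d_junction = P1[0] - x_in  # arc length to P1 along the upper wall
    s0 = max(0.5, d_junction - prox_coverage)

    def clip_chain(points, normals, s_from, s_to):
        """Sub-polyline of a chain between arc lengths s_from..s_to."""
        seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        s_from = max(0.0, s_from)
        s_to = min(cum[-1], s_to)
        if s_to <= s_from:
            return None
        def interp(s):
            k = np.clip(np.searchsorted(cum, s) - 1, 0, len(seglen) - 1)
            return points[k] + (s - cum[k]) / seglen[k] * (points[k + 1] - points[k])
        pts = [interp(s_from)]
        nrms = []
        for k in range(len(seglen)):
            if cum[k + 1] > s_from and cum[k] < s_to:
                nrms.append(normals[k])
                if cum[k + 1] < s_to:
                    pts.append(points[k + 1])
        pts.append(interp(s_to))
        return np.asarray(pts), np.asarray(nrms)

    upper = clip_chain(upper_chain, upper_normals, s0, s0 + stent_length)
    # lower chain: same span, but interrupted by the ostium gap
    lp = clip_chain(lower_prox, lower_prox_normals, s0, s0 + stent_length)
    gap_len = np.linalg.norm(P2 - np.array([x_in, -half_prox])) - s0
    ostium_len = float(np.linalg.norm(geom.ostium_segment[1] - geom.ostium_segment[0]))
    s_after_gap = s0 + stent_length - gap_len - ostium_len
    mbi = clip_chain(mb_inner, mb_inner_normals, 0.0, max(0.0, s_after_gap))

    slots: list[tuple[np.ndarray, np.ndarray, str]] = []
    if upper is not None:
        for p, n in _chain_slots(*upper, spec.ring_spacing):
            slots.append((p, n, "upper_wall"))
    for chain in (lp, mbi):
        if chain is not None:
            for p, n in _chain_slots(*chain, spec.ring_spacing):
                slots.append((p, n, "lower_wall"))

    n_wall = n_wa + n_ma
    if strategy == "BD-DES":
        # reserve the ostium ends for the connectors
        a_end = geom.ostium_segment[0]
        b_end = T_mb + 0.3 * u_mb
        slots = [
            (p, n, side) for p, n, side in slots
            if min(np.linalg.norm(p - a_end), np.linalg.norm(p - b_end)) > 0.3
        ]
        if n_fl > 2:
            raise GeometryError("BD-DES has only two ostial connector struts: "
                                "floating count > 2 is infeasible")
        # the two connectors are part of the device: they consume the floating
        # budget and, when self-positioned, the WA budget
        n_conn_wa = 2 - n_fl
        if n_wa < n_conn_wa:
            raise GeometryError("mix infeasible: BD-DES connectors exceed WA budget")
        n_wa -= n_conn_wa
        n_wall = n_wa + n_ma
    if n_wall > len(slots):
        raise GeometryError(
            f"mix infeasible: {n_wall} wall struts requested, {len(slots)} slots fit"
        )
    # pick n_wall slots evenly over the available positions (deterministic)
    idx = np.unique(np.round(np.linspace(0, len(slots) - 1, n_wall)).astype(int))
    k = 0
    while len(idx) < n_wall:  # resolve collisions from rounding
        if k not in idx:
            idx = np.sort(np.append(idx, k))
        k += 1
    chosen = [slots[i] for i in idx]

    ma_pick = set(rng.choice(len(chosen), size=n_ma, replace=False).tolist()) if n_ma else set()

    # well-apposed struts are seated slightly into the wall (flush-pressed):
    # an exact tangency would pinch the fluid domain into an unmeshable wedge
    sink = 0.1 * t_mm
    struts: list[Strut] = []
    for i, (p, n, side) in enumerate(chosen):
        if i in ma_pick:
            gap_um = rng.uniform(1.0, 2.0) * spec.thickness_um
            app = "MA"
            offset = gap_um / UM_PER_MM + _support_offset(n, t_mm)
        else:
            gap_um = 0.0
            app = "WA"
            offset = _support_offset(n, t_mm) - sink
        c = p + offset * n
        struts.append(Strut(tuple(c), side, gap_um, app, spec.thickness_um))

    # floating / connector struts on the ostium chord
    a, b = geom.ostium_segment
    chord = b - a
    if strategy == "BD-DES":
        zone = rng.uniform(*spec.connector_zone)
        if zone >= ostium_len:
            raise GeometryError("connector zone exceeds the ostium length")
        mid_f = 0.5
        offs = np.array([mid_f - zone / (2 * ostium_len), mid_f + zone / (2 * ostium_len)])
        # n_fl connectors float on the chord; the rest self-position at the
        # ostium ends, apposed to the wall
        wall_ends = ((a, np.array([0.0, 1.0])), (T_mb + 0.3 * u_mb, n_mb))
        for frac in offs[:n_fl]:
            c = a + frac * chord
            struts.append(Strut(tuple(c), "ostium", float("nan"), "FLOATING",
                                spec.thickness_um, is_connector=True))
        for p, nrm in wall_ends[: 2 - n_fl]:
            c = p + (_support_offset(nrm, t_mm) - sink) * nrm
            struts.append(Strut(tuple(c), "lower_wall", 0.0, "WA",
                                spec.thickness_um, is_connector=True))
    else:
        if n_fl * t_mm > 0.8 * ostium_len:
            raise GeometryError("floating struts cannot fit across the ostium")
        for i in range(n_fl):
            frac = (i + 0.5) / n_fl
            c = a + frac * chord
            struts.append(Strut(tuple(c), "ostium", float("nan"), "FLOATING",
                                spec.thickness_um))

    layout = StentLayout(strategy, struts, spec, seed, mix)
    _validate_layout(layout, poly)
    return layout


def _validate_layout(layout: StentLayout, poly: ShapelyPolygon) -> None:
    squares = [ShapelyPolygon(s.square()) for s in layout.struts]
    grown = poly.buffer(1e-9)
    for s, sq in zip(layout.struts, squares):
        if s.apposition == "WA":
            # flush-pressed: most of the square is in the lumen, the rest
            # embedded in the wall
            if sq.intersection(poly).area < 0.5 * sq.area:
                raise GeometryError(f"strut at {s.center} falls outside the lumen")
        elif not grown.contains(sq):
            raise GeometryError(f"strut at {s.center} falls outside the lumen")
        if s.apposition != s.expected_apposition():
            raise GeometryError(f"apposition label inconsistent at {s.center}")
    tree = shapely.STRtree(squares)
    for i, sq in enumerate(squares):
        for j in tree.query(sq):
            if j != i and squares[j].intersection(sq).area > 0:
                raise GeometryError("strut squares overlap")


# ----------------------------------------------------------------------
# inlet condition
# ----------------------------------------------------------------------

def inlet_velocity_from_flow(Q_ml_min: float, D_mm: float) -> float:
    """Mean inlet velocity (m/s) of a volumetric flow through a circular lumen.

    ``Q`` in mL/min, ``D`` in mm; 200 mL/min through the 5.5 mm proximal
    lumen gives 0.14 m/s, the bench inlet condition.
    """
    if Q_ml_min <= 0 or D_mm <= 0:
        raise GeometryError("flow rate and diameter must be positive")
    Q = Q_ml_min * 1e-6 / 60.0  # m^3/s
    area = math.pi * (D_mm * 1e-3 / 2.0) ** 2
    return Q / area
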