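"""INI-style configuration files for the pipeline.

Sections map onto the library dataclasses:

    [geometry]  -> BifurcationParams
    [stent]     -> strut/layout options of the cohort
    [mesh]      -> MeshConfig
    [fluid]     -> FluidProperties
    [flow]      -> FlowConditions + SolverOptions
    [metrics]   -> shear threshold and ROI choice
    [cohort]    -> CohortConfig scalars

Every key is optional; omitted keys keep the library defaults.
"""

from __future__ import annotations

import configparser
from dataclasses import replace

from .study import RunConfig

__all__ = ["load_run_config", "dump_run_config"]

_GEOM_KEYS = {
    "d_prox": ("D_prox", float), "d_mb": ("D_mb", float), "d_sb": ("D_sb", float),
    "angle_mb_sb": ("angle_mb_sb", float),
    "angle_branch_prox": ("angle_branch_prox", float),
    "l_prox": ("L_prox", float), "l_mb": ("L_mb", float), "l_sb": ("L_sb", float),
    "ostium_width": ("ostium_width", float),
    "carina_fillet": ("carina_fillet", float),
}


def _section(cp, name):
    return cp[name] if cp.has_section(name) else {}


def load_run_config(path: str) -> RunConfig:
    cp = configparser.ConfigParser()
    with open(path) as f:
        cp.read_file(f)

    cfg = RunConfig()

    geom = cfg.cohort.geometry
    sec = _section(cp, "geometry")
    kw = {}
    for key, (fieldname, cast) in _GEOM_KEYS.items():
        if key in sec:
            kw[fieldname] = cast(sec[key])
    if kw:
        geom = replace(geom, **kw)

    cohort = replace(cfg.cohort, geometry=geom)
    sec = _section(cp, "cohort")
    for key, cast in (("n_per_group", int), ("seed", int), ("noise_scale", float),
                      ("mix_concentration", float), ("ostium_z_mm", float)):
        if key in sec:
            cohort = replace(cohort, **{key: cast(sec[key])})
    sec = _section(cp, "stent")
    for key, cast in (("n_struts", int), ("ring_spacing", float),
                      ("stent_length", float), ("prox_coverage", float)):
        if key in sec:
            cohort = replace(cohort, **{key: cast(sec[key])})

    mesh = cfg.mesh
    sec = _section(cp, "mesh")
    for key, cast in (("h_max", float), ("near_wall_factor", float),
                      ("h_strut", float)):
        if key in sec:
            mesh = replace(mesh, **{key: cast(sec[key])})

    fluid = cfg.fluid
    sec = _section(cp, "fluid")
    for key, cast in (("density", float), ("viscosity", float)):
        if key in sec:
            fluid = replace(fluid, **{key: cast(sec[key])})

    conds = cfg.conditions
    solver = cfg.solver
    sec = _section(cp, "flow")
    if "inlet_mean_velocity" in sec:
        conds = replace(conds, inlet_mean_velocity=float(sec["inlet_mean_velocity"]))
    if "inlet_profile" in sec:
        conds = replace(conds, inlet_profile=sec["inlet_profile"])
    for key, cast in (("tol", float), ("max_iter", int), ("relaxation", float)):
        if key in sec:
            solver = replace(solver, **{key: cast(sec[key])})

    threshold = cfg.shear_threshold
    roi = cfg.roi
    sec = _section(cp, "metrics")
    if "shear_threshold" in sec:
        threshold = float(sec["shear_threshold"])
    if "roi" in sec:
        roi = sec["roi"]

    return RunConfig(cohort=cohort, mesh=mesh, fluid=fluid, conditions=conds,
                     solver=solver, shear_threshold=threshold, roi=roi)


def dump_run_config(cfg: RunConfig, path: str) -> None:
    cp = configparser.ConfigParser()
    g = cfg.cohort.geometry
    cp["geometry"] = {
        "d_prox": g.D_prox, "d_mb": g.D_mb, "d_sb": g.D_sb,
        "angle_mb_sb": g.angle_mb_sb, "angle_branch_prox": g.angle_branch_prox,
        "l_prox": g.L_prox, "l_mb": g.L_mb, "l_sb": g.L_sb,
        "carina_fillet": g.carina_fillet,
    }
    cp["stent"] = {
        "n_struts": cfg.cohort.n_struts,
        "ring_spacing": cfg.cohort.ring_spacing,
        "prox_coverage": cfg.cohort.prox_coverage,
    }
    if cfg.cohort.stent_length is not None:
        cp["stent"]["stent_length"] = str(cfg.cohort.stent_length)
    cp["cohort"] = {
        "n_per_group": cfg.cohort.n_per_group, "seed": cfg.cohort.seed,
        "noise_scale": cfg.cohort.noise_scale,
    }
    cp["mesh"] = {"h_max": cfg.mesh.h_max,
                  "near_wall_factor": cfg.mesh.near_wall_factor}
    if cfg.mesh.h_strut is not None:
        cp["mesh"]["h_strut"] = str(cfg.mesh.h_strut)
    cp["fluid"] = {"density": cfg.fluid.density, "viscosity": cfg.fluid.viscosity}
    cp["flow"] = {"inlet_mean_velocity": cfg.conditions.inlet_mean_velocity,
                  "inlet_profile": cfg.conditions.inlet_profile,
                  "tol": cfg.solver.tol}
    cp["metrics"] = {"shear_threshold": cfg.shear_threshold, "roi": cfg.roi}
    for sec in cp.sections():
        for k in cp[sec]:
            cp[sec][k] = str(cp[sec][k])
    with open(path, "w") as f:
        cp.write(f)
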