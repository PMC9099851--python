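"""End-to-end study runner: cohort -> mesh -> flow -> metrics -> statistics.

``run_study`` reproduces the shape of the bench comparison: for every
synthetic sample it meshes the stented lumen, solves the steady flow, reduces
the shear field to the high-shear-area and maximum-shear endpoints (ostium
ROI and whole domain), computes the OCT-style metrics from the sample's
pullback, and finally compares the groups metric-by-metric with median (IQR)
summaries, Kruskal-Wallis and gated Dunn tests.

Solver failures on individual samples are recorded and the sample dropped
with a warning - the contract is group-level - but a group losing all its
samples aborts the study.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, SyntheticSample, sample_cohort
from .flow import (
    FlowConditions,
    FluidProperties,
    SolverError,
    SolverOptions,
    compute_shear_rate_field,
    solve_steady_flow,
)
from .geometry import BifurcationParams, build_bifurcation
from .meshing import MeshConfig, MeshingError, generate_mesh
from .metrics import compute_shear_metrics, ostium_roi
from .oct import classify_struts, elliptical_index, proximal_summary, thrombus_area_top3
from .stats import GroupSamples, StatResult, analyze_groups

__all__ = ["RunConfig", "StudyReport", "run_study", "render_tables",
           "cfd_profile_cohort", "format_median_iqr"]

log = logging.getLogger("bifurcbench")


def cfd_profile_cohort(n_per_group: int = 5, seed: int = 0, **kw) -> CohortConfig:
    """Cohort configuration of the desk CFD profile.

    Same group calibration as the full-length model, on a shortened vessel
    (10 mm proximal, 8/5 mm branches) with a 14 mm stented span at 0.8 mm ring
    pitch and 32 strut cross-sections, so that a whole cohort solves in
    minutes on one CPU.  Hemodynamics near the ostium - where both endpoints
    live - is unaffected by the truncated far fields.
    """
    cfg = CohortConfig(
        n_per_group=n_per_group,
        seed=seed,
        geometry=BifurcationParams(L_prox=10.0, L_mb=8.0, L_sb=5.0),
        n_struts=32,
        stent_length=14.0,
        prox_coverage=5.5,
        ring_spacing=0.75,
        **kw,
    )
    return cfg


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=cfd_profile_cohort)
    mesh: MeshConfig = field(
        default_factory=lambda: MeshConfig(h_max=0.34, near_wall_factor=0.65,
                                           h_strut=0.055)
    )
    fluid: FluidProperties = field(default_factory=FluidProperties)
    conditions: FlowConditions = field(default_factory=FlowConditions)
    solver: SolverOptions = field(default_factory=lambda: SolverOptions(tol=1e-4))
    shear_threshold: float = 1000.0
    roi: str = "ostium"  # "ostium" | "whole"
    outdir: str | None = None
    do_cfd: bool = True
    save_figures: bool = False  # per-sample shear maps under outdir/figures

    def config_hash(self) -> str:
        d = _to_jsonable(self)
        d.pop("outdir", None)  # where results land is not part of the science
        blob = json.dumps(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _to_jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class StudyReport:
    per_sample: pd.DataFrame
    stats: dict[str, StatResult]
    failures: list[tuple[str, str]]
    seed: int
    config_hash: str
    version: str = __version__

    def stats_frame(self) -> pd.DataFrame:
        rows = []
        for metric, res in self.stats.items():
            row = {"metric": metric, "H": res.kw.H, "p_kw": res.kw.p,
                   "config_hash": self.config_hash}
            for lab, (med, q1, q3) in res.summaries.items():
                row[f"{lab}_median"] = med
                row[f"{lab}_q1"] = q1
                row[f"{lab}_q3"] = q3
            if res.dunn is not None:
                for pair, p in res.dunn.p.items():
                    row[f"p_{pair[0]}_vs_{pair[1]}"] = p
            rows.append(row)
        return pd.DataFrame(rows)


_METRIC_KINDS = {
    "A_high_roi_mm2": "area",
    "A_high_global_mm2": "area",
    "shear_max_roi": "shear",
    "shear_max_global": "shear",
    "pct_WA": "pct",
    "pct_MA": "pct",
    "pct_floating": "pct",
    "EI": "ratio",
    "thrombus_top3_mm2": "area",
    "proximal_Dmean_mm": "mm",
    "proximal_area_mm2": "area",
    "damage_cat1": "count",
    "damage_cat2": "count",
    "damage_cat3": "count",
    "damage_cat4": "count",
}


def _sample_row(sample: SyntheticSample, cfg: RunConfig) -> dict:
    row: dict = {"sample_id": sample.sample_id, "group": sample.group,
                 "seed": cfg.cohort.seed, "config_hash": cfg.config_hash()}
    cl = classify_struts(sample.pullback)
    row["pct_WA"] = cl.pct_WA
    row["pct_MA"] = cl.pct_MA
    row["pct_floating"] = cl.pct_floating
    ei, _ = elliptical_index(sample.pullback)
    row["EI"] = ei
    row["thrombus_top3_mm2"] = thrombus_area_top3(sample.pullback)
    dmin, dmean, dmax, area = proximal_summary(sample.pullback)
    row["proximal_Dmin_mm"] = dmin
    row["proximal_Dmean_mm"] = dmean
    row["proximal_Dmax_mm"] = dmax
    row["proximal_area_mm2"] = area
    for c, v in sample.coating_damage_counts.items():
        row[f"damage_cat{c}"] = v
    return row


def run_study(cfg: RunConfig | None = None) -> StudyReport:
    cfg = cfg or RunConfig()
    cohort = sample_cohort(cfg.cohort)
    geom = build_bifurcation(cfg.cohort.geometry)
    roi_geom = ostium_roi(geom) if cfg.roi == "ostium" else None

    rows = []
    failures: list[tuple[str, str]] = []
    for sample in cohort:
        row = _sample_row(sample, cfg)
        if cfg.do_cfd:
            try:
                mesh = generate_mesh(geom, sample.layout, cfg.mesh)
                fieldv = solve_steady_flow(mesh, cfg.fluid, cfg.conditions, cfg.solver)
                shear = compute_shear_rate_field(fieldv)
                m_roi = compute_shear_metrics(shear, cfg.shear_threshold, roi_geom)
                m_glob = compute_shear_metrics(shear, cfg.shear_threshold, None)
                row["A_high_roi_mm2"] = m_roi.A_high
                row["shear_max_roi"] = m_roi.shear_max
                row["A_high_global_mm2"] = m_glob.A_high
                row["shear_max_global"] = m_glob.shear_max
                row["n_elements"] = len(mesh.triangles)
                row["mass_imbalance"] = fieldv.net_flux_imbalance()
                if cfg.outdir and cfg.save_figures:
                    figdir = os.path.join(cfg.outdir, "figures")
                    os.makedirs(figdir, exist_ok=True)
                    save_shear_map(
                        mesh, shear.shear_rate,
                        os.path.join(figdir, f"{sample.sample_id}_shear.png"),
                        title=sample.sample_id,
                    )
            except (SolverError, MeshingError) as err:
                log.warning("sample %s dropped: %s", sample.sample_id, err)
                failures.append((sample.sample_id, str(err)))
                continue
        rows.append(row)

    df = pd.DataFrame(rows)
    groups_present = df["group"].unique().tolist() if len(df) else []
    for lab in {s.group for s in cohort}:
        if lab not in groups_present:
            raise RuntimeError(
                f"no successful samples in group {lab}: "
                f"failures: {failures}"
            )

    stats: dict[str, StatResult] = {}
    for metric in _METRIC_KINDS:
        if metric not in df.columns:
            continue
        labs = [g for g in df["group"].unique()]
        vals = [df.loc[df["group"] == g, metric].to_numpy() for g in labs]
        if any(len(v) == 0 for v in vals):
            continue
        stats[metric] = analyze_groups(GroupSamples(labs, vals), metric)

    report = StudyReport(df, stats, failures, cfg.cohort.seed, cfg.config_hash())
    if cfg.outdir:
        os.makedirs(cfg.outdir, exist_ok=True)
        df.to_csv(os.path.join(cfg.outdir, "per_sample.csv"), index=False)
        report.stats_frame().to_csv(os.path.join(cfg.outdir, "group_stats.csv"),
                                    index=False)
        with open(os.path.join(cfg.outdir, "tables.txt"), "w") as f:
            f.write(render_tables(report))
        with open(os.path.join(cfg.outdir, "provenance.json"), "w") as f:
            json.dump({"seed": cfg.cohort.seed, "config_hash": report.config_hash,
                       "version": report.version,
                       "failures": failures}, f, indent=1)
    return report


def save_shear_map(mesh, shear_rate: np.ndarray, path: str, title: str = "",
                   vmax: float | None = 2000.0) -> None:
    """Render the element shear-rate field of one sample to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 6))
    tpc = ax.tripcolor(
        mesh.points[:, 0], mesh.points[:, 1], mesh.triangles,
        facecolors=np.asarray(shear_rate), cmap="inferno", vmin=0.0, vmax=vmax,
    )
    fig.colorbar(tpc, ax=ax, label="shear rate (1/s)")
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


# ----------------------------------------------------------------------
# table rendering
# ----------------------------------------------------------------------

def format_median_iqr(values, kind: str = "mm") -> str:
    """'median (Q1-Q3)' with the table rounding convention: 2 dp for mm and
    mm^2 (and shear in 1/s uses 0 dp), 1 dp for percentages, integers for
    counts."""
    med, q1, q3 = np.percentile(np.asarray(values, dtype=float), [50, 25, 75])
    if kind in ("mm", "area", "ratio"):
        fmt = "{:.2f}"
    elif kind == "pct":
        fmt = "{:.1f}"
    elif kind == "shear":
        fmt = "{:.0f}"
    elif kind == "count":
        fmt = "{:.0f}"
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return f"{fmt.format(med)} ({fmt.format(q1)}–{fmt.format(q3)})"


def render_tables(report: StudyReport) -> str:
    """Plain-text group tables in the bench layout: one row per metric,
    median (IQR) per group, p-value column."""
    df = report.per_sample
    labs = list(df["group"].unique())
    width = max(len(m) for m in report.stats) + 2 if report.stats else 20
    colw = 22
    lines = []
    header = "Metric".ljust(width) + "".join(lab.ljust(colw) for lab in labs) + "p (KW)"
    lines.append(header)
    lines.append("-" * len(header))
    for metric, res in report.stats.items():
        kind = _METRIC_KINDS.get(metric, "mm")
        cells = []
        for lab in labs:
            vals = df.loc[df["group"] == lab, metric]
            cells.append(format_median_iqr(vals, kind).ljust(colw))
        lines.append(metric.ljust(width) + "".join(cells) + f"{res.kw.p:.4f}")
        if res.dunn is not None:
            for pair, p in res.dunn.p.items():
                lines.append(
                    " " * width + f"  Dunn {pair[0]} vs {pair[1]}: p = {p:.4f}"
                    f" (Bonferroni {res.dunn.p_bonferroni[pair]:.4f})"
                )
    lines.append("")
    lines.append("Values are median (interquartile range); Dunn rows appear only "
                 "when the Kruskal-Wallis test is significant at alpha = 0.05.")
    lines.append(f"config {report.config_hash}, seed {report.seed}, "
                 f"bifurcbench {report.version}")
    return "\n".join(lines)
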