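#!/usr/bin/env python
"""Validate the flow solver against its closed-form oracles.

Plane Poiseuille (centreline speed 1.5 U, wall shear 6U/h) and the
strut-free symmetric bifurcation (50/50 outlet split, exact mass balance).
Writes results/benchmarks.csv.
"""

import os

import numpy as np
import pandas as pd

from bifurcbench.flow import compute_shear_rate_field, solve_steady_flow
from bifurcbench.geometry import BifurcationParams, build_bifurcation, make_channel
from bifurcbench.meshing import MeshConfig, generate_mesh

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
U, H = 0.14, 5.5


def main():
    os.makedirs(OUT, exist_ok=True)
    rows = []

    mesh = generate_mesh(make_channel(H, 15.0), None,
                         MeshConfig(h_max=H / 20, near_wall_factor=0.5))
    field = solve_steady_flow(mesh)
    u_c = field.velocity_at(np.array([[7.5, 0.0]]))[0, 0]
    shear = compute_shear_rate_field(field)
    c = shear.centroids_mm
    wall = (np.abs(np.abs(c[:, 1]) - H / 2) < 0.15) & (c[:, 0] > 4) & (c[:, 0] < 11)
    g_wall = shear.shear_rate[wall].max()
    rows += [
        {"check": "poiseuille_centerline_m_s", "value": u_c, "reference": 1.5 * U},
        {"check": "poiseuille_wall_shear_1_s", "value": g_wall,
         "reference": 6 * U / (H * 1e-3)},
        {"check": "poiseuille_mass_imbalance", "value": field.net_flux_imbalance(),
         "reference": 0.0},
    ]
    print(f"Poiseuille: centreline {u_c:.5f} m/s (expect {1.5*U:.3f}), "
          f"wall shear {g_wall:.1f} 1/s (expect {6*U/(H*1e-3):.1f})")

    geom = build_bifurcation(BifurcationParams(L_prox=8.0, L_mb=6.0, L_sb=6.0))
    mesh = generate_mesh(geom, None, MeshConfig(h_max=0.34, near_wall_factor=0.6))
    field = solve_steady_flow(mesh)
    q_mb = field.boundary_flux("outlet_mb")
    q_sb = field.boundary_flux("outlet_sb")
    split = q_mb / (q_mb + q_sb)
    rows += [
        {"check": "symmetric_split_fraction", "value": split, "reference": 0.5},
        {"check": "symmetric_mass_imbalance", "value": field.net_flux_imbalance(),
         "reference": 0.0},
    ]
    print(f"Symmetric bifurcation: MB share {split:.6f} (expect 0.5), "
          f"mass imbalance {field.net_flux_imbalance():.2e}")

    pd.DataFrame(rows).to_csv(os.path.join(OUT, "benchmarks.csv"), index=False)


if __name__ == "__main__":
    main()
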