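"""Shipped example configurations used by the docs, tests and benchmarks."""

from __future__ import annotations

from .geometry import BifurcationParams, StrutSpec, build_bifurcation, place_struts
from .meshing import MeshConfig

__all__ = ["kio_example", "KIO_EXAMPLE_MIX"]

# normalized Table-style apposition medians for the jailed-ostium strategy
KIO_EXAMPLE_MIX = (0.791, 0.049, 0.160)


def kio_example(seed: int = 1):
    """Reference KIO (jailed side-branch) sample on the desk CFD geometry.

    Returns (geometry, layout, mesh_config): the shortened vessel used by the
    cohort CFD profile, a 32-strut layout at the KIO apposition mix, and the
    matching mesh sizing.
    """
    params = BifurcationParams(L_prox=10.0, L_mb=8.0, L_sb=5.0)
    geom = build_bifurcation(params)
    layout = place_struts(
        geom,
        "KIO",
        spec=StrutSpec(thickness_um=81.0, ring_spacing=0.75),
        mix=KIO_EXAMPLE_MIX,
        seed=seed,
        n_struts=32,
        stent_length=14.0,
        prox_coverage=5.5,
    )
    cfg = MeshConfig(h_max=0.34, near_wall_factor=0.65, h_strut=0.055)
    return geom, layout, cfg
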