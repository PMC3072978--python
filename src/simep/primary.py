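"""Non-dimensional primary current distribution model of the channel.

The primary model neglects surface and concentration losses: electrode
surfaces are equipotential and the non-dimensional potential solves the
Laplace equation with Dirichlet data 1 (anode) / 0 (cathode) on the bottom
edge and zero flux elsewhere.  Lengths are scaled by the active electrode
length l, potentials by the electrode potential difference V_d, so the
non-dimensional field E* converts to a dimensional one as E = E* V_d / l.

The figure of merit is |E*| at the channel mid-plane above the insulator
centre — probe point (X, Y) = (0.5, 1) in the height-scaled convention,
node (0.5, G) on our grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .geometry import ChannelGeometryND, Grid2D, build_channel_grid
from .laplace import (
    Dirichlet,
    ElectricField,
    PotentialField,
    ZeroFlux,
    electric_field,
    solve_laplace,
)

__all__ = [
    "PrimaryResult",
    "solve_primary",
    "sweep_primary",
    "percent_increase",
    "dimensionalize",
    "max_dimensional_field",
]

V_PER_M_TO_KV_PER_CM = 1e-5


@dataclass(frozen=True)
class PrimaryResult:
    geometry: ChannelGeometryND
    phi: PotentialField
    efield: ElectricField
    probe_value: float  # |E*| at (X=0.5, Y=1)
    n_base: int  # refinement level actually used
    converged: bool  # probe changed < rtol between the two finest levels


def _solve_once(
    geom: ChannelGeometryND, n_base: int, grading: float
) -> tuple[Grid2D, PotentialField, ElectricField, float]:
    grid = build_channel_grid(geom, n_base=n_base, grading=grading)
    anode = grid.segments["anode"]
    anode_vals = np.ones(anode.n_nodes)
    if grid.segments["insulator"].n_nodes == 0:
        # zero-width insulator: the junction node carries the mean of the
        # two electrode potentials (the potential is discontinuous there)
        anode_vals[-1] = 0.5
    bc = {
        "anode": Dirichlet(anode_vals),
        "cathode": Dirichlet(0.0),
        "insulator": ZeroFlux(),
        "left": ZeroFlux(),
        "right": ZeroFlux(),
        "top": ZeroFlux(),
    }
    phi = solve_laplace(grid, bc)
    ef = electric_field(phi)
    probe = _probe(ef, x=0.5, y=geom.G)
    return grid, phi, ef, probe


def _probe(ef: ElectricField, x: float, y: float) -> float:
    """Bilinear interpolation of |E| (a grid line always lies on X = 0.5
    and Y = 1 is the top boundary, so this degenerates to a node read)."""
    interp = RegularGridInterpolator(
        (ef.grid.y, ef.grid.x), ef.magnitude, method="linear"
    )
    return float(interp([[y, x]])[0])


def solve_primary(
    geom: ChannelGeometryND,
    n_base: int = 64,
    grading: float = 2.0,
    check_convergence: bool = True,
    rtol: float = 0.01,
) -> PrimaryResult:
    """Solve the primary model at geometry ``geom``.

    With ``check_convergence`` the model is solved at n_base and 2*n_base
    (nested refinement); the reported probe value comes from the fine grid
    and ``converged`` records whether it moved by less than ``rtol``
    relative between the two levels.
    """
    if check_convergence:
        *_, probe_coarse = _solve_once(geom, n_base, grading)
        n_fine = 2 * n_base
        grid, phi, ef, probe = _solve_once(geom, n_fine, grading)
        converged = abs(probe - probe_coarse) <= rtol * abs(probe)
        return PrimaryResult(geom, phi, ef, probe, n_fine, converged)
    grid, phi, ef, probe = _solve_once(geom, n_base, grading)
    return PrimaryResult(geom, phi, ef, probe, n_base, False)


def sweep_primary(
    G_list,
    eps_list,
    n_base: int = 64,
    grading: float = 2.0,
    check_convergence: bool = True,
) -> pd.DataFrame:
    """Parametric sweep over aspect ratio and relative insulator thickness.

    Returns one row per (G, epsilon) pair, G-major / epsilon-minor order,
    with columns G, epsilon, probe_E, refinement_level, converged.  The
    computation is deterministic: repeated calls give identical tables.
    """
    G_list = list(G_list)
    eps_list = list(eps_list)
    if not G_list or not eps_list:
        raise ValueError("G_list and eps_list must be non-empty")
    rows = []
    for G in G_list:
        for eps in eps_list:
            try:
                res = solve_primary(
                    ChannelGeometryND(G=G, epsilon=eps),
                    n_base=n_base,
                    grading=grading,
                    check_convergence=check_convergence,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"primary sweep failed at (G={G}, epsilon={eps}): {exc}"
                ) from exc
            rows.append(
                {
                    "G": G,
                    "epsilon": eps,
                    "probe_E": res.probe_value,
                    "refinement_level": res.n_base,
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(rows)


def percent_increase(value_at_eps0: float, value_at_eps: float) -> float:
    """Percent increase of the probe field going from a finite insulator
    to the zero-width (singular) one: 100 * (new - old) / old."""
    if value_at_eps0 <= 0 or value_at_eps <= 0:
        raise ValueError("probe field magnitudes must be positive")
    return 100.0 * (value_at_eps0 - value_at_eps) / value_at_eps


def dimensionalize(result: PrimaryResult, V_d: float, l: float) -> np.ndarray:
    """Dimensional field magnitudes in kV/cm: E = E* V_d / l."""
    if V_d <= 0 or l <= 0:
        raise ValueError("V_d and l must be positive")
    return result.efield.magnitude * (V_d / l) * V_PER_M_TO_KV_PER_CM


def max_dimensional_field(
    result: PrimaryResult, V_d: float, l: float, exclude_junctions: bool = True
) -> float:
    """Maximum dimensional field magnitude (kV/cm) over the domain nodes,
    optionally excluding the two singular insulator-junction corner nodes
    where the discrete value diverges with refinement."""
    mag = dimensionalize(result, V_d, l).copy()
    if exclude_junctions:
        grid = result.phi.grid
        ja = grid.segments["anode"].hi
        jc = grid.segments["cathode"].lo
        mag[0, ja] = 0.0
        mag[0, jc] = 0.0
        # at zero insulator width the singular node is the shared junction
        ins = grid.segments["insulator"]
        if ins.n_nodes == 0:
            mag[0, ja] = 0.0
    return float(mag.max())
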