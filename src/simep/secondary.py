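"""Secondary current distribution model of the singularity-induced
micro-electroporation configuration.

The electrolyte potential solves the Laplace equation; at each electrode
node the normal current density must equal the Butler-Volmer kinetic
current at the local surface overpotential, a nonlinear flux (Robin-type)
boundary condition.  The coupling is solved by damped Newton iteration:
every outer step linearises the kinetic law about the current boundary
potential, solves the resulting linear Robin problem with the shared
finite-difference core, and updates with a step-halving line search on the
boundary-current residual.  A continuation ladder in applied voltage
(steps <= 0.1 V) seeds each solve with the previous solution, which tames
the stiff exponential kinetics of the sluggish anode reaction.

Reported quantities follow the device literature: fields in kV/cm, power
per unit device footprint in uW/cm^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import Grid2D, SecondaryCellGeometry, build_secondary_grid
from .kinetics import (
    CellKinetics,
    bv_current,
    bv_current_derivative,
    exp_cap_active,
    platinum_water,
)
from .laplace import (
    BoundaryCurrent,
    ElectricField,
    Flux,
    PotentialField,
    ZeroFlux,
    boundary_current,
    electric_field,
    solve_laplace,
)

__all__ = [
    "SecondaryCellSpec",
    "SecondarySolution",
    "ConvergenceError",
    "solve_secondary",
    "centerline_profile",
    "power_input",
    "sweep_secondary",
    "insulator_centre_field",
]

logger = logging.getLogger(__name__)

V_PER_M_TO_KV_PER_CM = 1e-5
W_PER_M2_TO_UW_PER_CM2 = 100.0


class ConvergenceError(RuntimeError):
    """Outer Newton iteration failed; carries the residual history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class SecondaryCellSpec:
    """Everything that defines one secondary-model run."""

    geometry: SecondaryCellGeometry = field(default_factory=SecondaryCellGeometry)
    kinetics: CellKinetics = field(default_factory=platinum_water)
    sigma: float = 0.0005  # S/m
    V_app: float = 2.7  # V

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.V_app <= 0:
            raise ValueError(f"V_app must be positive, got {self.V_app}")


@dataclass(frozen=True)
class SecondarySolution:
    spec: SecondaryCellSpec
    phi: PotentialField  # electrolyte potential, V
    efield: ElectricField  # V/m
    anode_current: BoundaryCurrent
    cathode_current: BoundaryCurrent
    I_total: float  # A per metre of depth (kinetic integral at the anode)
    P: float  # power input per footprint area, uW/cm^2
    n_base: int
    converged: bool
    no_drive: bool
    diagnostics: dict = field(default_factory=dict)


def _electrode_info(grid: Grid2D, spec: SecondaryCellSpec):
    """Per-electrode (segment, metal potential, params) table."""
    return {
        "anode": (grid.segments["anode"], spec.V_app, spec.kinetics.anode),
        "cathode": (grid.segments["cathode"], 0.0, spec.kinetics.cathode),
    }


def _kinetic_density(phi_s: np.ndarray, phi_metal: float, params) -> np.ndarray:
    """Current density entering the electrolyte at electrode surface nodes."""
    return bv_current(phi_metal - phi_s - params.E_eq, params)


def _surface_values(phi: np.ndarray, seg) -> np.ndarray:
    """Electrolyte potential at the surface nodes of an electrode segment."""
    idx = slice(seg.lo, seg.hi + 1)
    if seg.edge == "bottom":
        return phi[0, idx]
    if seg.edge == "top":
        return phi[-1, idx]
    if seg.edge == "left":
        return phi[idx, 0]
    return phi[idx, -1]


def _newton_solve(
    grid: Grid2D,
    electrodes: dict,
    sigma: float,
    phi0: np.ndarray,
    outer_tol: float,
    max_outer: int,
) -> tuple[np.ndarray, list[float]]:
    """Damped Newton iteration at a single applied voltage.

    ``electrodes`` maps segment name -> (segment, metal potential, kinetic
    params); every other grid segment gets a zero-flux condition.
    """
    phi = phi0.copy()
    history: list[float] = []
    prev_density: dict[str, np.ndarray] = {}
    # absolute current-density floor for the relative residual: at (or very
    # near) open circuit every density tends to zero and a purely relative
    # measure would never converge; the smallest exchange current density
    # is the natural resolvable-current scale
    i_floor = min(params.i0 for (_, _, params) in electrodes.values())

    def densities(ph: np.ndarray) -> dict[str, np.ndarray]:
        return {
            name: bv_current(vm - _surface_values(ph, seg) - params.E_eq, params)
            for name, (seg, vm, params) in electrodes.items()
        }

    for _ in range(max_outer):
        bc: dict = {
            name: ZeroFlux()
            for name in grid.segments
            if name not in electrodes
        }
        dens_now = densities(phi)
        for name, (seg, vm, params) in electrodes.items():
            phi_s = _surface_values(phi, seg)
            eta = vm - phi_s - params.E_eq
            didphi = -bv_current_derivative(eta, params)  # d i / d phi_s
            # Robin linearisation: i(phi) ~ i_k + didphi*(phi - phi_k);
            # solve_laplace wants the inward gradient flux q + s*phi
            bc[name] = Flux(
                value=(dens_now[name] - didphi * phi_s) / sigma,
                slope=didphi / sigma,
            )
        sol = solve_laplace(grid, bc)
        step = sol.values - phi

        # residual: relative max change of the kinetic boundary density
        if prev_density:
            num = max(
                float(np.abs(dens_now[n] - prev_density[n]).max()) for n in dens_now
            )
            den = max(float(np.abs(dens_now[n]).max()) for n in dens_now)
            resid = num / max(den, i_floor)
        else:
            resid = np.inf
        history.append(resid)
        if resid <= outer_tol:
            return phi, history
        # machine-precision fixed point: the potential no longer moves
        # (covers exact open-circuit, where every density is zero and the
        # relative current residual is pure roundoff jitter)
        if float(np.abs(step).max()) <= 1e-12 * max(1.0, float(np.abs(phi).max())):
            history.append(0.0)
            return sol.values, history

        # damped update with halving on boundary-current residual increase
        lam = 1.0
        best = None
        den = max(float(np.abs(dens_now[n]).max()) for n in dens_now)
        for _ in range(8):
            trial = phi + lam * step
            d_trial = densities(trial)
            tr = max(
                float(np.abs(d_trial[n] - dens_now[n]).max()) for n in dens_now
            ) / max(den, i_floor)
            if best is None or tr < best[1]:
                best = (trial, tr)
            if len(history) < 2 or tr <= history[-1] or lam <= 1 / 64:
                break
            lam *= 0.5
        phi = best[0]
        prev_density = dens_now

    raise ConvergenceError(
        f"secondary solve did not converge in {max_outer} outer iterations "
        f"(last residual {history[-1]:.3e})",
        history,
    )


def solve_secondary(
    spec: SecondaryCellSpec,
    n_base: int = 64,
    grading: float = 2.5,
    outer_tol: float = 1e-6,
    max_outer: int = 60,
    continuation_step: float = 0.1,
) -> SecondarySolution:
    """Solve the coupled secondary model.

    Applied voltages above E_cell_eq + 0.1 V are reached by a continuation
    ladder (steps <= ``continuation_step``) starting just above the
    open-circuit point, each rung seeded with the previous potential.
    """
    grid = build_secondary_grid(spec.geometry, n_base=n_base, grading=grading)
    E_cell = spec.kinetics.E_cell_eq

    # continuation ladder in applied voltage
    if spec.V_app > E_cell + continuation_step:
        n_steps = int(np.ceil((spec.V_app - E_cell) / continuation_step))
        ladder = list(E_cell + (spec.V_app - E_cell) * np.arange(1, n_steps + 1) / n_steps)
    else:
        ladder = [spec.V_app]

    # initial guess: uniform potential halfway between the two zero-current
    # surface potentials (anode: V - E_a, cathode: -E_c)
    phi = np.full(
        grid.shape,
        0.5 * ((ladder[0] - spec.kinetics.anode.E_eq) + (-spec.kinetics.cathode.E_eq)),
    )
    history_all: list[float] = []
    for V in ladder:
        electrodes = {
            "anode": (grid.segments["anode"], V, spec.kinetics.anode),
            "cathode": (grid.segments["cathode"], 0.0, spec.kinetics.cathode),
        }
        phi, hist = _newton_solve(
            grid, electrodes, spec.sigma, phi, outer_tol, max_outer
        )
        history_all.extend(hist)
        logger.info(
            "continuation V=%.3f V converged in %d iterations", V, len(hist)
        )

    # overflow-guard audit on the converged overpotentials
    for name, (seg, vm, params) in _electrode_info(grid, spec).items():
        eta = vm - phi[0, seg.lo : seg.hi + 1] - params.E_eq
        if exp_cap_active(eta, params):
            raise ConvergenceError(
                f"overflow guard active at the {name} in a converged solve",
                history_all,
            )

    field_phi = PotentialField(grid=grid, values=phi)
    ef = electric_field(field_phi)
    an = boundary_current(field_phi, spec.sigma, "anode")
    ca = boundary_current(field_phi, spec.sigma, "cathode")

    # total current from the kinetic law (exact in the discrete BC sense)
    seg, vm, params = _electrode_info(grid, spec)["anode"]
    i_kin = _kinetic_density(phi[0, seg.lo : seg.hi + 1], vm, params)
    I_total = float(np.trapezoid(i_kin, grid.x[seg.lo : seg.hi + 1]))

    no_drive = I_total <= 0.0
    if no_drive:
        logger.warning(
            "V_app=%.3f V is at or below the open-circuit point: NO_DRIVE "
            "(I_total=%.3e A/m)", spec.V_app, I_total,
        )

    P = power_from_current(spec, I_total)

    # voltage-budget diagnostics
    a_seg = grid.segments["anode"]
    c_seg = grid.segments["cathode"]
    phi_s_a = float(phi[0, a_seg.lo : a_seg.hi + 1].mean())
    phi_s_c = float(phi[0, c_seg.lo : c_seg.hi + 1].mean())
    eta_a = spec.V_app - phi_s_a - spec.kinetics.anode.E_eq
    eta_c = -phi_s_c - spec.kinetics.cathode.E_eq
    diagnostics = {
        "residual_history": history_all,
        "ohmic_drop": phi_s_a - phi_s_c,
        "eta_a_mean": eta_a,
        "eta_c_mean": eta_c,
        "voltage_budget": spec.kinetics.E_cell_eq + eta_a - eta_c + (phi_s_a - phi_s_c),
    }
    return SecondarySolution(
        spec=spec,
        phi=field_phi,
        efield=ef,
        anode_current=an,
        cathode_current=ca,
        I_total=I_total,
        P=P,
        n_base=n_base,
        converged=True,
        no_drive=no_drive,
        diagnostics=diagnostics,
    )


def power_from_current(spec: SecondaryCellSpec, I_total: float) -> float:
    """P = V_app * I, normalised per unit device footprint area.

    The per-depth current (A/m) divided by the domain length gives an
    average current density (A/m^2); times V_app gives W/m^2, converted to
    uW/cm^2.
    """
    return spec.V_app * (I_total / spec.geometry.length) * W_PER_M2_TO_UW_PER_CM2


def power_input(sol: SecondarySolution) -> float:
    """Power input of a converged solution, uW/cm^2."""
    return power_from_current(sol.spec, sol.I_total)


def _centre_column(grid: Grid2D) -> int:
    return int(np.argmin(np.abs(grid.x - grid.x[-1] / 2.0)))


def insulator_centre_field(sol: SecondarySolution) -> float:
    """|E| (kV/cm) at the electrolyte node above the insulator midpoint
    (x = length/2, y = 0)."""
    j = _centre_column(sol.phi.grid)
    return float(sol.efield.magnitude[0, j]) * V_PER_M_TO_KV_PER_CM


def centerline_profile(sol: SecondarySolution) -> pd.DataFrame:
    """Field magnitude along the vertical centreline directly above the
    insulator, from its surface to the top boundary.

    Columns: y_um (micrometres above the insulator), E_kV_cm.
    """
    grid = sol.phi.grid
    j = _centre_column(grid)
    return pd.DataFrame(
        {
            "y_um": grid.y * 1e6,
            "E_kV_cm": sol.efield.magnitude[:, j] * V_PER_M_TO_KV_PER_CM,
        }
    )


def solve_facing_cell(
    gap: float,
    height: float,
    sigma: float,
    V_app: float,
    kinetics: CellKinetics | None = None,
    n: int = 33,
    outer_tol: float = 1e-10,
    max_outer: int = 60,
) -> float:
    """Facing-electrode emulation on the 2D machinery: anode on the left
    edge, cathode on the right, zero flux top/bottom.

    The geometry degenerates to a uniform 1D cell, so the mean anode
    current density must match the closed-form ``solve_1d_cell`` oracle;
    returns that mean density (A/m^2).
    """
    from .geometry import BoundarySegment, SegmentLabel

    kinetics = kinetics or platinum_water()
    x = np.linspace(0.0, gap, n)
    y = np.linspace(0.0, height, n)
    segments = {
        "anode": BoundarySegment("anode", "left", 0, n - 1, SegmentLabel.ANODE),
        "cathode": BoundarySegment("cathode", "right", 0, n - 1, SegmentLabel.CATHODE),
        "bottom": BoundarySegment("bottom", "bottom", 1, n - 2, SegmentLabel.ZERO_FLUX),
        "top": BoundarySegment("top", "top", 1, n - 2, SegmentLabel.ZERO_FLUX),
    }
    grid = Grid2D(x=x, y=y, segments=segments)
    electrodes = {
        "anode": (segments["anode"], V_app, kinetics.anode),
        "cathode": (segments["cathode"], 0.0, kinetics.cathode),
    }
    phi0 = np.full(
        grid.shape,
        0.5 * ((V_app - kinetics.anode.E_eq) + (-kinetics.cathode.E_eq)),
    )
    phi, _ = _newton_solve(grid, electrodes, sigma, phi0, outer_tol, max_outer)
    i = bv_current(V_app - phi[:, 0] - kinetics.anode.E_eq, kinetics.anode)
    return float(i.mean())


def sweep_secondary(
    sigma_list,
    vapp_list,
    geometry: SecondaryCellGeometry | None = None,
    kinetics: CellKinetics | None = None,
    n_base: int = 64,
    grading: float = 2.5,
) -> pd.DataFrame:
    """Parametric sweep over conductivity and applied voltage.

    Within each sigma the applied voltages are solved in increasing order
    (continuation); rows keep the caller's ordering.  Per-cell failures are
    recorded in the table (converged = False) and the sweep continues.
    """
    sigma_list = list(sigma_list)
    vapp_list = list(vapp_list)
    if not sigma_list or not vapp_list:
        raise ValueError("sigma_list and vapp_list must be non-empty")
    geometry = geometry or SecondaryCellGeometry()
    kinetics = kinetics or platinum_water()
    rows = []
    for sigma in sigma_list:
        for V in sorted(vapp_list):
            spec = SecondaryCellSpec(
                geometry=geometry, kinetics=kinetics, sigma=sigma, V_app=V
            )
            try:
                sol = solve_secondary(spec, n_base=n_base, grading=grading)
                rows.append(
                    {
                        "sigma": sigma,
                        "V_app": V,
                        "E_centre_kV_cm": insulator_centre_field(sol),
                        "I_total": sol.I_total,
                        "P_uW_cm2": sol.P,
                        "converged": True,
                    }
                )
            except (ConvergenceError, RuntimeError) as exc:
                logger.error("sweep cell (sigma=%g, V=%g) failed: %s", sigma, V, exc)
                rows.append(
                    {
                        "sigma": sigma,
                        "V_app": V,
                        "E_centre_kV_cm": np.nan,
                        "I_total": np.nan,
                        "P_uW_cm2": np.nan,
                        "converged": False,
                    }
                )
    df = pd.DataFrame(rows)
    # restore the caller's orderings (sigma-major, V_app-minor)
    s_order = {s: i for i, s in enumerate(sigma_list)}
    v_order = {v: i for i, v in enumerate(vapp_list)}
    df["_s"] = df["sigma"].map(s_order)
    df["_v"] = df["V_app"].map(v_order)
    df = df.sort_values(["_s", "_v"], kind="stable").drop(columns=["_s", "_v"])
    return df.reset_index(drop=True)
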