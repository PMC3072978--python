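"""Butler-Volmer electrode kinetics and the 1D cell oracle.

The secondary current distribution model closes the Laplace problem with a
current-overpotential law at each electrode.  This module holds that law,
the overpotential bookkeeping that splits the applied voltage into
equilibrium, surface (activation) and ohmic parts, the packaged
platinum/water parameter set, and a closed-form 1D facing-electrode cell
solved by scalar root finding — the independent oracle used to test the 2D
coupled solver.

Physical constants are fixed at F = 96500 C/mol and R = 8.314 J/(mol K),
the values the model parameters were stated with.

Sign conventions (one table, used everywhere):

===========  ==================================================
quantity     convention
===========  ==================================================
eta_a        V_app - phi_s(anode) - E_eq(anode); positive when driven
eta_c        -phi_s(cathode) - E_eq(cathode); negative when driven
i = bv(eta)  net anodic current density; > 0 at a driven anode
anode flux   current entering the electrolyte = +bv(eta_a)
cathode      current entering the electrolyte = +bv(eta_c) (< 0 driven)
===========  ==================================================

The cathode metal is the potential ground (phi_metal = 0); the anode metal
sits at V_app.  This choice shifts only the absolute potential level, never
fields or currents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "ButlerVolmerParams",
    "CellKinetics",
    "platinum_water",
    "bv_current",
    "bv_current_derivative",
    "bv_overpotential",
    "surface_overpotentials",
    "OneDCellSolution",
    "solve_1d_cell",
    "OverflowGuardError",
]

FARADAY = 96500.0  # C/mol
GAS_CONSTANT = 8.314  # J/(mol K)

# exponent cap for the overflow guard; a converged solution that still
# binds the cap is physically meaningless and is reported as an error
_EXP_CAP = 500.0


class OverflowGuardError(RuntimeError):
    """A converged solve relied on the clipped Butler-Volmer exponential."""


@dataclass(frozen=True)
class ButlerVolmerParams:
    """Kinetic constants of one half-reaction.

    i0: exchange current density (A/m^2); alpha_a / alpha_c: anodic and
    cathodic transfer coefficients; E_eq: standard reduction equilibrium
    potential (V); T: temperature (K).
    """

    i0: float
    alpha_a: float
    alpha_c: float
    E_eq: float
    T: float = 298.0

    def __post_init__(self) -> None:
        if self.i0 <= 0 or self.alpha_a <= 0 or self.alpha_c <= 0 or self.T <= 0:
            raise ValueError("i0, alpha_a, alpha_c and T must all be positive")


@dataclass(frozen=True)
class CellKinetics:
    """Anode and cathode half-reactions of one electrochemical cell."""

    anode: ButlerVolmerParams
    cathode: ButlerVolmerParams

    @property
    def E_cell_eq(self) -> float:
        """Cell equilibrium potential: anode minus cathode reduction
        equilibrium potentials."""
        return self.anode.E_eq - self.cathode.E_eq


def platinum_water(T: float = 298.0) -> CellKinetics:
    """Packaged parameter set: inert platinum electrodes in water.

    Anode (water oxidation to O2): E_eq = 1.23 V, i0 = 1e-8 A/cm^2
    = 1e-4 A/m^2.  Cathode (water reduction to H2): E_eq = -0.83 V,
    i0 = 10 A/cm^2 = 1e5 A/m^2.  Transfer coefficients 0.5 for both
    branches of both reactions.  The cell equilibrium potential is 2.06 V.

    Exchange current densities are stored in SI (A/m^2) but quoted above in
    the A/cm^2 unit electrochemical reference tables use, because the unit
    conversion is the single most error-prone step in reusing tabulated
    kinetics.  The sluggish oxygen-evolution anode (i0 nine orders of
    magnitude below the hydrogen cathode) is what rate-limits the cell.
    """
    return CellKinetics(
        anode=ButlerVolmerParams(i0=1e-4, alpha_a=0.5, alpha_c=0.5, E_eq=1.23, T=T),
        cathode=ButlerVolmerParams(i0=1e5, alpha_a=0.5, alpha_c=0.5, E_eq=-0.83, T=T),
    )


def _exponents(eta, p: ButlerVolmerParams):
    f = FARADAY / (GAS_CONSTANT * p.T)
    a = np.clip(p.alpha_a * f * np.asarray(eta, float), -_EXP_CAP, _EXP_CAP)
    c = np.clip(-p.alpha_c * f * np.asarray(eta, float), -_EXP_CAP, _EXP_CAP)
    return a, c


def bv_current(eta, p: ButlerVolmerParams):
    """Net current density i = i0 [exp(a_a F eta / RT) - exp(-a_c F eta / RT)].

    Exponent arguments are clipped at +/-500 as an overflow guard; solvers
    check ``exp_cap_active`` before trusting a converged answer.
    """
    if not np.all(np.isfinite(eta)):
        raise ValueError("overpotential must be finite")
    a, c = _exponents(eta, p)
    out = p.i0 * (np.exp(a) - np.exp(c))
    return float(out) if np.isscalar(eta) else out


def bv_current_derivative(eta, p: ButlerVolmerParams):
    """d(i)/d(eta); strictly positive (the polarization law is monotone)."""
    f = FARADAY / (GAS_CONSTANT * p.T)
    a, c = _exponents(eta, p)
    out = p.i0 * f * (p.alpha_a * np.exp(a) + p.alpha_c * np.exp(c))
    return float(out) if np.isscalar(eta) else out


def exp_cap_active(eta, p: ButlerVolmerParams) -> bool:
    f = FARADAY / (GAS_CONSTANT * p.T)
    e = np.asarray(eta, float)
    return bool(
        np.any(np.abs(p.alpha_a * f * e) >= _EXP_CAP)
        or np.any(np.abs(p.alpha_c * f * e) >= _EXP_CAP)
    )


def bv_overpotential(i: float, p: ButlerVolmerParams) -> float:
    """Invert the Butler-Volmer law: the eta with bv_current(eta, p) = i."""
    if i == 0.0:
        return 0.0
    f = FARADAY / (GAS_CONSTANT * p.T)
    # bracket from the Tafel estimate of the dominant branch
    mag = abs(i) / p.i0
    guess = np.log1p(mag) / (min(p.alpha_a, p.alpha_c) * f)
    hi = max(2.0 * guess, 1e-6)
    while bv_current(np.sign(i) * hi, p) * np.sign(i) < abs(i):
        hi *= 2.0
        if hi > _EXP_CAP / (min(p.alpha_a, p.alpha_c) * f):
            raise OverflowGuardError(
                "requested current density exceeds the overflow-guarded range"
            )
    lo, hi = (0.0, hi) if i > 0 else (-hi, 0.0)
    return float(brentq(lambda e: bv_current(e, p) - i, lo, hi, xtol=1e-14))


def surface_overpotentials(
    V_app: float,
    phi_s_anode: float,
    phi_s_cathode: float,
    k: CellKinetics,
) -> tuple[float, float]:
    """Surface overpotentials from the electrolyte potentials at the two
    electrode surfaces.

    With the anode metal at V_app and the cathode metal grounded:
    eta_a = V_app - phi_s_anode - E_eq(anode),
    eta_c = -phi_s_cathode - E_eq(cathode).
    These satisfy the voltage budget
    V_app = E_cell_eq + eta_a - eta_c + (phi_s_anode - phi_s_cathode)
    identically.
    """
    eta_a = V_app - phi_s_anode - k.anode.E_eq
    eta_c = -phi_s_cathode - k.cathode.E_eq
    return eta_a, eta_c


@dataclass(frozen=True)
class OneDCellSolution:
    """Uniform facing-electrode cell at a given applied voltage."""

    current_density: float  # A/m^2, positive in a driven cell
    eta_a: float
    eta_c: float
    ohmic_drop: float  # V
    no_drive: bool  # V_app at or below the open-circuit point


def solve_1d_cell(
    gap: float, sigma: float, V_app: float, k: CellKinetics
) -> OneDCellSolution:
    """Closed-form (scalar root) solution of a uniform 1D electrochemical
    cell: two facing planar electrodes a distance ``gap`` apart.

    Solves V_app = E_cell_eq + eta_a(i) - eta_c(i) + i * gap / sigma for the
    single unknown current density i, where eta_a/eta_c invert the
    Butler-Volmer laws (the cathode carries -i).  Serves as the independent
    oracle for the 2D secondary solver.
    """
    if gap <= 0 or sigma <= 0:
        raise ValueError("gap and sigma must be positive")

    def residual(i: float) -> float:
        eta_a = bv_overpotential(i, k.anode)
        eta_c = bv_overpotential(-i, k.cathode)
        return k.E_cell_eq + eta_a - eta_c + i * gap / sigma - V_app

    if residual(0.0) >= 0.0:
        # open-circuit or reverse drive: report i <= 0 explicitly
        if residual(0.0) == 0.0:
            return OneDCellSolution(0.0, 0.0, 0.0, 0.0, no_drive=True)
        hi = -1e-300
        lo = -k.anode.i0
        while residual(lo) > 0:
            lo *= 2.0
        i = brentq(residual, lo, hi, xtol=1e-300, rtol=8.9e-16)
    else:
        lo = 0.0
        hi = max(k.anode.i0, k.cathode.i0)
        while residual(hi) < 0:
            hi *= 2.0
        i = brentq(residual, lo, hi, xtol=1e-300, rtol=8.9e-16)
    eta_a = bv_overpotential(i, k.anode)
    eta_c = bv_overpotential(-i, k.cathode)
    return OneDCellSolution(
        current_density=float(i),
        eta_a=eta_a,
        eta_c=eta_c,
        ohmic_drop=float(i * gap / sigma),
        no_drive=i <= 0.0,
    )
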