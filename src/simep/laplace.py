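"""Finite-difference Laplace solver with mixed boundary conditions.

One numerical engine serves both current-distribution models: a standard
5-point stencil with non-uniform-spacing coefficients, zero-flux edges by
ghost-node reflection, Dirichlet electrodes (primary model) and linearised
flux/Robin electrodes (secondary model, where the Butler-Volmer current is
re-linearised every outer iteration).

Sign conventions, fixed once here:

* the outward normal points out of the electrolyte;
* a boundary *flux* value q is the inward normal potential gradient,
  q = -d(phi)/dn, so the current density entering the electrolyte is
  ``sigma * q`` — positive at a driving anode, negative at the cathode;
* ``boundary_current`` reports nodal densities with the same sign
  (positive = current entering the electrolyte).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Grid2D

__all__ = [
    "Dirichlet",
    "ZeroFlux",
    "Flux",
    "PotentialField",
    "ElectricField",
    "BoundaryCurrent",
    "solve_laplace",
    "electric_field",
    "boundary_current",
    "SingularSystemError",
]


class SingularSystemError(RuntimeError):
    """The discrete system does not determine the potential level (e.g. an
    all-flux problem) or the linear solve failed to converge."""


@dataclass(frozen=True)
class Dirichlet:
    """Prescribed potential; scalar or one value per segment node."""

    value: float | np.ndarray


@dataclass(frozen=True)
class ZeroFlux:
    """Insulating / symmetry boundary: d(phi)/dn = 0."""


@dataclass(frozen=True)
class Flux:
    """Prescribed (optionally Robin-linearised) inward gradient flux.

    The effective flux at a segment node is ``value + slope * phi`` where
    phi is the potential at that node.  ``slope`` supports Newton
    linearisation of nonlinear kinetic boundary conditions; plain prescribed
    flux has slope = 0.
    """

    value: float | np.ndarray
    slope: float | np.ndarray = 0.0


@dataclass(frozen=True)
class PotentialField:
    grid: Grid2D
    values: np.ndarray  # (ny, nx)

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")


@dataclass(frozen=True)
class ElectricField:
    grid: Grid2D
    ex: np.ndarray
    ey: np.ndarray
    magnitude: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.magnitude is None:
            object.__setattr__(
                self, "magnitude", np.hypot(self.ex, self.ey)
            )


@dataclass(frozen=True)
class BoundaryCurrent:
    segment: str
    coords: np.ndarray  # node positions along the segment
    density: np.ndarray  # A/m^2, positive = entering the electrolyte
    total: float  # A per metre of depth (trapezoid over the segment)


# ---------------------------------------------------------------------------
# assembly


def _second_derivative_coeffs(h: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Non-uniform 3-point second-derivative weights (cW, cP, cE) for
    interior nodes, given spacings h[i] = x[i+1]-x[i]."""
    hw = h[:-1]
    he = h[1:]
    cw = 2.0 / (hw * (hw + he))
    ce = 2.0 / (he * (hw + he))
    cp = -2.0 / (hw * he)
    return cw, cp, ce


def solve_laplace(
    grid: Grid2D,
    bc: dict[str, Dirichlet | ZeroFlux | Flux],
    rtol: float = 1e-10,
) -> PotentialField:
    """Solve the discrete Laplace problem on ``grid``.

    ``bc`` maps every segment name of the grid to a boundary condition.
    Unlabelled conditions or unknown segment names raise ``KeyError``.
    The sparse system is solved by direct factorisation; the relative
    residual of the assembled equations is checked against ``rtol``.
    """
    for name in grid.segments:
        if name not in bc:
            raise KeyError(f"no boundary condition supplied for segment '{name}'")
    for name in bc:
        if name not in grid.segments:
            raise KeyError(f"unknown boundary segment '{name}'")

    x, y = grid.x, grid.y
    nx, ny = grid.nx, grid.ny
    n = nx * ny
    hx = np.diff(x)
    hy = np.diff(y)

    # per-node stencil coefficient arrays (ny, nx)
    CW = np.zeros((ny, nx))
    CE = np.zeros((ny, nx))
    CS = np.zeros((ny, nx))
    CN = np.zeros((ny, nx))
    CP = np.zeros((ny, nx))
    RHS = np.zeros((ny, nx))

    # x-direction: interior columns get the non-uniform 3-point stencil,
    # the two edge columns get ghost reflection (zero tangential flux at
    # the side walls; Dirichlet rows are overwritten later anyway).
    cw, cp, ce = _second_derivative_coeffs(hx)
    CW[:, 1:-1] += cw
    CP[:, 1:-1] += cp
    CE[:, 1:-1] += ce
    CE[:, 0] += 2.0 / hx[0] ** 2
    CP[:, 0] += -2.0 / hx[0] ** 2
    CW[:, -1] += 2.0 / hx[-1] ** 2
    CP[:, -1] += -2.0 / hx[-1] ** 2

    # y-direction likewise
    cs, cp_y, cn = _second_derivative_coeffs(hy)
    CS[1:-1, :] += cs[:, None]
    CP[1:-1, :] += cp_y[:, None]
    CN[1:-1, :] += cn[:, None]
    CN[0, :] += 2.0 / hy[0] ** 2
    CP[0, :] += -2.0 / hy[0] ** 2
    CS[-1, :] += 2.0 / hy[-1] ** 2
    CP[-1, :] += -2.0 / hy[-1] ** 2

    dirichlet_mask = np.zeros((ny, nx), dtype=bool)
    dirichlet_vals = np.zeros((ny, nx))
    any_anchor = False

    def _edge_indices(seg):
        idx = np.arange(seg.lo, seg.hi + 1)
        if seg.edge == "bottom":
            return np.zeros_like(idx), idx
        if seg.edge == "top":
            return np.full_like(idx, ny - 1), idx
        if seg.edge == "left":
            return idx, np.zeros_like(idx)
        if seg.edge == "right":
            return idx, np.full_like(idx, nx - 1)
        raise ValueError(f"unknown edge '{seg.edge}'")

    for name, cond in bc.items():
        seg = grid.segments[name]
        if seg.n_nodes == 0:
            continue
        ii, jj = _edge_indices(seg)
        if isinstance(cond, Dirichlet):
            vals = np.broadcast_to(np.asarray(cond.value, float), ii.shape)
            dirichlet_mask[ii, jj] = True
            dirichlet_vals[ii, jj] = vals
            any_anchor = True
        elif isinstance(cond, ZeroFlux):
            pass  # ghost reflection already built into the edge stencils
        elif isinstance(cond, Flux):
            q = np.broadcast_to(np.asarray(cond.value, float), ii.shape)
            s = np.broadcast_to(np.asarray(cond.slope, float), ii.shape)
            # ghost elimination adds 2*(q + s*phi)/h_edge to the Laplacian row
            if seg.edge == "bottom":
                h_edge = hy[0]
            elif seg.edge == "top":
                h_edge = hy[-1]
            elif seg.edge == "left":
                h_edge = hx[0]
            else:
                h_edge = hx[-1]
            CP[ii, jj] += 2.0 * s / h_edge
            RHS[ii, jj] -= 2.0 * q / h_edge
            if np.any(s != 0):
                any_anchor = True
        else:
            raise TypeError(f"unsupported boundary condition {cond!r}")

    if not any_anchor:
        raise SingularSystemError(
            "no Dirichlet or Robin condition fixes the potential level"
        )

    # scale every non-Dirichlet row by its dual-cell area (finite-volume
    # weighting): this symmetrizes the operator and equilibrates the huge
    # dynamic range the graded meshes otherwise produce, which is what
    # limits the attainable accuracy of the direct solve
    wx = np.empty(nx)
    wx[1:-1] = 0.5 * (hx[:-1] + hx[1:])
    wx[0] = 0.5 * hx[0]
    wx[-1] = 0.5 * hx[-1]
    wy = np.empty(ny)
    wy[1:-1] = 0.5 * (hy[:-1] + hy[1:])
    wy[0] = 0.5 * hy[0]
    wy[-1] = 0.5 * hy[-1]
    W = wy[:, None] * wx[None, :]
    for arr in (CW, CE, CS, CN, CP, RHS):
        arr *= W

    # Dirichlet rows -> identity
    CW[dirichlet_mask] = 0.0
    CE[dirichlet_mask] = 0.0
    CS[dirichlet_mask] = 0.0
    CN[dirichlet_mask] = 0.0
    CP[dirichlet_mask] = 1.0
    RHS[dirichlet_mask] = dirichlet_vals[dirichlet_mask]

    k = np.arange(n).reshape(ny, nx)
    rows, cols, vals = [], [], []

    def _add(coef: np.ndarray, neighbour_offset: tuple[int, int]) -> None:
        di, dj = neighbour_offset
        mask = coef != 0.0
        ii, jj = np.nonzero(mask)
        rows.append(k[ii, jj])
        cols.append(k[ii + di, jj + dj])
        vals.append(coef[ii, jj])

    _add(CP, (0, 0))
    _add(CW, (0, -1))
    _add(CE, (0, 1))
    _add(CS, (-1, 0))
    _add(CN, (1, 0))

    A = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    b = RHS.ravel()
    try:
        lu = spla.splu(A)
    except RuntimeError as exc:  # singular factorization
        raise SingularSystemError(f"sparse factorization failed: {exc}") from exc
    phi = lu.solve(b)
    if not np.all(np.isfinite(phi)):
        raise SingularSystemError("linear solve returned non-finite values")
    scale = max(float(np.abs(A).sum(axis=1).max()) * float(np.abs(phi).max()), 1e-300)
    resid = float(np.abs(A @ phi - b).max()) / scale
    if resid > rtol:
        raise SingularSystemError(
            f"linear solve did not converge: relative residual {resid:.3e}"
        )
    return PotentialField(grid=grid, values=phi.reshape(ny, nx))


# ---------------------------------------------------------------------------
# derived quantities


def electric_field(phi: PotentialField) -> ElectricField:
    """E = -grad(phi): central differences at interior nodes, one-sided
    second-order differences at boundary nodes (non-uniform aware)."""
    dphi_dy, dphi_dx = np.gradient(
        phi.values, phi.grid.y, phi.grid.x, edge_order=2
    )
    return ElectricField(grid=phi.grid, ex=-dphi_dx, ey=-dphi_dy)


def _normal_gradient_bottom(phi: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Second-order one-sided d(phi)/dy at y = y[0] for every column."""
    h1 = y[1] - y[0]
    h2 = y[2] - y[1]
    c0 = -(2 * h1 + h2) / (h1 * (h1 + h2))
    c1 = (h1 + h2) / (h1 * h2)
    c2 = -h1 / (h2 * (h1 + h2))
    return c0 * phi[0, :] + c1 * phi[1, :] + c2 * phi[2, :]


def boundary_current(
    phi: PotentialField, sigma: float, segment: str
) -> BoundaryCurrent:
    """Normal current density and trapezoid-integrated current on a bottom
    boundary segment.

    Density is ``-sigma * d(phi)/dn`` with the outward normal, i.e. positive
    where current enters the electrolyte; at the bottom edge this equals
    ``-sigma * d(phi)/dy``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    seg = phi.grid.segments[segment]
    if seg.n_nodes == 0 or (seg.span is not None and seg.span_length == 0.0):
        raise ValueError(f"segment '{segment}' has zero length")
    if seg.edge != "bottom":
        raise ValueError("boundary_current supports bottom-edge segments")
    grad = _normal_gradient_bottom(phi.values, phi.grid.y)
    density = -sigma * grad[seg.lo : seg.hi + 1]
    coords = phi.grid.x[seg.lo : seg.hi + 1]
    total = float(np.trapezoid(density, coords))
    return BoundaryCurrent(segment=segment, coords=coords, density=density, total=total)
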