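import numpy as np
import pytest

from simep.geometry import ChannelGeometryND, build_channel_grid
from simep.laplace import (
    Dirichlet,
    Flux,
    SingularSystemError,
    ZeroFlux,
    boundary_current,
    electric_field,
    solve_laplace,
)

from conftest import make_rect_grid


def dense_reference_solve(x, y, bc_bottom, bc_top, q_top=None, s_top=None):
    """Independent brute-force dense assembly of the same stencil equations
    (plain nested loops; ghost reflection at zero-flux side walls)."""
    nx, ny = len(x), len(y)
    n = nx * ny
    A = np.zeros((n, n))
    b = np.zeros(n)

    def k(i, j):
        return i * nx + j

    for i in range(ny):
        for j in range(nx):
            row = k(i, j)
            if i == 0 and bc_bottom is not None:
                A[row, row] = 1.0
                b[row] = bc_bottom[j]
                continue
            if i == ny - 1 and bc_top is not None:
                A[row, row] = 1.0
                b[row] = bc_top[j]
                continue
            # x-direction second derivative (ghost reflection at side walls)
            if j == 0:
                h = x[1] - x[0]
                A[row, k(i, 1)] += 2 / h**2
                A[row, row] += -2 / h**2
            elif j == nx - 1:
                h = x[-1] - x[-2]
                A[row, k(i, nx - 2)] += 2 / h**2
                A[row, row] += -2 / h**2
            else:
                hw, he = x[j] - x[j - 1], x[j + 1] - x[j]
                A[row, k(i, j - 1)] += 2 / (hw * (hw + he))
                A[row, k(i, j + 1)] += 2 / (he * (hw + he))
                A[row, row] += -2 / (hw * he)
            # y-direction
            if i == 0:
                h = y[1] - y[0]
                A[row, k(1, j)] += 2 / h**2
                A[row, row] += -2 / h**2
            elif i == ny - 1:
                h = y[-1] - y[-2]
                A[row, k(ny - 2, j)] += 2 / h**2
                A[row, row] += -2 / h**2
                if q_top is not None:
                    qj = q_top[j] + (0.0 if s_top is None else 0.0)
                    A[row, row] += 2 * (s_top[j] if s_top is not None else 0.0) / h
                    b[row] += -2 * qj / h
            else:
                hs, hn = y[i] - y[i - 1], y[i + 1] - y[i]
                A[row, k(i - 1, j)] += 2 / (hs * (hs + hn))
                A[row, k(i + 1, j)] += 2 / (hn * (hs + hn))
                A[row, row] += -2 / (hs * hn)
    return np.linalg.solve(A, b).reshape(ny, nx)


class TestSolveLaplace:
    def test_linear_ramp_is_exact(self):
        grid = make_rect_grid(np.linspace(0, 1, 9), np.linspace(0, 1, 7))
        phi = solve_laplace(grid, {
            "bottom": Dirichlet(0.0),
            "top": Dirichlet(1.0),
            "left": ZeroFlux(),
            "right": ZeroFlux(),
        })
        expect = grid.y[:, None] * np.ones_like(grid.x)[None, :]
        assert phi.values == pytest.approx(expect, abs=1e-12)

    def test_dense_oracle_equivalence_dirichlet(self):
        # non-uniform 7x6 grid, Dirichlet bottom/top, zero-flux sides
        x = np.array([0.0, 0.1, 0.25, 0.45, 0.7, 0.85, 1.0])
        y = np.array([0.0, 0.15, 0.4, 0.6, 0.9, 1.0])
        grid = make_rect_grid(x, y)
        bottom = np.linspace(1.0, 0.0, x.size)
        top = np.full(x.size, 0.25)
        phi = solve_laplace(grid, {
            "bottom": Dirichlet(bottom),
            "top": Dirichlet(top),
            "left": ZeroFlux(),
            "right": ZeroFlux(),
        })
        ref = dense_reference_solve(x, y, bottom, top)
        assert phi.values == pytest.approx(ref, abs=1e-10)

    def test_dense_oracle_equivalence_robin_flux(self):
        # prescribed Robin flux on the top edge instead of Dirichlet
        x = np.linspace(0.0, 1.0, 6)
        y = np.array([0.0, 0.2, 0.45, 0.75, 1.0])
        grid = make_rect_grid(x, y)
        bottom = np.zeros(x.size)
        q = np.linspace(0.5, 1.5, x.size)
        s = np.full(x.size, -0.7)
        phi = solve_laplace(grid, {
            "bottom": Dirichlet(bottom),
            "top": Flux(value=q, slope=s),
            "left": ZeroFlux(),
            "right": ZeroFlux(),
        })
        ref = dense_reference_solve(x, y, bottom, None, q_top=q, s_top=s)
        assert phi.values == pytest.approx(ref, abs=1e-10)

    def test_discrete_maximum_principle(self):
        grid = build_channel_grid(ChannelGeometryND(G=0.5, epsilon=0.4), n_base=16)
        phi = solve_laplace(grid, {
            "anode": Dirichlet(1.0), "cathode": Dirichlet(0.0),
            "insulator": ZeroFlux(), "left": ZeroFlux(),
            "right": ZeroFlux(), "top": ZeroFlux(),
        })
        assert phi.values.min() >= -1e-12
        assert phi.values.max() <= 1.0 + 1e-12

    def test_all_flux_problem_is_rejected(self):
        grid = make_rect_grid(np.linspace(0, 1, 5), np.linspace(0, 1, 5))
        with pytest.raises(SingularSystemError):
            solve_laplace(grid, {
                "bottom": ZeroFlux(), "top": ZeroFlux(),
                "left": ZeroFlux(), "right": ZeroFlux(),
            })

    def test_missing_boundary_condition_is_an_error(self):
        grid = make_rect_grid(np.linspace(0, 1, 5), np.linspace(0, 1, 5))
        with pytest.raises(KeyError):
            solve_laplace(grid, {"bottom": Dirichlet(0.0)})

    def test_second_order_convergence_manufactured_solution(self):
        # phi = sin(pi x) sinh(pi y) is harmonic; on x in [0.5, 1.5] its
        # x-derivative vanishes at both walls, so the zero-flux sides are
        # exact and the bottom/top carry the matching Dirichlet data
        def solve_at(n):
            x = np.linspace(0.5, 1.5, n + 1)
            y = np.linspace(0.0, 1.0, n + 1)
            grid = make_rect_grid(x, y)
            exact = np.sin(np.pi * x)[None, :] * np.sinh(np.pi * y)[:, None]
            phi = solve_laplace(grid, {
                "bottom": Dirichlet(exact[0]),
                "top": Dirichlet(exact[-1]),
                "left": ZeroFlux(),
                "right": ZeroFlux(),
            })
            return np.abs(phi.values - exact).max()

        e1, e2 = solve_at(16), solve_at(32)
        assert 3.0 < e1 / e2 < 5.5  # ~4x per halving = second order


class TestElectricField:
    def test_gradient_of_linear_ramp(self):
        grid = make_rect_grid(np.linspace(0, 1, 7), np.linspace(0, 1, 5),
                              corner_owner="left_right")
        phi = solve_laplace(grid, {
            "bottom": ZeroFlux(), "top": ZeroFlux(),
            "left": Dirichlet(1.0), "right": Dirichlet(0.0),
        })
        ef = electric_field(phi)
        assert ef.ex == pytest.approx(np.ones(grid.shape), abs=1e-10)
        assert ef.ey == pytest.approx(np.zeros(grid.shape), abs=1e-10)
        assert ef.magnitude == pytest.approx(np.ones(grid.shape), abs=1e-10)

    def test_central_differences_exact_for_quadratic(self):
        from simep.laplace import PotentialField

        x = np.linspace(0, 1, 9)
        y = np.linspace(0, 1, 9)
        grid = make_rect_grid(x, y)
        phi = PotentialField(grid=grid, values=np.broadcast_to(x**2, grid.shape).copy())
        ef = electric_field(phi)
        assert ef.ex[:, 1:-1] == pytest.approx(
            np.broadcast_to(-2 * x[1:-1], (grid.ny, grid.nx - 2)), abs=1e-12
        )


class TestBoundaryCurrent:
    def _ramp_cell(self, sigma, V=1.0, G=0.5):
        # vertical ramp phi = V y / G; side walls carry the matching
        # Dirichlet data so the ramp is an exact discrete solution
        grid = build_channel_grid(ChannelGeometryND(G=G, epsilon=0.5), n_base=16)
        side = V * grid.segment_coords("left") / G
        phi = solve_laplace(grid, {
            "anode": Dirichlet(0.0), "cathode": Dirichlet(0.0),
            "insulator": Dirichlet(0.0),
            "left": Dirichlet(side), "right": Dirichlet(side),
            "top": Dirichlet(V),
        })
        return grid, phi

    def test_ohms_law_on_1d_ramp(self):
        sigma, V, G = 2.0, 1.0, 0.5
        grid, phi = self._ramp_cell(sigma, V, G)
        cur = boundary_current(phi, sigma, "anode")
        # current leaves through the bottom: density = -sigma * V/G
        assert cur.density == pytest.approx(
            np.full(cur.density.size, -sigma * V / G), rel=1e-9
        )
        assert cur.total == pytest.approx(-sigma * V / G * 0.25, rel=1e-9)

    def test_density_linear_in_sigma(self):
        grid, phi = self._ramp_cell(1.0)
        c1 = boundary_current(phi, 1.0, "anode")
        c2 = boundary_current(phi, 2.0, "anode")
        assert c2.density == pytest.approx(2.0 * c1.density, rel=1e-12)
        assert c2.total == pytest.approx(2.0 * c1.total, rel=1e-12)

    def test_zero_length_segment_rejected(self):
        grid = build_channel_grid(ChannelGeometryND(G=1.0, epsilon=0.0), n_base=16)
        phi = solve_laplace(grid, {
            "anode": Dirichlet(1.0), "cathode": Dirichlet(0.0),
            "insulator": ZeroFlux(), "left": ZeroFlux(),
            "right": ZeroFlux(), "top": ZeroFlux(),
        })
        with pytest.raises(ValueError):
            boundary_current(phi, 1.0, "insulator")

    def test_sigma_must_be_positive(self):
        grid, phi = self._ramp_cell(1.0)
        with pytest.raises(ValueError):
            boundary_current(phi, 0.0, "anode")
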