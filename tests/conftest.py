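import numpy as np
import pytest

from simep.geometry import BoundarySegment, Grid2D, SegmentLabel


def make_rect_grid(x, y, corner_owner: str = "bottom_top") -> Grid2D:
    """Rectangle with one segment per edge, for solver tests that need
    arbitrary boundary conditions.  ``corner_owner`` says which pair of
    edges owns the corner nodes (give them to the Dirichlet edges)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    if corner_owner == "bottom_top":
        bt = (0, nx - 1)
        lr = (1, ny - 2)
    else:
        bt = (1, nx - 2)
        lr = (0, ny - 1)
    segments = {
        "bottom": BoundarySegment("bottom", "bottom", bt[0], bt[1], SegmentLabel.ZERO_FLUX),
        "top": BoundarySegment("top", "top", bt[0], bt[1], SegmentLabel.ZERO_FLUX),
        "left": BoundarySegment("left", "left", lr[0], lr[1], SegmentLabel.ZERO_FLUX),
        "right": BoundarySegment("right", "right", lr[0], lr[1], SegmentLabel.ZERO_FLUX),
    }
    return Grid2D(x=x, y=y, segments=segments)


@pytest.fixture(scope="session")
def secondary_reference_solution():
    """One moderately resolved kinetic-cell solve shared by the invariant
    tests (sigma = 0.005 S/m, 2.9 V)."""
    from simep import SecondaryCellSpec, solve_secondary

    return solve_secondary(
        SecondaryCellSpec(sigma=0.005, V_app=2.9), n_base=48, grading=2.5
    )
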