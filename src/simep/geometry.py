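"""Structured rectangular grids for the micro-electroporation models.

Both the non-dimensional channel model and the dimensional secondary-cell
model share the same domain layout: a rectangle whose bottom edge is split
left-to-right into anode / insulator / cathode, with the remaining three
edges impermeable (zero normal current).  The electric field is singular at
the two insulator-electrode junctions, so the mesh is graded toward them.

Grading is realised as a fixed power-law stretching map applied to a uniform
parameter grid.  Because the map is independent of the node count, doubling
the number of intervals refines the grid *nested*: every coarse node is also
a fine node, which lets convergence studies compare solutions node-by-node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "SegmentLabel",
    "ChannelGeometryND",
    "SecondaryCellGeometry",
    "BoundarySegment",
    "Grid2D",
    "build_channel_grid",
    "build_secondary_grid",
]


class SegmentLabel(str, Enum):
    """Physical role of a boundary segment."""

    ANODE = "ANODE"
    CATHODE = "CATHODE"
    INSULATOR = "INSULATOR"
    ZERO_FLUX = "ZERO_FLUX"


@dataclass(frozen=True)
class ChannelGeometryND:
    """Non-dimensional channel geometry.

    Parameters
    ----------
    G:
        Aspect ratio, half channel height over active electrode length
        (h/l).  Small G is the shallow, high-field regime.
    epsilon:
        Relative insulator thickness, insulator width over active electrode
        length (d/l).  ``epsilon = 0`` encodes the singular zero-width
        insulator limit.
    """

    G: float
    epsilon: float

    def __post_init__(self) -> None:
        if not self.G > 0:
            raise ValueError(f"aspect ratio G must be positive, got {self.G}")
        if not (0 <= self.epsilon < 1):
            raise ValueError(
                f"relative insulator thickness must satisfy 0 <= epsilon < 1, "
                f"got {self.epsilon}"
            )


@dataclass(frozen=True)
class SecondaryCellGeometry:
    """Dimensional cell geometry in metres (defaults: 10 um x 20 um domain
    with a 100 nm insulator centred on the bottom edge)."""

    length: float = 10e-6
    insulator_thickness: float = 100e-9
    height: float = 20e-6

    def __post_init__(self) -> None:
        if not (0 < self.insulator_thickness < self.length):
            raise ValueError(
                "insulator thickness must lie strictly between 0 and the "
                f"domain length, got {self.insulator_thickness} vs {self.length}"
            )
        if not self.height > 0:
            raise ValueError(f"height must be positive, got {self.height}")


@dataclass(frozen=True)
class BoundarySegment:
    """A labelled run of nodes along one edge of the rectangle.

    ``lo``/``hi`` are inclusive node indices along the edge (x-index for
    bottom/top, y-index for left/right).  An empty segment (zero-width
    insulator) has ``hi < lo``.  ``span`` is the geometric extent of the
    segment along its edge; for the bottom partition the anode and cathode
    spans are closed intervals and the insulator span is their open
    complement, so junction nodes are owned by the electrodes while the
    three spans still tile the edge exactly.
    """

    name: str
    edge: str  # 'bottom' | 'top' | 'left' | 'right'
    lo: int
    hi: int
    label: SegmentLabel
    span: tuple[float, float] | None = None

    @property
    def n_nodes(self) -> int:
        return max(0, self.hi - self.lo + 1)

    @property
    def span_length(self) -> float:
        return 0.0 if self.span is None else self.span[1] - self.span[0]


@dataclass(frozen=True)
class Grid2D:
    """Tensor-product rectangular grid with labelled boundary segments."""

    x: np.ndarray
    y: np.ndarray
    segments: dict[str, BoundarySegment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.x) <= 0) or np.any(np.diff(self.y) <= 0):
            raise ValueError("grid coordinates must be strictly increasing")

    @property
    def nx(self) -> int:
        return self.x.size

    @property
    def ny(self) -> int:
        return self.y.size

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx) — field arrays are indexed [y, x]."""
        return (self.ny, self.nx)

    def segment_coords(self, name: str) -> np.ndarray:
        """Coordinates of the nodes of a named segment along its edge."""
        seg = self.segments[name]
        coords = self.x if seg.edge in ("bottom", "top") else self.y
        return coords[seg.lo : seg.hi + 1]

    def segment_length(self, name: str) -> float:
        c = self.segment_coords(name)
        return float(c[-1] - c[0]) if c.size >= 2 else 0.0


# ---------------------------------------------------------------------------
# stretching maps


def _stretch_to_end(t: np.ndarray, p: float) -> np.ndarray:
    """Cluster points toward t=1; p=1 is uniform."""
    return 1.0 - (1.0 - t) ** p


def _stretch_to_start(t: np.ndarray, p: float) -> np.ndarray:
    return t**p


def _stretch_both_ends(t: np.ndarray, p: float) -> np.ndarray:
    """Symmetric clustering toward both ends; p=1 is uniform."""
    tp = t**p
    return tp / (tp + (1.0 - t) ** p)


def _segment_nodes(a: float, b: float, n: int, mapper, p: float) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n + 1)
    s = mapper(t, p)
    # guard against round-off at the ends
    s[0], s[-1] = 0.0, 1.0
    return a + (b - a) * s


def _insulator_intervals(n_base: int) -> int:
    # even, so a node always sits at the insulator midpoint (the probe line)
    return 2 * max(1, n_base // 4)


def _build_grid(
    xa: float,
    xb: float,
    length: float,
    height: float,
    n_base: int,
    grading: float,
) -> Grid2D:
    """Shared builder: bottom edge [0, length] split at xa (anode/insulator
    junction) and xb (insulator/cathode junction); height up to ``height``."""
    if n_base < 8:
        raise ValueError(f"n_base must be at least 8, got {n_base}")
    if grading < 1:
        raise ValueError(f"grading exponent must be >= 1, got {grading}")

    n_e = n_base  # intervals per electrode
    zero_width = xb <= xa
    n_i = 0 if zero_width else _insulator_intervals(n_base)

    anode_x = _segment_nodes(0.0, xa, n_e, _stretch_to_end, grading)
    cathode_x = _segment_nodes(xb, length, n_e, _stretch_to_start, grading)
    if zero_width:
        x = np.concatenate([anode_x, cathode_x[1:]])
    else:
        ins_x = _segment_nodes(xa, xb, n_i, _stretch_both_ends, grading)
        x = np.concatenate([anode_x, ins_x[1:], cathode_x[1:]])

    if anode_x.size < 2 or cathode_x.size < 2:
        raise ValueError("electrode segments must contain at least 2 nodes")

    y = _segment_nodes(0.0, height, n_base, _stretch_to_start, grading)

    # corner precedence: electrode labels win over ZERO_FLUX, so the bottom
    # corners belong to the electrodes and the side walls start at y-index 1.
    ja = n_e  # node index of the anode/insulator junction
    jc = ja + n_i  # node index of the insulator/cathode junction
    nx, ny = x.size, y.size
    # at zero insulator width the single junction node is owned by the anode;
    # the primary solver overrides its Dirichlet value with the mean of the
    # two electrode potentials (the potential is discontinuous there).
    cathode_lo = jc if not zero_width else jc + 1
    segments = {
        "anode": BoundarySegment(
            "anode", "bottom", 0, ja, SegmentLabel.ANODE, span=(0.0, xa)
        ),
        "insulator": BoundarySegment(
            "insulator", "bottom", ja + 1, jc - 1, SegmentLabel.INSULATOR,
            span=(xa, xb if not zero_width else xa),
        ),
        "cathode": BoundarySegment(
            "cathode", "bottom", cathode_lo, nx - 1, SegmentLabel.CATHODE,
            span=(xb if not zero_width else xa, length),
        ),
        "left": BoundarySegment("left", "left", 1, ny - 1, SegmentLabel.ZERO_FLUX),
        "right": BoundarySegment("right", "right", 1, ny - 1, SegmentLabel.ZERO_FLUX),
        "top": BoundarySegment("top", "top", 1, nx - 2, SegmentLabel.ZERO_FLUX),
    }
    return Grid2D(x=x, y=y, segments=segments)


def build_channel_grid(
    geom: ChannelGeometryND, n_base: int = 64, grading: float = 2.0
) -> Grid2D:
    """Grid for the non-dimensional channel model.

    Both coordinates are scaled by the active electrode length, so the bottom
    edge has unit length (anode on [0,(1-eps)/2], insulator, cathode on
    [(1+eps)/2,1]) and the top edge sits at y = G, which is the channel
    mid-plane (Y = 1 in the height-scaled convention).
    """
    eps = geom.epsilon
    xa = (1.0 - eps) / 2.0
    xb = (1.0 + eps) / 2.0
    if eps > 0:
        # reject eps so close to 1 that an electrode segment degenerates
        if xa <= np.spacing(1.0) * 4:
            raise ValueError(f"epsilon={eps} leaves no room for the electrodes")
    return _build_grid(xa, xb, 1.0, geom.G, n_base, grading)


def build_secondary_grid(
    geom: SecondaryCellGeometry, n_base: int = 64, grading: float = 2.0
) -> Grid2D:
    """Grid for the dimensional secondary-cell model (metres), insulator
    centred at x = length/2."""
    xa = (geom.length - geom.insulator_thickness) / 2.0
    xb = (geom.length + geom.insulator_thickness) / 2.0
    return _build_grid(xa, xb, geom.length, geom.height, n_base, grading)
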