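"""Excursion masks, sub-pixel zero boundaries and their combinatorial partition.

The conjunction estimate is the excursion set at level zero of the pointwise
minimum of the standardised condition maps.  Its lattice boundary is the set
of 4-neighbour edges whose endpoint values straddle zero; each crossing is
located by linear interpolation along the edge.  Crossings are then
partitioned by which subset of conditions attains the minimum there (within
a tolerance), mirroring the decomposition of the boundary into segments
contributed by each combination of conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import GridSpec, ScalarField, as_values

__all__ = [
    "ExcursionMask",
    "BoundaryPoint",
    "BoundarySegmentSet",
    "min_standardised_field",
    "excursion_mask",
    "extract_zero_boundary",
    "partition_boundary",
    "interpolate_at_boundary",
    "boundary_edge_arrays",
]


@dataclass(frozen=True)
class ExcursionMask:
    """Boolean lattice mask of an excursion set (field >= level)."""

    inside: np.ndarray
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.inside, dtype=bool)
        object.__setattr__(self, "inside", m)
        grid = self.grid if self.grid is not None else GridSpec(m.shape)
        if tuple(grid.shape) != m.shape:
            raise ValueError("grid shape does not match mask shape")
        object.__setattr__(self, "grid", grid)

    def issubset(self, other: "ExcursionMask | np.ndarray") -> bool:
        o = other.inside if isinstance(other, ExcursionMask) else np.asarray(other, dtype=bool)
        return bool(np.all(o | ~self.inside))

    def intersection(self, other: "ExcursionMask") -> "ExcursionMask":
        return ExcursionMask(self.inside & other.inside, self.grid)

    def union(self, other: "ExcursionMask") -> "ExcursionMask":
        return ExcursionMask(self.inside | other.inside, self.grid)

    def complement(self) -> "ExcursionMask":
        return ExcursionMask(~self.inside, self.grid)

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExcursionMask):
            return NotImplemented
        return self.inside.shape == other.inside.shape and bool(np.all(self.inside == other.inside))


@dataclass(frozen=True)
class BoundaryPoint:
    """A sub-pixel zero crossing on a 4-neighbour lattice edge.

    ``p`` is the inside endpoint (field value >= 0), ``q`` the outside
    endpoint (value < 0) and ``w = f(p) / (f(p) - f(q))`` in [0, 1] places
    the interpolated zero at ``p + w * (q - p)``.
    """

    p: tuple[int, ...]
    q: tuple[int, ...]
    w: float

    @property
    def location(self) -> np.ndarray:
        p = np.asarray(self.p, dtype=np.float64)
        q = np.asarray(self.q, dtype=np.float64)
        return p + self.w * (q - p)


def min_standardised_field(fields: list[ScalarField | np.ndarray]) -> ScalarField:
    """Pointwise minimum across condition maps (symmetric in the input order)."""
    if len(fields) == 0:
        raise ValueError("need at least one field")
    values = [as_values(f) for f in fields]
    shape = values[0].shape
    for v in values[1:]:
        if v.shape != shape:
            raise ValueError("all fields must share a grid")
    return ScalarField(np.minimum.reduce(values))


def excursion_mask(fld: ScalarField | np.ndarray, level: float = 0.0) -> ExcursionMask:
    """Mask of lattice points where the field is at or above ``level``.

    Exact hits count as inside (the excursion sets are closed).
    """
    return ExcursionMask(as_values(fld) >= level)


def _crossings(values: np.ndarray):
    """Yield (p_index_array, q_index_array, w_array) over all 4-neighbour edges."""
    ndim = values.ndim
    inside = values >= 0
    for axis in range(ndim):
        lo = tuple(slice(0, -1) if ax == axis else slice(None) for ax in range(ndim))
        hi = tuple(slice(1, None) if ax == axis else slice(None) for ax in range(ndim))
        f0, f1 = values[lo], values[hi]
        in0, in1 = inside[lo], inside[hi]
        step = np.zeros(ndim, dtype=np.intp)
        step[axis] = 1
        # inside at the lower endpoint, outside at the upper
        idx = np.argwhere(in0 & ~in1)
        if idx.size:
            a, b = f0[tuple(idx.T)], f1[tuple(idx.T)]
            yield idx, idx + step, a / (a - b)
        # inside at the upper endpoint, outside at the lower
        idx = np.argwhere(in1 & ~in0)
        if idx.size:
            a, b = f1[tuple(idx.T)], f0[tuple(idx.T)]
            yield idx + step, idx, a / (a - b)


def extract_zero_boundary(fld: ScalarField | np.ndarray) -> list[BoundaryPoint]:
    """Sub-pixel zero crossings of a field along 4-neighbour lattice edges.

    For every edge whose endpoint values straddle zero (``>= 0`` versus
    ``< 0``) the linearly interpolated crossing is emitted.  A pixel with
    value exactly zero next to a negative neighbour yields a crossing with
    ``w = 0`` at the pixel itself.  The list may be empty.
    """
    values = as_values(fld)
    points: list[BoundaryPoint] = []
    for p_idx, q_idx, w in _crossings(values):
        points.extend(
            BoundaryPoint(tuple(int(c) for c in p), tuple(int(c) for c in q), float(wi))
            for p, q, wi in zip(p_idx, q_idx, w)
        )
    return points


def boundary_edge_arrays(points: list[BoundaryPoint]):
    """Vectorised view of a boundary point list: (P, Q, w) index/weight arrays."""
    if len(points) == 0:
        ndim = 2
        return (
            np.empty((0, ndim), dtype=np.intp),
            np.empty((0, ndim), dtype=np.intp),
            np.empty(0, dtype=np.float64),
        )
    p = np.asarray([pt.p for pt in points], dtype=np.intp)
    q = np.asarray([pt.q for pt in points], dtype=np.intp)
    w = np.asarray([pt.w for pt in points], dtype=np.float64)
    return p, q, w


def interpolate_at_boundary(fld: ScalarField | np.ndarray, points: list[BoundaryPoint]) -> np.ndarray:
    """Linear interpolation of a field (or stack of fields) at boundary points.

    ``fld`` may also be an array whose *trailing* axes match the grid, e.g. a
    residual stack of shape ``(n, *grid)``; interpolation is applied along
    each point's lattice edge for every leading layer, returning shape
    ``(..., n_points)``.
    """
    values = np.asarray(fld.values if isinstance(fld, ScalarField) else fld)
    p, q, w = boundary_edge_arrays(points)
    if len(points) == 0:
        return np.empty(values.shape[: max(values.ndim - 2, 0)] + (0,), dtype=np.float64)
    ndim = p.shape[1]
    vp = values[(Ellipsis,) + tuple(p[:, d] for d in range(ndim))]
    vq = values[(Ellipsis,) + tuple(q[:, d] for d in range(ndim))]
    return (1.0 - w) * vp + w * vq


@dataclass(frozen=True)
class BoundarySegmentSet:
    """Partition of boundary points by the set of conditions attaining the minimum.

    ``segments`` maps each realised subset ``phi`` of 0-based condition
    indices to the indices (into ``points``) of the crossings it owns.  The
    index lists partition ``range(len(points))``.
    """

    segments: dict[frozenset, list[int]]
    points: list[BoundaryPoint] = field(repr=False)
    tolerance: float = 0.0

    def segment_points(self, phi) -> list[BoundaryPoint]:
        return [self.points[i] for i in self.segments.get(frozenset(phi), [])]

    @property
    def n_points(self) -> int:
        return len(self.points)

    def labels(self) -> list[frozenset]:
        return list(self.segments)


def partition_boundary(
    points: list[BoundaryPoint],
    fields: list[ScalarField | np.ndarray],
    delta: float,
) -> BoundarySegmentSet:
    """Assign each boundary point to the subset of conditions attaining the minimum.

    Each condition map is linearly interpolated along the point's lattice
    edge; the point's label is ``phi = {i : v_i <= min_j v_j + delta}``.
    Every point lands in exactly one segment; a positive ``delta`` lets
    genuinely shared boundaries (several conditions vanishing together) be
    detected at finite sample size.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if len(fields) == 0:
        raise ValueError("need at least one field")
    vals = np.stack([interpolate_at_boundary(f, points) for f in fields])  # (M, P)
    segments: dict[frozenset, list[int]] = {}
    if vals.shape[1]:
        near_min = vals <= vals.min(axis=0, keepdims=True) + delta
        for j in range(vals.shape[1]):
            phi = frozenset(np.flatnonzero(near_min[:, j]).tolist())
            segments.setdefault(phi, []).append(j)
    return BoundarySegmentSet(segments=segments, points=list(points), tolerance=float(delta))
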