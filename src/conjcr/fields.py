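"""Lattice grids and scalar fields.

A :class:`ScalarField` holds one real value per lattice point and is the
universal image currency of the package: target functions, their estimates,
standard-error maps and standardised maps are all scalar fields on a common
:class:`GridSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "ScalarField", "as_values"]


@dataclass(frozen=True)
class GridSpec:
    """A regular pixel lattice.

    Pixel centres sit at integer coordinates, 0-based, one coordinate per
    axis.  Only the extent per axis is needed; spacing is implicitly one
    pixel.

    Parameters
    ----------
    shape
        Integer extent per axis.  Every extent must be at least 2 so that
        lattice edges (and hence boundary crossings) exist along each axis.
    """

    shape: tuple[int, ...]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in np.atleast_1d(np.asarray(self.shape, dtype=int)))
        if len(shape) == 0:
            raise ValueError("grid must have at least one axis")
        if any(s < 2 for s in shape):
            raise ValueError(f"all grid extents must be >= 2, got {shape}")
        object.__setattr__(self, "shape", shape)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))


@dataclass(frozen=True)
class ScalarField:
    """One finite real value per lattice point.

    Parameters
    ----------
    values
        Array of field values; its shape defines (or must match) ``grid``.
    grid
        Optional explicit grid; defaults to ``GridSpec(values.shape)``.
    """

    values: np.ndarray
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim == 0:
            raise ValueError("a scalar field needs at least one axis")
        if not np.all(np.isfinite(v)):
            raise ValueError("scalar field values must be finite")
        object.__setattr__(self, "values", v)
        grid = self.grid if self.grid is not None else GridSpec(v.shape)
        if tuple(grid.shape) != v.shape:
            raise ValueError(f"grid shape {grid.shape} does not match values shape {v.shape}")
        object.__setattr__(self, "grid", grid)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def map(self, fn) -> "ScalarField":
        """Return a new field with ``fn`` applied to the values."""
        return ScalarField(fn(self.values), self.grid)


def as_values(field) -> np.ndarray:
    """Return the value array of a :class:`ScalarField` or pass arrays through."""
    if isinstance(field, ScalarField):
        return field.values
    return np.asarray(field, dtype=np.float64)
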