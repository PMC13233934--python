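"""Toroidal grid geometry and periodic distance computations.

The network lives on a square lattice with periodic boundaries (a torus).
Excitatory neurons sit on the integer lattice with unit spacing; inhibitory
neurons sit on a twice-coarser lattice offset by half a grid spacing, so that
each inhibitory neuron is equidistant from the four excitatory neurons that
surround it.  All distances in the package use the minimal-image Euclidean
metric on the torus, in units of the excitatory grid spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "GridGeometry",
    "build_grid",
    "toroidal_distance",
    "toroidal_displacement",
    "neurons_in_disk",
]


@dataclass(frozen=True)
class GridGeometry:
    """Placement of the excitatory and inhibitory populations on a torus.

    Attributes
    ----------
    nrows
        Side length of the excitatory lattice (grid points).
    exc_positions
        ``(nrows**2, 2)`` array of (x, y) lattice coordinates, x = column,
        y = row, both in ``[0, nrows)``.  Neuron ``i`` sits at
        ``(i % nrows, i // nrows)``.
    inh_positions
        ``(nrows**2 // 4, 2)`` array of (x, y) coordinates on the offset
        lattice ``(2j + 0.5, 2k + 0.5)``.
    """

    nrows: int
    exc_positions: NDArray[np.float64] = field(repr=False)
    inh_positions: NDArray[np.float64] = field(repr=False)
    periodic: bool = True

    @property
    def n_exc(self) -> int:
        return self.exc_positions.shape[0]

    @property
    def n_inh(self) -> int:
        return self.inh_positions.shape[0]

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh

    def positions(self, population: str) -> NDArray[np.float64]:
        if population == "exc":
            return self.exc_positions
        if population == "inh":
            return self.inh_positions
        raise ValueError(f"unknown population {population!r}")


def build_grid(nrows: int) -> GridGeometry:
    """Place ``nrows**2`` excitatory and ``nrows**2 / 4`` inhibitory neurons.

    Parameters
    ----------
    nrows
        Even side length, at least 8.

    Raises
    ------
    ValueError
        If ``nrows`` is odd or smaller than 8 (the inhibitory lattice needs
        an even side, and smaller grids cannot hold a single kernel).
    """
    if nrows < 8 or nrows % 2 != 0:
        raise ValueError(f"nrows must be an even integer >= 8, got {nrows}")
    xs, ys = np.meshgrid(np.arange(nrows), np.arange(nrows))
    exc = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    half = nrows // 2
    xi, yi = np.meshgrid(np.arange(half), np.arange(half))
    inh = np.column_stack([2.0 * xi.ravel() + 0.5, 2.0 * yi.ravel() + 0.5])
    return GridGeometry(nrows=nrows, exc_positions=exc, inh_positions=inh)


def toroidal_displacement(
    a: ArrayLike, b: ArrayLike, nrows: int
) -> NDArray[np.float64]:
    """Minimal-image displacement ``b - a`` on the torus, per component.

    Each component is wrapped into ``[-nrows/2, nrows/2)``.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return (d + nrows / 2.0) % nrows - nrows / 2.0


def toroidal_distance(a: ArrayLike, b: ArrayLike, nrows: int) -> np.floating:
    """Euclidean distance under the minimal-image convention.

    Broadcasts over leading axes; the last axis holds (x, y).
    """
    d = toroidal_displacement(a, b, nrows)
    return np.sqrt(np.sum(d * d, axis=-1))


def neurons_in_disk(
    center: ArrayLike,
    radius: float,
    geometry: GridGeometry,
    population: str = "exc",
) -> NDArray[np.int64]:
    """Ids of neurons within a closed toroidal disk around ``center``.

    The disk is closed (distance <= radius), which makes a radius-6 disk on
    the excitatory lattice contain exactly 113 neurons.  An empty result is
    valid.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    pos = geometry.positions(population)
    dist = toroidal_distance(np.asarray(center, dtype=float), pos, geometry.nrows)
    return np.flatnonzero(dist <= radius + 1e-12).astype(np.int64)
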