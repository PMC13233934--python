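"""Periodic 2D gradient noise for sampling spatially correlated fields.

Random unit gradient vectors are placed on a coarse ``cells x cells`` lattice
that wraps around in both directions, so the generated field is continuous
across the torus seam by construction.  The value at a test point is the
smoothstep-blended dot product between the corner gradients of its cell and
the offsets from those corners — the classic gradient-noise scheme.  The cell
count controls the correlation length: few cells give large smooth domains,
``cells == nrows`` gives essentially independent values per lattice site.

Sample points are offset by half a cell relative to the gradient lattice.
Gradient noise vanishes identically on its own lattice nodes, so sampling at
the nodes would degenerate; the half-cell offset keeps every sample in the
interior of a cell at any cell count.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray

__all__ = ["periodic_gradient_noise"]


def _fade(t: NDArray) -> NDArray:
    # Quintic smoothstep: zero first and second derivative at cell borders.
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def periodic_gradient_noise(
    x: NDArray,
    y: NDArray,
    cells: int,
    extent: float,
    rng: np.random.Generator,
) -> NDArray[np.float64]:
    """Evaluate periodic gradient noise at points ``(x, y)``.

    Parameters
    ----------
    x, y
        Coordinates in ``[0, extent)``; any broadcastable shape.
    cells
        Number of gradient-lattice cells per side (>= 1).
    extent
        Period of the field in coordinate units (the grid side length).
    rng
        Source of the lattice gradients; a fixed generator state gives a
        deterministic field.

    Returns
    -------
    Values in roughly ``[-1, 1]``, identical for points congruent modulo
    ``extent``.
    """
    if cells < 1:
        raise ValueError(f"cells must be >= 1, got {cells}")
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(cells, cells))
    gx, gy = np.cos(theta), np.sin(theta)

    # Map to cell coordinates, offsetting by half a cell.
    u = (np.asarray(x, dtype=float) / extent) * cells + 0.5
    v = (np.asarray(y, dtype=float) / extent) * cells + 0.5
    i0 = np.floor(u).astype(int)
    j0 = np.floor(v).astype(int)
    fu = u - i0
    fv = v - j0
    i0 %= cells
    j0 %= cells
    i1 = (i0 + 1) % cells
    j1 = (j0 + 1) % cells

    def corner(ii: NDArray, jj: NDArray, du: NDArray, dv: NDArray) -> NDArray:
        return gx[ii, jj] * du + gy[ii, jj] * dv

    n00 = corner(i0, j0, fu, fv)
    n10 = corner(i1, j0, fu - 1.0, fv)
    n01 = corner(i0, j1, fu, fv - 1.0)
    n11 = corner(i1, j1, fu - 1.0, fv - 1.0)

    su, sv = _fade(fu), _fade(fv)
    nx0 = n00 + su * (n10 - n00)
    nx1 = n01 + su * (n11 - n01)
    # sqrt(2) normalization puts the range close to [-1, 1].
    return np.sqrt(2.0) * (nx0 + sv * (nx1 - nx0))
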