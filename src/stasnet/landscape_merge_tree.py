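"""Max-tree analysis of sequence-count landscapes on the torus.

Thresholding the per-neuron sequence-count landscape at a high level leaves
only the most reliable pathways as connected components; lowering the
threshold grows them until previously distinct components join.  Each such
join (a "merge") happens across a saddle of lower sequence count — an
unreliable pathway — and the cells that form the saddle are the
semi-transmissive bridge neurons.  Components use the 8-neighborhood with
toroidal wrap-around; thresholds sweep the integer count levels from the
landscape maximum down to 1, so a cell with count zero never activates.

A component is only considered a distinct pathway if it contains a peak (a
local maximum of the landscape) born strictly above the merge level; joins
involving components born at the merge level itself are not counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .topology import GridGeometry, toroidal_distance

__all__ = [
    "MergeEvent",
    "MergeTree",
    "BridgeSet",
    "build_max_tree",
    "extract_bridges",
    "merge_statistics",
]

_OFFSETS = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]


@dataclass(frozen=True)
class MergeEvent:
    """Two peak-bearing components joining at ``threshold``.

    ``comp_a`` / ``comp_b`` are the neuron ids of the two parent components
    restricted to cells strictly above the merge level.
    """

    threshold: int
    comp_a: NDArray[np.int64] = field(repr=False)
    comp_b: NDArray[np.int64] = field(repr=False)


@dataclass(frozen=True)
class MergeTree:
    """Merge events and end nodes of the descending threshold sweep."""

    merges: list[MergeEvent]
    n_end_nodes: int
    max_level: int

    @property
    def n_merges(self) -> int:
        return len(self.merges)


@dataclass(frozen=True)
class BridgeSet:
    """Semi-transmissive neurons produced by one merge."""

    neurons: NDArray[np.int64] = field(repr=False)
    merge_ref: int = 0
    d_max: float = 4.0
    neighbor_radius: float = 10.0


def _neighbor_ids(pixel: int, nrows: int) -> list[int]:
    y, x = divmod(pixel, nrows)
    return [((y + dy) % nrows) * nrows + (x + dx) % nrows for dx, dy in _OFFSETS]


class _Components:
    """Union-find over grid cells with per-root member lists and peak levels."""

    def __init__(self, n: int) -> None:
        self.parent = np.full(n, -1, dtype=np.int64)  # -1: inactive
        self.members: dict[int, list[int]] = {}
        self.peak_level: dict[int, int] = {}

    def activate(self, pixel: int, level: int) -> None:
        self.parent[pixel] = pixel
        self.members[pixel] = [pixel]
        self.peak_level[pixel] = level

    def find(self, a: int) -> int:
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:
            self.parent[a], a = root, self.parent[a]
        return root

    def union(self, a: int, b: int) -> tuple[int, int] | None:
        """Union the components of ``a`` and ``b``; return old roots if distinct."""
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return None
        if len(self.members[ra]) < len(self.members[rb]):
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.members[ra].extend(self.members.pop(rb))
        self.peak_level[ra] = max(self.peak_level[ra], self.peak_level.pop(rb))
        return ra, rb


def build_max_tree(landscape: NDArray, geometry: GridGeometry) -> MergeTree:
    """Descending integer-threshold sweep of the landscape.

    At each level the cells of that count are activated and connected to
    active toroidal 8-neighbors; a merge is recorded at the highest level
    where two components whose peaks were born strictly above that level
    join.  An all-zero landscape yields an empty tree.
    """
    img = np.asarray(landscape).ravel()
    if img.size != geometry.n_exc:
        raise ValueError("landscape size does not match the excitatory population")
    if np.any(img < 0) or not np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.int64)
        if np.any(img < 0):
            raise ValueError("landscape must be nonnegative integer counts")
    nrows = geometry.nrows
    vmax = int(img.max())
    if vmax == 0:
        return MergeTree(merges=[], n_end_nodes=0, max_level=0)

    comps = _Components(img.size)
    merges: list[MergeEvent] = []
    n_births = 0
    for level in range(vmax, 0, -1):
        new_pixels = np.flatnonzero(img == level)
        if new_pixels.size == 0:
            continue
        for p in new_pixels:
            comps.activate(int(p), level)
        # Same-level unions first: plateaus form single components.
        for p in new_pixels:
            for q in _neighbor_ids(int(p), nrows):
                if comps.parent[q] != -1 and img[q] == level:
                    comps.union(int(p), q)
        # Count births: same-level roots before attaching to higher components.
        level_roots = {comps.find(int(p)) for p in new_pixels}
        # Attach to higher components, recording peak-bearing merges.
        for p in new_pixels:
            for q in _neighbor_ids(int(p), nrows):
                if comps.parent[q] == -1 or img[q] <= level:
                    continue
                ra, rb = comps.find(int(p)), comps.find(q)
                if ra == rb:
                    continue
                peaks_above = (
                    comps.peak_level[ra] > level and comps.peak_level[rb] > level
                )
                if peaks_above:
                    a_hi = np.array(
                        [m for m in comps.members[ra] if img[m] > level], dtype=np.int64
                    )
                    b_hi = np.array(
                        [m for m in comps.members[rb] if img[m] > level], dtype=np.int64
                    )
                    merges.append(MergeEvent(threshold=level, comp_a=a_hi, comp_b=b_hi))
                comps.union(ra, rb)
        for root in level_roots:
            if comps.peak_level[comps.find(root)] == level:
                n_births += 1
    return MergeTree(merges=merges, n_end_nodes=n_births, max_level=vmax)


def extract_bridges(
    tree: MergeTree,
    landscape: NDArray,
    geometry: GridGeometry,
    d_max: float = 4.0,
    neighbor_radius: float = 10.0,
) -> list[BridgeSet]:
    """Semi-transmissive neurons for every merge of the tree.

    For a merge at level theta, bridge candidates are the cells of count
    theta lying within ``d_max`` of both parent components; the candidates'
    toroidal 8-neighbors within ``neighbor_radius`` of both components are
    included as well (the printed artifact filter).
    """
    img = np.asarray(landscape).ravel()
    nrows = geometry.nrows
    pos = geometry.exc_positions
    out: list[BridgeSet] = []
    for k, merge in enumerate(tree.merges):
        level_cells = np.flatnonzero(img == merge.threshold)
        if level_cells.size == 0:
            out.append(BridgeSet(np.empty(0, np.int64), k, d_max, neighbor_radius))
            continue

        def min_dist(cells: NDArray, comp: NDArray) -> NDArray:
            d = toroidal_distance(
                pos[cells][:, None, :], pos[comp][None, :, :], nrows
            )
            return d.min(axis=1)

        da = min_dist(level_cells, merge.comp_a)
        db = min_dist(level_cells, merge.comp_b)
        bridge = level_cells[(da <= d_max) & (db <= d_max)]
        if bridge.size:
            nb = np.unique(
                np.array(
                    [q for p in bridge for q in _neighbor_ids(int(p), nrows)],
                    dtype=np.int64,
                )
            )
            nb = np.setdiff1d(nb, bridge)
            if nb.size:
                keep = (min_dist(nb, merge.comp_a) <= neighbor_radius) & (
                    min_dist(nb, merge.comp_b) <= neighbor_radius
                )
                bridge = np.union1d(bridge, nb[keep])
        out.append(BridgeSet(bridge.astype(np.int64), k, d_max, neighbor_radius))
    return out


def merge_statistics(trees: list[MergeTree]) -> tuple[float, NDArray[np.int64]]:
    """Mean merges per tree and the histogram of merge counts.

    The histogram's index is the merge count (length ``max+1``).
    """
    if not trees:
        raise ValueError("need at least one merge tree")
    counts = np.array([t.n_merges for t in trees], dtype=np.int64)
    return float(counts.mean()), np.bincount(counts)
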