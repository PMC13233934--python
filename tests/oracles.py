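"""Independent brute-force oracles used to cross-check the package.

Each oracle is deliberately naive — full pairwise metrics, explicit BFS,
per-threshold relabeling, Python loops — and shares no code with the
implementation paths it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def wrap(d: np.ndarray, nrows: int) -> np.ndarray:
    return (d + nrows / 2.0) % nrows - nrows / 2.0


def toroidal_dist_brute(a, b, nrows: int) -> float:
    """Min over the 9 shifted images of the plain Euclidean distance."""
    best = np.inf
    for sx in (-nrows, 0, nrows):
        for sy in (-nrows, 0, nrows):
            d = np.hypot(a[0] - (b[0] + sx), a[1] - (b[1] + sy))
            best = min(best, d)
    return best


def extent_brute(x, y, nrows: int) -> float:
    """O(n^2) max pairwise toroidal distance over events."""
    best = 0.0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            dx = wrap(x[i] - x[j], nrows)
            dy = wrap(y[i] - y[j], nrows)
            best = max(best, float(np.hypot(dx, dy)))
    return best


def dbscan_toroidal_brute(x, y, t, eps, min_samples, nrows, time_scale=1.0):
    """Density clustering with the full toroidal metric (no shift trick).

    Returns labels (-1 for noise); core semantics match DBSCAN: a core point
    has >= min_samples neighbors within eps (itself included), clusters are
    connected components of core points, border points join a neighboring
    core's cluster.
    """
    n = len(x)
    dx = wrap(np.subtract.outer(x, x), nrows)
    dy = wrap(np.subtract.outer(y, y), nrows)
    dt = np.subtract.outer(t, t) * time_scale
    neigh = dx * dx + dy * dy + dt * dt <= eps * eps
    core = neigh.sum(axis=1) >= min_samples
    labels = np.full(n, -1, dtype=int)
    current = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        queue = deque([i])
        labels[i] = current
        while queue:
            j = queue.popleft()
            for k in np.flatnonzero(neigh[j]):
                if labels[k] == -1:
                    labels[k] = current
                    if core[k]:
                        queue.append(k)
        current += 1
    return labels


def partitions_equal(labels_a, groups_b) -> bool:
    """Compare a label vector with a list of index sets, up to relabeling."""
    sets_a = {}
    for idx, lab in enumerate(labels_a):
        if lab >= 0:
            sets_a.setdefault(lab, set()).add(idx)
    return sorted(map(frozenset, sets_a.values())) == sorted(
        frozenset(map(int, g)) for g in groups_b
    )


def _components(mask: np.ndarray) -> np.ndarray:
    """Toroidal 8-neighborhood connected components of a boolean image."""
    nrows = mask.shape[0]
    labels = np.full(mask.shape, -1, dtype=int)
    current = 0
    for sy, sx in zip(*np.nonzero(mask)):
        if labels[sy, sx] != -1:
            continue
        queue = deque([(sy, sx)])
        labels[sy, sx] = current
        while queue:
            y, x = queue.popleft()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    ny, nx = (y + dy) % nrows, (x + dx) % nrows
                    if mask[ny, nx] and labels[ny, nx] == -1:
                        labels[ny, nx] = current
                        queue.append((ny, nx))
        current += 1
    return labels


def merge_sweep_brute(img: np.ndarray) -> list[tuple[int, int]]:
    """Naive per-threshold sweep: (threshold, merge count) per level.

    At threshold theta, each component of ``img >= theta`` that contains k >= 2
    components of ``img >= theta + 1`` contributes k - 1 merges.
    """
    vmax = int(img.max())
    events = []
    for theta in range(vmax - 1, 0, -1):
        above = _components(img >= theta + 1)
        now = _components(img >= theta)
        n_above = above.max() + 1
        if n_above < 2:
            continue
        merged = 0
        for comp in range(now.max() + 1):
            inside = {
                above[y, x]
                for y, x in zip(*np.nonzero(now == comp))
                if above[y, x] >= 0
            }
            if len(inside) >= 2:
                merged += len(inside) - 1
        if merged:
            events.append((theta, merged))
    return events


def births_brute(img: np.ndarray) -> int:
    """Number of components born at a local-maximum level across the sweep."""
    vmax = int(img.max())
    births = 0
    for theta in range(vmax, 0, -1):
        above = _components(img >= theta + 1)
        now = _components(img >= theta)
        for comp in range(now.max() + 1):
            cells = list(zip(*np.nonzero(now == comp)))
            if all(above[y, x] < 0 for y, x in cells):
                births += 1
    return births


def transmission_brute(rows, pre, post):
    """Tally crossings from a list of row dicts by explicit looping."""
    by_seq = {}
    for row in rows:
        key = (row.get("run", 0), row["sequence_id"])
        by_seq.setdefault(key, {})[row["spot"]] = (
            row["t_first"] if row["crossed"] else None
        )
    n_pre = n_post = n_both = n_ordered = 0
    for spots in by_seq.values():
        tp = spots.get(pre)
        tq = spots.get(post)
        if tp is not None:
            n_pre += 1
        if tq is not None:
            n_post += 1
        if tp is not None and tq is not None:
            n_both += 1
            if tp <= tq:
                n_ordered += 1
    return n_pre, n_post, n_both, n_ordered
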