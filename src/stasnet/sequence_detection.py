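"""Detect spatio-temporal activity sequences (STAS) from rate traces.

Rates are thresholded into pseudo-spike events (x, y, t); events are
density-clustered with DBSCAN in the mixed (x, y, t) space.  Because the grid
is a torus a single Euclidean DBSCAN pass splits clusters that wrap around the
seam, so the cloud is clustered twice — once as-is and once with all positions
shifted by nrows/2 in both axes — and clusters from the two passes that share
events are merged (transitive union).  Surviving clusters are sequences;
sequences whose spatial extent (maximal pairwise toroidal distance) stays
below ``min_extent`` grid points are discarded as non-traveling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from sklearn.cluster import DBSCAN

from .dynamics import RateTrace
from .topology import GridGeometry, neurons_in_disk, toroidal_distance

__all__ = [
    "DetectionParams",
    "PseudoSpikeCloud",
    "Sequence",
    "DetectionSpot",
    "threshold_to_pseudospikes",
    "cluster_toroidal",
    "filter_sequences",
    "detect_sequences",
    "sequence_landscape",
    "spot_crossings",
    "network_effect_summary",
    "run_summary",
    "toroidal_extent",
    "is_static_bump_run",
]


@dataclass(frozen=True)
class DetectionParams:
    """Thresholding and clustering parameters.

    theta: rate threshold for pseudo-spikes; eps / min_samples: DBSCAN
    neighborhood radius and core-point minimum in the (x, y, time_scale * t)
    space; min_extent: minimal spatial traverse (grid points) for a cluster to
    count as a sequence.
    """

    theta: float = 0.4
    eps: float = 4.0
    min_samples: int = 50
    min_extent: float = 8.0
    time_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be in (0, 1)")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.min_extent < 0:
            raise ValueError("min_extent must be >= 0")


@dataclass(frozen=True)
class PseudoSpikeCloud:
    """Threshold crossings as events: lattice coordinates, time (ms), neuron id."""

    x: NDArray[np.float64] = field(repr=False)
    y: NDArray[np.float64] = field(repr=False)
    t: NDArray[np.float64] = field(repr=False)
    neuron: NDArray[np.int64] = field(repr=False)

    @property
    def n_events(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class Sequence:
    """One detected sequence: its events, participants, duration and extent."""

    id: int
    x: NDArray[np.float64] = field(repr=False)
    y: NDArray[np.float64] = field(repr=False)
    t: NDArray[np.float64] = field(repr=False)
    neuron: NDArray[np.int64] = field(repr=False)
    extent: float = 0.0

    @property
    def neurons(self) -> NDArray[np.int64]:
        return np.unique(self.neuron)

    @property
    def t_start(self) -> float:
        return float(self.t.min())

    @property
    def t_end(self) -> float:
        return float(self.t.max())

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class DetectionSpot:
    """A labeled disk used to register which sequences cross a location."""

    label: str
    center: tuple[float, float]
    radius: float = 2.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("spot radius must be positive")


def threshold_to_pseudospikes(
    trace: RateTrace, theta: float, geometry: GridGeometry
) -> PseudoSpikeCloud:
    """One event per (excitatory neuron, step) whose rate >= theta (inclusive)."""
    rates = trace.rates[:, : geometry.n_exc]
    step, neuron = np.nonzero(rates >= theta)
    pos = geometry.exc_positions[neuron]
    return PseudoSpikeCloud(
        x=pos[:, 0].astype(float),
        y=pos[:, 1].astype(float),
        t=step.astype(float) * trace.config.dt,
        neuron=neuron.astype(np.int64),
    )


def toroidal_extent(x: NDArray, y: NDArray, nrows: int) -> float:
    """Maximal pairwise toroidal distance over event coordinates.

    Computed on the unique (x, y) sites only — the extent is purely spatial —
    in blocks to bound memory.
    """
    coords = np.unique(np.column_stack([x, y]), axis=0)
    n = coords.shape[0]
    if n < 2:
        return 0.0
    best = 0.0
    for start in range(0, n, 512):
        block = coords[start : start + 512]
        d = toroidal_distance(block[:, None, :], coords[None, :, :], nrows)
        best = max(best, float(d.max()))
    return best


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_toroidal(
    cloud: PseudoSpikeCloud, params: DetectionParams, geometry: GridGeometry
) -> list[Sequence]:
    """Seam-safe density clustering of the pseudo-spike cloud (pre-filter).

    Runs DBSCAN on the original and on the half-grid-shifted coordinates and
    merges clusters from the two passes that share at least one event
    (transitively).  Events that are noise in both passes are discarded; every
    surviving event belongs to exactly one sequence.
    """
    if cloud.n_events == 0:
        return []
    nrows = geometry.nrows
    half = nrows / 2.0
    ts = cloud.t * params.time_scale

    pts1 = np.column_stack([cloud.x, cloud.y, ts])
    pts2 = np.column_stack([(cloud.x + half) % nrows, (cloud.y + half) % nrows, ts])
    db = dict(eps=params.eps, min_samples=params.min_samples)
    labels1 = DBSCAN(**db).fit_predict(pts1)
    labels2 = DBSCAN(**db).fit_predict(pts2)

    n1 = labels1.max() + 1
    n2 = labels2.max() + 1
    uf = _UnionFind(n1 + n2)
    both = (labels1 >= 0) & (labels2 >= 0)
    for a, b in set(zip(labels1[both].tolist(), labels2[both].tolist())):
        uf.union(a, n1 + b)

    # Assign each non-noise event to its merged group.
    group_of_event = np.full(cloud.n_events, -1, dtype=int)
    mask1 = labels1 >= 0
    group_of_event[mask1] = [uf.find(l) for l in labels1[mask1]]
    only2 = (~mask1) & (labels2 >= 0)
    group_of_event[only2] = [uf.find(n1 + l) for l in labels2[only2]]

    sequences: list[Sequence] = []
    for seq_id, g in enumerate(np.unique(group_of_event[group_of_event >= 0])):
        idx = np.flatnonzero(group_of_event == g)
        sequences.append(
            Sequence(
                id=seq_id,
                x=cloud.x[idx],
                y=cloud.y[idx],
                t=cloud.t[idx],
                neuron=cloud.neuron[idx],
                extent=toroidal_extent(cloud.x[idx], cloud.y[idx], nrows),
            )
        )
    return sequences


def filter_sequences(
    sequences: list[Sequence], params: DetectionParams, geometry: GridGeometry
) -> list[Sequence]:
    """Keep sequences that traverse at least ``min_extent`` grid points."""
    return [s for s in sequences if s.extent >= params.min_extent]


def detect_sequences(
    trace: RateTrace, params: DetectionParams, geometry: GridGeometry
) -> list[Sequence]:
    """Threshold, cluster and filter in one call."""
    cloud = threshold_to_pseudospikes(trace, params.theta, geometry)
    return filter_sequences(cluster_toroidal(cloud, params, geometry), params, geometry)


def sequence_landscape(
    sequences: list[Sequence], geometry: GridGeometry
) -> NDArray[np.int64]:
    """Number of sequences each excitatory neuron participated in."""
    counts = np.zeros(geometry.n_exc, dtype=np.int64)
    for seq in sequences:
        counts[seq.neurons] += 1
    return counts


def spot_crossings(
    sequences: list[Sequence],
    spots: list[DetectionSpot],
    geometry: GridGeometry,
) -> pd.DataFrame:
    """Which sequences cross which detection spots, and when first.

    A sequence crosses a spot if at least one participating neuron lies
    within the spot disk; the first-crossing time is the earliest event time
    of such neurons.  Returns one row per (sequence, spot).
    """
    spot_masks = {}
    for s in spots:
        mask = np.zeros(geometry.n_exc, dtype=bool)
        mask[neurons_in_disk(s.center, s.radius, geometry, "exc")] = True
        spot_masks[s.label] = mask
    rows = []
    for seq in sequences:
        for spot in spots:
            inside = spot_masks[spot.label][seq.neuron]
            crossed = bool(inside.any())
            rows.append(
                {
                    "sequence_id": seq.id,
                    "spot": spot.label,
                    "crossed": crossed,
                    "t_first": float(seq.t[inside].min()) if crossed else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["sequence_id", "spot", "crossed", "t_first"])


def run_summary(sequences: list[Sequence], seed: int) -> dict:
    """Per-run sequence count and mean duration (NaN if no sequences)."""
    durations = [s.duration for s in sequences]
    return {
        "seed": seed,
        "count": len(sequences),
        "mean_duration": float(np.mean(durations)) if durations else np.nan,
    }


def network_effect_summary(
    baseline_runs: pd.DataFrame, modulated_runs: pd.DataFrame
) -> dict:
    """Seed-matched differences in sequence count and mean duration.

    Both frames need columns (seed, count, mean_duration) over identical seed
    sets.  Returns mean +/- SEM (across seeds) of the per-seed differences.
    """
    base = pd.DataFrame(baseline_runs).set_index("seed").sort_index()
    mod = pd.DataFrame(modulated_runs).set_index("seed").sort_index()
    if len(base) < 2 or not base.index.equals(mod.index):
        raise ValueError("runs must cover identical seed sets with >= 2 seeds")
    d_count = (mod["count"] - base["count"]).to_numpy(dtype=float)
    d_dur = (mod["mean_duration"] - base["mean_duration"]).to_numpy(dtype=float)

    def mean_sem(v: NDArray) -> tuple[float, float]:
        v = v[np.isfinite(v)]
        if v.size == 0:
            return np.nan, np.nan
        sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        return float(np.mean(v)), sem

    dc, dc_sem = mean_sem(d_count)
    dd, dd_sem = mean_sem(d_dur)
    return {
        "delta_count_mean": dc,
        "delta_count_sem": dc_sem,
        "delta_duration_mean": dd,
        "delta_duration_sem": dd_sem,
    }


def is_static_bump_run(
    sequences: list[Sequence],
    t_sim: float,
    extent_threshold: float = 8.0,
    duration_fraction: float = 0.9,
) -> bool:
    """Screen for saturated stationary clusters (excluded landscapes).

    A run is flagged when any pre-filter sequence is spatially confined
    (extent < ``extent_threshold``) yet persists for at least
    ``duration_fraction`` of the simulated time.
    """
    return any(
        s.extent < extent_threshold and s.duration >= duration_fraction * t_sim
        for s in sequences
    )
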