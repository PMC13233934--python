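"""Deterministic small test inputs: planted event clouds, toy landscapes,
designed task circuits and scaled-down grids.

These generators are first-class package code: they define the controlled
conditions under which the detector, the merge-tree analysis and the motif
machinery are exercised, with planted ground truth (cluster labels, bridge
cells, junction layouts) known by construction.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray

from .sequence_detection import DetectionSpot, PseudoSpikeCloud
from .task_network import PatchSpec, PathwaySpec, TaskSpec
from .topology import GridGeometry, build_grid

__all__ = [
    "planted_cloud",
    "seam_cloud",
    "two_peak_landscape",
    "gapped_line_task",
    "diverging_y_task",
    "converging_y_task",
    "context_reversal_task",
    "generate_fixtures",
]


def planted_cloud(
    nrows: int = 40,
    n_clusters: int = 3,
    events_per_cluster: int = 80,
    spread: float = 1.2,
    seed: int = 0,
    straddle_seam: bool = False,
) -> tuple[PseudoSpikeCloud, NDArray[np.int64]]:
    """Moving event clusters with known labels, far apart in (x, y, t).

    Clusters travel along +x over ~40 ms; centers are spaced so that
    inter-cluster gaps far exceed the default DBSCAN eps.  With
    ``straddle_seam`` the first cluster is centered on the x-seam.
    """
    rng = np.random.default_rng(seed)
    if n_clusters == 0:
        empty = np.empty(0)
        return (
            PseudoSpikeCloud(x=empty, y=empty, t=empty, neuron=np.empty(0, np.int64)),
            np.empty(0, np.int64),
        )
    xs, ys, ts, labels = [], [], [], []
    for c in range(n_clusters):
        cx = nrows - 2.0 if straddle_seam and c == 0 else 5.0 + c * (nrows / n_clusters)
        cy = (c * 2 * nrows / n_clusters + 5.0) % nrows
        t0 = 100.0 * c
        u = rng.uniform(0.0, 40.0, events_per_cluster)
        x = np.rint(cx + 0.25 * u + rng.normal(0, spread, events_per_cluster)) % nrows
        y = np.rint(cy + rng.normal(0, spread, events_per_cluster)) % nrows
        xs.append(x)
        ys.append(y)
        ts.append(t0 + u)
        labels.append(np.full(events_per_cluster, c))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t = np.concatenate(ts)
    neuron = (y.astype(np.int64) * nrows + x.astype(np.int64))
    cloud = PseudoSpikeCloud(x=x, y=y, t=t, neuron=neuron)
    return cloud, np.concatenate(labels).astype(np.int64)


def seam_cloud(nrows: int = 40, n_events: int = 120, seed: int = 0) -> PseudoSpikeCloud:
    """A single dense blob straddling the x-seam at one time."""
    rng = np.random.default_rng(seed)
    x = np.rint(rng.normal(0.0, 1.5, n_events)) % nrows
    y = np.rint(nrows / 2 + rng.normal(0.0, 1.5, n_events)) % nrows
    t = rng.uniform(0.0, 3.0, n_events)
    neuron = y.astype(np.int64) * nrows + x.astype(np.int64)
    return PseudoSpikeCloud(x=x, y=y, t=t, neuron=neuron)


def two_peak_landscape(
    nrows: int = 20,
    peak_height: int = 3,
    ridge_height: int = 1,
    across_seam: bool = False,
) -> tuple[NDArray[np.int64], GridGeometry, int, NDArray[np.int64]]:
    """Two plateaus joined by a ridge of known level.

    Returns (landscape, geometry, expected merge level, planted ridge cells).
    """
    geometry = build_grid(nrows)
    img = np.zeros((nrows, nrows), dtype=np.int64)
    y0 = nrows // 2
    if across_seam:
        # ridge crosses the x-seam; every ridge cell is within 4 grid
        # points of both plateaus
        ax = slice(2, 5)
        bx = slice(nrows - 5, nrows - 2)
        ridge_x = [nrows - 2, nrows - 1, 0, 1]
    else:
        ax = slice(2, 5)
        bx = slice(nrows - 7, nrows - 4)
        ridge_x = list(range(5, nrows - 7))
    img[y0 - 1 : y0 + 2, ax] = peak_height
    img[y0 - 1 : y0 + 2, bx] = peak_height
    for x in ridge_x:
        img[y0, x] = ridge_height
    ridge_cells = np.array([y0 * nrows + x for x in ridge_x], dtype=np.int64)
    return img.ravel(), geometry, ridge_height, ridge_cells


def gapped_line_task(
    nrows: int = 40,
    y: float = 20.0,
    gap: tuple[float, float] = (17.0, 23.0),
    width: float = 3.0,
    p: float = 0.10,
) -> TaskSpec:
    """A straight pathway with an isotropic gap: the Repeat/Stop testbed.

    The incoming segment ends at the gap, the outgoing segment resumes after
    it; transmission across the gap is probabilistic.  Patches: ``start`` at
    the pathway origin, ``repeat`` (+p) and ``stop`` (-p) on the gap,
    ``anti`` (+p) on the strong segment just past the gap.  Spots ``pre``
    and ``post`` flank the gap two grid points outside it.
    """
    pathways = {
        "in": PathwaySpec(polyline=((4.0, y), (gap[0], y)), width=width),
        "out": PathwaySpec(polyline=((gap[1], y), (36.0, y)), width=width),
    }
    mid = ((gap[0] + gap[1]) / 2.0, y)
    patches = {
        "start": PatchSpec(center=(4.0, y), p=+p, radius=6.0, n_rec=40, seed=11),
        "repeat": PatchSpec(center=mid, p=+p, radius=4.0, n_rec=20, seed=12),
        "stop": PatchSpec(center=mid, p=-p, radius=4.0, n_rec=20, seed=12),
        "anti": PatchSpec(center=(gap[1] + 4.0, y), p=+p, radius=4.0, n_rec=20, seed=13),
    }
    spots = {
        "pre": DetectionSpot("pre", (gap[0] - 2.0, y)),
        "post": DetectionSpot("post", (gap[1] + 2.0, y)),
    }
    contexts = {name: (name,) for name in patches}
    return TaskSpec(pathways=pathways, motif_patches=patches, spots=spots, contexts=contexts)


def diverging_y_task(nrows: int = 40, width: float = 3.0, p: float = 0.10) -> TaskSpec:
    """Main pathway splitting into two symmetric branches: the Select testbed.

    Branch angles are kept shallow (~27 degrees) so that a traveling bump
    can follow either branch through the turn.
    """
    junction = (20.0, 20.0)
    pathways = {
        "main": PathwaySpec(polyline=((4.0, 20.0), junction), width=width),
        "b1": PathwaySpec(polyline=(junction, (34.0, 13.0)), width=width),
        "b2": PathwaySpec(polyline=(junction, (34.0, 27.0)), width=width),
    }
    patches = {
        "select_b2": PatchSpec(center=(24.0, 22.0), p=+p, radius=4.0, n_rec=20, seed=21),
        "deselect_b2": PatchSpec(center=(24.0, 22.0), p=-p, radius=4.0, n_rec=20, seed=21),
    }
    spots = {
        "M": DetectionSpot("M", (17.0, 20.0)),
        "B1": DetectionSpot("B1", (26.0, 17.0)),
        "B2": DetectionSpot("B2", (26.0, 23.0)),
    }
    contexts = {name: (name,) for name in patches}
    return TaskSpec(pathways=pathways, motif_patches=patches, spots=spots, contexts=contexts)


def converging_y_task(nrows: int = 40, width: float = 3.0, p: float = 0.10) -> TaskSpec:
    """Two branches merging into a main pathway: the Gate / competition testbed."""
    junction = (20.0, 20.0)
    pathways = {
        "b1": PathwaySpec(polyline=((6.0, 27.0), junction), width=width),
        "b2": PathwaySpec(polyline=((6.0, 13.0), junction), width=width),
        "main": PathwaySpec(polyline=(junction, (34.0, 20.0)), width=width),
    }
    patches = {
        "gate_weaken_b1": PatchSpec(center=(16.0, 22.0), p=-p, radius=3.0, n_rec=15, seed=31),
        "gate_strengthen_b1": PatchSpec(center=(16.0, 22.0), p=+p, radius=3.0, n_rec=15, seed=31),
    }
    spots = {
        "B1": DetectionSpot("B1", (14.0, 23.0)),
        "B2": DetectionSpot("B2", (14.0, 17.0)),
        "M": DetectionSpot("M", (24.0, 20.0)),
    }
    contexts = {name: (name,) for name in patches}
    return TaskSpec(pathways=pathways, motif_patches=patches, spots=spots, contexts=contexts)


def context_reversal_task(nrows: int = 40, width: float = 3.0, p: float = 0.10) -> TaskSpec:
    """Signal pathway -> trunk -> Select junction -> Left/Right readouts.

    The task contexts activate the whole motif chain, as the circuit
    prescribes: a Start patch on the signal pathway, a Repeat patch on the
    trunk, and a push-pull Select pair at the junction (strengthen the
    chosen branch, weaken the other).  Context "A" selects Left, context
    "B" selects Right; "baseline" applies no patches.  Spots: S on the
    signal pathway, M1 and M2 along the trunk, L and R on the branches.
    """
    junction = (16.0, 20.0)
    pathways = {
        "signal": PathwaySpec(polyline=((2.0, 20.0), (9.0, 20.0)), width=width),
        "main": PathwaySpec(polyline=((9.0, 20.0), junction), width=width),
        "left": PathwaySpec(polyline=(junction, (30.0, 13.0)), width=width),
        "right": PathwaySpec(polyline=(junction, (30.0, 27.0)), width=width),
    }
    patches = {
        "start": PatchSpec(center=(4.0, 20.0), p=+p, radius=6.0, n_rec=40, seed=41),
        "repeat": PatchSpec(center=(10.0, 20.0), p=+p, radius=4.0, n_rec=20, seed=44),
        "repeat2": PatchSpec(center=(14.0, 20.0), p=+p, radius=3.0, n_rec=15, seed=45),
        "select_L": PatchSpec(center=(20.5, 17.5), p=+2 * p, radius=4.0, n_rec=20, seed=42),
        "select_R": PatchSpec(center=(20.5, 22.5), p=+2 * p, radius=4.0, n_rec=20, seed=43),
        "deselect_L": PatchSpec(center=(20.5, 17.5), p=-2 * p, radius=4.0, n_rec=20, seed=42),
        "deselect_R": PatchSpec(center=(20.5, 22.5), p=-2 * p, radius=4.0, n_rec=20, seed=43),
    }
    spots = {
        "S": DetectionSpot("S", (7.0, 20.0)),
        "M1": DetectionSpot("M1", (10.5, 20.0)),
        "M2": DetectionSpot("M2", (14.0, 20.0)),
        "L": DetectionSpot("L", (21.0, 17.5)),
        "R": DetectionSpot("R", (21.0, 22.5)),
    }
    contexts = {
        "A": ("start", "repeat", "repeat2", "select_L", "deselect_R"),
        "B": ("start", "repeat", "repeat2", "select_R", "deselect_L"),
    }
    return TaskSpec(pathways=pathways, motif_patches=patches, spots=spots, contexts=contexts)


def generate_fixtures(kind: str, seed: int = 0, **params):
    """Dispatch fixture generation by kind: grid | cloud | landscape | task."""
    if kind == "grid":
        return build_grid(params.get("nrows", 40))
    if kind == "cloud":
        return planted_cloud(seed=seed, **params)
    if kind == "landscape":
        return two_peak_landscape(**params)
    if kind == "task":
        name = params.pop("name", "context_reversal")
        builders = {
            "gapped_line": gapped_line_task,
            "diverging_y": diverging_y_task,
            "converging_y": converging_y_task,
            "context_reversal": context_reversal_task,
        }
        if name not in builders:
            raise ValueError(f"unknown task fixture {name!r}")
        return builders[name](**params)
    raise ValueError(f"unknown fixture kind {kind!r}")
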