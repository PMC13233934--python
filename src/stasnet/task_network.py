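"""Compile direction fields that realize a designed circuit of pathways.

Instead of sampling preferred directions from gradient noise, the phi field is
written directly from a set of named polyline pathways: neurons within a
pathway's half-width get a preferred direction along the local tangent (toward
the next waypoint), neurons far from every pathway get no preferred direction
(zero kernel shift, an isotropic kernel).  Near junctions the tangents of all
pathways covering a neuron are blended by proximity.  Motif patches (Start,
Gate, Repeat, Select, ...) are placed on the pathways and switched on per
context; routing is read out from detection-spot transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .connectivity import Connectome, DirectionField
from .dynamics import NeuronParams, NoiseParams, SimConfig, simulate
from .modulation import apply_patch, make_patch
from .motif_analysis import pool_crossings, transmission
from .sequence_detection import (
    DetectionParams,
    DetectionSpot,
    detect_sequences,
    spot_crossings,
)
from .topology import GridGeometry, toroidal_displacement

__all__ = [
    "PathwaySpec",
    "PatchSpec",
    "TaskSpec",
    "compile_task_field",
    "run_context",
]


@dataclass(frozen=True)
class PathwaySpec:
    """An ordered polyline of waypoints with a half-width, in grid points."""

    polyline: tuple[tuple[float, float], ...]
    width: float = 3.0

    def __post_init__(self) -> None:
        if len(self.polyline) < 2:
            raise ValueError("a pathway needs at least 2 waypoints")
        if self.width <= 0:
            raise ValueError("pathway width must be positive")


@dataclass(frozen=True)
class PatchSpec:
    """A motif patch to be placed when a context activates it."""

    center: tuple[float, float]
    p: float
    radius: float = 6.0
    n_rec: int = 40
    seed: int = 0
    scope: str = "ee"


@dataclass(frozen=True)
class TaskSpec:
    """Named pathways, motif patches, detection spots and contexts.

    ``contexts`` maps a context name (e.g. "A", "B", "baseline") to the
    names of the active motif patches; "baseline" is implicitly empty.
    """

    pathways: dict[str, PathwaySpec]
    motif_patches: dict[str, PatchSpec] = dc_field(default_factory=dict)
    spots: dict[str, DetectionSpot] = dc_field(default_factory=dict)
    contexts: dict[str, tuple[str, ...]] = dc_field(default_factory=dict)

    def context_patches(self, context: str) -> list[PatchSpec]:
        if context == "baseline":
            return []
        if context not in self.contexts:
            raise ValueError(f"unknown context {context!r}")
        return [self.motif_patches[name] for name in self.contexts[context]]


def _segment_distance_tangent(
    points: NDArray, a: NDArray, b: NDArray, nrows: int
) -> tuple[NDArray, NDArray]:
    """Toroidal distance from each point to segment a-b, and its tangent angle.

    Valid for segments shorter than half the grid (minimal-image projection).
    """
    seg = toroidal_displacement(a, b, nrows)
    if np.max(np.abs(np.asarray(b) - np.asarray(a))) >= nrows / 2:
        raise ValueError(
            "pathway segments must be shorter than half the grid per axis; "
            "split long pathways into waypoints"
        )
    seg_len2 = float(seg @ seg)
    rel = toroidal_displacement(a, points, nrows)
    tproj = np.clip((rel @ seg) / seg_len2, 0.0, 1.0) if seg_len2 > 0 else 0.0
    closest = np.outer(tproj, seg)
    d = np.sqrt(np.sum((rel - closest) ** 2, axis=1))
    angle = float(np.arctan2(seg[1], seg[0]))
    return d, np.full(points.shape[0], angle)


def compile_task_field(task: TaskSpec, geometry: GridGeometry) -> DirectionField:
    """Write the phi field realizing the task's pathway structure.

    Each on-path neuron points along the tangent of the *nearest* pathway
    segment (toward its next waypoint).  Where pathways overlap — at
    junctions — the nearest segment wins, so a diverging junction produces a
    sharp bifurcation of the direction field along the symmetry axis: a bump
    arriving there is torn toward one branch, and which branch wins is
    decided by the bump's own fluctuations.  Off-path neurons get
    ``shift_scale = 0``: an isotropic kernel, not a random direction.
    """
    pos = geometry.exc_positions
    n = geometry.n_exc
    best_d = np.full(n, np.inf)
    best_angle = np.zeros(n)
    covered = np.zeros(n, dtype=bool)
    for spec in task.pathways.values():
        poly = np.asarray(spec.polyline, dtype=float)
        for k in range(len(poly) - 1):
            d, angle = _segment_distance_tangent(
                pos, poly[k], poly[k + 1], geometry.nrows
            )
            closer = d < best_d
            best_d = np.where(closer, d, best_d)
            best_angle = np.where(closer, angle, best_angle)
            covered |= d <= spec.width
    phi = np.mod(best_angle, 2.0 * np.pi)
    phi[~covered] = 0.0
    shift_scale = covered.astype(float)
    return DirectionField(phi=phi, noise_cells=0, seed=None, shift_scale=shift_scale)


def run_context(
    task: TaskSpec,
    connectome: Connectome,
    context: str,
    sim_config: SimConfig,
    detection: DetectionParams = DetectionParams(),
    neuron_params: NeuronParams = NeuronParams(),
    noise: NoiseParams = NoiseParams(),
    transitions: tuple[tuple[str, str], ...] = (
        ("S", "M1"),
        ("S", "M2"),
        ("S", "L"),
        ("S", "R"),
    ),
) -> dict:
    """Simulate a context and tabulate sequence routing across the task spots.

    Applies the context's patch set to the compiled connectome, runs
    ``sim_config.n_seeds`` noise realizations, detects sequences, and pools
    spot crossings.  Returns the pooled crossing table, per-transition
    ``TransmissionStats`` and a tidy routing table.
    """
    conn = connectome
    for spec in task.context_patches(context):
        patch = make_patch(
            spec.center, spec.radius, spec.n_rec, spec.p,
            connectome.geometry, spec.seed, spec.scope,
        )
        conn = apply_patch(conn, patch)

    spots = list(task.spots.values())
    crossings_by_run: dict[int, pd.DataFrame] = {}
    sequences_by_run: dict[int, list] = {}
    n_sequences = 0
    for k in range(sim_config.n_seeds):
        run_noise = noise.with_seed(noise.seed + k)
        trace = simulate(conn, neuron_params, run_noise, sim_config, record="exc")
        sequences = detect_sequences(trace, detection, connectome.geometry)
        n_sequences += len(sequences)
        sequences_by_run[run_noise.seed] = sequences
        crossings_by_run[run_noise.seed] = spot_crossings(
            sequences, spots, connectome.geometry
        )
    pooled = pool_crossings(crossings_by_run)
    stats = {f"{a}->{b}": transmission(pooled, a, b) for a, b in transitions}
    routing = pd.DataFrame(
        [
            {
                "transition": name,
                "n_pre": s.n_pre,
                "n_post": s.n_post,
                "n_ordered_both": s.n_ordered_both,
                "p": s.p_post_given_pre,
            }
            for name, s in stats.items()
        ]
    )
    return {
        "context": context,
        "crossings": pooled,
        "crossings_by_run": crossings_by_run,
        "sequences_by_run": sequences_by_run,
        "transmission": stats,
        "routing": routing,
        "n_sequences": n_sequences,
    }
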