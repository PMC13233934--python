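"""Local neuromodulation: patches of neurons with rescaled incoming synapses.

A patch is a disk of radius r (default 6 grid points) from which N_rec
(default 40) excitatory neurons are drawn at random; their incoming synaptic
weights are scaled by (1 + p) with p = +/-10% by default, tonically for the
whole simulation.  The default scope scales only incoming
excitatory-to-excitatory synapses; "all" also scales incoming inhibitory
weights.  The non-spatial control applies the same rule to neurons sampled
from the whole excitatory population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .connectivity import Connectome
from .topology import GridGeometry, neurons_in_disk

__all__ = ["Patch", "make_patch", "apply_patch", "apply_nonspatial_control", "SCOPES"]

SCOPES = ("ee", "all")


@dataclass(frozen=True)
class Patch:
    """A disk-shaped modulation site and its selected neurons."""

    center: tuple[float, float]
    radius: float
    n_rec: int
    p: float
    selected: NDArray[np.int64] = field(repr=False)
    seed: int | None = None
    scope: str = "ee"

    def __post_init__(self) -> None:
        if self.p <= -1.0:
            raise ValueError("p must be > -1 (weights cannot flip sign)")
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}; expected one of {SCOPES}")


def make_patch(
    center: tuple[float, float],
    radius: float,
    n_rec: int,
    p: float,
    geometry: GridGeometry,
    seed: int,
    scope: str = "ee",
) -> Patch:
    """Select ``n_rec`` excitatory neurons uniformly from the patch disk."""
    disk = neurons_in_disk(center, radius, geometry, "exc")
    if disk.size < n_rec:
        raise ValueError(
            f"patch disk at {center} radius {radius} holds only {disk.size} "
            f"excitatory neurons, need n_rec={n_rec}"
        )
    rng = np.random.default_rng(seed)
    selected = np.sort(rng.choice(disk, size=n_rec, replace=False))
    return Patch(
        center=tuple(float(c) for c in center),
        radius=float(radius),
        n_rec=int(n_rec),
        p=float(p),
        selected=selected,
        seed=seed,
        scope=scope,
    )


def _scale_incoming(connectome: Connectome, selected: NDArray, p: float, scope: str):
    """Return a weight matrix with selected rows' scoped inputs scaled by 1+p."""
    W = connectome.weights.tocsr(copy=True)
    n_exc = connectome.n_exc
    factor = 1.0 + p
    for row in np.asarray(selected):
        lo, hi = W.indptr[row], W.indptr[row + 1]
        if scope == "all":
            W.data[lo:hi] *= factor
        else:  # excitatory-to-excitatory inputs only
            cols = W.indices[lo:hi]
            W.data[lo:hi][cols < n_exc] *= factor
    return W


def apply_patch(connectome: Connectome, patch: Patch) -> Connectome:
    """Return a modulated copy; the input connectome is untouched."""
    if patch.selected.size and patch.selected.max() >= connectome.n_exc:
        raise ValueError("patch selects neurons outside the excitatory population")
    W = _scale_incoming(connectome, patch.selected, patch.p, patch.scope)
    return connectome.with_weights(W)


def apply_nonspatial_control(
    connectome: Connectome,
    n_rec: int,
    p: float,
    seed: int,
    scope: str = "ee",
) -> tuple[Connectome, NDArray[np.int64]]:
    """Scale incoming weights of ``n_rec`` neurons drawn network-wide.

    Returns the modulated copy and the sampled neuron ids.
    """
    if n_rec > connectome.n_exc:
        raise ValueError("n_rec exceeds the excitatory population size")
    if p <= -1.0:
        raise ValueError("p must be > -1")
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    rng = np.random.default_rng(seed)
    selected = np.sort(rng.choice(connectome.n_exc, size=n_rec, replace=False))
    W = _scale_incoming(connectome, selected, p, scope)
    return connectome.with_weights(W), selected.astype(np.int64)
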