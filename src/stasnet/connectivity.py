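"""Direction fields, anisotropic connectome construction, in-degree landscapes.

Each neuron makes a fixed number of connections whose displacements are drawn
from an isotropic 2D Gaussian — narrow for excitatory axons, broad for
inhibitory ones, which together form a Mexican-hat kernel (local excitation,
long-range inhibition).  Excitatory draws are additionally displaced by
``shift`` grid points along the neuron's preferred direction phi, making the
kernel asymmetric; this asymmetry is what lets activity travel.  The phi field
is sampled from spatially correlated periodic gradient noise, so neighboring
neurons prefer similar directions and anatomical chains (pathways) form.

Connection multiplicities are integers (multiple synapses between a pair are
allowed, self-connections are redrawn), so every neuron's out-degree onto each
population is conserved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numpy.typing import NDArray

from .gradient_noise import periodic_gradient_noise
from .topology import GridGeometry

__all__ = [
    "DirectionField",
    "KernelParams",
    "Connectome",
    "InDegreeDomains",
    "DOMAIN_NAMES",
    "sample_direction_field",
    "uniform_direction_field",
    "build_connectome",
    "in_degree_landscape",
    "classify_domains",
    "connectome_edge_list",
]

DOMAIN_NAMES = ("low", "low-mid", "mid", "mid-high", "high")


@dataclass(frozen=True)
class DirectionField:
    """Preferred projection direction per excitatory neuron.

    ``phi`` is in radians, ``[0, 2 pi)``.  ``shift_scale`` multiplies the
    kernel displacement per neuron: 1 means the full configured shift, 0 means
    no preferred direction (an isotropic kernel), as used by the task-network
    compiler for neurons far from any pathway.
    """

    phi: NDArray[np.float64] = field(repr=False)
    noise_cells: int = 0
    seed: int | None = None
    shift_scale: NDArray[np.float64] | None = field(default=None, repr=False)

    def effective_shift(self, shift: float) -> NDArray[np.float64]:
        scale = self.shift_scale if self.shift_scale is not None else 1.0
        return shift * np.broadcast_to(np.asarray(scale, float), self.phi.shape)


@dataclass(frozen=True)
class KernelParams:
    """Gaussian connectivity-kernel parameters (grid-point units).

    Defaults follow the reference parameter table: sigma_exc = 2.5,
    sigma_inh = 4.5, 3,750 connections onto the excitatory and 938 onto the
    inhibitory population per presynaptic neuron.  ``shift`` is the
    displacement of the excitatory kernel center along phi (default one grid
    spacing).
    """

    sigma_exc: float = 2.5
    sigma_inh: float = 4.5
    shift: float = 1.0
    n_out_exc: int = 3750
    n_out_inh: int = 938

    def __post_init__(self) -> None:
        if self.sigma_exc <= 0 or self.sigma_inh <= 0:
            raise ValueError("kernel sigmas must be positive")
        if self.sigma_inh <= self.sigma_exc:
            raise ValueError(
                "sigma_inh must exceed sigma_exc (Mexican-hat regime): "
                f"{self.sigma_inh} <= {self.sigma_exc}"
            )
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        if self.n_out_exc <= 0 or self.n_out_inh <= 0:
            raise ValueError("out-degrees must be positive")


@dataclass(frozen=True)
class Connectome:
    """Signed weight matrix and synapse multiplicities for a placed network.

    ``multiplicity[post, pre]`` counts synapses k between a pair; weights are
    ``k * J`` for excitatory presynaptic neurons and ``-k * g * J`` for
    inhibitory ones.  Neuron ids: excitatory ``0 .. n_exc-1`` then inhibitory
    ``n_exc .. n_exc+n_inh-1``.
    """

    weights: sp.csr_matrix = field(repr=False)
    multiplicity: sp.csr_matrix = field(repr=False)
    J: float
    g: float
    geometry: GridGeometry
    field: DirectionField = None  # type: ignore[assignment]
    kernel: KernelParams = None  # type: ignore[assignment]
    seed: int | None = None

    @property
    def n_exc(self) -> int:
        return self.geometry.n_exc

    @property
    def n_inh(self) -> int:
        return self.geometry.n_inh

    @property
    def n_total(self) -> int:
        return self.geometry.n_total

    def with_weights(self, weights: sp.csr_matrix) -> "Connectome":
        return replace(self, weights=weights)


def sample_direction_field(
    geometry: GridGeometry, noise_cells: int, seed: int
) -> DirectionField:
    """Sample a spatially correlated preferred-direction field.

    The scalar gradient-noise value at each excitatory position is mapped
    linearly from its observed [min, max] onto [0, 2 pi).  Few cells give
    large coherent direction domains (wide pathways); ``noise_cells == nrows``
    decorrelates neighbors.
    """
    if not 2 <= noise_cells <= geometry.nrows:
        raise ValueError(
            f"noise_cells must be in [2, nrows={geometry.nrows}], got {noise_cells}"
        )
    rng = np.random.default_rng(seed)
    pos = geometry.exc_positions
    values = periodic_gradient_noise(
        pos[:, 0], pos[:, 1], cells=noise_cells, extent=geometry.nrows, rng=rng
    )
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        phi = np.zeros_like(values)
    else:
        phi = (values - lo) / (hi - lo) * 2.0 * np.pi
        phi = np.mod(phi, 2.0 * np.pi)
    return DirectionField(phi=phi, noise_cells=noise_cells, seed=seed)


def uniform_direction_field(geometry: GridGeometry, angle: float = 0.0) -> DirectionField:
    """All neurons share one preferred direction (handy for controls/tests)."""
    return DirectionField(phi=np.full(geometry.n_exc, float(angle)), noise_cells=0)


def _snap_exc(points: NDArray, nrows: int) -> NDArray[np.int64]:
    ix = np.rint(points[..., 0]).astype(np.int64) % nrows
    iy = np.rint(points[..., 1]).astype(np.int64) % nrows
    return iy * nrows + ix


def _snap_inh(points: NDArray, nrows: int) -> NDArray[np.int64]:
    half = nrows // 2
    ix = np.rint((points[..., 0] - 0.5) / 2.0).astype(np.int64) % half
    iy = np.rint((points[..., 1] - 0.5) / 2.0).astype(np.int64) % half
    return iy * half + ix


def _draw_target_ids(
    centers: NDArray,
    sigma: float,
    n_draws: int,
    nrows: int,
    target: str,
    rng: np.random.Generator,
    self_ids: NDArray | None,
) -> NDArray[np.int64]:
    """Draw ``n_draws`` snapped target ids per row of ``centers``.

    Self-connection draws (where the snapped target equals ``self_ids``) are
    redrawn, preserving the exact out-degree.
    """
    n_pre = centers.shape[0]
    pts = centers[:, None, :] + rng.normal(0.0, sigma, size=(n_pre, n_draws, 2))
    snap = _snap_exc if target == "exc" else _snap_inh
    ids = snap(pts, nrows)
    if self_ids is not None:
        bad = ids == self_ids[:, None]
        while np.any(bad):
            rows, cols = np.nonzero(bad)
            pts = centers[rows] + rng.normal(0.0, sigma, size=(rows.size, 2))
            ids[rows, cols] = snap(pts, nrows)
            bad = ids == self_ids[:, None]
    return ids


def build_connectome(
    geometry: GridGeometry,
    direction_field: DirectionField,
    kernel: KernelParams,
    J: float,
    g: float,
    seed: int,
    chunk_size: int = 512,
) -> Connectome:
    """Construct the anisotropic connectome.

    For every presynaptic neuron, target displacements are Gaussian
    (``sigma_exc`` for excitatory, ``sigma_inh`` for inhibitory presynaptic
    neurons).  Excitatory draws are centered ``shift`` grid points along the
    neuron's phi (both its E and I projections); inhibitory projections are
    isotropic and unshifted.  Draws snap to the nearest lattice site of the
    target population with toroidal wrap-around.

    Out-degrees are conserved exactly: every neuron ends up with
    ``n_out_exc`` synapses onto the excitatory and ``n_out_inh`` onto the
    inhibitory population (summed multiplicities).
    """
    if J <= 0 or g <= 0:
        raise ValueError("J and g must be positive")
    if direction_field.phi.shape[0] != geometry.n_exc:
        raise ValueError("direction field size does not match geometry")
    rng = np.random.default_rng(seed)
    nrows = geometry.nrows
    n_exc, n_inh, n_total = geometry.n_exc, geometry.n_inh, geometry.n_total

    shift = direction_field.effective_shift(kernel.shift)
    offsets = np.column_stack(
        [shift * np.cos(direction_field.phi), shift * np.sin(direction_field.phi)]
    )
    exc_centers = geometry.exc_positions + offsets
    inh_centers = geometry.inh_positions

    keys: list[NDArray] = []
    counts: list[NDArray] = []

    def accumulate(pre_global: NDArray, target_ids: NDArray, target_offset: int) -> None:
        flat = (target_ids + target_offset) * np.int64(n_total) + pre_global[:, None]
        uniq, cnt = np.unique(flat.ravel(), return_counts=True)
        keys.append(uniq)
        counts.append(cnt.astype(np.int64))

    # Excitatory presynaptic neurons: shifted kernel, sigma_exc.
    for start in range(0, n_exc, chunk_size):
        stop = min(start + chunk_size, n_exc)
        pre = np.arange(start, stop, dtype=np.int64)
        ids_e = _draw_target_ids(
            exc_centers[start:stop], kernel.sigma_exc, kernel.n_out_exc,
            nrows, "exc", rng, self_ids=pre,
        )
        accumulate(pre, ids_e, 0)
        ids_i = _draw_target_ids(
            exc_centers[start:stop], kernel.sigma_exc, kernel.n_out_inh,
            nrows, "inh", rng, self_ids=None,
        )
        accumulate(pre, ids_i, n_exc)

    # Inhibitory presynaptic neurons: isotropic kernel, sigma_inh.
    for start in range(0, n_inh, chunk_size):
        stop = min(start + chunk_size, n_inh)
        pre_local = np.arange(start, stop, dtype=np.int64)
        pre = pre_local + n_exc
        ids_e = _draw_target_ids(
            inh_centers[start:stop], kernel.sigma_inh, kernel.n_out_exc,
            nrows, "exc", rng, self_ids=None,
        )
        accumulate(pre, ids_e, 0)
        ids_i = _draw_target_ids(
            inh_centers[start:stop], kernel.sigma_inh, kernel.n_out_inh,
            nrows, "inh", rng, self_ids=pre_local,
        )
        accumulate(pre, ids_i, n_exc)

    all_keys = np.concatenate(keys)
    all_counts = np.concatenate(counts)
    post = all_keys // n_total
    pre_idx = all_keys % n_total
    multiplicity = sp.coo_matrix(
        (all_counts, (post, pre_idx)), shape=(n_total, n_total), dtype=np.int64
    ).tocsr()
    multiplicity.sum_duplicates()

    # scale CSR data in place so weights share multiplicity's exact structure
    weights = multiplicity.astype(np.float64)
    weights.data *= np.where(weights.indices < n_exc, J, -g * J)

    return Connectome(
        weights=weights,
        multiplicity=multiplicity,
        J=J,
        g=g,
        geometry=geometry,
        field=direction_field,
        kernel=kernel,
        seed=seed,
    )


def in_degree_landscape(connectome: Connectome) -> NDArray[np.float64]:
    """J-weighted excitatory-to-excitatory in-degree per excitatory neuron.

    Inhibitory inputs are excluded: they are isotropic and act only as an
    offset, so the E-to-E mass alone carries the spatial structure.
    """
    n_exc = connectome.n_exc
    block = connectome.multiplicity[:n_exc, :n_exc]
    return np.asarray(block.sum(axis=1)).ravel() * connectome.J


@dataclass(frozen=True)
class InDegreeDomains:
    """Five equal-width in-degree domains: low .. high.

    ``bin_edges`` holds the 6 edges spanning the classification range;
    ``labels`` holds a domain index 0..4 per neuron (see ``DOMAIN_NAMES``).
    """

    in_degree: NDArray[np.float64] = field(repr=False)
    labels: NDArray[np.int64] = field(repr=False)
    bin_edges: NDArray[np.float64]
    clip_percentiles: tuple[float, float] | None = None

    def domain_name(self, neuron: int) -> str:
        return DOMAIN_NAMES[self.labels[neuron]]


def classify_domains(
    in_degree: NDArray,
    clip: tuple[float, float] | None = None,
) -> InDegreeDomains:
    """Label each neuron with one of five equal-width in-degree domains.

    With ``clip`` (e.g. ``(2.5, 97.5)``) the range is the given percentile
    span and out-of-range values fall into the extreme bins, so a handful of
    outliers cannot squeeze the interior domains.
    """
    values = np.asarray(in_degree, dtype=float)
    if values.size == 0:
        raise ValueError("in_degree must be nonempty")
    if clip is None:
        lo, hi = float(values.min()), float(values.max())
    else:
        lo, hi = (float(v) for v in np.percentile(values, clip))
    if hi <= lo:
        warnings.warn("constant in-degree field: degenerate single-bin labeling")
        edges = np.full(6, lo)
        labels = np.zeros(values.size, dtype=np.int64)
        return InDegreeDomains(values, labels, edges, clip)
    edges = np.linspace(lo, hi, 6)
    labels = np.clip(np.digitize(values, edges[1:-1]), 0, 4).astype(np.int64)
    return InDegreeDomains(values, labels, edges, clip)


def connectome_edge_list(connectome: Connectome) -> pd.DataFrame:
    """Plain edge list (pre, post, k, w) for interoperability exports."""
    coo = connectome.multiplicity.tocoo()
    w = connectome.weights.tocoo()
    return pd.DataFrame(
        {"pre": coo.col, "post": coo.row, "k": coo.data, "w": w.data}
    ).sort_values(["pre", "post"], ignore_index=True)
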