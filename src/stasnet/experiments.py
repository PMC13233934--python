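"""Reproducible experiment runner: configs, named RNG streams, persistence.

Every source of randomness draws from its own named stream derived from a
single master seed (connectivity, direction field, per-run external noise,
patch selection), so the connectivity can stay fixed while the external noise
is resampled across runs, exactly and reproducibly.  An experiment executes
build -> simulate (one run per noise seed) -> detect -> analyze, persists its
artifacts in one HDF5 container stamped with the config hash, and skips
stages that are already present when resumed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .connectivity import (
    Connectome,
    DirectionField,
    KernelParams,
    build_connectome,
    classify_domains,
    in_degree_landscape,
    sample_direction_field,
)
from .dynamics import NeuronParams, NoiseParams, SimConfig, simulate
from .landscape_merge_tree import build_max_tree, extract_bridges, merge_statistics
from .modulation import apply_patch, make_patch
from .sequence_detection import (
    DetectionParams,
    cluster_toroidal,
    detect_sequences,
    filter_sequences,
    is_static_bump_run,
    run_summary,
    sequence_landscape,
    threshold_to_pseudospikes,
)
from .task_network import PatchSpec
from .topology import build_grid

__all__ = [
    "NetworkConfig",
    "ExperimentConfig",
    "stream_seed",
    "build_network",
    "run_experiment",
    "load_config",
]

REFERENCE_NROWS = 100


def stream_seed(master_seed: int, label: str, index: int = 0) -> int:
    """Derive an independent, stable seed from a master seed and a label."""
    h = zlib.crc32(f"{label}:{index}".encode())
    ss = np.random.SeedSequence([int(master_seed), int(h)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class NetworkConfig:
    """Network block: grid, direction field and kernel parameters.

    Defaults are the reference full-scale values (100x100 grid, 3,750 / 938
    out-degrees, J = 0.275, g = 8).  ``scaled`` builds a reduced grid whose
    out-degrees shrink with the area ratio while J grows by its inverse, so
    the per-neuron synaptic input mass — and with it the operating point of
    the fixed sigmoid — is preserved.
    """

    nrows: int = 100
    noise_cells: int = 10
    sigma_exc: float = 2.5
    sigma_inh: float = 4.5
    shift: float = 1.0
    n_out_exc: int = 3750
    n_out_inh: int = 938
    J: float = 0.275
    g: float = 8.0

    @classmethod
    def scaled(cls, nrows: int, **overrides) -> "NetworkConfig":
        ratio = (nrows / REFERENCE_NROWS) ** 2
        defaults = dict(
            nrows=nrows,
            noise_cells=max(2, round(nrows / 10)),
            n_out_exc=max(1, round(3750 * ratio)),
            n_out_inh=max(1, round(938 * ratio)),
            J=0.275 / ratio,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def kernel(self) -> KernelParams:
        return KernelParams(
            sigma_exc=self.sigma_exc,
            sigma_inh=self.sigma_inh,
            shift=self.shift,
            n_out_exc=self.n_out_exc,
            n_out_inh=self.n_out_inh,
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment description; all defaults follow the reference table."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    noise_mu: float = 0.0
    noise_sigma: float = 30.0
    sim: SimConfig = field(default_factory=SimConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    patches: tuple[PatchSpec, ...] = ()
    master_seed: int = 0
    store_traces: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an ExperimentConfig from a YAML file of nested blocks."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "network" in raw:
        net = dict(raw["network"])
        if net.pop("scaled", False):
            kwargs["network"] = NetworkConfig.scaled(**net)
        else:
            kwargs["network"] = NetworkConfig(**net)
    if "neuron" in raw:
        kwargs["neuron"] = NeuronParams(**raw["neuron"])
    if "sim" in raw:
        kwargs["sim"] = SimConfig(**raw["sim"])
    if "detection" in raw:
        kwargs["detection"] = DetectionParams(**raw["detection"])
    if "patches" in raw:
        kwargs["patches"] = tuple(PatchSpec(**p) for p in raw["patches"])
    for key in ("noise_mu", "noise_sigma", "master_seed", "store_traces"):
        if key in raw:
            kwargs[key] = raw[key]
    return ExperimentConfig(**kwargs)


def build_network(config: ExperimentConfig) -> Connectome:
    """Grid, direction field and connectome from the network block."""
    geometry = build_grid(config.network.nrows)
    field_ = sample_direction_field(
        geometry,
        config.network.noise_cells,
        seed=stream_seed(config.master_seed, "direction_field"),
    )
    return build_connectome(
        geometry,
        field_,
        config.network.kernel(),
        J=config.network.J,
        g=config.network.g,
        seed=stream_seed(config.master_seed, "connectivity"),
    )


def _save_sparse(group: h5py.Group, name: str, matrix: sp.csr_matrix) -> None:
    g = group.create_group(name)
    g.create_dataset("data", data=matrix.data)
    g.create_dataset("indices", data=matrix.indices)
    g.create_dataset("indptr", data=matrix.indptr)
    g.attrs["shape"] = matrix.shape


def _load_sparse(group: h5py.Group, name: str) -> sp.csr_matrix:
    g = group[name]
    return sp.csr_matrix(
        (g["data"][...], g["indices"][...], g["indptr"][...]),
        shape=tuple(g.attrs["shape"]),
    )


def run_experiment(config: ExperimentConfig, out_path: str | Path) -> dict:
    """Execute build -> simulate -> detect -> analyze, persisting each stage.

    Artifacts land in one HDF5 file stamped with the config hash; a rerun
    with the same config resumes after the last completed stage, a rerun
    with a different config aborts.  Returns a bundle with the connectome,
    per-run sequence summaries, the sequence landscape and the merge report.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    with h5py.File(out_path, "a") as f:
        if "config_hash" in f.attrs:
            if f.attrs["config_hash"] != chash:
                raise ValueError(
                    f"config hash mismatch: file has {f.attrs['config_hash']}, "
                    f"config is {chash}"
                )
        else:
            f.attrs["config_hash"] = chash
            f.attrs["config_json"] = json.dumps(
                dataclasses.asdict(config), default=str
            )

        geometry = build_grid(config.network.nrows)
        if "connectome" not in f:
            connectome = build_network(config)
            _save_sparse(f, "connectome", connectome.multiplicity)
            f["connectome"].attrs["J"] = config.network.J
            f["connectome"].attrs["g"] = config.network.g
            f["connectome"].attrs["phi"] = connectome.field.phi
        else:
            multiplicity = _load_sparse(f, "connectome")
            n_exc = geometry.n_exc
            weights = multiplicity.astype(np.float64)
            weights.data *= np.where(
                weights.indices < n_exc, config.network.J, -config.network.g * config.network.J
            )
            connectome = Connectome(
                weights=weights,
                multiplicity=multiplicity,
                J=config.network.J,
                g=config.network.g,
                geometry=geometry,
                field=DirectionField(
                    phi=f["connectome"].attrs["phi"],
                    noise_cells=config.network.noise_cells,
                ),
                kernel=config.network.kernel(),
            )

        modulated = connectome
        for k, spec in enumerate(config.patches):
            patch = make_patch(
                spec.center, spec.radius, spec.n_rec, spec.p, geometry,
                seed=stream_seed(config.master_seed, "patch", k), scope=spec.scope,
            )
            modulated = apply_patch(modulated, patch)

        runs = []
        all_sequences = []
        excluded_runs = []
        seq_grp = f.require_group("sequences")
        for k in range(config.sim.n_seeds):
            key = f"seed_{k}"
            noise_seed = stream_seed(config.master_seed, "external_noise", k)
            if key in seq_grp:
                ev = seq_grp[key]
                ids = ev["seq_id"][...]
                from .sequence_detection import Sequence

                sequences = [
                    Sequence(
                        id=int(i),
                        x=ev["x"][...][ids == i],
                        y=ev["y"][...][ids == i],
                        t=ev["t"][...][ids == i],
                        neuron=ev["neuron"][...][ids == i],
                        extent=float(ev.attrs[f"extent_{i}"]),
                    )
                    for i in np.unique(ids)
                ]
                excluded = bool(ev.attrs.get("static_bump", False))
            else:
                trace = simulate(
                    modulated,
                    config.neuron,
                    NoiseParams(config.noise_mu, config.noise_sigma, seed=noise_seed),
                    config.sim,
                    record="exc",
                )
                cloud = threshold_to_pseudospikes(
                    trace, config.detection.theta, geometry
                )
                prefilter = cluster_toroidal(cloud, config.detection, geometry)
                excluded = is_static_bump_run(prefilter, config.sim.t_sim)
                sequences = filter_sequences(prefilter, config.detection, geometry)
                ev = seq_grp.create_group(key)
                ids = np.concatenate(
                    [np.full(s.x.size, s.id) for s in sequences]
                ) if sequences else np.empty(0, int)
                for col, vals in (
                    ("x", [s.x for s in sequences]),
                    ("y", [s.y for s in sequences]),
                    ("t", [s.t for s in sequences]),
                    ("neuron", [s.neuron for s in sequences]),
                ):
                    ev.create_dataset(
                        col,
                        data=np.concatenate(vals) if vals else np.empty(0),
                    )
                ev.create_dataset("seq_id", data=ids)
                for s in sequences:
                    ev.attrs[f"extent_{s.id}"] = s.extent
                ev.attrs["static_bump"] = excluded
                ev.attrs["noise_seed"] = noise_seed
                if config.store_traces:
                    f.require_group("traces").create_dataset(
                        key, data=trace.rates, compression="gzip"
                    )
            if excluded:
                excluded_runs.append(k)
            runs.append(run_summary(sequences, seed=noise_seed))
            all_sequences.append(sequences)

        landscape = sum(
            (sequence_landscape(seqs, geometry) for seqs in all_sequences),
            np.zeros(geometry.n_exc, dtype=np.int64),
        )
        if "landscape" not in f:
            f.create_dataset("landscape", data=landscape)
        tree = build_max_tree(landscape, geometry)
        bridges = extract_bridges(tree, landscape, geometry)
        if "merges" not in f and tree.n_merges:
            g = f.create_group("merges")
            g.create_dataset(
                "thresholds", data=np.array([m.threshold for m in tree.merges])
            )
            g.create_dataset(
                "bridge_sizes", data=np.array([b.neurons.size for b in bridges])
            )

    in_deg = in_degree_landscape(connectome)
    return {
        "connectome": connectome,
        "runs": pd.DataFrame(runs),
        "sequences": all_sequences,
        "landscape": landscape,
        "merge_tree": tree,
        "bridges": bridges,
        "in_degree": in_deg,
        "domains": classify_domains(in_deg, clip=(2.5, 97.5)),
        "excluded_runs": excluded_runs,
        "config_hash": chash,
    }
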