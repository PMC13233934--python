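"""Shared fixtures: a desk-scale random network, its baseline runs, and the
designed motif circuits.  Simulation-backed fixtures are session-scoped —
they are the expensive part of the suite and several test modules read them.

Desk scale is a 40x40 torus with out-degrees scaled by the area ratio and J
scaled by its inverse, which preserves the per-neuron synaptic input mass of
the full-scale parameter table.
"""

from __future__ import annotations

import numpy as np
import pytest

import stasnet as sn
from stasnet import fixtures as fx
from stasnet.experiments import NetworkConfig
from stasnet.task_network import compile_task_field, run_context

NROWS = 40
T_SIM = 3000.0


@pytest.fixture(scope="session")
def geometry40():
    return sn.build_grid(NROWS)


@pytest.fixture(scope="session")
def scaled_net():
    return NetworkConfig.scaled(NROWS)


@pytest.fixture(scope="session")
def random_network(geometry40, scaled_net):
    """Gradient-noise direction field, fixed connectivity seed."""
    field = sn.sample_direction_field(geometry40, scaled_net.noise_cells, seed=1)
    return sn.build_connectome(
        geometry40, field, scaled_net.kernel(), scaled_net.J, scaled_net.g, seed=2
    )


@pytest.fixture(scope="session")
def baseline_runs(random_network, geometry40):
    """Four noise realizations of the unmodulated desk-scale network."""
    params = sn.DetectionParams()
    runs = []
    for seed in range(4):
        trace = sn.simulate(
            random_network,
            sn.NeuronParams(),
            sn.NoiseParams(seed=seed),
            sn.SimConfig(t_sim=T_SIM, t_warmup=400.0),
            record="exc",
        )
        cloud = sn.threshold_to_pseudospikes(trace, params.theta, geometry40)
        prefilter = sn.cluster_toroidal(cloud, params, geometry40)
        sequences = sn.filter_sequences(prefilter, params, geometry40)
        runs.append(
            {
                "seed": seed,
                "trace": trace,
                "prefilter": prefilter,
                "sequences": sequences,
            }
        )
    return runs


def _bundle(spec, connectivity_seed, contexts, transitions, n_seeds=4):
    net = NetworkConfig.scaled(NROWS)
    geometry = sn.build_grid(NROWS)
    conn = sn.build_connectome(
        geometry,
        compile_task_field(spec, geometry),
        net.kernel(),
        net.J,
        net.g,
        seed=connectivity_seed,
    )
    out = {"spec": spec, "geometry": geometry}
    for ctx, seeds in contexts:
        out[ctx] = run_context(
            spec,
            conn,
            ctx,
            sn.SimConfig(t_sim=T_SIM, t_warmup=400.0, n_seeds=seeds),
            transitions=transitions,
        )
    return out


@pytest.fixture(scope="session")
def line_bundle():
    """Gapped straight pathway: Starter, Repeat, Stop, Anti-Repeat."""
    return _bundle(
        fx.gapped_line_task(),
        connectivity_seed=7,
        contexts=[(c, 4) for c in ("baseline", "start", "repeat", "stop", "anti")],
        transitions=(("pre", "post"),),
    )


@pytest.fixture(scope="session")
def select_bundle():
    """Diverging Y junction: Select motif."""
    return _bundle(
        fx.diverging_y_task(),
        connectivity_seed=7,
        contexts=[(c, 4) for c in ("baseline", "select_b2", "deselect_b2")],
        transitions=(("M", "B1"), ("M", "B2")),
    )


@pytest.fixture(scope="session")
def gate_bundle():
    """Converging Y junction: Gate motif and branch competition."""
    return _bundle(
        fx.converging_y_task(),
        connectivity_seed=10,
        contexts=[
            (c, 6)
            for c in ("baseline", "gate_weaken_b1", "gate_strengthen_b1")
        ],
        transitions=(("B1", "M"), ("B2", "M")),
    )


@pytest.fixture(scope="session")
def context_bundle():
    """Context-reversal circuit: contexts A (Left) and B (Right)."""
    return _bundle(
        fx.context_reversal_task(),
        connectivity_seed=7,
        contexts=[("baseline", 4), ("A", 8), ("B", 8)],
        transitions=(("S", "M1"), ("S", "M2"), ("S", "L"), ("S", "R")),
    )


@pytest.fixture(scope="session")
def tiny_connectome():
    """A small (8x8) connectome for dense-oracle comparisons."""
    geometry = sn.build_grid(8)
    field = sn.sample_direction_field(geometry, 4, seed=3)
    kernel = sn.KernelParams(n_out_exc=24, n_out_inh=6)
    return sn.build_connectome(geometry, field, kernel, J=1.0, g=8.0, seed=4)
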