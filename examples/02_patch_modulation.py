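"""Modulate a local patch of neurons and measure the network-wide effect.

Scales the incoming excitatory-to-excitatory weights of 40 neurons inside a
radius-6 disk by +10% and compares sequence counts and durations against the
unmodulated baseline over matched noise seeds.
"""

import pandas as pd

import stasnet as sn
from stasnet.experiments import NetworkConfig
from stasnet.sequence_detection import run_summary

net = NetworkConfig.scaled(40)
geometry = sn.build_grid(40)
field = sn.sample_direction_field(geometry, net.noise_cells, seed=1)
connectome = sn.build_connectome(geometry, field, net.kernel(), net.J, net.g, seed=2)

patch = sn.make_patch(
    center=(20.0, 20.0), radius=6.0, n_rec=40, p=0.10, geometry=geometry, seed=3
)
print(f"patch: {patch.n_rec} of {sn.neurons_in_disk(patch.center, patch.radius, geometry).size} "
      f"disk neurons, incoming E->E weights x{1 + patch.p:.2f}")
modulated = sn.apply_patch(connectome, patch)


def runs(conn):
    rows = []
    for seed in range(4):
        trace = sn.simulate(
            conn, sn.NeuronParams(), sn.NoiseParams(seed=seed),
            sn.SimConfig(t_sim=2000.0, t_warmup=400.0), record="exc",
        )
        rows.append(run_summary(
            sn.detect_sequences(trace, sn.DetectionParams(), geometry), seed=seed
        ))
    return pd.DataFrame(rows)


effect = sn.network_effect_summary(runs(connectome), runs(modulated))
print(f"delta sequence count: {effect['delta_count_mean']:+.2f} "
      f"+/- {effect['delta_count_sem']:.2f} (SEM over noise seeds)")
print(f"delta mean duration:  {effect['delta_duration_mean']:+.1f} "
      f"+/- {effect['delta_duration_sem']:.1f} ms")
# Positive modulation typically raises counts and/or lengthens sequences;
# the size of the effect depends strongly on the patch location's in-degree.
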