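# stasnet

Rate-network simulation and analysis of **spatio-temporal activity
sequences (STAS)** on a toroidal grid, and of their control by small local
synaptic changes.

Cortical activity often unfolds as sequences — clusters of elevated firing
that travel across a network.  `stasnet` implements a network of sigmoidal
rate neurons placed on a torus with an anisotropic Mexican-hat connectivity:
each excitatory neuron's Gaussian projection kernel is displaced along a
preferred direction φ sampled from spatially correlated gradient noise.
Traveling bumps of excitation, trailed by an inhibitory "shadow", propagate
along anatomical pathways formed by aligned φ's.  The package then asks a
control question: how much leverage does a *patch* — a disk of ~40 neurons
whose incoming synaptic weights are scaled by ±10%, mimicking local
neuromodulator release — have over network-wide sequence traffic?

It is a library for computational neuroscientists studying sequence
propagation, neuromodulation and routing in spatially structured circuits.

## Model

Each neuron obeys

    τ_M dr/dt = −r + Φ(I),     Φ(I) = 1 / (1 + exp(β (I₀ − I))),
    I_post = Σ_pre w_post,pre · r_pre − I_ext,

with `w = k·J` (excitatory presynaptic) or `−k·g·J` (inhibitory), k the
integer synapse multiplicity.  Reference parameters: 100×100 grid
(10,000 E + 2,500 I), out-degrees 3,750 / 938, J = 0.275, g = 8, τ_M = 12 ms,
β = 0.25, I₀ = 50, σ_ext = 30, forward Euler at dt = 1 ms.  Analyses:

- **Detection** — rates are thresholded (Θ = 0.4) into pseudo-spikes and
  clustered with a seam-safe DBSCAN (ε = 4, min_samples = 50, run twice with
  a half-grid shift and merged); clusters traversing ≥ 8 grid points are
  sequences.
- **Merge trees** — per-neuron sequence-participation counts form a
  landscape; a descending max-tree sweep finds where reliable pathways merge
  across low-count saddles, whose cells are the *semi-transmissive* neurons.
- **Motifs** — Start, Repeat/Stop, Anti-Repeat, Select and Gate patches are
  quantified through spot-crossing counts and conditional transmission
  probabilities P(post|pre), P(pre|post) pooled across noise seeds.
- **Task circuits** — direction fields compiled from named pathway polylines
  realize designed circuits, up to a context-reversal task routing sequences
  Left or Right by swapping one Select patch.

See `docs/methods.md` for modeling decisions (noise model, scaling rules,
fixture geometry) and known limitations.

## Worked example

`examples/01_build_and_simulate.py` builds a desk-scale (40×40) network —
out-degrees scaled by the area ratio, J by its inverse, preserving the
per-neuron input mass — simulates 4 s and detects sequences:

```text
network: 1600 excitatory + 400 inhibitory neurons
E->E in-degree: mean 1031, std 134
mean rate 0.0252, mean recurrent input -29.8 (negative: inhibition dominated)
99 sequences in 4 s; median duration 35 ms, median extent 10.2 grid points
```

The in-degree mean 1031 = 600 × 1.71875 matches the full-scale
3,750 × 0.275; the negative mean recurrent input shows the
inhibition-stabilized operating point; the ~100 detected sequences are
traveling clusters, each covering ~10 grid points in a few tens of ms.

The other examples follow the analysis chain: `02_patch_modulation.py`
(±10% patch vs baseline, Δcount and Δduration with SEM),
`03_merge_tree_bridges.py` (merge tree and semi-transmissive neurons),
`04_motif_transmission.py` (Repeat/Stop on a designed unreliable gap),
`05_context_reversal.py` (Left/Right routing reversal).  Each prints what
it computes and a line on what the numbers mean.

There is also a thin CLI over the experiment runner (`stasnet build`,
`simulate`, `detect`, `merges`, `motifs`, `task`, `report`, `fixtures`)
driven by YAML configs; every random draw comes from a named stream derived
from one master seed, and artifacts are persisted in a single HDF5 file per
experiment with a config hash for resumability.

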