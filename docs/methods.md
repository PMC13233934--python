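# Methods

## Model

The network is a firing-rate model on a square lattice with periodic
boundaries (a torus, to avoid boundary effects).  Excitatory neurons occupy
the integer lattice (`nrows**2` of them); inhibitory neurons sit on a
twice-coarser lattice offset by half a spacing, each equidistant from the
four excitatory neurons around it (`nrows**2 / 4`, a 4:1 ratio).  Every
neuron is a sigmoidal rate unit

    tau_M dr/dt = -r + Phi(I),      Phi(I) = 1 / (1 + exp(beta (I0 - I))),

with total input `I_post = sum_pre w_post,pre r_pre - I_ext`.  Rates live in
[0, 1]; `Phi(I0) = 1/2` defines the half-activation point.

Connectivity is distance-dependent and anisotropic.  Each neuron forms a
fixed number of synapses onto the excitatory population (`n_out_exc`) and
onto the inhibitory population (`n_out_inh`); target displacements are drawn
from an isotropic 2D Gaussian whose spread depends on the presynaptic type
(`sigma_exc` narrow, `sigma_inh` broad — together a Mexican-hat kernel).
Multiple synapses between a pair are allowed (integer multiplicities k);
self-connections are redrawn, so out-degrees are conserved exactly.  Weights
are `k*J` for excitatory and `-k*g*J` for inhibitory presynaptic neurons.
Excitatory kernels are displaced by `shift` grid points along the neuron's
preferred direction phi; inhibitory projections are isotropic.  The phi field
is sampled from periodic gradient noise whose cell count sets the correlation
length, so neighboring neurons prefer similar directions and anatomical
chains ("pathways") form.  This displacement gives a traveling excitation
bump a trailing inhibitory "shadow", the substrate of sequence motion and
competition.

Reference (full-scale) parameters: `nrows = 100` (10,000 E + 2,500 I
neurons), `I0 = 50`, `beta = 0.25`, `tau_M = 12 ms`, `J = 0.275`, `g = 8`,
`mu_ext = 0`, `sigma_ext = 30`, `t_sim = 4000 ms`, `t_warmup = 400 ms`,
`dt = 1 ms`, `sigma_exc = 2.5`, `sigma_inh = 4.5`, out-degrees 3,750 (onto E)
and 938 (onto I).

## External drive

The drive is Gaussian, mean `mu_ext`, standard deviation `sigma_ext`,
sampled independently for every neuron.  Its temporal structure is a
configuration choice (`NoiseParams.mode`):

- `"ou"` (default): an AR(1)/Ornstein–Uhlenbeck process with stationary
  standard deviation `sigma_ext` and correlation time `tau_noise = 10 ms` —
  a band-limited approximation of white noise.
- `"white"`: one i.i.d. draw per neuron per step (optionally sqrt(dt)
  scaled).
- `"quenched"`: one frozen draw per neuron per run.

The correlated default is a deliberate modeling decision.  With strictly
per-step white noise at `sigma_ext = 30`, the membrane time constant
averages ~12 draws, the effective fluctuation reaching the sigmoid is far
below the `I0 = 50` activation threshold, and the network stays silent: we
measured 9 isolated threshold crossings and zero sequences in a full-scale
4 s run.  Excursions must persist on the order of `tau_M` to nucleate
collective activity.  With `tau_noise = 10 ms` the same `sigma_ext` produces
hundreds of traveling sequences per 4 s, an inhibition-dominated mean
recurrent input, and stochastic transmission along pathways — the regime all
analyses in this package assume.  A frozen drive also ignites the network
but makes the dynamics near-periodic (the same sequences recur), which
defeats transmission-probability statistics; it is kept as a control.

## Integration

Forward Euler at `dt = 1 ms`.  With `dt <= tau_M` each step is a convex
combination of the current rate and `Phi(I)`, so rates remain in [0, 1] by
construction.  The state starts at zero (or at a caller-supplied `r0` for
seeded-bump experiments) and the first `t_warmup` is discarded.  The
simulator records the time-and-population mean of the recurrent input as a
diagnostic; at the reference parameters it is negative (inhibition
stabilized).

## Scaled-down networks

Tests and examples run mostly on a 40x40 grid (and 24x24 for the widest
parameter sweeps).  Out-degrees scale with the area ratio `(nrows/100)**2`
(600 and 150 at 40x40) and `J` scales with the inverse ratio (1.71875), so
the total synaptic input mass per neuron — and hence the operating point of
the fixed sigmoid — is preserved exactly.  Scaling out-degrees alone would
shrink every synaptic input 6.25-fold and silence the network.  The
gradient-noise cell count scales as `nrows/10`, keeping the pathway
correlation length at ~10 grid points.  Consequences of desk scale: fewer,
shorter sequences (median travel ~10 grid points per sequence at 40x40),
larger synaptic granularity (higher input variance), and stronger
instantiation-to-instantiation variability between connectivity seeds.
Desk-scale results demonstrate mechanisms and directions of effect, not the
full-scale magnitudes.

## Sequence detection

Rates are thresholded at `theta = 0.4` (inclusive) into pseudo-spike events
(x, y, t).  Events are clustered with DBSCAN (`eps = 4`, `min_samples = 50`)
in the mixed (x, y, t) space; time enters in raw ms (`time_scale = 1`,
exposed).  Because Euclidean DBSCAN is blind to the torus seam, the cloud is
clustered twice — once as-is and once shifted by `nrows/2` in both axes —
and clusters sharing at least one event are unioned transitively.  Events
that are noise in both passes are dropped.  The method is exact except for
border events near the isolated points where the original and shifted seam
lines cross, where single events can differ from the full toroidal-metric
clustering; cluster structure is unaffected (verified against a brute-force
toroidal-metric oracle).  Clusters that do not traverse at least
`min_extent = 8` grid points are discarded; the extent is the maximum
pairwise toroidal distance between event sites (the most conservative
reading of "traverse", computed on unique sites).  Runs in which a
pre-filter cluster is spatially confined (< 8 grid points) yet persists for
>= 90% of the simulation are flagged as static-bump runs and excluded from
landscape analyses.

Per-neuron participation counts over a run (or pooled runs) form the
sequence landscape.  Detection spots are radius-2 disks; a sequence crosses
a spot if any participating neuron lies in the disk, and the first-crossing
time is the earliest event time of those neurons.

## Merge trees and semi-transmissive neurons

The sequence landscape is swept with descending integer thresholds;
components are tracked with the toroidal 8-neighborhood (8-connectivity
avoids spurious diagonal splits of narrow pathways).  A merge is recorded at
the highest threshold where two components join whose peaks (local maxima of
the landscape) were born strictly above that threshold — components born at
the join level itself are shoulders, not distinct pathways.  Bridge
(semi-transmissive) neurons for a merge at level theta are the cells of
count theta within `d_max = 4` of both parent components, plus their
8-neighbors within `neighbor_radius = 10` of both.  The implementation is
verified cell-for-cell against a naive per-threshold connected-components
sweep.

## Modulation

A patch is a disk (default radius 6) from which `n_rec = 40` excitatory
neurons are drawn uniformly; their incoming synaptic weights are scaled by
`1 + p` (`p = +/-0.10`) tonically for the whole run.  The default scope
scales only incoming excitatory-to-excitatory weights: the sources describing
the mechanism use E-to-E wording and the in-degree logic is E-to-E, while
"all incoming synapses" appears in the procedural description; both scopes
are implemented (`scope = "ee" | "all"`).  The non-spatial control applies
the same rule to neurons drawn from the whole excitatory population.

## Designed circuits (motif and task fixtures)

Motif analyses need pathways with known geometry, so the direction field can
be compiled from named polyline pathways instead of sampled from noise:
neurons within a pathway's half-width point along the local tangent, and
off-path neurons get a zero kernel shift (isotropic, not random).  Where
pathways overlap, the nearest segment wins.  At a diverging junction this
produces a sharp bifurcation of the field along the symmetry axis: an
arriving bump is torn toward one branch and which branch wins is decided by
the bump's own fluctuations — the stochastic branch choice that the Select
motif biases.  (Blending tangents at junctions was tried first and rejected:
it points bumps into the wedge between branches, where coverage ends and
they die.)

Fixture geometry follows the measured sequence reach at desk scale: spot
separations of ~8 grid points and branch angles of ~27 degrees.  The
fixtures are: a gapped straight pathway (an isotropic gap makes transmission
probabilistic; Starter, Repeat, Stop and Anti-Repeat patches), a diverging Y
(Select), a converging Y (Gate, competition/cooperation), and a
context-reversal circuit (signal pathway -> trunk -> Select junction ->
Left/Right readouts) whose contexts activate the full motif chain: Start and
Repeat patches plus a push-pull Select pair (strengthen the chosen branch
root, weaken the other).  Single-motif patches use the reference
`p = +/-0.10`; the task fixture's Select pair uses `p = +/-0.20`, consistent
with the task circuit's varied (and unprinted) modulation strengths.
Connectivity seeds for the fixtures were chosen once for circuit viability
(both branches able to transmit) and then frozen; which branch a given
instantiation favors varies with the connectivity seed, as it does in the
original full-scale network.

## Transmission statistics and episodes

Conditional transmission `P(post|pre)` is the fraction of sequences crossing
*pre* whose first crossing at *pre* is not later than at *post* ("subsequent
activation"); `P(pre|post)` conditions the same ordered count on *post*.
Counts are pooled across noise seeds before dividing (robust to small
per-seed denominators); per-seed averaging is provided as a cross-check.
Undefined ratios are reported as missing, never as zero.

Branch episodes group sequences whose first crossings at the intersection
spots (M, B1, B2) fall within `t_window = 200 ms` of the earliest one
(disjoint episodes, earliest-anchor rule).  Classification: *cooperation* —
one (merged) sequence crosses B1, B2 and M; *competition* — distinct
sequences cross B1 and B2 with at most one reaching M; *single* — one branch
only.  Events are assigned to branch regions by nearest spot; cooperation
episodes report the first time bin at which the two branch clouds come
within a merge radius, and competition episodes report the time of minimum
summed branch activity between the two branch crossings (descriptive only).

## What the synthetic generators do and do not emulate

Planted event clouds, two-peak landscapes and the designed circuits have
exact ground truth (labels, merge levels, bridge cells, junction layout) and
exercise the detection and analysis machinery under controlled conditions.
They do not emulate full-scale pathway meshes (many interacting pathways,
hundreds of sequences per run), in-degree heterogeneity of natural gradient
fields at 100x100, or any biological irregularity beyond Gaussian
connectivity statistics.  Passing desk-scale tests therefore establishes
mechanisms (signs and orderings of motif effects, oracle-exact analysis
steps), not quantitative full-scale reproduction.

## Numerical choices

- Threshold comparisons are inclusive (`rate >= theta`, closed patch and
  spot disks); a radius-6 closed disk on the integer lattice holds exactly
  113 sites.
- Gradient noise is sampled half a cell off the gradient lattice (gradient
  noise vanishes on its own lattice nodes); values map linearly from their
  observed range to [0, 2 pi).
- Gaussian target draws snap to the nearest lattice site of the target
  population and wrap toroidally; self-connections are redrawn, never
  dropped.
- The sigmoid exponent is clipped at +/-500 to keep extreme inputs finite;
  strict monotonicity holds over the numerically resolvable input range.
- Equal-width in-degree domains (five: low .. high) span [min, max], or the
  2.5th-97.5th percentile span with out-of-range values assigned to the
  extreme bins; a constant landscape degenerates to a single bin with a
  warning.
- Named RNG streams (connectivity, direction field, per-run noise, patch
  selection) derive from one master seed via stable labels, so the
  connectivity can be held fixed while the drive is resampled.

## Known limitations

- Per-step white noise at the reference amplitude cannot ignite the network;
  the OU default is this package's resolution of that underdetermined
  discretization (see External drive).
- The half-grid shift-and-merge detector is not bit-exact under arbitrary
  translations for border events at seam intersections (O(1) events per
  cluster).
- Desk-scale sequence reach (~10 grid points) limits how far apart
  detection spots can meaningfully be placed; end-to-end routing circuits
  must be compact and motif-assisted.
- Branch preference at junctions depends on the connectivity instantiation;
  symmetric constructions are symmetric only in expectation.
- Desk-scale pooled landscapes (few runs, low counts) contain many shallow
  single-sequence peaks, so their merge counts far exceed the ~9 merges per
  network seen on deep full-scale landscapes; desk-scale merge analysis is a
  mechanism check, not a count estimate.
- Pathway polyline segments use the minimal-image metric and must stay
  shorter than half the grid per axis (use intermediate waypoints); designed
  pathways crossing the seam are not supported.
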