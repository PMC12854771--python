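# Methods

This note documents the models implemented in `ionspike`, the defaults
chosen where the design was open, the numerics, and what the synthetic
test beds do and do not establish.

## 1. Permeation counting and single-channel conductance

A trajectory table holds `(time ps, ion, x, y, z)` samples (Å). The pore
is a slab `z_lower < z < z_upper`, optionally with a lateral gate of
radius `r` around the pore axis. Crossings are detected per ion by a
three-state machine over below / inside / above: an up-crossing is a
below → inside → above passage with no intervening return to below and —
when the radius gate is enabled — no lateral excursion beyond `r` while
inside. A lateral excursion voids the transit entirely; a new transit can
begin only after the ion re-touches either side. The z coordinate is
unwrapped across periodic jumps larger than half the box height before
classification. Both the slab-only and the radius-gated dialects of this
criterion are in common use; the gate is configurable and disabled by
setting `radius=None`.

Current uses the **net** signed count, `I = (n_up − n_down)·z·e/T`
(gross counts are reported alongside), and `g = I/V_m`. With 19 net
unit-charge crossings in 500 ns at 600 mV this gives 6.088 pA and
10.147 pS. Block averaging splits the time span into equal blocks
(events assigned by exit time) and reports the mean conductance and its
standard error.

Note that 0.001 µS (1 nS) at a −65 mV driving force corresponds to
−65 pA of synaptic current (1 µS·mV = 1 nA); the package's unit table is
centralised in `ionspike.units`.

## 2. Variant scaling factors

`G = g_MD,variant / g_MD,baseline` with Q586R as baseline. The reporting
view rounds half-away-from-zero to one decimal (3.1, 1.0, 3.5, 28.0, 6.0,
6.0 for the shipped table). The coarse integer factors used in neuronal
runs round to the nearest integer with ties downward, except that the
28-fold factor is taken as 30, reproducing the published integer column.
The shipped table stores the tabulated per-variant averages; a separately
quoted wild-type average of 9.6 pS exists in the source literature, and
the tabulated 10.2 pS is treated as canonical here.

## 3. Compartmental cable solver

Morphologies are trees of tapered cylindrical segments (SWC I/O;
diameter discontinuities such as the soma–dendrite junction are encoded
as zero-length node pairs and merged on read). `discretize` splits each
segment into slices of at most `max_len` µm; frustum slice areas are
exact, and axial conductances use the midpoint-to-midpoint half-resistance
scheme with the exact frustum integral `R = r_a·l/(π r_p r_d)`.

Membrane dynamics: leak plus classic squid-axon Hodgkin–Huxley Na/K
currents (modern voltage convention, resting ≈ −65 mV), with per-region
maximal conductances (default: active soma at 0.12 / 0.036 S cm⁻²,
passive dendrites, leak 3·10⁻⁴ S cm⁻² at −54.387 mV, c_m = 1 µF cm⁻²,
r_a = 150 Ω cm, v_init = −65 mV). Rates scale as
`q10^((T − T_base)/10)` with q10 = 3; the library default references the
classic rates at T_base = 6.3 °C, while the coupled patch/neuron studies
reference them at 30 °C so the 20–40 °C scans bracket the reference
temperature instead of sitting far above it (classic kinetics run ~40×
faster at 40 °C referenced to 6.3 °C and lose excitability — heat block —
which would make a temperature scan vacuous).

Integration is backward Euler (default dt = 0.025 ms): gate variables
advance first by exponential integration at the current voltage, then the
voltage system — linear once conductances are frozen — is solved exactly
by Hines-ordered elimination on the tree. This is unconditionally stable
for stiff spikes and first-order accurate; the RC and steady-cable tests
verify 0.036 mV and <1 % agreement with closed forms at the default step.
Synaptic conductances are integrated implicitly through two auxiliary
exponential states per synapse, with events delivered at the end of the
step in which they occur.

Spike detection: upward crossings of −20 mV with a 2 ms refractory
window (both configurable). The biological initiation range (−53 to
−45 mV) is not used as the counting criterion because shoulder noise
there double-counts spikes.

## 4. Synaptic pipeline

Synaptic conductance is a peak-normalised double exponential: a single
event peaks at exactly `G·weight` at
`t_peak = τ_r τ_d/(τ_d−τ_r)·ln(τ_d/τ_r)`; events superpose linearly and
`G` multiplies the whole profile. Defaults τ_rise = 0.2 ms,
τ_decay = 1.7 ms (typical fast excitatory kinetics; configurable so
measured values can be dropped in), reversal E = 0 mV, so synaptic
current `g·(V_m − E)` is depolarising at rest.

Placement operates on the discretised dendritic compartments:
*localized* picks a random dendritic compartment as centre and samples 10
compartments within a 50 µm sphere (retrying with a new centre, and
permitting repeated compartments only on cells with fewer compartments
than synapses); *distributed* samples uniformly over all dendritic
compartments. Input is homogeneous Poisson at 10 Hz per synapse;
*correlated* input shares one identical train across synapses,
*uncorrelated* input draws independent trains.

**Weight calibration.** A literature value of 1.5 µS for the synaptic
weight is meaningful only for the specific large reconstructed cell it
was used with; on any other morphology the interpretable protocol is the
one that value implemented: choose the largest weight at which the
baseline variant under uncorrelated 10 Hz input fires no spikes, verified
to fire when scaled by a probe factor (default 30). `calibrate_baseline_weight`
finds this threshold baseline by geometric bisection to 5 % tolerance.

**Synthetic morphology.** The default random tree emulates a pyramidal
dendritic arbor at desk scale: a trunk and five branching levels
(deterministic bifurcation for the first two), segment lengths
80–150 µm, diameters tapering from 2.0 µm by 0.85 per level (floor
0.5 µm), ~50 dendritic segments spanning ~600–700 µm, on a 20 µm
cylindrical soma whose lateral area equals the equal-diameter sphere.
The size matters scientifically: on a cell this large, a single synaptic
event — even at 30-fold conductance — mostly saturates its local driving
force on a thin branch and stays subthreshold at the soma, so firing
requires spatial and temporal summation. That is the integration regime
in which correlated input recruits spikes at modest conductance scalings
while uncorrelated input needs large ones, and in which spike counts grow
with G. On much smaller cells single events become suprathreshold and
the uncorrelated protocol, which delivers ten times more event instants,
can overtake correlated input at high G; traces of this can still appear
at G = 30 for some input realisations. The shipped tests fix the
protocol seed; the behaviour at other seeds is reported, not asserted.
Real dendrites add active conductances, NMDA nonlinearity and synaptic
depression, none of which are modelled; passing tests establish the
integration logic of the pipeline, not quantitative thresholds for any
real neuron (the published ~10×/~30× thresholds are morphology-specific
and are deliberately not asserted).

## 5. Lattice Monte Carlo of channel gating

A periodic L×L square lattice holds one occupant per site: saturated
lipid, unsaturated lipid, or a channel (Na- or K-selective). Each channel
occupies one site and carries four voltage sensors facing its four
neighbours; orientation (4 states) permutes the sensor→neighbour map; a
channel conducts iff all four sensors are activated.

Hamiltonian (energies in units of k_B·T_ref, T_ref = 303.15 K):

* gating: each activated sensor contributes `ε_g − q·V_m·F_v`, with
  q = 1.5 e₀ per sensor and ε_g set so the isolated-sensor midpoint
  voltage `V_half = ε_g/(q F_v)` is −45 mV (Na) and −35 mV (K); an
  optional intra-channel sensor–sensor ring coupling defaults to 0, so
  "allosteric linkage" enters only through the all-four-open conduction
  rule.
* interaction: nearest-neighbour pair couplings — lipid–lipid
  J(like) = −0.35, J(unlike) = +0.35 (phase separation near room
  temperature); sensor–lipid J(activated, unsaturated) = −0.3,
  J(activated, saturated) = +0.1, resting pairs 0 (unsaturated-lipid
  domains stabilise the open state); channel–channel contacts are
  neutral.

Dynamics: Metropolis with move mixture (sensor flip 0.5, Kawasaki lipid
swap 0.3, channel translation 0.15, channel ±90° rotation 0.05).
Kawasaki exchange conserves lipid stoichiometry; proposals targeting
invalid pairs (channel–channel translation, swaps touching a channel)
count as attempted and rejected, preserving a well-defined proposal
distribution. Acceptance uses `min(1, exp(−ΔH·T_ref/T))`; ΔH is computed
from the bonds incident to the affected sites and verified against full
recomputation to 10⁻⁸ relative over 10⁵ sweeps. One sweep = L² attempted
moves. Observables per sweep: open-channel counts per selectivity, total
patch current `Σ n_open·γ·(V_m−E)` (γ = 20 pS, E_Na = +50 mV,
E_K = −77 mV), and energy. Equilibrium checks: the zero-coupling sensor
activation reproduces the two-state Boltzmann sigmoid across a 7-point
voltage grid, and a 3×3 single-channel system with flips only matches
the exact 16-state enumeration to total-variation distance < 0.02.
The physical area of one lattice site is left symbolic; inactivated
states and ternary lipid mixtures are out of scope.

## 6. Bidirectional coupling

The loop alternates on an exchange cadence (default 0.05 ms): run the
lattice MC for a window at the current somatic `V_m`; inject the
window-mean patch current, times an `area_scale` factor (default 1, i.e.
one patch stands for the whole soma), into the soma with a minus sign
(the patch current is an outward-positive membrane current, so inward Na
current depolarises); advance the solver over the window; feed the
end-of-window somatic voltage back to the MC. No physical sweep↔time
mapping exists a priori; the default maps 40 sweeps to 1 ms, chosen so
sensor kinetics relax on the millisecond scale of the action potential —
this mapping is a model choice, stated, not derived. Exchanging the
window mean rather than the endpoint halves the sensitivity to the
exchange interval.

The reference cell is the two-compartment soma+dendrite model
(20 µm soma, 100×1 µm passive dendrite) under an 80 pA current clamp
(default window 50–150 ms of a 400 ms run; onset/duration are model
choices). Replicas differ only in the MC seed; ensembles are summarised
by the pointwise median and first/third quartiles. Repolarization time is
measured per spike from the voltage peak until first return to within
5 mV of the pre-stimulus baseline; spikes that never return are counted
as right-censored and excluded from medians. Contract tests: a
zero-channel patch reproduces the solver-only run; a patch frozen fully
open matches the closed-form response of a membrane with the equivalent
constant conductance to 0.25 mV.

Cooling 40 → 20 °C prolongs the median repolarization (about ninefold
with the shipped defaults, dominated by the q10 slowing of the HH rates,
with lipid-coupled gating adding patch-current variability on top) while
the spike peak changes are reported but not asserted. Only this direction
is claimed; absolute time courses depend on the unavailable parameters of
the underlying patch model and are out of scope. Study sizes in the
shipped tests and acceptance script — 20 replicas, 400 ms runs, L = 16
patches with 20+20 channels — are the package's desk-scale defaults; the
full protocol (100 replicas, three temperatures) is available through
`CouplingConfig`.

## 7. Reproducibility

Every stochastic operation draws from an explicit seed: patches own a
generator seeded at construction (sweep kernels draw their sub-seeds from
it), experiment seeds are split into placement and train streams via
`SeedSequence`, and replica r uses `seed + r`. Identical configuration
and seeds give bit-identical observables, traces and spike counts. CLI
runs write a JSON metadata record (command, echoed config, seed, package
version, timing) beside their outputs. Lattice and trace outputs are
delimited text with JSON sidecars; full-lattice binary snapshots are not
implemented.
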