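# Methods

## The two-loop model

An experiment couples an *optimizee* (inner loop: one simulation per
parameter set, returning a fitness vector under the maximization
convention — losses are negated) to an *optimizer* (outer loop: a
population-to-population map). One generation is evaluate → scalarize with
the fitness weights (dot product) → optimizer step → re-apply parameter
bounds. Every evaluation draws its RNG from a seed derived with
`SeedSequence((experiment_seed, generation, individual_id))`, which makes a
run a pure function of (config, seed) regardless of the worker count; the
HPC back-end is abstracted behind a runner interface with a local
process-pool implementation. Failed evaluations are flagged and scored −∞
rather than aborting, so population sizes are conserved for the
population-based optimizers (a fully failed generation does abort, with the
first captured traceback).

The trajectory is append-only and self-describing on disk (HDF5: config
snapshot, per-generation parameter and fitness tables, per-evaluation
seeds) with a flat CSV export. External optimizees exchange
`params.csv` (name,index,value) / `fitness.csv` (one row of reals) through
a per-evaluation working directory.

## Optimizers: formulations and defaults

* **Ensemble Kalman inversion** — `u_j += C_ud (C_dd + γ I)⁻¹ (y − g(u_j))`
  with population (1/n) covariance normalization, solved through a Cholesky
  factorization that γ > 0 guarantees to exist. γ defaults to 0.5 and acts
  like an inverse learning rate. Parameters are mapped to [0, 1] over fixed
  declared bounds (not per-generation min/max, so the mapping is stable
  across generations). The ranking modification replaces the worst
  ⌊fraction·n⌋ members (default 10%) with rank-paired copies of the best,
  plus Gaussian noise (default scale 0.05 in normalized units; the scale is
  a free design constant, chosen small relative to the unit box).
* **Genetic algorithm** — tournament selection (size 3) with replacement,
  pairwise blend crossover (α = 0.5, probability 0.7), per-individual
  Gaussian mutation of every gene (probability 0.3, σ = 1), and a Hall of
  Fame whose tie rule keeps the *first* individual to attain a fitness
  level. These operator choices are declared, configurable, and tested.
* **Evolution strategies** — offspring `center + σ ε`, mirrored sampling by
  default; update `center += lr/(n σ) Σ u_i ε_i` with centered-rank
  utilities in [−0.5, 0.5] (ties share the mean rank, so a signal-free
  generation moves nothing).
* **Gradient ascent** — the local gradient is the least-squares slope of
  probe fitnesses on centered probe offsets (least-norm under rank
  deficiency); no analytic gradients are ever required. The multi-individual
  variant carries a grid cloud of parameter combinations per individual
  (the *expanded* representation linking each fitness to its parameters),
  re-centers on the best combination nudged by `lr · ĝ`, and emits a new
  cloud over a range shrunk by 0.9 per step (the *compressed* form).
* **Simulated annealing** — independent Metropolis chains at a shared
  temperature; exponential (`T₀ c^t`), linear, and logarithmic schedules,
  floored at 10⁻¹² T₀ so the acceptance rule stays defined.
* **Cross-entropy** — diagonal Gaussian refit to the top elite fraction
  (at least 2), smoothed toward the previous parameters, variance floored
  at 10⁻¹².
* **Grid search** — endpoints included; the combination count is checked
  against a cap (default 10⁶) before materializing and reported as a power
  (e.g. 20^500) when exceeded.

## The LIF simulator

Current-based delta-synapse leaky integrate-and-fire neurons,
forward-Euler: `V += dt/τ_m (−(V − V_rest) + R I)` plus the summed synaptic
jumps arriving that step; threshold crossing → reset and an absolute
refractory period. Defaults: τ_m 10 ms, rest/reset −70 mV, threshold
−55 mV, refractory 2 ms, R 10 MΩ, dt 0.1 ms. Synaptic weights are
dimensionless; a per-network `weight_scale` converts them to mV jumps.
Delays are integer steps ≥ 1 served from a ring buffer. At dt = 0.1 ms the
simulator matches the closed-form f–I curve
`rate = 1/(t_ref + τ_m ln(RI/(RI − ΔV)))` within 2% (tested), and the
maximal rate is pinned at `1/(t_ref + dt)` — the calibrated "500 Hz" DC
drive therefore realizes ≈476 Hz at dt 0.1.

Two engines share these semantics: a reference single-network simulator
with arbitrary delays, and a vectorized engine integrating B same-topology
networks in lockstep (unit delays; shared sparse connectivity plus
per-member weights for the readout/policy synapses). The mountain-car
pipeline additionally uses a JIT-compiled fusion of environment and policy
network whose episodes are asserted bitwise-identical to the vectorized
engine.

## Task networks

* **Reservoir (digit classification)** — at scale 1: 768 input neurons
  (one per pixel, Poisson sources at the 1–100 Hz pixel-rate code), 1600
  excitatory + 400 inhibitory reservoir neurons with 6%/8% outdegree caps,
  3 output clusters of 12 (10 exc., 2 inh.), recurrent within but never
  across clusters, and exactly 800 reservoir sources per output neuron
  (28 800 readout synapses total). Weights from N(70, 50) / N(−90, 50)
  sign-clamped by source type. `scale` shrinks all populations
  proportionally; images with more pixels than input neurons are subsampled
  on an even grid. Desk-scale calibration: `weight_scale` 0.05 mV/unit puts
  reservoir rates in a responsive 50–100 Hz regime with class-distinct
  patterns (larger scales saturate toward the refractory ceiling).
* **Ant brain** — 12 inputs (11 sensory + heartbeat), 10 hidden, 4 outputs;
  110 + 10 + 90 + 40 = 250 synapses in a fixed documented order so the
  250-weight/250-delay vectors map stably. Initial delays are integers in
  {1,…,6} while the bounding range is [1, 5] — both ranges are kept as
  stated, deliberately unreconciled. Only the colony fitness accounting is
  implemented (event logs in, scalar out); there is no agent world here.
* **Mountain-car policy** — 60 inputs (30 position bins over [−1.2, 0.6],
  30 velocity bins over [−0.07, 0.07]), 5 hidden, 3 outputs, all-to-all
  feed-forward, 315 weights. Bin width is (max − min)/n with the index
  floored and clamped. Active bin neurons get the f–I-calibrated DC;
  actions decode by winner-take-all with ties to the lowest index and
  "do nothing" when the output layer is silent.

## Testbeds and study configurations

**Digit training (ensemble Kalman).** Synthetic digits are stripe glyphs:
class k lights stripes k and k+3 of six equal canvas stripes at full
intensity with per-image contrast jitter and salt noise (probability 0.1 of
replacing a pixel with a uniform intensity). A nearest-centroid check
guarantees ≥95% separability at the default noise. One generation presents
a balanced batch of 10 images (100 ms warmup, 500 ms presentation, 200 ms
cooling, 5 Hz background noise; the protocol integrates at dt 1 ms);
per-image predictions are the softmax of output-cluster rates divided by a
temperature of 5 (raw rates saturate the softmax), the fitness is
1 − MSE against the one-hot label, and the filter assimilates the
concatenated softmax vectors toward the concatenated one-hots (γ = 0.5,
10% replace-and-perturb). The readout ensemble (20 members at scale 0.1)
initializes N(0, 50) clipped to the fixed [−150, 150] bounds: zero-mean
with enough spread that member predictions differ, which is what drives
the covariance-based update. Every 10th generation the best member is
scored on a held-out batch.

**Single-cell fitting.** The surrogate cell is an adaptive LIF
(C dV/dt = −g_L(V − E_L) − w + I; spike → reset, w += b; τ_w decay) with
spikes pasted at +20 mV so threshold-based features have support. Trace
fitness follows the maximization convention: the square loss is returned
as −(1/T²) Σ [U_ref − U_sim]² exactly as printed (a `normalization`
switch provides the conventional per-sample mean), and the feature pair is
L = |⟨U_ref⟩ − ⟨U_sim⟩| with S the mean of (U_ref − U_sim) over samples
where the reference exceeds the spike threshold σ (zero when none do).
The recovery study plants (g_L, E_L) = (0.05 µS, −70 mV) and fits them
with the GA (population 100, 200 generations, breeding in [0, 1]-normalized
coordinates, mutation σ 0.05). The default stimuli are two *subthreshold*
current steps (0.6 and 0.85 nA against a 1.0 nA rheobase): on spiking
traces the square loss is rugged under spike misalignment, while the
subthreshold response identifies both leak parameters smoothly —
suprathreshold clamps and the feature fitness remain available.

**Functional–structural fitting.** Regions are planar limit-cycle
oscillators (radius ≈ 0.5, heterogeneous angular velocities) coupled by
`coupling · Σ_j SC_ij x_j(t − d_ij)` with delays from an index-distance
proxy divided by the conduction speed, driven by noise shared across all
parameter combinations in a batch (common random numbers make the fitness
landscape deterministic, so optimization runs and grid oracles are
comparable). The fitness correlates the upper-triangular off-diagonal
functional connectivity (pairwise Pearson of the region series, transient
discarded) with the max-normalized structural weights. The fit uses
multi-gradient ascent: 4 individuals × 64-combination clouds over
(coupling ∈ [0, 1], speed ∈ [0.5, 5]), learning rate 0.01, 30 generations
on a 10-region modular SC; a 32×32 dense grid on the same landscape serves
as the oracle in tests.

**Mountain-car evolution.** Physics: v += 0.001(a−1) − 0.0025 cos(3p),
clamped to ±0.07; p += v, clamped to [−1.2, 0.6]; goal at p ≥ 0.5; resets
uniform in [−0.6, −0.4] with zero velocity. The printed velocity encoding
range [−0.7, 0.7] is treated as a typo for the environment's native ±0.07
(the encoder range stays configurable). Each environment step simulates
the policy network for 20 ms; the pipeline integrates at dt 0.2 ms
(policies are trained and evaluated at the same dt) with a policy
`weight_scale` of 0.5 mV/unit, without which random initial populations
are behaviorally silent and the fitness landscape flat. Training scores
each individual on one episode of at most 110 steps by the maximum
position reached, with per-individual episode seeds; evaluation episodes
cap at 200 steps.

The GA configuration was tuned empirically on this task (the population
size, fitness definition, 110-step training cap and ≤400-generation budget
are fixed study conditions): blend crossover probability 0.9 dominates the
search; mutation σ is 2.0 until the goal is first reached, then 1.5
(refinement); the best-ever individual is re-inserted every generation and
thereby re-evaluated on fresh starts. Because the raw fitness saturates at
0.5 once the goal is reached, an episode-budget curriculum tightens the
training cap 110 → 100 → 95 → 90 as soon as three individuals of a
generation reach the goal, keeping selection pressure on *fast*
completion (every episode still respects the ≤110-step condition). All
goal-reaching individuals enter a candidate pool; the run's champion is
the candidate with the lowest mean steps-to-goal over 40 validation
episodes whose start states are disjoint (by seeding) from both training
episodes and any later evaluation. For reference, a value-iteration bound
puts the optimal policy near 89 steps on average and plain
velocity-bang-bang at ≈125, so the ≤110 target requires genuinely better
than bang-bang behavior.

## What the synthetic testbeds do and do not show

The generators emulate the *structure* of the original tasks — rate-coded
images driving a fixed recurrent reservoir with a trainable readout,
stimulus/response traces of an excitable cell, delayed-coupling dynamics on
a modular connectome, a closed-loop control task — at sizes where every
pipeline runs on one CPU in minutes. They do not reproduce handwritten-digit
variability (stripe glyphs are linearly separable by construction),
morphologically detailed channel kinetics, empirically measured human
connectomes, or an actual foraging world. Passing tests therefore certify
the framework, the optimizers, the fitness definitions and the simulators —
not state-of-the-art task performance on real data.

## Numerical and degenerate-input conventions

Softmax subtracts the max before exponentiation. Pearson correlation raises
on zero-variance input rather than returning 0. A zero-spread ensemble is a
fixed point of the Kalman update. Winner-take-all ties break to the lowest
index; an all-silent output layer yields a configurable default action.
Bin indices clamp to [0, n−1] so range endpoints are valid. The trace
square loss requires equal length and sampling interval. `S` is 0 when no
reference sample crosses the spike threshold. Unstable integration steps
(dt above the fastest time constant) are refused. Grid search refuses to
materialize above its combination cap. Integer-kind parameters round before
clamping.

## Problem sizes

Default test and acceptance runs use the desk-scale configurations above:
reservoir scale 0.1 (20-member ensemble, ≤30 generations), cell recovery
at 100×200 GA evaluations over two 300 ms traces (dt 0.2 ms), FC fitting
with 256 simulations per generation for 30 generations plus a 1024-point
grid oracle, and the full 3×400-generation mountain-car evolution. The
full-scale reservoir (768 inputs, 2000 reservoir neurons, 28 800 readout
synapses) is built and structurally verified but not trained in the test
suite.

## Known limitations

No conductance-based synapses, plasticity, or morphological neurons; no
checkpoint/resume; no live visualization; natural evolution strategies and
parallel tempering are declared but unimplemented; the ant-colony testbed
scores event logs only. The ensemble Kalman optimizer expects the
optimizee's fitness vector to carry the model observations after the
scalar fitness (weight them 0), which is a convention, not a type-checked
contract.
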