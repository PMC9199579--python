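# metaloop

Two-loop (optimizee/optimizer) parameter and hyper-parameter exploration for
simulation-based neuroscience models, with self-contained desk-scale
testbeds: spiking reservoir digit classification, single-cell trace fitting,
ant-colony fitness accounting, whole-brain functional-connectivity fitting,
and a spiking policy network for the mountain-car task.

## The idea

Fitting a simulator — a spiking network, a single cell, a rate-based whole
brain model — rarely admits gradients. `metaloop` treats the simulation as a
black box in an **inner loop**: an *optimizee* maps one parameter set (an
*individual*) to a fitness value or fitness vector **f**, scalarized as
`f = w · f` with a configurable weight tuple. An **outer loop** *optimizer*
maps a whole generation's (individuals, fitnesses) to the next generation.
Generations are embarrassingly parallel; every evaluation gets its own RNG
seed derived from (experiment seed, generation, individual id), so serial
and parallel runs are bit-identical, and the complete history is recorded in
an append-only, HDF5-persisted *trajectory*.

Outer-loop optimizers (each registered by name):

| name | algorithm |
|---|---|
| `enkf` | regularized ensemble Kalman inversion `u_j += C_ud (C_dd + γI)⁻¹ (y − g(u_j))` with rank-based replace-and-perturb |
| `genetic-algorithm` | tournament selection, blend crossover, Gaussian mutation, elitist Hall of Fame |
| `evolution-strategies` | Gaussian perturbation with rank-shaped stochastic-gradient update |
| `gradient-ascent` / `multi-gradient-ascent` | probe-regression gradient; vectorized per-individual cloud variant with expand/compress |
| `simulated-annealing` | Metropolis acceptance with exponential/linear/logarithmic cooling |
| `cross-entropy` | elite refitting of a diagonal Gaussian with smoothing |
| `grid-search` | exhaustive Cartesian grid with a combination-count cap |

The inner loop can also be an external executable coupled via CSV
(`params.csv` in, `fitness.csv` out), mirroring how agent-based simulators
are driven from the shell.

## Worked example

Evolve a 2-d sphere optimizee with the genetic algorithm from a YAML config:

```yaml
# run.yaml
experiment: {name: demo, seed: 4, n_generations: 20, population: 16, results: results}
optimizee:  {name: sphere, params: {dimension: 2}}
optimizer:  {name: genetic-algorithm, params: {mutation_sigma: 0.3}}
```

```
$ metaloop run --config run.yaml
generations: 20
best fitness: -6.57593e-06 (individual 11, generation 17)
  x: [-0.00185804, 0.00176738]
results written to results
```

The best fitness is the negated squared distance to the optimum at the
origin; the trajectory (all 20 generations × 16 individuals, parameters and
fitnesses) is stored under `results/demo.h5` with a CSV export alongside,
and `metaloop show-trajectory results/demo.h5` summarizes it.

The headline testbed couples a 60-5-3 leaky integrate-and-fire policy
network to the mountain-car environment (20 ms of simulated network time
per environment step, winner-take-all action decoding) and evolves its 315
weights with the GA:

```python
>>> from metaloop.testbeds.mountain_car import evolve_mc_policy, evaluate_policy
>>> result = evolve_mc_policy(seed=1001)
>>> round(result.best_fitness, 3)     # max car position; the goal is 0.5
0.525
>>> steps = evaluate_policy(result.best_weights, n_episodes=100, max_steps=200, seed=0)
>>> steps.mean() <= 110               # task is solved at <= 110 steps on average
True
```

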