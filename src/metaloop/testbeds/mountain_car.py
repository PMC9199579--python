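"""Mountain-car task solved by an evolved spiking policy network.

The environment is the classic under-powered car in a valley: state is
(position, velocity), actions are {accelerate left, do nothing, accelerate
right}, and the goal (position 0.5) can only be reached by swinging to build
momentum. The policy is the 60-5-3 feed-forward LIF network: position and
velocity are each discretized into 30 bins, the two active bin neurons are
driven toward 500 Hz, the network integrates 20 ms of simulated time per
environment step, and a winner-take-all readout of the three output neurons
picks the action.

Training follows the genetic-algorithm recipe: population 32, 315 weights in
[-20, 20], fitness = maximum position over an episode of at most 110 steps.
Whole populations (and evaluation episode batches) are simulated in lockstep
by the vectorized LIF engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ContractError
from ..evaluation import individual_seed
from ..parameters import Individual, ParameterEntry, ParameterSpec
from ..optimizers.ga import GAConfig, HallOfFame, ga_step
from ..snn.builders import build_mc_policy
from ..snn.encoding import bin_index
from ..snn.simulator import BatchedLIF, dc_for_rate
from ..trajectory import FitnessRecord, Trajectory

__all__ = ["MCState", "mc_reset", "mc_step", "MCPolicyRunner",
           "run_mc_episode", "evaluate_policy", "evolve_mc_policy",
           "MCEvolutionResult", "mc_parameter_spec"]

POSITION_RANGE = (-1.2, 0.6)
VELOCITY_RANGE = (-0.07, 0.07)
GOAL_POSITION = 0.5
FORCE = 0.001
GRAVITY = 0.0025
N_BINS = 30
SNN_INTERVAL_MS = 20.0
DEFAULT_ACTION = 1  # do nothing when the output layer is silent


@dataclass
class MCState:
    position: float
    velocity: float


def mc_reset(rng: np.random.Generator) -> MCState:
    """Start near the valley bottom with zero velocity."""
    return MCState(position=float(rng.uniform(-0.6, -0.4)), velocity=0.0)


def mc_step(state: MCState, action: int) -> tuple[MCState, bool]:
    """One environment step; ``action`` in {0: left, 1: none, 2: right}."""
    if action not in (0, 1, 2):
        raise ContractError(f"invalid action {action}")
    v = state.velocity + FORCE * (action - 1) - GRAVITY * np.cos(3 * state.position)
    v = float(np.clip(v, *VELOCITY_RANGE))
    p = float(np.clip(state.position + v, *POSITION_RANGE))
    return MCState(position=p, velocity=v), p >= GOAL_POSITION


def mc_parameter_spec() -> ParameterSpec:
    return ParameterSpec((ParameterEntry("weights", 315, -20.0, 20.0),))


class MCPolicyRunner:
    """Batched closed-loop rollout of B policies (or B episodes).

    ``weights`` is (B, 315) — one policy per row — or (315,) broadcast over
    ``batch`` parallel episodes of the same policy. Environment dynamics and
    the LIF integration are fully deterministic given the initial states.
    """

    def __init__(self, weights: np.ndarray, batch: int | None = None,
                 dt: float = 0.1, velocity_encoding=VELOCITY_RANGE,
                 use_kernel: bool = True):
        weights = np.asarray(weights, dtype=float)
        template = build_mc_policy(np.zeros(315))
        self.net = template
        self.dt = dt
        self.velocity_encoding = velocity_encoding
        self.interval_steps = int(round(SNN_INTERVAL_MS / dt))
        self.dc = dc_for_rate(template.params, 500.0, dt)
        self.use_kernel = use_kernel
        n = template.n_neurons
        self.out = template.population("output")

        if weights.ndim == 1:
            B = batch or 1
            jumps = np.zeros((B, n, n))
            jumps[:, template.pre, template.post] = weights * template.weight_scale
        else:
            B = weights.shape[0]
            jumps = np.zeros((B, n, n))
            jumps[:, template.pre, template.post] = weights * template.weight_scale
        self.jumps = jumps
        self.engine = BatchedLIF(n, B, template.params, dt, member_jump=jumps)
        self.B = B

    def _drive(self, positions: np.ndarray, velocities: np.ndarray) -> np.ndarray:
        drive = np.zeros((self.B, self.net.n_neurons))
        for b in range(self.B):
            pb = bin_index(positions[b], *POSITION_RANGE, N_BINS)
            vb = bin_index(velocities[b], *self.velocity_encoding, N_BINS)
            drive[b, pb] = self.dc
            drive[b, N_BINS + vb] = self.dc
        return drive

    def rollout(self, initial_states: list[MCState], max_steps: int
                ) -> tuple[np.ndarray, np.ndarray]:
        """Run all episodes; returns (position traces (B, max_steps),
        steps_to_goal (B,), with ``max_steps`` for episodes that never
        reach the goal). Finished episodes hold their last position."""
        if len(initial_states) != self.B:
            raise ContractError("one initial state per batched episode")
        if self.use_kernel:
            from ._mc_kernel import mc_rollout_kernel
            p = self.net.params
            leak = self.dt / p.tau_m
            traces, steps = mc_rollout_kernel(
                self.jumps,
                np.array([s.position for s in initial_states]),
                np.array([s.velocity for s in initial_states]),
                max_steps, self.interval_steps,
                leak * p.resistance * self.dc, leak, p.v_rest,
                p.v_threshold, p.v_reset,
                int(round(p.t_refractory / self.dt)),
                POSITION_RANGE[0], POSITION_RANGE[1],
                VELOCITY_RANGE[0], VELOCITY_RANGE[1],
                GOAL_POSITION, N_BINS,
                self.velocity_encoding[0], self.velocity_encoding[1],
                DEFAULT_ACTION)
            return traces, steps
        self.engine.reset()
        pos = np.array([s.position for s in initial_states])
        vel = np.array([s.velocity for s in initial_states])
        done = np.zeros(self.B, dtype=bool)
        steps_to_goal = np.full(self.B, max_steps)
        traces = np.empty((self.B, max_steps))

        for t in range(max_steps):
            drive = self._drive(pos, vel)
            counts = np.zeros((self.B, 3))
            for _ in range(self.interval_steps):
                spiked = self.engine.step(ext_current=drive)
                counts += spiked[:, self.out]
            actions = np.where(counts.any(axis=1),
                               np.argmax(counts, axis=1), DEFAULT_ACTION)
            act = ~done
            v = vel + FORCE * (actions - 1) - GRAVITY * np.cos(3 * pos)
            v = np.clip(v, *VELOCITY_RANGE)
            p = np.clip(pos + v, *POSITION_RANGE)
            vel = np.where(act, v, vel)
            pos = np.where(act, p, pos)
            traces[:, t] = pos
            newly = act & (pos >= GOAL_POSITION)
            steps_to_goal[newly] = t + 1
            done = done | newly
            if done.all():
                traces[:, t + 1:] = pos[:, None]
                break
        return traces, steps_to_goal


def run_mc_episode(weights, max_steps: int = 110,
                   rng: np.random.Generator | None = None,
                   dt: float = 0.1) -> tuple[np.ndarray, int | None]:
    """Single-policy episode; returns (position trace, steps_to_goal or None)."""
    rng = rng or np.random.default_rng(0)
    runner = MCPolicyRunner(np.asarray(weights, dtype=float), batch=1, dt=dt)
    traces, steps = runner.rollout([mc_reset(rng)], max_steps)
    reached = bool(traces[0].max() >= GOAL_POSITION)
    if reached:
        return traces[0][: int(steps[0])], int(steps[0])
    return traces[0], None


def evaluate_policy(weights, n_episodes: int = 100, max_steps: int = 200,
                    seed: int = 0, dt: float = 0.1) -> np.ndarray:
    """Steps-to-goal over ``n_episodes`` random starts (cap counts as the
    episode length for failures)."""
    rng = np.random.default_rng(seed)
    starts = [mc_reset(rng) for _ in range(n_episodes)]
    runner = MCPolicyRunner(np.asarray(weights, dtype=float),
                            batch=n_episodes, dt=dt)
    _, steps = runner.rollout(starts, max_steps)
    return steps


@dataclass
class MCEvolutionResult:
    trajectory: Trajectory
    hof: HallOfFame
    best_fitness: float
    generations_run: int
    champion: np.ndarray | None = None     # validated goal-reaching policy
    champion_val_steps: float | None = None
    n_candidates: int = 0

    @property
    def best_weights(self) -> np.ndarray:
        return self.champion if self.champion is not None else self.hof.best_vector


def evolve_mc_policy(
    seed: int = 0,
    population: int = 32,
    max_generations: int = 400,
    train_steps: int = 110,
    ga_config: GAConfig | None = None,
    refine_config: GAConfig | None = None,
    dt: float = 0.2,
    record_trajectory: bool = False,
    curriculum: tuple[int, ...] = (110, 100, 95, 90),
    curriculum_advance_at: int = 3,
    pool_capacity: int = 256,
    validation_episodes: int = 40,
) -> MCEvolutionResult:
    """Evolve the 315 policy weights with the genetic algorithm.

    Each individual is scored on one training episode (its own random start,
    seeded from the experiment seed, the generation and its id) by the
    maximum position reached. Episodes are capped at ``train_steps`` (110)
    environment steps; once ``curriculum_advance_at`` individuals of a
    generation reach the goal, the cap is tightened along ``curriculum``,
    which keeps selection pressure on *fast* goal completion after the raw
    fitness saturates at the goal position (every episode still runs for at
    most ``train_steps`` steps). Weights are clipped to [-20, 20] after
    every step, and the best-ever individual is re-inserted each generation
    (elitism), so it keeps being re-evaluated on fresh starts.

    The GA runs with an exploration configuration (wide Gaussian mutation)
    until the goal is first reached, then switches to a refinement
    configuration with a smaller mutation scale; both use a high blend
    crossover probability, which empirically dominates the search here.

    All ``max_generations`` generations are run. Every distinct
    goal-reaching individual enters a candidate pool; the returned
    ``champion`` is the pool candidate with the lowest mean steps-to-goal
    over ``validation_episodes`` held-out episodes (a start-state set
    disjoint from training by seeding).
    """
    master = np.random.default_rng(seed)
    explore = ga_config or GAConfig(mutation_sigma=2.0, crossover_prob=0.9,
                                    hof_size=5)
    refine = refine_config or GAConfig(mutation_sigma=1.5, crossover_prob=0.9,
                                       hof_size=5)
    matrix = master.uniform(-20.0, 20.0, size=(population, 315))
    hof = HallOfFame(explore.hof_size)
    traj = Trajectory(config={"optimizee": "mc-policy", "optimizer": "genetic-algorithm",
                              "n_pop": population, "train_steps": train_steps},
                      seed=seed)
    caps = tuple(c for c in curriculum if c <= train_steps) or (train_steps,)
    pool: dict[bytes, np.ndarray] = {}
    first_hit = None
    cap_i = 0
    generations_run = 0

    for gen in range(max_generations):
        seeds = [individual_seed(seed, gen, i) for i in range(population)]
        starts = [mc_reset(np.random.default_rng(s)) for s in seeds]
        runner = MCPolicyRunner(matrix, dt=dt)
        traces, _ = runner.rollout(starts, caps[cap_i])
        fitnesses = traces.max(axis=1)
        generations_run = gen + 1
        if record_trajectory:
            individuals = [Individual(values={"weights": row.copy()}, id=i,
                                      generation=gen)
                           for i, row in enumerate(matrix)]
            records = [FitnessRecord(individual_id=i,
                                     fitness_vector=np.array([f]),
                                     scalar_fitness=float(f), seed=s)
                       for i, (f, s) in enumerate(zip(fitnesses, seeds))]
            traj.append(individuals, records)

        winners = np.flatnonzero(fitnesses >= GOAL_POSITION)
        for i in winners:
            key = matrix[i].tobytes()
            if key not in pool and len(pool) < pool_capacity:
                pool[key] = matrix[i].copy()
        hof.update(matrix, fitnesses)
        if winners.size and first_hit is None:
            first_hit = gen
        if winners.size >= curriculum_advance_at and cap_i < len(caps) - 1:
            cap_i += 1
        config = refine if first_hit is not None else explore
        matrix = ga_step(matrix, fitnesses, config, hof, master)
        matrix[0] = hof.best_vector  # elitism: re-evaluated on a fresh start
        matrix = np.clip(matrix, -20.0, 20.0)

    champion, champ_steps = None, None
    if pool:
        candidates = list(pool.values())
        val_seed = individual_seed(seed, 999_999, 0)  # common start set
        means = [evaluate_policy(w, validation_episodes, 2 * train_steps,
                                 seed=val_seed, dt=dt).mean()
                 for w in candidates]
        k = int(np.argmin(means))
        champion, champ_steps = candidates[k], float(means[k])

    return MCEvolutionResult(trajectory=traj, hof=hof,
                             best_fitness=hof.best_fitness,
                             generations_run=generations_run,
                             champion=champion,
                             champion_val_steps=champ_steps,
                             n_candidates=len(pool))
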