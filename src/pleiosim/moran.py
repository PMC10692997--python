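"""Moran birth-death simulation driver.

Each event is one fitness-proportional birth paired with one uniformly
random death, holding the population at exactly ``N`` individuals; ``N``
events make one generation.  The optimum trajectory is pre-drawn (see
:mod:`pleiosim.environment`) so the same environment can be replayed against
any engine or analysis.  By default populations are recorded during the last
tenth of the run every ten generations — with the defaults of 5,000
generations that is 50 snapshots per replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._engine import moran_events
from .core_model import ModelParams, fitness_array, phenotypes
from .environment import EnvironmentSpec, OptimumTrajectory, make_trajectory

__all__ = [
    "Population",
    "SimulationRecord",
    "snapshot_generations",
    "run_replicate",
    "run_batch",
]

logger = logging.getLogger(__name__)


@dataclass
class Population:
    """A population at one time point: genotype arrays plus phenotype/fitness caches."""

    a: np.ndarray          # (N, n_a)
    c: np.ndarray          # (N, n_traits, n_a)
    optimum: np.ndarray    # (n_traits,)
    z: np.ndarray = field(default=None)  # (N, n_traits)
    w: np.ndarray = field(default=None)  # (N,)
    selection_var: float = 1.0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        self.c = np.asarray(self.c, dtype=np.float64)
        self.optimum = np.asarray(self.optimum, dtype=np.float64)
        if self.z is None:
            self.z = phenotypes(self.a, self.c)
        if self.w is None:
            self.w = fitness_array(self.z, self.optimum, self.selection_var)

    @property
    def N(self) -> int:
        return self.a.shape[0]

    @property
    def n_traits(self) -> int:
        return self.c.shape[1]

    @property
    def n_a(self) -> int:
        return self.a.shape[1]

    def check_caches(self, atol: float = 0.0) -> bool:
        """True when cached phenotypes/fitnesses match recomputation exactly."""
        z = phenotypes(self.a, self.c)
        w = fitness_array(z, self.optimum, self.selection_var)
        if atol == 0.0:
            return bool(np.array_equal(z, self.z) and np.array_equal(w, self.w))
        return bool(np.allclose(z, self.z, atol=atol) and np.allclose(w, self.w, atol=atol))

    def copy(self) -> "Population":
        return Population(
            self.a.copy(), self.c.copy(), self.optimum.copy(),
            self.z.copy(), self.w.copy(), self.selection_var,
        )


@dataclass
class SimulationRecord:
    """Everything one replicate run produced: snapshots, fitness series, provenance."""

    replicate_id: int
    seed: int
    params: ModelParams
    env: EnvironmentSpec
    n_events: int
    snapshot_generations: np.ndarray   # (S,)
    snapshot_a: np.ndarray             # (S, N, n_a)
    snapshot_c: np.ndarray             # (S, N, n_traits, n_a)
    snapshot_optima: np.ndarray        # (S, n_traits)
    fitness_generations: np.ndarray    # (F,)
    mean_fitness: np.ndarray           # (F,)

    @property
    def n_snapshots(self) -> int:
        return int(self.snapshot_generations.shape[0])

    def population_at(self, index: int) -> Population:
        return Population(
            self.snapshot_a[index].copy(),
            self.snapshot_c[index].copy(),
            self.snapshot_optima[index].copy(),
            selection_var=self.params.selection_var,
        )

    def final_population(self) -> Population:
        return self.population_at(self.n_snapshots - 1)


def snapshot_generations(
    n_generations: int, every: int = 10, fraction: float = 0.1
) -> np.ndarray:
    """Recording schedule: every ``every`` generations within the final ``fraction`` of the run.

    For 5,000 generations with the defaults this yields the 50 generations
    4510, 4520, ..., 5000.  If the run is too short for the schedule the
    final generation alone is recorded.
    """
    start = n_generations - int(round(n_generations * fraction))
    gens = np.arange(start + every, n_generations + 1, every, dtype=np.int64)
    if gens.size == 0:
        gens = np.array([n_generations], dtype=np.int64)
    return gens


def _initial_arrays(params: ModelParams, initial: Population | None):
    if initial is None:
        # genetically uniform start at the origin of trait space
        a = np.zeros((params.N, params.n_a))
        c = np.zeros((params.N, params.n_traits, params.n_a))
    else:
        if initial.N != params.N:
            raise ValueError(f"initial population has N={initial.N}, params.N={params.N}")
        a = initial.a.copy()
        c = initial.c.copy()
    return a, c


def run_replicate(
    params: ModelParams,
    spec: EnvironmentSpec,
    n_events: int,
    seed: int,
    *,
    replicate_id: int = 0,
    initial: Population | None = None,
    init_optimum: np.ndarray | None = None,
    trajectory: OptimumTrajectory | None = None,
    snapshot_gens: Sequence[int] | None = None,
    fitness_every: int = 10,
    engine: str = "incremental",
) -> SimulationRecord:
    """Run one replicate for ``n_events`` birth-death events.

    The seed splits into an environment stream and an event stream, so the
    optimum trajectory can be regenerated independently of the simulation.
    ``engine="naive"`` recomputes every phenotype and fitness from scratch at
    every event; it consumes the random stream identically and must produce a
    bit-identical result to the default cached engine.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if engine not in ("incremental", "naive"):
        raise ValueError(f"unknown engine {engine!r}")

    ss = np.random.SeedSequence(seed)
    env_seed, engine_seed = ss.generate_state(2)
    engine_seed = int(engine_seed % (2**31))

    n_gens = max(1, n_events // params.N)
    if trajectory is None:
        if init_optimum is None:
            init_optimum = np.zeros(params.n_traits)
        trajectory = make_trajectory(
            spec, n_gens, init_optimum, np.random.default_rng(env_seed)
        )
    opt_epochs = np.ascontiguousarray(trajectory.epoch_optima())
    events_per_epoch = spec.period_generations * params.N

    if snapshot_gens is None:
        snap_g = snapshot_generations(n_gens)
    else:
        snap_g = np.asarray(sorted(snapshot_gens), dtype=np.int64)
    snap_events = snap_g * params.N
    if snap_events.size and snap_events[-1] > n_events:
        raise ValueError("snapshot schedule extends past the end of the run")

    fit_g = np.arange(fitness_every, n_gens + 1, fitness_every, dtype=np.int64)
    if fit_g.size == 0:
        fit_g = np.array([n_gens], dtype=np.int64)
    fit_events = fit_g * params.N

    a, c = _initial_arrays(params, initial)
    K = snap_events.shape[0]
    snap_a = np.empty((K, params.N, params.n_a))
    snap_c = np.empty((K, params.N, params.n_traits, params.n_a))
    snap_opt = np.empty((K, params.n_traits))
    fit_out = np.empty(fit_events.shape[0])

    moran_events(
        a, c,
        opt_epochs, events_per_epoch, n_events,
        params.mu_a, params.mu_c, float(np.sqrt(params.mut_var)),
        1.0 / (2.0 * params.selection_var),
        params.sexual, params.selection,
        engine_seed, engine == "naive",
        snap_events, snap_a, snap_c, snap_opt,
        fit_events, fit_out,
    )

    return SimulationRecord(
        replicate_id=replicate_id,
        seed=int(seed),
        params=params,
        env=spec,
        n_events=int(n_events),
        snapshot_generations=snap_g,
        snapshot_a=snap_a,
        snapshot_c=snap_c,
        snapshot_optima=snap_opt,
        fitness_generations=fit_g,
        mean_fitness=fit_out,
    )


def run_batch(
    params: ModelParams,
    spec: EnvironmentSpec,
    n_replicates: int,
    n_events: int,
    master_seed: int,
    **kwargs,
) -> list[SimulationRecord]:
    """Run independent replicates from one recorded master seed.

    Each replicate receives its own sub-seed spawned from the master seed, so
    the result set is reproducible and independent of execution order.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    sub_seeds = [
        int(s % (2**31))
        for s in np.random.SeedSequence(master_seed).generate_state(n_replicates, np.uint64)
    ]
    records = []
    for r, sub in enumerate(sub_seeds):
        logger.info("replicate %d/%d (seed %d)", r + 1, n_replicates, sub)
        records.append(
            run_replicate(params, spec, n_events, sub, replicate_id=r, **kwargs)
        )
    return records
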