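"""mu+lambda evolution strategy on dynamic fitness landscapes.

A population of ``popsize`` haploid, asexual genotypes is evaluated each
generation against the current environment's target pattern.  The top
``mu`` individuals survive unchanged and each produces
``lambda = popsize/mu - 1`` mutated offspring, keeping the population size
constant (a carrying-capacity assumption).  Four schedules are supported:

* ``static`` — one target throughout;
* ``variable`` — a landscape pair whose two targets alternate every
  ``season_length`` generations, starting with target A;
* ``mutation_pulse`` — a static target, but every season boundary every
  weight of every individual additionally receives N(0, pulse_sd) noise
  (random displacement of the whole population);
* ``random_target`` — a static target for most of each season, with the
  last ``random_target_span`` generations of every season selecting for a
  freshly drawn random real-valued target (random selection direction).

Randomness is split into independent named streams derived from the one
root seed (initialisation, mutation, pulses, random targets, sampling), so
a schedule variant leaves the streams it does not use untouched — a pulse
run is bit-identical to its static control up to the first pulse.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ca import LandscapePair, TargetPattern
from .development import (
    DevelopmentConfig,
    MutationConfig,
    develop_population,
    fitness_population,
    init_population,
    mutate_population,
)

__all__ = [
    "EvolutionConfig",
    "EnvironmentSchedule",
    "GenerationRecord",
    "RunTrace",
    "seed_streams",
    "environment_at",
    "truncation_select",
    "step_generation",
    "run_experiment",
    "run_static",
    "run_variable",
    "run_mutation_pulse",
    "run_random_target",
    "run_replicates",
]

STREAM_NAMES = ("init", "mutation", "pulse", "random_target", "sampling")

SCHEDULE_KINDS = ("static", "variable", "mutation_pulse", "random_target")


@dataclass(frozen=True)
class EvolutionConfig:
    """All hyperparameters of one evolutionary run."""

    popsize: int = 1000
    mu: int = 100
    generations: int = 10000
    season_length: int = 300
    mutation: MutationConfig = field(default_factory=MutationConfig)
    development: DevelopmentConfig = field(default_factory=DevelopmentConfig)
    schedule_kind: str = "static"
    pulse_sd: float = 1.0
    random_target_span: int = 3
    seed: int = 0
    snapshot_count: int = 33
    track_dual_fitness: bool = False
    dual_sample_fraction: float = 0.10
    mutate_parents: bool = False

    def __post_init__(self) -> None:
        if self.popsize <= 0 or self.mu <= 0:
            raise ValueError("popsize and mu must be positive")
        if self.popsize % self.mu != 0:
            raise ValueError(f"popsize {self.popsize} must be divisible by mu {self.mu}")
        if self.popsize // self.mu - 1 < 1:
            raise ValueError("lambda = popsize/mu - 1 must be >= 1")
        if self.season_length < 1:
            raise ValueError("season_length must be >= 1")
        if self.schedule_kind not in SCHEDULE_KINDS:
            raise ValueError(f"unknown schedule_kind {self.schedule_kind!r}")
        if not 0 <= self.random_target_span <= self.season_length:
            raise ValueError("random_target_span must be in [0, season_length]")

    @property
    def lam(self) -> int:
        """Offspring per survivor."""
        return self.popsize // self.mu - 1

    def to_dict(self) -> dict:
        d = {
            "popsize": self.popsize,
            "mu": self.mu,
            "generations": self.generations,
            "season_length": self.season_length,
            "schedule_kind": self.schedule_kind,
            "pulse_sd": self.pulse_sd,
            "random_target_span": self.random_target_span,
            "seed": self.seed,
            "snapshot_count": self.snapshot_count,
            "track_dual_fitness": self.track_dual_fitness,
            "dual_sample_fraction": self.dual_sample_fraction,
            "mutate_parents": self.mutate_parents,
            "mutation": vars(self.mutation).copy(),
            "development": vars(self.development).copy(),
        }
        return d


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Which target is selected for at each generation."""

    targets: tuple[TargetPattern, ...]
    kind: str = "static"
    season_length: int = 300

    @classmethod
    def static(cls, target: TargetPattern) -> "EnvironmentSchedule":
        return cls(targets=(target,), kind="static")

    @classmethod
    def variable(cls, pair: LandscapePair, season_length: int = 300) -> "EnvironmentSchedule":
        return cls(targets=pair.targets, kind="variable", season_length=season_length)


@dataclass
class GenerationRecord:
    max_fit: float
    mean_fit: float
    fitnesses: np.ndarray
    best_index: int


@dataclass
class RunTrace:
    """Per-generation record of one run plus switch events and snapshots."""

    generation: np.ndarray
    env: np.ndarray
    max_fit: np.ndarray
    mean_fit: np.ndarray
    switches: list[dict]
    snapshots: list[tuple[int, np.ndarray]]
    dual: list[tuple[int, np.ndarray]]
    seed: int
    config: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "env": self.env,
                "max_fit": self.max_fit,
                "mean_fit": self.mean_fit,
            }
        )

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def seed_streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent named generators derived deterministically from one seed."""
    return {
        name: np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(i,)))
        for i, name in enumerate(STREAM_NAMES)
    }


def environment_at(generation: int, sched: EnvironmentSchedule) -> int:
    """Environment index active at a generation (0 or 1)."""
    if generation < 0:
        raise ValueError("generation must be >= 0")
    if sched.kind == "variable" and len(sched.targets) > 1:
        return (generation // sched.season_length) % 2
    return 0


def truncation_select(fitnesses, mu: int) -> np.ndarray:
    """Indices of the mu fittest individuals; ties broken by lower index."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if mu > fitnesses.size:
        raise ValueError("mu exceeds population size")
    order = np.argsort(-fitnesses, kind="stable")
    return order[:mu]


def snapshot_generations(generations: int, count: int) -> np.ndarray:
    """`count` generation indices spread evenly over the run, endpoints included."""
    if count <= 0 or generations <= 0:
        return np.array([], dtype=int)
    pts = np.linspace(0, generations - 1, num=min(count, generations))
    return np.unique(np.round(pts).astype(int))


def step_generation(weights, target_grid, ic, cfg: EvolutionConfig, rng):
    """One evaluate-select-reproduce cycle.

    Returns the next population and a record of the evaluated one.  Parents
    survive unchanged unless ``cfg.mutate_parents`` is set; offspring are
    laid out survivor-major (all of parent 0's offspring first).
    """
    phens = develop_population(weights, ic, cfg.development)
    fits = fitness_population(phens, target_grid)
    survivors = truncation_select(fits, cfg.mu)
    parents = weights[survivors]
    offspring = mutate_population(np.repeat(parents, cfg.lam, axis=0), cfg.mutation, rng)
    if cfg.mutate_parents:
        parents = mutate_population(parents, cfg.mutation, rng)
    new_weights = np.concatenate([parents, offspring], axis=0)
    record = GenerationRecord(
        max_fit=float(fits.max()),
        mean_fit=float(fits.mean()),
        fitnesses=fits,
        best_index=int(survivors[0]),
    )
    return new_weights, record


def run_experiment(cfg: EvolutionConfig, sched: EnvironmentSchedule) -> RunTrace:
    """Run one full evolutionary experiment and record its trace.

    Deterministic given ``cfg.seed``.  Fitness is evaluated at the start of
    each generation against that generation's environment, so the
    post-switch fitness drop shows up at the first generation of a season.
    """
    streams = seed_streams(cfg.seed)
    dev = cfg.development
    weights = init_population(cfg.popsize, dev, cfg.mutation, streams["init"])

    base = sched.targets[0]
    if base.ic is None:
        raise ValueError("schedule target needs an initial condition for development")
    snap_at = set(snapshot_generations(cfg.generations, cfg.snapshot_count).tolist())

    gens = np.arange(cfg.generations)
    env_ids = np.zeros(cfg.generations, dtype=int)
    max_fit = np.empty(cfg.generations)
    mean_fit = np.empty(cfg.generations)
    switches: list[dict] = []
    snapshots: list[tuple[int, np.ndarray]] = []
    dual: list[tuple[int, np.ndarray]] = []

    random_target: np.ndarray | None = None
    prev_env = None

    for g in range(cfg.generations):
        env = environment_at(g, sched)
        env_ids[g] = env

        if cfg.schedule_kind == "mutation_pulse" and g > 0 and g % cfg.season_length == 0:
            weights = weights + streams["pulse"].normal(0.0, cfg.pulse_sd, size=weights.shape)

        if cfg.schedule_kind == "random_target" and cfg.random_target_span > 0:
            pos = g % cfg.season_length
            onset = cfg.season_length - cfg.random_target_span
            if pos == onset:
                random_target = streams["random_target"].normal(
                    0.0, 1.0, size=(dev.n_rows, dev.n_cells)
                )
            in_random_span = pos >= onset
            target_grid = random_target if in_random_span else base.grid
            ic = base.ic
        else:
            current = sched.targets[env] if len(sched.targets) > env else base
            target_grid, ic = current.grid, current.ic

        weights_before = weights
        weights, rec = step_generation(weights_before, target_grid, ic, cfg, streams["mutation"])
        max_fit[g] = rec.max_fit
        mean_fit[g] = rec.mean_fit

        if prev_env is not None and env != prev_env:
            switches.append(
                {
                    "generation": g,
                    "old_env": int(prev_env),
                    "new_env": int(env),
                    "pre_max": float(max_fit[g - 1]),
                    "pre_mean": float(mean_fit[g - 1]),
                    "post_max": float(max_fit[g]),
                    "post_mean": float(mean_fit[g]),
                }
            )

        if g in snap_at:
            snapshots.append((g, weights_before[rec.best_index].copy()))
            if cfg.track_dual_fitness and sched.kind == "variable" and len(sched.targets) > 1:
                k = max(1, int(round(cfg.dual_sample_fraction * cfg.popsize)))
                idx = streams["sampling"].choice(cfg.popsize, size=k, replace=False)
                cols = []
                for t in sched.targets:
                    ph = develop_population(weights_before[idx], t.ic, dev)
                    cols.append(fitness_population(ph, t.grid))
                dual.append((g, np.column_stack(cols)))

        prev_env = env

    return RunTrace(
        generation=gens,
        env=env_ids,
        max_fit=max_fit,
        mean_fit=mean_fit,
        switches=switches,
        snapshots=snapshots,
        dual=dual,
        seed=cfg.seed,
        config=cfg.to_dict(),
    )


def run_static(cfg: EvolutionConfig, target: TargetPattern) -> RunTrace:
    cfg = replace(cfg, schedule_kind="static")
    return run_experiment(cfg, EnvironmentSchedule.static(target))


def run_variable(cfg: EvolutionConfig, pair: LandscapePair) -> RunTrace:
    cfg = replace(cfg, schedule_kind="variable")
    return run_experiment(cfg, EnvironmentSchedule.variable(pair, cfg.season_length))


def run_mutation_pulse(cfg: EvolutionConfig, static_target: TargetPattern) -> RunTrace:
    """Static selection with a dense N(0, pulse_sd) mutation pulse each season."""
    cfg = replace(cfg, schedule_kind="mutation_pulse")
    sched = EnvironmentSchedule(targets=(static_target,), kind="mutation_pulse",
                                season_length=cfg.season_length)
    return run_experiment(cfg, sched)


def run_random_target(cfg: EvolutionConfig, static_target: TargetPattern) -> RunTrace:
    """Static selection except the season's last ``random_target_span``
    generations select for a fresh N(0,1) random target."""
    cfg = replace(cfg, schedule_kind="random_target")
    sched = EnvironmentSchedule(targets=(static_target,), kind="random_target",
                                season_length=cfg.season_length)
    return run_experiment(cfg, sched)


def run_replicates(cfg: EvolutionConfig, sched: EnvironmentSchedule, seeds) -> list[RunTrace]:
    """Run the same configuration under several seeds (one trace per seed)."""
    return [run_experiment(replace(cfg, seed=int(s)), sched) for s in seeds]
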