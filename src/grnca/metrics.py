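"""Robustness, variability, evolvability and landscape-exploration metrics.

These estimators operate on genotypes and run traces produced by
:mod:`grnca.evolution`:

* mutational robustness — perturb a genotype into clones and measure how
  little phenotype and fitness move (2,500 clones in the full-scale study);
* phenotypic variability map — per-position SD of clone phenotypes (10,000
  clones), with a bias summary splitting positions where a landscape pair's
  targets agree versus differ;
* dual-environment fitness of a population sample;
* season metrics — post-switch fitness drops, recovery lengths and their
  least-squares trends over seasons;
* offspring-improvement fraction at environment switches — the operational
  evolvability readout;
* genotype-space exploration — snapshot distances, across-replicate weight
  SD, and a 2-component metric MDS embedding;
* treatment comparisons — Mann–Whitney U with Benjamini–Hochberg FDR,
  Kruskal–Wallis, and aligned-rank-transform two-way ANOVA (in
  :mod:`grnca.stats`);
* target difficulty and the variable-minus-static best-fitness effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress
from sklearn.manifold import MDS

from .ca import LandscapePair, TargetPattern
from .development import (
    DevelopmentConfig,
    Genotype,
    MutationConfig,
    develop,
    develop_population,
    fitness,
    fitness_population,
    mutate_population,
)
from .evolution import RunTrace

__all__ = [
    "RobustnessReport",
    "VariabilityMap",
    "SeasonSummary",
    "ExplorationReport",
    "clone_weights",
    "mutational_robustness",
    "variability_map",
    "variability_bias",
    "dual_fitness",
    "season_metrics",
    "offspring_improvement_fraction",
    "improvement_slope",
    "mds_embed",
    "genotype_exploration",
    "difficulty",
    "best_effect_summary",
]


@dataclass(frozen=True)
class RobustnessReport:
    """Average phenotype/fitness displacement of mutated clones.

    ``phenotypic_robustness`` is the mean absolute per-entry phenotype
    change over clones (0 = perfectly robust, 1 = every entry flipped to its
    opposite); ``fitness_robustness`` is the mean signed clone-minus-parent
    fitness change.
    """

    phenotypic_robustness: float
    fitness_robustness: float
    n_clones: int


@dataclass(frozen=True)
class VariabilityMap:
    """Per-position SD of clone phenotypes over a [rows x cells] grid."""

    grid: np.ndarray
    n_clones: int


@dataclass(frozen=True)
class SeasonSummary:
    """Per-season fitness statistics of a variable run and their trends."""

    seasons: pd.DataFrame
    slopes: pd.DataFrame
    statistic: str


@dataclass(frozen=True)
class ExplorationReport:
    """How far snapshot genotypes travelled through weight space."""

    distance_from_start: np.ndarray        # (n_replicates, n_snapshots)
    distance_from_previous: np.ndarray     # (n_replicates, n_snapshots)
    replicate_weight_sd: float
    embedding: np.ndarray                  # (n_replicates * n_snapshots, 2)
    stress: float
    labels: pd.DataFrame


def _as_weights(genotype) -> np.ndarray:
    if isinstance(genotype, Genotype):
        return genotype.weights
    return np.asarray(genotype, dtype=float)


def clone_weights(genotype, mcfg: MutationConfig, n_clones: int, rng,
                  dense: bool = False, dense_sd: float | None = None) -> np.ndarray:
    """Mutated clones of one genotype, shape (n_clones, G, G+2).

    Default uses the evolutionary operator (per-weight Bernoulli(rate) +
    N(0, sd)); ``dense=True`` perturbs every weight with N(0, dense_sd or
    mcfg.sd) instead.
    """
    w = _as_weights(genotype)
    stack = np.repeat(w[None], n_clones, axis=0)
    if dense:
        sd = mcfg.sd if dense_sd is None else dense_sd
        return stack + rng.normal(0.0, sd, size=stack.shape)
    return mutate_population(stack, mcfg, rng)


def mutational_robustness(genotype, target, mcfg: MutationConfig,
                          devcfg: DevelopmentConfig, n_clones: int = 2500,
                          rng=None, dense: bool = False,
                          dense_sd: float | None = None) -> RobustnessReport:
    """Explore a genotype's mutational neighbourhood with clone perturbations."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if not isinstance(target, TargetPattern) or target.ic is None:
        raise ValueError("target must be a TargetPattern with an initial condition")
    parent_phen = develop(genotype, target.ic, devcfg)
    parent_fit = fitness(parent_phen, target)
    clones = clone_weights(genotype, mcfg, n_clones, rng, dense=dense, dense_sd=dense_sd)
    clone_phens = develop_population(clones, target.ic, devcfg)
    clone_fits = fitness_population(clone_phens, target)
    pheno = float(np.abs(clone_phens - parent_phen[None]).mean())
    return RobustnessReport(
        phenotypic_robustness=pheno,
        fitness_robustness=float((clone_fits - parent_fit).mean()),
        n_clones=n_clones,
    )


def variability_map(genotype, ic, mcfg: MutationConfig, devcfg: DevelopmentConfig,
                    n_clones: int = 10000, rng=None, dense: bool = False,
                    dense_sd: float | None = None) -> VariabilityMap:
    """Per-position SD of clone phenotypes (population SD over clones).

    Row 0 is the clamped initial condition, so it is identically zero.
    """
    if n_clones < 2:
        raise ValueError("n_clones must be >= 2 to estimate an SD")
    if rng is None:
        rng = np.random.default_rng()
    clones = clone_weights(genotype, mcfg, n_clones, rng, dense=dense, dense_sd=dense_sd)
    phens = develop_population(clones, ic, devcfg)
    return VariabilityMap(grid=phens.std(axis=0), n_clones=n_clones)


def variability_bias(vmap: VariabilityMap, pair: LandscapePair) -> dict:
    """Mean clone-phenotype SD where the pair's targets agree vs differ.

    When the targets are identical the differing-position set is empty and
    ``mean_sd_differ`` is ``None`` (absent, not zero).
    """
    a, b = pair.target_a.grid, pair.target_b.grid
    if a.shape != vmap.grid.shape or b.shape != vmap.grid.shape:
        raise ValueError("variability map and target shapes differ")
    differ = a != b
    agree = ~differ
    return {
        "mean_sd_agree": float(vmap.grid[agree].mean()) if agree.any() else None,
        "mean_sd_differ": float(vmap.grid[differ].mean()) if differ.any() else None,
        "n_agree": int(agree.sum()),
        "n_differ": int(differ.sum()),
    }


def dual_fitness(weights, pair: LandscapePair, devcfg: DevelopmentConfig,
                 sample_fraction: float = 0.10, rng=None):
    """Fitness of a random population sample in both environments.

    Each sampled individual is developed once per environment (the two
    environments may differ in initial condition).  Returns the sampled
    indices and a (k, 2) fitness array with env 1 = target A in column 0.
    """
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if rng is None:
        rng = np.random.default_rng()
    k = max(1, int(round(sample_fraction * n)))
    idx = np.sort(rng.choice(n, size=k, replace=False)) if k < n else np.arange(n)
    cols = []
    for t in pair.targets:
        phens = develop_population(w[idx], t.ic, devcfg)
        cols.append(fitness_population(phens, t.grid))
    return idx, np.column_stack(cols)


def _season_blocks(env: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous (start, end_exclusive, env) blocks of a trace's env column."""
    blocks = []
    start = 0
    for g in range(1, env.size + 1):
        if g == env.size or env[g] != env[start]:
            blocks.append((start, g, int(env[start])))
            start = g
    return blocks


def _ols(x, y):
    if len(x) < 2:
        return float("nan"), float("nan")
    res = linregress(np.asarray(x, float), np.asarray(y, float))
    return float(res.slope), float(res.rvalue ** 2)


def season_metrics(trace: RunTrace, statistic: str = "mean") -> SeasonSummary:
    """Post-switch drops, recovery lengths, and their trends over seasons.

    ``statistic`` picks the population summary ("mean" or "max") used for
    both the pre- and post-switch values.  For each season after the first:
    drop = (statistic at the last generation of the previous season) minus
    (statistic at the first generation of the new season); recovery length
    = generations until the statistic first regains its pre-switch value,
    capped at the season length.  Slopes are ordinary least squares of the
    drop and of the post-switch value against season index, separately per
    environment.
    """
    if statistic not in ("mean", "max"):
        raise ValueError("statistic must be 'mean' or 'max'")
    series = trace.mean_fit if statistic == "mean" else trace.max_fit
    blocks = _season_blocks(trace.env)
    if len(blocks) < 2:
        raise ValueError("season metrics need a trace with at least two seasons")

    rows = []
    for j, (start, end, env) in enumerate(blocks):
        row = {
            "season": j,
            "env": env,
            "start": start,
            "end": end - 1,
            "end_max": float(trace.max_fit[end - 1]),
            "end_mean": float(trace.mean_fit[end - 1]),
            "post_switch": np.nan,
            "drop": np.nan,
            "recovery": np.nan,
        }
        if j > 0:
            pre = float(series[start - 1])
            post = float(series[start])
            row["post_switch"] = post
            row["drop"] = pre - post
            within = series[start:end]
            reached = np.nonzero(within >= pre)[0]
            row["recovery"] = int(reached[0]) if reached.size else int(end - start)
        rows.append(row)
    seasons = pd.DataFrame(rows)

    slope_rows = []
    switched = seasons[seasons["season"] > 0]
    for env, grp in switched.groupby("env"):
        drop_slope, drop_r2 = _ols(grp["season"], grp["drop"])
        post_slope, post_r2 = _ols(grp["season"], grp["post_switch"])
        slope_rows.append(
            {
                "env": int(env),
                "drop_slope": drop_slope,
                "drop_r2": drop_r2,
                "post_switch_slope": post_slope,
                "post_switch_r2": post_r2,
            }
        )
    slopes = pd.DataFrame(slope_rows)
    return SeasonSummary(seasons=seasons, slopes=slopes, statistic=statistic)


def offspring_improvement_fraction(parent_weights, new_target: TargetPattern,
                                   mcfg: MutationConfig, devcfg: DevelopmentConfig,
                                   lam: int = 9, rng=None) -> float:
    """Fraction of mutant offspring strictly fitter than their parent in a
    new environment.

    Each parent contributes ``lam`` offspring generated with the run's
    mutation operator; ties count as not improved.
    """
    if rng is None:
        rng = np.random.default_rng()
    w = np.asarray(parent_weights, dtype=float)
    if w.ndim == 2:
        w = w[None]
    parent_phens = develop_population(w, new_target.ic, devcfg)
    parent_fits = fitness_population(parent_phens, new_target.grid)
    offspring = mutate_population(np.repeat(w, lam, axis=0), mcfg, rng)
    off_phens = develop_population(offspring, new_target.ic, devcfg)
    off_fits = fitness_population(off_phens, new_target.grid)
    return float((off_fits > np.repeat(parent_fits, lam)).mean())


def improvement_slope(fractions) -> float:
    """Least-squares slope of improvement fractions over switch index."""
    fractions = np.asarray(fractions, dtype=float)
    slope, _ = _ols(np.arange(fractions.size), fractions)
    return slope


def mds_embed(dissimilarity: np.ndarray, seed: int = 0) -> tuple[np.ndarray, float]:
    """Metric 2-component MDS of a precomputed distance matrix."""
    model = MDS(
        n_components=2,
        dissimilarity="precomputed",
        n_init=8,
        max_iter=3000,
        eps=1e-12,
        random_state=seed,
    )
    with np.errstate(invalid="ignore"):
        coords = model.fit_transform(np.asarray(dissimilarity, dtype=float))
    return coords, float(model.stress_)


def genotype_exploration(snapshots_by_replicate, seed: int = 0) -> ExplorationReport:
    """Distances travelled by best-genotype snapshots, plus an MDS map.

    ``snapshots_by_replicate`` is a list (one entry per replicate) of
    equal-length lists of weight matrices, ordered by generation.  Distances
    are Euclidean on the flattened weights.  The across-replicate weight SD
    takes the final snapshot of every replicate, computes the per-weight SD
    across replicates and averages it into one scalar.
    """
    flats = []
    counts = {len(snaps) for snaps in snapshots_by_replicate}
    if len(counts) != 1:
        raise ValueError(f"replicates disagree on snapshot count: {sorted(counts)}")
    n_snaps = counts.pop()
    if n_snaps < 2:
        raise ValueError("need at least two snapshots per replicate")
    for snaps in snapshots_by_replicate:
        flats.append(np.stack([np.asarray(w, float).ravel() for w in snaps]))
    cube = np.stack(flats)  # (reps, snaps, weights)

    d_start = np.linalg.norm(cube - cube[:, :1, :], axis=2)
    d_prev = np.zeros_like(d_start)
    d_prev[:, 1:] = np.linalg.norm(cube[:, 1:, :] - cube[:, :-1, :], axis=2)

    finals = cube[:, -1, :]
    replicate_sd = float(finals.std(axis=0, ddof=1).mean()) if cube.shape[0] > 1 else 0.0

    pooled = cube.reshape(-1, cube.shape[2])
    dist = squareform(pdist(pooled))
    embedding, stress = mds_embed(dist, seed=seed)
    labels = pd.DataFrame(
        {
            "replicate": np.repeat(np.arange(cube.shape[0]), n_snaps),
            "snapshot": np.tile(np.arange(n_snaps), cube.shape[0]),
        }
    )
    return ExplorationReport(
        distance_from_start=d_start,
        distance_from_previous=d_prev,
        replicate_weight_sd=replicate_sd,
        embedding=embedding,
        stress=stress,
        labels=labels,
    )


def difficulty(static_traces) -> float:
    """Mean over replicates of the best mean-population fitness reached."""
    traces = list(static_traces)
    if not traces:
        raise ValueError("need at least one static trace")
    return float(np.mean([t.mean_fit.max() for t in traces]))


def best_effect_summary(variable_traces, static_a_traces, static_b_traces) -> dict:
    """Variable-minus-static difference in best fitness ever reached.

    For each environment and each statistic (max and mean population
    fitness): average over replicates the highest value the statistic ever
    reached in the variable runs, subtract the same quantity from the
    corresponding static runs.  Positive values mean variability helped.
    """
    def best(traces, attr):
        vals = [getattr(t, attr).max() for t in traces]
        if not vals:
            raise ValueError("empty trace list")
        return float(np.mean(vals))

    out = {}
    for attr, tag in (("max_fit", "max"), ("mean_fit", "mean")):
        v = best(variable_traces, attr)
        out[f"delta_{tag}_env1"] = v - best(static_a_traces, attr)
        out[f"delta_{tag}_env2"] = v - best(static_b_traces, attr)
    return out
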