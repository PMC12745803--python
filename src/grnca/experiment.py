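"""Experiment orchestration: config schema, seeds, replicate sweeps, bundles.

A YAML/JSON experiment config names one landscape pair (a CA rule plus two
initial conditions, or two rules sharing one initial condition), a list of
treatments, a replicate count and a root seed.  Every (treatment,
replicate) run receives a distinct seed derived deterministically from the
root seed, so a manifest is sufficient to reproduce every trace
byte-for-byte.
"""

from __future__ import annotations

import copy
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ca import (
    InitialCondition,
    LandscapePair,
    generate_ic_pairs,
    generate_target,
    manual_spaced_ic,
)
from .development import DevelopmentConfig, MutationConfig
from .evolution import (
    EvolutionConfig,
    RunTrace,
    run_mutation_pulse,
    run_random_target,
    run_static,
    run_variable,
)
from . import metrics
from .io import save_trace

__all__ = [
    "ExperimentSpec",
    "ResultsBundle",
    "DEFAULT_CONFIG",
    "TREATMENTS",
    "derive_seed",
    "load_config",
    "save_config",
    "build_pair",
    "run_suite",
    "demo_reduced_study",
]

logger = logging.getLogger("grnca")

TREATMENTS = ("static_a", "static_b", "variable", "pulse", "random_target")

DEFAULT_CONFIG: dict = {
    "pair": {
        "rule": 54,
        "rule_b": None,          # set for a rule-switch pair (shares ic_a)
        "steps": None,           # default: n_rows - 1
        "ic_a": None,            # bit-string; None -> manual 4-ones spaced IC
        "ic_b": None,            # bit-string; None -> manual 6-ones spaced IC
    },
    "treatments": ["static_a", "static_b", "variable"],
    "replicates": 3,
    "seed": 0,
    "out_dir": None,
    "evolution": {
        "popsize": 1000,
        "mu": 100,
        "generations": 10000,
        "season_length": 300,
        "pulse_sd": 1.0,
        "random_target_span": 3,
        "snapshot_count": 33,
        "track_dual_fitness": False,
        "dual_sample_fraction": 0.10,
        "mutate_parents": False,
    },
    "mutation": {"rate": 0.10, "sd": 0.5, "init_sd": 1.0},
    "development": {
        "n_genes": 8,
        "n_cells": 22,
        "n_rows": 22,
        "gain": 10.0,
        "offset": 5.0,
        "comm_left_idx": 0,
        "comm_right_idx": -1,
        "target_gene_idx": 1,
        "neighbor_source": "intermediate",
    },
}


@dataclass
class ExperimentSpec:
    """A fully resolved experiment configuration."""

    pair: dict
    treatments: list[str]
    replicates: int
    seed: int
    out_dir: str | None
    evolution: dict
    mutation: dict
    development: dict

    def __post_init__(self) -> None:
        for t in self.treatments:
            if t not in TREATMENTS:
                raise ValueError(f"unknown treatment {t!r}; choose from {TREATMENTS}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        # construct eagerly so schema errors (e.g. popsize/mu divisibility)
        # surface at load time
        self.evolution_config()

    def development_config(self) -> DevelopmentConfig:
        return DevelopmentConfig(**self.development)

    def mutation_config(self) -> MutationConfig:
        return MutationConfig(**self.mutation)

    def evolution_config(self) -> EvolutionConfig:
        return EvolutionConfig(
            mutation=self.mutation_config(),
            development=self.development_config(),
            seed=self.seed,
            **self.evolution,
        )

    def to_dict(self) -> dict:
        return {
            "pair": copy.deepcopy(self.pair),
            "treatments": list(self.treatments),
            "replicates": self.replicates,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "evolution": copy.deepcopy(self.evolution),
            "mutation": copy.deepcopy(self.mutation),
            "development": copy.deepcopy(self.development),
        }


@dataclass
class ResultsBundle:
    """Manifest + traces + aggregate tables of one experiment suite."""

    manifest: dict
    traces: dict = field(default_factory=dict)
    summary: dict | None = None
    incomplete: bool = False
    errors: list = field(default_factory=list)


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key {here!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path) -> ExperimentSpec:
    """Load a YAML/JSON experiment config, filling in all defaults.

    Unknown keys are rejected with the offending key named.
    """
    text = Path(str(path)).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("experiment config must be a mapping")
    merged = _merge(DEFAULT_CONFIG, data)
    return ExperimentSpec(**merged)


def save_config(spec: ExperimentSpec, path) -> None:
    Path(str(path)).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def derive_seed(root_seed: int, treatment: str, replicate: int) -> int:
    """Deterministic per-run seed from (root seed, treatment, replicate)."""
    h = zlib.crc32(f"{treatment}:{replicate}".encode())
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(h, int(replicate)))
    return int(ss.generate_state(1)[0] % (2**31))


def _parse_ic(bits: str | None, fallback: InitialCondition) -> InitialCondition:
    if bits is None:
        return fallback
    return InitialCondition(bits=tuple(int(b) for b in str(bits)), label="config")


def build_pair(spec: ExperimentSpec) -> LandscapePair:
    """Materialise the configured landscape pair."""
    dev = spec.development_config()
    steps = spec.pair.get("steps") or dev.n_rows - 1
    ic_a = _parse_ic(spec.pair.get("ic_a"), manual_spaced_ic(dev.n_cells, 4))
    rule_a = int(spec.pair["rule"])
    rule_b = spec.pair.get("rule_b")
    if rule_b is not None:
        # rule-switch pair: both targets share ic_a
        ta = generate_target(rule_a, ic_a, steps)
        tb = generate_target(int(rule_b), ic_a, steps)
        return LandscapePair(mode="rule_switch", target_a=ta, target_b=tb)
    ic_b = _parse_ic(spec.pair.get("ic_b"), manual_spaced_ic(dev.n_cells, 6))
    ta = generate_target(rule_a, ic_a, steps)
    tb = generate_target(rule_a, ic_b, steps)
    return LandscapePair(mode="ic_switch", target_a=ta, target_b=tb)


def _run_one(treatment: str, cfg: EvolutionConfig, pair: LandscapePair) -> RunTrace:
    if treatment == "static_a":
        return run_static(cfg, pair.target_a)
    if treatment == "static_b":
        return run_static(cfg, pair.target_b)
    if treatment == "variable":
        return run_variable(cfg, pair)
    # displacement controls run on the second member of the pair
    if treatment == "pulse":
        return run_mutation_pulse(cfg, pair.target_b)
    if treatment == "random_target":
        return run_random_target(cfg, pair.target_b)
    raise ValueError(f"unknown treatment {treatment!r}")


def run_suite(spec: ExperimentSpec) -> ResultsBundle:
    """Execute all (treatment, replicate) runs of a spec and summarise them.

    Traces are written under ``spec.out_dir`` when set.  A failing run is
    logged and surfaced through ``bundle.errors`` with the bundle marked
    incomplete; completed runs are kept.
    """
    from dataclasses import replace

    pair = build_pair(spec)
    base_cfg = spec.evolution_config()
    out_dir = Path(spec.out_dir) if spec.out_dir else None
    bundle = ResultsBundle(
        manifest={"config": spec.to_dict(), "runs": []},
    )

    for treatment in spec.treatments:
        for rep in range(spec.replicates):
            seed = derive_seed(spec.seed, treatment, rep)
            cfg = replace(base_cfg, seed=seed)
            try:
                trace = _run_one(treatment, cfg, pair)
            except Exception as exc:  # pragma: no cover - partial-failure path
                logger.error("run %s rep %d failed: %s", treatment, rep, exc)
                bundle.errors.append({"treatment": treatment, "replicate": rep, "error": str(exc)})
                bundle.incomplete = True
                continue
            bundle.traces[(treatment, rep)] = trace
            entry = {"treatment": treatment, "replicate": rep, "seed": seed}
            if out_dir is not None:
                files = save_trace(out_dir / f"{treatment}_rep{rep}", trace, snapshots=True)
                entry["trace_csv"] = files["csv"]
                entry["trace_json"] = files["json"]
            bundle.manifest["runs"].append(entry)
            logger.info(
                "finished %s rep %d (seed %d): final max %.3f mean %.3f",
                treatment, rep, seed, trace.max_fit[-1], trace.mean_fit[-1],
            )

    have = {t for (t, _) in bundle.traces}
    if {"variable", "static_a", "static_b"} <= have:
        by = lambda t: [tr for (name, _), tr in sorted(bundle.traces.items()) if name == t]
        bundle.summary = metrics.best_effect_summary(
            by("variable"), by("static_a"), by("static_b")
        )
        if out_dir is not None:
            pd.DataFrame([bundle.summary]).to_csv(out_dir / "summary.csv", index=False)
    if out_dir is not None:
        (out_dir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))
    return bundle


def demo_reduced_study(out_dir, seed: int = 0, *, rules=(54, 30), popsize: int = 100,
                       mu: int = 10, generations: int = 600, season_length: int = 100,
                       replicates: int = 3, n_clones: int = 300,
                       snapshot_count: int = 7) -> dict:
    """Desk-scale end-to-end study: two landscape pairs, three treatments.

    Runs static/static/variable arms for each rule on the evenly spaced
    4-vs-6 initial-condition pair, then computes the variable-minus-static
    fitness effect, season drop metrics, clone robustness of the final best
    genotypes, and genotype-space exploration.  All outputs land as
    CSV/JSON under ``out_dir``.
    """
    out = Path(str(out_dir))
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    summary_rows, robustness_rows, season_rows = [], [], []

    for rule in rules:
        spec = ExperimentSpec(
            pair={"rule": int(rule), "rule_b": None, "steps": None, "ic_a": None, "ic_b": None},
            treatments=["static_a", "static_b", "variable"],
            replicates=replicates,
            seed=int(seed),
            out_dir=str(out / f"rule{rule}"),
            evolution={
                **DEFAULT_CONFIG["evolution"],
                "popsize": popsize,
                "mu": mu,
                "generations": generations,
                "season_length": season_length,
                "snapshot_count": snapshot_count,
            },
            mutation=dict(DEFAULT_CONFIG["mutation"]),
            development=dict(DEFAULT_CONFIG["development"]),
        )
        bundle = run_suite(spec)
        results[rule] = bundle
        if bundle.summary is not None:
            summary_rows.append({"rule": rule, **bundle.summary})

        pair = build_pair(spec)
        devcfg = spec.development_config()
        mcfg = spec.mutation_config()
        for (treatment, rep), trace in bundle.traces.items():
            if trace.snapshots:
                _, best = trace.snapshots[-1]
                rng = np.random.default_rng(derive_seed(seed, f"robust-{treatment}", rep))
                rep_target = pair.target_a if treatment != "static_b" else pair.target_b
                rob = metrics.mutational_robustness(
                    best, rep_target, mcfg, devcfg, n_clones=n_clones, rng=rng
                )
                robustness_rows.append(
                    {
                        "rule": rule,
                        "treatment": treatment,
                        "replicate": rep,
                        "phenotypic_robustness": rob.phenotypic_robustness,
                        "fitness_robustness": rob.fitness_robustness,
                    }
                )
            if treatment == "variable":
                summ = metrics.season_metrics(trace)
                for _, row in summ.seasons.iterrows():
                    season_rows.append(
                        {"rule": rule, "replicate": rep, **row.to_dict()}
                    )

        var_snaps = [
            [w for _, w in bundle.traces[("variable", r)].snapshots]
            for r in range(replicates)
            if ("variable", r) in bundle.traces
        ]
        if len(var_snaps) >= 2:
            explo = metrics.genotype_exploration(var_snaps, seed=int(seed))
            (out / f"rule{rule}" / "exploration.json").write_text(
                json.dumps(
                    {
                        "replicate_weight_sd": explo.replicate_weight_sd,
                        "mean_distance_from_start": explo.distance_from_start[:, -1].mean(),
                        "mds_stress": explo.stress,
                    },
                    indent=2,
                )
            )

    if summary_rows:
        pd.DataFrame(summary_rows).to_csv(out / "best_effect_summary.csv", index=False)
    if robustness_rows:
        pd.DataFrame(robustness_rows).to_csv(out / "robustness.csv", index=False)
    if season_rows:
        pd.DataFrame(season_rows).to_csv(out / "seasons.csv", index=False)
    return results
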