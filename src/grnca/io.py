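"""Plain-text serialisation: pattern grids, genotypes, traces, manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ca import InitialCondition, SuiteManifest, TargetPattern, pattern_features
from .development import DevelopmentConfig
from .evolution import RunTrace

__all__ = [
    "save_grid",
    "load_grid",
    "save_genotype",
    "load_genotype",
    "save_trace",
    "load_trace",
    "save_suite",
]


def save_grid(path, grid) -> None:
    """Write a grid as rows of space-separated values (ints if binary)."""
    grid = np.asarray(grid)
    fmt = "%d" if np.issubdtype(grid.dtype, np.integer) or np.isin(grid, (0, 1)).all() else "%.10g"
    np.savetxt(path, grid, fmt=fmt)


def load_grid(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path))


def save_genotype(path_csv, weights, devcfg: DevelopmentConfig | None = None) -> None:
    """Genotype as a CSV weight matrix plus a JSON sidecar with gene roles."""
    weights = np.asarray(weights, dtype=float)
    np.savetxt(path_csv, weights, delimiter=",")
    if devcfg is not None:
        left, right, target = devcfg.roles
        sidecar = Path(str(path_csv)).with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "n_genes": devcfg.n_genes,
                    "comm_left_idx": left,
                    "comm_right_idx": right,
                    "target_gene_idx": target,
                },
                indent=2,
            )
        )


def load_genotype(path_csv) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path_csv, delimiter=","))


def save_trace(prefix, trace: RunTrace, snapshots: bool = False) -> dict:
    """Write a trace as <prefix>.csv (per-generation) + <prefix>.json (meta).

    With ``snapshots=True`` each snapshot genotype goes to
    <prefix>.snap<generation>.csv.
    """
    prefix = Path(str(prefix))
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    trace.to_dataframe().to_csv(csv_path, index=False)
    meta = {
        "seed": trace.seed,
        "config": trace.config,
        "config_hash": trace.config_hash,
        "switches": trace.switches,
        "snapshot_generations": [int(g) for g, _ in trace.snapshots],
    }
    snap_files = []
    if snapshots:
        for g, w in trace.snapshots:
            p = prefix.parent / f"{prefix.name}.snap{g}.csv"
            np.savetxt(p, np.asarray(w), delimiter=",")
            snap_files.append(p.name)
        meta["snapshot_files"] = snap_files
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=2))
    return {"csv": str(csv_path), "json": str(json_path), "snapshots": snap_files}


def load_trace(prefix) -> RunTrace:
    """Rebuild a RunTrace from save_trace output (snapshots included if present)."""
    prefix = Path(str(prefix))
    df = pd.read_csv(prefix.with_suffix(".csv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    snapshots = []
    for name in meta.get("snapshot_files", []):
        g = int(name.rsplit(".snap", 1)[1].split(".")[0])
        snapshots.append((g, np.atleast_2d(np.loadtxt(prefix.parent / name, delimiter=","))))
    return RunTrace(
        generation=df["generation"].to_numpy(),
        env=df["env"].to_numpy(),
        max_fit=df["max_fit"].to_numpy(),
        mean_fit=df["mean_fit"].to_numpy(),
        switches=meta["switches"],
        snapshots=snapshots,
        dual=[],
        seed=meta["seed"],
        config=meta["config"],
    )


def _ic_to_str(ic: InitialCondition | None) -> str | None:
    return "".join(map(str, ic.bits)) if ic is not None else None


def save_suite(manifest: SuiteManifest, out_dir) -> Path:
    """Write every target grid and a JSON manifest referencing them."""
    out = Path(str(out_dir))
    out.mkdir(parents=True, exist_ok=True)

    def dump_target(t: TargetPattern, name: str) -> dict:
        save_grid(out / f"{name}.txt", t.grid)
        return {
            "file": f"{name}.txt",
            "rule_code": t.rule_code,
            "ic": _ic_to_str(t.ic),
        }

    entries = []
    for i, pair in enumerate(manifest.pairs):
        entries.append(
            {
                "mode": pair.mode,
                "target_a": dump_target(pair.target_a, f"pair{i:03d}_a"),
                "target_b": dump_target(pair.target_b, f"pair{i:03d}_b"),
                "features": pattern_features(pair),
            }
        )
    doc = {
        "rules": [list(r) if isinstance(r, (tuple, list)) else int(r) for r in manifest.rules],
        "n_pairs": len(manifest.pairs),
        "n_statics": len(manifest.statics),
        "pairs": entries,
    }
    path = out / "suite.json"
    path.write_text(json.dumps(doc, indent=2))
    return path
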