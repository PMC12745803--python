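"""Elementary cellular automata: rule codec, pattern rollout, target suites.

An elementary cellular automaton (ECA) updates a ring of binary cells; the
next state of a cell depends only on its own state and that of its two
immediate neighbours.  Each of the 2^8 = 256 possible update rules is named
by the Wolfram code obtained by reading the outputs for the eight
neighbourhoods 111, 110, ..., 000 as an 8-bit binary number (111 most
significant).  Rolling a rule out from a binary initial condition produces a
two-dimensional space-time pattern; these patterns serve as the selection
targets for the developmental model in :mod:`grnca.development`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RuleTable",
    "InitialCondition",
    "TargetPattern",
    "LandscapePair",
    "SuiteManifest",
    "DEFAULT_RULES",
    "rule_to_table",
    "table_to_code",
    "eca_step",
    "generate_target",
    "rotation_classes_equal",
    "manual_spaced_ic",
    "generate_ic_pairs",
    "build_suite",
    "pattern_features",
]

#: Neighbourhoods in code order: (1,1,1) first, (0,0,0) last.
NEIGHBORHOODS = tuple(itertools.product((1, 0), repeat=3))

#: Rules identifiable from the published pattern figures, padded with nine
#: visually complex ECA rules to reach the 15 used by the default suite.
DEFAULT_RULES = (18, 30, 50, 54, 70, 122, 22, 45, 60, 90, 105, 106, 110, 126, 150)


@dataclass(frozen=True)
class RuleTable:
    """An ECA rule: its 0-255 code and the eight neighbourhood outputs.

    ``outputs[i]`` is the new cell state for the neighbourhood whose 3-bit
    value (left, centre, right) equals ``7 - i``; i.e. the output for 111
    comes first and the output for 000 last, matching how the code is read.
    """

    code: int
    outputs: tuple[int, ...]

    def lookup(self) -> np.ndarray:
        """Output bit indexed by the neighbourhood's 3-bit value 0..7."""
        return np.array(self.outputs[::-1], dtype=np.uint8)


@dataclass(frozen=True)
class InitialCondition:
    """A binary row of length C used both as CA seed and developmental input."""

    bits: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.bits) == 0:
            raise ValueError("initial condition must be nonempty")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("initial condition bits must be 0 or 1")

    def __len__(self) -> int:
        return len(self.bits)

    def as_array(self) -> np.ndarray:
        return np.array(self.bits, dtype=np.uint8)


@dataclass(frozen=True)
class TargetPattern:
    """A [rows x cells] target grid with its generating rule and seed row.

    CA-generated targets are binary; random selection targets (used by the
    random-target-selection experiments) hold real values and carry
    ``rule_code=None``.
    """

    grid: np.ndarray
    rule_code: int | None = None
    ic: InitialCondition | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class LandscapePair:
    """Two alternative targets defining a pair of fitness landscapes.

    In ``ic_switch`` mode both targets share the CA rule and differ in
    initial condition (the organism is told about the environment through
    its developmental input); in ``rule_switch`` mode both share the initial
    condition and differ in rule (the switch is invisible to the organism).
    """

    mode: str
    target_a: TargetPattern
    target_b: TargetPattern

    def __post_init__(self) -> None:
        if self.mode not in ("ic_switch", "rule_switch"):
            raise ValueError(f"unknown pair mode {self.mode!r}")
        if self.mode == "ic_switch":
            if self.target_a.rule_code != self.target_b.rule_code:
                raise ValueError("ic_switch pair must share the CA rule")
        else:
            if self.target_a.ic is None or self.target_b.ic is None:
                raise ValueError("rule_switch pair needs initial conditions")
            if self.target_a.ic.bits != self.target_b.ic.bits:
                raise ValueError("rule_switch pair must share the initial condition")

    @property
    def targets(self) -> tuple[TargetPattern, TargetPattern]:
        return (self.target_a, self.target_b)


@dataclass
class SuiteManifest:
    """The full combinatorial suite of landscape pairs and static targets."""

    rules: list
    ic_pairs: list
    pairs: list[LandscapePair] = field(default_factory=list)
    statics: list[TargetPattern] = field(default_factory=list)


def rule_to_table(code: int) -> RuleTable:
    """Decode a Wolfram code into its eight neighbourhood outputs."""
    code = int(code)
    if not 0 <= code <= 255:
        raise ValueError(f"ECA rule code must be in [0, 255], got {code}")
    outputs = tuple((code >> (7 - i)) & 1 for i in range(8))
    return RuleTable(code=code, outputs=outputs)


def table_to_code(table) -> int:
    """Encode eight neighbourhood outputs (111 first) back to the 0-255 code."""
    outputs = table.outputs if isinstance(table, RuleTable) else tuple(table)
    if len(outputs) != 8 or any(b not in (0, 1) for b in outputs):
        raise ValueError("rule table must be eight bits")
    code = 0
    for bit in outputs:
        code = (code << 1) | bit
    return code


def _as_rule(rule) -> RuleTable:
    return rule if isinstance(rule, RuleTable) else rule_to_table(rule)


def eca_step(row, rule) -> np.ndarray:
    """Apply one ECA update to a binary row with periodic boundaries."""
    rule = _as_rule(rule)
    row = np.asarray(row)
    if row.ndim != 1 or row.size == 0:
        raise ValueError("row must be a nonempty 1-D sequence")
    if not np.isin(row, (0, 1)).all():
        raise ValueError("row must be binary")
    row = row.astype(np.uint8)
    left = np.roll(row, 1)
    right = np.roll(row, -1)
    idx = (left << 2) | (row << 1) | right
    return rule.lookup()[idx]


def generate_target(rule, ic: InitialCondition, steps: int) -> TargetPattern:
    """Roll a rule out for ``steps`` updates; the grid has ``steps + 1`` rows."""
    rule = _as_rule(rule)
    if steps < 0:
        raise ValueError("steps must be >= 0")
    rows = [ic.as_array()]
    for _ in range(steps):
        rows.append(eca_step(rows[-1], rule))
    grid = np.stack(rows)
    grid.setflags(write=False)
    return TargetPattern(grid=grid, rule_code=rule.code, ic=ic)


def _canonical_rotation(bits: tuple[int, ...]) -> tuple[int, ...]:
    n = len(bits)
    return min(tuple(bits[i:] + bits[:i]) for i in range(n))


def rotation_classes_equal(a, b) -> bool:
    """True when two binary rows are identical up to cyclic rotation."""
    a, b = tuple(a), tuple(b)
    return len(a) == len(b) and _canonical_rotation(a) == _canonical_rotation(b)


def manual_spaced_ic(n_cells: int, n_ones: int, label: str = "") -> InitialCondition:
    """Place ``n_ones`` ON cells as evenly as the ring allows.

    Cell ``i`` of the ones goes to position ``round(i * C / n_ones) mod C``
    (half-up rounding), the canonical lattice choice when C is not divisible
    by the number of ones.
    """
    if not 0 < n_ones <= n_cells:
        raise ValueError("need 0 < n_ones <= n_cells")
    positions = {int(np.floor(i * n_cells / n_ones + 0.5)) % n_cells for i in range(n_ones)}
    if len(positions) != n_ones:
        raise ValueError("even spacing collides; too many ones for this ring")
    bits = [0] * n_cells
    for p in positions:
        bits[p] = 1
    return InitialCondition(bits=tuple(bits), label=label or f"spaced-{n_ones}")


def generate_ic_pairs(
    n_cells: int = 22,
    n_random_pairs: int = 6,
    seed=None,
    include_manual: bool = True,
    manual_ones: tuple[int, int] = (4, 6),
    max_retries: int = 1000,
    rng: np.random.Generator | None = None,
) -> list[tuple[InitialCondition, InitialCondition]]:
    """Build the initial-condition pairs for a target suite.

    Random pairs are shuffles of a half-ones/half-zeros row, with the
    constraint that no two of the random rows are equal under cyclic
    rotation (rotated seeds would generate rotated — effectively duplicate —
    landscapes).  The final, manually constructed pair places 4 versus 6 ON
    cells evenly spaced around the ring; it is appended last.
    """
    if n_random_pairs < 0:
        raise ValueError("n_random_pairs must be >= 0")
    if n_random_pairs > 0 and n_cells % 2 != 0:
        raise ValueError("n_cells must be even to shuffle equal ones and zeros")
    if rng is None:
        rng = np.random.default_rng(seed)

    base = np.array([1] * (n_cells // 2) + [0] * (n_cells - n_cells // 2), dtype=np.uint8)
    seen: set[tuple[int, ...]] = set()
    random_ics: list[InitialCondition] = []
    for k in range(2 * n_random_pairs):
        for _ in range(max_retries):
            bits = tuple(int(b) for b in rng.permutation(base))
            canon = _canonical_rotation(bits)
            if canon not in seen:
                seen.add(canon)
                random_ics.append(InitialCondition(bits=bits, label=f"random-{k}"))
                break
        else:
            raise RuntimeError(
                "could not draw rotation-distinct initial conditions "
                f"after {max_retries} reshuffles (C={n_cells})"
            )

    pairs = [(random_ics[2 * i], random_ics[2 * i + 1]) for i in range(n_random_pairs)]
    if include_manual:
        pairs.append(
            (
                manual_spaced_ic(n_cells, manual_ones[0]),
                manual_spaced_ic(n_cells, manual_ones[1]),
            )
        )
    return pairs


def build_suite(rules, ic_pairs, mode: str = "ic_switch", steps: int | None = None) -> SuiteManifest:
    """Cross rules with initial-condition pairs into the full landscape suite.

    ``ic_switch`` mode takes rule codes and IC pairs: each (rule, IC pair)
    yields one landscape pair (same rule, two seeds).  ``rule_switch`` mode
    takes rule-code pairs and single ICs: each (rule pair, IC) yields one
    pair (two rules, same seed).  Ordering is deterministic with rules outer
    and ICs inner.  Static targets enumerate both members of every pair.
    """
    rules = list(rules)
    ic_pairs = list(ic_pairs)
    if not rules or not ic_pairs:
        raise ValueError("rules and ic_pairs must be nonempty")

    if mode == "ic_switch":
        if len(set(int(r) for r in rules)) != len(rules):
            raise ValueError("duplicate rule codes")
        keys = [tuple(a.bits) + tuple(b.bits) for a, b in ic_pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate initial-condition pairs")
        n_cells = len(ic_pairs[0][0])
        n_steps = (n_cells - 1) if steps is None else steps
        pairs, statics = [], []
        for rule in rules:
            table = _as_rule(rule)
            for ic_a, ic_b in ic_pairs:
                ta = generate_target(table, ic_a, n_steps)
                tb = generate_target(table, ic_b, n_steps)
                pairs.append(LandscapePair(mode="ic_switch", target_a=ta, target_b=tb))
                statics.extend([ta, tb])
    elif mode == "rule_switch":
        rule_pairs = [tuple(int(c) for c in rp) for rp in rules]
        if len(set(rule_pairs)) != len(rule_pairs):
            raise ValueError("duplicate rule pairs")
        ics = [p if isinstance(p, InitialCondition) else p[0] for p in ic_pairs]
        keys = [tuple(ic.bits) for ic in ics]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate initial conditions")
        n_cells = len(ics[0])
        n_steps = (n_cells - 1) if steps is None else steps
        pairs, statics = [], []
        for code_a, code_b in rule_pairs:
            for ic in ics:
                ta = generate_target(code_a, ic, n_steps)
                tb = generate_target(code_b, ic, n_steps)
                pairs.append(LandscapePair(mode="rule_switch", target_a=ta, target_b=tb))
                statics.extend([ta, tb])
    else:
        raise ValueError(f"unknown suite mode {mode!r}")

    return SuiteManifest(rules=rules, ic_pairs=ic_pairs, pairs=pairs, statics=statics)


def pattern_features(pair: LandscapePair) -> dict:
    """ON-cell counts of each target and the fraction of positions that agree."""
    a, b = pair.target_a.grid, pair.target_b.grid
    if a.shape != b.shape:
        raise ValueError(f"target shapes differ: {a.shape} vs {b.shape}")
    return {
        "on_count_a": int(np.sum(a == 1)),
        "on_count_b": int(np.sum(b == 1)),
        "overlap": float(np.mean(a == b)),
    }
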