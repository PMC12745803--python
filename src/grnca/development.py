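"""Multicellular development of a shared gene-regulatory network.

An individual is a ring of ``C`` cells, each running the same GRN of ``G``
genes.  The genotype is a single weight matrix ``W_full`` of shape
``G x (G + 2)``: the first ``G`` columns are the fully connected internal
regulation matrix ``W_int``, and the two extra columns weight the signals
arriving from the left and right neighbouring cells.  Two designated
*communication genes* carry those signals (one gene's expression is sent to
the left neighbour, another's to the right); a designated non-communication
*target gene* is read out in every cell at every step to form the
two-dimensional phenotype.

Each developmental step squashes through the sigmoid
``sigma(x) = 1 / (1 + exp(-a*x + c))`` twice: first an internal update
``p_int = sigma(W_int @ p)``, then a communication update that combines
``p_int`` with the neighbours' communication-gene values through ``W_full``.
At time 0 every gene is silent except the target gene, which is clamped to
the binary initial condition — the same row that seeds the CA target, so a
genotype must evolve a developmental *process* that regenerates the target
pattern from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .ca import InitialCondition, TargetPattern

__all__ = [
    "DevelopmentConfig",
    "MutationConfig",
    "Genotype",
    "sigmoid",
    "develop",
    "develop_population",
    "fitness",
    "fitness_population",
    "init_genotype",
    "init_population",
    "mutate",
    "mutate_population",
]


@dataclass(frozen=True)
class DevelopmentConfig:
    """Geometry and nonlinearity of the developmental model.

    ``n_rows`` counts phenotype rows: row 0 is the clamped initial condition
    and each of the remaining ``n_rows - 1`` rows is one developmental step.
    ``gain``/``offset`` are the sigmoid's ``a`` and ``c``.  The neighbour
    signal defaults to the synchronously computed intermediate state
    (``"intermediate"``); ``"previous"`` sources it from the last completed
    step instead.
    """

    n_genes: int = 8
    n_cells: int = 22
    n_rows: int = 22
    gain: float = 10.0
    offset: float = 5.0
    comm_left_idx: int = 0
    comm_right_idx: int = -1
    target_gene_idx: int = 1
    neighbor_source: str = "intermediate"

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("need at least 3 genes: two communication + one target")
        if self.n_rows < 1 or self.n_cells < 1:
            raise ValueError("n_rows and n_cells must be >= 1")
        left = self.comm_left_idx % self.n_genes
        right = self.comm_right_idx % self.n_genes
        target = self.target_gene_idx % self.n_genes
        if left == right:
            raise ValueError("communication genes must be distinct")
        if target in (left, right):
            raise ValueError("target gene must not be a communication gene")
        if self.neighbor_source not in ("intermediate", "previous"):
            raise ValueError(f"unknown neighbor_source {self.neighbor_source!r}")

    @property
    def roles(self) -> tuple[int, int, int]:
        """(left-comm, right-comm, target) gene indices, normalised."""
        g = self.n_genes
        return (self.comm_left_idx % g, self.comm_right_idx % g, self.target_gene_idx % g)


@dataclass(frozen=True)
class MutationConfig:
    """Mutation operator: each weight gets +N(0, sd) with probability rate."""

    rate: float = 0.10
    sd: float = 0.5
    init_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")
        if self.sd < 0 or self.init_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class Genotype:
    """One individual's full GRN weight matrix, shape G x (G + 2)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != w.shape[0] + 2:
            raise ValueError(f"weights must be G x (G+2), got {w.shape}")
        if not np.isfinite(w).all():
            raise ValueError("weights must be finite")
        object.__setattr__(self, "weights", w)

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    @property
    def w_int(self) -> np.ndarray:
        return self.weights[:, : self.n_genes]


def sigmoid(x, gain: float = 10.0, offset: float = 5.0):
    """Logistic squashing 1 / (1 + exp(-gain*x + offset)), strictly in (0,1)."""
    return expit(gain * np.asarray(x, dtype=float) - offset)


def _weights_3d(genotypes) -> np.ndarray:
    if isinstance(genotypes, Genotype):
        return genotypes.weights[None]
    w = np.asarray(genotypes, dtype=float)
    if w.ndim == 2:
        w = w[None]
    if w.ndim != 3 or w.shape[2] != w.shape[1] + 2:
        raise ValueError(f"expected (N, G, G+2) weights, got {w.shape}")
    return w


def _ic_bits(ic) -> np.ndarray:
    if isinstance(ic, InitialCondition):
        return ic.as_array().astype(float)
    return np.asarray(ic, dtype=float)


def develop_population(genotypes, ic, cfg: DevelopmentConfig) -> np.ndarray:
    """Develop N genotypes from one initial condition; returns (N, R, C) phenotypes.

    The loop is vectorised over individuals and cells; periodic boundaries
    are realised with ``np.roll`` along the cell axis, so a single cell is
    its own left and right neighbour.
    """
    W = _weights_3d(genotypes)
    g, c, r = cfg.n_genes, cfg.n_cells, cfg.n_rows
    if W.shape[1] != g:
        raise ValueError(f"genotype has {W.shape[1]} genes, config expects {g}")
    bits = _ic_bits(ic)
    if bits.shape != (c,):
        raise ValueError(f"initial condition length {bits.shape} != n_cells {c}")
    left, right, target = cfg.roles

    w_int = W[:, :, :g]
    w_from_left = W[:, :, g]      # weights on the signal arriving from the left
    w_from_right = W[:, :, g + 1]

    n = W.shape[0]
    state = np.zeros((n, c, g))
    state[:, :, target] = bits
    phen = np.empty((n, r, c))
    phen[:, 0, :] = bits

    for t in range(1, r):
        inter = sigmoid(np.einsum("ngh,nch->ncg", w_int, state), cfg.gain, cfg.offset)
        src = inter if cfg.neighbor_source == "intermediate" else state
        # the left neighbour exports its right-communication gene, and vice versa
        from_left = np.roll(src[:, :, right], 1, axis=1)
        from_right = np.roll(src[:, :, left], -1, axis=1)
        drive = (
            np.einsum("ngh,nch->ncg", w_int, inter)
            + from_left[:, :, None] * w_from_left[:, None, :]
            + from_right[:, :, None] * w_from_right[:, None, :]
        )
        state = sigmoid(drive, cfg.gain, cfg.offset)
        phen[:, t, :] = state[:, :, target]
    return phen


def develop(genotype, ic, cfg: DevelopmentConfig) -> np.ndarray:
    """Develop a single genotype; returns the (R, C) phenotype grid."""
    return develop_population(genotype, ic, cfg)[0]


def _target_grid(target) -> np.ndarray:
    if isinstance(target, TargetPattern):
        return np.asarray(target.grid, dtype=float)
    return np.asarray(target, dtype=float)


def fitness(phenotype, target) -> float:
    """Normalised Manhattan similarity: 1 - mean |phenotype - target|.

    1 is a perfect match; for binary targets and phenotypes in [0, 1] the
    value stays in [0, 1] and reaches 0 only at the exact complement.
    Random (real-valued) targets use the same formula and may push the value
    below 0.
    """
    p = np.asarray(phenotype, dtype=float)
    t = _target_grid(target)
    if p.shape != t.shape:
        raise ValueError(f"phenotype shape {p.shape} != target shape {t.shape}")
    return float(1.0 - np.abs(p - t).mean())


def fitness_population(phenotypes, target) -> np.ndarray:
    """Fitness of an (N, R, C) phenotype stack against one target."""
    p = np.asarray(phenotypes, dtype=float)
    t = _target_grid(target)
    if p.shape[1:] != t.shape:
        raise ValueError(f"phenotype shape {p.shape[1:]} != target shape {t.shape}")
    return 1.0 - np.abs(p - t[None]).mean(axis=(1, 2))


def init_population(n: int, cfg: DevelopmentConfig, mcfg: MutationConfig, rng) -> np.ndarray:
    """Draw N genotypes with i.i.d. N(0, init_sd) weights, shape (N, G, G+2)."""
    g = cfg.n_genes
    return rng.normal(0.0, mcfg.init_sd, size=(n, g, g + 2))


def init_genotype(cfg: DevelopmentConfig, mcfg: MutationConfig, rng) -> Genotype:
    return Genotype(weights=init_population(1, cfg, mcfg, rng)[0])


def mutate_population(weights: np.ndarray, mcfg: MutationConfig, rng) -> np.ndarray:
    """Per-weight Bernoulli(rate) additive N(0, sd) mutation; pure function.

    Always consumes two fixed-size draws from ``rng`` so that disabling the
    operator's effect (rate=0 or sd=0) does not shift the random stream.
    """
    w = np.asarray(weights, dtype=float)
    mask = rng.random(w.shape) < mcfg.rate
    noise = rng.normal(0.0, mcfg.sd, size=w.shape)
    return w + mask * noise


def mutate(genotype: Genotype, mcfg: MutationConfig, rng) -> Genotype:
    """Mutated copy of one genotype; the input is left untouched."""
    return Genotype(weights=mutate_population(genotype.weights[None], mcfg, rng)[0])
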