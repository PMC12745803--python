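# Methods

## The model

`grnca` simulates the evolution of a developmental genotype–phenotype map
on dynamic fitness landscapes. Three layers make up the model.

**Targets.** Selection targets are space-time patterns of elementary
cellular automata (ECA): a ring of `C` binary cells repeatedly updated by
one of the 256 radius-1 rules, each rule named by its Wolfram code (the
outputs for neighbourhoods 111…000 read as an 8-bit number, 111 most
significant). A *landscape pair* is two targets generated either by the
same rule from two different seed rows (`ic_switch` — the organism is told
about the environment through its developmental input) or by two rules
from the same seed row (`rule_switch` — the switch is invisible to the
organism). The default suite crosses 15 rules with 7 seed-row pairs:
6 pairs are random shuffles of 11 ones and 11 zeros on a 22-cell ring,
constrained to be pairwise distinct under cyclic rotation (rotated seeds
would generate effectively duplicate landscapes), and the 7th places 4
versus 6 ON cells evenly spaced (ones at positions `round(i·C/k) mod C` —
the ring size is not divisible by 4 or 6, so "evenly spaced" is realised
as the nearest-lattice placement). That crossing yields 105 pairs and 210
static targets. The 15 default rule codes pad the six rules identifiable
from published pattern figures (18, 30, 50, 54, 70, 122) with nine
visually complex standard ECA rules (22, 45, 60, 90, 105, 106, 110, 126,
150); the list is a configurable stand-in, not a canonical catalogue.

**Development.** An individual is a ring of `C` cells sharing one gene
regulatory network of `G` genes. The genotype is the full weight matrix
`W_full` of shape `G × (G+2)`: a fully connected internal matrix `W_int`
plus two columns weighting the signals arriving from the left and right
neighbours. Two designated communication genes export their expression to
the neighbours; a designated non-communication target gene is read out in
every cell at every step. Each step applies

    p_int  = σ(W_int · p_t)                      (internal update)
    p_t+1  = σ(W_int · p_int + w_L·left + w_R·right)   (communication update)
    σ(x)   = 1 / (1 + e^(−a·x + c)),   a = 10, c = 5

with periodic boundaries. At t = 0 all genes are silent except the target
gene, clamped to the binary initial condition — the same row that seeds
the CA target, so the population must evolve a developmental *process*
rather than memorise a static pattern. The phenotype is the `R × C` grid
of target-gene expression (row 0 = the clamped seed). Fitness is the
normalised Manhattan similarity `1 − Σ|p − target| / (R·C)`; it includes
row 0, which matches by construction and therefore only rescales fitness
by a constant.

*Neighbour-signal timing.* The left/right values in the communication
update are taken from the neighbours' `p_int`, computed synchronously for
all cells in the same step (`neighbor_source="intermediate"`); only
`p_int` exists at that stage of the update. A `"previous"` option sources
them from the last completed step instead, for sensitivity checks.

**Evolution.** A (μ+λ) evolution strategy with truncation selection:
popsize 1000, μ = 100 survivors, λ = popsize/μ − 1 = 9 offspring per
survivor, initial weights i.i.d. N(0,1), and per-weight mutation —
each weight independently perturbed by N(0, 0.5) with probability
m = 0.10 (an independent Bernoulli per weight, so m is the *average*
mutated fraction, not a fixed count). Parents survive unchanged; a
`mutate_parents` flag exists for sensitivity analysis. Fitness is
evaluated at the start of each generation against that generation's
environment, so the post-switch fitness drop appears at the first
generation of a new season, before any selection under the new target.
Variable runs alternate the pair's targets every 300 generations starting
with target A. Two displacement controls replace the environment switch:
a *mutation pulse* (every weight of every individual gets N(0,1) noise at
each season boundary) and *random-target selection* (the last 3
generations of each season select for a fresh per-cell N(0,1) real-valued
target; the same fitness formula applies and may leave [0,1]).

## Randomness and reproducibility

One root seed feeds five named, independent generator streams
(initialisation, mutation, pulses, random targets, sampling) derived via
`SeedSequence` spawn keys. Disabling a variant therefore leaves the other
streams untouched: a pulse run is bit-identical to its static control up
to the first pulse, and a random-target run with span 0 equals the static
run exactly. Identical seed + configuration reproduce traces
byte-for-byte. Experiment sweeps derive one seed per (treatment,
replicate) from the root seed by CRC-hashing the treatment name, so
adding a treatment never shifts another treatment's seeds.

## Metrics

* **Mutational robustness** — clone the genotype `n` times with the run's
  mutation operator (default; a dense flag perturbs every weight
  instead), develop each clone, and report the mean absolute per-entry
  phenotype change and the mean signed fitness change. The phenotype
  average includes the clamped row 0, consistent with the fitness
  definition. Full-scale default n = 2,500.
* **Variability map** — per-position SD of clone phenotypes (default
  n = 10,000), with a bias summary splitting positions where a pair's
  targets agree versus differ; an empty differing set reports absent,
  not zero.
* **Dual fitness** — a random 10 % population sample developed and scored
  in both environments.
* **Season metrics** — per season: post-switch value, drop
  (pre-switch minus post-switch, same statistic for both; mean fitness by
  default, max available), and recovery length (generations until the
  statistic regains its pre-switch value, capped at the season length —
  the literature speaks of faster recovery without giving a formula).
  Trends are ordinary least-squares slopes against season index,
  separately per environment.
* **Offspring-improvement fraction** — fraction of mutant offspring
  strictly fitter than their parent in the new environment (ties count as
  not improved), plus its slope over switches: the operational
  evolvability readout.
* **Exploration** — Euclidean distances between flattened snapshot weight
  matrices (33 equally spaced snapshots of the fittest genotype by
  default), across-replicate per-weight SD of the final snapshots
  averaged to one scalar, and a 2-component metric MDS embedding
  (scikit-learn SMACOF) of all snapshots.
* **Comparisons** — per-pair two-sided Mann–Whitney U with
  Benjamini–Hochberg FDR across pairs, pooled Kruskal–Wallis, and a
  hand-rolled two-way aligned-rank-transform ANOVA (standard recipe:
  align each response by cell-residual plus the focal effect's cell-mean
  estimate, rank, factorial OLS ANOVA on ranks via statsmodels).
* **Difficulty / best-effect** — difficulty of a target is the
  replicate-mean of the best mean-population fitness a static run
  reaches; the best-effect summary is the variable-minus-static
  difference of the best-ever max and mean fitness per environment.

## Numerical choices and degenerate inputs

* Truncation selection breaks fitness ties by lower index (stable sort),
  making runs deterministic.
* The sigmoid keeps expression mathematically inside (0,1); in float64 it
  saturates to exactly 0.0/1.0 once |a·x − c| ≳ 37, which is expected and
  harmless for fitness.
* The mutation operator always consumes the same number of random draws,
  so `rate=0` or `sd=0` do not shift the stream.
* Clone SD uses the population (ddof = 0) estimator; across-replicate
  weight SD uses ddof = 1.
* Slopes over fewer than two seasons of an environment are NaN, not 0.
* Rotation-distinct seed rows are drawn with a bounded reshuffle budget
  (default 1,000) and fail loudly when the ring cannot supply enough
  rotation classes.

## Default scales

Full-scale defaults are popsize 1000, μ 100, 10,000 generations,
300-generation seasons, C = 22, R = 22, a = 10, c = 5, m = 0.10,
mutation SD 0.5. `G = 8` genes is a declared
stand-in: the gene count is not fixed by the model's public description,
and the wiring example with G = 4 (24 weights) is used in tests. The
bundled reduced study (`demo_reduced_study`, CLI `demo`) runs two rules ×
the 4-vs-6 spaced pair × {static A, static B, variable} × 3 replicates at
popsize 100, μ 10, six 100-generation seasons — the package's desk-scale
configuration, also used by the test suite's dynamical checks.

## What the generated data do and do not show

All inputs are generated internally; there is no external data. The
simulator emulates a population adapting a developmental program to
alternating pattern-formation tasks. It does not model diploid or sexual
genetics, gene duplication or topology-changing mutations, environmental
noise during development, or dynamic population sizes. Reduced-scale runs
reproduce the qualitative dynamics (elitist monotone static fitness,
post-switch drops, rising post-switch baselines over encounters) but not
the full-scale study's specific statistics: with 100-generation seasons
the post-switch baseline can rise above the previous season's end, so a
late-season "drop" can be negative — at full scale, with 300-generation
seasons and 10× larger populations, drops grow with accumulated fitness.
Passing the reduced-scale dynamical tests therefore demonstrates the
mechanics of the simulator, not quantitative agreement with any
full-scale experiment.
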