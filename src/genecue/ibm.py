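"""Forward-time individual-based simulation of the full life cycle.

Haploid individuals carry a biallelic cue locus (allelic effects x = -1, +1)
and a real-valued modifier genome whose architecture determines the liability
parameters ``a0`` and ``ag``; the investment phenotype is the sigmoid
``z = expit(a0 + ag * x)``.  Each cycle runs the same sequence as the
deterministic analysis: (i) the public-goods game in groups of ``N_i`` with
offspring production proportional to (clamped) payoff, (ii) within- and
between-habitat migration into dispersal pools, (iii) random mating with
per-locus recombination against the cue locus and mutation at gamete
formation, and (iv) group founding back to capacity followed by one asexual
generation (each of the ``N_i`` offspring group members copies a uniformly
chosen founder).

Four modifier architectures are supported:

* ``A`` — ``a0`` fixed, ``ag`` encoded by a single locus (recombination rate
  ``rho`` to the cue locus);
* ``B`` — one locus each for ``a0`` and ``ag``;
* ``C`` — ``a0`` built from 5 positive-effect plus 5 negative-effect unlinked
  small-effect loci, ``ag`` from 5 unlinked additive loci;
* ``D`` — as ``C`` with two additional unlinked loci setting evolvable
  expression thresholds on the positive and negative sets:
  ``a0 = min(S+, T+) - min(S-, T-)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import ModelParams

__all__ = [
    "MutationParams",
    "Architecture",
    "architecture_A",
    "architecture_B",
    "architecture_C",
    "architecture_D",
    "SimConfig",
    "Population",
    "init_population",
    "life_cycle_step",
    "run_simulation",
    "run_replicates",
    "SimulationResult",
    "phenotype_distribution",
    "count_modes",
]


@dataclass(frozen=True)
class MutationParams:
    """Mutation model applied at gamete formation.

    ``rate``: per-locus probability of a mutation on a modifier locus;
    ``sd``: standard deviation of the zero-mean Gaussian perturbation of the
    allelic value; ``cue_flip``: probability the cue allele flips.
    """

    rate: float = 0.005
    sd: float = 0.2
    cue_flip: float = 1e-4

    def __post_init__(self):
        if not (0 <= self.rate <= 1 and 0 <= self.cue_flip <= 1):
            raise ValueError("mutation probabilities must lie in [0, 1]")
        if self.sd < 0:
            raise ValueError("mutation kernel sd must be >= 0")


@dataclass(frozen=True)
class Architecture:
    """Modifier-genome layout: locus roles, linkage and initial values.

    ``recomb[l]`` is the recombination rate between modifier locus ``l`` and
    the cue locus (0 = fully linked, 0.5 = unlinked).  Positive/negative
    ``a0`` loci and thresholds express ``max(value, 0)``.
    """

    name: str
    n_loci: int
    recomb: tuple[float, ...]
    init: tuple[float, ...]
    a0_fixed: float | None = None
    # locus-index slices by role
    a0_loci: tuple[int, ...] = ()
    a0_neg_loci: tuple[int, ...] = ()
    ag_loci: tuple[int, ...] = ()
    threshold_loci: tuple[int, ...] = ()  # (T+, T-) for architecture D

    def __post_init__(self):
        if len(self.recomb) != self.n_loci or len(self.init) != self.n_loci:
            raise ValueError("recomb and init must have one entry per locus")
        if any(not 0 <= r <= 0.5 for r in self.recomb):
            raise ValueError("per-locus recombination rates must lie in [0, 0.5]")

    def a0_of(self, genome: np.ndarray) -> np.ndarray:
        """Baseline liability per individual, genome shape (n, n_loci)."""
        if self.a0_fixed is not None:
            return np.full(genome.shape[0], self.a0_fixed)
        pos = np.clip(genome[:, self.a0_loci], 0.0, None).sum(axis=1) \
            if self.a0_neg_loci else genome[:, self.a0_loci].sum(axis=1)
        if not self.a0_neg_loci:
            return pos
        neg = np.clip(genome[:, self.a0_neg_loci], 0.0, None).sum(axis=1)
        if self.threshold_loci:
            tpos = np.clip(genome[:, self.threshold_loci[0]], 0.0, None)
            tneg = np.clip(genome[:, self.threshold_loci[1]], 0.0, None)
            pos = np.minimum(pos, tpos)
            neg = np.minimum(neg, tneg)
        return pos - neg

    def ag_of(self, genome: np.ndarray) -> np.ndarray:
        return genome[:, self.ag_loci].sum(axis=1)

    def liability(self, genome: np.ndarray, x: np.ndarray) -> np.ndarray:
        return self.a0_of(genome) + self.ag_of(genome) * x

    def phenotype(self, genome: np.ndarray, x: np.ndarray) -> np.ndarray:
        return expit(self.liability(genome, x))


def architecture_A(rho: float, a0_fixed: float, ag_init: float = 1.5) -> Architecture:
    """Single evolvable ``ag`` locus at recombination rate ``rho`` to the cue
    locus; ``a0`` is a fixed constant (conventionally the logit of the
    monomorphic singular strategy, placing the sigmoid midpoint there)."""
    return Architecture(
        name="A",
        n_loci=1,
        recomb=(float(rho),),
        init=(float(ag_init),),
        a0_fixed=float(a0_fixed),
        ag_loci=(0,),
    )


def architecture_B(
    rho_a0: float,
    rho_ag: float,
    a0_init: float,
    ag_init: float = 1.5,
) -> Architecture:
    """One evolvable locus each for ``a0`` and ``ag``."""
    return Architecture(
        name="B",
        n_loci=2,
        recomb=(float(rho_a0), float(rho_ag)),
        init=(float(a0_init), float(ag_init)),
        a0_loci=(0,),
        ag_loci=(1,),
    )


def architecture_C(
    a0_init: float, ag_init: float = 1.5, n_each: int = 5
) -> Architecture:
    """Polygenic: ``n_each`` unlinked positive-effect and ``n_each``
    negative-effect small loci build ``a0``; ``n_each`` unlinked additive
    loci build ``ag``.  Initial expressions split the targets evenly, with
    the negative set offset so that positive minus negative equals
    ``a0_init``."""
    pos0 = 0.3
    neg0 = pos0 - a0_init / n_each
    if neg0 < 0:
        pos0, neg0 = pos0 - neg0, 0.0
    init = (pos0,) * n_each + (neg0,) * n_each + (ag_init / n_each,) * n_each
    return Architecture(
        name="C",
        n_loci=3 * n_each,
        recomb=(0.5,) * (3 * n_each),
        init=init,
        a0_loci=tuple(range(n_each)),
        a0_neg_loci=tuple(range(n_each, 2 * n_each)),
        ag_loci=tuple(range(2 * n_each, 3 * n_each)),
    )


def architecture_D(
    a0_init: float,
    ag_init: float = 1.5,
    n_each: int = 5,
    threshold_init: float = 2.0,
) -> Architecture:
    """As ``C`` plus two unlinked expression-threshold loci:
    ``a0 = min(S+, T+) - min(S-, T-)`` with evolvable ``T+``, ``T-``
    (initialized above the initial sums, so initially inactive)."""
    base = architecture_C(a0_init, ag_init, n_each)
    n = base.n_loci
    return Architecture(
        name="D",
        n_loci=n + 2,
        recomb=base.recomb + (0.5, 0.5),
        init=base.init + (float(threshold_init),) * 2,
        a0_loci=base.a0_loci,
        a0_neg_loci=base.a0_neg_loci,
        ag_loci=base.ag_loci,
        threshold_loci=(n, n + 1),
    )


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation run; a seed is mandatory."""

    params: ModelParams
    architecture: Architecture
    cycles: int
    seed: int
    record_every: int = 50
    mutation: MutationParams = field(default_factory=MutationParams)
    init_cue_freq: float = 0.5

    def __post_init__(self):
        if self.cycles < 1 or self.record_every < 1:
            raise ValueError("cycles and record_every must be >= 1")
        if not 0.0 < self.init_cue_freq < 1.0:
            raise ValueError("initial cue frequency must be in (0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic runs")


@dataclass
class Population:
    """Census-state population: per habitat, cue alleles (0/1) and modifier
    genomes; individuals are ordered so that groups of ``N_i`` are
    contiguous."""

    cue: list[np.ndarray]
    genome: list[np.ndarray]

    def habitat_sizes(self) -> tuple[int, int]:
        return tuple(len(c) for c in self.cue)

    def cue_effects(self, i: int) -> np.ndarray:
        """Allelic effect x: -1.0 for allele x1 (code 0), +1.0 for x2."""
        return 2.0 * self.cue[i] - 1.0

    def phenotypes(self, arch: Architecture, i: int) -> np.ndarray:
        return arch.phenotype(self.genome[i], self.cue_effects(i))

    def copy(self) -> "Population":
        return Population(
            cue=[c.copy() for c in self.cue],
            genome=[g.copy() for g in self.genome],
        )


class PoolExtinctionError(RuntimeError):
    """A dispersal pool emptied during the stochastic life cycle."""


def init_population(config: SimConfig, rng: np.random.Generator) -> Population:
    """Habitats filled to capacity, cue alleles at the configured frequency
    (deterministic counts, shuffled positions), modifier alleles at the
    architecture's initial values."""
    arch = config.architecture
    cue = []
    genome = []
    for i in range(2):
        cap = config.params.habitats.capacity[i]
        n1 = int(round(cap * (1.0 - config.init_cue_freq)))
        alleles = np.concatenate(
            [np.zeros(n1, dtype=np.int8), np.ones(cap - n1, dtype=np.int8)]
        )
        rng.shuffle(alleles)
        cue.append(alleles)
        genome.append(np.tile(np.asarray(arch.init, dtype=float), (cap, 1)))
    return Population(cue=cue, genome=genome)


def _group_fecundity(
    pop: Population, config: SimConfig, i: int
) -> np.ndarray:
    """Clamped public-goods payoff of every individual in habitat i."""
    params = config.params
    N = params.habitats.N[i]
    z = pop.phenotypes(config.architecture, i)
    zbar = z.reshape(-1, N).mean(axis=1).repeat(N)
    w = (
        params.game.W[i]
        + params.game.b[i] * zbar
        - params.game.c[i] * z * z
    )
    return np.maximum(w, 0.0)


def _mate_pool(
    pool_cue: np.ndarray,
    pool_genome: np.ndarray,
    n_gametes: int,
    recomb: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random mating in a dispersal pool: each gamete is produced by a random
    pair, carries the cue allele of one parent (fair coin) and, per modifier
    locus, stays with the cue-carrying parent with probability ``1 - r_l``.

    Returns (gamete cue, gamete genome, index of the cue-donor parent) —
    the donor index supports direct tests of realized cue inheritance.
    """
    S = len(pool_cue)
    if S == 0:
        raise PoolExtinctionError("empty dispersal pool")
    pa = rng.integers(0, S, n_gametes)
    pb = rng.integers(0, S, n_gametes)
    cue_from_a = rng.random(n_gametes) < 0.5
    donor = np.where(cue_from_a, pa, pb)
    other = np.where(cue_from_a, pb, pa)
    gam_cue = pool_cue[donor]
    cross = rng.random((n_gametes, len(recomb))) < recomb[None, :]
    gam_genome = np.where(
        cross, pool_genome[other, :], pool_genome[donor, :]
    )
    return gam_cue, gam_genome, donor


def _mutate(
    gam_cue: np.ndarray,
    gam_genome: np.ndarray,
    mut: MutationParams,
    rng: np.random.Generator,
) -> None:
    """In-place mutation of gametes."""
    if mut.rate > 0:
        hits = rng.random(gam_genome.shape) < mut.rate
        n_hits = int(hits.sum())
        if n_hits:
            gam_genome[hits] += rng.normal(0.0, mut.sd, n_hits)
    if mut.cue_flip > 0:
        flips = rng.random(len(gam_cue)) < mut.cue_flip
        gam_cue[flips] = 1 - gam_cue[flips]


def life_cycle_step(
    pop: Population, config: SimConfig, rng: np.random.Generator
) -> Population:
    """One full life cycle; returns the next census population.

    Offspring are drawn multinomially with probabilities proportional to
    clamped payoffs (pool-wide per habitat, one offspring slot per census
    individual), migrate independently, mate in the destination pool, and the
    resulting gametes found groups that each produce ``N_i`` offspring by
    uniform founder copying.
    """
    params = config.params
    arch = config.architecture
    recomb = np.asarray(arch.recomb, dtype=float)
    mmat = params.dispersal.matrix

    # (i) game + offspring production, (ii) migration
    pool_cue: list[list[np.ndarray]] = [[], []]
    pool_genome: list[list[np.ndarray]] = [[], []]
    for i in range(2):
        cap = params.habitats.capacity[i]
        w = _group_fecundity(pop, config, i)
        tot = w.sum()
        if tot <= 0:
            raise PoolExtinctionError(f"zero total payoff in habitat {i + 1}")
        parents = rng.choice(len(w), size=cap, p=w / tot)
        dest = np.where(rng.random(cap) < mmat[1 - i, i], 1 - i, i)
        for j in range(2):
            sel = parents[dest == j]
            pool_cue[j].append(pop.cue[i][sel])
            pool_genome[j].append(pop.genome[i][sel, :])

    # (iii) mating + recombination + mutation, (iv) founding + asexual copy
    new_cue = []
    new_genome = []
    for j in range(2):
        cap = params.habitats.capacity[j]
        N = params.habitats.N[j]
        pcue = np.concatenate(pool_cue[j])
        pgen = np.vstack(pool_genome[j])
        gam_cue, gam_genome, _ = _mate_pool(pcue, pgen, cap, recomb, rng)
        _mutate(gam_cue, gam_genome, config.mutation, rng)
        # founders are laid out in groups of N; each offspring group member
        # copies a uniformly chosen founder of its own group
        group_base = (np.arange(cap) // N) * N
        idx = group_base + rng.integers(0, N, cap)
        new_cue.append(gam_cue[idx])
        new_genome.append(gam_genome[idx, :])
    return Population(cue=new_cue, genome=new_genome)


@dataclass
class SimulationResult:
    """Trajectory records plus the final population and summary statistics."""

    trajectory: pd.DataFrame
    final: Population
    config: SimConfig
    summary: dict

    def liabilities(self) -> tuple[np.ndarray, np.ndarray]:
        """(liability, habitat label) arrays over the final population."""
        arch = self.config.architecture
        liab = np.concatenate(
            [
                arch.liability(self.final.genome[i], self.final.cue_effects(i))
                for i in range(2)
            ]
        )
        hab = np.concatenate(
            [np.full(len(self.final.cue[i]), i) for i in range(2)]
        )
        return liab, hab


def _record(pop: Population, config: SimConfig, cycle: int) -> list[dict]:
    arch = config.architecture
    rows = []
    for i in range(2):
        z = pop.phenotypes(arch, i)
        a0 = arch.a0_of(pop.genome[i])
        ag = arch.ag_of(pop.genome[i])
        for k in range(2):
            sel = pop.cue[i] == k
            if not sel.any():
                rows.append(
                    dict(cycle=cycle, habitat=i + 1, allele=k + 1, n=0,
                         mean_z=np.nan, sd_z=np.nan, mean_a0=np.nan,
                         mean_ag=np.nan)
                )
                continue
            rows.append(
                dict(
                    cycle=cycle,
                    habitat=i + 1,
                    allele=k + 1,
                    n=int(sel.sum()),
                    mean_z=float(z[sel].mean()),
                    sd_z=float(z[sel].std()),
                    mean_a0=float(a0[sel].mean()),
                    mean_ag=float(ag[sel].mean()),
                )
            )
    return rows


def run_simulation(config: SimConfig) -> SimulationResult:
    """Run the configured number of cycles, recording class statistics every
    ``record_every`` cycles; the summary holds final-epoch (last 20% of
    records) time-averaged per-cue-allele mean phenotypes and allele
    frequencies."""
    rng = np.random.default_rng(config.seed)
    pop = init_population(config, rng)
    rows = _record(pop, config, 0)
    for cycle in range(1, config.cycles + 1):
        pop = life_cycle_step(pop, config, rng)
        if cycle % config.record_every == 0 or cycle == config.cycles:
            rows.extend(_record(pop, config, cycle))
    traj = pd.DataFrame(rows)
    last = traj[traj.cycle >= traj.cycle.max() * 0.8]
    summary: dict = {}
    for k in (0, 1):
        sub = last[(last.allele == k + 1) & (last.n > 0)]
        wsum = float((sub.mean_z * sub.n).sum())
        nsum = float(sub.n.sum())
        summary[f"mean_z_allele{k + 1}"] = (
            wsum / nsum if nsum > 0 else np.nan
        )
        summary[f"freq_allele{k + 1}"] = float(
            last[last.allele == k + 1].n.sum() / last.n.sum()
        )
    final_rows = traj[traj.cycle == traj.cycle.max()]
    summary["final_mean_ag"] = float(
        (final_rows.mean_ag * final_rows.n).sum() / final_rows.n.sum()
    )
    return SimulationResult(
        trajectory=traj, final=pop, config=config, summary=summary
    )


def run_replicates(config: SimConfig, n_replicates: int) -> list[SimulationResult]:
    """Independent replicates seeded ``seed, seed+1, ...``."""
    return [
        run_simulation(replace(config, seed=config.seed + r))
        for r in range(n_replicates)
    ]


def phenotype_distribution(
    z_values: np.ndarray,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of phenotypes on [0, 1], renormalized to
    integrate to 1 on the grid.

    Bandwidth defaults to Silverman's rule with a floor of 0.01 so that
    degenerate (single-value) populations still yield a proper density.
    """
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ValueError("empty phenotype sample")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    if bandwidth is None:
        sd = float(z.std())
        bandwidth = max(0.9 * sd * z.size ** (-0.2), 0.01)
    u = (grid[:, None] - z[None, :]) / bandwidth
    dens = np.exp(-0.5 * u * u).sum(axis=1) / (
        z.size * bandwidth * np.sqrt(2 * np.pi)
    )
    area = np.trapezoid(dens, grid)
    return grid, dens / area


def two_cluster_split(values: np.ndarray) -> tuple[float, float, float]:
    """Optimal 1-d two-cluster split (minimum within-cluster variance).

    Returns ``(separation, weight_low, weight_high)``: the distance between
    the two cluster means and the fraction of values in each cluster.  Used
    to decide whether a modifier locus has become polymorphic (two allelic
    clusters of appreciable weight) rather than merely mutationally fuzzy.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2:
        return 0.0, 1.0, 0.0
    c1 = np.cumsum(v)
    tot = c1[-1]
    ks = np.arange(1, n)
    mean_lo = c1[:-1] / ks
    mean_hi = (tot - c1[:-1]) / (n - ks)
    # maximize between-cluster sum of squares
    bss = ks * (n - ks) / n * (mean_hi - mean_lo) ** 2
    k = int(np.argmax(bss)) + 1
    sep = float(mean_hi[k - 1] - mean_lo[k - 1])
    return sep, k / n, (n - k) / n


def count_modes(
    grid: np.ndarray, density: np.ndarray, rel_prominence: float = 0.05
) -> int:
    """Number of local maxima of a density curve with prominence at least
    ``rel_prominence`` times the maximum density (boundary maxima counted)."""
    from scipy.signal import find_peaks

    padded = np.concatenate([[0.0], density, [0.0]])
    peaks, _ = find_peaks(padded, prominence=rel_prominence * density.max())
    return int(len(peaks))
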