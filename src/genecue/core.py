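"""Parameter containers and payoff machinery for the two-habitat public-goods game.

The model: two habitats, each holding many social groups. A group in habitat
``i`` (``i = 1, 2``; indexed 0/1 in code) is founded by ``N_i`` haploid
individuals drawn at random from that habitat's dispersal pool. Founders
reproduce asexually, each of the ``N_i`` offspring group members being a copy
of a uniformly chosen founder, so the pairwise probability of identity by
descent since founding is ``r_i = 1/N_i``. Offspring group members play a
public-goods game: an individual investing ``z`` in a group with mean
investment ``zbar`` receives payoff

    w_i(z, zbar) = W_i + b_i * zbar - c_i * z**2,

i.e. the benefit is proportional to the group mean while the cost is
individual and quadratic. Payoff is a fecundity; consumers clamp it at zero.

Phenotypes are set by a genetic cue: allele ``x_k`` at the cue locus induces
investment ``z_k`` through a sigmoid map of the liability ``a0 + ag * x``.

This module holds the closed-form expectations used by the deterministic
analysis (rare-mutant payoff, per-class resident payoff, their derivative)
together with exact combinatorial enumerations of the group-formation process
that serve as independent cross-checks for small ``N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit
from scipy.stats import binom

__all__ = [
    "GameParams",
    "HabitatConfig",
    "DispersalConfig",
    "Dimorphism",
    "LiabilityParams",
    "ModelParams",
    "relatedness",
    "payoff",
    "expected_mutant_payoff",
    "resident_class_payoff",
    "payoff_derivative",
    "enumerate_mutant_payoff",
    "enumerate_class_payoff",
    "size_biased_founder_copies",
    "liability_to_phenotype",
]


def _check_pair(value, name: str) -> tuple[float, float]:
    pair = tuple(float(v) for v in value)
    if len(pair) != 2:
        raise ValueError(f"{name} must have length 2, got {value!r}")
    if not all(math.isfinite(v) for v in pair):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return pair


@dataclass(frozen=True)
class GameParams:
    """Per-habitat payoff constants of the public-goods game.

    ``W``: baseline payoff, ``b``: benefit coefficient on the group mean
    investment, ``c``: cost coefficient on the squared own investment.
    """

    W: tuple[float, float]
    b: tuple[float, float]
    c: tuple[float, float]

    def __post_init__(self):
        object.__setattr__(self, "W", _check_pair(self.W, "W"))
        object.__setattr__(self, "b", _check_pair(self.b, "b"))
        object.__setattr__(self, "c", _check_pair(self.c, "c"))
        if any(bi < 0 for bi in self.b):
            raise ValueError("benefit coefficients b must be >= 0")
        if any(ci <= 0 for ci in self.c):
            raise ValueError("cost coefficients c must be > 0")


@dataclass(frozen=True)
class HabitatConfig:
    """Founders per group and census capacity for the two habitats.

    ``N[i]`` founders per group in habitat ``i``; within-group relatedness is
    ``r_i = 1/N_i``.  ``capacity[i]`` is the number of (offspring) individuals
    at the census point; it must hold whole groups.
    """

    N: tuple[int, int]
    capacity: tuple[int, int]

    def __post_init__(self):
        N = tuple(int(n) for n in self.N)
        cap = tuple(int(c) for c in self.capacity)
        if len(N) != 2 or len(cap) != 2:
            raise ValueError("N and capacity must have length 2")
        if any(n < 1 for n in N):
            raise ValueError("founders per group N must be >= 1")
        if any(c < n or c % n != 0 for c, n in zip(cap, N)):
            raise ValueError("capacity must be a positive multiple of N (whole groups)")
        object.__setattr__(self, "N", N)
        object.__setattr__(self, "capacity", cap)

    @property
    def r(self) -> tuple[float, float]:
        """Within-group relatedness ``r_i = 1/N_i``."""
        return tuple(1.0 / n for n in self.N)


@dataclass(frozen=True)
class DispersalConfig:
    """Migration rates between habitats and cue-modifier recombination rate.

    ``m12`` is the rate from habitat 2 into habitat 1 and ``m21`` the rate
    from 1 into 2 (``m_ji`` = rate from ``i`` to ``j``); ``rho`` is the
    recombination rate between the cue locus and the modifier locus.
    """

    m12: float
    m21: float
    rho: float

    def __post_init__(self):
        for name in ("m12", "m21"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
            object.__setattr__(self, name, v)
        rho = float(self.rho)
        if not 0.0 <= rho <= 0.5:
            raise ValueError(f"rho must lie in [0, 0.5], got {rho}")
        object.__setattr__(self, "rho", rho)

    @classmethod
    def symmetric(cls, m: float, rho: float = 0.0) -> "DispersalConfig":
        return cls(m12=m, m21=m, rho=rho)

    @property
    def matrix(self) -> np.ndarray:
        """Migration matrix ``m[j, i]`` = rate from habitat i to habitat j.

        Columns sum to one: offspring either stay or move to the other habitat.
        """
        return np.array(
            [[1.0 - self.m21, self.m12], [self.m21, 1.0 - self.m12]]
        )


@dataclass(frozen=True)
class Dimorphism:
    """Pair of investment phenotypes induced by the two cue alleles."""

    z1: float
    z2: float

    def __post_init__(self):
        for name in ("z1", "z2"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
            object.__setattr__(self, name, v)

    @property
    def z(self) -> np.ndarray:
        return np.array([self.z1, self.z2])


@dataclass(frozen=True)
class LiabilityParams:
    """Sigmoid genotype-phenotype map parameters: ``z = expit(a0 + ag*x)``."""

    a0: float
    ag: float
    x: float

    def __post_init__(self):
        for name in ("a0", "ag", "x"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
            object.__setattr__(self, name, v)

    @property
    def phenotype(self) -> float:
        return liability_to_phenotype(self.a0, self.ag, self.x)


@dataclass(frozen=True)
class ModelParams:
    """Bundle of game, habitat and dispersal parameters for one model instance."""

    game: GameParams
    habitats: HabitatConfig
    dispersal: DispersalConfig

    @classmethod
    def reference(
        cls,
        m: float = 0.05,
        rho: float = 0.0,
        capacity: tuple[int, int] = (2000, 2000),
    ) -> "ModelParams":
        """The standard parameter set used throughout: N1=20, N2=2 (so
        r1=0.05, r2=0.5), W=0.5, b=3.0, c=1.5 in both habitats, equal
        capacities, symmetric migration."""
        return cls(
            game=GameParams(W=(0.5, 0.5), b=(3.0, 3.0), c=(1.5, 1.5)),
            habitats=HabitatConfig(N=(20, 2), capacity=capacity),
            dispersal=DispersalConfig.symmetric(m, rho),
        )

    def with_migration(self, m: float) -> "ModelParams":
        return replace(
            self, dispersal=replace(self.dispersal, m12=float(m), m21=float(m))
        )

    def with_rho(self, rho: float) -> "ModelParams":
        return replace(self, dispersal=replace(self.dispersal, rho=float(rho)))


def relatedness(N: int) -> float:
    """Pairwise identity-by-descent probability since founding, ``r = 1/N``.

    Each of the N offspring group members is an independent copy of one of the
    N founders, so two group members share a founder with probability 1/N.
    """
    if not float(N).is_integer() or int(N) < 1:
        raise ValueError(f"N must be a positive integer, got {N!r}")
    return 1.0 / int(N)


def payoff(z: float, zbar: float, habitat: int, game: GameParams) -> float:
    """Raw public-goods payoff ``W_i + b_i*zbar - c_i*z**2``.

    May be negative for extreme (z, zbar); fecundity users clamp at zero.
    """
    if habitat not in (0, 1):
        raise IndexError(f"habitat index must be 0 or 1, got {habitat}")
    if not (0.0 <= z <= 1.0 and 0.0 <= zbar <= 1.0):
        raise ValueError("investments z, zbar must lie in [0, 1]")
    return game.W[habitat] + game.b[habitat] * zbar - game.c[habitat] * z * z


def _self_weight(N: int) -> float:
    """Expected share of the group mean contributed by the focal lineage.

    For a focal founder whose offspring count K ~ Binomial(N, 1/N), a randomly
    chosen (size-biased) offspring of that founder sits in a group where the
    founder's copies contribute E[K^2]/(N*E[K]) = (2N-1)/N^2 of the mean and
    the other N-1 founders the complement (N-1)^2/N^2.
    """
    return (2 * N - 1) / (N * N)


def _conditional_expected_payoff(
    z_self: float, ztilde: float, habitat: int, game: GameParams, N: int
) -> float:
    w_self = _self_weight(N)
    ezbar = w_self * z_self + (1.0 - w_self) * ztilde
    return (
        game.W[habitat]
        + game.b[habitat] * ezbar
        - game.c[habitat] * z_self * z_self
    )


def _check_freqs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (2, 2):
        raise ValueError(f"frequency table must be 2x2, got shape {p.shape}")
    if np.any(p < -1e-12) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("per-habitat allele frequencies must be normalized")
    return p


def _ztilde(dim: Dimorphism, p: np.ndarray, habitat: int) -> float:
    return p[habitat, 0] * dim.z1 + p[habitat, 1] * dim.z2


def expected_mutant_payoff(
    zprime: float,
    habitat: int,
    dim: Dimorphism,
    p: np.ndarray,
    game: GameParams,
    habitats: HabitatConfig,
) -> float:
    """Expected payoff of a randomly chosen rare mutant expressing ``zprime``.

    Mutant groups are founded by a single mutant among ``N_i - 1`` residents
    sampled from the habitat frequencies ``p[i, k]`` of the resident
    dimorphism.  Averaging the (linear-in-zbar) payoff over founder draws,
    offspring copy-assignments and the size-biased choice of the focal mutant
    gives the closed form

        W + b*( s*z' + (1-s)*ztilde_i ) - c*z'**2,   s = (2N-1)/N^2,

    with ``ztilde_i = p_i1*z1 + p_i2*z2`` the mean resident phenotype.
    """
    p = _check_freqs(p)
    if habitat not in (0, 1):
        raise IndexError(f"habitat index must be 0 or 1, got {habitat}")
    return _conditional_expected_payoff(
        zprime, _ztilde(dim, p, habitat), habitat, game, habitats.N[habitat]
    )


def resident_class_payoff(
    k: int,
    habitat: int,
    dim: Dimorphism,
    p: np.ndarray,
    game: GameParams,
    habitats: HabitatConfig,
) -> float:
    """Expected payoff of a random resident carrying cue allele ``x_k``.

    Same size-biasing logic as the rare-mutant payoff: the focal individual's
    own founder lineage over-contributes to its group mean, the remaining
    ``N-1`` founders are i.i.d. draws from the habitat pool.
    """
    p = _check_freqs(p)
    if habitat not in (0, 1) or k not in (0, 1):
        raise IndexError("habitat and allele indices must be 0 or 1")
    z_self = dim.z[k]
    return _conditional_expected_payoff(
        z_self, _ztilde(dim, p, habitat), habitat, game, habitats.N[habitat]
    )


def payoff_derivative(
    habitat: int, zk: float, game: GameParams, habitats: HabitatConfig
) -> float:
    """Derivative ``d_ik`` of the expected rare-mutant payoff at ``z' = z_k``:

        d_ik = (b_i/N_i) * (1 + (N_i - 1) * r_i) - 2 * c_i * z_k,

    with ``r_i = 1/N_i``.  The first factor is the size-biased number of
    focal-lineage copies among the group's N members, divided by N.
    """
    if habitat not in (0, 1):
        raise IndexError(f"habitat index must be 0 or 1, got {habitat}")
    if not 0.0 <= zk <= 1.0:
        raise ValueError("resident phenotype must lie in [0, 1]")
    N = habitats.N[habitat]
    r = 1.0 / N
    return (
        game.b[habitat] / N * (1.0 + (N - 1) * r)
        - 2.0 * game.c[habitat] * zk
    )


_ENUM_MAX_N = 8


def _enumerate_conditional_payoff(
    z_self: float,
    habitat: int,
    dim: Dimorphism,
    p: np.ndarray,
    game: GameParams,
    habitats: HabitatConfig,
) -> float:
    """Exact expectation over founder draws, copy-assignments and size-biased
    focal choice, for one focal founder expressing ``z_self`` among ``N-1``
    resident founders drawn from habitat frequencies.  Test oracle for the
    closed forms; combinatorial, so capped at N <= 8."""
    p = _check_freqs(p)
    N = habitats.N[habitat]
    if N > _ENUM_MAX_N:
        raise ValueError(f"enumeration limited to N <= {_ENUM_MAX_N}, got {N}")
    p1 = p[habitat, 0]
    z1, z2 = dim.z1, dim.z2
    num = 0.0
    den = 0.0
    # j = number of z1-residents among the N-1 non-focal founders
    for j in range(N):
        wj = binom.pmf(j, N - 1, p1)
        if wj == 0.0:
            continue
        # (K, A, B): offspring copies of the focal founder, of z1-residents,
        # of z2-residents; multinomial over the N offspring with cell
        # probabilities (1/N, j/N, (N-1-j)/N)
        for K in range(N + 1):
            for A in range(N - K + 1):
                B = N - K - A
                w = (
                    wj
                    * math.comb(N, K)
                    * math.comb(N - K, A)
                    * (1.0 / N) ** K
                    * (j / N) ** A
                    * ((N - 1 - j) / N) ** B
                )
                if w == 0.0 or K == 0:
                    continue
                zbar = (K * z_self + A * z1 + B * z2) / N
                num += w * K * payoff(z_self, zbar, habitat, game)
                den += w * K
    return num / den


def enumerate_mutant_payoff(
    zprime: float,
    habitat: int,
    dim: Dimorphism,
    p: np.ndarray,
    game: GameParams,
    habitats: HabitatConfig,
) -> float:
    """Brute-force expected rare-mutant payoff (single mutant founder)."""
    return _enumerate_conditional_payoff(zprime, habitat, dim, p, game, habitats)


def enumerate_class_payoff(
    k: int,
    habitat: int,
    dim: Dimorphism,
    p: np.ndarray,
    game: GameParams,
    habitats: HabitatConfig,
) -> float:
    """Brute-force expected payoff of a random resident with allele ``x_k``."""
    if k not in (0, 1):
        raise IndexError("allele index must be 0 or 1")
    return _enumerate_conditional_payoff(
        dim.z[k], habitat, dim, p, game, habitats
    )


def size_biased_founder_copies(N: int) -> float:
    """Size-biased mean offspring count of a founder, E[K^2]/E[K] with
    K ~ Binomial(N, 1/N); equals ``1 + (N-1)*r`` with ``r = 1/N``.

    Computed by direct summation over the binomial pmf (not the identity), so
    it can serve as a numerical cross-check.
    """
    if int(N) != N or N < 1:
        raise ValueError("N must be a positive integer")
    ks = np.arange(N + 1)
    pmf = binom.pmf(ks, N, 1.0 / N)
    return float((pmf * ks * ks).sum() / (pmf * ks).sum())


def liability_to_phenotype(a0: float, ag: float, x: float) -> float:
    """Sigmoid genotype-phenotype map ``z = 1/(1 + exp(-(a0 + ag*x)))``.

    Strictly increasing in the liability; overflow saturates at 0/1.
    """
    return float(expit(a0 + ag * x))
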