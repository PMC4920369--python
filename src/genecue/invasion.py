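"""Mutant-modifier invasion analysis: projection matrix, invasion fitness,
reproductive values and the selection gradient.

A rare mutant modifier changes the phenotype induced by cue allele ``x_k``
from ``z_k`` to ``z'_k``.  Its lineage is tracked over the four classes
(habitat ``j``, linked cue allele ``x_l``); one life cycle on the resident
equilibrium background gives the projection matrix

    M[(j,l), (i,k)] = phi_j * m_ji * wbar'_i(z'_k) * h_jlk,

where ``wbar'`` is the expected rare-mutant payoff, ``phi_j`` the founding
probability in pool ``j``, and the cue inheritance

    h_jlk = (1 - rho) * delta_lk + rho * p_jl

mixes faithful transmission with recombination onto a random pool haplotype.
Invasion fitness is ``F = log(lambda)`` of the leading eigenvalue; the
resident played as its own mutant has ``lambda = 1`` exactly (the equilibrium
abundances are the right eigenvector), which is the primary correctness
oracle for the construction.

The selection gradient (derivative of F in the mutant traits at the resident)
decomposes into reproductive-value and habitat-information weights:

    dF/dz'_k = V_1k * d_1k * p_k * q_1k + V_2k * d_2k * p_k * q_2k,

with ``V_ik`` the reproductive value of an offspring of a player in habitat
``i`` carrying ``x_k``, ``d_ik`` the payoff derivative, ``q_ik`` the habitat
probability conditional on the allele, and ``p_k`` the dilution factor.

The cue locus itself is fully linked to itself, so invasion of a cue allele
into a monomorphism reduces to a 2-class (habitat-only) matrix; those helpers
live here too and power the coexistence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    Dimorphism,
    ModelParams,
    expected_mutant_payoff,
    payoff,
    payoff_derivative,
)
from .resident import ResidentEquilibrium, find_resident_equilibrium

__all__ = [
    "InvasionResult",
    "GradientResult",
    "cue_inheritance",
    "mutant_projection_matrix",
    "resident_projection_matrix",
    "invasion_analysis",
    "invasion_fitness",
    "reproductive_values",
    "selection_gradient",
    "monomorphic_phi",
    "cue_invasion_matrix",
    "cue_invasion_fitness",
    "monomorphic_gradient",
]


def cue_inheritance(rho: float, pool_p: np.ndarray) -> np.ndarray:
    """Cue-inheritance probabilities ``h[j, l, k]``: offspring founded in
    habitat ``j`` carries allele ``x_l`` given the parent carried ``x_k``.

    ``h = (1 - rho) * delta_lk + rho * p_jl`` with ``p_jl`` the dispersal-pool
    frequency in habitat ``j``.
    """
    if not 0.0 <= rho <= 0.5:
        raise ValueError(f"rho must lie in [0, 0.5], got {rho}")
    pool_p = np.asarray(pool_p, dtype=float)
    if pool_p.shape != (2, 2) or np.any(
        np.abs(pool_p.sum(axis=1) - 1.0) > 1e-9
    ):
        raise ValueError("pool frequencies must be a row-normalized 2x2 table")
    h = np.empty((2, 2, 2))
    for j in range(2):
        for l in range(2):
            for k in range(2):
                h[j, l, k] = (1.0 - rho) * (l == k) + rho * pool_p[j, l]
    return h


def _class_index(j: int, l: int) -> int:
    # class ordering: (hab1, x1), (hab1, x2), (hab2, x1), (hab2, x2)
    return 2 * j + l


def mutant_projection_matrix(
    zprime: tuple[float, float],
    dim: Dimorphism,
    eq: ResidentEquilibrium,
    params: ModelParams,
) -> np.ndarray:
    """4x4 projection matrix of a rare mutant modifier expressing
    ``zprime[k]`` when linked to cue allele ``x_k``, on the resident
    equilibrium background."""
    if not eq.converged:
        raise ValueError("resident equilibrium did not converge")
    mmat = params.dispersal.matrix
    h = cue_inheritance(params.dispersal.rho, eq.pool_p)
    wbar = np.empty((2, 2))
    for i in range(2):
        for k in range(2):
            wbar[i, k] = max(
                expected_mutant_payoff(
                    zprime[k], i, dim, eq.p, params.game, params.habitats
                ),
                0.0,
            )
    M = np.empty((4, 4))
    for j in range(2):
        for l in range(2):
            for i in range(2):
                for k in range(2):
                    M[_class_index(j, l), _class_index(i, k)] = (
                        eq.phi[j] * mmat[j, i] * wbar[i, k] * h[j, l, k]
                    )
    return M


def resident_projection_matrix(
    dim: Dimorphism, eq: ResidentEquilibrium, params: ModelParams
) -> np.ndarray:
    """Projection matrix of the resident played as its own mutant
    (``z'_k = z_k``); its leading eigenvalue is 1 at equilibrium."""
    return mutant_projection_matrix((dim.z1, dim.z2), dim, eq, params)


def _leading_triple(M: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Leading eigenvalue with right and left eigenvectors of a non-negative
    matrix; eigenvectors sign-fixed non-negative, u summing to 1, v.u = 1."""
    vals, right = np.linalg.eig(M)
    idx = int(np.argmax(vals.real))
    lam = vals[idx]
    if abs(lam.imag) > 1e-9 * max(1.0, abs(lam.real)):
        raise ArithmeticError("leading eigenvalue is not real (degenerate matrix)")
    u = right[:, idx].real
    vals_l, left = np.linalg.eig(M.T)
    idx_l = int(np.argmin(np.abs(vals_l - lam)))
    v = left[:, idx_l].real
    # Perron vectors have one sign; fix to non-negative
    if u.sum() < 0:
        u = -u
    if v.sum() < 0:
        v = -v
    u = u / u.sum()
    vu = float(v @ u)
    if abs(vu) < 1e-300:
        raise ArithmeticError("degenerate eigenstructure: v.u = 0")
    v = v / vu
    return float(lam.real), u, v


@dataclass(frozen=True)
class InvasionResult:
    """Invasion analysis of one mutant modifier against one resident."""

    matrix: np.ndarray   # 4x4 projection over classes (j, l)
    lam: float           # leading eigenvalue
    F: float             # invasion fitness log(lam)
    u: np.ndarray        # stable class distribution, (2, 2) over (j, l)
    v: np.ndarray        # reproductive values v_jl, (2, 2), v.u = 1
    V: np.ndarray        # offspring reproductive values V_ik, (2, 2)
    eq: ResidentEquilibrium


def _offspring_reproductive_values(
    v: np.ndarray, eq: ResidentEquilibrium, params: ModelParams
) -> np.ndarray:
    """``V_ik = sum_jl v_jl * phi_j * h_jlk * m_ji``: the reproductive value
    of an offspring of a habitat-``i`` player carrying cue allele ``x_k``,
    after migration, mating/recombination and founding."""
    mmat = params.dispersal.matrix
    h = cue_inheritance(params.dispersal.rho, eq.pool_p)
    V = np.zeros((2, 2))
    for i in range(2):
        for k in range(2):
            for j in range(2):
                for l in range(2):
                    V[i, k] += v[j, l] * eq.phi[j] * h[j, l, k] * mmat[j, i]
    return V


def invasion_analysis(
    zprime: tuple[float, float],
    dim: Dimorphism,
    params: ModelParams,
    eq: ResidentEquilibrium | None = None,
) -> InvasionResult:
    """Build the mutant projection matrix and its spectral quantities."""
    if eq is None:
        eq = find_resident_equilibrium(dim, params)
    M = mutant_projection_matrix(zprime, dim, eq, params)
    try:
        lam, u_flat, v_flat = _leading_triple(M)
        u = u_flat.reshape(2, 2)
        v = v_flat.reshape(2, 2)
        V = _offspring_reproductive_values(v, eq, params)
    except ArithmeticError:
        # degenerate leading eigenvalue (e.g. rho = 0 resident-as-mutant,
        # where both allele blocks grow at rate 1): the eigenvalue itself is
        # still well defined
        lam = float(np.max(np.linalg.eigvals(M).real))
        u = v = V = np.full((2, 2), np.nan)
    return InvasionResult(
        matrix=M, lam=lam, F=float(np.log(lam)), u=u, v=v, V=V, eq=eq
    )


def invasion_fitness(
    zprime1: float,
    zprime2: float,
    dim: Dimorphism,
    params: ModelParams,
    eq: ResidentEquilibrium | None = None,
) -> float:
    """Invasion fitness ``F = log(lambda)`` of a mutant modifier inducing
    phenotypes (zprime1, zprime2) on cue alleles (x1, x2); positive F means
    the modifier invades the resident dimorphism."""
    for z in (zprime1, zprime2):
        if not 0.0 <= z <= 1.0:
            raise ValueError("mutant phenotypes must lie in [0, 1]")
    return invasion_analysis((zprime1, zprime2), dim, params, eq=eq).F


def _blockwise_values(
    eq: ResidentEquilibrium, dim: Dimorphism, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reproductive values at rho = 0, where the projection matrix is block
    diagonal over cue-allele lineages and the leading eigenvalue 1 of the
    dimorphic resident is degenerate (both allele lineages grow at rate 1).

    Each allele's 2x2 habitat block is treated separately: its right
    eigenvector is the allele's habitat distribution ``q_ik`` and the left
    eigenvector is normalized against it, per block.
    """
    mmat = params.dispersal.matrix
    v = np.empty((2, 2))  # v[j, l]
    V = np.empty((2, 2))  # V[i, k]
    u = eq.n / eq.n.sum()
    for k in range(2):
        wbar = np.array(
            [
                max(
                    expected_mutant_payoff(
                        dim.z[k], i, dim, eq.p, params.game, params.habitats
                    ),
                    0.0,
                )
                for i in range(2)
            ]
        )
        B = eq.phi[:, None] * mmat * wbar[None, :]
        lam, ub, vb = _leading_triple(B)
        # normalize against the allele's own habitat distribution
        uk = eq.q_given_allele[:, k]
        vb = vb / (vb @ uk)
        v[:, k] = vb
        V[:, k] = (vb * eq.phi) @ mmat
    return v, V, u


def reproductive_values(
    eq: ResidentEquilibrium, dim: Dimorphism, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Census reproductive values ``v_jl``, offspring values ``V_ik`` and the
    stable class distribution ``u`` of the resident-valued matrix."""
    if params.dispersal.rho == 0.0 and eq.monomorphic is None:
        return _blockwise_values(eq, dim, params)
    res = invasion_analysis((dim.z1, dim.z2), dim, params, eq=eq)
    return res.v, res.V, res.u


@dataclass(frozen=True)
class GradientResult:
    """Selection gradient at a resident dimorphism.

    ``g[k]`` is dF/dz'_k at the resident; for a monomorphic resident only the
    surviving allele's component is defined (the other is NaN) and
    ``monomorphic`` holds that allele's index.
    """

    g: np.ndarray
    eq: ResidentEquilibrium
    V: np.ndarray | None
    d: np.ndarray | None
    monomorphic: int | None


def selection_gradient(
    dim: Dimorphism,
    params: ModelParams,
    eq: ResidentEquilibrium | None = None,
) -> GradientResult:
    """Selection gradient on the mutant-modifier traits at the resident:

        g_k = V_1k * d_1k * p_k * q_1k + V_2k * d_2k * p_k * q_2k.

    If the resident equilibrium is monomorphic (the dimorphism is not
    protected), the gradient of the surviving phenotype is computed from the
    2-class habitat-only machinery and flagged.
    """
    if eq is None:
        eq = find_resident_equilibrium(dim, params)
    if eq.monomorphic is not None:
        k = eq.monomorphic
        g = np.full(2, np.nan)
        g[k] = monomorphic_gradient(dim.z[k], params)
        return GradientResult(g=g, eq=eq, V=None, d=None, monomorphic=k)
    v, V, u = reproductive_values(eq, dim, params)
    d = np.empty((2, 2))
    for i in range(2):
        for k in range(2):
            d[i, k] = payoff_derivative(i, dim.z[k], params.game, params.habitats)
    g = np.empty(2)
    for k in range(2):
        g[k] = eq.p_allele[k] * sum(
            V[i, k] * d[i, k] * eq.q_given_allele[i, k] for i in range(2)
        )
    return GradientResult(g=g, eq=eq, V=V, d=d, monomorphic=None)


# ---------------------------------------------------------------------------
# 2-class (habitat-only) machinery for monomorphic residents.  A cue allele is
# fully linked to itself, so its invasion into a monomorphism of the other is
# independent of rho and uses habitat classes only.
# ---------------------------------------------------------------------------


def monomorphic_phi(z: float, params: ModelParams) -> np.ndarray:
    """Founding probabilities ``phi_j`` of a monomorphic-z resident at its
    demographic equilibrium (habitats at capacity)."""
    cap = np.asarray(params.habitats.capacity, dtype=float)
    mmat = params.dispersal.matrix
    w = np.array([max(payoff(z, z, i, params.game), 0.0) for i in range(2)])
    pool = mmat @ (cap * w)
    if np.any(pool <= 0):
        raise ValueError("monomorphic resident has an empty dispersal pool")
    return cap / pool


def cue_invasion_matrix(
    z_invader: float, z_resident: float, params: ModelParams
) -> np.ndarray:
    """2x2 habitat projection matrix of a rare cue allele inducing
    ``z_invader`` in a monomorphic ``z_resident`` population:
    ``B[j, i] = phi_j * m_ji * wbar'_i(z_invader)``."""
    phi = monomorphic_phi(z_resident, params)
    mmat = params.dispersal.matrix
    dim = Dimorphism(z1=z_resident, z2=z_resident)
    p = np.full((2, 2), 0.5)  # resident is monomorphic, mix is z_resident
    wbar = np.array(
        [
            max(
                expected_mutant_payoff(
                    z_invader, i, dim, p, params.game, params.habitats
                ),
                0.0,
            )
            for i in range(2)
        ]
    )
    return phi[:, None] * mmat * wbar[None, :]


def cue_invasion_fitness(
    z_invader: float, z_resident: float, params: ModelParams
) -> float:
    """log(lambda) of a rare cue allele invading a monomorphic resident."""
    B = cue_invasion_matrix(z_invader, z_resident, params)
    lam, _, _ = _leading_triple(B)
    if lam <= 0:
        return -np.inf
    return float(np.log(lam))


def monomorphic_gradient(z: float, params: ModelParams) -> float:
    """Selection gradient of gradual evolution in a monomorphic population:
    the reproductive-value-weighted combination of the per-habitat payoff
    derivatives, dF/dz' at z' = z for the 2-class matrix."""
    B = cue_invasion_matrix(z, z, params)
    lam, u, v = _leading_triple(B)
    # resident at its own equilibrium: lambda must be 1
    if abs(lam - 1.0) > 1e-8:
        raise ArithmeticError(
            f"monomorphic resident eigenvalue deviates from 1: {lam}"
        )
    phi = monomorphic_phi(z, params)
    mmat = params.dispersal.matrix
    d = np.array(
        [payoff_derivative(i, z, params.game, params.habitats) for i in range(2)]
    )
    weights = (v * phi) @ mmat  # weights_i = sum_j v_j phi_j m_ji
    return float(np.sum(weights * d * u))
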