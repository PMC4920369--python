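"""Deterministic resident dynamics over (habitat, cue allele) classes.

The resident population is tracked by class abundances ``n[i, k]`` (habitat
``i``, cue allele ``x_k``) in the infinite-population limit.  One life cycle
maps the census state through (i) offspring production proportional to the
expected class payoff, (ii) migration into per-habitat dispersal pools,
(iii) random mating (which leaves resident cue-allele frequencies unchanged,
since residents carry identical modifiers), and (iv) group founding that
regulates each habitat back to its fixed capacity.  Iterating the map to a
fixed point yields the population-dynamical equilibrium that all invasion
quantities are built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Dimorphism, ModelParams, resident_class_payoff

__all__ = [
    "ExtinctionError",
    "StepResult",
    "ResidentEquilibrium",
    "resident_step",
    "find_resident_equilibrium",
    "conditional_habitat_probability",
]

EXTINCTION_TOL = 1e-10


class ExtinctionError(RuntimeError):
    """The dispersal pool of a habitat is empty (zero total fecundity)."""


@dataclass(frozen=True)
class StepResult:
    n: np.ndarray        # next census abundances, (2, 2)
    phi: np.ndarray      # founding probability per habitat pool, (2,)
    pool: np.ndarray     # unnormalized pool sizes pool[j, k], (2, 2)

    @property
    def pool_p(self) -> np.ndarray:
        """Post-migration pool composition, rows normalized per habitat."""
        return self.pool / self.pool.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class ResidentEquilibrium:
    """Equilibrium state of the resident dimorphism.

    ``n[i, k]``: class abundances; ``p[i, k]``: within-habitat allele
    frequencies; ``q_habitat[i]``: prior probability of habitat ``i``;
    ``q_given_allele[i, k]``: probability of habitat ``i`` conditional on
    carrying allele ``x_k``; ``p_allele[k]``: overall allele frequency (the
    dilution factor); ``phi[j]``: probability for a pool member in habitat
    ``j`` to found a group; ``pool_p[j, k]``: pool composition.
    """

    n: np.ndarray
    p: np.ndarray
    q_habitat: np.ndarray
    q_given_allele: np.ndarray
    p_allele: np.ndarray
    phi: np.ndarray
    pool_p: np.ndarray
    dim: Dimorphism
    converged: bool
    monomorphic: int | None  # surviving allele index, or None if dimorphic
    n_iter: int
    residual: float

    def to_frame(self):
        """One row per (habitat, allele) class, for TSV export."""
        import pandas as pd

        rows = []
        for i in range(2):
            for k in range(2):
                rows.append(
                    {
                        "habitat": i + 1,
                        "allele": k + 1,
                        "n": self.n[i, k],
                        "p": self.p[i, k],
                        "q_habitat": self.q_habitat[i],
                        "q_given_allele": self.q_given_allele[i, k],
                        "p_allele": self.p_allele[k],
                        "phi": self.phi[i],
                        "pool_p": self.pool_p[i, k],
                    }
                )
        return pd.DataFrame(rows)


def _class_fecundity(
    p: np.ndarray, dim: Dimorphism, params: ModelParams
) -> np.ndarray:
    """Expected (clamped) payoff of each class at census composition p.

    Vectorized form of :func:`genecue.core.resident_class_payoff` over the
    four (habitat, allele) classes.
    """
    N = np.asarray(params.habitats.N, dtype=float)
    s = (2 * N - 1) / N**2  # size-biased self weight, per habitat
    z = dim.z
    W = np.asarray(params.game.W)
    b = np.asarray(params.game.b)
    c = np.asarray(params.game.c)
    ztilde = p @ z  # mean resident phenotype per habitat
    ezbar = s[:, None] * z[None, :] + (1.0 - s)[:, None] * ztilde[:, None]
    w = W[:, None] + b[:, None] * ezbar - c[:, None] * z[None, :] ** 2
    return np.maximum(w, 0.0)


def resident_step(
    n: np.ndarray, dim: Dimorphism, params: ModelParams
) -> StepResult:
    """One full life cycle of the deterministic resident dynamics.

    Habitat totals are regulated back to capacity at founding; ``phi[j]`` is
    capacity_j divided by the pool size, the per-pool-member founding
    probability used by the invasion machinery.
    """
    n = np.asarray(n, dtype=float)
    if n.shape != (2, 2) or np.any(n < 0):
        raise ValueError("state must be a non-negative 2x2 abundance table")
    cap = np.asarray(params.habitats.capacity, dtype=float)
    totals = n.sum(axis=1)
    if np.any(totals <= 0):
        raise ExtinctionError("empty habitat in input state")
    p = n / totals[:, None]
    w = _class_fecundity(p, dim, params)
    mmat = params.dispersal.matrix
    # pool[j, k] = sum_i m[j, i] * n[i, k] * w[i, k]
    pool = mmat @ (n * w)
    pool_tot = pool.sum(axis=1)
    if np.any(pool_tot <= 0):
        j = int(np.argmin(pool_tot))
        raise ExtinctionError(f"dispersal pool of habitat {j + 1} is empty")
    n_new = cap[:, None] * pool / pool_tot[:, None]
    phi = cap / pool_tot
    return StepResult(n=n_new, phi=phi, pool=pool)


def _monomorphic_equilibrium(
    k: int, dim: Dimorphism, params: ModelParams, n_iter: int, residual: float
) -> ResidentEquilibrium:
    """Exact boundary equilibrium with only allele ``x_k`` present."""
    cap = np.asarray(params.habitats.capacity, dtype=float)
    n = np.zeros((2, 2))
    n[:, k] = cap
    p = np.zeros((2, 2))
    p[:, k] = 1.0
    step = resident_step(n, dim, params)
    q_hab = cap / cap.sum()
    q_given = np.full((2, 2), np.nan)
    q_given[:, k] = cap / cap.sum()
    p_allele = np.zeros(2)
    p_allele[k] = 1.0
    return ResidentEquilibrium(
        n=n,
        p=p,
        q_habitat=q_hab,
        q_given_allele=q_given,
        p_allele=p_allele,
        phi=step.phi,
        pool_p=step.pool_p,
        dim=dim,
        converged=True,
        monomorphic=k,
        n_iter=n_iter,
        residual=residual,
    )


def find_resident_equilibrium(
    dim: Dimorphism,
    params: ModelParams,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
    start: np.ndarray | None = None,
    extinction_tol: float = EXTINCTION_TOL,
) -> ResidentEquilibrium:
    """Iterate the resident life cycle to its fixed point.

    ``start`` may give initial within-habitat frequencies of allele 1 (shape
    (2,)) or a full 2x2 frequency table; default is 0.5 in both habitats.
    If one allele's overall frequency drops below ``extinction_tol`` the
    boundary (monomorphic) equilibrium is returned, flagged as such.
    Convergence is measured as the max absolute frequency change per cycle;
    the iteration is damped if the residual stops contracting.
    """
    cap = np.asarray(params.habitats.capacity, dtype=float)
    if start is None:
        p = np.full((2, 2), 0.5)
    else:
        start = np.asarray(start, dtype=float)
        if start.shape == (2,):
            p = np.stack([start, 1.0 - start], axis=1)
        elif start.shape == (2, 2):
            p = start / start.sum(axis=1, keepdims=True)
        else:
            raise ValueError("start must have shape (2,) or (2, 2)")
    mmat = params.dispersal.matrix
    q_hab_w = cap / cap.sum()

    def _step_p(pmat: np.ndarray) -> np.ndarray:
        """One life cycle on within-habitat frequencies (lean inner loop)."""
        w = _class_fecundity(pmat, dim, params)
        pool = mmat @ (cap[:, None] * pmat * w)
        tot = pool.sum(axis=1, keepdims=True)
        if np.any(tot <= 0):
            raise ExtinctionError("dispersal pool of a habitat is empty")
        return pool / tot

    def _p_residual(p1: np.ndarray) -> np.ndarray:
        """Fixed-point residual in the allele-1 frequencies (p11, p21)."""
        p1 = np.clip(p1, 0.0, 1.0)
        pfull = np.stack([p1, 1.0 - p1], axis=1)
        return _step_p(pfull)[:, 0] - p1

    def _try_newton(pmat):
        """Quasi-Newton solve for the fixed point; returns a refined interior
        frequency table only when the root is dynamically stable (an
        unprotected dimorphism has an unstable interior point whose true
        attractor is a boundary; boundary roots prove nothing since the
        monomorphic states are always fixed points)."""
        from scipy.optimize import root as _root

        sol = _root(_p_residual, pmat[:, 0], method="hybr",
                    options={"xtol": 1e-13})
        if not sol.success:
            return None, None
        if not (np.all(sol.x > extinction_tol)
                and np.all(sol.x < 1.0 - extinction_tol)):
            return None, None
        h = 1e-7
        J = np.empty((2, 2))
        f0 = _p_residual(sol.x)
        for a in range(2):
            e = np.zeros(2)
            e[a] = h
            J[:, a] = (_p_residual(sol.x + e) - f0) / h
        rad = float(np.max(np.abs(np.linalg.eigvals(J + np.eye(2)))))
        stable = rad <= 1.0 + 1e-6
        return np.stack([sol.x, 1.0 - sol.x], axis=1), stable

    damping = 1.0
    grow_count = 0
    prev_residual = np.inf
    residual = np.inf
    minor_hist: list[float] = []
    interior_unstable = False
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        p_new = _step_p(p)
        residual = float(np.max(np.abs(p_new - p)))
        if damping < 1.0:
            p_new = (1.0 - damping) * p + damping * p_new
        p = p_new
        p_overall = q_hab_w @ p
        minor = float(p_overall.min())
        if minor < extinction_tol:
            k = int(np.argmax(p_overall))
            return _monomorphic_equilibrium(k, dim, params, it, residual)
        if residual < tol:
            converged = True
            break
        if it % 500 == 100:
            # slow linear convergence (near-neutral dimorphisms mix at rate
            # ~m): polish the 2-d fixed point with a quasi-Newton solve
            refined, stable = _try_newton(p)
            if refined is not None and stable:
                p = refined
                residual = float(np.max(np.abs(_step_p(p)[:, 0] - p[:, 0])))
                if residual < tol:
                    converged = True
                    break
            elif refined is not None:
                interior_unstable = True
        if it % 2000 == 0:
            # extinction can be geometrically slow near the protection
            # threshold: extrapolate a sustained geometric decay of the minor
            # allele instead of iterating it below extinction_tol
            minor_hist.append(minor)
            if len(minor_hist) >= 4:
                f = np.array(minor_hist[-4:])
                ratios = f[1:] / f[:-1]
                if np.all(ratios < 0.9995) and (
                    np.std(np.log(ratios)) < 0.2 * abs(np.mean(np.log(ratios)))
                    or interior_unstable
                ):
                    k = int(np.argmax(p_overall))
                    return _monomorphic_equilibrium(
                        k, dim, params, it, residual
                    )
        # crude oscillation guard: persistent residual growth triggers damping
        if residual > prev_residual:
            grow_count += 1
            if grow_count >= 50 and damping > 0.24:
                damping *= 0.5
                grow_count = 0
        else:
            grow_count = 0
        prev_residual = residual
    n = cap[:, None] * p
    step = resident_step(n, dim, params)
    q_hab = cap / cap.sum()
    n_allele = n.sum(axis=0)
    q_given = n / n_allele[None, :]
    p_allele = n_allele / n.sum()
    return ResidentEquilibrium(
        n=n,
        p=p,
        q_habitat=q_hab,
        q_given_allele=q_given,
        p_allele=p_allele,
        phi=step.phi,
        pool_p=step.pool_p,
        dim=dim,
        converged=converged,
        monomorphic=None,
        n_iter=it,
        residual=residual,
    )


def conditional_habitat_probability(n: np.ndarray) -> np.ndarray:
    """Habitat probability conditional on the cue allele,
    ``q[i, k] = n[i, k] / (n[0, k] + n[1, k])``; NaN columns for extinct
    alleles."""
    n = np.asarray(n, dtype=float)
    if n.shape != (2, 2) or np.any(n < 0):
        raise ValueError("class counts must be a non-negative 2x2 table")
    tot = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(tot > 0, n / tot[None, :], np.nan)
    return q
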