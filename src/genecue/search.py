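"""Coexistence scanning, gradient-path equilibrium search and parameter sweeps.

A phenotype pair (z1, z2) is a *protected dimorphism* when each cue allele can
invade a monomorphism of the other (mutual invasibility at the cue locus,
computed with the 2-class habitat matrix — the cue allele is fully linked to
itself, so rho plays no role there).  Inside the coexistence region the
evolutionary dynamics of the modifier-controlled phenotypes follow the
selection gradient; equilibria are found by a path of small fitness-increasing
steps through (z1, z2)-space, re-solving the resident population equilibrium
at every step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import Dimorphism, ModelParams
from .invasion import (
    cue_invasion_fitness,
    invasion_fitness,
    monomorphic_gradient,
    selection_gradient,
)
from .resident import find_resident_equilibrium

__all__ = [
    "PolymorphismCollapse",
    "AscentResult",
    "SweepResult",
    "coexistence_test",
    "coexistence_region",
    "ascend_to_equilibrium",
    "monomorphic_singular_strategy",
    "no_dispersal_optima",
    "sweep",
]

logger = logging.getLogger(__name__)

BOUNDARY_TOL = 1e-6


class PolymorphismCollapse(RuntimeError):
    """The gradient path left the coexistence region (an allele went extinct)
    or the phenotype divergence shrank to zero: the cue polymorphism cannot
    be maintained and the outcome is a monomorphism.

    ``surviving`` is the surviving allele index when an allele went extinct,
    or None when the divergence collapsed onto z1 = z2 (the alleles become
    phenotypically equivalent and the polymorphism is neutral)."""

    def __init__(self, message: str, dim: Dimorphism, surviving: int | None):
        super().__init__(message)
        self.dim = dim
        self.surviving = surviving


#: phenotype pairs closer than this are treated as a collapsed (monomorphic)
#: outcome: the resident dynamics become quasi-neutral and the dimorphism is
#: not numerically resolvable
DIAG_TOL = 2e-3


def coexistence_test(z1: float, z2: float, params: ModelParams) -> bool:
    """Mutual invasibility of the two phenotypes at the cue locus: true iff
    z2 invades a z1-monomorphism and z1 invades a z2-monomorphism.  Equal
    phenotypes are neutral and return False."""
    if abs(z1 - z2) < 1e-12:
        return False
    return (
        cue_invasion_fitness(z2, z1, params) > 0.0
        and cue_invasion_fitness(z1, z2, params) > 0.0
    )


def coexistence_region(
    params: ModelParams, grid_step: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean coexistence mask over a (z1, z2) grid on the unit square.

    Returns ``(grid, mask)`` with ``mask[a, b]`` the result of
    ``coexistence_test(grid[a], grid[b])``.  The test is symmetric in the
    pair, so only the upper triangle is computed and mirrored; the diagonal
    is False.
    """
    if not 0.0 < grid_step <= 0.1:
        raise ValueError("grid_step must lie in (0, 0.1]")
    n = int(round(1.0 / grid_step))
    grid = np.linspace(0.0, 1.0, n + 1)
    mask = np.zeros((n + 1, n + 1), dtype=bool)
    for a in range(n + 1):
        for b in range(a + 1, n + 1):
            ok = coexistence_test(grid[a], grid[b], params)
            mask[a, b] = ok
            mask[b, a] = ok
    return grid, mask


@dataclass(frozen=True)
class AscentResult:
    dim: Dimorphism
    gradient: np.ndarray
    grad_norm: float
    n_steps: int
    converged: bool
    boundary: bool  # an equilibrium phenotype pinned at z = 0 or 1


def ascend_to_equilibrium(
    start: Dimorphism,
    params: ModelParams,
    step_size: float = 0.01,
    tol: float = 1e-6,
    max_steps: int = 5000,
) -> AscentResult:
    """Follow the selection gradient to an equilibrium dimorphism.

    Projected gradient steps ``z <- clip(z + eta * g)`` with an adaptive
    rate: ``eta`` is halved whenever the gradient direction flips between
    consecutive steps (overshoot across the ridge — invasion fitness alone
    cannot detect this because near a branching-type equilibrium mutants on
    both sides invade), and grown gently otherwise.  Near the equilibrium
    the remaining gradient root is polished with a quasi-Newton solve.
    Terminates when the gradient norm drops below ``tol``; a path that leaves
    the coexistence region raises :class:`PolymorphismCollapse`.
    """
    z = np.array([start.z1, start.z2], dtype=float)
    if abs(z[1] - z[0]) < DIAG_TOL:
        raise ValueError("start must be an off-diagonal dimorphism")
    order = 1.0 if z[1] > z[0] else -1.0
    eta = step_size / 0.03  # initial rate giving ~step_size moves at |g|~0.03
    max_move = 5 * step_size
    eq = None
    grad_prev = None
    grad = np.full(2, np.nan)
    gnorm = np.inf
    steps = 0
    escapes = 0
    clamp_count = 0
    last_polish = -100

    def gradient_at(zvec, warm):
        dim = Dimorphism(z1=zvec[0], z2=zvec[1])
        eq_loc = find_resident_equilibrium(
            dim, params, start=None if warm is None else warm.p
        )
        if eq_loc.monomorphic is not None:
            raise PolymorphismCollapse(
                f"cue polymorphism collapsed at z = {tuple(zvec)}",
                dim,
                eq_loc.monomorphic,
            )
        return selection_gradient(dim, params, eq=eq_loc).g, eq_loc

    def clamp_divergence(zvec):
        """Keep the pair off the (quasi-neutral) diagonal, preserving order."""
        if order * (zvec[1] - zvec[0]) >= DIAG_TOL:
            return zvec, False
        mid = zvec.mean()
        half = order * DIAG_TOL / 2
        return np.clip(np.array([mid - half, mid + half]), 0.0, 1.0), True

    def is_attractor(zvec, warm, h=1e-4):
        """Check that a stationary point is a local attractor of the gradient
        field (all Jacobian eigenvalues <= 0); the diagonal z1 = z2 is always
        stationary, so saddles must be rejected."""
        J = np.empty((2, 2))
        try:
            for a in range(2):
                e = np.zeros(2)
                e[a] = h
                gp, _ = gradient_at(np.clip(zvec + e, 0.0, 1.0), warm)
                gm, _ = gradient_at(np.clip(zvec - e, 0.0, 1.0), warm)
                J[:, a] = (gp - gm) / (2 * h)
        except PolymorphismCollapse:
            # a probe step collapsed: the point sits on the edge of the
            # coexistence region; accept it as the path's end point
            return True, None
        vals, vecs = np.linalg.eig(J)
        idx = int(np.argmax(vals.real))
        if vals.real[idx] <= 1e-6:
            return True, None
        vec = vecs[:, idx].real
        return False, vec / np.linalg.norm(vec)

    for steps in range(max_steps + 1):
        grad, eq = gradient_at(z, eq)
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol:
            if _at_boundary(z):
                break
            ok, direction = is_attractor(z, eq)
            if ok:
                break
            # saddle: escape along the unstable direction and keep climbing
            escapes += 1
            if escapes > 5:
                logger.warning("repeated saddle escapes at z = %s", z)
                break
            z, _ = clamp_divergence(np.clip(z + 0.02 * direction, 0.0, 1.0))
            grad_prev = None
            eta = step_size / 0.03
            continue
        if grad_prev is not None and float(grad @ grad_prev) < 0.0:
            eta *= 0.5
        else:
            eta *= 1.1
        grad_prev = grad
        move = eta * grad
        mnorm = float(np.linalg.norm(move))
        if mnorm > max_move:
            move *= max_move / mnorm
        z_new = np.clip(z + move, 0.0, 1.0)
        z_new, clamped = clamp_divergence(z_new)
        if clamped:
            clamp_count += 1
            if clamp_count >= 15:
                dim = Dimorphism(z1=z_new[0], z2=z_new[1])
                raise PolymorphismCollapse(
                    "phenotype divergence collapsed onto z1 = z2 near "
                    f"z = {z_new.mean():.4f}",
                    dim,
                    None,
                )
        else:
            clamp_count = 0
        if np.max(np.abs(z_new - z)) < 1e-14:
            break  # pinned against the boundary
        z = z_new
        # quasi-Newton polish once the path has levelled off near the root
        # (rate-limited: during a slow divergence collapse the root solve
        # would otherwise fire on every step and find nothing)
        if (
            gnorm < 1e-3
            and steps - last_polish >= 20
            and not _at_boundary(z)
            and not clamped
        ):
            last_polish = steps
            from scipy.optimize import root

            def _poll(zz):
                zz = np.clip(zz, 0.0, 1.0)
                if order * (zz[1] - zz[0]) < DIAG_TOL:
                    # keep the solver off the quasi-neutral diagonal
                    return np.array([1.0, -1.0]) * order
                return gradient_at(zz, eq)[0]

            try:
                sol = root(_poll, z, method="hybr", options={"xtol": 1e-12})
            except PolymorphismCollapse:
                sol = None
            if sol is not None and sol.success:
                z_pol = np.clip(sol.x, 0.0, 1.0)
                if order * (z_pol[1] - z_pol[0]) >= DIAG_TOL:
                    try:
                        g_pol, eq_pol = gradient_at(z_pol, eq)
                    except PolymorphismCollapse:
                        g_pol = None
                    if g_pol is not None and float(
                        np.linalg.norm(g_pol)
                    ) < tol:
                        z, grad, eq = z_pol, g_pol, eq_pol
                        gnorm = float(np.linalg.norm(grad))
                        # next loop pass re-checks stationarity and stability
    dim = Dimorphism(z1=z[0], z2=z[1])
    boundary = _at_boundary(z)
    converged = bool(gnorm < tol or boundary)
    if not converged:
        logger.warning(
            "gradient ascent stopped after %d steps, |g| = %.3g", steps, gnorm
        )
    return AscentResult(
        dim=dim,
        gradient=grad,
        grad_norm=gnorm,
        n_steps=steps,
        converged=converged,
        boundary=boundary,
    )


def _at_boundary(z: np.ndarray) -> bool:
    return bool(np.any(z < BOUNDARY_TOL) or np.any(z > 1.0 - BOUNDARY_TOL))


def monomorphic_singular_strategy(params: ModelParams) -> float:
    """Equilibrium of gradual evolution in a monomorphic population: the root
    of the monomorphic selection gradient on [0, 1], found by bracketing.

    Independent of the migration and recombination rates for habitat-symmetric
    game parameters.
    """
    g0 = monomorphic_gradient(0.0, params)
    g1 = monomorphic_gradient(1.0, params)
    if g0 * g1 > 0:
        raise ValueError(
            "monomorphic gradient has no sign change on [0, 1] "
            f"(g(0)={g0:.4g}, g(1)={g1:.4g}): boundary optimum"
        )
    return float(brentq(lambda z: monomorphic_gradient(z, params), 0.0, 1.0,
                        xtol=1e-12))


def no_dispersal_optima(params: ModelParams) -> tuple[float, float]:
    """Habitat-specific singular investments in the no-dispersal limit: roots
    of the per-habitat payoff derivative, z_i* = b_i (2N_i - 1) / (2 c_i N_i^2),
    clamped to [0, 1]."""
    out = []
    for i in range(2):
        N = params.habitats.N[i]
        z = params.game.b[i] * (2 * N - 1) / (2 * params.game.c[i] * N * N)
        out.append(min(max(z, 0.0), 1.0))
    return tuple(out)


def dimorphic_outcome(
    params: ModelParams,
    starts: list[Dimorphism] | None = None,
    tol: float = 1e-6,
) -> AscentResult | None:
    """Outcome of gradual modifier evolution: the dimorphic attractor reached
    by the gradient path, or None when every path collapses (the cue
    polymorphism is not maintained and the outcome is a monomorphism)."""
    if starts is None:
        starts = _default_starts(params)
    for start in starts:
        if not coexistence_test(start.z1, start.z2, params):
            continue
        try:
            res = ascend_to_equilibrium(start, params, tol=tol)
        except PolymorphismCollapse:
            continue
        if res.converged and abs(res.dim.z2 - res.dim.z1) > 2 * DIAG_TOL:
            return res
    return None


def collapse_threshold(
    params: ModelParams,
    m_values,
    rho_values=(0.0, 0.25, 0.5),
) -> float | None:
    """Smallest scanned migration rate at which the cue polymorphism is not
    maintained for any of the tested recombination rates (the evolutionary
    outcome is monomorphic), or None if no scanned m collapses."""
    for m in sorted(m_values):
        if all(
            dimorphic_outcome(params.with_migration(m).with_rho(rho)) is None
            for rho in rho_values
        ):
            return float(m)
    return None


@dataclass(frozen=True)
class SweepResult:
    """Equilibrium dimorphisms over an (m, rho) grid plus the monomorphic
    reference strategy."""

    table: pd.DataFrame
    params: ModelParams


def _default_starts(params: ModelParams) -> list[Dimorphism]:
    zlo, zhi = sorted(no_dispersal_optima(params))
    starts = []
    for pull in (0.1, 0.3, 0.45):
        a = zlo + pull * (zhi - zlo)
        b = zhi - pull * (zhi - zlo)
        if b - a > 1e-6:
            starts.append(Dimorphism(z1=a, z2=b))
    return starts


def sweep(
    params: ModelParams,
    m_values,
    rho_values,
    tol: float = 1e-6,
) -> SweepResult:
    """Equilibrium dimorphisms for every (m, rho) combination.

    Each cell runs the gradient-path search from a coexisting start near the
    no-dispersal optima; cells whose coexistence region is empty (or whose
    path collapses) are recorded as monomorphic.  Individual failures are
    recorded and the sweep continues.
    """
    z_mono = monomorphic_singular_strategy(params)
    rows = []
    for m in m_values:
        for rho in rho_values:
            p = params.with_migration(m).with_rho(rho)
            row = {
                "m": m,
                "rho": rho,
                "z1": np.nan,
                "z2": np.nan,
                "z_mono": z_mono,
                "converged": False,
                "coexists": False,
            }
            start = next(
                (
                    s
                    for s in _default_starts(p)
                    if coexistence_test(s.z1, s.z2, p)
                ),
                None,
            )
            if start is None:
                row["converged"] = True  # monomorphic outcome, not a failure
                rows.append(row)
                continue
            try:
                res = ascend_to_equilibrium(start, p, tol=tol)
            except PolymorphismCollapse:
                row["converged"] = True
                rows.append(row)
                continue
            except Exception as exc:  # record, keep sweeping
                logger.warning("sweep cell m=%s rho=%s failed: %s", m, rho, exc)
                rows.append(row)
                continue
            row.update(
                z1=res.dim.z1,
                z2=res.dim.z2,
                converged=res.converged,
                coexists=coexistence_test(res.dim.z1, res.dim.z2, p),
            )
            rows.append(row)
    return SweepResult(table=pd.DataFrame(rows), params=params)
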