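"""Invasion machinery: cue inheritance, projection matrix, gradient."""

import numpy as np
import pytest

from genecue.core import Dimorphism, ModelParams
from genecue.invasion import (
    cue_inheritance,
    cue_invasion_fitness,
    invasion_analysis,
    invasion_fitness,
    monomorphic_gradient,
    mutant_projection_matrix,
    reproductive_values,
    resident_projection_matrix,
    selection_gradient,
)
from genecue.resident import find_resident_equilibrium


class TestCueInheritance:
    def test_full_linkage_is_identity(self):
        h = cue_inheritance(0.0, np.full((2, 2), 0.5))
        for j in range(2):
            assert np.allclose(h[j], np.eye(2))

    def test_hand_value_free_recombination(self):
        pool = np.array([[0.8, 0.2], [0.8, 0.2]])
        h = cue_inheritance(0.5, pool)
        assert h[0, 0, 0] == pytest.approx(0.9)
        assert h[0, 1, 0] == pytest.approx(0.1)

    def test_rows_sum_to_one(self, rng):
        for _ in range(10):
            p1 = rng.uniform(0, 1, 2)
            pool = np.stack([p1, 1 - p1], axis=1)
            h = cue_inheritance(rng.uniform(0, 0.5), pool)
            assert np.allclose(h.sum(axis=1), 1.0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            cue_inheritance(0.7, np.full((2, 2), 0.5))
        with pytest.raises(ValueError):
            cue_inheritance(0.1, np.array([[0.5, 0.4], [0.5, 0.5]]))


class TestProjectionMatrix:
    def test_resident_neutrality_across_parameters(self, rng):
        """The resident played as its own mutant has leading eigenvalue 1 to
        1e-8: the primary correctness oracle of the matrix construction."""
        for _ in range(8):
            m = rng.uniform(0.01, 0.12)
            rho = rng.uniform(0.0, 0.5)
            z1 = rng.uniform(0.05, 0.35)
            z2 = rng.uniform(0.55, 0.85)
            params = ModelParams.reference(m=m, rho=rho)
            dim = Dimorphism(z1, z2)
            eq = find_resident_equilibrium(dim, params)
            if eq.monomorphic is not None:
                continue
            M = resident_projection_matrix(dim, eq, params)
            lam = np.max(np.linalg.eigvals(M).real)
            assert lam == pytest.approx(1.0, abs=1e-8)

    def test_stable_distribution_matches_equilibrium(self, reference_params):
        params = reference_params.with_rho(0.3)
        dim = Dimorphism(0.2, 0.7)
        eq = find_resident_equilibrium(dim, params)
        res = invasion_analysis((dim.z1, dim.z2), dim, params, eq=eq)
        assert np.allclose(res.u, eq.n / eq.n.sum(), atol=1e-9)

    def test_rho_zero_block_structure(self, reference_params):
        """At rho = 0 mutant lineages never change cue background: the
        cross-allele blocks of the projection matrix vanish."""
        dim = Dimorphism(0.2, 0.7)
        eq = find_resident_equilibrium(dim, reference_params)
        M = mutant_projection_matrix((0.25, 0.65), dim, eq, reference_params)
        # class order (hab, allele): cross-allele entries have l != k
        for j in range(2):
            for i in range(2):
                assert M[2 * j + 0, 2 * i + 1] == 0.0
                assert M[2 * j + 1, 2 * i + 0] == 0.0

    def test_no_migration_no_recombination_decouples(self):
        params = ModelParams.reference(m=0.0, rho=0.0)
        dim = Dimorphism(0.2, 0.7)
        eq = find_resident_equilibrium(
            dim, params, start=np.array([0.7, 0.3])
        )
        M = mutant_projection_matrix((0.25, 0.65), dim, eq, params)
        off = M - np.diag(np.diag(M))
        assert np.allclose(off, 0.0)

    def test_matrix_nonnegative(self, reference_params):
        dim = Dimorphism(0.2, 0.7)
        eq = find_resident_equilibrium(dim, reference_params)
        M = mutant_projection_matrix((1.0, 0.0), dim, eq, reference_params)
        assert np.all(M >= 0.0)


class TestInvasionFitness:
    def test_resident_is_neutral(self, reference_params):
        dim = Dimorphism(0.2, 0.7)
        assert invasion_fitness(0.2, 0.7, dim, reference_params) == pytest.approx(
            0.0, abs=1e-8
        )

    def test_habitat_relabelling_symmetry(self):
        """Swapping habitat labels (group sizes, migration) and the allele
        roles leaves invasion fitness unchanged."""
        from genecue.core import DispersalConfig, GameParams, HabitatConfig

        base = ModelParams(
            game=GameParams(W=(0.5, 0.5), b=(3.0, 3.0), c=(1.5, 1.5)),
            habitats=HabitatConfig(N=(20, 2), capacity=(2000, 2000)),
            dispersal=DispersalConfig.symmetric(0.05, 0.3),
        )
        flipped = ModelParams(
            game=base.game,
            habitats=HabitatConfig(N=(2, 20), capacity=(2000, 2000)),
            dispersal=base.dispersal,
        )
        F1 = invasion_fitness(0.25, 0.65, Dimorphism(0.2, 0.7), base)
        F2 = invasion_fitness(0.65, 0.25, Dimorphism(0.7, 0.2), flipped)
        assert F1 == pytest.approx(F2, abs=1e-9)


class TestSelectionGradient:
    def test_matches_finite_differences(self, rng):
        """The reproductive-value decomposition of the gradient equals
        central finite differences of log(lambda) to 1e-6."""
        h = 1e-5
        checked = 0
        while checked < 6:
            m = rng.uniform(0.02, 0.1)
            rho = rng.uniform(0.05, 0.5)
            dim = Dimorphism(rng.uniform(0.08, 0.3), rng.uniform(0.55, 0.8))
            params = ModelParams.reference(m=m, rho=rho)
            eq = find_resident_equilibrium(dim, params)
            if eq.monomorphic is not None:
                continue
            g = selection_gradient(dim, params, eq=eq).g
            for k in range(2):
                zp = [dim.z1, dim.z2]
                zp[k] += h
                Fp = invasion_fitness(zp[0], zp[1], dim, params, eq=eq)
                zp[k] -= 2 * h
                Fm = invasion_fitness(zp[0], zp[1], dim, params, eq=eq)
                assert g[k] == pytest.approx((Fp - Fm) / (2 * h), abs=1e-6)
            checked += 1

    def test_rho_zero_gradient_matches_per_block_fitness(self):
        """At rho = 0 each component equals p_k times the derivative of the
        corresponding allele-lineage (2x2 habitat block) log-eigenvalue."""
        from genecue.core import expected_mutant_payoff

        params = ModelParams.reference(m=0.05, rho=0.0)
        dim = Dimorphism(0.2, 0.7)
        eq = find_resident_equilibrium(dim, params)
        g = selection_gradient(dim, params, eq=eq).g
        mmat = params.dispersal.matrix
        h = 1e-5

        def block_loglam(zk, k):
            wbar = np.array(
                [
                    max(
                        expected_mutant_payoff(
                            zk, i, dim, eq.p, params.game, params.habitats
                        ),
                        0.0,
                    )
                    for i in range(2)
                ]
            )
            B = eq.phi[:, None] * mmat * wbar[None, :]
            return np.log(np.max(np.linalg.eigvals(B).real))

        for k in range(2):
            fd = (
                block_loglam(dim.z[k] + h, k) - block_loglam(dim.z[k] - h, k)
            ) / (2 * h)
            assert g[k] == pytest.approx(eq.p_allele[k] * fd, abs=1e-6)

    def test_monomorphic_equilibrium_flagged(self):
        params = ModelParams.reference(m=0.2)
        res = selection_gradient(Dimorphism(0.1, 0.2), params)
        assert res.monomorphic is not None
        k = res.monomorphic
        assert np.isnan(res.g[1 - k]) and np.isfinite(res.g[k])


class TestReproductiveValues:
    def test_normalization(self, reference_params):
        params = reference_params.with_rho(0.2)
        dim = Dimorphism(0.2, 0.7)
        eq = find_resident_equilibrium(dim, params)
        v, V, u = reproductive_values(eq, dim, params)
        assert float((v * u).sum()) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_neutral_values_equal(self):
        """Equal group sizes and equal phenotypes: every class has the same
        reproductive value."""
        from genecue.core import DispersalConfig, GameParams, HabitatConfig

        params = ModelParams(
            game=GameParams(W=(0.5, 0.5), b=(3.0, 3.0), c=(1.5, 1.5)),
            habitats=HabitatConfig(N=(5, 5), capacity=(1000, 1000)),
            dispersal=DispersalConfig.symmetric(0.1, 0.25),
        )
        dim = Dimorphism(0.36, 0.36)
        eq = find_resident_equilibrium(dim, params)
        v, V, u = reproductive_values(eq, dim, params)
        assert np.allclose(v, v.flat[0], atol=1e-6)


class TestMonomorphicMachinery:
    def test_cue_invasion_neutral_resident(self, reference_params):
        assert cue_invasion_fitness(0.3, 0.3, reference_params) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_monomorphic_gradient_root_is_singular_strategy(
        self, reference_params
    ):
        # z* = b[(2N1-1)/N1^2 + (2N2-1)/N2^2]/(4c) for the symmetric game
        assert monomorphic_gradient(0.42375, reference_params) == pytest.approx(
            0.0, abs=1e-10
        )
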