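"""Payoff machinery: closed forms against hand values and exact enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genecue.core import (
    Dimorphism,
    GameParams,
    HabitatConfig,
    ModelParams,
    enumerate_class_payoff,
    enumerate_mutant_payoff,
    expected_mutant_payoff,
    liability_to_phenotype,
    payoff,
    payoff_derivative,
    relatedness,
    resident_class_payoff,
    size_biased_founder_copies,
)

GAME = GameParams(W=(0.5, 0.5), b=(3.0, 3.0), c=(1.5, 1.5))


def hab(N1, N2=None):
    N2 = N1 if N2 is None else N2
    return HabitatConfig(N=(N1, N2), capacity=(20 * N1, 20 * N2))


class TestRelatedness:
    @pytest.mark.parametrize(
        "N, expected", [(1, 1.0), (20, 0.05), (2, 0.5), (4, 0.25)]
    )
    def test_closed_form(self, N, expected):
        assert relatedness(N) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("bad", [0, -3, 2.5])
    def test_rejects_invalid_group_size(self, bad):
        with pytest.raises(ValueError):
            relatedness(bad)

    def test_monte_carlo_founding_process(self, rng):
        """Simulating the founding + asexual-copying process recovers
        r = 1/N: two random offspring group members share a founder with
        probability 1/N (checked within 3 standard errors)."""
        for N in (20, 2):
            groups = 30000
            counts = rng.multinomial(N, np.full(N, 1.0 / N), size=groups)
            # P(two distinct offspring share a founder) per group
            same = (counts * (counts - 1)).sum(axis=1) / (N * (N - 1))
            est, se = same.mean(), same.std(ddof=1) / np.sqrt(groups)
            assert abs(est - relatedness(N)) < 3 * se + 1e-12


class TestPayoff:
    @pytest.mark.parametrize(
        "z, zbar, expected",
        [(0.0, 0.0, 0.5), (0.75, 0.75, 1.90625), (1.0, 0.0, -1.0)],
    )
    def test_hand_values(self, z, zbar, expected):
        assert payoff(z, zbar, 0, GAME) == pytest.approx(expected, abs=1e-12)

    def test_habitat_index_checked(self):
        with pytest.raises(IndexError):
            payoff(0.2, 0.2, 2, GAME)


class TestExpectedMutantPayoff:
    def test_neutral_mutant_recovers_monomorphic_payoff(self):
        dim = Dimorphism(0.3, 0.3)
        p = np.array([[1.0, 0.0], [1.0, 0.0]])
        got = expected_mutant_payoff(0.3, 0, dim, p, GAME, hab(5))
        assert got == pytest.approx(payoff(0.3, 0.3, 0, GAME), abs=1e-14)

    def test_hand_value_n2(self):
        # z' = 0, N = 2, resident mix 0.75 -> 0.5 + 1.5*(0.5*0.75) = 1.0625
        dim = Dimorphism(0.75, 0.75)
        p = np.array([[0.5, 0.5], [0.5, 0.5]])
        got = expected_mutant_payoff(0.0, 0, dim, p, GAME, hab(2))
        assert got == pytest.approx(1.0625, abs=1e-12)

    def test_rejects_unnormalized_frequencies(self):
        dim = Dimorphism(0.2, 0.7)
        with pytest.raises(ValueError):
            expected_mutant_payoff(
                0.1, 0, dim, np.array([[0.5, 0.4], [0.5, 0.5]]), GAME, hab(2)
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        N=st.integers(1, 6),
        zp=st.floats(0, 1),
        z1=st.floats(0, 1),
        z2=st.floats(0, 1),
        p1=st.floats(0, 1),
    )
    def test_matches_enumeration_oracle(self, N, zp, z1, z2, p1):
        """Closed form equals the exact sum over founder draws, offspring
        copy-assignments and size-biased focal choice, for N in 1..6."""
        dim = Dimorphism(z1, z2)
        p = np.array([[p1, 1 - p1], [p1, 1 - p1]])
        closed = expected_mutant_payoff(zp, 0, dim, p, GAME, hab(N))
        exact = enumerate_mutant_payoff(zp, 0, dim, p, GAME, hab(N))
        assert closed == pytest.approx(exact, abs=1e-12)

    def test_enumeration_capped(self):
        dim = Dimorphism(0.2, 0.7)
        p = np.full((2, 2), 0.5)
        with pytest.raises(ValueError):
            enumerate_mutant_payoff(0.1, 0, dim, p, GAME, hab(9))


class TestResidentClassPayoff:
    def test_monomorphic_reduces_to_plain_payoff(self):
        dim = Dimorphism(0.4, 0.4)
        p = np.array([[0.6, 0.4], [0.6, 0.4]])
        got = resident_class_payoff(0, 0, dim, p, GAME, hab(7))
        assert got == pytest.approx(payoff(0.4, 0.4, 0, GAME), abs=1e-14)

    def test_hand_value(self):
        # N=2, z_k=0.75, ztilde=0.5: 0.5 + 3*(0.75*0.75 + 0.25*0.5) - 1.5*0.5625
        dim = Dimorphism(0.75, 0.25)
        p = np.full((2, 2), 0.5)
        got = resident_class_payoff(0, 0, dim, p, GAME, hab(2))
        assert got == pytest.approx(1.71875, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        N=st.integers(1, 6),
        z1=st.floats(0, 1),
        z2=st.floats(0, 1),
        p1=st.floats(0, 1),
        k=st.integers(0, 1),
    )
    def test_matches_enumeration_oracle(self, N, z1, z2, p1, k):
        dim = Dimorphism(z1, z2)
        p = np.array([[p1, 1 - p1], [p1, 1 - p1]])
        closed = resident_class_payoff(k, 0, dim, p, GAME, hab(N))
        exact = enumerate_class_payoff(k, 0, dim, p, GAME, hab(N))
        assert closed == pytest.approx(exact, abs=1e-12)


class TestPayoffDerivative:
    @pytest.mark.parametrize(
        "N, z, expected",
        [(2, 0.75, 0.0), (20, 0.0, 0.2925), (20, 0.0975, 0.0)],
    )
    def test_hand_values(self, N, z, expected):
        got = payoff_derivative(0, z, GAME, hab(N))
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("N", [1, 2, 5, 20])
    def test_matches_numerical_derivative_of_expected_payoff(self, N):
        """Central differences of the expected mutant payoff reproduce the
        analytical derivative to 1e-8."""
        dim = Dimorphism(0.3, 0.6)
        p = np.array([[0.7, 0.3], [0.2, 0.8]])
        h = 1e-5
        for zk in (0.1, 0.42, 0.8):
            fd = (
                expected_mutant_payoff(zk + h, 0, dim, p, GAME, hab(N))
                - expected_mutant_payoff(zk - h, 0, dim, p, GAME, hab(N))
            ) / (2 * h)
            assert payoff_derivative(0, zk, GAME, hab(N)) == pytest.approx(
                fd, abs=1e-8
            )


class TestSizeBiasedCopies:
    def test_binomial_identity_at_n20(self):
        # E[K^2]/E[K] for K ~ Binomial(20, 1/20) = 1 + 19 * 0.05 = 1.95
        assert size_biased_founder_copies(20) == pytest.approx(1.95, abs=1e-12)

    @pytest.mark.parametrize("N", [1, 2, 3, 10, 50])
    def test_equals_one_plus_relatedness_form(self, N):
        expected = 1 + (N - 1) * relatedness(N)
        assert size_biased_founder_copies(N) == pytest.approx(
            expected, abs=1e-10
        )


class TestSelfWeights:
    @pytest.mark.parametrize("N", [1, 2, 3, 7, 20])
    def test_mean_weights_sum_to_one(self, N):
        """The coefficients of own and others' phenotypes in the expected
        group mean sum to one exactly."""
        s = (2 * N - 1) / N**2
        assert s + (N - 1) ** 2 / N**2 == pytest.approx(1.0, abs=1e-15)
        assert 0 < s <= 1


class TestLiabilityMap:
    def test_midpoint_and_hand_value(self):
        assert liability_to_phenotype(0.0, 5.0, 0.0) == 0.5
        assert liability_to_phenotype(2.0, 0.0, 3.0) == pytest.approx(
            0.88079708, abs=1e-8
        )

    def test_saturates_without_overflow(self):
        assert liability_to_phenotype(1000.0, 0.0, 0.0) == 1.0
        assert liability_to_phenotype(-1000.0, 0.0, 0.0) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a0=st.floats(-20, 20),
        ag=st.floats(-10, 10),
        x=st.floats(-2, 2),
        da=st.floats(1e-6, 5),
    )
    def test_strictly_monotone_in_liability(self, a0, ag, x, da):
        lo = liability_to_phenotype(a0, ag, x)
        hi = liability_to_phenotype(a0 + da, ag, x)
        assert hi > lo


class TestParameterContainers:
    def test_game_invariants(self):
        with pytest.raises(ValueError):
            GameParams(W=(0.5, 0.5), b=(-1.0, 3.0), c=(1.5, 1.5))
        with pytest.raises(ValueError):
            GameParams(W=(0.5, 0.5), b=(3.0, 3.0), c=(0.0, 1.5))

    def test_habitat_requires_whole_groups(self):
        with pytest.raises(ValueError):
            HabitatConfig(N=(20, 2), capacity=(2010, 2000))
        assert HabitatConfig(N=(20, 2), capacity=(2000, 2000)).r == (0.05, 0.5)

    def test_dispersal_matrix_columns_sum_to_one(self, reference_params):
        m = reference_params.dispersal.matrix
        assert np.allclose(m.sum(axis=0), 1.0)

    def test_dimorphism_bounds(self):
        with pytest.raises(ValueError):
            Dimorphism(-0.1, 0.5)

    def test_reference_set(self):
        p = ModelParams.reference()
        assert p.habitats.N == (20, 2)
        assert p.game.W == (0.5, 0.5)
        assert p.game.b == (3.0, 3.0)
        assert p.game.c == (1.5, 1.5)
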