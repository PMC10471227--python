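"""Deterministic recursion operators and mutation-selection balance."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import phenoswitch as ps
from conftest import random_distribution


def _neutral_bitstring(L: int = 2) -> ps.BitstringLandscape:
    return ps.BitstringLandscape(L=L, fitness=np.ones(2 ** L), wild_type=0)


class TestSwitching:
    def test_zero_rates_identity(self, rng, pre_motif):
        dist = random_distribution(rng, pre_motif.n_genotypes)
        out = ps.apply_switching(dist, ps.SwitchingRates(0.0, 0.0))
        assert np.array_equal(out.freqs, dist.freqs)

    def test_direct_substitution(self, pre_motif):
        dist = ps.PhenoGenotypeDistribution.delta(pre_motif)
        out = ps.apply_switching(dist, ps.SwitchingRates(0.21, 0.63))
        wt = pre_motif.wild_type_index
        assert out.freqs[0, wt] == pytest.approx(0.79)
        assert out.freqs[1, wt] == pytest.approx(0.21)

    @given(g1=st.floats(0, 1), g2=st.floats(0, 1), seed=st.integers(0, 100))
    def test_genotype_marginals_conserved(self, g1, g2, seed):
        rng = np.random.default_rng(seed)
        dist = random_distribution(rng, 12)
        out = ps.apply_switching(dist, ps.SwitchingRates(g1, g2))
        np.testing.assert_allclose(
            out.genotype_marginal(), dist.genotype_marginal(), atol=1e-15
        )
        assert out.freqs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_stationary_mix_is_fixed_point(self, rng):
        """A distribution with p_M = g1/(g1+g2) uniformly across genotypes is
        invariant under switching (verified by iterating to convergence)."""
        g1, g2 = 0.3, 0.1
        rates = ps.SwitchingRates(g1, g2)
        profile = rng.random(8)
        profile /= profile.sum()
        f = np.vstack([(g2 / (g1 + g2)) * profile, (g1 / (g1 + g2)) * profile])
        dist = ps.PhenoGenotypeDistribution(f)
        for _ in range(100):
            dist = ps.apply_switching(dist, rates)
        np.testing.assert_allclose(dist.freqs, f, atol=1e-14)


class TestMutationKernel:
    def test_zero_rate_identity(self, pre_motif):
        params = ps.MutationParams(U=0.0, tau=100, n=5000, s=0.1)
        kern = ps.build_mutation_kernel(params, pre_motif)
        assert np.array_equal(kern.u, np.eye(pre_motif.n_genotypes))
        assert np.array_equal(kern.u_tilde, np.eye(pre_motif.n_genotypes))

    def test_poisson_terms(self, baseline_kernel, pre_motif):
        """Background single-step probability is e^{-U} U (times the
        no-environment-mutation factor) for non-mutators; the mutator's
        no-mutation probability carries e^{-tau U}."""
        U, tau, mu = 4e-5, 100, 4e-5 / 5000
        i = pre_motif.index(ps.SimpleGenotype(0, 0))
        j = pre_motif.index(ps.SimpleGenotype(0, 1))
        assert baseline_kernel.u[i, j] == pytest.approx(
            np.exp(-U) * U * (1 - mu) ** 2, rel=1e-12
        )
        assert baseline_kernel.u_tilde[i, i] == pytest.approx(
            np.exp(-tau * U) * (1 - tau * mu) ** 2, rel=1e-12
        )
        # e^{-0.004} ~ 0.996008 for the mutator's background factor alone
        assert np.exp(-tau * U) == pytest.approx(0.996008, abs=5e-7)

    def test_rows_stochastic_no_back_mutation(self, baseline_kernel, pre_motif):
        for mat in (baseline_kernel.u, baseline_kernel.u_tilde):
            np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-12)
        # no back mutation: zero probability of losing mutations
        for i, gi in enumerate(pre_motif.genotypes()):
            for j, gj in enumerate(pre_motif.genotypes()):
                if gj.a < gi.a or gj.b < gi.b:
                    assert baseline_kernel.u[i, j] == 0.0

    def test_excess_rate_rejected(self, pre_motif):
        params = ps.MutationParams(U=0.9, tau=100, n=5, s=0.1)
        with pytest.raises(ps.ParameterError, match="per-locus"):
            ps.build_mutation_kernel(params, pre_motif)

    def test_bitstring_kernel_flip_probabilities(self):
        land = _neutral_bitstring(3)
        params = ps.MutationParams(U=0.01, tau=10, n=5000, s=0.1)
        kern = ps.build_mutation_kernel(params, land)
        # per-locus rate defaults to U on bitstring landscapes
        assert kern.u[0, 0] == pytest.approx(0.99 ** 3)
        assert kern.u[0, 1] == pytest.approx(0.01 * 0.99 ** 2)
        assert kern.u_tilde[0, 7] == pytest.approx(0.1 ** 3)
        override = ps.build_mutation_kernel(params, land, per_locus_rate=1e-4)
        assert override.u[0, 1] == pytest.approx(1e-4 * (1 - 1e-4) ** 2)


class TestMutationStep:
    def test_identity_kernel(self, rng):
        dist = random_distribution(rng, 5)
        kern = ps.MutationKernel(u=np.eye(5), u_tilde=np.eye(5))
        out = ps.apply_mutation(dist, kern)
        assert np.array_equal(out.freqs, dist.freqs)

    def test_single_step_from_wild_type(self, baseline_kernel, pre_motif):
        """One generation of mutation moves e^{-U} U (1-mu)^A of the
        wild-type mass to the single-background-mutant class."""
        U, mu = 4e-5, 4e-5 / 5000
        dist = ps.PhenoGenotypeDistribution.delta(pre_motif)
        out = ps.apply_mutation(dist, baseline_kernel)
        j = pre_motif.index(ps.SimpleGenotype(0, 1))
        assert out.freqs[0, j] == pytest.approx(np.exp(-U) * U * (1 - mu) ** 2,
                                                rel=1e-12)

    @given(seed=st.integers(0, 50))
    def test_mass_conserved(self, baseline_kernel, seed):
        rng = np.random.default_rng(seed)
        dist = random_distribution(rng, baseline_kernel.n_genotypes)
        out = ps.apply_mutation(dist, baseline_kernel)
        assert out.freqs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out.freqs >= 0)

    def test_dimension_mismatch(self, baseline_kernel):
        dist = ps.PhenoGenotypeDistribution(np.full((2, 3), 1 / 6))
        with pytest.raises(ps.StructuralError):
            ps.apply_mutation(dist, baseline_kernel)


class TestSelection:
    def test_flat_fitness_identity(self, rng):
        land = _neutral_bitstring(3)
        dist = random_distribution(rng, 8)
        out, wbar = ps.apply_selection(dist, land)
        np.testing.assert_allclose(out.freqs, dist.freqs, atol=1e-15)
        assert wbar == pytest.approx(1.0)

    def test_two_genotype_hand_value(self):
        land = ps.BitstringLandscape(L=1, fitness=np.array([1.0, 0.9]),
                                     wild_type=0)
        dist = ps.PhenoGenotypeDistribution(np.array([[0.5, 0.5], [0.0, 0.0]]))
        out, wbar = ps.apply_selection(dist, land)
        assert wbar == pytest.approx(0.95)
        assert out.freqs[0, 0] == pytest.approx(10 / 19)
        assert out.freqs[0, 1] == pytest.approx(9 / 19)

    def test_zero_class_stays_zero(self, rng, post_valley):
        dist = random_distribution(rng, post_valley.n_genotypes)
        dist.freqs[1, 5] = 0.0
        dist = ps.PhenoGenotypeDistribution(dist.freqs / dist.freqs.sum())
        out, _ = ps.apply_selection(dist, post_valley)
        assert out.freqs[1, 5] == 0.0


class TestGenerationStep:
    def test_identity_when_all_processes_off(self):
        land = _neutral_bitstring(2)
        params = ps.MutationParams(U=0.0, tau=1, n=4, s=0.1)
        kern = ps.build_mutation_kernel(params, land)
        rates = ps.SwitchingRates(0.0, 0.0)
        f = np.array([[0.4, 0.1, 0.05, 0.05], [0.2, 0.1, 0.05, 0.05]])
        dist = ps.PhenoGenotypeDistribution(f)
        out, wbar = ps.generation_step(dist, rates, kern, land)
        np.testing.assert_allclose(out.freqs, f, atol=1e-15)
        assert wbar == pytest.approx(1.0)

    def test_matches_sequential_operators(self, baseline_kernel, pre_motif):
        rates = ps.SwitchingRates(0.01, 0.002)
        dist = ps.PhenoGenotypeDistribution.delta(pre_motif)
        one, wbar = ps.generation_step(dist, rates, baseline_kernel, pre_motif)
        manual = ps.apply_switching(dist, rates)
        manual = ps.apply_mutation(manual, baseline_kernel)
        manual, wbar2 = ps.apply_selection(manual, pre_motif)
        np.testing.assert_allclose(one.freqs, manual.freqs, atol=1e-15)
        assert wbar == pytest.approx(wbar2)

    def test_no_hidden_state_over_ten_steps(self, baseline_kernel, pre_motif):
        """Ten composed steps equal an independently coded ten-step loop
        written directly from the update formulas."""
        rates = ps.SwitchingRates(1e-3, 1e-3)
        g1, g2 = rates.gamma1, rates.gamma2
        w = pre_motif.fitness_vector()
        fm = np.zeros(pre_motif.n_genotypes)
        fM = np.zeros(pre_motif.n_genotypes)
        fm[pre_motif.wild_type_index] = 1.0
        for _ in range(10):
            fpm = (1 - g1) * fm + g2 * fM
            fpM = g1 * fm + (1 - g2) * fM
            fppm = baseline_kernel.u.T @ fpm
            fppM = baseline_kernel.u_tilde.T @ fpM
            wbar = w @ (fppm + fppM)
            fm, fM = w * fppm / wbar, w * fppM / wbar
            total = fm.sum() + fM.sum()
            fm, fM = fm / total, fM / total
        dist = ps.PhenoGenotypeDistribution.delta(pre_motif)
        for _ in range(10):
            dist, _ = ps.generation_step(dist, rates, baseline_kernel, pre_motif)
        np.testing.assert_allclose(dist.freqs, np.vstack([fm, fM]), atol=1e-13)


class TestMSB:
    def test_neutral_landscape_matches_switching_chain(self):
        land = _neutral_bitstring(2)
        params = ps.MutationParams(U=4e-5, tau=100, n=5000, s=0.1)
        kern = ps.build_mutation_kernel(params, land)
        for g1, g2 in [(0.3, 0.7), (0.05, 0.01)]:
            res = ps.solve_msb_eigen(ps.SwitchingRates(g1, g2), kern, land)
            assert res.p_M == pytest.approx(g1 / (g1 + g2), abs=1e-12)

    def test_no_switching_keeps_population_non_mutator(self, baseline_kernel,
                                                       pre_motif):
        res = ps.solve_msb_iterate(ps.SwitchingRates(0.0, 0.0), baseline_kernel,
                                   pre_motif)
        assert res.converged
        assert res.p_M == 0.0
        # classical one-phenotype balance: mean fitness ~ e^{-U} (load U)
        assert res.w_bar == pytest.approx(np.exp(-4e-5), abs=1e-6)

    def test_iterate_matches_eigen(self, baseline_kernel, pre_motif):
        rates = ps.SwitchingRates(1e-3, 1e-3)
        it = ps.solve_msb_iterate(rates, baseline_kernel, pre_motif)
        eg = ps.solve_msb_eigen(rates, baseline_kernel, pre_motif)
        assert it.converged
        assert it.distribution.l1_distance(eg.distribution) < 1e-8
        assert eg.w_bar == pytest.approx(it.w_bar, abs=1e-10)

    def test_pM_nondecreasing_in_gamma1(self, baseline_kernel, pre_motif):
        pMs = [
            ps.solve_msb_eigen(ps.SwitchingRates(g1, 1e-3), baseline_kernel,
                               pre_motif).p_M
            for g1 in (1e-5, 1e-4, 1e-3, 1e-2, 1e-1)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(pMs, pMs[1:]))

    def test_nonconvergence_flagged_not_raised(self, baseline_kernel, pre_motif):
        res = ps.solve_msb_iterate(ps.SwitchingRates(1e-4, 1e-4),
                                   baseline_kernel, pre_motif, max_iter=5)
        assert not res.converged
        assert res.iterations == 5

    def test_msb_result_serializes(self, baseline_kernel, pre_motif):
        res = ps.solve_msb_eigen(ps.SwitchingRates(1e-3, 1e-3), baseline_kernel,
                                 pre_motif)
        d = res.to_dict()
        assert d["p_M"] == res.p_M
        assert d["frequencies"]["m"]["0\\0"] == res.distribution.freqs[0, 0]
        total = sum(sum(v.values()) for v in d["frequencies"].values())
        assert total == pytest.approx(1.0, abs=1e-9)


class TestInvariants:
    @given(
        g1=st.floats(1e-6, 0.5), g2=st.floats(1e-6, 0.5),
        seed=st.integers(0, 20),
    )
    def test_generation_preserves_mass_and_positivity(
        self, baseline_kernel, pre_motif, g1, g2, seed
    ):
        rng = np.random.default_rng(seed)
        dist = random_distribution(rng, pre_motif.n_genotypes)
        out, _ = ps.generation_step(dist, ps.SwitchingRates(g1, g2),
                                    baseline_kernel, pre_motif)
        assert out.freqs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out.freqs >= 0)

    def test_flat_landscape_attractor_is_switching_stationary(self):
        """With flat fitness and no mutation the unique attractor is the
        switching chain's stationary distribution."""
        land = _neutral_bitstring(2)
        params = ps.MutationParams(U=0.0, tau=1, n=4, s=0.1)
        kern = ps.build_mutation_kernel(params, land)
        rates = ps.SwitchingRates(0.4, 0.2)
        rng = np.random.default_rng(5)
        dist = random_distribution(rng, 4)
        for _ in range(2000):
            dist, _ = ps.generation_step(dist, rates, kern, land)
        assert dist.p_M == pytest.approx(0.4 / 0.6, abs=1e-12)
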