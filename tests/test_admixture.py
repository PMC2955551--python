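"""Gibbs sampler updates against closed forms, plus full-run behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import aimpanel as ap
from aimpanel.admixture import AdmixtureState, EncodedGenotypes, _assignment_counts


def encoded(calls, ids=None, names=None, missing=-9):
    ids = ids or [f"i{n}" for n in range(len(calls))]
    names = names or [f"L{j}" for j in range(np.asarray(calls).shape[1])]
    g = ap.GenotypeMatrix.from_calls(ids, names, np.asarray(calls), missing)
    return EncodedGenotypes.from_matrix(g)


def fresh_state(K, data, q=None, p=None, alpha=None):
    N, L, a_max = data.n_individuals, data.n_loci, data.a_max
    return AdmixtureState(
        z=np.zeros((N, L, 2), dtype=np.int64),
        p=np.full((K, L, a_max), 1.0 / a_max) if p is None else np.asarray(p, float),
        q=np.full((N, K), 1.0 / K) if q is None else np.asarray(q, float),
        alpha=np.ones(K) if alpha is None else np.asarray(alpha, float),
    )


class TestUpdateZ:
    def test_k1_everything_assigned_to_the_only_cluster(self):
        data = encoded([[[120, 122]], [[120, 120]]])
        state = fresh_state(1, data)
        ap.update_z(state, data, np.random.default_rng(0))
        assert np.all(state.z == 0)

    def test_exclusive_allele_forces_assignment(self):
        data = encoded([[[120, 120]]])
        p = np.array([[[1.0, 0.0]], [[0.0, 1.0]]])  # allele 120 only in cluster 1
        state = fresh_state(2, data, q=[[0.5, 0.5]], p=p)
        ap.update_z(state, data, np.random.default_rng(1))
        assert np.all(state.z == 0)

    def test_assignment_rate_matches_posterior(self):
        # single copy per individual-locus setup replicated over many
        # individuals: q = (.5, .5), p1 = .8, p2 = .2 for the observed
        # allele => P(cluster 1) = 0.8
        n = 100_000
        data = encoded([[[120, 120]]] * n, ids=[f"i{j}" for j in range(n)])
        p = np.array([[[0.8, 0.2]], [[0.2, 0.8]]])
        state = fresh_state(2, data, q=np.full((n, 2), 0.5), p=p)
        ap.update_z(state, data, np.random.default_rng(2))
        # 0.8*0.5 / (0.8*0.5 + 0.2*0.5) = 0.8
        rate = (state.z == 0).mean()
        assert rate == pytest.approx(0.8, abs=0.01)


class TestUpdateP:
    def test_prior_draw_when_cluster_empty(self):
        data = encoded([[[120, 122]]])
        rng = np.random.default_rng(3)
        means = np.zeros(2)
        n = 4000
        for _ in range(n):
            state = fresh_state(2, data)
            state.z[:] = 0  # cluster 2 gets nothing
            ap.update_p(state, data, rng, lam=1.0)
            means += state.p[1, 0]
        means /= n
        assert means == pytest.approx([0.5, 0.5], abs=0.03)

    def test_posterior_mean_matches_dirichlet(self):
        # counts (8, 0) with lambda = 1 => mean (9/10, 1/10)
        calls = [[[120, 120]], [[120, 120]], [[120, 120]], [[120, 122]]]
        data = encoded(calls)
        # make allele 122 appear once so the locus has 2 alleles; assign
        # all 8 copies of the first 4 individuals... use first 3 inds
        # (6 copies of 120) plus the het ind (120,122) -> fix z so that
        # cluster 0 sees exactly the 8 copies of allele 120
        rng = np.random.default_rng(4)
        means = np.zeros(2)
        n = 4000
        for _ in range(n):
            state = fresh_state(1, data)
            state.z[:] = 0
            # drop the het individual's 122 copy from the tally by masking
            data2 = EncodedGenotypes(
                data.alleles, data.valid.copy(), data.a_l,
                data.locus_names, data.individuals,
            )
            data2.valid[3, 0] = False
            ap.update_p(state, data2, rng, lam=1.0)
            means += state.p[0, 0]
        means /= n
        # 6 copies of allele 120 among the unmasked: mean = (1+6)/(2+6)
        assert means == pytest.approx([7 / 8, 1 / 8], abs=0.02)

    def test_simplex_constraint_every_draw(self):
        data = encoded([[[120, 122], [140, 144]]])
        rng = np.random.default_rng(5)
        state = fresh_state(3, data)
        for _ in range(50):
            ap.update_z(state, data, rng)
            ap.update_p(state, data, rng, lam=0.3)
            assert np.allclose(state.p.sum(axis=2), 1.0)


class TestUpdateQ:
    def test_posterior_mean_single_locus(self):
        # both copies in cluster 1, K = 2, alpha = (1, 1): mean q1 = 3/4
        data = encoded([[[120, 122]]])
        rng = np.random.default_rng(6)
        total = 0.0
        n = 6000
        for _ in range(n):
            state = fresh_state(2, data)
            state.z[:] = 0
            ap.update_q(state, data, rng)
            total += state.q[0, 0]
        assert total / n == pytest.approx(0.75, abs=0.01)

    def test_all_missing_draws_from_prior(self):
        data = EncodedGenotypes(
            alleles=np.zeros((1, 1, 2), dtype=np.int64),
            valid=np.zeros((1, 1), dtype=bool),
            a_l=np.array([2]),
            locus_names=["L0"],
            individuals=["i0"],
        )
        rng = np.random.default_rng(7)
        total = np.zeros(2)
        n = 6000
        for _ in range(n):
            state = fresh_state(2, data, alpha=[3.0, 1.0])
            ap.update_q(state, data, rng)
            total += state.q[0]
        assert total / n == pytest.approx([0.75, 0.25], abs=0.02)

    def test_rows_sum_to_one_every_draw(self):
        data = encoded([[[120, 122]], [[122, 122]]])
        rng = np.random.default_rng(8)
        state = fresh_state(4, data)
        for _ in range(50):
            ap.update_z(state, data, rng)
            ap.update_q(state, data, rng)
            assert np.allclose(state.q.sum(axis=1), 1.0)


class TestUpdateAlpha:
    @staticmethod
    def oracle_alpha(q, alpha0, seed, sd=0.1, alpha_max=10.0):
        """Mirror of the Metropolis schedule using direct Dirichlet
        density-ratio evaluation."""
        rng = np.random.default_rng(seed)
        alpha = np.asarray(alpha0, float).copy()
        n = q.shape[0]
        logq = np.log(q).sum(axis=0)
        for k in range(alpha.size):
            prop = alpha[k] + rng.normal(0.0, sd)
            u = rng.random()
            if prop <= 0 or prop > alpha_max:
                continue
            new = alpha.copy()
            new[k] = prop

            def logdens(a):
                return n * (gammaln(a.sum()) - gammaln(a).sum()) + ((a - 1) * logq).sum()

            if np.log(u) < logdens(new) - logdens(alpha):
                alpha = new
        return alpha

    def test_matches_independent_density_ratio(self):
        q = np.array([[0.7, 0.3], [0.4, 0.6]])
        for seed in range(20):
            state = AdmixtureState(
                z=np.zeros((2, 1, 2), int), p=np.zeros((2, 1, 1)),
                q=q.copy(), alpha=np.array([1.0, 1.0]),
            )
            ap.update_alpha(state, np.random.default_rng(seed), proposal_sd=0.1)
            expected = self.oracle_alpha(q, [1.0, 1.0], seed)
            assert state.alpha == pytest.approx(expected)

    def test_shared_alpha_stays_uniform_across_clusters(self):
        q = np.random.default_rng(9).dirichlet(np.ones(3), size=10)
        state = AdmixtureState(
            z=np.zeros((10, 1, 2), int), p=np.zeros((3, 1, 1)),
            q=q, alpha=np.ones(3),
        )
        for seed in range(10):
            ap.update_alpha(state, np.random.default_rng(seed),
                            proposal_sd=0.5, separate=False)
            assert len(set(state.alpha.tolist())) == 1

    def test_out_of_range_proposal_rejected_without_error(self):
        state = AdmixtureState(
            z=np.zeros((1, 1, 2), int), p=np.zeros((1, 1, 1)),
            q=np.ones((1, 1)), alpha=np.array([9.999]),
        )
        # enormous sd: proposals fly out of (0, 10] and must be ignored
        ap.update_alpha(state, np.random.default_rng(0), proposal_sd=1e6)
        assert state.alpha[0] == 9.999


class TestLogLikelihood:
    def test_k1_equals_multinomial_logprob(self):
        calls = [[[120, 122], [140, 140]], [[120, 120], [144, 140]]]
        data = encoded(calls)
        # pooled frequencies: L0 has 3x120, 1x122; L1 has 3x140, 1x144
        p = np.array([[[0.75, 0.25], [0.75, 0.25]]])
        state = fresh_state(1, data, p=p)
        expected = 3 * np.log(0.75) + np.log(0.25) + 3 * np.log(0.75) + np.log(0.25)
        assert ap.log_likelihood(state, data) == pytest.approx(expected)

    def test_certain_locus_adds_zero(self):
        data1 = encoded([[[120, 122]]])
        p1 = np.array([[[0.6, 0.4]]])
        s1 = fresh_state(1, data1, p=p1)
        data2 = encoded([[[120, 122], [140, 140]]])
        p2 = np.zeros((1, 2, 2))
        p2[0, 0] = [0.6, 0.4]
        p2[0, 1] = [1.0, 0.0]
        s2 = fresh_state(1, data2, p=p2)
        assert ap.log_likelihood(s2, data2) == pytest.approx(
            ap.log_likelihood(s1, data1)
        )

    def test_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(10)
        calls = 100 + 2 * rng.integers(0, 4, size=(6, 5, 2))
        data = encoded(calls)
        q = rng.dirichlet(np.ones(3), size=6)
        p = rng.dirichlet(np.ones(data.a_max), size=(3, 5))
        state = fresh_state(3, data, q=q, p=p)
        base = ap.log_likelihood(state, data)
        perm = [2, 0, 1]
        state2 = fresh_state(3, data, q=q[:, perm], p=p[perm])
        assert ap.log_likelihood(state2, data) == pytest.approx(base)


class TestRunMcmc:
    def test_k1_gives_unit_q(self, sim_three_pops):
        cfg = ap.AdmixtureConfig(k=1, burn_in=5, iterations=5, seed=0)
        run = ap.run_mcmc(sim_three_pops.genotypes, cfg)
        assert np.allclose(run.q_mean, 1.0)

    def test_same_seed_bit_identical(self, sim_three_pops):
        cfg = ap.AdmixtureConfig(k=3, burn_in=20, iterations=20, seed=42)
        a = ap.run_mcmc(sim_three_pops.genotypes, cfg)
        b = ap.run_mcmc(sim_three_pops.genotypes, cfg)
        assert np.array_equal(a.q_mean, b.q_mean)
        assert np.array_equal(a.p_mean, b.p_mean)
        assert a.ln_prob == b.ln_prob

    def test_posterior_means_live_on_the_simplex(self, sim_three_pops):
        cfg = ap.AdmixtureConfig(k=3, burn_in=30, iterations=30, seed=1)
        run = ap.run_mcmc(sim_three_pops.genotypes, cfg)
        assert np.allclose(run.q_mean.sum(axis=1), 1.0)
        valid = run.p_mean.sum(axis=2)
        assert np.allclose(valid, 1.0)
        assert run.ln_prob <= run.loglik_mean

    def test_k_exceeding_gene_copies_rejected(self):
        data = encoded([[[120, 122]]])
        with pytest.raises(ap.AdmixtureError, match="gene copies"):
            ap.run_mcmc(
                ap.GenotypeMatrix.from_calls(["a"], ["L0"], np.array([[[120, 122]]])),
                ap.AdmixtureConfig(k=5, burn_in=2, iterations=2),
            )

    def test_q_rmse_shrinks_with_more_loci(self):
        rmses = []
        for L in (12, 36, 72):
            cfg = ap.SimulationConfig(
                k_true=3, n_loci=L, n_alleles=10, F=0.3, n_ref=25,
                cohorts=(ap.Cohort("adm", 15, alpha=(1.0, 1.0, 1.0)),), seed=6,
            )
            sim = ap.simulate_dataset(cfg)
            run = ap.run_mcmc(
                sim.genotypes,
                ap.AdmixtureConfig(k=3, burn_in=300, iterations=300, seed=7),
            )
            perm = ap.best_permutation(sim.Q_true, run.q_mean)
            rmse = np.sqrt(((run.q_mean[:, perm] - sim.Q_true) ** 2).mean())
            rmses.append(rmse)
        assert rmses[0] > rmses[1] > rmses[2]


class TestReferenceLabeling:
    def test_one_hot_references_label_bijectively(self):
        q = pd.DataFrame(
            np.eye(3)[[0, 0, 1, 1, 2, 2]],
            index=[f"s{i}" for i in range(6)],
            columns=["cluster1", "cluster2", "cluster3"],
        )
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "population_label": ["AF", "AF", "EU", "EU", "EA", "EA"],
                "declared_group": [None] * 6,
                "role": ["reference"] * 6,
            }
        )
        lab = ap.label_clusters_by_reference(q, meta)
        assert sorted(lab.labels) == ["AF", "EA", "EU"]
        assert not any(lab.tied)

    def test_tie_breaks_lexicographically_and_flags(self):
        q = pd.DataFrame(
            [[1.0, 0.0], [1.0, 0.0]],
            index=["s0", "s1"], columns=["cluster1", "cluster2"],
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["s0", "s1"],
                "population_label": ["ZZ", "AA"],
                "declared_group": [None, None],
                "role": ["reference", "reference"],
            }
        )
        lab = ap.label_clusters_by_reference(q, meta)
        assert lab.labels[0] == "AA"
        assert lab.tied[0]

    def test_no_references_is_an_error(self):
        q = pd.DataFrame([[1.0]], index=["s0"], columns=["cluster1"])
        meta = pd.DataFrame(
            {
                "sample_id": ["s0"], "population_label": [None],
                "declared_group": ["x"], "role": ["query"],
            }
        )
        with pytest.raises(ap.AdmixtureError, match="reference"):
            ap.label_clusters_by_reference(q, meta)

    def test_simulated_references_recover_group_identities(self, sim_three_pops):
        run = ap.run_mcmc(
            sim_three_pops.genotypes,
            ap.AdmixtureConfig(k=3, burn_in=200, iterations=200, seed=3),
        )
        lab = ap.label_clusters_by_reference(run.q_frame(), sim_three_pops.metadata)
        assert sorted(lab.labels) == ["pop1", "pop2", "pop3"]
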