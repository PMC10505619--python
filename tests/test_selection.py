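import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from oracles import bh_stepup

from adaptscan.codons import CODON_INDEX, N_CODONS, PAIR_I, PAIR_IS_SYNONYMOUS, PAIR_J
from adaptscan.io_formats import Alignment, SeqRecord
from adaptscan.selection import (
    CodonLikelihood,
    CodonModelParams,
    beb_posteriors,
    branch_site_test,
    codon_rate_matrix,
    f3x4_frequencies,
    fdr_bh,
    fit_branch_site,
    fit_m0,
    lrt_pvalue,
    substitution_rate,
    transition_matrix,
)
from adaptscan.synthetic_data import simulate_codon_alignment, simulate_tree


def uniform_pi():
    return np.full(N_CODONS, 1.0 / N_CODONS)


def random_pi(rng):
    pi = rng.dirichlet(np.ones(N_CODONS) * 5)
    return pi / pi.sum()


class TestRateMatrix:
    def test_omega_zero_kills_nonsynonymous_entries(self):
        Q = codon_rate_matrix(2.0, 0.0, uniform_pi())
        nonsyn = ~PAIR_IS_SYNONYMOUS
        assert np.all(Q[PAIR_I[nonsyn], PAIR_J[nonsyn]] == 0)
        syn = PAIR_IS_SYNONYMOUS
        assert np.all(Q[PAIR_I[syn], PAIR_J[syn]] > 0)

    def test_rows_sum_to_zero_and_reversibility(self, rng):
        for _ in range(10):
            pi = random_pi(rng)
            kappa = float(rng.uniform(0.5, 10))
            omega = float(rng.uniform(0.01, 5))
            Q = codon_rate_matrix(kappa, omega, pi)
            assert np.abs(Q.sum(axis=1)).max() < 1e-12
            flux = pi[:, None] * Q
            assert np.abs(flux - flux.T).max() < 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            codon_rate_matrix(-1.0, 0.5, uniform_pi())
        with pytest.raises(ValueError):
            codon_rate_matrix(2.0, 0.5, np.zeros(N_CODONS))


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        Q = codon_rate_matrix(2.0, 0.5, uniform_pi())
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(N_CODONS))

    def test_semigroup_property(self):
        Q = codon_rate_matrix(3.0, 0.2, uniform_pi())
        P1, P2, P3 = (transition_matrix(Q, t) for t in (0.3, 0.5, 0.8))
        assert np.abs(P1 @ P2 - P3).max() < 1e-8

    def test_rows_sum_to_one(self):
        Q = codon_rate_matrix(2.0, 1.5, uniform_pi())
        P = transition_matrix(Q, 2.0)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
        assert P.min() >= 0

    def test_small_time_taylor_expansion(self):
        Q = codon_rate_matrix(2.0, 0.5, uniform_pi())
        t = 1e-4
        assert np.abs(transition_matrix(Q, t) - (np.eye(N_CODONS) + Q * t)).max() < 5e-8

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(codon_rate_matrix(2, 1, uniform_pi()), -0.1)


class TestLikelihood:
    def two_taxon_setup(self, codon_a="ATG", codon_b="AAA", t1=0.2, t2=0.3):
        from adaptscan.io_formats import read_newick

        tree = read_newick(f"(A:{t1},B:{t2});")
        aln = Alignment(
            [SeqRecord("A", codon_a), SeqRecord("B", codon_b)], "codon"
        )
        return tree, aln

    def test_two_taxon_closed_form(self):
        tree, aln = self.two_taxon_setup()
        eng = CodonLikelihood(aln, tree)
        kappa, omega = 2.0, 0.4
        got = eng.loglik_m0(kappa, omega)
        pi = eng.pi
        Q = codon_rate_matrix(kappa, omega, pi)
        Q /= substitution_rate(Q, pi)
        # reversibility: lnL = log sum_i pi_i P(t1)_{i,a} P(t2)_{i,b}
        P1, P2 = expm(Q * 0.2), expm(Q * 0.3)
        ia, ib = CODON_INDEX["ATG"], CODON_INDEX["AAA"]
        want = np.log((pi * P1[:, ia] * P2[:, ib]).sum())
        assert got == pytest.approx(float(want), rel=1e-10)

    def test_duplicating_columns_doubles_loglik(self):
        tree = simulate_tree(5, seed=4, focal="FOCAL")
        params = CodonModelParams(2.0, 0.3, 2.0, 0.6, 0.3)
        aln, _ = simulate_codon_alignment(tree, params, 20, seed=8, foreground="FOCAL")
        doubled = Alignment(
            [SeqRecord(r.id, r.seq * 2) for r in aln.records], "codon"
        )
        e1 = CodonLikelihood(aln, tree, foreground="FOCAL")
        e2 = CodonLikelihood(doubled, tree, foreground="FOCAL", pi=e1.pi)
        assert e2.loglik_branch_site(params) == pytest.approx(
            2 * e1.loglik_branch_site(params), rel=1e-12
        )

    def test_tip_order_permutation_invariance(self, rng):
        tree = simulate_tree(6, seed=5, focal="FOCAL")
        params = CodonModelParams(2.0, 0.2, 3.0, 0.7, 0.2)
        aln, _ = simulate_codon_alignment(tree, params, 30, seed=9, foreground="FOCAL")
        perm = Alignment(list(rng.permutation(aln.records)), "codon")
        e1 = CodonLikelihood(aln, tree, foreground="FOCAL")
        e2 = CodonLikelihood(perm, tree, foreground="FOCAL", pi=e1.pi)
        assert e2.loglik_branch_site(params) == pytest.approx(
            e1.loglik_branch_site(params), rel=1e-12
        )

    def test_f3x4_is_a_distribution_reflecting_composition(self):
        aln = Alignment(
            [SeqRecord("A", "ATGATGATG"), SeqRecord("B", "ATGATGATG")], "codon"
        )
        pi = f3x4_frequencies(aln)
        assert pi.sum() == pytest.approx(1.0)
        assert pi.min() > 0
        assert pi[CODON_INDEX["ATG"]] == pi.max()


class TestFitting:
    def test_alternative_never_below_null(self):
        tree = simulate_tree(5, seed=21, focal="FOCAL", mean_branch=0.2)
        aln, _ = simulate_codon_alignment(
            tree, CodonModelParams(2.0, 0.2, 1.0, 0.7, 0.2), 60, seed=3,
            foreground="FOCAL",
        )
        fit = branch_site_test(aln, tree, "FOCAL", n_starts=1, seed=0)
        assert fit.lnL_alt >= fit.lnL_null - 1e-6
        assert 0 <= fit.pvalue <= 1

    def test_refit_is_deterministic(self):
        tree = simulate_tree(5, seed=22, focal="FOCAL", mean_branch=0.2)
        aln, _ = simulate_codon_alignment(
            tree, CodonModelParams(2.0, 0.2, 4.0, 0.7, 0.2), 50, seed=4,
            foreground="FOCAL",
        )
        runs = [branch_site_test(aln, tree, "FOCAL", n_starts=2, seed=7) for _ in range(2)]
        assert runs[0].lnL_alt == pytest.approx(runs[1].lnL_alt, abs=1e-9)
        assert runs[0].lnL_null == pytest.approx(runs[1].lnL_null, abs=1e-9)


class TestLrtAndFdr:
    def test_lrt_reference_values(self):
        stat, p = lrt_pvalue(-100.0, -98.0)
        assert stat == pytest.approx(4.0) and p == pytest.approx(0.0455, abs=2e-4)
        assert lrt_pvalue(-50.0, -50.0) == (0.0, 1.0)
        stat, p = lrt_pvalue(-100.0, -100.0 + 10.83 / 2)
        assert p == pytest.approx(0.001, abs=5e-5)

    def test_mixture_convention_halves_tail(self):
        _, p_chi = lrt_pvalue(-10, -8, "chi2_1")
        _, p_mix = lrt_pvalue(-10, -8, "mixture")
        assert p_mix == pytest.approx(p_chi / 2)
        assert lrt_pvalue(-10, -10, "mixture")[1] == 1.0

    def test_bh_reference_vector(self):
        assert np.allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]), 0.04)
        assert fdr_bh([0.2]) == pytest.approx([0.2])
        assert np.allclose(fdr_bh([1.0, 1.0, 1.0]), 1.0)

    def test_bh_matches_stepup_oracle(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            assert np.allclose(fdr_bh(p), bh_stepup(p), atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestBeb:
    def test_posteriors_bounded_and_ranked(self):
        tree = simulate_tree(6, seed=11, focal="FOCAL", mean_branch=0.15)
        params = CodonModelParams(2.0, 0.1, 8.0, 0.7, 0.15)
        aln, classes = simulate_codon_alignment(
            tree, params, 200, seed=3, foreground="FOCAL"
        )
        fit = branch_site_test(aln, tree, "FOCAL", n_starts=2, seed=0)
        for mode in ("beb", "neb"):
            fg = beb_posteriors(fit._engine, fit._alt_fit, mode=mode)
            assert fg.shape == (200,)
            assert fg.min() >= 0 and fg.max() <= 1
            assert fg[classes >= 2].mean() > fg[classes == 0].mean()
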