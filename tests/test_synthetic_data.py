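import numpy as np
import pytest

from adaptscan.divergence import root_to_tip
from adaptscan.gene_families import bd_transition_prob
from adaptscan.io_formats import write_newick
from adaptscan.selection import CodonModelParams
from adaptscan.synthetic_data import (
    CohortSpec,
    jitter_tree,
    simulate_bd_branch,
    simulate_codon_alignment,
    simulate_cohort,
    simulate_family_counts,
    simulate_protein_alignment,
    simulate_tree,
)


class TestTrees:
    def test_same_seed_identical_newick(self):
        a = simulate_tree(10, seed=5, focal="FOCAL")
        b = simulate_tree(10, seed=5, focal="FOCAL")
        assert write_newick(a) == write_newick(b)
        c = simulate_tree(10, seed=6, focal="FOCAL")
        assert write_newick(a) != write_newick(c)

    def test_focal_scaling_plants_strict_max(self):
        t = simulate_tree(
            12, seed=7, focal="FOCAL", scale=5.0, shape="coalescent", depth=1.0
        )
        d = root_to_tip(t)
        others = [v for k, v in d.items() if k != "FOCAL"]
        assert d["FOCAL"] > max(others)

    def test_unscaled_focal_is_unremarkable(self):
        # over many trees the focal tip should win the root-to-tip
        # maximum about as often as any other tip
        wins = 0
        for seed in range(200):
            d = root_to_tip(simulate_tree(8, seed=seed, focal="FOCAL"))
            wins += max(d, key=d.get) == "FOCAL"
        assert 10 <= wins <= 60  # ~1/8 of 200 = 25 expected

    def test_ultrametric_and_coalescent_depths(self):
        for shape, kw in (("join", {"ultrametric": True}), ("coalescent", {})):
            t = simulate_tree(9, seed=3, depth=50.0, shape=shape, **kw)
            d = root_to_tip(t)
            assert np.allclose(list(d.values()), 50.0, atol=1e-8)

    def test_jitter_preserves_topology(self):
        base = simulate_tree(8, seed=1, focal="FOCAL", shape="coalescent", depth=1.0)
        j = jitter_tree(base, seed=2, focal="FOCAL", focal_scale=3.0)
        assert {l.taxon.label for l in j.leaf_node_iter()} == {
            l.taxon.label for l in base.leaf_node_iter()
        }
        assert write_newick(j) != write_newick(base)


class TestCodonSimulation:
    def test_same_seed_identical_alignment(self):
        tree = simulate_tree(5, seed=2, focal="FOCAL")
        p = CodonModelParams(2.0, 0.2, 3.0, 0.7, 0.2)
        a1, c1 = simulate_codon_alignment(tree, p, 30, seed=4, foreground="FOCAL")
        a2, c2 = simulate_codon_alignment(tree, p, 30, seed=4, foreground="FOCAL")
        assert [r.seq for r in a1.records] == [r.seq for r in a2.records]
        assert (c1 == c2).all()

    def test_vanishing_branch_lengths_give_identical_rows(self):
        tree = simulate_tree(6, seed=2, mean_branch=1e-9)
        p = CodonModelParams(2.0, 0.2)
        aln, _ = simulate_codon_alignment(tree, p, 50, seed=1)
        seqs = {r.seq for r in aln.records}
        assert len(seqs) == 1

    def test_class_proportions_roughly_respected(self):
        tree = simulate_tree(4, seed=2, focal="FOCAL")
        p = CodonModelParams(2.0, 0.2, 5.0, 0.5, 0.3)
        _, classes = simulate_codon_alignment(tree, p, 5000, seed=9, foreground="FOCAL")
        freqs = np.bincount(classes, minlength=4) / 5000
        assert np.abs(freqs - p.proportions).max() < 0.03

    def test_neutral_simulation_balances_syn_nonsyn_rates(self):
        # under omega = 1 the nonsynonymous fraction of substitutions on a
        # two-taxon branch matches the fraction of nonsynonymous rate flow
        from adaptscan.codons import encode_codon_sequence, CODON_AA
        from adaptscan.io_formats import read_newick
        from scipy.stats import binomtest

        # short branches so observed differences are single substitutions
        tree = read_newick("(A:0.02,B:0.02);")
        p = CodonModelParams(1.0, 1.0)
        aln, _ = simulate_codon_alignment(tree, p, 20000, seed=13)
        xa = encode_codon_sequence(aln.records[0].seq)
        xb = encode_codon_sequence(aln.records[1].seq)
        diff = xa != xb
        nonsyn = [
            CODON_AA[a] != CODON_AA[b] for a, b in zip(xa[diff], xb[diff])
        ]
        # expected nonsynonymous fraction under uniform pi and kappa=1,
        # computed from the rate matrix structure
        from adaptscan.codons import PAIR_IS_SYNONYMOUS

        frac_rate = (~PAIR_IS_SYNONYMOUS).sum() / len(PAIR_IS_SYNONYMOUS)
        res = binomtest(int(np.sum(nonsyn)), len(nonsyn), frac_rate)
        assert res.pvalue > 0.001


class TestProteinFixtures:
    def test_no_planting_no_hits(self):
        from adaptscan.substitutions import scan_unique_substitutions

        aln, truth = simulate_protein_alignment(10, 40, seed=3)
        assert truth == []
        assert scan_unique_substitutions(aln, "FOCAL") == []

    def test_determinism(self):
        a1, _ = simulate_protein_alignment(6, 30, planted=[(4, "K", "R")], seed=5)
        a2, _ = simulate_protein_alignment(6, 30, planted=[(4, "K", "R")], seed=5)
        assert [r.seq for r in a1.records] == [r.seq for r in a2.records]

    def test_planted_column_collisions_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            simulate_protein_alignment(5, 20, planted=[(3, "K", "R"), (3, "W", "G")])


class TestFamilySimulation:
    def test_lambda_zero_limit_counts_equal_root(self):
        tree = simulate_tree(5, seed=4, ultrametric=True, depth=100)
        counts, internals = simulate_family_counts(tree, 1e-9, 50, seed=6)
        assert (counts.values == counts.values[:, [0]]).all()

    def test_determinism(self):
        tree = simulate_tree(5, seed=4, ultrametric=True, depth=100)
        c1, i1 = simulate_family_counts(tree, 0.002, 80, seed=9)
        c2, i2 = simulate_family_counts(tree, 0.002, 80, seed=9)
        assert c1.equals(c2) and i1.equals(i2)

    def test_event_driven_branch_matches_analytic_law(self):
        lam, t = 0.2 / 40.0, 40.0  # lambda*t = 0.2
        draws = simulate_bd_branch(1, lam, t, 30000, seed=12)
        for j in range(4):
            th = bd_transition_prob(1, j, lam, t)
            emp = (draws == j).mean()
            se = np.sqrt(th * (1 - th) / len(draws))
            assert abs(emp - th) < 3.5 * se


class TestCohort:
    def test_fixture_layout_and_ground_truth(self, cohort_dir):
        for sub in ("proteins", "cds", "alignments", "trees"):
            assert (cohort_dir / sub).is_dir()
        from adaptscan.io_formats import read_tsv, read_orthogroup_table

        truth = read_tsv(cohort_dir / "ground_truth.tsv")
        assert truth.msa_expected.sum() == 3
        spec = CohortSpec(seed=42)
        species = [f"S{i:02d}" for i in range(1, spec.n_taxa)] + [spec.focal]
        table = read_orthogroup_table(cohort_dir / "orthogroups.tsv", species)
        assert len(table) == spec.n_orthogroups + spec.n_incomplete
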