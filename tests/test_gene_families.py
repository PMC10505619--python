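import numpy as np
import pandas as pd
import pytest

from oracles import enumeration_family_loglik

from adaptscan.gene_families import (
    BirthDeathModel,
    ParameterError,
    _root_prior,
    _transition_stack,
    bd_alpha,
    bd_transition_matrix,
    bd_transition_prob,
    classify_family,
    compile_ultrametric,
    family_log_likelihood,
    filter_families,
    fit_lambdas,
    table_log_likelihoods,
)
from adaptscan.io_formats import read_newick
from adaptscan.synthetic_data import simulate_family_counts, simulate_tree


class TestTransitionProbabilities:
    def test_no_time_no_events(self):
        for i in (1, 3, 10):
            assert bd_transition_prob(i, i, 1e-7, 1e-3) == pytest.approx(1.0, abs=1e-6)

    def test_single_copy_closed_forms(self, rng):
        for _ in range(10):
            lam = float(rng.uniform(1e-4, 0.005))
            t = float(rng.uniform(1, 100))
            a = bd_alpha(lam, t)
            assert bd_transition_prob(1, 0, lam, t) == pytest.approx(a, rel=1e-12)
            assert bd_transition_prob(1, 1, lam, t) == pytest.approx((1 - a) ** 2, rel=1e-12)

    def test_extinction_absorbing(self):
        assert bd_transition_prob(0, 0, 0.01, 10) == 1.0
        assert bd_transition_prob(0, 3, 0.01, 10) == 0.0

    def test_rows_sum_to_one_up_to_cap(self):
        P = bd_transition_matrix(0.004, 40, 80)
        assert np.abs(P[:40].sum(axis=1) - 1).max() < 1e-6

    def test_alpha_regime_enforced(self):
        with pytest.raises(ParameterError, match="alpha"):
            bd_transition_prob(1, 1, 0.5, 10)


class TestFamilyLikelihood:
    def test_single_branch_reduces_to_one_transition(self):
        tree = read_newick("(A:50.0,B:50.0);")
        tree.is_rooted = True
        model = BirthDeathModel({0: 0.002, 1: 0.002}, n_max=10)
        lnl = family_log_likelihood({"A": 2, "B": 2}, tree, model)
        P = bd_transition_matrix(0.002, 50.0, 10)
        prior = _root_prior(10)
        want = np.log(sum(prior[r] * P[r, 2] * P[r, 2] for r in range(11)))
        assert lnl == pytest.approx(float(want), rel=1e-12)

    def test_pruning_matches_enumeration(self):
        tree = simulate_tree(4, seed=2, ultrametric=True, depth=100)
        model = BirthDeathModel({0: 0.004, 1: 0.004}, n_max=6)
        ct = compile_ultrametric(tree)
        stack = _transition_stack(ct, model.lambdas, 6)
        counts = {sp: c for sp, c in zip(sorted(ct.tip_species.values()), [2, 3, 1, 2])}
        got = family_log_likelihood(counts, tree, model)
        want = enumeration_family_loglik(counts, ct, stack, _root_prior(6))
        assert got == pytest.approx(want, rel=1e-10)

    def test_identical_counts_dominate_as_lambda_vanishes(self):
        tree = simulate_tree(4, seed=2, ultrametric=True, depth=100)
        tiny = BirthDeathModel({0: 1e-7, 1: 1e-7}, n_max=10)
        same = family_log_likelihood({sp: 3 for sp in "ABCD"}, tree_relabel(tree), tiny)
        diff = family_log_likelihood(
            dict(zip("ABCD", [3, 3, 3, 5])), tree_relabel(tree), tiny
        )
        assert same == pytest.approx(np.log(_root_prior(10)[3]), abs=1e-3)
        assert diff < same - 10

    def test_non_ultrametric_tree_rejected(self):
        tree = read_newick("((A:1,B:2):1,C:4);")
        tree.is_rooted = True
        with pytest.raises(Exception, match="not ultrametric"):
            compile_ultrametric(tree)


def tree_relabel(tree):
    for leaf, lab in zip(tree.leaf_node_iter(), "ABCD"):
        leaf.taxon.label = lab
    return tree


class TestFiltering:
    def make_table(self, rows):
        return pd.DataFrame(rows).set_index("family")[["A", "B", "C", "D"]]

    def tree(self):
        t = read_newick("((A:50,B:50):50,(C:50,D:50):50);")
        t.is_rooted = True
        return t

    def test_copy_cap_and_clade_rules(self):
        table = self.make_table(
            [
                {"family": "f1", "A": 120, "B": 3, "C": 3, "D": 1},  # cap
                {"family": "f2", "A": 2, "B": 1, "C": 0, "D": 0},  # one clade
                {"family": "f3", "A": 2, "B": 0, "C": 1, "D": 0},  # spans root
                {"family": "f4", "A": 0, "B": 0, "C": 0, "D": 5},  # one clade
            ]
        )
        kept = filter_families(table, self.tree())
        assert list(kept.index) == ["f3"]

    def test_row_by_row_oracle_on_random_fixture(self, rng):
        rows = []
        for i in range(20):
            rows.append(
                {
                    "family": f"f{i}",
                    **{sp: int(rng.integers(0, 130)) for sp in "ABCD"},
                }
            )
        table = self.make_table(rows)
        kept = set(filter_families(table, self.tree()).index)
        for fam, row in table.iterrows():
            cap = (row > 100).any()
            present = {sp for sp in "ABCD" if row[sp] > 0}
            clade = present <= {"A", "B"} or present <= {"C", "D"}
            assert (fam in kept) == (not cap and not clade)

    def test_single_species_rule(self):
        table = self.make_table(
            [{"family": "f1", "A": 5, "B": 0, "C": 0, "D": 0},
             {"family": "f2", "A": 5, "B": 1, "C": 0, "D": 0}]
        )
        kept = filter_families(table, self.tree(), clade_rule="single_species")
        assert list(kept.index) == ["f2"]


class TestFitAndClassify:
    def test_one_lambda_nested_in_two(self):
        tree = simulate_tree(5, seed=9, focal="FOCAL", ultrametric=True, depth=120)
        counts, _ = simulate_family_counts(
            tree, {0: 0.002, 1: 0.005}, 150, seed=3, focal="FOCAL"
        )
        two = fit_lambdas(counts, tree, focal="FOCAL", two_lambda=True)
        one = fit_lambdas(counts, tree, focal="FOCAL", two_lambda=False)
        assert two.lnL >= one.lnL - 1e-6

    def test_fit_is_deterministic(self):
        tree = simulate_tree(5, seed=9, focal="FOCAL", ultrametric=True, depth=120)
        counts, _ = simulate_family_counts(tree, 0.002, 100, seed=4, focal="FOCAL")
        fits = [fit_lambdas(counts, tree, focal="FOCAL") for _ in range(2)]
        assert fits[0].lambdas == fits[1].lambdas

    def test_classification_rules(self):
        tree = simulate_tree(6, seed=1, focal="FOCAL", ultrametric=True, depth=120)
        model = BirthDeathModel({0: 0.002, 1: 0.002}, n_max=40)

        def classify(focal_count, background):
            counts = {sp: background for sp in
                      (l.taxon.label for l in tree.leaf_node_iter())}
            counts["FOCAL"] = focal_count
            return classify_family(counts, tree, model, "FOCAL")

        res = classify(15, 4)
        assert res.direction == "expanded" and res.highly_changed
        res = classify(8, 12)
        assert res.direction == "contracted" and not res.highly_changed
        res = classify(6, 6)
        assert res.direction == "unchanged" and not res.highly_changed

    def test_delta_rule_alternative(self):
        tree = simulate_tree(6, seed=1, focal="FOCAL", ultrametric=True, depth=120)
        model = BirthDeathModel({0: 0.002, 1: 0.002}, n_max=60)
        counts = {sp: 30 for sp in (l.taxon.label for l in tree.leaf_node_iter())}
        counts["FOCAL"] = 41
        size_rule = classify_family(counts, tree, model, "FOCAL", high_rule="family_size")
        delta_rule = classify_family(counts, tree, model, "FOCAL", high_rule="delta")
        assert size_rule.highly_changed
        assert delta_rule.highly_changed == (abs(delta_rule.delta) > 10)
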