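from itertools import product

import numpy as np
import pytest

from circlin import (
    BirthDeathRates,
    GuideTree,
    PhyleticMatrix,
    ancestral_states,
    fit_rates,
    group_core,
    likelihood,
    lineage_specific,
    simulate_gene_content,
)
from circlin.gene_content import _transition_matrices


def brute_force_loglik(pattern, tree, rates):
    """Sum the joint probability over every internal-state assignment."""
    P = _transition_matrices(tree, rates)
    pi = [1 - rates.root_prior, rates.root_prior]
    fixed = {i: pattern[lab] for i, lab in zip(tree.leaf_indices, tree.leaf_labels)}
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    total = 0.0
    for assign in product([0, 1], repeat=len(internal)):
        st = dict(zip(internal, assign))
        st.update(fixed)
        p = pi[st[tree.root]]
        for par, ch in tree.branches():
            p *= P[ch, st[par], st[ch]]
        total += p
    return np.log(total) if total > 0 else -np.inf


TOPOLOGIES = [
    "(A:0.4,B:0.9);",
    "(A:0.2,(B:0.5,C:0.3):0.4);",
    "((A:0.3,B:0.6):0.2,(C:0.7,D:0.1):0.5);",
    "(A:0.2,(B:0.3,(C:0.4,D:0.5):0.6):0.7);",
    "((A:0.3,B:0.7):0.5,(C:0.2,(D:0.4,E:0.1):0.6):0.3);",
    "(A:0.1,(B:0.2,(C:0.3,(D:0.4,E:0.5):0.2):0.3):0.4);",
    "(A:0.5,B:0.5,C:0.5);",  # polytomy handled natively
]


class TestLikelihood:
    @pytest.mark.parametrize("newick", TOPOLOGIES)
    def test_pruning_equals_enumeration(self, newick, rng):
        tree = GuideTree.from_newick(newick)
        for _ in range(15):
            g, l = rng.uniform(0.02, 3.0, size=2)
            rates = BirthDeathRates(float(g), float(l))
            pattern = {
                lab: int(v)
                for lab, v in zip(tree.leaf_labels, rng.integers(0, 2, tree.n_leaves))
            }
            assert likelihood(pattern, tree, rates) == pytest.approx(
                brute_force_loglik(pattern, tree, rates), abs=1e-10
            )

    def test_frozen_dynamics_all_present(self):
        tree = GuideTree.from_newick("(A:1,B:1);")
        rates = BirthDeathRates(0.0, 0.0, root_presence_prior=1.0)
        assert likelihood({"A": 1, "B": 1}, tree, rates) == pytest.approx(0.0)

    def test_frozen_dynamics_impossible_pattern(self):
        tree = GuideTree.from_newick("(A:1,B:1);")
        rates = BirthDeathRates(0.0, 0.0, root_presence_prior=1.0)
        assert likelihood({"A": 1, "B": 0}, tree, rates) == -np.inf

    def test_missing_leaf_rejected(self):
        tree = GuideTree.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="missing"):
            likelihood({"A": 1}, tree, BirthDeathRates(0.1, 0.1))


class TestAncestralStates:
    def test_two_leaf_root_posterior_matches_closed_form(self):
        tree = GuideTree.from_newick("(A:0.5,B:1.2);")
        rates = BirthDeathRates(0.3, 0.7)
        patterns = [(1, 1), (1, 0), (0, 1), (0, 0)]
        matrix = PhyleticMatrix(
            [f"f{i}" for i in range(4)], ["A", "B"],
            np.array(patterns, dtype=np.int64),
        )
        rec = ancestral_states(matrix, tree, rates)
        P = _transition_matrices(tree, rates)
        pi = [1 - rates.root_prior, rates.root_prior]
        iA, iB = tree.leaf_indices
        for fi, (xa, xb) in enumerate(patterns):
            num = pi[1] * P[iA, 1, xa] * P[iB, 1, xb]
            den = num + pi[0] * P[iA, 0, xa] * P[iB, 0, xb]
            assert rec.posterior[tree.root, fi] == pytest.approx(num / den)

    def test_leaf_posteriors_equal_observations(self, five_leaf_tree):
        rates = BirthDeathRates(0.2, 0.4)
        matrix = simulate_gene_content(five_leaf_tree, rates, 50, seed=1)
        rec = ancestral_states(matrix, five_leaf_tree, rates)
        obs = matrix.presence
        for col, i in enumerate(five_leaf_tree.leaf_indices):
            assert np.allclose(rec.posterior[i], obs[:, col])

    def test_all_absent_without_gain_or_loss_stays_absent(self):
        tree = GuideTree.from_newick("(A:1,B:1);")
        rates = BirthDeathRates(0.0, 0.0, root_presence_prior=0.5)
        matrix = PhyleticMatrix(["f1"], ["A", "B"], np.zeros((1, 2), dtype=np.int64))
        rec = ancestral_states(matrix, tree, rates)
        assert np.all(rec.posterior == 0.0)

    def test_all_absent_with_loss_leaves_root_ambiguous(self):
        # absent leaves under gain 0 / loss l still admit a present root
        # that lost the family on both branches
        tree = GuideTree.from_newick("(A:1,B:1);")
        rates = BirthDeathRates(0.0, 0.5, root_presence_prior=0.5)
        matrix = PhyleticMatrix(["f1"], ["A", "B"], np.zeros((1, 2), dtype=np.int64))
        rec = ancestral_states(matrix, tree, rates)
        p10 = 1 - np.exp(-0.5)
        expected = 0.5 * p10**2 / (0.5 + 0.5 * p10**2)
        assert rec.posterior[tree.root, 0] == pytest.approx(expected)
        assert not rec.calls[tree.root, 0]

    def test_omnipresent_family_called_present_at_root(self, five_leaf_tree):
        rates = BirthDeathRates(0.05, 0.05)
        matrix = PhyleticMatrix(["f1"], list("ABCDE"), np.ones((1, 5), dtype=np.int64))
        rec = ancestral_states(matrix, five_leaf_tree, rates)
        assert rec.posterior[five_leaf_tree.root, 0] > 0.5
        assert rec.calls[five_leaf_tree.root, 0]

    def test_gain_requires_absent_parent_present_child(self, five_leaf_tree):
        rates = BirthDeathRates(0.3, 0.5)
        matrix = simulate_gene_content(five_leaf_tree, rates, 300, seed=2)
        rec = ancestral_states(matrix, five_leaf_tree, rates)
        for p, c in five_leaf_tree.branches():
            gains = (~rec.calls[p] & rec.calls[c]).sum()
            losses = (rec.calls[p] & ~rec.calls[c]).sum()
            assert rec.branch_gains[c] == gains
            assert rec.branch_losses[c] == losses


class TestFitRates:
    def test_parameter_recovery(self, eight_leaf_tree):
        fit = fit_rates(
            simulate_gene_content(eight_leaf_tree, BirthDeathRates(0.05, 0.2), 10000, seed=7),
            eight_leaf_tree,
        )
        assert fit.gain_rate == pytest.approx(0.05, rel=0.2)
        assert fit.loss_rate == pytest.approx(0.2, rel=0.2)

    def test_recovery_with_ascertainment_correction(self, eight_leaf_tree):
        full = simulate_gene_content(eight_leaf_tree, BirthDeathRates(0.05, 0.2), 10000, seed=8)
        observed = full.presence.any(axis=1)
        matrix = PhyleticMatrix(
            [f for f, o in zip(full.families, observed) if o],
            full.genomes, full.counts[observed],
        )
        fit = fit_rates(matrix, eight_leaf_tree, correction_for_unobservable=True)
        assert fit.gain_rate == pytest.approx(0.05, rel=0.25)
        assert fit.loss_rate == pytest.approx(0.2, rel=0.25)

    def test_all_present_pushes_loss_to_lower_bound(self, five_leaf_tree):
        matrix = PhyleticMatrix(
            [f"f{i}" for i in range(50)], list("ABCDE"),
            np.ones((50, 5), dtype=np.int64),
        )
        fit = fit_rates(matrix, five_leaf_tree, root_presence_prior=1.0)
        assert fit.loss_rate < 1e-4


class TestSimulator:
    def test_no_gain_gives_exponential_survival(self):
        tree = GuideTree.from_newick("(A:0.5,B:2.0);")
        rates = BirthDeathRates(0.0, 0.3, root_presence_prior=1.0)
        matrix = simulate_gene_content(tree, rates, 20000, seed=3)
        pres = matrix.presence.mean(axis=0)
        depths = {"A": 0.5, "B": 2.0}
        for col, leaf in enumerate(matrix.genomes):
            expected = np.exp(-0.3 * depths[leaf])
            assert pres[col] == pytest.approx(expected, abs=0.01)

    def test_no_loss_prior_one_gives_all_ones(self, five_leaf_tree):
        rates = BirthDeathRates(0.4, 0.0, root_presence_prior=1.0)
        matrix = simulate_gene_content(five_leaf_tree, rates, 100, seed=4)
        assert matrix.presence.all()

    def test_seed_determinism(self, eight_leaf_tree):
        rates = BirthDeathRates(0.1, 0.3)
        m1 = simulate_gene_content(eight_leaf_tree, rates, 200, seed=5)
        m2 = simulate_gene_content(eight_leaf_tree, rates, 200, seed=5)
        assert np.array_equal(m1.counts, m2.counts)


def random_matrix(rng, n_fam=50, n_gen=10):
    return PhyleticMatrix(
        [f"f{i}" for i in range(n_fam)],
        [f"g{i}" for i in range(n_gen)],
        rng.integers(0, 3, size=(n_fam, n_gen)),
    )


class TestPhyleticSets:
    def test_group_core_equals_brute_force(self, rng):
        m = random_matrix(rng)
        group = ["g1", "g4", "g7"]
        expected = {
            f for fi, f in enumerate(m.families)
            if all(m.counts[fi, m.genomes.index(g)] >= 1 for g in group)
        }
        assert group_core(m, group) == expected

    def test_core_anti_monotone_in_group_size(self, rng):
        m = random_matrix(rng)
        assert group_core(m, m.genomes) <= group_core(m, m.genomes[:4])

    def test_singleton_group_is_presence_set(self, rng):
        m = random_matrix(rng)
        expected = {f for fi, f in enumerate(m.families) if m.counts[fi, 0] >= 1}
        assert group_core(m, ["g0"]) == expected

    def test_lineage_specific_equals_brute_force(self, rng):
        m = random_matrix(rng)
        in_g, out_g = ["g0", "g1"], ["g5", "g6", "g7"]
        expected = {
            f for fi, f in enumerate(m.families)
            if all(m.counts[fi, m.genomes.index(g)] >= 1 for g in in_g)
            and all(m.counts[fi, m.genomes.index(g)] == 0 for g in out_g)
        }
        assert lineage_specific(m, in_g, out_g) == expected

    def test_overlapping_groups_rejected(self, rng):
        m = random_matrix(rng)
        with pytest.raises(ValueError, match="overlap"):
            lineage_specific(m, ["g0", "g1"], ["g1", "g2"])

    def test_unknown_genome_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            group_core(random_matrix(rng), ["nope"])


class TestMatrixIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        m = random_matrix(rng, n_fam=8, n_gen=4)
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        m2 = PhyleticMatrix.from_tsv(p)
        assert m2.families == m.families
        assert m2.genomes == m.genomes
        assert np.array_equal(m2.counts, m.counts)

    def test_unit_branch_lengths_when_missing(self, caplog):
        tree = GuideTree.from_newick("(A,(B,C));")
        assert np.all(tree.blen[tree.parent >= 0] == 1.0)
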