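"""Birth-death gene-family model: transition kernel, likelihood vs
enumeration, model scans, reconstruction and the error model."""

import math

import numpy as np
import pandas as pd
import pytest

import erosionscan as es
from erosionscan.gene_families import (
    BirthDeathModel,
    FamilyCountTable,
    _emission_matrix,
    bd_transition_matrix,
    cluster_branch_rates,
    default_n_max,
    estimate_observation_error,
    family_set_loglik,
    fit_birth_death,
    infer_branch_changes,
    reconstruct_ancestral_counts,
    scan_two_class_models,
)
from erosionscan.phylo import Phylogeny


class TestBdTransitionMatrix:
    def test_zero_rates_identity(self):
        P = bd_transition_matrix(0.0, 0.0, 5.0, 6)
        assert np.allclose(P, np.eye(7))

    def test_extinction_absorbing(self):
        P = bd_transition_matrix(0.3, 0.7, 2.0, 8)
        assert P[0, 0] == pytest.approx(1.0)
        assert np.allclose(P[0, 1:], 0.0)

    def test_kendall_critical_case_closed_form(self):
        # lambda = mu: P(1 -> 0 in time t) = lambda t / (1 + lambda t)
        P = bd_transition_matrix(0.1, 0.1, 1.0, 40)
        assert P[1, 0] == pytest.approx(1.0 / 11.0, abs=1e-10)
        P2 = bd_transition_matrix(0.5, 0.5, 3.0, 60)
        assert P2[1, 0] == pytest.approx(1.5 / 2.5, abs=1e-8)

    @pytest.mark.parametrize("lam,mu,t", [(0.02, 0.05, 3.0),
                                          (0.4, 0.1, 1.5),
                                          (0.0, 0.3, 10.0)])
    def test_rows_stochastic_and_chapman_kolmogorov(self, lam, mu, t):
        n = 30
        P = bd_transition_matrix(lam, mu, t, n)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
        Ps = bd_transition_matrix(lam, mu, t / 2, n)
        assert np.abs(Ps @ Ps - P).max() < 1e-8

    def test_invalid_cap(self):
        with pytest.raises(ValueError):
            bd_transition_matrix(0.1, 0.1, 1.0, 0)


def _two_leaf_tree():
    return Phylogeny.from_newick("(A:2.0,B:3.0)r;", unit="Ma")


def _brute_force_loglik(table, tree, model):
    """Exhaustive enumeration over root and internal states (<= 3 leaves)."""
    n = model.n_max
    mats = {}
    for node in tree.branches():
        lam, mu = model.branch_rates(node.label)
        mats[node.label] = bd_transition_matrix(lam, mu, node.length, n)
    emis = {
        sp: _emission_matrix(model.eps.get(sp, 0.0), n)
        for sp in tree.leaf_labels()
    }

    def subtree_lik(node, state, obs):
        if node.is_leaf:
            return emis[node.label][state, obs[node.label]]
        total = 1.0
        for ci in node.children:
            child = tree.nodes[ci]
            s = sum(
                mats[child.label][state, m] * subtree_lik(child, m, obs)
                for m in range(n + 1)
            )
            total *= s
        return total

    def subtree_ext(node, state):
        if node.is_leaf:
            return 1.0 if state == 0 else 0.0
        total = 1.0
        for ci in node.children:
            child = tree.nodes[ci]
            total *= sum(
                mats[child.label][state, m] * subtree_ext(child, m)
                for m in range(n + 1)
            )
        return total

    surv = 1.0 - sum(
        model.root_prior[r] * subtree_ext(tree.root, r)
        for r in range(n + 1)
    )
    ll = 0.0
    for fam in table.families:
        obs = {sp: int(table.counts.loc[fam, sp]) for sp in table.species}
        lik = sum(
            model.root_prior[r] * subtree_lik(tree.root, r, obs)
            for r in range(n + 1)
        )
        ll += math.log(lik) - math.log(surv)
    return ll


class TestFamilyLoglik:
    def test_matches_enumeration_two_leaves(self):
        tree = _two_leaf_tree()
        table = FamilyCountTable(
            pd.DataFrame({"A": [1, 2, 0, 3], "B": [1, 1, 2, 3]},
                         index=["f1", "f2", "f3", "f4"])
        )
        model = BirthDeathModel(
            rates={"all": (0.08, 0.12)},
            classes={"A": "all", "B": "all"},
            n_max=3,
            eps={"A": 0.1, "B": 0.05},
        )
        got = family_set_loglik(table, tree, model)
        want = _brute_force_loglik(table, tree, model)
        assert got == pytest.approx(want, abs=1e-10)

    def test_matches_enumeration_three_leaves(self):
        tree = Phylogeny.from_newick("((A:1.0,B:2.0)ab:1.5,C:2.5)r;",
                                     unit="Ma")
        table = FamilyCountTable(
            pd.DataFrame({"A": [2, 1], "B": [1, 0], "C": [3, 4]},
                         index=["f1", "f2"])
        )
        model = BirthDeathModel(
            rates={"fast": (0.15, 0.2), "slow": (0.02, 0.01)},
            classes={"A": "fast", "B": "slow", "ab": "slow", "C": "slow"},
            n_max=4,
            eps={"C": 0.2},
        )
        got = family_set_loglik(table, tree, model)
        want = _brute_force_loglik(table, tree, model)
        assert got == pytest.approx(want, abs=1e-10)

    def test_frozen_dynamics_reduce_to_root_prior(self):
        tree = _two_leaf_tree()
        table = FamilyCountTable(
            pd.DataFrame({"A": [2, 2, 2], "B": [2, 2, 2]},
                         index=["f1", "f2", "f3"])
        )
        model = BirthDeathModel(
            rates={"all": (0.0, 0.0)}, classes={"A": "all", "B": "all"},
            n_max=5,
        )
        # every family likelihood is the prior mass of its (certain) root
        assert family_set_loglik(table, tree, model) == pytest.approx(
            3 * math.log(1.0 / 5.0)
        )

    def test_count_above_cap_instructs_increase(self):
        tree = _two_leaf_tree()
        table = FamilyCountTable(
            pd.DataFrame({"A": [9], "B": [1]}, index=["f1"])
        )
        model = BirthDeathModel(rates={"all": (0.1, 0.1)},
                                classes={"A": "all", "B": "all"}, n_max=4)
        with pytest.raises(ValueError, match="cap"):
            family_set_loglik(table, tree, model)

    def test_likelihood_invariant_under_family_relabeling(self, study):
        tree, part = study
        cfg = es.SimulationConfig(seed=21, n_families=50)
        table, _ = es.simulate_family_counts(cfg)
        model = BirthDeathModel(
            rates={"test": (0.004, 0.002), "reference": (0.002, 0.003)},
            classes=dict(part.classes), n_max=default_n_max(table),
        )
        ll1 = family_set_loglik(table, tree, model)
        shuffled = FamilyCountTable(
            table.counts.sample(frac=1.0, random_state=4).rename(
                index=lambda s: s + "_x"
            )
        )
        assert family_set_loglik(shuffled, tree, model) == pytest.approx(
            ll1, abs=1e-9
        )


class TestScanAndCluster:
    def test_two_leaf_tree_with_root_stem_gives_three_focal_models(self):
        tree = Phylogeny.from_newick("(A:2.0,B:3.0)r:1.0;", unit="Ma")
        table = FamilyCountTable(
            pd.DataFrame({"A": [1, 2, 1], "B": [2, 1, 1]},
                         index=["f1", "f2", "f3"])
        )
        est = scan_two_class_models(table, tree, restarts=1, seed=0)
        assert len(est.estimates) == 3
        assert set(est.estimates) == {"A", "B", "r"}

    def test_fast_loss_branch_has_maximal_mu(self, study):
        tree, part = study
        rates = {"test": (0.002, 0.002), "reference": (0.002, 0.002)}
        # plant a 10x loss rate on one terminal branch via a custom class
        classes = dict(part.classes)
        classes["P_argentina"] = "fast"
        cfg = es.SimulationConfig(
            seed=29, n_families=400,
            family_rates={**rates, "fast": (0.002, 0.02)},
        )
        table, _ = es.simulate_family_counts(
            cfg, tree=tree,
            partition=es.BranchPartition(classes),
        )
        est = scan_two_class_models(table, tree, restarts=2, seed=1)
        mus = {b: mu for b, (_, mu) in est.estimates.items()}
        assert max(mus, key=mus.get) == "P_argentina"

    def test_identical_estimates_collapse_and_min_k_wins(self, study):
        tree, _ = study
        cfg = es.SimulationConfig(seed=31, n_families=150)
        table, _ = es.simulate_family_counts(cfg)
        from erosionscan.gene_families import BranchRateEstimates

        est = BranchRateEstimates(
            estimates={b: (0.002, 0.002) for b in tree.branch_labels()},
            loglik={b: 0.0 for b in tree.branch_labels()},
            converged={b: True for b in tree.branch_labels()},
        )
        out = cluster_branch_rates(est, table, tree, k_range=range(2, 4),
                                   nstart=5, restarts=1, seed=0)
        # all centers coincide: the refit collapses to one shared rate
        # class and AIC picks the smallest k
        assert out.chosen_k == 2
        assert len(set(out.assignment.values())) == 1

    def test_k_larger_than_branch_count_rejected(self, study):
        tree, _ = study
        cfg = es.SimulationConfig(seed=33, n_families=60)
        table, _ = es.simulate_family_counts(cfg)
        est = scan_two_class_models(table, tree, restarts=1, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_branch_rates(est, table, tree, k_range=range(2, 40),
                                 nstart=2, restarts=1)


class TestBranchChanges:
    def test_frozen_dynamics_no_changes(self, study):
        tree, part = study
        cfg = es.SimulationConfig(
            seed=35, n_families=100,
            family_rates={"test": (0.0, 0.0), "reference": (0.0, 0.0)},
        )
        table, _ = es.simulate_family_counts(cfg)
        model = BirthDeathModel(
            rates={"test": (0.0, 0.0), "reference": (0.0, 0.0)},
            classes=dict(part.classes), n_max=default_n_max(table),
        )
        changes = infer_branch_changes(table, tree, model)
        assert (changes["expansions"] == 0).all()
        assert (changes["contractions"] == 0).all()

    def test_reconstruction_matches_bruteforce_two_leaves(self):
        tree = _two_leaf_tree()
        table = FamilyCountTable(
            pd.DataFrame({"A": [3], "B": [1]}, index=["f1"])
        )
        model = BirthDeathModel(
            rates={"all": (0.05, 0.15)}, classes={"A": "all", "B": "all"},
            n_max=5,
        )
        states = reconstruct_ancestral_counts(table, tree, model)
        # brute-force joint max posterior over (root, leafA, leafB) truths
        mats = {
            b: bd_transition_matrix(*model.rates["all"],
                                    tree.node(b).length, 5)
            for b in ("A", "B")
        }
        best, best_states = -1.0, None
        for r in range(6):
            for ta in range(6):
                for tb in range(6):
                    lik = (
                        model.root_prior[r]
                        * mats["A"][r, ta] * (ta == 3)
                        * mats["B"][r, tb] * (tb == 1)
                    )
                    if lik > best:
                        best, best_states = lik, (r, ta, tb)
        assert states["r"][0] == best_states[0]
        assert states["A"][0] == best_states[1]
        assert states["B"][0] == best_states[2]

    def test_pure_loss_branch_shows_contractions(self, study):
        tree, part = study
        cfg = es.SimulationConfig(
            seed=37, n_families=400,
            family_rates={"test": (0.0, 0.05), "reference": (0.001, 0.001)},
        )
        table, _ = es.simulate_family_counts(cfg)
        model = BirthDeathModel(
            rates={"test": (0.0, 0.05), "reference": (0.001, 0.001)},
            classes=dict(part.classes), n_max=default_n_max(table),
        )
        changes = infer_branch_changes(table, tree, model)
        para = changes.loc["P_argentina"]
        assert para["contractions"] > para["expansions"]
        assert para["loss_per_gene_per_kyr"] > 0


class TestObservationError:
    def test_error_free_data_gives_zero_eps(self, study):
        tree, part = study
        cfg = es.SimulationConfig(seed=39, n_families=250, eps=0.0)
        table, _ = es.simulate_family_counts(cfg)
        model = BirthDeathModel(
            rates=dict(cfg.family_rates), classes=dict(part.classes),
            n_max=default_n_max(table),
        )
        eps_hat, profiles = estimate_observation_error(
            table, tree, model, grid=np.array([0.0, 0.05, 0.1]), sweeps=1
        )
        assert all(v == 0.0 for v in eps_hat.values())
        for lls in profiles.values():
            assert np.argmax(lls) == 0

    def test_loglik_increases_toward_true_eps(self, study):
        # with data generated at eps = 0.2, the likelihood profile over a
        # shared eps rises from 0 toward a maximum near 0.2
        tree, part = study
        cfg = es.SimulationConfig(seed=41, n_families=500, eps=0.2)
        table, _ = es.simulate_family_counts(cfg)
        n_max = default_n_max(table)
        lls = []
        for e in (0.0, 0.1, 0.2, 0.35):
            model = BirthDeathModel(
                rates=dict(cfg.family_rates), classes=dict(part.classes),
                n_max=n_max,
                eps={sp: e for sp in tree.leaf_labels()},
            )
            lls.append(family_set_loglik(table, tree, model))
        assert lls[1] > lls[0]
        assert lls[2] > lls[1]
        assert lls[3] < lls[2]


class TestFitBirthDeath:
    def test_tie_rates_reduces_parameters(self, study):
        tree, part = study
        cfg = es.SimulationConfig(seed=43, n_families=150)
        table, _ = es.simulate_family_counts(cfg)
        model, ll, ok = fit_birth_death(
            table, tree, dict(part.classes), restarts=1, seed=0,
            tie_rates=True,
        )
        for lam, mu in model.rates.values():
            assert lam == pytest.approx(mu)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            BirthDeathModel(rates={"a": (-0.1, 0.2)}, classes={}, n_max=5)
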