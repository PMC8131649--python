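"""Codon-model machinery: rate matrix, pruning likelihood, the
relaxation test and its summaries."""

import math

import numpy as np
import pytest

import erosionscan as es
from erosionscan._codons import get_code
from erosionscan.alignments import CodonAlignment
from erosionscan.phylo import BranchPartition, Phylogeny
from erosionscan.selection import (
    Mg94Params,
    RelaxModel,
    RelaxResult,
    alignment_loglik,
    background_omega,
    benjamini_hochberg,
    fit_relax,
    mg94_rate_matrix,
    summarize_selection_intensity,
    transition_matrix,
)

CODE = get_code(1)


class TestMg94RateMatrix:
    def test_uniform_neutral_rates_all_equal(self):
        Q, _ = mg94_rate_matrix(Mg94Params(kappa=1.0, omega=1.0))
        off = Q[~np.eye(61, dtype=bool)]
        nonzero = off[off > 0]
        assert np.allclose(nonzero, nonzero[0])

    @pytest.mark.parametrize(
        "kappa,omega,pi_nuc",
        [
            (2.0, 0.5, (0.25, 0.25, 0.25, 0.25)),
            (4.7, 1.8, (0.1, 0.2, 0.3, 0.4)),
            (0.6, 0.0, (0.4, 0.1, 0.1, 0.4)),
        ],
    )
    def test_detailed_balance_and_scaling(self, kappa, omega, pi_nuc):
        Q, pi = mg94_rate_matrix(Mg94Params(kappa, omega, np.array(pi_nuc)))
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-10
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        if omega > 0:
            assert -np.dot(pi, np.diag(Q)) == pytest.approx(1.0, abs=1e-10)

    def test_syn_transition_vs_nonsyn_transversion_ratio(self):
        # TTT->TTC is a synonymous transition, TTT->TTA a nonsynonymous
        # transversion: their unscaled rate ratio is kappa/omega
        Q, _ = mg94_rate_matrix(Mg94Params(kappa=2.0, omega=0.5))
        i, j, a = CODE.index["TTT"], CODE.index["TTC"], CODE.index["TTA"]
        assert Q[i, j] / Q[i, a] == pytest.approx(2.0 / 0.5)

    def test_single_step_sparsity(self):
        Q, _ = mg94_rate_matrix(Mg94Params())
        for i, x in enumerate(CODE.codons):
            for j, y in enumerate(CODE.codons):
                if i == j:
                    continue
                ndiff = sum(c1 != c2 for c1, c2 in zip(x, y))
                assert (Q[i, j] > 0) == (ndiff == 1)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError, match="zero stationary"):
            mg94_rate_matrix(
                Mg94Params(pi_nuc=np.array([0.5, 0.5, 0.0, 0.0]))
            )

    def test_transition_matrix_stochastic_and_identity_at_zero(self):
        Q, pi = mg94_rate_matrix(Mg94Params(kappa=3.0, omega=0.2))
        P = transition_matrix(Q, pi, 0.7)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
        P0 = transition_matrix(Q, pi, 0.0)
        assert np.abs(P0 - np.eye(61)).max() < 1e-10


def _brute_force_loglik(aln, tree, part, model):
    """Exhaustive sum over all ancestral codon assignments."""
    specs = {}
    for ci, (w, p) in enumerate(zip(model.omegas, model.props)):
        mats = {}
        for node in tree.branches():
            weff = w ** model.k if part is not None and part.is_test(
                node.label) else w
            Q, pi = mg94_rate_matrix(
                Mg94Params(model.kappa, weff, model.pi_nuc)
            )
            mats[node.label] = transition_matrix(Q, pi, node.length or 0.0)
        specs[ci] = (mats, pi)

    internals = [n for n in tree.nodes if not n.is_leaf]
    total = 0.0
    for s in range(aln.n_codons):
        obs = {
            sp: CODE.index[aln.sequences[sp][3 * s: 3 * s + 3]]
            for sp in aln.species
        }
        site = 0.0
        for ci, p in enumerate(model.props):
            mats, pi = specs[ci]
            lik = 0.0
            import itertools

            for states in itertools.product(range(61),
                                            repeat=len(internals)):
                st = {n.index: s_ for n, s_ in zip(internals, states)}
                for leaf in tree.leaves():
                    st[leaf.index] = obs[leaf.label]
                term = pi[st[tree.root.index]]
                for node in tree.branches():
                    term *= mats[node.label][st[node.parent], st[node.index]]
                lik += term
            site += p * lik
        total += math.log(site)
    return total


class TestPruningLikelihood:
    def test_matches_enumeration_three_taxa(self):
        tree = Phylogeny.from_newick("((A:0.3,B:0.2)ab:0.1,C:0.4)r;")
        part = BranchPartition(
            {"A": "test", "B": "reference", "ab": "reference",
             "C": "reference"}
        )
        rng = np.random.default_rng(1)
        aln = CodonAlignment(
            {
                sp: "".join(CODE.codons[i]
                            for i in rng.integers(0, 61, 10))
                for sp in "ABC"
            }
        )
        model = RelaxModel((0.2, 0.7, 1.5), (0.5, 0.3, 0.2), k=0.5)
        got = alignment_loglik(aln, tree, part, model)
        want = _brute_force_loglik(aln, tree, part, model)
        assert got == pytest.approx(want, abs=1e-8)

    def test_matches_enumeration_four_taxa(self):
        tree = Phylogeny.from_newick(
            "(((A:0.2,B:0.3)ab:0.2,C:0.25)abc:0.15,D:0.5)r;"
        )
        part = BranchPartition(
            {b: ("test" if b in {"A", "ab"} else "reference")
             for b in tree.branch_labels()}
        )
        rng = np.random.default_rng(2)
        aln = CodonAlignment(
            {
                sp: "".join(CODE.codons[i] for i in rng.integers(0, 61, 3))
                for sp in "ABCD"
            }
        )
        model = RelaxModel((0.1, 0.9, 1.2), (0.4, 0.4, 0.2), k=2.0)
        got = alignment_loglik(aln, tree, part, model)
        want = _brute_force_loglik(aln, tree, part, model)
        assert got == pytest.approx(want, abs=1e-8)

    def test_star_tree_single_site_collapses_to_pi(self):
        tree = Phylogeny.from_newick("(A:0.0,B:0.0,C:0.0)r;")
        aln = CodonAlignment({sp: "GGT" for sp in "ABC"})
        model = RelaxModel((1.0, 1.0, 1.0), (1.0, 0.0, 0.0))
        ll = alignment_loglik(aln, tree, None, model)
        pi = Mg94Params().pi
        assert ll == pytest.approx(math.log(pi[CODE.index["GGT"]]),
                                   abs=1e-10)

    def test_category_split_leaves_likelihood_unchanged(self):
        tree = Phylogeny.from_newick("((A:0.3,B:0.2)ab:0.1,C:0.4)r;")
        rng = np.random.default_rng(3)
        aln = CodonAlignment(
            {
                sp: "".join(CODE.codons[i]
                            for i in rng.integers(0, 61, 15))
                for sp in "ABC"
            }
        )
        one = RelaxModel((0.4, 0.4, 1.0), (0.7, 0.0, 0.3))
        split = RelaxModel((0.4, 0.4, 1.0), (0.35, 0.35, 0.3))
        a = alignment_loglik(aln, tree, None, one)
        b = alignment_loglik(aln, tree, None, split)
        assert a == pytest.approx(b, abs=1e-9)

    def test_gaps_are_missing_data(self):
        tree = Phylogeny.from_newick("((A:0.3,B:0.2)ab:0.1,C:0.4)r;")
        aln_full = CodonAlignment({"A": "GGTACA", "B": "GGCACA",
                                   "C": "GGAACA"})
        aln_gap = CodonAlignment({"A": "GGT---", "B": "GGC---",
                                  "C": "GGA---"})
        model = RelaxModel((0.5, 0.9, 1.1), (0.3, 0.4, 0.3))
        ll_first_codon_only = alignment_loglik(
            CodonAlignment({"A": "GGT", "B": "GGC", "C": "GGA"}),
            tree, None, model,
        )
        assert alignment_loglik(aln_gap, tree, None, model) == pytest.approx(
            ll_first_codon_only, abs=1e-9
        )
        # and gapped lnL differs from the fully observed one
        assert alignment_loglik(aln_full, tree, None, model) != \
            pytest.approx(ll_first_codon_only, abs=1e-3)

    def test_species_mismatch_lists_offenders(self, study):
        tree, part = study
        aln = CodonAlignment({"A_echinatior": "GGT"})
        with pytest.raises(ValueError, match="At_colombica"):
            alignment_loglik(aln, tree, part,
                             RelaxModel((1, 1, 1), (1, 0, 0)))


class TestFitRelax:
    def test_recovers_intensification_direction(self, study):
        # mirrored recovery: data simulated with k = 3 should give
        # median k-hat above 1
        tree, part = study
        khats = []
        for rep in range(4):
            cfg = es.SimulationConfig(seed=400 + rep, n_sites=300, k=3.0)
            aln, _ = es.simulate_codon_alignment(cfg)
            r = fit_relax(aln, tree, part, restarts=1, seed=rep,
                          branch_scale=cfg.clock_subs_per_codon_per_ma)
            khats.append(r.k)
        assert np.median(khats) > 1.0

    def test_alternative_dominates_null(self, study):
        tree, part = study
        cfg = es.SimulationConfig(seed=42, n_sites=200, k=0.5)
        aln, _ = es.simulate_codon_alignment(cfg)
        r = fit_relax(aln, tree, part, restarts=1, seed=0,
                      branch_scale=cfg.clock_subs_per_codon_per_ma)
        assert r.lrt >= -1e-6
        assert 0.0 <= r.p <= 1.0
        assert r.log2_k == pytest.approx(math.log2(r.k))

    def test_requires_nonempty_branch_sets(self, study):
        tree, _ = study
        aln = es.simulate_codon_alignment(
            es.SimulationConfig(seed=1, n_sites=10))[0]
        allref = BranchPartition(
            {b: "reference" for b in tree.branch_labels()}
        )
        with pytest.raises(ValueError, match="non-empty"):
            fit_relax(aln, tree, allref)


def _result(k=1.0, omegas=(0.2, 0.8, 1.5), props=(0.5, 0.3, 0.2), p=0.5):
    return RelaxResult(
        gene=None, lnL_alt=0.0, lnL_null=0.0, lrt=0.0, p=p, k=k,
        kappa=2.0, omegas=omegas, props=props, null_omegas=omegas,
        null_props=props, null_kappa=2.0, pi_nuc=np.full(4, 0.25),
    )


class TestBackgroundOmega:
    def test_reference_weighted_mean(self):
        r = _result(omegas=(0.2, 0.8, 1.5), props=(0.5, 0.5, 0.0))
        assert background_omega(r, "reference") == pytest.approx(0.5)

    def test_degenerate_single_category(self):
        r = _result(omegas=(0.3, 0.9, 1.5), props=(1.0, 0.0, 0.0))
        assert background_omega(r, "reference") == pytest.approx(0.3)

    def test_test_set_applies_k_exponent(self):
        r = _result(k=0.5, omegas=(0.25, 0.81, 1.5), props=(0.5, 0.5, 0.0))
        assert background_omega(r, "test") == pytest.approx(0.7)

    def test_absent_when_no_subneutral_mass(self):
        r = _result(props=(0.0, 0.0, 1.0))
        assert background_omega(r, "test") is None


class TestSummary:
    def test_bins_left_closed(self):
        results = [_result(k=2.0 ** v) for v in (-3, -1, 1, 3)]
        s = summarize_selection_intensity(results)
        assert s.bin_counts == (1, 1, 1, 1)

    def test_neutral_k_in_third_bin(self):
        s = summarize_selection_intensity([_result(k=1.0)] * 4)
        assert s.bin_counts == (0, 0, 4, 0)

    def test_mean_omega_cap_excludes_gene(self):
        high = _result(omegas=(0.5, 1.0, 40.0), props=(0.0, 0.0, 1.0))
        ok = _result()
        s = summarize_selection_intensity([high, ok], rate_cap=10.0)
        assert s.excluded == [high]
        assert sum(s.bin_counts) == 1

    def test_fdr_split_by_direction(self):
        res = [_result(k=0.2, p=1e-4), _result(k=4.0, p=1e-4),
               _result(k=0.5, p=0.9)]
        s = summarize_selection_intensity(res, fdr=0.1)
        assert len(s.relaxed_significant) == 1
        assert s.relaxed_significant[0].k == 0.2
        assert len(s.intensified_significant) == 1
        assert all(r.q is not None and r.q >= r.p for r in s.retained)

    def test_empty_input(self):
        s = summarize_selection_intensity([])
        assert s.bin_counts == (0, 0, 0, 0)
        assert s.retained == []


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_and_saturated(self):
        assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_matches_independent_step_up(self, rng):
        p = rng.uniform(size=25)
        q = benjamini_hochberg(p)
        # independent step-up computation
        order = np.argsort(p)
        m = len(p)
        raw = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(raw[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(stepped, 1.0)
        assert np.allclose(q, expect)
        assert np.all(q >= p - 1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])
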