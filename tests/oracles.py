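"""Independent brute-force oracles used to validate the dynamic-programming
implementations. These deliberately enumerate states instead of pruning."""

import itertools
import math

from erosionscan._codons import get_code
from erosionscan.gene_families import _emission_matrix, bd_transition_matrix
from erosionscan.selection import (
    Mg94Params,
    mg94_rate_matrix,
    transition_matrix,
)

CODE = get_code(1)


def brute_force_codon_loglik(aln, tree, part, model):
    """Exhaustive sum over all ancestral codon assignments."""
    specs = {}
    for ci, (w, p) in enumerate(zip(model.omegas, model.props)):
        mats = {}
        for node in tree.branches():
            weff = (w ** model.k
                    if part is not None and part.is_test(node.label) else w)
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
            for states in itertools.product(range(61),
                                            repeat=len(internals)):
                st = {n.index: s_ for n, s_ in zip(internals, states)}
                for leaf in tree.leaves():
                    st[leaf.index] = obs[leaf.label]
                term = pi[st[tree.root.index]]
                for node in tree.branches():
                    term *= mats[node.label][st[node.parent],
                                             st[node.index]]
                lik += term
            site += p * lik
        total += math.log(site)
    return total


def brute_force_family_loglik(table, tree, model):
    """Exhaustive enumeration over root and internal count states."""
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
            total *= sum(
                mats[child.label][state, m] * subtree_lik(child, m, obs)
                for m in range(n + 1)
            )
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


def brute_force_min_events(gtree, stree):
    """Minimal duplications + losses over all valid species mappings."""
    snodes = stree.nodes
    ancestors = {}
    for n in snodes:
        anc, i = set(), n.index
        while i is not None:
            anc.add(i)
            i = snodes[i].parent
        ancestors[n.index] = anc
    depth = {stree.root.index: 0}
    for n in snodes:
        for c in n.children:
            depth[c] = depth[n.index] + 1

    def species_lca(i, j):
        common = ancestors[i] & ancestors[j]
        return max(common, key=lambda x: len(ancestors[x]))

    gnodes = gtree.tree.postorder()
    leaves_map = {
        n.index: stree.node(gtree.species_of[n.label]).index
        for n in gnodes if n.is_leaf
    }
    internal = [n for n in gnodes if not n.is_leaf]

    best = None
    for assign in itertools.product(range(len(snodes)),
                                    repeat=len(internal)):
        m = dict(leaves_map)
        for n, s in zip(internal, assign):
            m[n.index] = s
        if any(
            m[n.index] not in ancestors[m[c]]
            for n in internal for c in n.children
        ):
            continue
        events = 0
        for n in internal:
            cl, cr = n.children
            lca = species_lca(m[cl], m[cr])
            # a speciation requires the children to split exactly at the
            # mapped node; anything else is a duplication
            dup = not (m[n.index] == lca
                       and m[cl] != m[n.index] and m[cr] != m[n.index])
            events += dup
            for c in n.children:
                events += depth[m[c]] - depth[m[n.index]] - 1 + dup
        if best is None or events < best:
            best = events
    return best
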