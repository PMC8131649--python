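"""Gene-tree / species-tree LCA reconciliation and the parasite-vs-host
event-asymmetry test.

Each gene-tree node is mapped to the last common ancestor (in the species
tree) of the species under it; a node is a duplication when its mapping
coincides with a child's mapping, otherwise a speciation. Losses are
counted by the standard path-depth rule and attributed to the species-tree
branches that hang off the mapping path, so per-branch duplication and
loss tallies can be compared between parasitic and free-living branch sets
with a Pearson chi-square test on the resulting 2x2 event table.

Gene trees are consumed pre-rooted; leaf labels carry the species either
via a configurable separator (default ``species|gene``) or a caller-
supplied mapping function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phylo import BranchPartition, Phylogeny, parse_newick

__all__ = [
    "GeneTree",
    "ReconciliationResult",
    "clades_of_size",
    "lca_reconcile",
    "minimal_duplication_rooting",
    "event_asymmetry_test",
]


@dataclass
class GeneTree:
    """Rooted gene tree whose leaves carry (species, gene id)."""

    tree: Phylogeny
    species_of: dict[str, str]  # leaf label -> species

    @classmethod
    def from_newick(cls, newick: str, separator: str = "|",
                    species_fn=None) -> "GeneTree":
        tree = parse_newick(newick)
        mapping = {}
        for leaf in tree.leaves():
            if species_fn is not None:
                mapping[leaf.label] = species_fn(leaf.label)
            else:
                mapping[leaf.label] = leaf.label.split(separator)[0]
        return cls(tree, mapping)

    def validate(self, stree: Phylogeny) -> list[str]:
        report = []
        known = set(stree.leaf_labels())
        for leaf, sp in self.species_of.items():
            if sp not in known:
                report.append(f"leaf {leaf}: unknown species {sp}")
        for node in self.tree.nodes:
            if node.children and len(node.children) != 2:
                report.append(f"non-binary internal node {node.label}")
        return report


def clades_of_size(tree: Phylogeny, min_size: int) -> list[list[str]]:
    """Partition the leaves into maximal disjoint clades of >= min_size.

    Recursive rule: descend into a node's children only while every child
    subtree still holds at least ``min_size`` leaves; otherwise the node
    itself becomes a clade. Every leaf is assigned to exactly one clade.
    When min_size exceeds the leaf count the whole tree is the single
    clade.
    """
    sizes: dict[int, int] = {}
    for node in tree.postorder():
        sizes[node.index] = (
            1 if node.is_leaf
            else sum(sizes[c] for c in node.children)
        )

    clades: list[list[str]] = []

    def leaves_under(i: int) -> list[str]:
        node = tree.nodes[i]
        if node.is_leaf:
            return [node.label]
        out: list[str] = []
        for c in node.children:
            out.extend(leaves_under(c))
        return out

    def walk(i: int) -> None:
        node = tree.nodes[i]
        children = node.children
        if children and all(sizes[c] >= min_size for c in children):
            for c in children:
                walk(c)
        else:
            clades.append(leaves_under(i))

    walk(tree.root.index)
    return clades


@dataclass
class ReconciliationResult:
    """Per-node mappings/events and per-species-branch event counts."""

    #: gene-tree node label -> species-tree node label
    mapping: dict[str, str]
    #: gene-tree internal node label -> "speciation" | "duplication"
    events: dict[str, str]
    #: species-tree branch (node label) -> counts
    duplications: dict[str, int]
    losses: dict[str, int]

    @property
    def total_duplications(self) -> int:
        return sum(self.duplications.values())

    @property
    def total_losses(self) -> int:
        return sum(self.losses.values())


def lca_reconcile(gtree: GeneTree, stree: Phylogeny) -> ReconciliationResult:
    """Standard LCA duplication-loss reconciliation.

    The mapping is the unique one taking each gene node to the LCA of its
    descendant species; duplication/loss counts are parsimony-minimal for
    the given rooting. Unknown species labels raise ``ValueError``.
    """
    unknown = sorted(
        {sp for sp in gtree.species_of.values()}
        - set(stree.leaf_labels())
    )
    if unknown:
        raise ValueError(f"species not in species tree: {unknown}")

    # species-node depth (root = 0) and parent hops
    depth: dict[int, int] = {stree.root.index: 0}
    for node in stree.nodes:
        for c in node.children:
            depth[c] = depth[node.index] + 1

    mapping_idx: dict[int, int] = {}
    mapping: dict[str, str] = {}
    events: dict[str, str] = {}
    dup_counts = {n.label: 0 for n in stree.nodes}
    loss_counts = {n.label: 0 for n in stree.nodes}

    def species_lca(i: int, j: int) -> int:
        a, b = i, j
        while depth[a] > depth[b]:
            a = stree.nodes[a].parent
        while depth[b] > depth[a]:
            b = stree.nodes[b].parent
        while a != b:
            a = stree.nodes[a].parent
            b = stree.nodes[b].parent
        return a

    for node in gtree.tree.postorder():
        if node.is_leaf:
            sp = gtree.species_of[node.label]
            mapping_idx[node.index] = stree.node(sp).index
        else:
            child_maps = [mapping_idx[c] for c in node.children]
            m = child_maps[0]
            for other in child_maps[1:]:
                m = species_lca(m, other)
            mapping_idx[node.index] = m
            is_dup = any(cm == m for cm in child_maps)
            events[node.label] = "duplication" if is_dup else "speciation"
            if is_dup:
                dup_counts[stree.nodes[m].label] += 1
        mapping[node.label] = stree.nodes[mapping_idx[node.index]].label

    # losses: walk each gene edge's species path; every species node passed
    # strictly between the child's mapping and the stopping point sheds a
    # loss on its off-path child branch
    for node in gtree.tree.postorder():
        if node.parent is None:
            continue
        parent = gtree.tree.nodes[node.parent]
        m_child = mapping_idx[node.index]
        m_parent = mapping_idx[parent.index]
        if m_child == m_parent:
            continue
        stop_below = (
            events[parent.label] == "duplication"
            if parent.label in events else False
        )
        cur = m_child
        while True:
            par = stree.nodes[cur].parent
            if par == m_parent and not stop_below:
                break
            # the sibling branch of `cur` under `par` loses the gene
            for sib in stree.nodes[par].children:
                if sib != cur:
                    loss_counts[stree.nodes[sib].label] += 1
            cur = par
            if cur == m_parent:
                break
    return ReconciliationResult(
        mapping=mapping,
        events=events,
        duplications={k: v for k, v in dup_counts.items() if v},
        losses={k: v for k, v in loss_counts.items() if v},
    )


def minimal_duplication_rooting(
    gtree: GeneTree, stree: Phylogeny
) -> tuple[GeneTree, ReconciliationResult]:
    """Re-root a gene tree to minimize duplications + losses.

    Tries every internal edge of the unrooted topology as the root
    position and reconciles each candidate; returns the best-scoring
    rooted tree and its reconciliation (ties: fewest duplications, then
    first encountered). Off by default in the pipeline — gene trees are
    normally consumed pre-rooted.
    """
    import dendropy

    dtree = dendropy.Tree.get(
        data=gtree.tree.to_newick(), schema="newick",
        preserve_underscores=True,
    )
    species_of = dict(gtree.species_of)
    best: tuple[int, int, GeneTree, ReconciliationResult] | None = None
    for edge in list(dtree.preorder_edge_iter()):
        if edge.tail_node is None:
            continue
        work = dtree.clone(depth=1)
        # find the corresponding edge in the clone by leaf bipartition
        target_leaves = {
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        }
        cand = None
        for e2 in work.preorder_edge_iter():
            if e2.tail_node is None:
                continue
            if {lf.taxon.label for lf in e2.head_node.leaf_iter()} \
                    == target_leaves:
                cand = e2
                break
        if cand is None:
            continue
        work.reroot_at_edge(cand, update_bipartitions=False)
        rooted = GeneTree(
            parse_newick(work.as_string(schema="newick",
                                        suppress_rooting=True)),
            species_of,
        )
        try:
            res = lca_reconcile(rooted, stree)
        except ValueError:
            continue
        score = (res.total_duplications + res.total_losses,
                 res.total_duplications)
        if best is None or score < best[:2]:
            best = (*score, rooted, res)
    if best is None:
        res = lca_reconcile(gtree, stree)
        return gtree, res
    return best[2], best[3]


@dataclass
class AsymmetryTest:
    table: np.ndarray  # rows: parasitic / other, cols: duplication / loss
    expected: np.ndarray
    chi2: float
    p: float
    df: int
    low_expected: bool


def event_asymmetry_test(dup_counts: dict[str, int],
                         loss_counts: dict[str, int],
                         partition: BranchPartition,
                         yates: bool = False) -> AsymmetryTest:
    """Pearson chi-square test of duplication/loss asymmetry between the
    parasitic ("test") branch set and all other branches.

    Builds the 2x2 table [parasitic, other] x [duplications, losses];
    df = 1; Yates continuity correction is off by default. Raises on a
    zero margin (the test is undefined) and flags expected counts < 5.
    """
    def split(counts):
        para = sum(
            v for b, v in counts.items() if partition.classes.get(b) ==
            BranchPartition.TEST
        )
        return para, sum(counts.values()) - para

    dup_p, dup_o = split(dup_counts)
    loss_p, loss_o = split(loss_counts)
    table = np.array([[dup_p, loss_p], [dup_o, loss_o]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square test undefined")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=yates)
    return AsymmetryTest(
        table=table,
        expected=expected,
        chi2=float(chi2),
        p=float(p),
        df=int(df),
        low_expected=bool((expected < 5).any()),
    )
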