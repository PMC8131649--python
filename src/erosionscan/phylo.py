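"""Species-tree data model: rooted phylogenies with branch lengths,
branch-class partitions (e.g. parasite "test" vs free-living "reference"
branch sets), Newick I/O and validation.

Every non-root node defines the branch leading to it, and branches are
addressed by the child node's label. Internal nodes without a Newick label
are assigned deterministic labels ``n1, n2, ...`` in preorder so that branch
partitions can always be written as plain two-column tables.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "Phylogeny",
    "BranchPartition",
    "validate_phylogeny",
    "parse_newick",
    "write_newick",
]


@dataclass
class Node:
    index: int
    label: str
    parent: int | None
    children: list[int] = field(default_factory=list)
    length: float | None = None
    age: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted tree with branch lengths and optional node ages.

    Parameters
    ----------
    nodes:
        Node records; ``nodes[0]`` must be the root.
    unit:
        declared branch-length unit, ``"Ma"`` or ``"subs/site"``.
    """

    def __init__(self, nodes: list[Node], unit: str = "subs/site"):
        self.nodes = nodes
        self.unit = unit
        self._by_label = {n.label: n.index for n in nodes}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, unit: str = "subs/site") -> "Phylogeny":
        return parse_newick(newick, unit=unit)

    @classmethod
    def from_file(cls, path, unit: str = "subs/site") -> "Phylogeny":
        with open(path) as fh:
            return parse_newick(fh.read(), unit=unit)

    # -- topology queries --------------------------------------------------

    @property
    def root(self) -> Node:
        return self.nodes[0]

    def node(self, label: str) -> Node:
        try:
            return self.nodes[self._by_label[label]]
        except KeyError:
            raise KeyError(f"no node labelled {label!r}") from None

    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root.index]
        seen: list[int] = []
        while stack:
            i = stack.pop()
            seen.append(i)
            stack.extend(self.nodes[i].children)
        for i in reversed(seen):
            out.append(self.nodes[i])
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.nodes if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def branches(self) -> list[Node]:
        """Non-root nodes, each standing for the branch above it."""
        return [n for n in self.nodes if n.parent is not None]

    def branch_labels(self) -> list[str]:
        return [n.label for n in self.branches()]

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.branches())

    def mrca(self, labels) -> Node:
        sets = []
        for lab in labels:
            anc = set()
            i = self._by_label[lab]
            while i is not None:
                anc.add(i)
                i = self.nodes[i].parent
            sets.append(anc)
        common = set.intersection(*sets)
        # deepest common ancestor = the one with no child in `common`
        for i in common:
            if not any(c in common for c in self.nodes[i].children):
                return self.nodes[i]
        raise RuntimeError("unreachable")

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        return write_newick(self)

    def copy(self) -> "Phylogeny":
        nodes = [
            Node(n.index, n.label, n.parent, list(n.children), n.length, n.age)
            for n in self.nodes
        ]
        return Phylogeny(nodes, unit=self.unit)


def parse_newick(newick: str, unit: str = "subs/site") -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Raises ``ValueError`` (with the parser's position information) when the
    string is not valid Newick.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy errors carry line/column context
        raise ValueError(f"unparseable Newick tree: {exc}") from exc

    nodes: list[Node] = []
    index_of: dict[int, int] = {}
    counter = 0
    for dnode in dtree.preorder_node_iter():
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        if label is None:
            counter += 1
            label = f"n{counter}"
        parent = None
        if dnode.parent_node is not None:
            parent = index_of[id(dnode.parent_node)]
        idx = len(nodes)
        index_of[id(dnode)] = idx
        length = dnode.edge.length
        nodes.append(Node(idx, label, parent, [], length))
        if parent is not None:
            nodes[parent].children.append(idx)

    labels = [n.label for n in nodes]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate node labels in tree: {dupes}")
    return Phylogeny(nodes, unit=unit)


def write_newick(tree: Phylogeny) -> str:
    """Newick string with branch lengths to 10 significant digits."""

    def render(i: int) -> str:
        n = tree.nodes[i]
        if n.is_leaf:
            s = n.label
        else:
            inner = ",".join(render(c) for c in n.children)
            s = f"({inner}){n.label}"
        if n.length is not None:
            s += f":{n.length:.10g}"
        return s

    return render(tree.root.index) + ";"


@dataclass
class BranchPartition:
    """Assignment of every branch (child-node label) to a named class.

    The classes ``"test"`` and ``"reference"`` are distinguished: "test"
    marks the parasite branch set, "reference" the free-living set.
    """

    classes: dict[str, str]

    TEST = "test"
    REFERENCE = "reference"

    def branch_class(self, label: str) -> str:
        return self.classes[label]

    def branches_in(self, cls: str) -> list[str]:
        return [b for b, c in self.classes.items() if c == cls]

    @property
    def test_branches(self) -> list[str]:
        return self.branches_in(self.TEST)

    @property
    def reference_branches(self) -> list[str]:
        return self.branches_in(self.REFERENCE)

    def is_test(self, label: str) -> bool:
        return self.classes.get(label) == self.TEST

    @classmethod
    def from_tsv(cls, path_or_buf) -> "BranchPartition":
        close = False
        if isinstance(path_or_buf, (str, bytes, os.PathLike)):
            fh = open(path_or_buf)
            close = True
        else:
            fh = path_or_buf
        try:
            classes: dict[str, str] = {}
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                branch, klass = line.split("\t")[:2]
                classes[branch] = klass
            return cls(classes)
        finally:
            if close:
                fh.close()

    def to_tsv(self, path_or_buf=None) -> str | None:
        buf = io.StringIO()
        for branch, klass in self.classes.items():
            buf.write(f"{branch}\t{klass}\n")
        text = buf.getvalue()
        if path_or_buf is None:
            return text
        if isinstance(path_or_buf, (str, bytes, os.PathLike)):
            with open(path_or_buf, "w") as fh:
                fh.write(text)
        else:
            path_or_buf.write(text)
        return None


def validate_phylogeny(
    tree: Phylogeny, partition: BranchPartition | None = None
) -> list[str]:
    """Check the tree (and optionally a branch partition) invariants.

    Returns a list of human-readable violations; an empty list means every
    invariant holds. Each entry names the offending node or branch.
    """
    report: list[str] = []

    roots = [n for n in tree.nodes if n.parent is None]
    if len(roots) != 1:
        report.append(f"expected exactly one root, found {len(roots)}")

    labels = [n.label for n in tree.leaves()]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            report.append(f"duplicate leaf label: {lab}")
        seen.add(lab)

    for n in tree.branches():
        if n.length is not None and n.length < 0:
            report.append(f"negative branch length on branch {n.label}")

    ages = [n for n in tree.nodes if n.age is not None]
    if ages:
        for n in tree.nodes:
            if n.parent is None or n.age is None:
                continue
            parent = tree.nodes[n.parent]
            if parent.age is not None and not parent.age > n.age:
                report.append(
                    f"age of {parent.label} ({parent.age}) not greater than "
                    f"age of child {n.label} ({n.age})"
                )

    if partition is not None:
        branch_labels = set(tree.branch_labels())
        for b in branch_labels:
            if b not in partition.classes:
                report.append(f"branch {b} missing from partition")
        for b in partition.classes:
            if b not in branch_labels:
                report.append(f"partition names unknown branch {b}")
        for b, c in partition.classes.items():
            if not c:
                report.append(f"empty class name for branch {b}")
    return report
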