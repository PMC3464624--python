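"""Phylogenies whose branches carry class labels.

A :class:`LabeledTree` is a rooted tree with branch lengths and a class label
on every branch (e.g. ``within`` / ``between``, or ``background`` /
``foreground``).  Labels drive the branch-class and branch-site codon models
and the branch-class simulator.  Newick I/O supports PAML-style ``#label``
suffixes on node names and an optional external label mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

DEFAULT_LABEL = "background"


@dataclass
class _Node:
    name: str | None
    parent: int  # -1 for root
    length: float
    label: str
    children: list = field(default_factory=list)


class LabeledTree:
    """Rooted tree with branch lengths and per-branch class labels."""

    def __init__(self):
        self.nodes: list[_Node] = []

    # -- construction -----------------------------------------------------
    def add_node(self, name=None, parent=-1, length=0.0, label=DEFAULT_LABEL) -> int:
        if length < 0:
            raise ValueError("branch lengths must be >= 0")
        idx = len(self.nodes)
        self.nodes.append(_Node(name=name, parent=parent, length=float(length), label=label))
        if parent >= 0:
            self.nodes[parent].children.append(idx)
        return idx

    # -- queries ----------------------------------------------------------
    @property
    def root(self) -> int:
        return 0

    def is_leaf(self, idx: int) -> bool:
        return not self.nodes[idx].children

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(len(self.nodes)) if self.is_leaf(i)]

    @property
    def leaf_names(self) -> list[str]:
        return [self.nodes[i].name for i in self.leaves]

    @property
    def branch_labels(self) -> set:
        return {n.label for i, n in enumerate(self.nodes) if i != self.root}

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.nodes[node].children)
        return order[::-1]

    def total_length(self) -> float:
        return sum(n.length for i, n in enumerate(self.nodes) if i != self.root)

    def copy(self) -> "LabeledTree":
        t = LabeledTree()
        for n in self.nodes:
            t.nodes.append(_Node(n.name, n.parent, n.length, n.label, list(n.children)))
        return t

    def set_lengths(self, lengths: dict[int, float]) -> None:
        for idx, ln in lengths.items():
            if ln < 0:
                raise ValueError("branch lengths must be >= 0")
            self.nodes[idx].length = float(ln)

    def validate(self) -> None:
        seen = set()
        for i, n in enumerate(self.nodes):
            if i == self.root:
                continue
            if n.parent < 0 or n.parent >= len(self.nodes):
                raise ValueError(f"node {i} has invalid parent")
            if self.is_leaf(i):
                if not n.name:
                    raise ValueError(f"leaf {i} has no name")
                if n.name in seen:
                    raise ValueError(f"duplicate leaf name {n.name!r}")
                seen.add(n.name)

    # -- newick I/O --------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, labels: dict | None = None,
                    default_label: str = DEFAULT_LABEL) -> "LabeledTree":
        """Parse a newick string.

        Branch labels are read from (in order of precedence) the ``labels``
        mapping keyed by node/leaf name, or a ``#label`` suffix on the node
        name (PAML style, e.g. ``taxon1#within``); unlabeled branches get
        ``default_label``.
        """
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick",
                                   suppress_internal_node_taxa=True)
        except Exception as e:  # noqa: BLE001 - normalize parser errors
            raise ValueError(f"could not parse newick: {e}") from e
        tree = cls()
        index = {}

        def node_name(nd):
            if nd.taxon is not None:
                return nd.taxon.label
            return nd.label

        for nd in dt.preorder_node_iter():
            raw = node_name(nd)
            label = default_label
            name = raw
            if raw and "#" in raw:
                name, _, label = raw.partition("#")
                name = name or None
            if labels and name in labels:
                label = labels[name]
            parent = index[id(nd.parent_node)] if nd.parent_node is not None else -1
            ln = nd.edge.length if nd.edge.length is not None else 0.0
            index[id(nd)] = tree.add_node(name=name, parent=parent,
                                          length=ln, label=label)
        tree.validate()
        return tree

    def to_newick(self, include_labels: bool = True) -> str:
        def render(idx: int) -> str:
            n = self.nodes[idx]
            if self.is_leaf(idx):
                base = n.name or ""
            else:
                base = "(" + ",".join(render(c) for c in n.children) + ")"
                base += n.name or ""
            if idx == self.root:
                return base
            if include_labels and n.label != DEFAULT_LABEL:
                base += f"#{n.label}"
            return f"{base}:{n.length:.10g}"

        return render(self.root) + ";"
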