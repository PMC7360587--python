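"""Species trees with named clade and branch labels.

A :class:`SpeciesTree` wraps a rooted topology (parsed with dendropy) and a
set of labels: *clade* labels name a monophyletic tip set and refer to every
edge inside that crown group; *branch* labels name a single internal edge
(the stem of a clade). Labels drive the mapping of tree edges to dN/dS
classes in branch models, and the placement of gene-loss events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import yaml


class TreeLabelError(ValueError):
    """A clade/branch label does not identify a valid (monophyletic) group."""


@dataclass
class SpeciesTree:
    """Rooted species tree with clade/branch labels.

    Internal representation: nodes in postorder (root last); edge *i* is the
    edge above node *i* (the root carries no edge). Branch lengths are
    expected substitutions per codon site.
    """

    taxa: list[str]
    parent: list[int]                 # parent[i] = parent node id; root -> -1
    children: list[list[int]]
    lengths: list[float]              # length of edge above node i (root: 0)
    node_taxon: list[str | None]      # tip name, or None for internal nodes
    clade_labels: dict[str, frozenset[str]] = field(default_factory=dict)
    branch_labels: dict[str, frozenset[str]] = field(default_factory=dict)

    # ------------------------------------------------------------------ build
    @classmethod
    def from_newick_string(
        cls,
        newick: str,
        clade_labels: dict[str, list[str]] | None = None,
        branch_labels: dict[str, list[str]] | None = None,
        default_length: float = 0.1,
    ) -> "SpeciesTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  preserve_underscores=True)
        nodes = list(dtree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent, children, lengths, node_taxon = [], [], [], []
        for n in nodes:
            parent.append(index[id(n.parent_node)] if n.parent_node else -1)
            children.append([index[id(c)] for c in n.child_nodes()])
            ln = n.edge.length
            lengths.append(float(ln) if ln is not None else
                           (0.0 if n.parent_node is None else default_length))
            node_taxon.append(n.taxon.label if n.taxon else None)
        taxa = [t for t in node_taxon if t is not None]
        if len(set(taxa)) != len(taxa):
            raise TreeLabelError("duplicate tip names in tree")
        tree = cls(taxa=taxa, parent=parent, children=children,
                   lengths=lengths, node_taxon=node_taxon)
        for label, tips in (clade_labels or {}).items():
            tree.add_clade_label(label, tips)
        for label, tips in (branch_labels or {}).items():
            tree.add_branch_label(label, tips)
        return tree

    # ------------------------------------------------------------- structure
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    def tip_node(self, name: str) -> int:
        for i, t in enumerate(self.node_taxon):
            if t == name:
                return i
        raise KeyError(f"tip '{name}' not in tree")

    def subtree_tips(self, node: int) -> frozenset[str]:
        out: list[str] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.node_taxon[v] is not None:
                out.append(self.node_taxon[v])
            stack.extend(self.children[v])
        return frozenset(out)

    def subtree_nodes(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out

    def mrca(self, tips: frozenset[str] | set[str]) -> int:
        tips = frozenset(tips)
        unknown = tips - set(self.taxa)
        if unknown:
            raise TreeLabelError(f"tips not in tree: {sorted(unknown)}")
        # deepest postorder node whose subtree contains all of `tips`
        for v in range(self.n_nodes):
            if tips <= self.subtree_tips(v):
                return v
        return self.root

    # ---------------------------------------------------------------- labels
    def add_clade_label(self, label: str, tips: list[str] | set[str]) -> None:
        tips = frozenset(tips)
        m = self.mrca(tips)
        covered = self.subtree_tips(m)
        if covered != tips:
            raise TreeLabelError(
                f"clade label '{label}' is not monophyletic: MRCA also "
                f"contains {sorted(covered - tips)}"
            )
        self._check_disjoint(label, self._clade_edges(m))
        self.clade_labels[label] = tips

    def add_branch_label(self, label: str, tips: list[str] | set[str]) -> None:
        tips = frozenset(tips)
        m = self.mrca(tips)
        if self.subtree_tips(m) != tips:
            raise TreeLabelError(
                f"branch label '{label}' does not match any edge: no node "
                f"subtends exactly {sorted(tips)}"
            )
        if m == self.root:
            raise TreeLabelError(f"branch label '{label}' names the root")
        self._check_disjoint(label, {m})
        self.branch_labels[label] = tips

    def _clade_edges(self, mrca_node: int) -> set[int]:
        return {v for v in self.subtree_nodes(mrca_node) if v != mrca_node}

    def label_edges(self, label: str) -> set[int]:
        """Edge ids (child-node ids) referred to by a clade or branch label."""
        if label in self.clade_labels:
            return self._clade_edges(self.mrca(self.clade_labels[label]))
        if label in self.branch_labels:
            return {self.mrca(self.branch_labels[label])}
        raise KeyError(f"unknown label '{label}'")

    def _check_disjoint(self, label: str, edges: set[int]) -> None:
        for other in list(self.clade_labels) + list(self.branch_labels):
            if other == label:
                continue
            overlap = self.label_edges(other) & edges
            if overlap:
                raise TreeLabelError(
                    f"label '{label}' overlaps edges of label '{other}'"
                )

    # --------------------------------------------------------------- export
    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if not self.children[v]:
                name = self.node_taxon[v] or ""
                return f"{name}:{self.lengths[v]:g}"
            inner = ",".join(fmt(c) for c in self.children[v])
            if v == self.root:
                return f"({inner});"
            return f"({inner}):{self.lengths[v]:g}"

        return fmt(self.root)


def read_labeled_tree(newick_path: str | Path,
                      labels_path: str | Path | None = None) -> SpeciesTree:
    """Read a Newick tree plus an optional YAML label file.

    The label file maps names to tip lists under two keys::

        clades:   {A1: [seal_a, seal_b], ...}
        branches: {BranchA1: [seal_a, seal_b], ...}

    Clade monophyly is verified; a branch label must identify exactly one
    edge (the one subtending the listed tips).
    """
    newick = Path(newick_path).read_text()
    clades: dict[str, list[str]] = {}
    branches: dict[str, list[str]] = {}
    if labels_path is not None:
        spec = yaml.safe_load(Path(labels_path).read_text()) or {}
        clades = spec.get("clades", {}) or {}
        branches = spec.get("branches", {}) or {}
    return SpeciesTree.from_newick_string(newick, clades, branches)
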