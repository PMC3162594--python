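"""PhyloTree: a thin validated wrapper around a dendropy tree.

Branch lengths are in substitutions/site. A tree is either unrooted
(as read from Newick) or rooted by ``root_on_clade``; root-to-tip
queries require a rooted tree.
"""

from __future__ import annotations

import dendropy

from .model import ValidationError


class PhyloTree:
    def __init__(self, tree: dendropy.Tree, rooted: bool = False):
        self._tree = tree
        self.rooted = rooted
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick_file(cls, path: str) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises several parse errors
            raise ValidationError(f"Newick parse error: {exc}") from exc
        return cls(tree, rooted=False)

    def _validate(self) -> None:
        names = self.leaf_names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate leaf names: {dupes}")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.edge.length is None:
                raise ValidationError(
                    "missing branch length on an edge "
                    f"(above {'leaf ' + node.taxon.label if node.taxon else 'an internal node'})")
            if node.edge.length < 0:
                raise ValidationError("negative branch length")

    # -- queries ----------------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def branch_length_of(self, leaf_name: str) -> float:
        for lf in self._tree.leaf_node_iter():
            if lf.taxon.label == leaf_name:
                return lf.edge.length
        raise KeyError(leaf_name)

    def leaf_pair_distances(self) -> dict[frozenset, float]:
        """All-pairs leaf path lengths (rooting-invariant)."""
        pdm = self._tree.phylogenetic_distance_matrix()
        out = {}
        taxa = list(self._tree.taxon_namespace)
        for i, t1 in enumerate(taxa):
            for t2 in taxa[i + 1:]:
                out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
        return out

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick",
                                    suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def copy(self) -> "PhyloTree":
        cloned = self._tree.clone(depth=1)
        # give the clone its own namespace so pruning cannot leak back
        cloned.migrate_taxon_namespace(dendropy.TaxonNamespace())
        return PhyloTree(cloned, rooted=self.rooted)
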