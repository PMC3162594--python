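"""Fast-evolving-taxon removal: outgroup rooting, root-to-tip distances,
distance-sorted ranking, and pruning.

Root-to-tip distance — the sum of branch lengths from the root to a leaf —
is a proxy for a lineage's evolutionary rate; removing the largest-distance
taxa is a standard guard against long-branch attraction. The root is placed
at the midpoint of the edge subtending the designated outgroup clade; any
other split point shifts every distance by the same offset, so the ranking
(the procedure's actual product) is offset-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ValidationError
from .tree import PhyloTree


@dataclass
class DistanceRanking:
    """(taxon, root-to-tip distance) pairs, descending; ties alphabetical."""

    entries: list[tuple[str, float]]

    def taxa(self) -> list[str]:
        return [t for t, _ in self.entries]

    def distance_of(self, taxon: str) -> float:
        for t, d in self.entries:
            if t == taxon:
                return d
        raise KeyError(taxon)


def root_on_clade(tree: PhyloTree, clade_taxa: set[str],
                  offset: float = 0.5) -> PhyloTree:
    """Root on the edge subtending a monophyletic clade.

    ``offset`` is the fraction of the subtending edge placed on the clade
    side of the root (default: midpoint). Leaf-pair path lengths are
    unchanged by rooting.
    """
    clade_taxa = set(clade_taxa)
    leaves = set(tree.leaf_names)
    unknown = clade_taxa - leaves
    if unknown:
        raise ValidationError(f"unknown taxa: {sorted(unknown)}")
    if not (0.0 <= offset <= 1.0):
        raise ValueError("offset must be in [0,1]")

    work = tree.copy()
    dt = work._tree
    if len(dt.seed_node.child_nodes()) == 2:
        # canonicalize to the unrooted shape so the basal bifurcation's
        # two half-edges act as the single edge they represent
        dt.deroot()
    target = None
    complement_target = None
    for node in dt.preorder_node_iter():
        if node is dt.seed_node:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == clade_taxa:
            target = node
            break
        if complement_target is None and (leaves - below) == clade_taxa:
            complement_target = node
    if target is None:
        target = complement_target
    if target is None:
        # name the smallest subtree that contains the clade, for the error
        mrca = dt.mrca(taxon_labels=sorted(clade_taxa))
        extra = sorted({lf.taxon.label for lf in mrca.leaf_iter()}
                       - clade_taxa)
        raise ValidationError(
            f"clade {sorted(clade_taxa)} is not monophyletic; its smallest "
            f"containing subtree also holds {extra}")

    edge_len = target.edge.length
    clade_side_is_below = ({lf.taxon.label for lf in target.leaf_iter()}
                           == clade_taxa)
    if clade_side_is_below:
        len_below = offset * edge_len
    else:
        len_below = (1.0 - offset) * edge_len
    dt.reroot_at_edge(target.edge, length1=edge_len - len_below,
                      length2=len_below,
                      suppress_unifurcations=True)
    # reroot_at_edge leaves the old seed node's stale edge state behind in
    # some topologies; rebuild bipartitions lazily by touching nothing else.
    dt.seed_node.edge.length = None
    return PhyloTree(dt, rooted=True)


def root_to_tip_distances(tree: PhyloTree) -> DistanceRanking:
    """Path length from the root to every leaf, ranked descending."""
    if not tree.rooted:
        raise ValidationError("root_to_tip_distances requires a rooted tree")
    dt = tree._tree
    dist: dict[str, float] = {}
    stack = [(dt.seed_node, 0.0)]
    while stack:
        node, d = stack.pop()
        if node.is_leaf():
            dist[node.taxon.label] = d
        for ch in node.child_nodes():
            stack.append((ch, d + (ch.edge.length or 0.0)))
    entries = sorted(dist.items(), key=lambda kv: (-kv[1], kv[0]))
    return DistanceRanking(entries)


def remove_fast_taxa(tree: PhyloTree, k: int | None = None,
                     names: list[str] | None = None,
                     keep: set[str] | None = None
                     ) -> tuple[list[str], PhyloTree]:
    """Remove the k largest-distance taxa (exempting ``keep``), or exactly
    the named taxa. Returns (removed names, pruned tree); degree-2 nodes
    created by pruning are suppressed with branch lengths summed, so
    survivor pairwise path lengths are unchanged.
    """
    if (k is None) == (names is None):
        raise ValueError("specify exactly one of k or names")
    leaves = set(tree.leaf_names)
    keep = set(keep or ())
    if names is not None:
        unknown = set(names) - leaves
        if unknown:
            raise ValidationError(f"unknown taxa: {sorted(unknown)}")
        to_remove = list(names)
    else:
        if k >= tree.n_leaves:
            raise ValueError("k must be smaller than the leaf count")
        ranking = root_to_tip_distances(tree)
        to_remove = [t for t in ranking.taxa() if t not in keep][:k]
    work = tree.copy()
    work._tree.prune_taxa_with_labels(to_remove,
                                      suppress_unifurcations=True)
    work._tree.purge_taxon_namespace()
    return to_remove, PhyloTree(work._tree, rooted=tree.rooted)
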