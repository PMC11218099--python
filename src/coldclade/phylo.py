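"""Species-tree handling: outgroup rooting, deterministic sorting, clade queries.

The contrast design needs two baselines per focal group: all non-polar
genomes, and the focal group's *clade neighbours* — the non-focal
ingroup leaves of the smallest clade above the focal group's MRCA that
contains any.  Everything here is deterministic so that a given newick
plus group table always yields the same sorted tree and neighbour sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

__all__ = [
    "GroupedPhylogeny",
    "CladeNeighbourSet",
    "read_newick",
    "root_with_outgroup",
    "ladderize_increasing",
    "is_monophyletic",
    "clade_neighbours",
    "leafset_bipartitions",
    "read_groups",
]


def read_newick(path_or_string, from_string: bool = False) -> dendropy.Tree:
    kwargs = dict(schema="newick", preserve_underscores=True)
    if from_string:
        return dendropy.Tree.get(data=path_or_string, **kwargs)
    return dendropy.Tree.get(path=str(path_or_string), **kwargs)


def _leaf_labels(node) -> set[str]:
    return {leaf.taxon.label for leaf in node.leaf_iter()}


def _check_known(tree: dendropy.Tree, ids) -> None:
    known = {t.label for t in tree.taxon_namespace}
    unknown = sorted(set(ids) - known)
    if unknown:
        raise ValueError(f"leaf ids not in tree: {unknown}")


def _mrca(tree: dendropy.Tree, labels: set[str]):
    """Most recent common ancestor by postorder leaf-set scan.

    dendropy's own ``mrca`` encodes bipartitions and, on a tree it takes
    to be unrooted, collapses the basal bifurcation as a side effect;
    this traversal leaves the tree untouched.
    """
    best = None
    leafsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = {node.taxon.label}
        else:
            leafsets[node] = set().union(*(leafsets[k] for k in node.child_nodes()))
        if labels <= leafsets[node]:
            if best is None or len(leafsets[node]) < len(leafsets[best]):
                best = node
    return best


def root_with_outgroup(tree: dendropy.Tree, outgroup_ids: list[str]) -> dendropy.Tree:
    """Root on the branch separating the outgroup from the ingroup.

    The outgroup must form a split of the unrooted tree (monophyletic in
    the unrooted sense) or be a single leaf.  The split branch length is
    apportioned equally to the two daughter edges of the new root.  The
    input tree is not modified.
    """
    if not outgroup_ids:
        raise ValueError("empty outgroup")
    _check_known(tree, outgroup_ids)
    work = tree.clone(depth=1)
    tns = work.taxon_namespace
    og_mask = tns.taxa_bitmask(labels=list(outgroup_ids))
    full_mask = tns.all_taxa_bitmask()
    work.encode_bipartitions()
    target = None
    for edge in work.preorder_edge_iter():
        if edge.head_node is work.seed_node:
            continue
        m = edge.bipartition.leafset_bitmask
        if m == og_mask or m == (full_mask ^ og_mask):
            target = edge
            break
    if target is None:
        raise ValueError(
            f"outgroup not monophyletic in the unrooted tree: {sorted(outgroup_ids)}"
        )
    if target.length is not None:
        work.reroot_at_edge(target, length1=target.length / 2.0, length2=target.length / 2.0)
    else:
        work.reroot_at_edge(target)
    work.is_rooted = True
    return work


def ladderize_increasing(tree: dendropy.Tree) -> dendropy.Tree:
    """Sort children at every node by increasing subtree leaf count.

    Ties break to the clade containing the lexicographically smallest
    leaf label, so repeated application is a fixed point.  Returns the
    same tree object, sorted in place.
    """
    size: dict = {}
    smallest: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            size[node] = 1
            smallest[node] = node.taxon.label
        else:
            kids = node.child_nodes()
            size[node] = sum(size[k] for k in kids)
            smallest[node] = min(smallest[k] for k in kids)
            node.set_child_nodes(sorted(kids, key=lambda k: (size[k], smallest[k])))
    return tree


def is_monophyletic(tree: dendropy.Tree, leaf_ids) -> bool:
    """True iff the MRCA of ``leaf_ids`` contains exactly those leaves."""
    leaf_ids = set(leaf_ids)
    if not leaf_ids:
        raise ValueError("empty leaf set")
    _check_known(tree, leaf_ids)
    return _leaf_labels(_mrca(tree, leaf_ids)) == leaf_ids


@dataclass
class CladeNeighbourSet:
    """Non-focal ingroup leaves of the smallest clade enclosing a group."""

    focal_group: str
    neighbour_ids: list[str]
    clade_size: int
    none_found: bool = False


def clade_neighbours(
    tree: dendropy.Tree,
    focal_ids,
    focal_group: str = "",
    outgroup_ids=(),
    min_neighbours: int = 1,
    override: list[str] | None = None,
) -> CladeNeighbourSet:
    """Walk from the focal MRCA toward the root until enough neighbours appear.

    ``override`` pins an explicit neighbour list (used to reproduce
    hand-enumerated baselines) and bypasses the walk entirely.
    """
    focal = set(focal_ids)
    if not focal:
        raise ValueError("empty focal set")
    _check_known(tree, focal)
    if override is not None:
        _check_known(tree, override)
        clash = sorted(set(override) & focal)
        if clash:
            raise ValueError(f"override neighbours intersect focal group: {clash}")
        return CladeNeighbourSet(focal_group, sorted(override), len(focal) + len(override))
    excluded = focal | set(outgroup_ids)
    node = _mrca(tree, focal)
    while node is not None:
        leaves = _leaf_labels(node)
        neighbours = leaves - excluded
        if len(neighbours) >= min_neighbours:
            return CladeNeighbourSet(focal_group, sorted(neighbours), len(leaves))
        node = node.parent_node
    return CladeNeighbourSet(focal_group, [], 0, none_found=True)


def leafset_bipartitions(tree: dendropy.Tree, restrict: set[str] | None = None) -> set[frozenset]:
    """Unrooted bipartitions as frozensets of leaf labels (smaller side kept).

    With ``restrict``, leaf sets are intersected with the given labels
    first; trivial (empty / single / full) splits are dropped.  Used to
    compare topologies irrespective of rooting or child order.
    """
    # actual leaves, not the taxon namespace: pruned taxa linger in the latter
    all_leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if restrict is not None:
        all_leaves &= set(restrict)
    out: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter():
        side = _leaf_labels(node)
        if restrict is not None:
            side &= set(restrict)
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(frozenset(side), frozenset(other), key=lambda s: (len(s), sorted(s))))
    return out


@dataclass
class GroupedPhylogeny:
    """Rooted, sorted species tree plus the genome -> group assignment."""

    tree: dendropy.Tree
    groups: dict[str, str]
    outgroup_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        leaves = {t.label for t in self.tree.taxon_namespace}
        missing = sorted(leaves - set(self.groups))
        if missing:
            raise ValueError(f"leaves without a group label: {missing}")
        if not self.outgroup_ids:
            self.outgroup_ids = sorted(g for g, lab in self.groups.items() if lab == "outgroup")

    @classmethod
    def load(cls, newick_path, groups_path, root: bool = True, sort: bool = True) -> "GroupedPhylogeny":
        tree = read_newick(newick_path)
        groups = read_groups(groups_path)
        obj = cls(tree=tree, groups=groups)
        if root and obj.outgroup_ids:
            obj.tree = root_with_outgroup(obj.tree, obj.outgroup_ids)
        if sort:
            ladderize_increasing(obj.tree)
        return obj

    def members(self, group_label: str) -> list[str]:
        return sorted(g for g, lab in self.groups.items() if lab == group_label)

    @property
    def ingroup_ids(self) -> list[str]:
        return sorted(g for g in self.groups if g not in set(self.outgroup_ids))

    def neighbours_of(
        self, group_label: str, min_neighbours: int = 1, override: list[str] | None = None
    ) -> CladeNeighbourSet:
        return clade_neighbours(
            self.tree,
            self.members(group_label),
            focal_group=group_label,
            outgroup_ids=self.outgroup_ids,
            min_neighbours=min_neighbours,
            override=override,
        )


def read_groups(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"genome_id", "group_label"} <= set(df.columns):
        raise ValueError("groups TSV needs genome_id and group_label columns")
    return dict(zip(df["genome_id"], df["group_label"]))
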