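"""Phylogeny preparation: Newick parsing, grafting, correlation matrices.

Comparative analyses here require (i) a rooted ultrametric tree whose tips
cover every analysis taxon, and (ii) the phylogenetic correlation matrix A
derived from it, used as the covariance structure of the phylogenetic random
effect.  Taxa missing from the source tree are grafted onto the most recent
common ancestor (MRCA) of their genus or, failing that, their family, with
pendant branch lengths chosen to keep the tree ultrametric.

Trees are `dendropy.Tree` objects throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .errors import TreeError, UnresolvableTaxonError

#: Relative tolerance for the ultrametricity invariant: all root-to-tip path
#: lengths must agree within ULTRAMETRIC_RTOL * tree height.
ULTRAMETRIC_RTOL = 1e-8


@dataclass
class RankMap:
    """taxon -> (genus, family) lookup, total over analysis taxa.

    Genus falls back to the first whitespace-separated token of the binomial
    when a taxon has no explicit entry; family has no fallback.
    """

    entries: dict[str, tuple[str, str | None]]

    def genus(self, taxon: str) -> str:
        if taxon in self.entries:
            return self.entries[taxon][0]
        return taxon.split()[0]

    def family(self, taxon: str) -> str | None:
        if taxon in self.entries:
            return self.entries[taxon][1]
        return None


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick string with branch lengths.

    Raises TreeError on malformed input.  Non-ultrametric trees parse
    fine (and are flagged by `is_ultrametric`), they are never silently
    corrected here.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"Newick parse error: {exc}") from exc
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate tip labels")
    tree.is_rooted = True
    return tree


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}


def tree_height(tree: dendropy.Tree) -> float:
    return max(tip_depths(tree).values())


def is_ultrametric(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> bool:
    depths = np.array(list(tip_depths(tree).values()))
    height = depths.max()
    if height <= 0:
        return False
    return bool((height - depths.min()) <= rtol * height)


def repair_ultrametric(tree: dendropy.Tree) -> dendropy.Tree:
    """Extend every tip's pendant edge to the maximum root-to-tip depth.

    Only for small rounding violations in a source tree; must be requested
    explicitly.
    """
    tree.calc_node_root_distances()
    height = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + (height - leaf.root_distance)
    return tree


def _tip_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def _mrca(nodes: list[dendropy.Node]) -> dendropy.Node:
    # robust against tree mutation (no reliance on cached bipartitions)
    ancestor_sets = []
    for node in nodes:
        seen = set()
        n = node
        while n is not None:
            seen.add(id(n))
            n = n.parent_node
        ancestor_sets.append(seen)
    common = set.intersection(*ancestor_sets)
    n = nodes[0]
    while id(n) not in common:
        n = n.parent_node
    return n


def _attach_at_node(
    tree: dendropy.Tree, node: dendropy.Node, label: str, pendant: float
) -> None:
    taxon = tree.taxon_namespace.new_taxon(label=label)
    node.new_child(taxon=taxon, edge_length=pendant)


def _attach_to_single_tip(
    tree: dendropy.Tree, tip: dendropy.Node, label: str
) -> None:
    # The MRCA of a single-member genus is undefined; insert a new node at
    # the midpoint of the existing tip's pendant edge and hang both tips
    # from it, preserving ultrametricity.
    parent = tip.parent_node
    length = tip.edge.length
    if parent is None or length is None or length <= 0:
        raise TreeError(f"cannot split pendant edge of {tip.taxon.label!r}")
    half = length / 2.0
    new_node = dendropy.Node(edge_length=half)
    parent.remove_child(tip)
    parent.add_child(new_node)
    tip.edge.length = half
    new_node.add_child(tip)
    taxon = tree.taxon_namespace.new_taxon(label=label)
    new_node.new_child(taxon=taxon, edge_length=half)


def graft_missing_taxa(
    tree: dendropy.Tree, wanted: list[str], ranks: RankMap
) -> dendropy.Tree:
    """Graft every missing wanted taxon onto the tree; return a new tree.

    Attachment point is the MRCA of tips sharing the taxon's genus;
    if the genus is absent, the MRCA of its family (from ``ranks``).  The
    pendant branch length is tree height minus the attachment node's depth,
    so the output stays ultrametric.  Taxa already present are left alone.
    Grafts are processed in order, so an earlier graft can anchor a later
    congener.
    """
    if not is_ultrametric(tree):
        raise TreeError("graft requires an ultrametric input tree")
    tree = tree.clone(depth=1)
    height = tree_height(tree)

    for taxon in wanted:
        tips = _tip_map(tree)
        if taxon in tips:
            continue
        genus = ranks.genus(taxon)
        members = [
            t for label, t in tips.items() if ranks.genus(label) == genus
        ]
        if not members:
            family = ranks.family(taxon)
            if family is not None:
                members = [
                    t for label, t in tips.items() if ranks.family(label) == family
                ]
        if not members:
            raise UnresolvableTaxonError(
                f"taxon {taxon!r}: genus {genus!r} and family "
                f"{ranks.family(taxon)!r} both absent from tree"
            )
        if len(members) == 1:
            _attach_to_single_tip(tree, members[0], taxon)
        else:
            node = _mrca(members)
            tree.calc_node_root_distances()
            pendant = height - node.root_distance
            if pendant <= 0:
                raise TreeError(f"degenerate attachment depth for {taxon!r}")
            _attach_at_node(tree, node, taxon, pendant)
    return tree


@dataclass
class CorrelationMatrix:
    """Phylogenetic correlation among an ordered list of taxa.

    values[i, j] is the shared root-to-MRCA path length of taxa i and j
    divided by tree height; the diagonal is exactly 1.  Symmetric, entries
    in [0, 1], positive semi-definite.
    """

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise TreeError("correlation matrix shape mismatch")

    def reindex(self, taxa: list[str]) -> "CorrelationMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return CorrelationMatrix(list(taxa), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def write(self, path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index_label="taxon")

    @classmethod
    def read(cls, path, sep: str = ",") -> "CorrelationMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(list(df.columns), df.to_numpy())


def phylo_correlation(tree: dendropy.Tree, taxa: list[str]) -> CorrelationMatrix:
    """Correlation matrix for ``taxa`` (all must be tips) from an ultrametric tree.

    Computed in one postorder pass: a pair's correlation is the depth of its
    MRCA divided by tree height.  Scale-invariant in the branch lengths.
    """
    tips = _tip_map(tree)
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise TreeError(f"taxa not found as tips: {missing}")
    tree.calc_node_root_distances()
    height = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    if height <= 0:
        raise TreeError("tree height must be positive")

    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    A = np.zeros((n, n))
    # postorder: each internal node contributes its depth as the correlation
    # of tip pairs split across its children
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            below[id(node)] = [index[label]] if label in index else []
            continue
        groups = [below.pop(id(ch)) for ch in node.child_nodes()]
        depth = node.root_distance
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        A[a, b] = A[b, a] = depth / height
        below[id(node)] = [i for g in groups for i in g]
    np.fill_diagonal(A, 1.0)
    return CorrelationMatrix(list(taxa), A)
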