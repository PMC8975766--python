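"""Thin helpers over dendropy trees.

All trees in this package are rooted dendropy.Tree objects whose branch
lengths are either in millions of years ("Myr") or expected substitutions
per site ("subs/site").  The unit is carried as an annotation on the tree
object so that downstream code can refuse to mix them.
"""

from __future__ import annotations

import io

import dendropy

UNITS = ("Myr", "subs/site")


class NewickError(ValueError):
    """Raised for malformed Newick input or trees violating invariants."""


def parse_newick(
    text: str,
    units: str = "Myr",
    allow_missing_lengths: bool = False,
) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree with validated branch lengths.

    Parameters
    ----------
    text : str
        Newick description of a single tree.
    units : str
        Declared branch-length unit, ``"Myr"`` or ``"subs/site"``.
    allow_missing_lengths : bool
        If True, edges without a stated length are assigned 0 instead of
        raising.

    Raises
    ------
    NewickError
        On syntax errors, duplicate tip labels, negative branch lengths or
        (unless allowed) missing branch lengths.
    """
    if units not in UNITS:
        raise ValueError(f"units must be one of {UNITS}, got {units!r}")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickError(f"malformed Newick: {exc}") from exc

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        seen, dups = set(), set()
        for lab in labels:
            (dups if lab in seen else seen).add(lab)
        raise NewickError(f"duplicate tip labels: {sorted(dups)}")

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            if node.edge.length is None:
                node.edge.length = 0.0
            continue
        if node.edge.length is None:
            if allow_missing_lengths:
                node.edge.length = 0.0
            else:
                raise NewickError(
                    f"missing branch length above {describe_node(node)}"
                )
        if node.edge.length < 0:
            raise NewickError(
                f"negative branch length ({node.edge.length}) above "
                f"{describe_node(node)}"
            )
    tree.units = units
    return tree


def read_newick(path, units: str = "Myr", **kw) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read(), units=units, **kw)


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialise a tree to Newick; writes to *path* if given."""
    text = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def describe_node(node) -> str:
    if node.taxon is not None:
        return f"tip {node.taxon.label!r}"
    return f"internal node with {len(node.leaf_nodes())} descendant tips"


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the left-to-right order of the written tree (preorder)."""
    return [
        nd.taxon.label for nd in tree.preorder_node_iter() if nd.is_leaf()
    ]


def leaf_map(tree: dendropy.Tree) -> dict:
    return {nd.taxon.label: nd for nd in tree.leaf_node_iter()}


def cached_leaf_map(tree: dendropy.Tree) -> dict:
    """Leaf map memoised on the tree object.  Only safe on trees whose
    topology is no longer being edited."""
    cache = getattr(tree, "_divrates_leaf_cache", None)
    if cache is None:
        cache = leaf_map(tree)
        tree._divrates_leaf_cache = cache
    return cache


def node_depths(tree: dendropy.Tree) -> dict:
    """Distance from root to each node, keyed by node object."""
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    depths = node_depths(tree)
    return max(depths[nd] for nd in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = node_depths(tree)
    tip_depths = [depths[nd] for nd in tree.leaf_node_iter()]
    hi = max(tip_depths)
    if hi == 0:
        return True
    return (hi - min(tip_depths)) <= rel_tol * hi


def mrca(tree: dendropy.Tree, labels) -> dendropy.Node:
    """Most recent common ancestor of a set of tip labels.

    Uses a single postorder pass, so it is safe for trees whose bipartition
    encoding has not been computed.
    """
    want = set(labels)
    if not want:
        raise ValueError("empty label set")
    lmap = cached_leaf_map(tree)
    missing = want - lmap.keys()
    if missing:
        raise KeyError(f"tips not in tree: {sorted(missing)}")
    if len(want) == 1:
        return lmap[next(iter(want))]
    # walk up from one member, testing coverage by marked-leaf counts of
    # the remaining members' ancestor chains
    chains = []
    for lab in want:
        chain = set()
        nd = lmap[lab]
        while nd is not None:
            chain.add(id(nd))
            nd = nd.parent_node
        chains.append(chain)
    common = set.intersection(*chains)
    nd = lmap[next(iter(want))]
    while id(nd) not in common:
        nd = nd.parent_node
    return nd


def descendant_labels(node) -> set[str]:
    return {leaf.taxon.label for leaf in node.leaf_iter()}
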