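"""Sister-pair selection on a backbone phylogeny.

The sampling unit of the comparative analysis is the *sister pair*: two
clades of equal age descending from the same ancestral node and sharing
tips with no other pair.  Pairs are found by collapsing the backbone tree
to one representative tip per taxonomic group (family or genus) with
sequence data, taking every cherry of the collapsed tree, and expanding
each cherry back to the full membership of its two groups.

Downstream hygiene implemented here: the mutual-monophyly filter over a
distribution of complete trees, clade sizes averaged over that
distribution, random tip balancing within pairs, and nearest-neighbour
quartet construction for outgroup rooting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import trees as trlib

logger = logging.getLogger(__name__)

RANKS = ("genus", "family")


@dataclass
class SisterPair:
    pair_id: str
    rank: str
    clade_a_tips: frozenset
    clade_b_tips: frozenset
    size_a: float = 0.0
    size_b: float = 0.0
    age: float | None = None
    balanced_a: frozenset | None = None
    balanced_b: frozenset | None = None

    def __post_init__(self):
        if self.clade_a_tips & self.clade_b_tips:
            raise ValueError(f"{self.pair_id}: clades share tips")

    @property
    def all_tips(self) -> frozenset:
        return self.clade_a_tips | self.clade_b_tips


@dataclass
class Quartet:
    focal_pair: SisterPair
    outgroup_pair: SisterPair

    def __post_init__(self):
        if self.focal_pair.pair_id == self.outgroup_pair.pair_id:
            raise ValueError("focal and outgroup pairs must differ")
        if self.focal_pair.all_tips & self.outgroup_pair.all_tips:
            raise ValueError("focal and outgroup tip sets overlap")


def read_taxonomy(path) -> dict:
    """Read a 3-column TSV (tip_id, genus, family; header required) into a
    tip -> (genus, family) map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["tip_id", "genus", "family"]
    if list(df.columns[:3]) != expected:
        raise ValueError(
            f"taxonomy header must be {expected}, got {list(df.columns)}"
        )
    if df[expected].isna().any().any() or (df[expected] == "").any().any():
        raise ValueError("taxonomy has empty fields")
    return {r.tip_id: (r.genus, r.family) for r in df.itertuples()}


def _group_of(tax: dict, tip: str, rank: str) -> str:
    try:
        genus, family = tax[tip]
    except KeyError:
        raise KeyError(f"tip {tip!r} missing from taxonomy") from None
    return family if rank == "family" else genus


def collapse_to_rank(
    tree: dendropy.Tree,
    tax: dict,
    rank: str,
    has_data: set | None = None,
) -> dendropy.Tree:
    """Collapse a tree to one tip per data-bearing taxonomic group.

    The retained tip of each group is the first member, in the
    left-to-right tip order of the written tree, that has data.  Groups
    with no data tips disappear entirely.  Pruning sums branch lengths
    through suppressed degree-2 nodes.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be in {RANKS}")
    tips = trlib.tip_labels(tree)
    if has_data is None:
        has_data = set(tips)
    unknown = has_data - set(tips)
    if unknown:
        raise KeyError(f"has_data tips not in tree: {sorted(unknown)}")
    keep = []
    seen_groups = set()
    for tip in tips:
        if tip not in has_data:
            continue
        group = _group_of(tax, tip, rank)
        if group not in seen_groups:
            seen_groups.add(group)
            keep.append(tip)
    if not keep:
        raise ValueError("no taxonomic group has any data tips")
    reduced = tree.extract_tree_with_taxa_labels(keep)
    reduced.units = getattr(tree, "units", None)
    return reduced


def extract_sister_pairs(
    reduced: dendropy.Tree,
    tree: dendropy.Tree,
    tax: dict,
    rank: str,
) -> list[SisterPair]:
    """Every cherry of the collapsed tree, expanded back to full group
    membership on the original tree.

    Multifurcating nodes yield no cherry (logged); pairs are mutually
    tip-disjoint because each group appears in exactly one collapsed tip.
    """
    members: dict[str, set] = {}
    for tip in trlib.tip_labels(tree):
        members.setdefault(_group_of(tax, tip, rank), set()).add(tip)
    pairs = []
    n = 0
    for node in reduced.preorder_node_iter():
        children = node.child_nodes()
        if len(children) == 2 and all(ch.is_leaf() for ch in children):
            a, b = (ch.taxon.label for ch in children)
            n += 1
            pairs.append(SisterPair(
                pair_id=f"pair{n:04d}",
                rank=rank,
                clade_a_tips=frozenset(members[_group_of(tax, a, rank)]),
                clade_b_tips=frozenset(members[_group_of(tax, b, rank)]),
            ))
        elif len(children) > 2:
            n_leaf = sum(ch.is_leaf() for ch in children)
            if n_leaf >= 2:
                logger.warning(
                    "multifurcation with %d tip children skipped "
                    "(no cherry extracted)", n_leaf
                )
    return pairs


def _pair_clades_in_tree(tree, pair, mol_tips=None):
    """Locate the pair's two clades in an arbitrary tree via the MRCA of
    each clade's molecular tips; returns (labels_under_a, labels_under_b)
    or None if tips are missing from the tree."""
    present = {lf.taxon.label for lf in tree.leaf_node_iter()}
    a = set(pair.clade_a_tips) & present
    b = set(pair.clade_b_tips) & present
    if mol_tips is not None:
        a &= mol_tips
        b &= mol_tips
    if not a or not b:
        return None
    return (
        trlib.descendant_labels(trlib.mrca(tree, a)),
        trlib.descendant_labels(trlib.mrca(tree, b)),
    )


def is_pair_monophyletic_in_tree(tree, pair, tax, mol_tips=None) -> bool:
    """A pair is non-monophyletic in a tree iff some genus has members
    inside both sister clades, the clades being re-identified as the full
    descendant sets of the MRCAs of each clade's molecular tips."""
    clades = _pair_clades_in_tree(tree, pair, mol_tips)
    if clades is None:
        raise KeyError("pair tips missing from tree")
    under_a, under_b = clades
    genera_a = {tax[t][0] for t in under_a if t in tax}
    genera_b = {tax[t][0] for t in under_b if t in tax}
    return not (genera_a & genera_b)


def monophyly_filter(
    pairs: list[SisterPair],
    tree_set: list[dendropy.Tree],
    tax: dict,
    threshold: float = 0.80,
    mol_tips: set | None = None,
):
    """Remove pairs that fail mutual monophyly in at least ``threshold``
    of the trees (inclusive).  Returns (kept, removed)."""
    if not tree_set:
        raise ValueError("tree_set is empty")
    kept, removed = [], []
    for pair in pairs:
        n_bad = n_eval = 0
        for tree in tree_set:
            try:
                mono = is_pair_monophyletic_in_tree(
                    tree, pair, tax, mol_tips
                )
            except KeyError:
                logger.warning(
                    "%s: tips missing from a tree; tree skipped",
                    pair.pair_id,
                )
                continue
            n_eval += 1
            n_bad += not mono
        if n_eval == 0:
            raise ValueError(
                f"{pair.pair_id}: tips missing from every tree"
            )
        (removed if n_bad / n_eval >= threshold else kept).append(pair)
    return kept, removed


def average_clade_sizes(
    pair: SisterPair,
    tree_set: list[dendropy.Tree],
    mol_tips: set | None = None,
) -> tuple[float, float]:
    """Arithmetic mean over the tree set of the number of tips (data and
    no-data alike) descending from each clade's MRCA."""
    if not tree_set:
        raise ValueError("tree_set is empty")
    counts_a, counts_b = [], []
    for tree in tree_set:
        clades = _pair_clades_in_tree(tree, pair, mol_tips)
        if clades is None:
            raise KeyError(f"{pair.pair_id}: tips missing from a tree")
        counts_a.append(len(clades[0]))
        counts_b.append(len(clades[1]))
    return float(np.mean(counts_a)), float(np.mean(counts_b))


def balance_tips(
    pair: SisterPair,
    has_data: set,
    rng: np.random.Generator | int | None = None,
) -> SisterPair | None:
    """Randomly thin the larger clade's data tips to match the smaller's.

    Returns the pair with ``balanced_a`` / ``balanced_b`` set, or None if
    either clade has no data tips (the pair is dropped with a logged
    reason).  Deterministic given the rng seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    a = sorted(pair.clade_a_tips & has_data)
    b = sorted(pair.clade_b_tips & has_data)
    if not a or not b:
        logger.info(
            "%s dropped: a clade has no tips with data", pair.pair_id
        )
        return None
    k = min(len(a), len(b))
    keep_a = a if len(a) == k else sorted(
        rng.choice(a, size=k, replace=False)
    )
    keep_b = b if len(b) == k else sorted(
        rng.choice(b, size=k, replace=False)
    )
    pair.balanced_a = frozenset(keep_a)
    pair.balanced_b = frozenset(keep_b)
    return pair


def build_quartets(
    pairs: list[SisterPair], reduced: dendropy.Tree
) -> list[Quartet]:
    """Match each pair with the pair whose MRCA is nearest by patristic
    distance on the collapsed tree (nodal distance if lengths absent).

    The matching need not be exclusive; distance ties go to the pair
    earlier in tree tip order.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs to build quartets")
    tips = trlib.tip_labels(reduced)
    present = set(tips)
    depths = trlib.node_depths(reduced)
    has_lengths = any(
        nd.edge.length for nd in reduced.preorder_node_iter()
        if nd.parent_node is not None
    )

    def edge_len(nd):
        return (nd.edge.length or 0.0) if has_lengths else 1.0

    # ancestor chains from each pair MRCA to the root
    mrcas = []
    for pair in pairs:
        reps = (pair.clade_a_tips | pair.clade_b_tips) & present
        mrcas.append(trlib.mrca(reduced, reps))

    def chain(nd):
        out = {}
        d = 0.0
        while nd is not None:
            out[id(nd)] = (d, nd)
            d += edge_len(nd)
            nd = nd.parent_node
        return out

    chains = [chain(nd) for nd in mrcas]

    def dist(i, j):
        ci, cj = chains[i], chains[j]
        best = np.inf
        for key, (dj, _) in cj.items():
            if key in ci:
                best = min(best, ci[key][0] + dj)
        return best

    # tie-break ordering: first appearance of any pair tip in tip order
    order = {}
    for rank_i, tip in enumerate(tips):
        for j, pair in enumerate(pairs):
            if j not in order and tip in pair.all_tips:
                order[j] = rank_i
    quartets = []
    for i, pair in enumerate(pairs):
        cands = sorted(
            (j for j in range(len(pairs)) if j != i),
            key=lambda j: (dist(i, j), order.get(j, np.inf)),
        )
        quartets.append(Quartet(pair, pairs[cands[0]]))
    return quartets


def pairs_to_frame(pairs: list[SisterPair],
                   flags: dict | None = None) -> pd.DataFrame:
    """Pair table in the standard column layout; ``flags`` optionally
    maps pair_id -> semicolon-joined filter annotations."""
    flags = flags or {}
    rows = []
    for p in pairs:
        rows.append({
            "pair_id": p.pair_id,
            "rank": p.rank,
            "clade_a_tips": ";".join(sorted(p.clade_a_tips)),
            "clade_b_tips": ";".join(sorted(p.clade_b_tips)),
            "size_a": p.size_a,
            "size_b": p.size_b,
            "age": p.age,
            "filter_flags": flags.get(p.pair_id, ""),
        })
    return pd.DataFrame(rows)
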