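"""Per-clade substitution-rate summaries from branch-length trees.

The clade summary statistic is a *phylogenetically averaged* root-to-tip
path length: sister branches are averaged successively from the tips down
and the result added to the parent branch at each step, so every daughter
lineage gets equal weight and speciose subclades do not dominate.  For a
clade measured from the pair's common ancestor this includes the clade's
stem branch.

Branch lengths are expected in substitutions per site (total, dS or dN
trees produced by external ML software, or by the synthetic generator).
Pairs whose synonymous path average exceeds a saturation threshold are
discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import pandas as pd

from . import trees as trlib
from .pairs import SisterPair

logger = logging.getLogger(__name__)


@dataclass
class CladeRateSummary:
    pair_id: str
    clade: str                      # "a" | "b"
    n_tips: int
    rate_total: float | None = None
    rate_dS: float | None = None
    rate_dN: float | None = None

    def __post_init__(self):
        vals = (self.rate_total, self.rate_dS, self.rate_dN)
        if all(v is None for v in vals):
            raise ValueError("at least one rate field required")
        if any(v is not None and v < 0 for v in vals):
            raise ValueError("rates must be non-negative")

    def rate(self, rate_type: str) -> float | None:
        return getattr(self, f"rate_{rate_type}")


def phylo_average_path(clade_root, stem_length: float | None = None) -> float:
    """Equal-daughter-weight average substitutions/site from the clade's
    stem to its tips.

    value(tip) = 0; value(node) = mean over children of (child branch +
    value(child)); returns stem + value(clade_root).  ``stem_length``
    defaults to the clade root's own edge length (0 at a tree root).
    """
    if stem_length is None:
        stem_length = clade_root.edge.length or 0.0
    if stem_length < 0:
        raise ValueError("negative stem branch length")

    def value(node):
        children = node.child_nodes()
        if not children:
            return 0.0
        acc = 0.0
        for ch in children:
            if ch.edge.length is None or ch.edge.length < 0:
                raise ValueError(
                    f"missing/negative branch length above "
                    f"{trlib.describe_node(ch)}"
                )
            acc += ch.edge.length + value(ch)
        return acc / len(children)

    return stem_length + value(clade_root)


def phylo_average_path_restricted(clade_root, keep: set,
                                  stem_length: float | None = None) -> float:
    """phylo_average_path on the subtree induced by the tip set ``keep``.

    Equivalent to pruning the clade to ``keep`` (suppressing degree-2
    nodes by summing branch lengths) and averaging, without building the
    pruned tree.
    """
    def value(node):
        # returns (extra_stem, value) for the induced subtree under node,
        # or None if node has no kept descendant
        if node.is_leaf():
            return (0.0, 0.0) if node.taxon.label in keep else None
        sub = []
        for ch in node.child_nodes():
            r = value(ch)
            if r is not None:
                extra, val = r
                sub.append((ch.edge.length + extra, val))
        if not sub:
            return None
        if len(sub) == 1:  # pass-through node: merge edge into stem
            return sub[0]
        return 0.0, sum(e + v for e, v in sub) / len(sub)

    if stem_length is None:
        stem_length = clade_root.edge.length or 0.0
    r = value(clade_root)
    if r is None:
        raise ValueError("no kept tips under clade root")
    extra, val = r
    return stem_length + extra + val


def summarize_rates(
    quartet_tree: dendropy.Tree,
    pair: SisterPair,
    rate_type: str = "total",
) -> tuple[CladeRateSummary, CladeRateSummary]:
    """Summarise both sister clades of a pair from one branch-length tree.

    The tree must contain the pair's (balanced) tips, each clade
    monophyletic; each clade is measured from the pair's MRCA, i.e. its
    stem branch is included.
    """
    tips_a = set(pair.balanced_a or pair.clade_a_tips)
    tips_b = set(pair.balanced_b or pair.clade_b_tips)
    present = {lf.taxon.label for lf in quartet_tree.leaf_node_iter()}
    tips_a &= present
    tips_b &= present
    if not tips_a or not tips_b:
        raise KeyError(f"{pair.pair_id}: clade tips absent from tree")
    node = trlib.mrca(quartet_tree, tips_a | tips_b)
    out = []
    for label, tips in (("a", tips_a), ("b", tips_b)):
        clade = trlib.mrca(quartet_tree, tips)
        if trlib.descendant_labels(clade) != tips:
            raise ValueError(
                f"{pair.pair_id}: clade {label} not monophyletic in tree"
            )
        # stem measured from the pair MRCA: sum edges clade -> node
        stem = 0.0
        cur = clade
        while cur is not node:
            stem += cur.edge.length or 0.0
            cur = cur.parent_node
        rate = phylo_average_path_restricted(clade, tips, stem_length=stem)
        out.append(CladeRateSummary(
            pair_id=pair.pair_id,
            clade=label,
            n_tips=len(tips),
            **{f"rate_{rate_type}": rate},
        ))
    return out[0], out[1]


def saturation_filter(
    pair_summaries: list[tuple[CladeRateSummary, CladeRateSummary]],
    max_dS: float = 2.0,
):
    """Drop pairs in which either clade's dS exceeds ``max_dS`` (strict
    inequality: dS == max_dS is retained).  Returns (kept, removed)."""
    kept, removed = [], []
    for a, b in pair_summaries:
        if a.rate_dS is None or b.rate_dS is None:
            raise ValueError(f"{a.pair_id}: dS missing")
        if a.rate_dS > max_dS or b.rate_dS > max_dS:
            removed.append((a, b))
        else:
            kept.append((a, b))
    return kept, removed


def summaries_to_frame(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "pair_id": s.pair_id,
            "clade": s.clade,
            "n_tips": s.n_tips,
            "rate_total": s.rate_total,
            "rate_dS": s.rate_dS,
            "rate_dN": s.rate_dN,
        })
    return pd.DataFrame(rows)
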