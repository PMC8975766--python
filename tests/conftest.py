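"""Shared fixtures: small hand-built trees and random tree factories.

All randomness is seeded so the suite is reproducible run to run.
"""

from __future__ import annotations

import numpy as np
import pytest

from divrates import parse_newick
from divrates import trees as trlib


@pytest.fixture
def cherry_tree():
    """((a:1,b:1):1,c:2); — ultrametric 3-tip tree of depth 2."""
    return parse_newick("((a:1,b:1):1,c:2);")


@pytest.fixture
def eight_tip_tree():
    """Balanced 8-tip ultrametric tree, families F1 = {t1,t2,t3},
    F2 = {t4,t5}, F3 = {t6,t7,t8}."""
    nwk = (
        "(((t1:1,t2:1):1,(t3:1.5,t4:1.5):0.5):2,"
        "((t5:1,t6:1):1.5,(t7:2,t8:2):0.5):1.5);"
    )
    return parse_newick(nwk)


@pytest.fixture
def eight_tip_taxonomy():
    fam = {
        "t1": "F1", "t2": "F1", "t3": "F1",
        "t4": "F2", "t5": "F2",
        "t6": "F3", "t7": "F3", "t8": "F3",
    }
    return {tip: (f"G_{tip}", fam[tip]) for tip in fam}


def random_binary_newick(rng: np.random.Generator, n_tips: int,
                         ultrametric: bool = False) -> str:
    """Random binary tree with uniform branch lengths; tips r0..r{n-1}."""
    if ultrametric:
        # coalescent-style: repeatedly join two random subtrees at an
        # increasing height
        heights = {f"r{i}": 0.0 for i in range(n_tips)}
        sub = {f"r{i}": f"r{i}" for i in range(n_tips)}
        h = 0.0
        keys = list(sub)
        while len(keys) > 1:
            h += float(rng.uniform(0.2, 1.0))
            i, j = rng.choice(len(keys), size=2, replace=False)
            a, b = keys[i], keys[j]
            la = h - heights[a]
            lb = h - heights[b]
            merged = f"({sub[a]}:{la:.6f},{sub[b]}:{lb:.6f})"
            key = a + b
            sub[key] = merged
            heights[key] = h
            keys = [k for k in keys if k not in (a, b)] + [key]
        return sub[keys[0]] + ";"
    subs = [f"r{i}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_tips)]
    while len(subs) > 1:
        i, j = sorted(rng.choice(len(subs), size=2, replace=False))
        b = subs.pop(j)
        a = subs.pop(i)
        subs.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
    return subs[0].rsplit(":", 1)[0] + ";"


@pytest.fixture
def random_tree_factory():
    def make(seed: int, n_tips: int, ultrametric: bool = False):
        rng = np.random.default_rng(seed)
        return parse_newick(
            random_binary_newick(rng, n_tips, ultrametric=ultrametric),
            units="subs/site",
        )
    return make


def tip_depth_map(tree):
    depths = trlib.node_depths(tree)
    return {nd.taxon.label: depths[nd] for nd in tree.leaf_node_iter()}
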