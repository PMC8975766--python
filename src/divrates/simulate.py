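"""Synthetic data generator.

Produces the objects the comparative analysis consumes, with the causal
structure the analysis is designed to detect:

* a birth-death time tree in which each lineage carries its own
  substitution rate, evolving as Brownian motion on the log scale;
* optional coupling of the speciation rate to the substitution rate
  (per-lineage speciation rate ``lambda0 * (r / r0) ** gamma``), so that
  ``gamma > 0`` makes fast-evolving lineages diversify faster;
* a substitutions-per-site tree on the same topology, with optional
  Poisson sampling noise at a stated alignment length;
* a taxonomy in which genera and families are the clades whose stem
  branches cross fixed age thresholds;
* a pseudo-posterior of complete trees in which a fraction of tips is
  treated as having no molecular data and is re-placed at random within
  its family, mimicking stochastic placement of unsequenced species.

Within a branch the speciation rate is evaluated at the rate the lineage
inherited at its birth; the log-rate increment over the branch is drawn
when the branch ends.  The branch's expected substitutions use the
midpoint of the log-Brownian bridge endpoints, exp((ln r_start + ln
r_end) / 2) * duration, an approximation whose error vanishes as sigma2
goes to 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from . import trees as trlib

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Parameters of the synthetic study system.

    Rates are per million years; ages in millions of years; substitution
    rates in substitutions per site per million years.
    """

    lambda0: float = 0.10      # base speciation rate /Myr
    mu: float = 0.05           # extinction rate /Myr
    T: float = 100.0           # crown-to-present simulation time, Myr
    n_tips: int | None = None  # stop instead when this many tips are extant
    r0: float = 1e-3           # root substitution rate, subs/site/Myr
    sigma2: float = 0.05       # variance of BM on ln(rate), per Myr
    gamma: float = 0.0         # speciation-rate coupling exponent
    sites: int = 2500          # alignment length for Poisson noise; 0 = none
    genus_age: float = 10.0    # stem-age threshold defining genera, Myr
    family_age: float = 25.0   # stem-age threshold defining families, Myr
    missing_frac: float = 0.2  # fraction of tips without molecular data
    n_pseudo_trees: int = 100  # size of the pseudo-posterior
    min_tips: int = 4
    max_tips: int = 50_000     # reject runaway radiations
    retry_cap: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.lambda0, self.T, self.r0) <= 0:
            raise ValueError("lambda0, T and r0 must be positive")
        if self.mu < 0 or self.sigma2 < 0:
            raise ValueError("mu and sigma2 must be non-negative")
        if not (0 <= self.missing_frac < 1):
            raise ValueError("missing_frac must be in [0, 1)")
        if self.genus_age >= self.family_age:
            raise ValueError("genus_age must be below family_age")


@dataclass
class SimOutput:
    config: SimConfig
    time_tree: dendropy.Tree          # ultrametric, Myr
    subs_tree: dendropy.Tree          # same topology, realized subs/site
    subs_tree_expected: dendropy.Tree  # noise-free expected subs/site
    branch_rates: dict                # tip-set frozenset -> mean rate of stem
    taxonomy: dict                    # tip -> (genus, family)
    tree_set: list = field(default_factory=list)   # pseudo-posterior
    molecular_tips: set = field(default_factory=set)
    no_data_tips: set = field(default_factory=set)

    def truth_record(self) -> dict:
        return {
            "gamma": self.config.gamma,
            "sigma2": self.config.sigma2,
            "r0": self.config.r0,
            "seed": self.config.seed,
            "n_tips": len(self.time_tree.leaf_nodes()),
        }


class _Lineage:
    __slots__ = (
        "parent", "children", "t_birth", "t_end",
        "ln_r_birth", "ln_r_end", "extinct", "label",
    )

    def __init__(self, parent, t_birth, ln_r_birth):
        self.parent = parent
        self.children = []
        self.t_birth = t_birth
        self.t_end = None
        self.ln_r_birth = ln_r_birth
        self.ln_r_end = None
        self.extinct = False
        self.label = None


def _gillespie(config: SimConfig, rng: np.random.Generator):
    """One forward birth-death pass; returns (root lineage, extant list)."""
    ln_r0 = math.log(config.r0)
    root = _Lineage(None, 0.0, ln_r0)

    def birth_rate(lin):
        return config.lambda0 * math.exp(
            config.gamma * (lin.ln_r_birth - ln_r0)
        )

    # array bookkeeping with swap-removal keeps each event O(n) in numpy
    cap = 1024
    alive = [root]
    lam = np.empty(cap)
    lam[0] = birth_rate(root)
    m = 1
    t = 0.0
    while m:
        if m > config.max_tips:
            raise _TooLarge
        if config.n_tips is not None and m >= config.n_tips:
            break
        total = lam[:m].sum() + config.mu * m
        t_next = t + rng.exponential(1.0 / total)
        if t_next >= config.T:
            break
        t = t_next
        weights = lam[:m] + config.mu
        idx = int(rng.choice(m, p=weights / weights.sum()))
        lin = alive[idx]
        lin.t_end = t
        dt = t - lin.t_birth
        lin.ln_r_end = lin.ln_r_birth + rng.normal(
            0.0, math.sqrt(config.sigma2 * dt)
        )
        speciates = rng.random() < lam[idx] / weights[idx]
        # swap-remove the parent from the alive set
        alive[idx] = alive[m - 1]
        lam[idx] = lam[m - 1]
        alive.pop()
        m -= 1
        if speciates:
            if m + 2 > cap:
                cap *= 2
                lam = np.resize(lam, cap)
            for _ in range(2):
                child = _Lineage(lin, t, lin.ln_r_end)
                lin.children.append(child)
                alive.append(child)
                lam[m] = birth_rate(child)
                m += 1
        else:
            lin.extinct = True
    t_stop = t if config.n_tips is not None and m >= config.n_tips \
        else config.T
    for lin in alive:
        lin.t_end = t_stop
        dt = t_stop - lin.t_birth
        lin.ln_r_end = lin.ln_r_birth + rng.normal(
            0.0, math.sqrt(config.sigma2 * dt)
        )
    return root, alive


class _TooLarge(Exception):
    pass


def _survival_map(root: _Lineage) -> dict:
    """Iterative postorder: lineage -> has an extant descendant."""
    surv = {}
    stack = [(root, False)]
    while stack:
        lin, expanded = stack.pop()
        if not lin.children:
            surv[id(lin)] = not lin.extinct
        elif expanded:
            surv[id(lin)] = any(surv[id(ch)] for ch in lin.children)
        else:
            stack.append((lin, True))
            stack.extend((ch, False) for ch in lin.children)
    return surv


def _survives(lin: _Lineage) -> bool:
    return _survival_map(lin)[id(lin)]


def _collapse(lin: _Lineage, surv: dict | None = None):
    """Reduce to the reconstructed tree: drop extinct subtrees, merge
    pass-through lineages, accumulating duration and expected substitutions.

    Returns (duration, expected_subs_per_site, node) where node is either a
    tip label carrier or a list of child triples.
    """
    if surv is None:
        surv = _survival_map(lin)
    dur = lin.t_end - lin.t_birth
    exp_subs = math.exp(0.5 * (lin.ln_r_birth + lin.ln_r_end)) * dur
    surviving = [ch for ch in lin.children if surv[id(ch)]]
    if not lin.children:
        return dur, exp_subs, lin
    if len(surviving) == 1:
        d2, e2, node = _collapse(surviving[0], surv)
        return dur + d2, exp_subs + e2, node
    return dur, exp_subs, [_collapse(ch, surv) for ch in surviving]


def _build_dendropy(root_triple, taxon_namespace):
    """Convert the collapsed lineage structure to a dendropy tree with
    edge annotations: length (Myr), expected_subs (subs/site)."""
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    counter = [0]

    def attach(parent_nd, triple):
        dur, exp_subs, payload = triple
        nd = dendropy.Node()
        parent_nd.add_child(nd)
        nd.edge.length = dur
        nd.edge.expected_subs = exp_subs
        if isinstance(payload, list):
            for tr in payload:
                attach(nd, tr)
        else:
            counter[0] += 1
            label = f"t{counter[0]:05d}"
            nd.taxon = taxon_namespace.require_taxon(label=label)
        return nd

    dur, exp_subs, payload = root_triple
    seed = tree.seed_node
    seed.edge.length = 0.0
    seed.edge.expected_subs = 0.0
    if isinstance(payload, list):
        # discard the root stem: the crown node becomes the tree root
        for tr in payload:
            attach(seed, tr)
    else:
        attach(seed, (dur, exp_subs, payload))
    return tree


def simulate_tree(config: SimConfig, seed: int | None = None) -> SimOutput:
    """Simulate one dataset (time tree, rates, taxonomy, pseudo-posterior).

    Deterministic given (config, seed); the seed argument overrides
    ``config.seed``.  Retries on total extinction or on exceeding
    ``max_tips``, up to ``retry_cap`` attempts.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    for attempt in range(config.retry_cap):
        try:
            root, alive = _gillespie(config, rng)
        except _TooLarge:
            logger.debug("attempt %d exceeded max_tips; retrying", attempt)
            continue
        surv = _survival_map(root)
        n_ok = sum(1 for lin in _iter_lineages(root) if _tip_survives(lin))
        if surv[id(root)] and n_ok >= config.min_tips:
            break
        logger.debug("attempt %d extinct/too small; retrying", attempt)
    else:
        raise RuntimeError(
            f"no surviving tree with >= {config.min_tips} tips in "
            f"{config.retry_cap} attempts"
        )

    tns = dendropy.TaxonNamespace()
    triple = _collapse(root, surv)
    time_tree = _build_dendropy(triple, tns)
    time_tree.units = "Myr"

    subs_expected = _clone_with_lengths(
        time_tree, lambda e: e.expected_subs
    )
    subs_expected.units = "subs/site"
    subs_tree = substitution_branch_lengths(subs_expected, config.sites, rng)

    branch_rates = {}
    for nd in time_tree.preorder_node_iter():
        if nd.parent_node is None or nd.edge.length == 0:
            continue
        key = frozenset(trlib.descendant_labels(nd))
        branch_rates[key] = nd.edge.expected_subs / nd.edge.length

    taxonomy = assign_taxonomy(
        time_tree, config.genus_age, config.family_age
    )

    out = SimOutput(
        config=config,
        time_tree=time_tree,
        subs_tree=subs_tree,
        subs_tree_expected=subs_expected,
        branch_rates=branch_rates,
        taxonomy=taxonomy,
    )
    tip_set = set(trlib.tip_labels(time_tree))
    if config.n_pseudo_trees > 0:
        tree_set, mol_tips, nodata = make_pseudoposterior(
            time_tree,
            taxonomy,
            config.missing_frac,
            config.n_pseudo_trees,
            rng,
        )
        out.tree_set = tree_set
        out.molecular_tips = mol_tips
        out.no_data_tips = nodata
    else:
        out.tree_set = []
        out.molecular_tips = tip_set
        out.no_data_tips = set()
    return out


def _iter_lineages(root):
    stack = [root]
    while stack:
        lin = stack.pop()
        yield lin
        stack.extend(lin.children)


def _tip_survives(lin):
    return not lin.children and not lin.extinct


def _clone_with_lengths(tree: dendropy.Tree, length_fn) -> dendropy.Tree:
    """Structural copy (shared taxa, fresh nodes) with lengths taken from
    ``length_fn(edge)`` of the source; much cheaper than a deep copy."""
    clone = dendropy.Tree(taxon_namespace=tree.taxon_namespace)

    clone.seed_node.edge.length = 0.0
    stack = [(tree.seed_node, clone.seed_node)]
    while stack:
        src, dst = stack.pop()
        dst.taxon = src.taxon
        for ch_src in src.child_nodes():
            ch_dst = dendropy.Node()
            dst.add_child(ch_dst)
            ch_dst.edge.length = length_fn(ch_src.edge)
            stack.append((ch_src, ch_dst))
    return clone


def substitution_branch_lengths(
    expected_tree: dendropy.Tree,
    sites: int,
    rng: np.random.Generator | int | None = None,
) -> dendropy.Tree:
    """Realize substitutions-per-site branch lengths.

    ``expected_tree`` carries noise-free expected subs/site lengths.  With
    ``sites > 0`` each branch length becomes Poisson(expected * sites) /
    sites, the sampling noise of counting substitutions over a finite
    alignment; with ``sites == 0`` the expected lengths are returned
    unchanged.
    """
    if sites == 0:
        clone = _clone_with_lengths(expected_tree, lambda e: e.length)
        clone.units = "subs/site"
        return clone
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    clone = _clone_with_lengths(
        expected_tree,
        lambda e: rng.poisson(e.length * sites) / sites,
    )
    clone.units = "subs/site"
    return clone


def assign_taxonomy(
    time_tree: dendropy.Tree, genus_age: float, family_age: float
) -> dict:
    """Assign every tip to a genus nested within a family.

    A genus is a maximal clade whose stem branch crosses ``genus_age``
    (node age < threshold <= parent age); families likewise at
    ``family_age``.  Requires an ultrametric tree.
    """
    if genus_age >= family_age:
        raise ValueError("genus_age must be below family_age")
    if not trlib.is_ultrametric(time_tree, rel_tol=1e-4):
        raise ValueError("taxonomy assignment requires an ultrametric tree")
    depths = trlib.node_depths(time_tree)
    height = max(depths[nd] for nd in time_tree.leaf_node_iter())
    age = {nd: height - depths[nd] for nd in depths}

    def rank_roots(threshold):
        roots = []
        for nd in time_tree.preorder_node_iter():
            parent_age = (
                math.inf if nd.parent_node is None else age[nd.parent_node]
            )
            if age[nd] < threshold <= parent_age:
                roots.append(nd)
        if not roots:  # whole tree younger than threshold
            roots = [time_tree.seed_node]
        return roots

    taxonomy = {}
    fam_of = {}
    for i, nd in enumerate(rank_roots(family_age), 1):
        name = f"F{i:04d}"
        for tip in trlib.descendant_labels(nd):
            fam_of[tip] = name
    for i, nd in enumerate(rank_roots(genus_age), 1):
        name = f"G{i:05d}"
        for tip in trlib.descendant_labels(nd):
            taxonomy[tip] = (name, fam_of[tip])
    return taxonomy


def make_pseudoposterior(
    time_tree: dendropy.Tree,
    taxonomy: dict,
    missing_frac: float,
    n_trees: int,
    rng: np.random.Generator | int | None = None,
):
    """Emulate a distribution of complete trees with unsequenced species
    placed stochastically.

    A fixed fraction of tips is designated "no-data"; in each of
    ``n_trees`` replicates every no-data tip is detached and re-attached
    uniformly at random to a branch within its family's clade (the MRCA of
    the family's data tips), at a uniformly chosen height on that branch,
    preserving ultrametricity.  Families whose tips are all no-data fall
    back to attachment anywhere in the tree, with a warning.

    Returns (tree_set, molecular_tips, no_data_tips).
    """
    if not (0 <= missing_frac < 1):
        raise ValueError("missing_frac must be in [0, 1)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    tips = trlib.tip_labels(time_tree)
    n_missing = math.ceil(missing_frac * len(tips))
    # never strip a family of all its data if avoidable: sample tips, then
    # report families that end up fully missing
    nodata = set(
        rng.choice(len(tips), size=n_missing, replace=False)
    ) if n_missing else set()
    nodata = {tips[i] for i in nodata}
    mol_tips = set(tips) - nodata
    fam_members = {}
    for tip in tips:
        fam_members.setdefault(taxonomy[tip][1], set()).add(tip)
    orphan_fams = {
        fam for fam, members in fam_members.items()
        if not (members & mol_tips)
    }
    if orphan_fams:
        logger.warning(
            "families with no data tips (re-placement falls back to the "
            "whole tree): %s", sorted(orphan_fams)
        )

    if missing_frac == 0:
        return (
            [time_tree.clone(depth=1) for _ in range(n_trees)],
            mol_tips,
            nodata,
        )

    tree_set = []
    for _ in range(n_trees):
        rep = time_tree.clone(depth=1)
        _strip_edge_annotations(rep)
        taxa = [lf.taxon for lf in rep.leaf_node_iter()
                if lf.taxon.label in mol_tips]
        rep.retain_taxa(taxa)
        height = trlib.tree_height(rep)
        for tip in sorted(nodata):
            fam = taxonomy[tip][1]
            anchors = fam_members[fam] & mol_tips
            present = {
                lf.taxon.label for lf in rep.leaf_node_iter()
            }
            anchors = (anchors | (fam_members[fam] & present)) & present
            if anchors:
                clade_root = trlib.mrca(rep, anchors)
            else:
                clade_root = rep.seed_node
            _attach_tip(rep, clade_root, tip, height, rng)
        tree_set.append(rep)
    return tree_set, mol_tips, nodata


def _strip_edge_annotations(tree):
    for nd in tree.preorder_node_iter():
        if hasattr(nd.edge, "expected_subs"):
            del nd.edge.expected_subs


def _attach_tip(tree, clade_root, label, height, rng):
    """Graft *label* onto a uniformly chosen edge below clade_root, at a
    uniformly chosen height along that edge, keeping the tree ultrametric."""
    edges = [nd for nd in clade_root.preorder_iter() if nd is not clade_root]
    if not edges:
        # single-tip clade: its pendant edge is the only candidate
        edges = [clade_root]
    child = edges[rng.integers(len(edges))]
    depths = trlib.node_depths(tree)
    d_child = depths[child]
    d_parent = d_child - (child.edge.length or 0.0)
    d_attach = rng.uniform(d_parent, d_child)
    parent = child.parent_node
    new_inner = dendropy.Node()
    if parent is None:
        raise RuntimeError("cannot attach above the root")
    parent.remove_child(child)
    parent.add_child(new_inner)
    new_inner.edge.length = d_attach - d_parent
    new_inner.add_child(child)
    child.edge.length = d_child - d_attach
    new_tip = dendropy.Node()
    new_inner.add_child(new_tip)
    new_tip.edge.length = height - d_attach
    new_tip.taxon = tree.taxon_namespace.require_taxon(label=label)
    cache = getattr(tree, "_divrates_leaf_cache", None)
    if cache is not None:
        cache[label] = new_tip


def write_sim_output(out: SimOutput, out_dir):
    """Write a simulated dataset to disk: Newick trees, taxonomy TSV,
    numbered pseudo-posterior trees and a JSON truth record."""
    import json
    import os

    os.makedirs(out_dir, exist_ok=True)
    trlib.write_newick(out.time_tree, os.path.join(out_dir, "time_tree.nwk"))
    trlib.write_newick(out.subs_tree, os.path.join(out_dir, "subs_tree.nwk"))
    trlib.write_newick(
        out.subs_tree_expected,
        os.path.join(out_dir, "subs_tree_expected.nwk"),
    )
    with open(os.path.join(out_dir, "taxonomy.tsv"), "w") as fh:
        fh.write("tip_id\tgenus\tfamily\n")
        for tip in sorted(out.taxonomy):
            g, f = out.taxonomy[tip]
            fh.write(f"{tip}\t{g}\t{f}\n")
    pp_dir = os.path.join(out_dir, "pseudoposterior")
    os.makedirs(pp_dir, exist_ok=True)
    for i, tree in enumerate(out.tree_set, 1):
        trlib.write_newick(tree, os.path.join(pp_dir, f"tree_{i:03d}.nwk"))
    record = out.truth_record()
    record["config"] = asdict(out.config)
    record["no_data_tips"] = sorted(out.no_data_tips)
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(record, fh, indent=1)
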