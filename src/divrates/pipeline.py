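"""End-to-end pipeline on a synthetic dataset.

Stages, in order: simulate -> collapse to rank -> sister pairs ->
monophyly filter -> clade sizes & ages -> tip balancing -> quartets ->
rate summaries -> saturation filter -> contrasts -> outlier filter ->
Welch filter -> regression through the origin, plus the whole-tree
node-density test.  Every filtering stage records pairs entering, kept
and removed in the run manifest, so the bookkeeping can be audited
(entering = kept + removed at every stage).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import contrasts as ctr
from . import pairs as pr
from . import rates as rt
from . import trees as trlib
from . import treemodel as tm
from .config import RunConfig
from .regression import OriginRegression
from .simulate import simulate_tree

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    manifest: dict
    pairs: list
    contrasts: pd.DataFrame          # pairs surviving every filter
    regression: object | None
    tree_report: object | None = None
    contrasts_all: pd.DataFrame | None = None  # with filter flag columns
    sim: object = field(default=None, repr=False)


def _stage(manifest, name, entering, kept, removed):
    manifest["stages"].append({
        "stage": name,
        "entering": entering,
        "kept": kept,
        "removed": removed,
    })
    if entering != kept + removed:
        raise RuntimeError(f"bookkeeping violated at stage {name}")


def summarize_pair_from_tree(subs_tree, pair, rate_type="total"):
    """Rate summaries for a pair measured directly on a full
    substitutions-per-site tree, using the balanced tip subsets and the
    induced-subtree path average."""
    tips_a = set(pair.balanced_a or pair.clade_a_tips)
    tips_b = set(pair.balanced_b or pair.clade_b_tips)
    present = {lf.taxon.label for lf in subs_tree.leaf_node_iter()}
    tips_a &= present
    tips_b &= present
    if not tips_a or not tips_b:
        raise KeyError(f"{pair.pair_id}: no clade tips in tree")
    node = trlib.mrca(subs_tree, tips_a | tips_b)
    out = []
    for label, tips in (("a", tips_a), ("b", tips_b)):
        clade = trlib.mrca(subs_tree, tips)
        under = trlib.descendant_labels(clade)
        if under & (tips_a | tips_b) != tips:
            raise ValueError(
                f"{pair.pair_id}: clade {label} not monophyletic"
            )
        stem = 0.0
        cur = clade
        while cur is not node:
            stem += cur.edge.length or 0.0
            cur = cur.parent_node
        rate = rt.phylo_average_path_restricted(
            clade, tips, stem_length=stem
        )
        out.append(rt.CladeRateSummary(
            pair_id=pair.pair_id, clade=label, n_tips=len(tips),
            **{f"rate_{rate_type}": rate},
        ))
    return out[0], out[1]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis on one synthetic dataset.

    Deterministic given the config (including its seed).  Writes result
    tables and a JSON manifest to ``config.out_dir`` when set.
    """
    rng = np.random.default_rng(config.seed)
    manifest = {
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": [],
    }

    sim = simulate_tree(config.sim, seed=config.seed)
    time_tree = sim.time_tree
    tax = sim.taxonomy
    mol = set(sim.molecular_tips)
    manifest["n_tips"] = len(time_tree.leaf_nodes())

    reduced = pr.collapse_to_rank(time_tree, tax, config.rank, has_data=mol)
    pairs = pr.extract_sister_pairs(reduced, time_tree, tax, config.rank)
    manifest["n_pairs_initial"] = len(pairs)
    if not pairs:
        raise RuntimeError("no sister pairs found")

    tree_set = sim.tree_set or [time_tree]
    if config.apply_monophyly and len(tree_set) > 1:
        kept, removed = pr.monophyly_filter(
            pairs, tree_set, tax,
            threshold=config.monophyly_threshold, mol_tips=mol,
        )
        _stage(manifest, "monophyly", len(pairs), len(kept), len(removed))
        pairs = kept

    depths = trlib.node_depths(time_tree)
    height = max(depths[nd] for nd in time_tree.leaf_node_iter())
    for pair in pairs:
        pair.size_a, pair.size_b = pr.average_clade_sizes(
            pair, tree_set, mol_tips=mol
        )
        node = trlib.mrca(time_tree, pair.all_tips & mol)
        pair.age = height - depths[node]

    balanced = []
    for pair in pairs:
        got = pr.balance_tips(pair, mol, rng)
        if got is not None:
            balanced.append(got)
    _stage(manifest, "balance", len(pairs), len(balanced),
           len(pairs) - len(balanced))
    pairs = balanced

    if len(pairs) >= 2:
        quartets = pr.build_quartets(pairs, reduced)
        manifest["n_quartets"] = len(quartets)

    summaries, failed = [], 0
    for pair in pairs:
        try:
            summaries.append(
                summarize_pair_from_tree(
                    sim.subs_tree, pair, rate_type=config.rate_type
                )
            )
        except (KeyError, ValueError) as exc:
            logger.warning("rate summary failed: %s", exc)
            failed += 1
    _stage(manifest, "rates", len(pairs), len(summaries), failed)

    if config.apply_saturation:
        kept_s, removed_s = [], []
        for a, b in summaries:
            ra, rb = a.rate(config.rate_type), b.rate(config.rate_type)
            if ra > config.max_dS or rb > config.max_dS:
                removed_s.append((a, b))
            else:
                kept_s.append((a, b))
        _stage(manifest, "saturation", len(summaries),
               len(kept_s), len(removed_s))
        summaries = kept_s

    contrasts = ctr.compute_contrasts(
        pairs, summaries, rate_type=config.rate_type
    )
    _stage(manifest, "contrasts", len(summaries), len(contrasts),
           len(summaries) - len(contrasts))
    contrasts_all = contrasts.assign(
        outlier_removed=False, welch_removed=False
    )

    if config.apply_outlier:
        kept_df, removed_df = ctr.small_rate_outlier_filter(
            contrasts,
            min_mean_rate=config.outlier_min_mean_rate,
            max_abs_contrast=config.outlier_max_abs_contrast,
        )
        _stage(manifest, "small_rate_outlier", len(contrasts),
               len(kept_df), len(removed_df))
        contrasts_all.loc[
            contrasts_all["pair_id"].isin(removed_df["pair_id"]),
            "outlier_removed",
        ] = True
        contrasts = kept_df

    if config.apply_welch and len(contrasts) >= 3:
        kept_df, removed_df, trace = ctr.welch_filter(
            contrasts, alpha=config.welch_alpha
        )
        _stage(manifest, "welch", len(contrasts),
               len(kept_df), len(removed_df))
        manifest["welch_trace"] = [
            {"n": t.n_pairs, "slope": t.slope, "p": t.p_one_sided,
             "removed": t.removed_pair}
            for t in trace
        ]
        contrasts_all.loc[
            contrasts_all["pair_id"].isin(removed_df["pair_id"]),
            "welch_removed",
        ] = True
        contrasts = kept_df

    regression = None
    if len(contrasts) >= 2 and (contrasts["d_log_rate"] != 0).any():
        regression = OriginRegression.from_contrasts(contrasts).fit()
        manifest["regression"] = {
            "rate_type": config.rate_type,
            "n_pairs": regression.nobs,
            "coeff": regression.slope,
            "std_err": regression.bse,
            "t": regression.tvalue,
            "p": regression.pvalue,
        }
    else:
        logger.warning("too few usable contrasts for regression")

    tree_report = None
    if config.run_tree_test:
        mol_subs = sim.subs_tree.clone(depth=1)
        taxa = [lf.taxon for lf in mol_subs.leaf_node_iter()
                if lf.taxon.label in mol]
        mol_subs.retain_taxa(taxa)
        tree_report = tm.node_density_test(mol_subs)
        manifest["tree_test"] = {
            "slope": tree_report.gls.slope,
            "likelihood_ratio": tree_report.gls.lrt,
            "p": tree_report.gls.pvalue,
            "delta_path_response": tree_report.delta_path_response.delta,
            "delta_nodes_response": tree_report.delta_nodes_response.delta,
            "artefact_flag": tree_report.artefact_flag,
        }

    result = PipelineResult(
        manifest=manifest, pairs=pairs, contrasts=contrasts,
        regression=regression, tree_report=tree_report,
        contrasts_all=contrasts_all, sim=sim,
    )
    if config.out_dir:
        _write_outputs(result, config)
    return result


def null_calibration_config(seed: int = 0) -> RunConfig:
    """Study conditions for the no-coupling null: family-level pairs on
    moderate birth-death trees with rate heterogeneity but gamma = 0, so
    any association between size and rate contrasts is spurious."""
    from .simulate import SimConfig

    return RunConfig(
        rank="family", seed=seed, run_tree_test=False,
        apply_monophyly=False,
        sim=SimConfig(
            lambda0=0.1, mu=0.05, T=100.0, sigma2=0.05, gamma=0.0,
            sites=2500, n_pseudo_trees=0, missing_frac=0.0,
            min_tips=30, seed=seed,
        ),
    )


COUPLED_POWER_N_TREES = 16


def coupled_power_config(seed: int = 0) -> RunConfig:
    """Study conditions for the strong-coupling power experiment:
    gamma = 1, sigma2 = 0.05, ~100 family pairs pooled over
    ``COUPLED_POWER_N_TREES`` independent clades (rate-coupled
    radiations are too imbalanced for one tree to carry that many
    equal-aged pairs)."""
    from .simulate import SimConfig

    return RunConfig(
        rank="family", seed=seed, run_tree_test=False,
        apply_monophyly=False,
        sim=SimConfig(
            lambda0=0.12, mu=0.04, T=300.0, n_tips=700, sigma2=0.05,
            gamma=1.0, sites=2500, family_age=8.0, genus_age=3.0,
            n_pseudo_trees=0, missing_frac=0.0, min_tips=60,
            max_tips=20_000, seed=seed,
        ),
    )


def run_pooled(config: RunConfig, n_trees: int, seed: int | None = None
               ) -> PipelineResult:
    """Pool pairs from several independent simulated clades into one
    regression.

    Sister pairs are statistically independent comparisons, so pairs
    drawn from separate simulated trees can be combined into a single
    contrast regression; this emulates a comparative dataset assembled
    across a large paraphyletic group, and under rate-coupled
    diversification it yields many more equal-aged pairs than any single
    highly imbalanced tree can.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    frames = []
    manifests = []
    for _ in range(n_trees):
        sub = RunConfig(**{
            **config.to_dict(),
            "sim": config.sim,
            "seed": int(rng.integers(2 ** 31)),
            "out_dir": None,
            "apply_welch": False,
            "run_tree_test": False,
        })
        try:
            res = run_pipeline(sub)
        except RuntimeError as exc:
            # a tree can come out too young or too clumped to yield pairs
            logger.warning("pooled component tree skipped: %s", exc)
            continue
        frames.append(res.contrasts)
        manifests.append(res.manifest)
    if not frames:
        raise RuntimeError("no component tree yielded pairs")
    contrasts = pd.concat(frames, ignore_index=True)
    contrasts["pair_id"] = [
        f"tree{i:02d}_{pid}"
        for i, frame in enumerate(frames)
        for pid in frame["pair_id"]
    ]
    if config.apply_welch and len(contrasts) >= 3:
        contrasts, _, _ = ctr.welch_filter(
            contrasts, alpha=config.welch_alpha
        )
    regression = None
    if len(contrasts) >= 2 and (contrasts["d_log_rate"] != 0).any():
        regression = OriginRegression.from_contrasts(contrasts).fit()
    manifest = {
        "seed": seed,
        "n_trees": n_trees,
        "per_tree": manifests,
        "n_pairs_pooled": len(contrasts),
    }
    return PipelineResult(
        manifest=manifest, pairs=[], contrasts=contrasts,
        regression=regression,
    )


def _write_outputs(result: PipelineResult, config: RunConfig):
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    pr.pairs_to_frame(result.pairs).to_csv(
        os.path.join(out, "pairs.tsv"), sep="\t", index=False
    )
    table = (result.contrasts_all if result.contrasts_all is not None
             else result.contrasts)
    table.to_csv(
        os.path.join(out, "contrasts.tsv"), sep="\t", index=False
    )
    if result.regression is not None:
        pd.DataFrame([{
            "dataset": "synthetic",
            "rate_type": config.rate_type,
            "n_pairs": result.regression.nobs,
            "coeff": result.regression.slope,
            "std_err": result.regression.bse,
            "t": result.regression.tvalue,
            "p": result.regression.pvalue,
        }]).to_csv(
            os.path.join(out, "regression.tsv"), sep="\t", index=False
        )
    if result.tree_report is not None:
        rep = result.tree_report
        pd.DataFrame([{
            "tree": "synthetic_molecular",
            "slope": rep.gls.slope,
            "likelihood_ratio": rep.gls.lrt,
            "p_value": rep.gls.pvalue,
            "delta": rep.delta_path_response.delta,
        }]).to_csv(
            os.path.join(out, "tree_test.tsv"), sep="\t", index=False
        )
        rep.per_tip.to_csv(
            os.path.join(out, "path_stats.tsv"), sep="\t", index=False
        )
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=1, default=str)
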