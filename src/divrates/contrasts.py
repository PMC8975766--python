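"""Per-pair log contrasts and the pre-regression filters.

For each sister pair the analysis works with differences of natural
logarithms between clade A and clade B, in both clade size (a proxy for
the net diversification rate contrast, the clades being equal-aged) and
phylogenetically averaged substitutions per site.

Two filters guard the regression:

* the shallow-pair ("Welch") filter iteratively removes the youngest
  pair while the absolute rate contrast declines significantly with the
  square root of pair age — shallow pairs carry noisy rate estimates
  whose inflated contrasts sap power;
* the small-rate outlier filter removes pairs whose mean rate is tiny
  yet whose rate contrast is extreme, the signature of unstable ML
  branch-length optimisation on near-zero branches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONTRAST_COLUMNS = [
    "pair_id", "rank", "rate_type", "d_log_size", "d_log_rate",
    "age", "mean_rate",
]


def compute_contrasts(pairs, summaries, rate_type: str = "total"
                      ) -> pd.DataFrame:
    """Log contrasts (clade A minus clade B throughout) per pair.

    ``summaries`` is a list of (CladeRateSummary_a, CladeRateSummary_b)
    aligned with ``pairs`` by pair_id.  Pairs with a zero rate on either
    side cannot be log-transformed and are excluded with a logged reason.
    """
    by_id = {a.pair_id: (a, b) for a, b in summaries}
    rows = []
    for pair in pairs:
        if pair.pair_id not in by_id:
            continue
        a, b = by_id[pair.pair_id]
        ra, rb = a.rate(rate_type), b.rate(rate_type)
        if ra is None or rb is None:
            continue
        if ra <= 0 or rb <= 0:
            logger.info(
                "%s excluded from contrasts: zero %s rate",
                pair.pair_id, rate_type,
            )
            continue
        if pair.size_a < 1 or pair.size_b < 1:
            raise ValueError(f"{pair.pair_id}: clade sizes must be >= 1")
        rows.append({
            "pair_id": pair.pair_id,
            "rank": pair.rank,
            "rate_type": rate_type,
            "d_log_size": math.log(pair.size_a) - math.log(pair.size_b),
            "d_log_rate": math.log(ra) - math.log(rb),
            "age": pair.age,
            "mean_rate": 0.5 * (ra + rb),
        })
    return pd.DataFrame(rows, columns=CONTRAST_COLUMNS)


@dataclass
class WelchTrace:
    n_pairs: int
    slope: float
    p_one_sided: float
    removed_pair: str | None


def welch_filter(
    contrasts: pd.DataFrame,
    alpha: float = 0.05,
    normalise: str = "raw",
) -> tuple[pd.DataFrame, pd.DataFrame, list[WelchTrace]]:
    """Iteratively remove the shallowest pair while |rate contrast|
    declines significantly with sqrt(age).

    At each step an ordinary least-squares line (with intercept) of the
    absolute normalised rate contrast on sqrt(age) is fitted; if the
    slope is negative with one-sided p < alpha, the youngest pair is
    removed and the test repeated.  Stops when the relationship is no
    longer significantly negative, or fewer than 3 pairs remain.

    ``normalise`` selects the contrast variant tested: "raw" uses
    |d_log_rate| itself; "sqrt_age" divides it by sqrt(age).

    Returns (kept, removed, trace).
    """
    if normalise not in ("raw", "sqrt_age"):
        raise ValueError("normalise must be 'raw' or 'sqrt_age'")
    work = contrasts.copy()
    if work["age"].isna().any():
        raise ValueError("welch_filter requires ages for every pair")
    removed_idx = []
    trace: list[WelchTrace] = []
    while True:
        if len(work) < 3:
            logger.warning(
                "welch_filter stopped: fewer than 3 pairs remain"
            )
            break
        x = np.sqrt(work["age"].to_numpy(dtype=float))
        y = np.abs(work["d_log_rate"].to_numpy(dtype=float))
        if normalise == "sqrt_age":
            y = y / np.sqrt(work["age"].to_numpy(dtype=float))
        if np.ptp(x) == 0:
            logger.warning(
                "welch_filter: all ages equal; regression on sqrt(age) "
                "undefined, no removals"
            )
            break
        fit = stats.linregress(x, y)
        p_one = fit.pvalue / 2 if fit.slope < 0 else 1 - fit.pvalue / 2
        if fit.slope < 0 and p_one < alpha:
            youngest = work["age"].idxmin()
            trace.append(WelchTrace(
                len(work), fit.slope, p_one, work.loc[youngest, "pair_id"]
            ))
            removed_idx.append(youngest)
            work = work.drop(index=youngest)
        else:
            trace.append(WelchTrace(len(work), fit.slope, p_one, None))
            break
    removed = contrasts.loc[removed_idx]
    return work, removed, trace


def small_rate_outlier_filter(
    contrasts: pd.DataFrame,
    min_mean_rate: float = 1e-4,
    max_abs_contrast: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove pairs with mean rate below ``min_mean_rate`` AND absolute
    log-rate contrast above ``max_abs_contrast`` (both conditions jointly).
    """
    if contrasts.empty:
        return contrasts, contrasts
    bad = (contrasts["mean_rate"] < min_mean_rate) & (
        contrasts["d_log_rate"].abs() > max_abs_contrast
    )
    return contrasts[~bad], contrasts[bad]
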