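"""Poisson power analysis for sister-pair rate contrasts.

Over a pair of age A Myr, rate r subs/site/Myr and an alignment of L
sites, the number of substitutions accumulated along one side is
approximated as Poisson with mean lambda = A * r * L.  If the two clades'
underlying rates differ by a factor ``fold``, the chance that the truly
faster clade also shows the larger observed count is a tail probability
of the Skellam distribution (the difference of two independent Poisson
counts); ties count as failures.  This quantifies how often a real rate
contrast survives sampling noise as a positive observed contrast, and
hence how alignment length and pair age trade off against the number of
pairs in a sign test across pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class PowerSpec:
    age: float     # pair age, Myr
    rate: float    # substitutions/site/Myr
    sites: float   # alignment length, bases
    fold: float = 1.1  # ratio of underlying clade rates (>= 1)

    def __post_init__(self):
        if min(self.age, self.rate, self.sites) <= 0:
            raise ValueError("age, rate and sites must be positive")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")


@dataclass
class PowerResult:
    lam: float         # Poisson mean count in the lower-rate clade
    p_positive: float  # P(higher-rate clade shows the larger count)


def poisson_mean(spec: PowerSpec) -> float:
    """Expected substitution count: age * rate * sites."""
    return spec.age * spec.rate * spec.sites


def prob_positive_contrast(lam: float, fold: float) -> float:
    """P(X2 > X1) for independent X1 ~ Poisson(lam), X2 ~ Poisson(fold*lam).

    Computed exactly as the upper tail of the Skellam distribution of
    X2 - X1 at zero; equal counts do not count as positive.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    return float(stats.skellam.sf(0, fold * lam, lam))


def prob_positive_contrast_normal(lam: float, fold: float) -> float:
    """Normal approximation with continuity correction, documenting the
    regime in which the exact Skellam value is well approximated."""
    mean = (fold - 1.0) * lam
    sd = np.sqrt((fold + 1.0) * lam)
    return float(stats.norm.sf(0.5, loc=mean, scale=sd))


def analyse(spec: PowerSpec) -> PowerResult:
    lam = poisson_mean(spec)
    return PowerResult(lam=lam, p_positive=prob_positive_contrast(
        lam, spec.fold
    ))


def _sign_test_power(n: int, p: float, alpha: float = 0.05) -> float:
    """Power of the one-sided exact binomial sign test of H0: P = 0.5
    against P > 0.5, at per-pair success probability p."""
    # critical value: smallest c with P(Bin(n, .5) >= c) <= alpha
    crit = int(stats.binom.isf(alpha, n, 0.5))
    while stats.binom.sf(crit - 1, n, 0.5) > alpha:
        crit += 1
    while crit > 0 and stats.binom.sf(crit - 2, n, 0.5) <= alpha:
        crit -= 1
    return float(stats.binom.sf(crit - 1, n, p))


def power_equivalent_pairs(
    n_pairs: int,
    p_old: float,
    p_new: float,
    alpha: float = 0.05,
    max_added: int = 10_000,
) -> int:
    """How many extra pairs at per-pair success probability ``p_old``
    match the sign-test power gained by raising the probability to
    ``p_new`` at the original ``n_pairs``.

    Returns the smallest k such that the one-sided exact binomial sign
    test with n_pairs + k pairs at p_old meets or exceeds its power with
    n_pairs pairs at p_new.
    """
    if not (0.5 < p_old <= p_new < 1):
        raise ValueError("require 0.5 < p_old <= p_new < 1")
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    target = _sign_test_power(n_pairs, p_new, alpha)
    for k in range(max_added + 1):
        if _sign_test_power(n_pairs + k, p_old, alpha) >= target:
            return k
    raise RuntimeError(
        f"no k <= {max_added} reaches the target power {target:.4f}"
    )
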