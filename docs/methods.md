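# Methods

`divrates` tests whether lineages that diversify faster also evolve
faster at the molecular level. It implements both of the standard
designs for this question — sister-pair contrast regression and the
whole-tree node-count/path-length analysis — together with the exact
Poisson power calculation for contrast sign recovery and a synthetic
data generator that embodies the causal structure the analysis is meant
to detect. This note records the models, the defaults and why they are
set where they are, and the design choices that were genuinely open.

## Sister-pair contrast analysis

A *sister pair* is two clades descending from the same ancestral node
and sharing tips with no other pair. Because both clades are exactly the
same age, a difference in their extant species numbers reflects a
difference in net diversification rate, and a difference in their
accumulated substitutions per site reflects a difference in molecular
rate — no absolute dating is needed, and pairs are mutually independent
comparisons.

**Selection.** Tips are grouped at a taxonomic rank (family or genus);
the tree is collapsed to one representative tip per group with sequence
data (the first such tip in the written order of the tree); every cherry
of the collapsed tree is a sister pair, expanded back to the full group
membership. A pair is discarded when, in at least 80% (inclusive) of a
distribution of complete trees with stochastically placed no-data
species, some genus has members inside both of its clades — unresolved
placements make such pairs' sizes unreliable. Clade sizes are the
arithmetic mean, over the same tree distribution, of the tip count
descending from each clade's MRCA (located by the clade's sequenced
tips). Within each pair the larger clade's sequenced tips are randomly
thinned to match the smaller clade's count, which equalises the
node-density footprint of the two sides; each pair is then joined to its
nearest neighbouring pair (minimal patristic distance between pair
MRCAs on the collapsed tree, ties to the earlier pair in tip order) to
form a quartet whose second pair serves as outgroup.

**Alignment pruning.** Per quartet, a codon (coding partitions) or site
(non-coding partitions) is kept only if at least one tip in clade A, one
in clade B and one in the outgroup carry an unambiguous A/C/G/T there; a
codon counts as covered for a tip only when all three positions are
unambiguous. Quartets retaining 100 or fewer bases are dropped (strictly
"≤ 100": 101 bases survive). Mixed alignments carry an explicit
partition table and the 100-base rule applies to the concatenated total.

**Clade rate summary.** From a branch-length tree in substitutions per
site, each clade's rate is the *equal-daughter-weight* path average:
value(tip) = 0, value(node) = mean over children of (child branch +
child value), and the clade summary adds its stem branch measured from
the pair's MRCA. Equal weighting at every node stops speciose subclades
from dominating the average. The stem branch is included — the recursive
definition adds the parent branch at every level, and the pair MRCA is
the natural origin for both clades; this is stated here because the
alternative (crown-only) convention exists in the literature. Pairs in
which either clade's synonymous path average exceeds 2 substitutions per
site are discarded as saturated (strict inequality: exactly 2.0 is
kept).

**Contrasts and filters.** Per pair, contrasts are natural-log
differences, clade A minus clade B throughout: Δln(size) and Δln(rate)
per rate type. Natural logs are used throughout; the base only rescales
the slope. Two filters precede the regression:

* *Shallow-pair (Welch) filter.* Rate estimates in young pairs are
  noise-dominated and their absolute contrasts are inflated. An OLS line
  (with intercept) of |Δln rate| on √age is fitted; while the slope is
  negative with one-sided p < 0.05, the youngest pair is removed and the
  test repeated (stopping below 3 pairs, or when √age has zero
  variance). Requiring significance, not just a negative sign, keeps the
  filter from eating small datasets by chance. The contrast may
  optionally be divided by √age ("normalised" variant); the default
  tests the raw log contrast, which is already scale-free.
* *Small-rate outlier filter.* Pairs with mean rate < 1e-4 subs/site
  **and** |Δln rate| > 2 are removed: that joint signature arises from
  unstable ML optimisation of near-zero branch lengths, not from
  biology. Both thresholds are configuration values.

**Regression through the origin.** With x = Δln(rate) and y = Δln(size),
the slope is b = Σxy/Σx², residual variance s² = Σ(y − bx)²/(n − 1), SE
= √(s²/Σx²), and b/SE is referred to Student's t with n − 1 df (Wald
test, two-sided). The intercept is suppressed because two clades with no
rate contrast carry no information about the sign of their size
contrast: the expected size contrast at zero rate contrast is zero.

## Whole-tree analysis

For each root-to-tip path of a substitutions-per-site phylogeny the
package records the path length and the number of internal nodes
strictly between root and tip (edges − 1; the root is excluded, and any
constant offset is absorbed by the intercept — the convention is fixed
so results are reproducible). Path length is regressed on node count by
maximum-likelihood GLS, y ~ MVN(Xb, σ²V), with V[i,j] the root-to-MRCA
shared path length of tips i and j. Significance is a likelihood-ratio
test against the slope-0 model (intercept and σ² re-estimated), referred
to χ²₁. ML rather than REML is used so the LRT is coherent across
nested models.

**The δ node-density test.** Substitutions are systematically
under-recovered on paths with few intervening nodes, which can fake a
positive association. The three-parameter model

    response = β · predictor^(1/δ) + intercept + ε,   ε ~ MVN(0, σ²V)

is fitted with each of node count and path length as response.
Conditional on δ the model is linear, so (β, intercept, σ²) have closed
forms after Cholesky whitening and δ is found by a deterministic
1-D search: a 41-point geometric grid over [0.1, 10] followed by bounded
scalar minimisation between the bracketing grid points (the profile can
be multimodal near the linear limit; the grid stage makes the optimiser
reproducible). δ̂ pinned at a search bound raises a warning. A fit with
δ̂ > 1 together with a significant LRT for β is the artefact signature;
the report's overall flag is raised if either response direction shows
it. Under β = 0, δ is unidentifiable and the χ²₁ reference for the
profiled LRT is approximate (Davies' problem); the measured null flag
rate in the test suite is well under 10%.

**Covariance choice.** By default V is computed from the analysed tree
itself. When branch lengths carry strong counting noise this is mildly
anticonservative — the tip depths of V are then literally the response —
so `node_density_test` accepts an alternative tree (e.g. a time tree)
for V, and the simulation calibrations in the test suite use the known
noise-free generating tree, which restores exact nominal behaviour
(measured: 5% GLS null rejection; δ flags ≤ 4%; injected artefacts
flagged in ≳ 90% of replicates).

**Artefact injection.** For validation, `inject_node_density_artefact`
replaces every branch length t by τ(1 − e^(−t/τ)) with τ = tree
height/4: long unbroken branches saturate and lose proportionally more
length, so low-node paths end up disproportionately short — exactly the
curvature the δ test targets.

## Poisson power analysis

Over a pair of age A Myr with rate r subs/site/Myr and L aligned sites,
the substitution count on one side is approximated as Poisson with mean
λ = A·r·L. With underlying clade rates (r, 1.1r) — the "10% difference"
is implemented as means (λ, 1.1λ); symmetric ±5% variants are a
configuration option — the probability that the faster clade shows the
strictly larger count is the upper Skellam tail P(X₂ − X₁ > 0), computed
exactly; ties count against detection. At the family-level mitochondrial
setting (A = 74, r = 1e-3, L = 2500; λ = 185) this is 0.8195 ≈ 82%; at
the genus-level nuclear setting (A = 48, L = 1200; λ = 57.6) it is
0.684 ≈ 68%. A normal approximation with continuity correction agrees
with the exact value to < 0.01 for λ ≥ 50. `power_equivalent_pairs`
converts a gain in per-pair success probability into the equivalent
number of added pairs under a one-sided exact binomial sign test
(H₀: P = 0.5, α = 0.05): the smallest k with power(n + k, p_old) ≥
power(n, p_new). The sign-test formalisation is one defensible reading
of "equivalent power"; the statistic and n must be stated for the
number to be meaningful.

## Synthetic data generator

The generator is the package's definition of the study conditions, not a
tuning knob.

* **Tree process.** Gillespie forward simulation of birth–death with
  per-lineage speciation rate λ₀·(r/r₀)^γ and constant extinction μ;
  ln r evolves as Brownian motion with variance σ² per Myr, sampled at
  branch ends (the speciation rate of a branch uses the rate inherited
  at its birth). Coupling acts on speciation only, matching the
  hypothesis that faster molecular evolution speeds the completion of
  speciation. Extinct subtrees are pruned; the crown node becomes the
  root. Simulation stops at time T or, alternatively, when a target
  number of extant tips is reached — under strong coupling (γ = 1,
  σ² = 0.05) the radiation accelerates without bound and only the
  n-tips stopping rule yields controlled tree sizes.
* **Substitution lengths.** A branch of duration d contributes expected
  subs/site exp((ln r_start + ln r_end)/2)·d — the midpoint of the
  log-Brownian endpoints, an approximation whose error vanishes as
  σ² → 0. With an alignment of L sites the realized length is
  Poisson(expected·L)/L, the same sampling model the power analysis
  assumes; L = 0 gives noise-free lengths.
* **Taxonomy.** Genera and families are the maximal clades whose stem
  branches cross fixed age thresholds, so every tip has exactly one
  genus nested in one family.
* **Pseudo-posterior.** A fixed fraction of tips is declared "no-data";
  in each replicate tree every such tip is re-attached uniformly at
  random to a branch strictly inside its family's clade, at a uniform
  height, preserving ultrametricity. Confining placement to the family
  is a deliberate simplification of published interpolation procedures;
  it conserves family sizes exactly, which the test suite checks. A
  family whose tips are all no-data falls back to placement anywhere in
  the tree, with a warning.

**What the generator does not emulate:** real sequence evolution (no
codon model, hence no dS/dN distinction — the synthetic rate type is
"total"), non-ultrametric dating error, taxonomic misassignment, gene
tree/species tree discordance, and placement error that crosses family
boundaries. Passing calibration on these data therefore validates the
statistical machinery — selection logic, filters, estimators, test
calibration — not robustness to those further realities.

## Calibration experiments and problem sizes

Two canonical experiment configurations ship with the package
(`null_calibration_config`, `coupled_power_config`):

* *Null:* γ = 0, σ² = 0.05, λ₀ = 0.1, μ = 0.05, T = 100 Myr, families at
  25 Myr, 2.5 kb alignments — trees of a few hundred tips yielding
  ~15–20 family pairs. Over 500 replicates the origin regression rejects
  at the nominal 5% within binomial error.
* *Power:* γ = 1, σ² = 0.05, λ₀ = 0.12, μ = 0.04, 700-tip trees
  (n-tips stopping), families at 8 Myr. A single rate-coupled tree is
  far too imbalanced to carry ~100 equal-aged family pairs, so each
  replicate pools pairs from 16 independent simulated clades
  (`run_pooled`) — legitimate because pairs are independent comparisons
  by construction; this emulates a dataset assembled across a large
  paraphyletic group. Replicates average ~90 pooled pairs and a positive
  significant slope is detected in ≥ 80% of 100 replicates (typically
  all of them).

These sizes were chosen as the smallest at which the binomial error of
the replicate counts is comfortably smaller than the effects the
calibration statements assert.

## Numerical notes and edge cases

* Covariance factorisations first try an exact Cholesky, then escalate
  a diagonal jitter (10⁻¹⁰ → 10⁻⁴ of the mean diagonal) before failing;
  the LRT is invariant to uniform rescaling of V.
* The origin regression with an exact fit (zero residuals) reports
  SE = 0 and p = 0 rather than dividing by zero.
* Multifurcations yield no cherries (logged); a node with > 2 children
  never forms a pair.
* `balance_tips` is deterministic given its seed; all simulation and
  pipeline randomness flows from a single integer seed per run, and
  rerunning a pipeline with the same configuration reproduces its
  output tables byte for byte.
* Monophyly assessment skips (with a warning) trees missing a pair's
  tips and errors only if every tree is unusable; the removal threshold
  is inclusive (≥ 0.80 of assessable trees).

## Known limitations

* dS/dN estimation from sequences is out of scope; the package consumes
  branch-length trees produced by external ML software (or synthetic
  ones) and treats "which rate type" as a column label.
* The δ test's LRT reference is approximate under the null (above), and
  with same-tree V under heavy noise the whole-tree analysis is
  anticonservative; supply an independent tree for V when one exists.
* The pseudo-posterior emulates placement uncertainty only within
  families, so the monophyly filter's behaviour against cross-family
  misplacement is exercised only through hand-constructed cases in the
  test suite.
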