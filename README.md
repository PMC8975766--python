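# divrates

Sister-pair and whole-tree tests of the association between **net
diversification rate** and the **rate of molecular evolution**.

Across the tree of life, clades that accumulate more species often also
show faster molecular evolution. `divrates` implements the two standard
comparative designs for detecting such a link on a phylogeny, the
diagnostic for its best-known artefact, and the power analysis that says
when the data could have detected it at all:

* **Sister-pair contrasts** — select all mutually disjoint pairs of
  equal-aged sister clades at a taxonomic rank, summarise each clade's
  substitutions/site by equal-daughter-weight path averaging, and
  regress Δln(clade size) on Δln(rate) through the origin
  (b = Σxy/Σx², Wald t with n−1 df). Includes the monophyly filter over
  a distribution of complete trees, tip balancing, quartet outgroups,
  codon-coverage alignment pruning with the 100-base rule, the dS > 2
  saturation filter, the shallow-pair (Welch) filter and the small-rate
  outlier filter.
* **Whole-tree analysis** — per root-to-tip path, node count and path
  length; phylogenetic GLS (y ~ MVN(Xb, σ²V), V = shared root-to-MRCA
  path lengths) with a likelihood-ratio test; and the δ node-density
  test, `response = β·predictor^(1/δ) + intercept + ε`, where δ̂ > 1
  with significant β signals systematic underestimation of low-node
  paths.
* **Poisson power analysis** — substitution counts per clade as
  Poisson(λ), λ = age × rate × sites; the probability that a true rate
  difference shows up as a positive observed contrast is an exact
  Skellam tail, and sign-test power converts alignment length into an
  equivalent number of extra pairs.
* **Synthetic data** — birth–death trees with Brownian-motion rates on
  the log scale, optional speciation–rate coupling
  (λ = λ₀(r/r₀)^γ), Poisson branch-length noise at a stated alignment
  length, age-threshold taxonomy, and a pseudo-posterior of complete
  trees with randomly re-placed "no-data" tips — everything needed to
  exercise the full pipeline end to end with known truth.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

Simulate a coupled dataset (γ = 1: faster-evolving lineages speciate
more), run the full pipeline, and read off the regression:

```python
from divrates import RunConfig, SimConfig, run_pipeline

cfg = RunConfig(
    rank="family", seed=7, apply_monophyly=False,
    sim=SimConfig(lambda0=0.12, mu=0.04, T=300.0, n_tips=700,
                  sigma2=0.05, gamma=1.0, sites=2500,
                  family_age=8.0, genus_age=3.0,
                  n_pseudo_trees=0, missing_frac=0.0,
                  min_tips=60, max_tips=20000),
)
res = run_pipeline(cfg)
print(res.regression.summary())
```

```
Regression through the origin (Wald test)
=============================================
n pairs                      8
coefficient             2.2247
std. error              0.7003
t                        3.177
P>|t| (df=7)           0.01556
```

Eight family pairs survive selection on this 700-tip clade; the slope of
Δln(size) on Δln(rate) is positive (clades with higher substitution
rates hold more species) and the Wald test rejects slope 0 at p ≈ 0.016.
With γ = 0 the same pipeline yields slopes near 0
and p spread uniformly (the test suite verifies the 5% false-positive
rate over 500 replicates). The per-stage pair bookkeeping is in
`res.manifest["stages"]`; `run_pooled` combines pairs from several
independent clades when one tree cannot supply enough.

The power analysis behind "could we have seen it?":

```python
from divrates import PowerSpec, poisson_mean, prob_positive_contrast
spec = PowerSpec(age=74, rate=1e-3, sites=2500, fold=1.1)
lam = poisson_mean(spec)              # 185.0 expected substitutions
prob_positive_contrast(lam, 1.1)      # 0.8195...
```

i.e. with 2.5 kb alignments on 74-Myr-old pairs, a 10% rate difference
appears as a positive observed contrast 82% of the time; at 1.2 kb and
48 Myr (λ = 57.6) only 68%.

A command-line interface mirrors the library
(`divrates simulate | select-pairs | regress | tree-test | power |
power-pairs | run`); `divrates run --seed 6 --out-dir out/` writes the
pair, contrast, regression and tree-test tables plus a JSON manifest
recording the seed, parameters and per-filter pair counts.

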