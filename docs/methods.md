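# Methods

## The problem

Uniform differential item functioning (DIF) screening asks whether two
groups with the same standing on a latent trait have different probabilities
of endorsing an item. Logistic-regression screens condition on the observed
total score X as a proxy for the trait. When the groups differ in *extreme
response style* (ERS) — the tendency to over-use endpoint categories
irrespective of content — X is contaminated: two respondents with the same
trait but different styles earn systematically different totals, matching
breaks down, and DIF-free items get flagged. `ersdif` implements (a) a
generative model for style-contaminated ordinal responses, (b) the two
standard logistic-regression detectors, (c) modified detectors that add the
per-person variance of item scores as an extra matching variable, and (d) a
Monte-Carlo harness that measures false/true-positive rates.

## Generative model: the ERS-GPCM

For person *n* with latent trait θ_n and style multiplier ω_n > 0, and item
*i* with slope β_i > 0, location δ_i and step thresholds τ_i1..τ_i,M−1, the
adjacent-category log-odds are

    log[P(Y=j) / P(Y=j−1)] = β_i (θ_n − (δ_i + ω_n τ_ij)),  j = 1..M−1.

Category probabilities are softmax-normalized cumulative sums of those
steps, with the j = 0 sum defined as 0. Small ω compresses the thresholds
(extreme responding), large ω disperses them (mild responding), and ω ≡ 1
recovers the generalized partial credit model exactly. θ and ω are
independent.

Populations: θ ~ Normal(0, 1); log ω ~ Normal(μ, σ²_ω). Specifying the mean
and variance of ω on the log scale is the only coherent choice for a
positive variable with "mean zero". The study conditions fix σ²_ω = 0.6 and
move the group means of log ω symmetrically: (0, 0) for condition I,
(+0.2, −0.2) for II, (+0.3, −0.3) for III — gaps of 0, 0.4 and 0.6. A
plausible alternative reading of the ω spread sets the *natural-scale*
variance of ω to 0.6 (i.e. a smaller, group-dependent σ²_ω); it produces
visibly weaker contamination (e.g. the 10-item condition III OLR rate drops
from ≈0.43 to ≈0.29 and the item-1 ASD from ≈0.078 to ≈0.058). We fix the
log-scale-variance convention package-wide, consistent with the
lognormal(0, 0.3²) notation used for item slopes, and note that the choice
materially affects every condition II/III rate.

Item populations: δ ~ Uniform(−2, 2), β ~ lognormal(0, 0.3²), τ fixed at
(−0.6, 0, 0.6) for four-category items. Two frozen benchmark instruments
(10 and 20 items, `fixtures.benchmark_items`) are used by the studies so
every rate table refers to the same items; items are sampled once and held
fixed across replications while persons are redrawn each replication.

## Detectors

All four detectors test uniform DIF on one studied item with response Y,
given total score X = Σ_i Y_i (studied item included — the instrument total
is the matching variable and no purification is attempted) and group
G ∈ {0 = reference, 1 = focal}.

* **OLR** — proportional-odds model logit P(Y ≤ j) = c_j + γ1 X + γ2 G;
  flag if γ2 ≠ 0 at level α.
* **LDFA** — binary logistic model logit P(G = 1) = α0 + α1 X + α2 Y; flag
  if α2 ≠ 0.
* **OLR-m / LDFA-m** — the same models augmented with S, the per-person
  sample variance (denominator I − 1) of the I item scores, and the
  interaction X·S. S is a direct observable proxy for ω (endpoint-heavy
  response vectors have large score variance; the simulated correlation
  between S and ω is ≈ −0.4), so conditioning on it absorbs the group
  difference in style before γ2/α2 is assessed. Variance is used rather
  than SD because its correlation with ω is slightly stronger; both are
  exposed in `ers_indicator_correlation`.

The group coefficient's Wald z-test is the default decision rule; a
likelihood-ratio test is available via `DetectorConfig(test="lrt")` (the two
agree asymptotically; their p-values correlate > 0.99 on null data).
Non-uniform DIF terms (X·G, X·Y) are constrained to zero by default
(`uniform_only=True`); the API can fit them but their operating
characteristics are not studied here. Direction marks code "+" as favoring
the focal group (higher endorsement at matched total).

Numerical notes. The proportional-odds fitter is a damped Newton-Raphson
with analytic gradient and Hessian on the cutpoints-plus-shared-slopes
parameterization, started at the marginal cumulative logits; it converges
in ~5 iterations at n = 1,000 and is cross-checked against statsmodels'
`OrderedModel` (log-likelihood agreement to 1e-6, ~20× faster, which is
what makes 1,000-replication studies practical). Unobserved outcome
categories are collapsed before fitting. Rank-deficient designs raise
immediately; a constant score-variance column silently reduces the modified
design to the standard one (S then carries no information). The binary
logit is statsmodels' `Logit`; separation or non-convergence is recorded on
the result (`converged=False`, never flagged) rather than raised, and
failed fits are counted and retained — silently regenerating a replication
would bias the rates.

## Study harness

A `StudyCondition` fixes instrument length (10/20), style condition
(I/II/III), 500 simulees per group, four categories, optional DIF
injection, and 1,000 replications. Replication seeds are spawned from the
master seed (`SeedSequence`), so every rate table is exactly reproducible.
The per-item flag proportion across replications is the false-positive rate
(DIF-free items) or true-positive rate (injected items); condition averages
are arithmetic means over the relevant item set.

DIF injection shifts the focal group's δ by ∓0.2 logits on the first 20% of
items ("favoring" a group = lowering its δ, which raises its expected
score; the assignment of DIF to the lowest item indices is a convention,
configurable via `item_indices`). Balanced injection favors each group on
half the DIF items; unbalanced favors the focal group on all of them.

The **average score difference** (ASD) diagnostic draws 100,000 simulees
per group, computes each simulee's model-expected item score from their
true (θ, ω), and reports the absolute difference in group means per item.
On DIF-free items a non-zero ASD measures exactly the contamination that
total-score matching cannot remove; across the 20-item benchmark it ranks
items in nearly the same order as their false-positive rates.

## What the simulations do and do not show

The generator emulates style-contaminated Likert data with a
unidimensional trait, style acting only multiplicatively on thresholds,
item parameters identical across groups (except injected DIF), independent
θ and ω, and complete responses. Real scales violate several of these
(correlated traits and styles, acquiescence, missingness, multidimensional
content), so nominal error control here demonstrates that the modified
detectors remove *this* contamination mechanism, not that they are robust
to every response-style process.

Against the published benchmark tables this implementation reproduces:
nominal error control of all four detectors without a style gap (average FP
≈ 0.05); severe, gap-monotone inflation of the standard detectors with OLR
worse than LDFA; near-nominal rates for the modified detectors (10-item
OLR-m ≈ 0.07, 20-item LDFA-m ≈ 0.055 under the large gap); and the
positive ASD-FP association. The *magnitude* of inflation in conditions
II/III is sensitive to the lognormal-ω convention discussed above: under
the log-scale-variance convention the 10-item standard-OLR rates come out
around 0.26/0.43 (moderate/large gap) versus published values of
0.19/0.31, and the item-1 ASD at 0.078 versus 0.05, while the 20-item
condition III OLR average (≈0.37) matches. No single convention we
examined reproduces all printed values simultaneously (in particular, the
published tables show more inflation for the 20-item than the 10-item
instrument, whereas longer tests yield better matching — hence less
inflation — under every convention here).

## Problem sizes

Default test-suite and acceptance runs use the study's full design
(500/group, 1,000 replications) for the headline rates; the null-condition
check in the test suite uses 250 replications with a correspondingly wider
tolerance, and the examples use 100 replications. These sizes are the
package's chosen defaults; all are parameters of `StudyCondition`.
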