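# ersdif

Response-style-aware detection of differential item functioning (DIF) in
Likert-type scales.

## The problem

Survey items are screened for DIF to make sure that, say, men and women
with the same level of anxiety have the same probability of endorsing "I
felt nervous". The standard logistic-regression screens match respondents
on the instrument's total score X. But groups often differ in *extreme
response style* (ERS) — the habit of ticking endpoint categories regardless
of content. A style gap distorts total scores without any item being
biased, the matching breaks, and perfectly fair items get flagged: in the
simulations here, the usual 5% false-positive rate grows to 25-40% under a
large style gap.

`ersdif` provides:

* **ERS-GPCM simulator** — a generalized partial credit model in which each
  person's step thresholds are scaled by a style multiplier ω
  (`log[P(Y=j)/P(Y=j−1)] = β(θ − (δ + ωτ_j))`): small ω = extreme
  responder, large ω = mild responder, ω ≡ 1 = plain GPCM.
* **Four uniform-DIF detectors** — standard ordinal logistic regression
  (OLR: `logit P(Y ≤ j) = c_j + γ1X + γ2G`, test γ2) and logistic
  discriminant function analysis (LDFA: `logit P(G=1) = α0 + α1X + α2Y`,
  test α2), plus modified variants (OLR-m, LDFA-m) that add the per-person
  variance of item scores S and its interaction X·S as extra matching
  covariates to absorb the style gap.
* **Monte-Carlo harness** — replication studies of false/true-positive
  rates on frozen 10- and 20-item benchmark instruments, DIF injection,
  and the average-score-difference (ASD) diagnostic.
* **Empirical pipeline + CLI** — screen your own `group + items` CSV with
  all four methods (`ers-dif empirical`), or use the `simulate`, `detect`,
  `study` and `asd` subcommands.

## Worked example

`examples/03_false_positive_study.py` runs a scaled-down (100-replication)
null study — every item DIF-free — while widening the group gap in mean
log ω from 0 (condition I) to 0.4 (II) and 0.6 (III):

```
condition   olr     ldfa    olr_m   ldfa_m   (average FP, nominal 0.05)
  I       0.049   0.044   0.052   0.047
  II      0.261   0.173   0.061   0.051
  III     0.430   0.285   0.079   0.063
```

Reading the rows: with no style gap every method holds the 5% nominal
false-positive rate; as the gap grows the standard OLR and LDFA flag up to
43% and 29% of perfectly fair items, while the variance-augmented OLR-m and
LDFA-m stay near nominal. The other examples show the simulator's category
usage, a single-dataset screen, and the per-item ASD diagnostic that
explains *which* items get falsely flagged (discriminating items located
far from the trait mean).

Library use in five lines:

```python
from ersdif import DetectorConfig, benchmark_items, detect_dif_all, read_response_csv

data = read_response_csv("responses.csv")          # group column + item columns
for r in detect_dif_all(data, DetectorConfig(method="olr_m")):
    print(r.item_index + 1, round(r.p_value, 4), r.flagged, r.direction)
```

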