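# multimorbid

Unsupervised discovery of **multimorbidity patterns** — which chronic
diseases cluster together in a population — from survey-style cohort data of
older adults. The package targets epidemiologists and health-services
researchers working with wide binary disease matrices (one row per subject,
one column per condition) of the kind produced by community health
screenings: 21 chronic conditions including hyperuricemia (derived from
serum uric acid), hypertension, diabetes, hyperlipidemia and coronary heart
disease.

## Method

The core is a **two-stage clustering**:

1. **Self-organizing map (SOM).** A 30×30 hexagonal Kohonen lattice is
   trained online on the binary disease matrix `X ∈ {0,1}^{N×21}`. At step
   *t* a random subject `x(t)` is presented, its best-matching unit (BMU)
   `c = argmin_i ‖x − m_i‖²` located, and every prototype updated by

   `m_i ← m_i + α(t) · h_ci(t) · (x − m_i)`,

   with learning rate `α(t)` decaying linearly 0.05 → 0.01 over 20,000
   iterations and Gaussian neighborhood
   `h_ci = exp(−d²(c,i)/2σ(t)²)` on the hex lattice.

2. **Activation-weighted k-means.** The codebook vectors `m_j` are
   clustered by k-means in which each node is weighted by its **activation
   frequency** `w_j` (number of subjects whose BMU it is), minimizing

   `J = Σ_j w_j · ‖m_j − c_{a(j)}‖²`

   with weighted-mean centroid updates and weighted k-means++ seeding, best
   of 20 restarts. `k` is chosen from the weighted within-cluster
   sum-of-squares (WSS) elbow; subjects inherit the cluster of their BMU.
   Weighting by activation frequency makes the second stage respect how the
   population is actually distributed over the map instead of treating every
   node as one point.

Around the clustering the package provides the standard descriptive
apparatus: per-disease **prevalence**, **overall comorbidity rate**
(subjects with the disease *and* another condition, over N) and **internal
comorbidity rate** (same numerator, over the disease's patients); top-k
two- and three-disease combination prevalences; stratified multimorbidity
tables and ordinal trend tests; from-scratch **Apriori** association-rule
mining (support ≥ 3%, confidence ≥ 30%, ≤ 3 antecedents) overall and per
cluster; and per-cluster profiles with chi-square / ANOVA / Tukey HSD
between-cluster comparisons.

Because real screening cohorts are rarely shareable, the package ships a
seeded **synthetic cohort generator** with a planted latent-class structure
(four clusters: all-hypertension; hypertension+diabetes; low-disease;
all-hyperuricemia) whose mixture marginals are calibrated to published
older-adult prevalences, so the whole pipeline is testable end to end with
known ground truth.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from multimorbid import (
    synthetic_study, two_stage_cluster, comorbidity_table,
    combination_prevalence, mine_rules,
)

synth, prep = synthetic_study(n_subjects=8911, seed=1)   # generate + preprocess
res = two_stage_cluster(prep.matrix, k=4, seed=1, scan_k=(1, 8))

print(res.elbow.round(1))                 # weighted-WSS elbow table
print(comorbidity_table(prep.matrix).head(4))
print(combination_prevalence(prep.matrix, 2, top_k=3))
print(adjusted_rand_score(synth.true_labels, res.assignment))
print(mine_rules(prep.matrix).head(3))
```

Representative output (seed 1):

```
 k    wss
 1 5480.9
 2 3481.5
 3 2327.3
 4 1608.3      <- elbow flattens after k=4
 ...

                patients  prevalence_pct  overall_pct  internal_pct
hyperuricemia       3628           40.71        25.07         61.58
hypertension        3160           35.46        26.35         74.30
diabetes            1350           15.15        11.60         76.59
hyperlipidemia      1017           11.41         9.58         83.97

hypertension, hyperuricemia  17.18%   <- most common disease pair
diabetes, hypertension        8.16%
hyperlipidemia, hypertension  6.94%

ARI vs planted labels: 0.848

                     antecedent      consequent  support  confidence   lift
      (diabetes, hyperuricemia) (hypertension,)   0.0384       0.624  1.760
(hyperlipidemia, hyperuricemia) (hypertension,)   0.0323       0.623  1.758
              (hyperlipidemia,) (hypertension,)   0.0694       0.608  1.714
```

Reading it: hyperuricemia and hypertension dominate the cohort (40.7% and
35.5% prevalence) and their pair is by far the most common comorbidity
(17.2% of all subjects). The elbow flattens after k=4, and the two-stage
clustering recovers the four planted clusters with an adjusted Rand index
of 0.85; the recovered "hypertension" cluster is 100% hypertensive. The top
association rules all point into hypertension, the most connected disease.

A `multimorbid` console script exposes the same pipeline stage by stage
(`synth`, `preprocess`, `som-train`, `cluster`, `stats`, `rules`,
`profile`); run `multimorbid --help`.

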