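# Methods

## Problem setting

The package analyzes multimorbidity — the simultaneous presence of two or
more chronic diseases — in survey cohorts of adults aged 60–92. The unit of
analysis is a wide binary matrix over 21 chronic conditions (canonical
column order in `multimorbid.diseases.DISEASES`). Twenty indicators are
self-reported; hyperuricemia is derived from serum uric acid with
sex-specific strict thresholds (males > 420 μmol/L, females > 360 μmol/L;
"exceeding" is read literally, so a value equal to the threshold is
negative). Cardiometabolic multimorbidity means at least two of
{hypertension, diabetes, coronary heart disease, stroke, hyperlipidemia}.

## Preprocessing and exclusions

`build_matrix` drops and logs (with one reason code each) rows with an
unusable sex, missing age or age < 60, missing or non-positive uric acid, or
any missing/miscoded disease indicator. "Multiple missing values" criteria
in field practice vary; this operationalization is deliberately strict —
any missing disease indicator excludes the subject — because imputation is
out of scope and partial disease vectors would corrupt the count-based
definitions. A missing BMI is tolerated (its class is left missing) since
BMI does not enter the disease matrix. BMI classes are half-open
(<18.5 / [18.5,25) / [25,30) / ≥30 kg/m²); age groups are 60–65, 66–70,
71–75 with 76+ pooled.

## Two-stage clustering

**Stage 1 — SOM.** Online Kohonen training on the binary matrix. Choices the
literature leaves open, all exposed as estimator parameters:

* *Grid*: 30 × 30 hexagonal (offset coordinates, odd rows shifted +0.5,
  row spacing √3/2; lattice distance is the Euclidean distance between node
  centers, so immediate hex neighbours sit at distance 1).
* *Initialization*: codebook vectors sampled from data rows uniformly with
  replacement (seeded).
* *Sampling*: one row per iteration, uniform with replacement, 20,000
  iterations; on a ~9k cohort this is ≈ 2.2 presentations per subject.
* *Learning rate*: linear 0.05 → 0.01 (the "initial/final" phrasing of the
  usual recipe read as linear interpolation).
* *Neighborhood*: Gaussian `exp(−d²/2σ²)` with σ decaying linearly from
  ⅔·max(grid dims) = 20 to 1.0 — standard Kohonen practice; nothing in the
  method depends on this exact kernel and it is configurable.
* *Distance*: squared Euclidean, which equals Hamming distance on binary
  rows; no column scaling since all columns share the {0,1} scale.
* *Ties*: BMU ties break to the lowest node index (deterministic).

Every update is a convex combination of the current prototype and a data
row, so codebooks trained on binary data remain in [0,1]²¹ exactly.
Quantization error (mean Euclidean distance of subjects to their BMU) is
recorded at evenly spaced checkpoints *during* training; the pre-training
value is not a useful baseline here because a codebook seeded with data rows
trivially near-matches binary data before any smoothing has happened.

**Stage 2 — weighted k-means.** Node activation frequencies (subjects per
BMU) weight the codebook clustering: J = Σ w_j‖m_j − c_{a(j)}‖², Lloyd
alternation with weighted-mean centroid updates, weighted k-means++ seeding
(selection probability ∝ w·D²), 20 restarts by default, convergence when
assignments stop changing or after 300 iterations. Zero-activation nodes are
excluded from the objective and centroid updates and assigned to their
nearest centroid afterwards — empty map regions should not distort
centroids. An empty cluster during Lloyd is re-seeded at the point with the
largest weighted distance contribution. k is chosen by the user from the
weighted-WSS elbow table (`elbow_scan`); the pipeline default is k = 4 and
the elbow table is always available. Subjects inherit their BMU's cluster.

## Descriptive statistics

For disease *d* with `patients` carriers, of whom `with_other` have at least
one additional condition, over N included subjects:
prevalence = patients/N, overall comorbidity rate = with_other/N, internal
comorbidity rate = with_other/patients, so overall = internal × prevalence
exactly. Combination prevalence counts subjects carrying *all* diseases of a
set regardless of others, hence is anti-monotone under set inclusion; top-k
ranking breaks ties lexicographically on the sorted disease-name tuple so
output order is deterministic. Report percentages are rounded half-up to two
decimals; exact fractions are kept in the numeric columns.

The trend of disease count across an ordered stratification (age group, BMI
class) is tested by OLS of the count on ordinal scores 1..G with the
two-sided zero-slope p-value — the simplest reading of a "linear trend
test"; a constant response returns p = 1.

## Association rules

Level-wise Apriori written in-package (no miner in the dependency stack):
size-ℓ candidates joined from frequent (ℓ−1)-sets sharing a prefix, pruned
by downward closure, counted in one vectorized pass per level. Thresholds
follow the convention for older-adult multimorbidity surveys: support ≥ 3%,
confidence ≥ 30%, antecedents ≤ 3 (itemsets explored to size 4). The support
denominator is all included subjects, not only multimorbid ones, consistent
with the combination-prevalence definition. Consequents are single diseases
by default (`singleton_consequents=False` enables multi-item consequents).
Rules are sorted by lift, support, then lexicographically.

## Between-cluster comparisons

Sex: chi-square on the sex × cluster table plus all pairwise 2×2 follow-ups,
continuity correction off by default (switchable), and no further
multiplicity adjustment on the pairwise chi-squares — users who want one can
apply it to the reported p-values. Age and BMI: one-way ANOVA plus Tukey HSD
for all cluster pairs (statsmodels implementation; exact adjusted p-values,
not the rounded summary table). Zero-variance clusters are flagged, not
fatal, and empty clusters are reported rather than raised since
elbow-chosen k on small runs can produce them.

## Synthetic cohort generator

The generator defines the study conditions for all tests: a latent-class
mixture in which each subject draws a cluster, then the 21 diseases
independently given the cluster, so every marginal and pairwise rate has a
closed form (`GeneratorConfig.mixture_marginals`). The default plants four
clusters with proportions (2477, 736, 3644, 2054)/8911:

1. **Hypertension cluster** — hypertension 1.0, hyperuricemia 0.4832,
   hyperlipidemia 0.1514, coronary heart disease 0.0751, arthritis 0.0593.
2. **Hypertension+diabetes cluster** — both 0.9966 (joint ≈ 0.9932),
   hyperuricemia 0.4649, hyperlipidemia 0.3204, coronary heart disease
   0.1554.
3. **Low-disease cluster** — per disease, the residual probability that
   makes the mixture marginal equal the target overall prevalence
   (clipped to [0,1]); e.g. diabetes 0.106, hyperlipidemia 0.063,
   hypertension and hyperuricemia ≈ 0.
4. **Hyperuricemia cluster** — hyperuricemia 1.0, hypertension 0, diabetes
   0.1032, hyperlipidemia 0.0813.

Diseases with no cluster-specific information receive the overall target
prevalence in every cluster. Demographics: per-cluster truncated-normal age
(means 68.51/69.11/67.07/67.41, SDs ≈ 5.1–5.7, bounds [60, 92] years) and
BMI (bounds [14, 45] kg/m²; means/SDs chosen so the truncated-normal class
masses approximate the observed per-cluster BMI class fractions, e.g. 25.3
± 3.1 in cluster 1 vs 24.0 ± 3.0 in cluster 3); per-cluster female
proportions (0.417/0.428/0.418/0.457); education, smoking and drinking from
overall survey margins, independent of cluster. Serum uric acid is drawn
per sex (male 360 ± 60, female 310 ± 55 μmol/L) truncated to the side of
the sex threshold dictated by the drawn hyperuricemia indicator, so the
preprocessing threshold rule recovers the planted indicator exactly. The
uric-acid parameters are shared across clusters: the cluster signal lives
in the indicator, not the continuous value.

**What the generator does not emulate:** within-cluster disease
correlation (diseases are conditionally independent given the class), which
real cohorts have — published lift values for multi-disease rules are
therefore not numerically reproducible from this generator (the
conditional-independence mixture implies, e.g., lift ≈ 1.2–1.8 for the top
rules rather than any particular published figure); cluster-dependent
education/smoking/drinking gradients; longitudinal disease onset; and
survey artifacts such as misreporting. Passing tests therefore demonstrate
that the pipeline recovers a planted latent-class structure of realistic
size and separation, not that it would produce identical clusters on any
particular real cohort.

## Problem sizes and numerical choices

The full-scale checks run the complete pipeline at n = 8,911 with the
default 30×30 map and 20,000 iterations (a few seconds of CPU); oracle
checks use exhaustively enumerable sizes (≤ 10 nodes for the partition
minimum, ≤ 10 items for itemset enumeration); calibration checks use 1,000
null replicates. Elbow monotonicity in k is only guaranteed up to restart
noise; with 20 restarts it holds to 1e-9 in the shipped tests. Weighted WSS
is recomputed at the accepted solution with the non-expanded squared
distance form to avoid catastrophic cancellation. The planted-cluster
recovery criterion is an adjusted Rand index of at least 0.8: the
activation-weighted second stage reliably separates the hypertension,
hypertension+diabetes, low-disease and hyperuricemia groups, with the
residual disagreement coming from boundary nodes that mix low-prevalence
subjects.

## Known limitations

* Clustering quality is assessed only against the generator's planted
  labels and the weighted-WSS elbow; silhouette/gap statistics and the
  comparison baselines (latent class analysis, MCA+k-means, plain k-means)
  are out of scope.
* The SOM neighborhood kernel, radius schedule and sampling regime are
  conventional defaults, not fitted quantities; conclusions about map
  topology should be checked for sensitivity via the exposed parameters.
* No imputation: subjects with missing indicators are excluded, which
  biases toward complete responders.
* Confidence intervals on prevalences are not provided.
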