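# Methods

`tfcia` infers which transcription factors (TFs) are associated with an
acquired-resistance phenotype by coupling two tables that share their gene
index: a gene × sample expression matrix from a parental line and two
resistant sublines, and gene × motif counts of TF binding sites (TFBS) in
the same genes' promoters, provided at four position-specific scoring
matrix (PSSM) match thresholds (0.70/0.75/0.80/0.85). It also implements
the clinical statistics used to validate such a prediction in an
immunohistochemistry (IHC)-scored metastatic cohort.

## Discovery arm

### Moderated differential expression

Expression values are assumed to be RMA-style log2 intensities. Columns are
quantile-normalized to the mean empirical distribution (ties averaged over
their target positions). For each resistant-vs-parental comparison the
per-gene statistic is a two-sample mean difference with pooled variance
s²_g on d_g = n_A + n_B − 2 df, moderated by an empirical-Bayes scaled-F
prior: (d₀, s₀²) are moment-matched on z_g = log s²_g via a digamma
correction and a trigamma (Newton) inversion of the excess variance of z,
exactly as in the standard microarray formulation; the posterior variance
is s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) and t̃_g = β̂_g / √(s̃²_g(1/n_A+1/n_B))
is referred to a t distribution on d_g + d₀ df. When the log-variances are
under-dispersed relative to pure χ² sampling noise the inversion has no
solution and d₀ is set to ∞ (full shrinkage) with a logged warning — the
correct limit when residual variances are genuinely constant, as in the
default generator. The implementation is cross-checked against the
Bioconductor reference fit (`limma::eBayes` via Rscript) to ~1e-8 in a
test. P-values are Benjamini–Hochberg adjusted (statsmodels step-up,
verified against a brute-force oracle), and the final gene list is the
*consistent overlap*: adjusted P < 0.01 in **both** comparisons with the
same sign of the log fold change. Sign concordance is one reading of
"consistent"; a flag (`require_sign_concordance=False`) gives joint
significance alone.

A property worth knowing: quantile normalization assumes near-identical
column distributions. When a planted (or real) shift affects a noticeable
gene fraction in most samples, QN attenuates the fold changes of those
genes by roughly the shifted-sample fraction. The moderated test itself has
essentially full power for |logFC| ≥ 2 at n = 4+4, σ = 0.5 (verified by
simulation); downstream of QN the recovered fraction is lower. The
TF-consensus arm is robust to this attenuation because it uses relative
gene contrasts, not absolute calls.

### Non-symmetric correspondence analysis (NSCA)

Both coupled tables are decomposed as NSCA triplets. With P the table
scaled to unit grand total, row masses r_i = Σ_j p_ij and column masses
c_j = Σ_i p_ij, the transformed table is

    q_ij = p_ij / c_j − r_i,

i.e. column profiles centered by the mean profile, decomposed by the SVD
of Q with columns weighted √c_j (rows unweighted). The total inertia
Σ_j c_j Σ_i q²_ij is the numerator of Goodman–Kruskal's τ with columns as
predictors, and equals the eigenvalue sum (tested to 1e-10 relative on
random tables). All-zero columns are rejected (undefined profile);
all-zero gene rows are tolerated (they simply carry no inertia). Axes get
a deterministic sign (largest-|loading| column element positive) so reruns
are bit-identical.

NSCA of near-homogeneous log-intensity tables has very small absolute
inertia (profiles are nearly equal across samples); only relative
structure matters, and every downstream quantity (RV, rankings) is
scale-normalized.

### Co-inertia analysis (CIA) and its row metric

CIA decomposes Z = A_wᵀ D B_w, the weighted cross-product of the two
transformed tables over their shared gene rows; the squared singular
values sum to the total co-inertia ‖Z‖²_F, and

    RV = ‖Z_AB‖²_F / √(‖Z_AA‖²_F · ‖Z_BB‖²_F) ∈ [0, 1]

summarizes the coupling (RV(A,A)=1 by construction). The two NSCA triplets
have different natural row masses, but coupled triplets must share one row
metric. Both tables are therefore re-expressed with **uniform gene
weights**, uniformly both in D = I/n and in the centering (profiles
centered by their unweighted gene mean). This choice makes a motif column
that is constant across genes load exactly zero — the behaviour one wants
from a "no information" motif — which mass-centering would not give.
Significance of RV is assessed by Monte-Carlo row permutation of one
table (self-co-inertias are permutation-invariant, so only the cross term
is recomputed), p = (1 + #{null ≥ observed})/(B + 1).

### Between-group analysis (BGA) and the supervised axis

BGA ordinates the table of per-group mean columns with the same NSCA
transform, yielding at most K−1 axes for K groups (the column-mass-weighted
combination of Q's columns vanishes identically), and projects the original
samples supplementarily. The between/total inertia ratio is reported;
under a no-structure null it concentrates near the random-projection value
(K−1)/(n_samples−1) — about 0.18 for a 12-sample/3-group design — not near
zero, so it should be read against that baseline. Group means (not merged
sums) are used; with equal replicate counts, the default design, the two
coincide after normalization.

The supervised run restricts the expression side to one
resistant-vs-parental pair, reduces it to the two group-mean columns, and
couples it with one motif table under the uniform row metric. The single
informative co-inertia axis is oriented so the **resistant centroid is
positive**; the signed motif loadings on that axis rank motifs by
association with resistance (ties broken lexicographically by motif id; an
option ranks by |loading| for direction-agnostic screening).

### Rank products and the consensus

For each comparison, the four per-threshold rankings r_{m,t} are combined
by the rank product RP_m = (Π_t r_{m,t})^{1/T}. Significance uses the
permutation null in which each list is an independent uniform permutation
of 1..M: p_m = (1 + #{rounds with null RP_m ≤ RP_m})/(B + 1), and the
estimated proportion of false predictions is pfp_m = p_m·M/rank(p_m).
Because a single motif's null rank profile is uniform over the M^T
combinations, the null is **enumerated exhaustively in complete sweeps**
whenever M^T fits inside the permutation budget — exact at desk scale and
testable against hand enumeration — and sampled otherwise. Integer rank
products are compared exactly, so ties need no epsilon. The final TF list
is the overlap of the two comparisons' top-k rank-product lists (k = 20 by
default — generous relative to the ~10 TFs such consensus lists typically
contain, so true hits are not cut off), ordered by the sum of final ranks.

## Clinical validation arm

Sites carry nuclear IHC scores 0–3 (0 none, 1 faint, 2 moderate, 3 strong,
each in >10% of epithelial cells); a site is positive/high at 2–3.
Unusable cores are flagged and excluded from every statistic, never
silently dropped. Patients are summarized by the mean score of their
usable sites per compartment (bone, soft tissue, both) and dichotomized at
the scale midpoint (mean ≥ 1.5 → high, midpoint inclusive, configurable) —
the site-level 0/1-vs-2/3 rule does not by itself determine a patient-level
rule, so the midpoint convention is an explicit, documented choice. Positivity percentages are rounded to the
nearest integer, half away from zero. Association of site class with site
type uses Pearson chi-square (1 df, continuity correction off by default)
and the two-sided Fisher exact test (sum of hypergeometric masses ≤ the
observed table's, with the standard 1e-7 relative tie tolerance; equal to
full enumeration on all small tables). Continuous association uses
Spearman mid-rank correlation. Survival from three baselines (prostate
cancer diagnosis, castration resistance, first bone metastasis) uses the
Kaplan–Meier product-limit estimator and the log-rank test (lifelines;
events precede censorings at tied times; medians are reported as undefined
when Ŝ never crosses 0.5). Cox/stepwise multivariate modelling is out of
scope; the clinical schema keeps the covariate columns so users can fit
their own.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analysis assumes,
not any real dataset:

- **Motif tables.** Counts at the loosest threshold are per-cell
  Poisson(`motif_rate`); each stricter table binomially thins the previous
  one with probability `retention` per step, so tables are element-wise
  non-increasing in threshold by construction — the defining property of
  threshold-nested PSSM scans. Defaults: `motif_rate = 0.02` occurrences
  per motif per promoter (≈ 2 total occurrences per promoter over 100
  motifs, emulating the sparsity of cross-species-conserved TFBS
  resources), `retention = 0.8`. A draw with an all-zero motif column is
  re-drawn (or raises, per flag).
- **Expression.** log2 value = `baseline_mean` (8.0, an RMA-like scale) +
  `effect_size` (1.0 per active-motif occurrence) × occurrence count ×
  resistance indicator + N(0, `noise_sd` = 0.5), for 3 groups × 4
  replicates. The same effect applies to both resistant groups so the
  consistent overlap has a non-empty truth; `group_effect_scale` can plant
  discordance. Values are returned as non-negative log2 intensities by
  default (clipped at 0, which at baseline 8 and σ 0.5 is a 16σ event);
  base-2 exponentiation is available. Not emulated: probe-level effects,
  batch structure, heavy-tailed noise, mean–variance dependence —
  so passing tests demonstrate correctness of the machinery under the
  stated model, not robustness to microarray pathologies.
- **Cohort.** Each patient has a latent high/low TF class
  (P(high) = 0.4); usable sites draw scores from class-conditional
  distributions chosen to give ≈ 35% positive sites overall; survival from
  each baseline is exponential with per-year baseline hazards
  (0.14, 0.25, 0.33) — medians of roughly 5, 2.8 and 2.1 years, the scale
  of a metastatic castration-resistant cohort — multiplied by
  `hazard_ratio` (3.0) for TF-high patients, under independent exponential
  censoring (0.05/yr). Real cohorts have correlated site counts, informative
  censoring and non-proportional hazards; none are modelled.

All three generators draw from independent streams spawned from one seed,
so partial pipelines are reproducible and `simulate → analyze` is
bit-deterministic given (config, seed).

## Numerical choices

- SVD rank cut at 1e-12 relative to the leading singular value; retained
  axes default to min(5, rank) (displays use 2).
- Zero-inertia (≤ 1e-20, i.e. a constant table up to rounding) ordinations
  refuse to couple: the RV normalization is meaningless there.
- Quantile-normalization ties: average of the tied positions' target
  values, via mid-ranks and linear interpolation.
- Trigamma inversion by Newton steps on the standard reciprocal-scale
  start, 50-iteration cap, 1e-8 relative tolerance.
- Fisher tie comparison uses the conventional (1 + 1e-7) relative slack.
- TSV output at 6 significant digits; identical-seed reruns are compared
  byte-for-byte in the determinism test.

## Problem sizes used in the checks

The reference configuration is 2,000 genes × 100 motifs × 12 samples with
5 planted motifs, four thresholds, and rank-product B = 1,000; calibration
checks use 5,000-gene null panels (20 replicates), 500 simulated cohorts
for log-rank uniformity, and exhaustive enumerations for the Fisher and
rank-product exactness checks. These sizes make every property measurable
with comfortable Monte-Carlo margins while keeping a full run on one CPU
in seconds.

## Known limitations

- The probe→gene collapse of real array platforms is out of scope; gene
  identifiers join by exact string match in one namespace.
- The NSCA margin convention (genes depend on samples/motifs; genes as
  rows) is fixed by the shared-gene linkage; the transposed convention is
  not offered.
- Study-scale discovery numbers (hundreds of differential probes, specific
  fold changes, patient-level correlations) depend on raw datasets that are
  not publicly deposited and are not reproduction targets; the pipeline's
  claims are the property-level ones above.
- With k = 20 and 100 motifs, a handful of unplanted motifs typically
  enter the consensus (mean consensus size ≈ 13 with all 5 planted motifs
  recovered); k trades recall against precision and is configurable.
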