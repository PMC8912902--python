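# Methods

## Scope and data model

`refstab` operates on three kinds of input: long-format Cq tables
(gene, sample, group, technical replicate, Cq), DESeq2-style RNA-Seq
results tables (gene, baseMean, log2FoldChange, padj, dispersion), and
normalized-count matrices. Cq is treated throughout as a log2-scale
quantity: one cycle corresponds to a two-fold abundance difference under
ideal amplification, which is why primer efficiency is gated to
E ∈ [1.9, 2.1] before any base-2 arithmetic is trusted.

## Technical-replicate QC

Each biological sample is measured in R ≥ 2 technical replicates
(typically triplicate). The per-cell rule:

- replicate SD ≤ 0.20 cycles → mean of all replicates, flag `ok`;
- SD > 0.20 → remove the single replicate farthest from the replicate
  median (ties broken by the lowest replicate index — a deterministic,
  robust choice, since "remove one outlier" underdetermines which), then
  if the remaining SD < 0.20 flag `outlier_dropped`, else flag
  `inconsistent` and report the mean over all original replicates.

Inconsistent cells are retained with their flag rather than dropped;
downstream steps may exclude them by configuration. SDs use the n−1
denominator. With the default technical SD of 0.05 cycles the triplicate
SD follows a scaled chi distribution and exceeds 0.20 in ≪1% of cells,
matching the rarity of the flag in practice.

## Efficiency QC

Ordinary least squares of mean Cq on log10 relative concentration over a
serial dilution; E = 10^(−1/slope). QC passes at 1.9 ≤ E ≤ 2.1 and
R² ≥ 0.99. An out-of-range final dilution is excluded by the caller
(mask in, not automagic), keeping the regression auditable. A zero slope
is reported as a degenerate result, not an exception.

## Candidate screen

CVfromDisp = 100·√dispersion re-expresses the negative-binomial
dispersion as a percent coefficient of variation. The four filters are a
pure conjunction (order-irrelevant, idempotent): padj **strictly** above
0.05 (missing padj excludes a gene — it cannot affirmatively pass),
−0.1 ≤ log2FC ≤ 0.1 inclusive, 10 ≤ CVfromDisp ≤ 20 inclusive,
baseMean ≥ 500 inclusive. Boundary semantics follow the wording of the
source filters ("above", "between", "greater than or equal to"). The
pool is ranked by baseMean and cut into four rank-quartiles (ties to the
lower quartile; Q1 = lowest expression by default, configurable since
"first quartile" is a convention); 3/3/3/1 genes are drawn per quartile
either uniformly at random (seeded) or by lowest CVfromDisp
(deterministic; ties by gene id). Target genes use the complementary
filters: padj < 0.05 and log2FC strictly beyond ±0.6, sampled per
direction with a seed.

## Stability analysis

**CV gate.** CV% = 100·SD/mean of the linearized signal 2^−Cq over all
samples pooled (both groups). Genes with CV > 50% (strict) are excluded
from the model-based step: at 50% the SD equals half the mean, and such
genes destabilize the variance-components fit. Significance in the
intrinsic-variation test does *not* exclude a gene — a significant gene
can still enter the best pair if its deviation is small in absolute
terms; the flag is reported for the analyst.

**Intrinsic variation.** Exact two-sided Mann–Whitney per gene between
the two groups, computed on the 2^−ΔCq profile (ranks are invariant to
the monotone transform). For combined n ≤ 20 the p-value enumerates all
C(N, n1) assignments of pooled mid-ranks (exact even under ties); larger
samples use the normal approximation with tie and continuity
corrections.

**Variance-components estimator.** For Cq values y_igj (gene i = 1..k,
group g = 1..G, sample j = 1..n_g), per group the doubly centered
residuals r_igj = y_igj − ȳ_ig· − ȳ_·gj + ȳ_··g remove gene effects and
the per-sample loading effect; the naive variance ŝ²_ig = Σ_j r²_igj/(n_g−1)
is bias-corrected to

σ̂²_ig = max{ (ŝ²_ig − S_g/(k(k−1))) · k/(k−2), 0 },  S_g = Σ_i ŝ²_ig,

which requires k ≥ 3 (the k/(k−2) factor) and is why small panels cannot
be scored. Gene-group interactions a_ig = ȳ_ig· − ȳ_··g give intergroup
deviations d_ig = a_ig − mean_g(a_ig) (sum to zero over groups per gene
and over genes per group, asserted to 1e−10 in tests). The deviations
are shrunken toward zero through the empirical-Bayes variance

γ̂² = max{ Σ_ig d²_ig / ((G−1)(k−1)) − mean_ig(σ̂²_ig/n_g), 0 },
d̃_ig = d_ig · γ̂²/(γ̂² + σ̂²_ig/n_g),

and the stability score averages deviation and sampling-variance terms
over groups:

S_i = (1/G) Σ_g ( |d̃_ig| + sqrt( (σ̂²_ig/n_g) · γ̂²/(γ̂² + σ̂²_ig/n_g) ) ).

Lower S is more stable. The best pair minimizes the same functional for
the two-gene average: pair deviation (d̃_a + d̃_b)/2, pair variance
(σ̂²_a + σ̂²_b)/(4 n_g), shrunken identically; the search is exhaustive
over all C(k, 2) pairs with lexicographic tie-breaking. Cq feeds the
estimator directly (it is already log2-scale; the sign flip relative to
abundance changes neither variances nor |d|). Negative moment estimates
of σ² and γ² are clipped at zero; when γ̂² = 0 (no detectable intergroup
structure) every d̃ and variance term collapses and all scores tie at 0
— the lexicographic tie-break then picks the pair, which is the correct
degenerate answer since all candidates are equally (perfectly) stable.

Because published reports of this estimator family typically give scores
without printing formulas, correctness is established by simulation
rather than by comparison to a binary tool: with k = 10 genes, two groups of 50 and
no group effects, the mean σ̂²_ig over 500 replicates lands within a few
percent of the planted truth and γ̂² is below 1% of the mean true
variance (see `analysis/05_simulation_studies.py` and the acceptance
script, which recompute this at run time).

## Normalization and quantification

NF(s) = (Cq_a(s) + Cq_b(s))/2 for the best pair (a, b) — the Cq-scale
equivalent of a geometric mean of expression levels. For a target,
ΔCq = Cq_target − NF per sample, ΔΔCq subtracts the **arithmetic mean**
of the calibrator group's ΔCq (equivalently the geometric mean on the
linear scale), FC = 2^−ΔΔCq. Calibrator fold changes therefore scatter
around a geometric mean of exactly 1. Per-sample additive Cq shifts
applied jointly to target and both NF genes (loading/pipetting error)
cancel exactly. RNA-Seq fold changes divide each sample's normalized
count by the calibrator group's mean normalized count — a convention
chosen so the calibrator's mean FC is 1 by construction; other
calibrator conventions exist, and this one is documented rather than
claimed canonical. Efficiency-corrected (Pfaffl) quantification is out
of scope because primers are pre-gated to near-ideal efficiency.

## Cross-method comparison

Per target, the fold-change distributions from the compared
normalization routes are tested with the tie-corrected Kruskal–Wallis H
(H divided by 1 − ΣT/(N³−N), chi-square tail) followed by Dunn's z for
each method against a designated control, using the pooled mid-ranks and
the tie-corrected variance N(N+1)/12 − ΣT/(12(N−1)). Adjustment is
Bonferroni over the G−1 planned comparisons by default (the family is
planned and small; Šidák and none are available). The calibrator group
is omitted from this comparison: its fold changes average 1 under every
method, so including it only dilutes the test.

## Synthetic data

The Cq generator draws
y_igjr = μ_i + δ_ig + b_gj + e_igj + t_igjr with loading effect
b ~ N(0, σ_s²) shared by all genes within a sample, biological noise
e ~ N(0, σ_b,i²), technical noise t ~ N(0, σ_t²), and per-gene group
shifts δ realized as centered profiles (Σ_g δ_ig = 0) from a stated
total intergroup difference. Gaussian noise on the Cq scale is exactly
the assumption of the variance-components estimator, which is the point:
the generator provides a ground truth under the model, so recovery
failures indicate estimator bugs rather than model mismatch. Defaults
mirror the targeted study design: triplicates, 7 samples per group,
baselines 18–26 cycles, σ_b = 0.1, σ_s = 0.2, σ_t = 0.05 cycles.

The count generator draws NB(mean q_i·s_j·2^θ_ig, dispersion α_i) per
gene and sample (α = 0 degrades to Poisson). The results-table builder
reproduces the median-of-ratios size factors exactly but replaces the
DESeq2 GLM/Wald machinery with Welch's t on log2(normalized + 0.5) and
Benjamini–Hochberg adjustment: the screen consumes the *table schema and
filters*, not the DE engine, and a transparent surrogate keeps the
planted truth interpretable. The pseudo-count for all count-log
transforms is 0.5. The method-of-moments dispersion
max{(var − mean)/mean², 0} can be overridden by the simulation's true α
when exact CVfromDisp values are wanted.

What the generators do **not** emulate: amplification-efficiency
heterogeneity between primers, plate/batch effects beyond a single
loading term, non-Gaussian Cq error (dropouts near the detection limit),
RNA-Seq GC/length biases, and outlier dispersion genes. Passing tests
therefore demonstrate correctness of the estimators under their stated
models and calibration of the tests — not robustness to every wet-lab
failure mode.

## Simulation studies and problem sizes

Four studies (in `refstab.experiments`, driven by the test suite, the
acceptance script and `analysis/05`):

- **Variance recovery** — k = 10, G = 2, n_g = 50, σ_b ∈ [0.1, 0.5],
  no group effects, 500 replicates; checks mean σ̂² within 10% of truth
  and γ̂² below 5% of the mean true variance (the natural quantitative
  reading of "γ̂² → 0 under the null").
- **Ranking recovery** — 8 stable genes + one 0.8-cycle shift gene + one
  σ_b = 0.6 noise gene, n_g = 7, 100 seeded runs; both planted genes
  must land in the bottom 3 ranks and outside the best pair in ≥95% of
  runs. The ranking runs on the full panel; the CV gate (which already
  removes the noise gene in a quarter of runs, CV ≈ 43% in expectation)
  is reported separately.
- **Workflow equivalence** — two disjoint 10-gene stable panels and six
  targets with planted log2 effects ±{0.7, 1, 2} on one simulated plate,
  n_g = 7, 100 runs; the two NFs must agree in mean log2 FC within 0.1,
  Kruskal–Wallis + Dunn must find no adjusted p < 0.05 in ≥90% of runs,
  and each planted effect must be recovered within ±3 Monte-Carlo SEs of
  the cross-run mean. Three SEs rather than 1.96 because six correlated
  per-target checks are evaluated jointly; estimator unbiasedness was
  verified separately at 400 runs (|bias| ≤ 0.004 log2 units).
- **Dunn calibration** — 3 groups × 7 iid normal samples, 2000
  replicates; the Bonferroni-adjusted control-versus-others family-wise
  error must not exceed 5% beyond Monte-Carlo error.

These sizes keep the full suite under a minute of compute while leaving
each check adequately powered; they are the package's chosen validation
conditions, stated here so they can be scaled up by anyone wanting
tighter Monte-Carlo error.

## Numerical and degenerate-input policy

- Sample SDs everywhere use ddof = 1; CV is undefined (error) at zero
  mean; zero-variance standard curves raise a degenerate-design error.
- Exact Mann–Whitney two-sided p = min(1, 2·min(P(U ≤ u), P(U ≥ u))),
  the standard doubling convention; identical groups give p = 1.
- All-identical Kruskal–Wallis input returns H = 0, p = 1 rather than a
  division-by-zero error.
- Double-centering identities and shrinkage bounds (|d̃| ≤ |d|) are
  asserted in tests at 1e−10.
- Seeds: every stochastic routine takes an explicit seed; per-replicate
  child seeds are drawn from `numpy` PCG64 streams and kept below 2³¹.

## Known limitations

- The stability estimator assumes shared intragroup variance structure
  across groups only through its per-group estimates; heavily unbalanced
  or single-digit group sizes (n_g < 4) make σ̂² noisy and the clip at
  zero biases small variances upward.
- The exact Mann–Whitney enumeration grows combinatorially; above
  combined n = 20 the implementation switches to the corrected normal
  approximation, which is slightly conservative at moderate n with heavy
  ties.
- The DE surrogate (Welch + BH) is not DESeq2; padj values agree in
  spirit, not numerically, with a GLM/Wald analysis. Consumers needing
  DESeq2-exact tables should supply real DESeq2 output — the screen
  reads it directly.
- `inconsistent` cells enter downstream means unless the caller excludes
  them; no dataset-level exclusion rule is imposed because none is
  established.
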