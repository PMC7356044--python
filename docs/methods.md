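# Methods

## Design and model

The unit of analysis is a gene × sample matrix of non-negative integer
counts over a 2 × 2 factorial: genotypes `T29` (high nitrogen-use
efficiency, stress-tolerant) and `T13` (low NUE, stress-sensitive) under
control (`C`, normal nitrogen) and N-deficit (`T`) conditions, with r
replicates per cell.  Counts for gene i in sample j are modelled as
negative binomial with mean μ_ij = q_i(cell(j)) · s_j and variance
μ + αμ², where q_i is the cell-level expression, s_j a sample-specific
size factor, and α the dispersion.  This mean–dispersion parameterization
(α, not "size") is used everywhere; α = 0 is the Poisson limit and is
handled exactly.

## Differential expression

**Size factors** are median-of-ratios: s_j = median over all-positive
genes of k_ij / (∏_j k_ij)^{1/m}.  If no gene is positive in every sample
the estimate is refused with an explicit error rather than silently
switching reference; factors are estimated once per dataset and shared by
all four contrasts.

**Dispersion** is estimated per gene by method of moments on normalized
counts, α̂ = max(0, (w − q̄)/q̄²), with w the pooled within-group sample
variance and q̄ the overall normalized mean.  At realistic replicate
counts (2–3 per group) the raw per-gene estimator is noisy enough that the
genes whose variance it underestimates dominate the test's behaviour: on
10⁴ simulated null genes (3v3, α = 0.05) raw per-gene moments give a raw
p < 0.05 rate of 0.11 and hundreds of spurious BH calls.  The default
therefore floors every estimate at the across-gene median
(`moderation="max_median"`), the conservative max-of-(per-gene, pooled)
rule of the classic NB exact-test lineage; this restores the nominal rate
(measured 0.05) while costing essentially no power at fourfold effects
(recall 0.99 at baseline mean ≈ 148).  A 50/50 median blend and the raw
estimator remain selectable.  Genes with zero normalized mean are flagged
untestable; with a single sample per group the estimator falls back to
Poisson with a warning.

**Test.**  For each gene the two group sums K_A, K_B are modelled as NB
with means q̄₀S_A, q̄₀S_B (q̄₀ the pooled normalized mean, S the summed
size factors) and sum-level dispersions α·Σs²/S².  Conditioning on the
total T = K_A + K_B, the two-sided p-value is the normalized probability
of all partitions (a, T−a) whose null probability does not exceed the
observed one (ties included with 1e-9 relative tolerance, evaluated in
log space).  With α = 0 this is exactly the two-sided exact binomial
test, which the test suite verifies by full enumeration for all T ≤ 50.
For T above 10,000 (configurable) a continuity-corrected normal
approximation to the conditional law is substituted — mean
M_A + V_A/(V_A+V_B)·(T−M_A−M_B), variance V_AV_B/(V_A+V_B) — which agrees
with the exact computation to a few percent near the cap.

**Calls.**  Genes with total raw count < 10 are not tested (p = padj = 1);
the threshold guards the moment estimator and is configurable.  Tested
p-values are Benjamini–Hochberg step-up adjusted
(padj_(j) = min_{l≥j} m·p_(l)/l, capped at 1); DEG ⇔ padj < 0.05.
Fold changes are reported both as log2((mean_B+c)/(mean_A+c)) and in the
signed convention FC = r if r ≥ 1 else −1/r, with pseudocount c = 1
normalized count so zero-mean cells stay finite.

## Contrasts and set algebra

Four contrasts with fixed orientation: R29 = T29_T vs T29_C,
R13 = T13_T vs T13_C, GC = T29_C vs T13_C, GT = T29_T vs T13_T ("up" in
GC/GT means higher in T29).  Unique responders of a genotype are DEGs of
its response contrast minus the other's — membership only, no equivalence
testing of effect sizes.  Venn summaries report per-contrast counts,
pairwise overlaps, and the union over all four.

## Pattern classification

For the focal (sensitive) genotype F with tolerant counterpart O, the
ratios r_C = (mean O_C + c)/(mean F_C + c) and r_T = (mean O_T + c)/
(mean F_T + c) place each unique responder on the classification plane;
ρ_F = ln(mean_C/mean_T) within F and ρ_O within O describe response
magnitudes.  Rules, applied in order with strict inequalities at 1:

* R0 `opposite`: significant in both response contrasts, discordant
  directions.
* R1 `frontloaded`: focal direction up, r_C > 1 and r_T < 1.
* R2 `relatively_upregulated`: focal direction down and r_T > 1.
* R3 `stress_tolerance`: up with r_C ≤ 1, or down with r_C ≤ 1 and
  r_T ≤ 1.
* R4 `unclassified`: everything else, including dual responders with
  concordant directions.

An optional dead-band ε treats |ln r| < ε as a tie (neither side of 1);
the default is ε = 0.  The "muted response" of the tolerant genotype is
operationalized as non-significance of its response contrast (already
guaranteed by the unique-responder definition) rather than a fold-change
ratio cutoff, so the ρ quantities are descriptive.  Mirroring the focal
genotype swaps genotype roles in every ratio; classification of a dataset
with focal T13 equals classification of the genotype-relabelled dataset
with focal T29 label-for-label (a tested invariant).

The direction-consistency check is a 1-df chi-square of the split between
unique responders with |ρ_F| > |ρ_O| and the rest against a 50:50 null
(the null is a package choice and is recorded in the output; ties count
toward the other genotype).

## Synthetic data

The generator plants, per archetype, the four cell means as multiples of
a per-gene baseline b ~ logNormal(5.0, 1.5) (natural-log scale; median
count ≈ 148), then samples NB counts with shared dispersion α = 0.05
after scaling by per-sample library factors.  With response fold f = 4
and constitutive fold g = 3 (defaults), focal genotype F, tolerant O:

| archetype | F_C | F_T | O_C | O_T |
|---|---|---|---|---|
| frontloaded | b | f·b | g·b | g·b |
| stress_tolerance_up | b | f·b | b/g | b/g |
| stress_tolerance_down | b | b/f | b/(fg) | b/(fg) |
| relatively_upregulated | b | b/f | b | b |
| opposite | b | f·b | b | b/f |
| constitutive | b | b | g·b | g·b |
| null | b | b | b | b |

Stress-tolerance genes place the tolerant genotype *strictly* below the
focal one (by 1/g, and additionally below F_T in the down case): the class
describes equal-or-lower constitutive expression, and planting means
exactly on the r = 1 boundary would make recovery a coin flip by
construction rather than a property of the method.  The default universe
is 4,224 genes: 100 frontloaded, 10+10 stress-tolerance, 100 relatively
upregulated, 4 opposite, 4,000 null.  Defaults use 3 replicates per cell —
the minimum at which per-gene NB inference has reasonable power — while
2-replicate pooled designs remain configurable.  Gene lengths are drawn
log-uniformly on 200–10,000 bp for FPKM computation.  Everything is
deterministic given the config seed.

What the generator does **not** emulate: gene–gene correlation, per-gene
dispersion heterogeneity (α is shared), GC/length biases, time-course or
tissue structure within pooled samples, and annotation redundancy.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated model, not performance on any
particular real dataset.

## QC

Replicate QC: Pearson r of log10(FPKM+1) over genes for every within-cell
replicate pair, flagged below 0.9.  FPKM uses column totals as the
library size: FPKM = 10⁹·k/(L·N).  qPCR concordance: 2^−ΔΔCt ratios
(technical replicates averaged on the Ct scale, efficiency fixed at 2)
are compared with DE directions; |log2 ratio| < 0.1 counts as "no change"
and matches direction `none`.  The pipeline's qPCR stage is an in-silico
positive control: it simulates Ct values realizing the observed log2 fold
changes of the top DEGs (Ct noise sd 0.2, one cycle per doubling) and
checks the round trip.

## Numerical choices and limitations

* Exact-test tie tolerance 1e-9 (relative, log space); approximation cap
  T = 10,000; BH implemented directly and cross-checked against an
  independent brute-force oracle and statsmodels.
* Pseudocount 1 normalized count in every ratio; dead-band ε = 0.
* Problem sizes in the test and acceptance suites (e.g. 10⁴ null genes,
  20 recovery seeds at defaults, 600-gene fixtures) were chosen to make
  Monte-Carlo bands tight relative to the properties asserted.
* Single-factor contrasts only — no multi-factor GLM, shrinkage
  estimators, or surrogate-variable correction; genotype × treatment
  interaction is addressed through set algebra and ratios, not an
  interaction coefficient.
* The chi-square null (50:50) and the membership-based definition of
  "unique" are modelling choices; both are recorded in outputs.
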