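# Methods

## Problem and model

Bulk tumour cohorts carry recurrent focal deletions at common fragile
sites (CFS). The question the pipeline answers is: *which genes inside a
fragile site change expression when the site is deleted, in which
direction, and is the change attributable to the deletion rather than to
tumour composition?* The secondary analyses characterize one mechanism —
a deletion that removes an intronic antisense element and thereby
de-represses the surviving host gene — through an exon-level breakpoint
contrast, chromosomal-instability signature scoring, and a
nascent-transcription exon profile.

### Deletion calls

Segments are filtered on their segmentation value (log2 copy ratio)
**strictly below −0.1**; the boundary value is excluded. A patient is
deleted for a region when ≥ 1 bp of the region is covered by a
qualifying segment. `overlap_bp` counts the union of covered bases;
the quantitative `weighted_seg_value` is Σ(overlapᵢ·seg_meanᵢ)/Σoverlapᵢ
over the qualifying segments. The ≥ 1 bp rule is the minimal reading of
a presence/absence call; no minimum overlap fraction or marker count is
imposed, but the weighted value is carried so users can threshold it.

For gene sub-portion classification (5′/central/3′), deletions spanning
several portions are labelled with precedence
`three_prime_deleted > central_deleted > other`, so that the 3′-deleted
vs wild-type contrast has a deterministic group assignment for mixed
events.

### Z-scores against normal tissue

Per tumour type, z_gs = (x_gs − μ̂_g)/σ̂_g with μ̂_g, σ̂_g estimated from
the normal samples of that type, σ̂ with denominator n − 1 (pinned so
the self-consistency property — normals re-scored have mean 0, SD 1 — is
exact). At least two normal samples are required; genes with σ̂ = 0 are
dropped and reported. Expression is transformed as log(1 + FPKM) before
scaling by default (`log_transform=False` to disable): FPKM is
heavy-tailed, and z-scores on the raw scale are dominated by extreme
values that the robust regression would then have to absorb. The choice
is recorded in the z-panel object.

### Robust association

Per gene: `z ~ β₀ + β₁·deletion + β₂·purity`, fitted by iteratively
reweighted least squares with Tukey's biweight ψ, tuning constant
c = 4.685 (95% efficiency under Gaussian errors), scale from the median
absolute deviation, iterated to a relative coefficient change < 1e-8 or
50 iterations (statsmodels `RLM`, `conv="coefs"`). Tumour purity — the
fraction of tumour cells in the bulk sample — enters as a covariate
because the expression consequence of a somatic lesion is diluted
linearly by the normal-cell fraction, making purity a genuine
confounder of the deletion indicator. Two-sided p-values use the t
reference with n − 3 residual degrees of freedom (the conventional
finite-sample summary for a robust fit; pinned for determinism).

Samples with missing purity are dropped from the fit (counted in the
log), never imputed. A design that is rank-deficient or has fewer than
3 samples in either deletion group (configurable floor) yields an
`untestable` result with no p-value rather than an unstable estimate.

Bonferroni: p_adj = min(1, m·p) with m = the number of tests actually
fitted in the run (across regions and tumour types when run jointly) —
the most conservative defensible family, reported explicitly. The
significant set is restricted to protein-coding genes at adjusted
p < 0.01; direction is the sign of β₁.

One numerical caveat is documented rather than hidden: on outlier-free
Gaussian data the biweight estimate is not numerically identical to OLS
(it is a 95%-efficient estimator, so the two differ by a statistical
O(SE) amount that scales with the residual SD). The test suite checks
1e-3 absolute agreement on low-noise data (residual SD 0.05 at n = 200)
and checks robustness — beating OLS under 10% ×10 contamination — at
unit noise.

### Exon contrast

Per exon: mean(values, 3′-deleted) − mean(values, wild-type), with a
95% percentile bootstrap band obtained by resampling samples within each
group (B = 1000 by default, seeded). Groups of size 1 give a degenerate
band and are flagged. Inputs are whatever per-exon measure the caller
supplies (z-scores or FPKM on a common scale); the statistic is a plain
difference of group means, robust variants being unnecessary once the
measure is z-scored.

### Instability signatures

The CIN25/CIN70 signatures (genes whose elevated expression tracks
chromosomal instability and functional aneuploidy; reconstruction of the
Carter et al. 2006 lists with modern HGNC symbols, shipped as
user-overridable text files) are scored as the **mean z-score of the
signature genes found in the panel** — the minimal monotone aggregate
under which higher score = higher instability. Missing signature genes
are reported, never imputed. Group comparison is a two-sided
Mann-Whitney U test, with U reported for the element-deleted group.
When both groups have ≤ 7 samples the p-value is computed by full
enumeration of all C(n₁+n₂, n₁) labelings with midranks for ties
(two-sided tail: |U − n₁n₂/2| at least as extreme as observed);
otherwise the tie-corrected normal approximation is used.

### Nascent-transcription profile

For a set of coverage tracks i over a gene's exons:
E_{e,i} = (Σ per-base signal over exon e)/length(e); exon expression =
ln(1 + Σᵢ E_{e,i}); rescaled = (x − min)/(max − min) (a constant profile
maps to zeros with a warning). Natural log is pinned; rescaling makes
the base irrelevant for ordering but not for intermediate values, so the
choice is recorded. Exon ordinals follow transcription direction: for a
minus-strand gene the coordinate-sorted exon list is reversed. The
post-element drop statistic for an element between exons k and k+1 is
mean(rescaled, exons > k) − mean(rescaled, exons ≤ k); negative values
indicate attenuation past the element. Summation over samples happens
before the log (one profile per condition), not per-sample logs
averaged.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
not real genomes:

* **Deletions.** Per tumour and fragile site, deletion ~
  Bernoulli(prevalence 0.3 by default). A deleted sample carries one
  focal segment: a uniformly placed sub-interval of the site (≥ 50% of
  its length) with seg_mean ~ U(−1.0, −0.3), safely below the −0.1
  filter while exercising value variation. All samples carry near-zero
  background segments (seg_mean ~ N(0, 0.02)).
* **Expression.** Natural-log scale:
  y = baseline + effect·deletion·purity + N(0, σ), FPKM = exp(y), with
  σ = 0.5 and baseline log-FPKM 5 by default. Effects are specified as
  z-shifts (units of σ), so a planted shift of +1.5 is the expected
  z-difference at purity 1. Purity multiplies the effect (not the
  baseline): the minimal model in which purity genuinely confounds the
  deletion–expression relation. Purity ~ Beta(6, 2) (mean 0.75, a
  typical bulk-tumour purity distribution); normals have no purity.
* **Exon panels.** In 3′-deleted samples, exons inside the deleted
  central block are shifted by −s and surviving exons by +s (s = 1 by
  default) over unit Gaussian noise; wild-type samples are flat.
* **Coverage.** Per-base Poisson with mean 100 upstream of the element
  and 100·drop_factor downstream (in transcription direction).

Default cohort size: 200 tumours, 50 normals, one tumour type. The
shipped demo annotation is a synthetic fragile-site locus (one
1.5-Mb site on chr4 hosting an 11-exon resident gene with an intronic
antisense element between exons 8 and 9, plus background genes carrying
the CIN25 symbols); the gene body is compressed to 24 kb so per-base
coverage fixtures stay small — none of the statistics depend on
physical span. Identical seed + config ⇒ bit-identical outputs, and
fixtures written to disk re-read into the identical in-memory cohort
(SEG/bedGraph writers print floats in shortest-round-trip form).

**What passing tests do and do not show.** The generator plants clean
Bernoulli deletions, a single-gene cis effect, independent Gaussian
log-expression noise and Poisson coverage. Real cohorts add segmentation
noise, germline CNV, correlated expression programs, batch effects,
tumour-type heterogeneity and purity-estimation error; recovery on the
synthetic cohort demonstrates the statistical machinery end to end, not
performance on TCGA-scale data.

## Problem sizes and numerical choices

* Type-I-error checks use 500-gene null cohorts (200 tumours, 50
  normals) and 20 cohort seeds for the family-wise check; recovery
  checks use 20 seeds of the default cohort. These sizes give stable
  empirical rates while keeping the suite quick to run.
* IRLS: c = 4.685, MAD scale, tol 1e-8 on coefficients, ≤ 50
  iterations. Ties in the exact Mann-Whitney use midranks; the
  two-sided tail includes labelings at distance ≥ observed − 1e-12 to
  make ties in the statistic itself deterministic.
* Degenerate inputs: all-deleted/all-wild-type designs → untestable
  result; constant expression profile → zero rescale with warning;
  empty contrast group → error; zero overlap → deletion call false with
  missing weighted value (NaN).

## Known limitations

* Bonferroni only (an FDR switch would be a trivial extension but is
  out of scope); no empirical-Bayes shrinkage of effect sizes.
* The association model is additive in purity while the generative
  model (and plausibly reality) is multiplicative deletion×purity; the
  deletion coefficient therefore estimates an attenuated,
  purity-averaged effect. This is intentional — it mirrors the analysis
  design — and recovery tests show it does not compromise detection.
* Signature lists are reconstructions; analyses depending on exact
  signature membership should supply their own lists.
* The exact Mann-Whitney branch enumerates up to C(14,7) = 3432
  labelings; larger groups fall back to the asymptotic test rather than
  a Monte-Carlo permutation p.
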