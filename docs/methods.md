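# Methods

## Rank-product gene-set test

### Model

Given a log2-scale expression matrix of G transcripts over two conditions
with n replicates each, every transcript gets a two-sample t-statistic for
disease − control and the transcriptome is ranked. The statistic for a set
S of m measured members is the rank product RP(S) = ∏ rank_x/G, handled
throughout as log RP = Σ log(rank_x/G). The null model asserts the set's
members are exchangeable with the rest of the transcriptome, so their ranks
are a uniform draw of m distinct values from 1..G; the test compares the
observed log RP against Monte-Carlo samples from that null. This is a
competitive test: it asks whether the set sits at more extreme ranks than a
random set of the same size, not whether individual members pass a
significance threshold.

Assumptions worth stating: rank exchangeability under the null (satisfied
by construction in the synthetic generator; approximately true for
normalized arrays without strong inter-gene correlation), and independence
of the draws from the observed data (the null depends only on G and m).
Correlated member genes make the test anti-conservative on real data — a
known property of competitive gene-set tests that the permutation of ranks
cannot repair; the calibration results below quantify behaviour under
independence only.

### Key choices

- **Ranking mode.** Default `abs_desc`: rank 1 = largest |t|, because
  "dysregulation" is two-sided (members may move in either direction).
  Signed ascending/descending modes are exposed for directional analyses.
  Ties break by transcript id so ranks are reproducible.
- **t variant.** Welch by default (unequal variances is the safer default
  at n = 3); pooled Student t selectable. Degenerate transcripts (zero
  variance in both groups, equal means) are assigned t = 0, p = 1.
- **Fold change.** Signed linear convention: +2^d for d ≥ 0, −2^(−d)
  otherwise (d = log2 mean difference), so |FC| ≥ 1 and sign = direction.
- **Null sampling.** m distinct ranks per draw (without replacement) —
  random sets of m distinct transcripts have distinct ranks. A
  with-replacement mode exists only for distribution-limit checks.
- **p-value.** Add-one correction (k+1)/(n+1); guarantees validity and
  p > 0. The raw fraction k/n is reported alongside. Default n = 100 000
  draws.
- **Ties in the comparison.** Log rank-products are computed by summing
  logs in sorted-rank order, so identical rank multisets compare exactly
  equal; a 1e-9 absolute slack guards residual rounding. The gap between
  distinct rank products at testable sizes is orders of magnitude larger.
- **Exact oracle.** `exact_set_test` enumerates all C(G, m) subsets
  (budget 10^6 by default) and is used to validate the Monte-Carlo path on
  every problem with G ≤ 8, m ≤ 3.
- **Unmeasured members.** Set members absent from the ranked platform are
  dropped, with a logged warning, before m is fixed — only measured
  transcripts count.

## Candidate-gene allelic association

Per SNP the 2×2 allele table is (minor, major) × (case, control), with
minor counts = Σ dosage over non-missing genotypes and major counts =
2·n_nonmissing − minor. The default test is the 1-df Pearson chi-square
without continuity correction, computed by the direct formula
N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) (vectorised across SNPs); when any cell is
zero, Fisher's exact p replaces it and the odds ratio takes the
Haldane–Anscombe +0.5 correction. A degenerate margin yields chi² = 0,
p = 1. No covariates and no relatedness adjustment: samples are modelled as
founders.

FDR control is Benjamini–Hochberg step-up (via statsmodels) over the
candidate gene's SNP family by default — the hypothesis-based scope — with
a whole-panel family available behind a flag.

**Random-gene resampling.** The validation draws `n_genes` (default 500)
distinct genes other than the target; each drawn gene contributes a SNP
family size-matched *exactly* to the target's SNP count (subsampled when
larger, topped up from the pooled non-target SNPs when smaller — exact
matching avoids an arbitrary "approximately equal" tolerance). A draw is a
hit when any of its SNPs passes FDR < 0.05, and the empirical p is
(hits + 1)/(n_genes + 1). One behaviour to be aware of: under a completely
null panel with continuously distributed p-values, the probability that a
k-SNP family produces any BH rejection at level α is exactly α (Simes), so
the per-draw hit rate is ~5% and the empirical p concentrates near 0.05
rather than far below it. The resampling is decisive when the null genes
are uninformative or conservative (sparse minor alleles, discrete exact
p-values), which is the regime candidate-gene panels typically occupy.

## Nucleolar morphometry

Per pre-cropped single-nucleus image pair: nuclear mask = pixels strictly
above the Otsu threshold of the nuclear channel (a fixed threshold can be
supplied; Otsu is the default because the protocol defines the nuclear area
by the DAPI stain without stating a threshold); nucleolar mask =
protein-channel pixels with intensity in the inclusive band [50, 100]
(8-bit two-slider convention) intersected with the nuclear mask. The
readout is 100 × |nucleolar| / |nuclear| ∈ [0, 100], monotone in band
width and invariant to anything outside the nucleus. Group comparison is
the relative difference of means, 100 × (mean_B − mean_A)/mean_A — a
descriptive effect size; no inferential test is attached.

## Synthetic-data generators

All generators are pure functions of their parameters and a seed, and
return ground truth alongside the data.

- **Expression** (`synthesize_expression`): baseline log2 means
  ~ N(7, 1.5) per transcript (typical normalized-array intensities),
  i.i.d. N(0, 0.25) replicate noise (a realistic post-normalization
  replicate SD for cell-line arrays), 2 conditions × 3 replicates by
  default, set size 61 by default. A fraction `frac_affected` of set
  members is shifted by ±delta log2 units in group B (sign + with
  probability `sign_mix`, default 0.5 — dysregulation is bidirectional).
  Data are generated directly on the normalized scale; array
  preprocessing (RMA-style normalization) is upstream of this package's
  scope. Not emulated: inter-gene correlation, intensity-dependent
  variance, probe effects — so passing calibration here demonstrates
  correctness under exchangeability, not robustness to correlated sets.
- **Genotypes** (`synthesize_genotypes`): per-SNP minor-allele frequency
  uniform on [0.05, 0.5] shared across groups; genotypes binomial(2, MAF)
  within each phenotype group (Hardy–Weinberg, founders); exactly one
  designated SNP in the target gene has control MAF 0.01 and case MAF =
  control/5 by default (a protective minor allele five times more common in
  controls, at 4890 cases vs 5191 controls — control count is a parameter).
  No linkage disequilibrium and no population structure are simulated.
- **Images** (`synthesize_cell_images`): concentric disks — nucleus of
  intensity 220, nucleolar disk of intensity 75 (inside the measurement
  band) whose area scales by (1 + inflation), optional Gaussian pixel noise
  clipped to [0, 255]. Real microscopy features not emulated: point-spread
  blur, uneven illumination, multi-nucleolar morphology.

## Validation summary (what the tests compute)

The acceptance suite re-derives, at run time: Monte-Carlo/exact agreement
within 3 binomial SEs for every set placement at G ≤ 8, m ≤ 3 (100 000
draws, one fixed-seed null per problem size); type-I error within
[0.03, 0.07] over 500 null datasets (G = 2000, 3 vs 3, m = 61, 10 000
draws each) with an approximately uniform p histogram; power nondecreasing
over delta ∈ {0, 0.5, 1} (100 replicates each, 4000 draws); the BH worked
example (0.01, 0.02, 0.03, 0.04) → (0.04, ×4) with order invariance;
planted-SNP recovery (minimum raw p + FDR < 0.05) in ≥ 95% of 200
study-scale panels with unbiased log-OR; forced-null resampling p = 1/501
and a null spurious-call rate ≤ 0.05 + 3 SE over 200 panels; disk
morphometry within 1% relative of the analytic area ratio and recovery of a
38.6% planted inflation within a ±3-point band that covers disk-mask
pixelation (≈0.8 points at radius 10–12 px); and byte-identical outputs
under repeated seeds. `scripts/acceptance.py` recomputes the same
quantities (calibration at the same 500 × 10 000 size; association
recovery and power at 100 replicates) and finishes in a few minutes on one
CPU.

## Known limitations

- The set test's null ignores inter-gene correlation (see above).
- The allelic test is unadjusted; confounding by stratification must be
  handled upstream.
- The resampling validation inherits the α-level hit rate of BH under
  continuous nulls (see above), so its discrimination depends on the
  panel's null behaviour.
- Morphometry assumes one nucleus per image and a bimodal nuclear channel
  (Otsu); it measures area only, not nucleolar count or shape.
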