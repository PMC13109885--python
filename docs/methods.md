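# Methods

## Models

All linear predictors are special cases of the single-trait animal
model

    y = X b + Z a + e,    a ~ N(0, K σ²g),    e ~ N(0, I σ²e)

with `K` the relationship matrix appropriate to the information used:

- **ABLUP** — `K = A`, the pedigree numerator relationship matrix,
  built by the tabular recursion `A[i,i] = 1 + ½A[s,d]`,
  `A[i,j] = ½(A[j,s] + A[j,d])`, unknown parents contributing zero.
  Fixed effects are an intercept, a batch factor (dummy-coded,
  first level as reference) and optional covariates such as genomic
  PCs. Corrected phenotypes are `y_c = y − Xb̂ = â + ê`, returned only
  for record-bearing animals.
- **GBLUP / WGBLUP** — `K = G = ZDZ' / Σ 2pᵢ(1−pᵢ)`, where `Z` is the
  dosage matrix column-centered by twice the observed counted-allele
  frequency and `D` is a diagonal SNP-weight matrix (identity for
  GBLUP). `pᵢ` is the frequency of the counted allele, not folded to
  the minor allele: centering requires the counted-allele frequency.
  The denominator is unweighted, so rescaling weights followed by
  trace renormalization leaves `G` unchanged. Because `G` built from
  observed frequencies annihilates the ones vector, a working matrix
  is blended before inversion: `0.95 G + 0.05 A₂₂` when a pedigree is
  modeled, `0.95 G + 0.05 I` otherwise. GBLUP-family models take `y_c`
  as response with an intercept-only fixed part, since `y_c` is
  already adjusted for fixed effects.
- **ssGBLUP** — `K = H`, combining all pedigreed animals with the
  genotyped subset through
  `H⁻¹ = A⁻¹ + [[0,0],[0, G_w⁻¹ − A₂₂⁻¹]]` on the genotyped block.
  The single-step model is fitted on raw phenotypes with the ABLUP
  fixed effects; `y_c` may be supplied instead, but raw `y` is the
  default because the pedigree side of `H` is there to absorb exactly
  the information `y_c` would have pre-absorbed.

### Variance components

`em_reml` runs EM-REML for the single-random-effect model. `K` is
eigendecomposed once; each iteration then costs O(np²) for p fixed
effects, so a few hundred iterations at n ≈ 2,000 are cheap. Updates
are the standard conditional-expectation forms
`σ²g ← σ²g + σ⁴g (y'PKPy − tr(KP))/n` and
`σ²e ← σ²e + σ⁴e (y'PPy − tr(P))/n`, with `P` the REML projection.
Convergence is a relative change below 1e-6 in both components, capped
at 200 iterations; non-convergence is flagged, not raised, because EM
approaches boundary optima (σ² → 0) geometrically slowly while the
estimates are already accurate. `K = I` makes the two components
non-separable; this is detected and flagged. Components are floored at
1e-12·var(y).

### Solving

`solve_mme` assembles Henderson's mixed-model equations with
`λ = σ²e/σ²g` and solves them densely; at these scales (n ≤ ~5,000)
sparse inverses buy nothing and dense systems are directly
oracle-checkable. When the caller supplies `K` whose smallest
eigenvalue is below 1e-10 of the largest (the unblended `G` case), the
MME needs a `K⁻¹` that does not exist, so the solver switches to the
mathematically equivalent variance-scale form
`b̂ = (X'V⁻¹X)⁻¹X'V⁻¹y`, `â = σ²g K Z' V⁻¹ (y − Xb̂)`. Positive-definite
inversions use Cholesky with a single jitter retry of
`1e-8 · mean(diag)`.

## wssGWAS weighting

Starting from `D₀ = I`: fit ssGBLUP with the current weighted `G`;
backsolve marker effects `û = D Z' G_w⁻¹ â_g / Σ 2pᵢ(1−pᵢ)` (the
blended, invertible `G_w` of the current iteration); set
`dᵢ = ûᵢ² 2pᵢ(1−pᵢ)`; renormalize `D` to trace M; rebuild `G` and
repeat. The loop returns to the full ssGBLUP refit (not just the
backsolve) each iteration — the stronger, better-defined variant — and
runs two iterations by default, after which weights are known to decay
toward noise. Window variance shares are
`var(Z_w û_w)/var(Z û)` over non-overlapping 20-SNP windows in map
order; shares need not sum to one because window contributions covary.
Weights can be learned on a CV training fold only (`fold`, the
pipeline default — no leakage) or on the full data (`full`, matching
the common practice of importing weights from a prior full-data GWAS;
see Limitations).

## Marker QC, pruning, PCs

QC rules run in a fixed order: SNP call rate < 0.98, MAF strictly
< 0.05, exact Hardy–Weinberg P < 1e-6 (two-sided exact test on
heterozygote counts conditional on allele counts), individual call
rate < 0.95, then markers on the unplaced-chromosome label "0". A
marker removed by an earlier rule is not re-tested; re-running QC on
its own output removes nothing. Missing dosages are mean-imputed per
marker before `G`, pruning, PCs and ML features.

LD pruning mirrors windowed pairwise pruning: a 50-SNP window slides in
steps of 5; in each window every surviving pair with dosage `r²` above
the threshold loses its lower-MAF member (ties remove the later map
position — a deterministic rule, since the reference implementation's
internal tie-break is undocumented). Pruning is genome-wide in map
order. PCs come from the eigendecomposition of `G`; scores are
eigenvectors scaled by the root eigenvalue.

## Machine-learning predictors

Features are raw 0/1/2 dosages without standardization. KRR is
implemented natively: the training response is centered by its mean,
`α = (K + λI)⁻¹(y − ȳ)` is solved directly, and predictions add the
mean back; kernels are linear (`XX'`) and RBF
(`exp(−γ‖x−x'‖²)`). With a linear kernel on centered dosages and
`λ = σ²e Σ2pᵢ(1−pᵢ)/σ²g`, KRR, SNP-ridge and GBLUP coincide to
machine precision — the test suite asserts this three-way identity.
SVR and random forests delegate to scikit-learn behind the same
fit/predict contract; `RFSpec.bootstrap` defaults to the standard
bootstrapped forest. Grid search is exhaustive over candidate lists,
scored by mean Pearson r across an internal five-fold CV, ties broken
by grid order. Default grids bracket the optima reported for data of
this kind: λ and C in {0.01, 0.1, 1, 10}, γ in {1e-5, 1e-4, 1e-3},
forests of {100, 200, 500} trees at depth {5, 10, ∞} and minimum split
{2, 5}.

## Cross-validation and metrics

`make_folds` partitions individuals uniformly at random into k folds
per repeat (sizes differing by at most one; 3,737 ids at k = 5 give
748/748/747/747/747), default 10 repeats × 5 folds = 50 rounds. Folds
are drawn over individuals with a non-missing corrected phenotype for
the trait, since per-trait record counts are below the genotyped
total. Accuracy is Pearson r between `y_c` and GEBV in the validation
fold; bias is the OLS slope of `y_c` on GEBV (1 = no dispersion); MSE
and MAE are plain means of squared and absolute errors. Summaries are
mean ± SE over all rounds (not repeat means). Model comparison uses
one-way ANOVA on per-round accuracies with Tukey HSD at α = 0.05.
Bland–Altman limits are bias ± 1.96 SD of paired differences; a zero
difference SD collapses the limits, which is flagged, with agreement
reported as 100% since every difference equals the bias.

Each CV predictor trains strictly on the training ids: variance
components are re-estimated per fold by default (a config switch
allows run-level components for speed/comparability), and fold-local
wssGWAS weights are the default for WGBLUP.

## Synthetic data

The generator emulates a closed nucleus line. Pedigree: founders plus
per-generation random matings, each mating a distinct (sire, dam) pair
from the previous generation with parents reusable across matings.
Founder haplotypes come from a pool of 2·n_founders haplotypes built as
block mosaics (25-marker blocks) of 30 template haplotypes with 2%
per-site regeneration noise — this induces short-range LD that decays
with distance while anchoring allele frequencies to the target MAF
spectrum (uniform on the configured range, randomly polarized).
Offspring haplotypes are formed by meiosis with Poisson(L) crossovers
per chromosome at uniform genetic positions (1 cM ≡ 1 Mb physically).

Traits are additive: marker effects are drawn normal (all markers for
the polygenic architecture; for the oligogenic one, n_qtl markers carry
`variance_share` of the genetic variance over a polygenic background),
then rescaled so the realized sample variance of `Zβ` equals
`h² · sd²` — an analytic scale from allele frequencies alone drifts
under LD, so the realized-variance rescale is what keeps the
calibration invariant (mean realized h² within ±0.03 of target) true.
Residuals are N(0, (1−h²)sd²); a batch factor with uniformly assigned
levels and normal level effects models hatch/pen structure (the
emulated study names batch but not its cardinality; the preset uses 4
levels at 5% of the trait SD). Missingness applies to phenotypes only,
per generation, mimicking culling-driven record loss with age.

The `wenchang` preset: 735 founders, 1,152 then 717 matings of two
offspring → 4,473 birds over three generations, 3,738 genotyped in the
last two; six trait presets (body weight and ultrasound abdominal-fat
thickness at 22/32/45 weeks) carry the line's means, SDs,
heritabilities and effective record counts (e.g. 32-week body weight:
mean 1.905, SD 0.228, h² 0.264, 3,153 records). Founders carry a
0.999 missing rate (the rate domain excludes 1.0).

What the generator does **not** model: selection and assortative
mating, genotyping error and imputation uncertainty, dominance or
epistasis, genotype-by-environment interaction, and realistic
genome-wide LD beyond the block-mosaic approximation. Passing tests
therefore demonstrate internal consistency and correct algebra on data
satisfying the additive model's assumptions, not performance on real
populations.

## Reproducibility experiments and problem sizes

`scripts/acceptance.py` (and the mirror tests) use deliberately
reduced problem sizes chosen for a single-core desktop run:

- EM-REML recovery: 10 replicates of a ~550-animal pedigree with 2,000
  markers at h² = 0.30.
- Generator calibration: 20 replicates at n = 1,000, 500 markers,
  target h² = 0.264.
- Directional model comparison: 10 seeded runs of an 800-animal
  pedigree, 800 post-QC markers, oligogenic trait (10 QTL, 60% of
  genetic variance, h² = 0.30), 3×5-fold CV. Variance components are
  estimated once per run (the run-level switch), and WGBLUP uses
  full-data wssGWAS weights, mirroring the provenance of weights
  imported from a prior full-data analysis.

## Limitations

- Full-data wssGWAS weights leak validation phenotypes into the
  weights and inflate the apparent WGBLUP gain well beyond what
  fold-local weights give; the directional experiment reports
  direction, not magnitude. The pipeline default (`fold`) is the
  leak-free protocol.
- EM-REML is robust but slow near variance boundaries; AI-REML would
  converge faster and is deliberately out of scope.
- Dense algebra bounds practical population size at roughly 5,000–
  10,000 animals on a workstation.
- The exact HWE test assumes autosomal biallelic markers; sex
  chromosomes are not treated specially.
- `ld_prune` prunes genome-wide in map order; per-chromosome pruning
  would differ only at chromosome boundaries within a window.
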