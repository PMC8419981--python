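# Methods

## Model and notation

A quantitative trait follows Y = **X**β + ε with **X** the vector of p
biallelic SNP dosages, β fixed per-allele effects and ε zero-mean
normal noise; **y** and **x**_j are the observed, mean-centered N × 1
phenotype and genotype columns. GWAS summary statistics are the
per-SNP marginal regression outputs

    β̂_j = (x_j'x_j)^{-1} x_j'y,
    SE(β̂_j) = sqrt( ê_j'ê_j / ((N−1) x_j'x_j) ),

plus the two-sided normal p-value, per-SNP sample size N_j, and minor
allele frequency f_j. Everything downstream works with the score
statistic S_j = x_j'y, which for independent individuals is a sum of N
iid contributions X_j·Y and hence asymptotically normal.

## Subsampling score statistics

For a random training subset of N−n individuals, exact conditional
algebra for a sum of N iid terms gives

    S_j^(tr) | S_j ~ N( (N−n)/N · S_j ,  n(N−n)/N · Σ_j ),

with Σ_j = Var(X_j Y) the per-individual variance. The validation
statistic is the complement S_j^(v) = S_j − S_j^(tr). Σ_j is estimated
from the summary statistics themselves as Σ̂_j = N[SE(β̂_j)·σ̂_j²]²
with σ̂_j² = 2f_j(1−f_j), the HWE variance of a centered additive
genotype; this uses the identity ê_j'ê_j/N ≈ N·SE²·σ̂_j² and the fact
that per-SNP effects in GWAS are individually tiny.

**Variance convention.** The conditional variance can also be read
"literally" as ((N−n)/N)·Σ̂_j, without the factor n. We implement the
finite-sample form n(N−n)/N·Σ̂_j as the default because (i) it is the
exact conditional-normal algebra for partial sums, (ii) it is symmetric
in the two partitions, and (iii) it is the unique scaling under which
the per-SNP sampling distribution of the subsampled β̂^(tr) matches
literal individual-level re-regression on random subsamples in both
mean and variance (the calibration test in `tests/test_subsampler.py`).
`variance_convention="literal"` is available for comparison.

**Independence.** Sampling is per-SNP independent (diagonal
covariance). This is justified only for LD-pruned input; the
off-diagonal terms β̂_jβ̂_iσ̂_j²σ̂_i² are exposed as diagnostics
(`cov_offdiag`, `theoretical_cov_offdiag`) and are orders of magnitude
below the diagonal on independent SNPs. Clumped input is rejected with
a warning rather than supported: clumping selects SNPs by full-sample
p-values, which leaks ranking information into every subsampled fold
and produces tuning curves unrelated to external validation.

**Recovered training statistics.** β̂_j^(tr) = S_j^(tr)/((N−n)σ̂_j²),
SE^(tr) = SE·√(N/(N−n)) (exact, independent of the draw), and the
training p-value is recomputed from β̂^(tr)/SE^(tr) — never reused from
the full sample, for the same leak-avoidance reason.

**K-fold partitioning.** K−1 subsamples of per-SNP size
round-half-even(N_j/K) are drawn independently from the conditional
distribution with mean S_j·n_k/N_j; the K-th is the exact residual, so
sizes and scores both sum to the input. Pooling training folds sums
score statistics and sample sizes and recomputes β̂/SE analytically,
which is exact under the same algebra. Each fold consumes an
independent `SeedSequence` substream, so individual folds are
reproducible in isolation.

**Conservation in floating point.** The complement S^(v) = S − S^(tr)
is exact by construction; re-adding the pair reproduces S to within one
ulp of the summands. Bitwise equality of the re-added pair is not
attainable in IEEE arithmetic when the drawn value nearly cancels the
total, so tests assert the construction identity exactly and the
additive reconstruction at one-ulp tolerance.

**Heterogeneous sample sizes.** When N_j varies (meta-analyses), the
validation size is held constant at round(0.25·min_j N_j) while each
SNP keeps its own training size. Upstream QC can drop SNPs below the
30% quantile (type-7/linear interpolation) of the N distribution —
mis-specified N distorts the R² scale more than the ranking, so this
step mostly aids interpretability.

## Summary-level R²

For P+T weights w_j = β̂_j^(tr)·1[p_j^(tr) ≤ λ],

    R̂²(λ) = ( (1/n) Σ_j w_j S_j^(v) )² / ( V̂ar(Y) · Σ_j w_j² σ̂_j² ).

The denominator's Σ w²σ̂² approximates Var(Ŷ) for independent SNPs.
V̂ar(Y) uses per-SNP proxies v_j = N_j·SE_j²·σ̂_j² (each approximates
the marginal residual variance, which is ≈ Var(Y) when per-SNP effects
are small): `max` takes max_j v_j; the default `quantile90` takes the
90% type-7 quantile, robust to a few SNPs with inflated SEs. The
product N·SE² is invariant under the subsampling SE rescaling, so
either the full-sample or training frame gives the same V̂ar(Y).
Var(Y) only scales R̂²; it never moves the argmax.

Conventions: an empty model scores 0 (profiles and argmax stay total);
R̂² is invariant to rescaling all weights (c² cancels) and to the
measurement scale of Y; exact ties in the profile resolve to the
smaller λ (sparser model). For binary traits, logistic β̂/SE are
consumed unchanged and the output is an "approximated R²" whose
ranking, not scale, is meaningful; no AUC or liability-scale conversion
is attempted. Under K-fold partitioning with heterogeneous N_j the
per-SNP validation sizes can differ slightly; the 1/n normalizer uses
their mean.

Tuning procedures: `tune_split` (one split), `tune_repeated` (K
independent splits, Monte Carlo cross-validation; the default K=4 and
valid_frac=0.25 mirror the 4-fold design used throughout validation),
`tune_kfold` (one exact partition, K rotations). All average R̂² per λ
across folds and select the argmax.

## LD pruning

Sliding-window greedy pruning (defaults: window 100 variants, step 5,
r² ≤ 0.1) guarantees that every kept pair within a window satisfies
the r² ceiling; when a pair violates it, the variant with the larger
GWAS p-value (if supplied) or the later one in position order is
removed. The output is deterministic given input order and parameters.
This is not a PLINK re-implementation — only the r² guarantee is
promised. Missing genotypes are mean-imputed per variant before
correlation.

## Synthetic-data generator

The generator emulates the *post-pruning* regime the method assumes:

- Genotypes: independent Binomial(2, f_j) dosages, f_j ~
  Uniform(0.01, 0.5). Real panels have LD, missingness and HWE
  departures; none of these are modeled, so passing tests validate the
  statistical machinery on independent SNPs, not robustness to residual
  LD or genotyping artifacts.
- Effects: a causal subset of size round(M·p_causal) with raw effects
  N(0, h²/(M·p_causal)), rescaled by [2f_j(1−f_j)]^α for
  α ∈ {−2,…,2}; α < 0 loads heritability on rare variants, α > 0 on
  common ones. Defaults h² = 0.5 and p_causal ∈ {0.001, 0.1} represent
  sparse and polygenic architectures.
- Quantitative trait: y = X_c β* + ε with Var(ε) set from the realized
  genetic variance so the realized heritability equals the nominal h²
  (genotypes enter centered but unstandardized; the α-scalings are
  interpreted on that scale).
- Binary trait: the same liability thresholded at the prevalence
  quantile (default 50%), then cases/controls subsampled to the
  configured ratio (default 1:1); per-SNP logistic regressions supply
  the summary statistics, and the individual-level oracle scores AUC.

`oracle_repeated_learning` is the gold standard: literal sample
splits, GWAS re-run on each training split, held-out individuals
scored, squared Pearson correlation (or AUC) recorded per λ.

## Problem sizes used in validation

Full-scale GWAS validation is not meaningful at desk scale, so the
test-suite replications use deliberately scaled designs:

- Variance-estimator fidelity: 2,000 × 5,000 SNPs, h²=0.5,
  p_causal=0.1 — the Pearson correlation between theoretical and
  estimated score variances exceeds 0.99.
- Summary vs. individual-level equivalence: 5,000 × 5,000, ten
  replicate seeds per architecture (p_causal 0.001 and 0.1), 4-fold,
  λ grid 1e-5…1; compared by Spearman correlation of seed-averaged
  profiles and per-seed agreement of the selected λ.
- Polygenic selection behavior: 2,000 × 40,000 at p_causal=0.1, chosen
  so the per-causal-SNP noncentrality N·h²/(M·p) ≈ 0.25 matches the
  full-scale polygenic design; in that regime the profile rises with λ
  and dense cutoffs win, while the sparse design concentrates on
  stringent cutoffs.

## Known limitations

- Only the classic P+T model is tuned; no LDpred-style or penalized
  weights.
- No LD-aware (off-diagonal) subsampling: input must be pruned, and
  clumped input is explicitly unsupported for tuning.
- The binary-trait R² is a ranking device, not a calibrated accuracy
  measure.
- Per-SNP logistic regressions loop in Python; binary simulation is
  intended for moderate SNP counts.
- Samples are assumed independent (no family structure) and summary
  statistics are assumed to come from one homogeneous GWAS.
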