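# sumtune

Fine-tune pruning-and-thresholding (P+T) polygenic scores using **GWAS
summary statistics only** — no individual-level validation cohort
required.

## The problem

A P+T polygenic score predicts a trait as Ŷ = **Xw**, with
w_j = β̂_j·1[p_j ≤ λ]: each SNP passing a p-value cutoff λ contributes
its marginal GWAS effect. The cutoff λ is a tuning parameter, and tuning
it normally requires held-out individual-level data — which for most
published GWAS nobody has. `sumtune` solves this with two steps:

1. **Subsample summary statistics.** The score statistic
   S_j = **x**_j᷀ᵀ**y** of a random training subset of N−n individuals,
   conditional on the full-sample value, is normal:

       S_j⁽ᵗʳ⁾ | S_j ~ N( (N−n)/N · S_j ,  n(N−n)/N · Σ̂_j ),
       Σ̂_j = N·[SE(β̂_j)·σ̂_j²]²,   σ̂_j² = 2f_j(1−f_j).

   The validation statistic is the exact complement
   S_j⁽ᵛ⁾ = S_j − S_j⁽ᵗʳ⁾, and training-set β̂/SE/p are recovered
   analytically (SE⁽ᵗʳ⁾ = SE·√(N/(N−n))). This yields training and
   validation GWAS without touching a single genotype.

2. **Evaluate R² from summary statistics.** The predictive R² of the
   P+T model on the (synthetic) validation set is estimated as

       R̂² = ( (1/n)·Σ_j w_j S_j⁽ᵛ⁾ )² / ( V̂ar(Y) · Σ_j w_j² σ̂_j² ),

   with V̂ar(Y) the 90% quantile (or max) of the per-SNP proxies
   N·SE_j²·σ̂_j². Selecting λ̂ = argmax_λ R̂²(λ) — averaged over
   repeated splits or K-fold partitions of the score statistics —
   reproduces the choice an individual-level validation cohort would
   make.

Input must be **LD-pruned** (the per-SNP independence the sampler
assumes); tuning on *clumped* statistics is invalid, because clumping
selects SNPs with full-sample p-values, and the CLI warns if you try.

## Worked example

```python
import sumtune

# simulate a pruned GWAS: 5,000 individuals, 5,000 independent SNPs,
# h2 = 0.5, 0.1% of SNPs causal (a sparse architecture)
cfg = sumtune.SimConfig(n_samples=5000, n_snps=5000, h2=0.5,
                        p_causal=0.001, seed=11)
data = sumtune.simulate_dataset(cfg)
stats = sumtune.marginal_gwas(data)           # full-sample summary statistics

grid = [1e-5, 1e-4, 1e-3, 0.01, 0.1, 0.5, 1.0]
res = sumtune.tune_repeated(stats, grid=grid, K=4, seed=3)
print(res.lambda_star)                        # 1e-05
print([round(r, 4) for r in res.r2_mean])
# [0.5195, 0.5195, 0.5034, 0.4323, 0.2407, 0.1361, 0.1267]

# individual-level gold standard on the same data agrees:
orc = sumtune.oracle_repeated_learning(data, grid=grid, K=4, seed=3)
print(orc.lambda_star)                        # 1e-05
```

The R̂² profile peaks at the most stringent cutoff — with only 5 causal
SNPs of large effect, adding more SNPs only adds noise — and the
summary-level choice matches the literal repeated-learning oracle that
re-runs the GWAS on actual sample splits. A polygenic architecture
(`p_causal=0.1` at low per-SNP power) instead selects dense cutoffs
(λ ≥ 0.1).

From the shell:

```bash
sumtune simulate --n-samples 5000 --n-snps 2000 --h2 0.5 --p-causal 0.01 \
    --seed 1 --out sim
sumtune tune --sumstats sim.sumstats.tsv --method repeated --k 4 \
    --valid-frac 0.25 --seed 42 --out tuned
# -> tuned.results.tsv (per-fold profile), tuned.model.tsv (snp/allele/weight),
#    tuned.manifest.json (selected lambda*, config echo)
```

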