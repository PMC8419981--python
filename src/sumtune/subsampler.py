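"""Subsample GWAS summary statistics via conditional normal draws.

The marginal association between SNP j and a centered trait is summarised
by the score statistic S_j = x_j' y.  For N independent individuals S_j is
a sum of N iid terms X_j Y, so by the CLT it is approximately normal, and
the score statistic of a random training subset of N - n individuals,
conditional on the full-sample value, is

    S_j^(tr) | S_j  ~  Normal( (N - n)/N * S_j ,  n (N - n)/N * Sigma_j )

where Sigma_j = Var(X_j Y) is the per-individual variance of the score
contribution.  The validation-set statistic is the exact complement
S_j^(v) = S_j - S_j^(tr), so the two partitions always reconstruct the
input.  Sigma_j is estimated from the summary statistics themselves as

    Sigma_hat_j = N * [ SE(beta_hat_j) * sigma_hat_j^2 ]^2

with sigma_hat_j^2 = 2 f_j (1 - f_j) the HWE genotype variance at minor
allele frequency f_j.  Off-diagonal covariance terms are negligible for
LD-pruned input and are exposed only as diagnostics; sampling is per-SNP
independent.

Subsampled training summary statistics are recovered analytically:

    beta_hat_j^(tr) = S_j^(tr) / ( (N - n) sigma_hat_j^2 )
    SE(beta_hat_j^(tr)) = sqrt( N / (N - n) ) * SE(beta_hat_j)

and the training p-value is recomputed from beta/SE (never reused from
the full sample, which would leak full-sample ranking into tuning).
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

VarianceConvention = Literal["exact", "literal"]


class SubsampleError(ValueError):
    pass


def snp_variance(maf) -> np.ndarray:
    """Genotype variance 2 f (1 - f) of a centered additive dosage under HWE.

    ``maf`` must lie in (0, 0.5]; scalar or array.
    """
    f = np.asarray(maf, dtype=float)
    if np.any(~((f > 0) & (f <= 0.5))):
        raise SubsampleError("MAF must lie in (0, 0.5]")
    out = 2.0 * f * (1.0 - f)
    return out if out.ndim else float(out)


def to_score_stats(stats: pd.DataFrame) -> pd.DataFrame:
    """Convert marginal summary statistics to score statistics.

    Inverts beta_hat_j = (x_j'x_j)^{-1} x_j'y with x_j'x_j ~ N sigma_j^2:

        s_full = N * sigma_j^2 * beta_hat_j
        var_s  = N * (SE * sigma_j^2)^2      (per-individual Var(X_j Y))

    Requires ``maf`` to be present for every SNP.
    """
    if stats["maf"].isna().any():
        raise SubsampleError("MAF required for every SNP; run fill_maf first")
    sigma2 = snp_variance(stats["maf"].to_numpy())
    n = stats["n"].to_numpy(dtype=float)
    se = stats["se"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "snp": stats["snp"].to_numpy(),
            "s_full": n * sigma2 * stats["beta"].to_numpy(dtype=float),
            "sigma2": sigma2,
            "var_s": n * (se * sigma2) ** 2,
            "n": stats["n"].to_numpy(dtype=int),
            "se_full": se,
        }
    )
    if np.any(out["var_s"] <= 0):
        raise SubsampleError("nonpositive score variance; check SE and MAF")
    return out


def cov_offdiag(stats_i: pd.Series, stats_j: pd.Series) -> float:
    """Estimated covariance of score statistics for two SNPs (diagnostic).

    beta_i * beta_j * sigma_i^2 * sigma_j^2 — negligible for pruned input
    and never used in sampling.
    """
    s2i = snp_variance(stats_i["maf"])
    s2j = snp_variance(stats_j["maf"])
    return float(stats_i["beta"] * stats_j["beta"] * s2i * s2j)


def _conditional_sd(
    n_valid: np.ndarray, n_full: np.ndarray, var_s: np.ndarray,
    convention: VarianceConvention,
) -> np.ndarray:
    n_train = n_full - n_valid
    if convention == "exact":
        # finite-sample conditional variance for a sum of N iid terms
        var = n_valid * n_train / n_full * var_s
    elif convention == "literal":
        var = n_train / n_full * var_s
    else:
        raise SubsampleError(f"unknown variance convention {convention!r}")
    return np.sqrt(var)


def _train_summary(s_train, n_train, sigma2, se_full, n_full):
    beta = s_train / (n_train * sigma2)
    se = se_full * np.sqrt(n_full / n_train)
    p = 2.0 * sps.norm.sf(np.abs(beta / se))
    return beta, se, p


def subsample_split(
    score: pd.DataFrame,
    n_valid: int,
    rng_seed,
    variance_convention: VarianceConvention = "exact",
) -> pd.DataFrame:
    """Draw one training/validation partition of the score statistics.

    ``n_valid`` is the validation sample size, constant across SNPs (for
    heterogeneous per-SNP N the conventional choice is 25% of the minimal
    N); each SNP keeps its own training size n_train = N_j - n_valid.

    Returns a SplitStats frame with the drawn score statistics, the
    analytic training-set beta/SE/p, and the validation-side equivalents.
    ``n_valid = 0`` is the degenerate deterministic split.
    """
    rng = np.random.default_rng(rng_seed)
    n_full = score["n"].to_numpy(dtype=float)
    if np.any(n_valid >= n_full) or n_valid < 0:
        bad = score.loc[n_valid >= n_full, "snp"]
        raise SubsampleError(
            f"n_valid={n_valid} not in [0, N) for SNP(s) {list(bad.head())}"
        )
    n_train = n_full - n_valid
    s_full = score["s_full"].to_numpy(dtype=float)
    mean = n_train / n_full * s_full
    if n_valid == 0:
        s_train = s_full.copy()
    else:
        sd = _conditional_sd(float(n_valid), n_full, score["var_s"].to_numpy(), variance_convention)
        s_train = rng.normal(mean, sd)
    # exact complement by construction; adding the pair back reconstructs
    # s_full to within one ulp of the summands
    s_valid = s_full - s_train

    sigma2 = score["sigma2"].to_numpy()
    se_full = score["se_full"].to_numpy()
    beta_tr, se_tr, p_tr = _train_summary(s_train, n_train, sigma2, se_full, n_full)
    out = pd.DataFrame(
        {
            "snp": score["snp"].to_numpy(),
            "s_train": s_train,
            "s_valid": s_valid,
            "n_train": n_train.astype(int),
            "n_valid": int(n_valid),
            "beta_train": beta_tr,
            "se_train": se_tr,
            "p_train": p_tr,
            "sigma2": sigma2,
        }
    )
    if n_valid > 0:
        beta_v, se_v, p_v = _train_summary(s_valid, float(n_valid), sigma2, se_full, n_full)
        out["beta_valid"], out["se_valid"], out["p_valid"] = beta_v, se_v, p_v
    return out


def kfold_partition(
    score: pd.DataFrame,
    K: int,
    rng_seed,
    variance_convention: VarianceConvention = "exact",
) -> list[pd.DataFrame]:
    """Partition score statistics into K subsamples that sum to the input.

    K - 1 subsamples are drawn independently, each with per-SNP sample
    size round(N_j / K) (round-half-even) and conditional mean S_j / K
    scaled by its size; the K-th subsample is the exact residual, so the
    per-SNP sizes and score statistics both sum to the full-sample values.

    Each fold uses an independent, documented RNG substream, so folds are
    reproducible individually.
    """
    if K < 2:
        raise SubsampleError(f"K must be >= 2, got {K}")
    n_full = score["n"].to_numpy(dtype=float)
    n_k = np.rint(n_full / K)
    if np.any(n_k < 1) or np.any(n_full - (K - 1) * n_k < 1):
        raise SubsampleError("K too large for the smallest per-SNP sample size")
    s_full = score["s_full"].to_numpy(dtype=float)
    var_s = score["var_s"].to_numpy(dtype=float)

    streams = np.random.SeedSequence(rng_seed).spawn(K - 1)
    folds = []
    for k in range(K - 1):
        rng = np.random.default_rng(streams[k])
        mean = n_k / n_full * s_full
        sd = _conditional_sd(n_k, n_full, var_s, variance_convention)
        s_k = rng.normal(mean, sd)
        folds.append(
            pd.DataFrame({"snp": score["snp"].to_numpy(), "s": s_k, "n_k": n_k.astype(int)})
        )
    partial = np.zeros_like(s_full)
    for f in folds:
        partial = partial + f["s"].to_numpy()
    s_res = s_full - partial  # exact complement of the accumulated draws
    n_res = n_full - (K - 1) * n_k
    folds.append(
        pd.DataFrame({"snp": score["snp"].to_numpy(), "s": s_res, "n_k": n_res.astype(int)})
    )
    return folds


def default_n_valid(n: np.ndarray | pd.Series, valid_frac: float = 0.25) -> int:
    """Validation sample size: ``round(valid_frac * min_j N_j)``.

    With heterogeneous per-SNP N the validation size is held constant
    across SNPs (anchored at the minimal N) while training sizes vary.
    """
    if not 0.0 < valid_frac < 1.0:
        raise SubsampleError(f"valid_frac must be in (0, 1), got {valid_frac}")
    return int(np.rint(valid_frac * float(np.min(np.asarray(n)))))


def split_sizes(n: int, valid_frac: float = 0.25) -> tuple[int, int]:
    """(training, validation) sample sizes for a uniform-N split."""
    n_valid = default_n_valid(np.array([n]), valid_frac)
    return n - n_valid, n_valid
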