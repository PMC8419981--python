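"""Synthetic GWAS generator and the individual-level tuning oracle.

The generator emulates a pruned (LD-free) GWAS: independent biallelic
SNPs with dosages Binomial(2, f_j), f_j ~ Uniform(maf_range); a causal
subset of size round(M * p_causal) with raw effects beta_j ~
Normal(0, h2 / (M * p_causal)); and a frequency-dependent rescaling

    beta*_j = beta_j * [2 f_j (1 - f_j)]^alpha,   alpha in {-2,...,2}

so that alpha < 0 concentrates heritability on rare variants and
alpha > 0 on common ones.  Quantitative traits are y = Xc beta* + eps
with the residual variance targeted so the realized genetic variance
fraction equals h2; binary traits threshold the same liability at the
population-prevalence quantile, then subsample cases/controls to the
configured ratio.

``marginal_gwas`` produces the per-SNP marginal regression summary
statistics (closed form for quantitative traits, logistic regression for
binary) that the summary-level machinery consumes, and
``oracle_repeated_learning`` is the literal individual-level repeated
learning procedure — actually splitting samples, re-running the GWAS on
the training split, scoring held-out individuals — against which the
summary-level results are validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ld_ops import GenotypeMatrix
from .prs_eval import DEFAULT_GRID
from .tuner import TuneResult

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study conditions for one synthetic GWAS."""

    n_samples: int = 5000
    n_snps: int = 5000
    h2: float = 0.5
    p_causal: float = 0.1
    alpha: int = 0
    maf_range: tuple = (0.01, 0.5)
    trait: str = "quantitative"  # or "binary"
    prevalence: float = 0.5
    case_control_ratio: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if not 0.0 < self.p_causal <= 1.0:
            raise ValueError("p_causal must be in (0, 1]")
        if self.maf_range[0] < 0.01 or self.maf_range[1] > 0.5:
            raise ValueError("maf_range must lie within [0.01, 0.5]")
        if self.trait not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait type {self.trait!r}")


@dataclass
class SimDataset:
    genotypes: GenotypeMatrix
    phenotype: np.ndarray
    beta_true: np.ndarray
    causal_set: np.ndarray
    epsilon_var: float
    config: SimConfig = None
    liability: np.ndarray = field(default=None, repr=False)


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator) -> GenotypeMatrix:
    """Independent Binomial(2, f) dosages with f ~ Uniform(maf_range)."""
    f = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    dos = rng.binomial(2, f, size=(cfg.n_samples, cfg.n_snps)).astype(np.float64)
    snps = np.array([f"rs{j + 1}" for j in range(cfg.n_snps)])
    a1 = np.full(cfg.n_snps, "A")
    a2 = np.full(cfg.n_snps, "G")
    return GenotypeMatrix(dos, snps, a1, a2)


def simulate_effects(cfg: SimConfig, freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw sparse per-allele effects with frequency-dependent scaling.

    ``freqs`` are the per-SNP allele frequencies f_j used in the
    [2 f (1-f)]^alpha rescaling (the generator passes the realized
    empirical frequencies).
    """
    m = cfg.n_snps
    n_causal = int(np.rint(m * cfg.p_causal))
    if n_causal == 0:
        raise ValueError("p_causal too small: no causal SNP")
    causal = rng.choice(m, size=n_causal, replace=False)
    beta = np.zeros(m)
    raw = rng.normal(0.0, np.sqrt(cfg.h2 / (m * cfg.p_causal)), size=n_causal)
    het = 2.0 * freqs[causal] * (1.0 - freqs[causal])
    beta[causal] = raw * het**cfg.alpha
    return beta


def simulate_phenotype(
    geno: GenotypeMatrix, beta_true: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> SimDataset:
    """Generate the trait from centered genotypes and true effects.

    The residual variance is set from the realized genetic variance
    Var(Xc beta*) so the realized heritability matches the nominal h2.
    Binary traits threshold the liability at the prevalence quantile and
    subsample to the case/control ratio.
    """
    xc = geno.dosages - geno.dosages.mean(axis=0)
    g = xc @ beta_true
    var_g = float(g.var())
    if cfg.h2 == 0.0 or var_g == 0.0:
        g = np.zeros_like(g)
        eps_var = 1.0
    elif cfg.h2 == 1.0:
        eps_var = 0.0
    else:
        eps_var = var_g * (1.0 - cfg.h2) / cfg.h2
    liability = g + rng.normal(0.0, np.sqrt(eps_var), size=len(g))
    causal = np.flatnonzero(beta_true != 0.0)

    if cfg.trait == "quantitative":
        return SimDataset(geno, liability, beta_true, causal, eps_var, cfg, liability)

    cutoff = np.quantile(liability, 1.0 - cfg.prevalence)
    case = liability > cutoff
    case_idx = np.flatnonzero(case)
    ctrl_idx = np.flatnonzero(~case)
    n_case = min(len(case_idx), int(np.rint(len(ctrl_idx) * cfg.case_control_ratio)))
    n_ctrl = min(len(ctrl_idx), int(np.rint(n_case / cfg.case_control_ratio)))
    keep = np.sort(
        np.concatenate(
            [
                rng.choice(case_idx, size=n_case, replace=False),
                rng.choice(ctrl_idx, size=n_ctrl, replace=False),
            ]
        )
    )
    sub = GenotypeMatrix(
        geno.dosages[keep], geno.snps, geno.a1, geno.a2, geno.chrom, geno.pos
    )
    return SimDataset(
        sub, case[keep].astype(float), beta_true, causal, eps_var, cfg, liability[keep]
    )


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Genotypes + effects + phenotype from one config and seed."""
    rng = np.random.default_rng(cfg.seed)
    geno = simulate_genotypes(cfg, rng)
    freqs = geno.dosages.mean(axis=0) / 2.0
    beta = simulate_effects(cfg, freqs, rng)
    return simulate_phenotype(geno, beta, cfg, rng)


# ---------------------------------------------------------------------------
# Marginal GWAS
# ---------------------------------------------------------------------------

def _marginal_linear(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-SNP marginal regression on centered data.

    beta_j = x_j'y / x_j'x_j, SE_j = sqrt(e_j'e_j / ((N-1) x_j'x_j)) with
    e_j the marginal residual; vectorized across SNPs without forming the
    residual matrix (e_j'e_j = y'y - beta_j x_j'y).
    """
    n = len(y)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ yc
    beta = sxy / sxx
    rss = float(yc @ yc) - beta * sxy
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(rss / ((n - 1) * sxx))
    return beta, se


def marginal_gwas(data: SimDataset) -> pd.DataFrame:
    """Per-SNP marginal association scan; returns canonical summary statistics.

    Quantitative traits use the exact closed-form linear regression on
    centered data; binary traits run per-SNP logistic regressions.
    Monomorphic SNPs are dropped with a warning.
    """
    geno = data.genotypes
    freq = geno.dosages.mean(axis=0) / 2.0
    poly = (freq > 0.0) & (freq < 1.0)
    if not poly.all():
        logger.warning("dropping %d monomorphic SNPs from the scan", int((~poly).sum()))
    x = geno.dosages[:, poly]
    y = np.asarray(data.phenotype, dtype=float)

    if data.config is not None and data.config.trait == "binary":
        beta, se = _marginal_logistic(x, y)
    else:
        beta, se = _marginal_linear(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2.0 * sps.norm.sf(np.abs(beta / se))
    f = freq[poly]
    return pd.DataFrame(
        {
            "snp": geno.snps[poly],
            "a1": np.asarray(geno.a1)[poly],
            "a2": np.asarray(geno.a2)[poly],
            "beta": beta,
            "se": se,
            "p": p,
            "n": len(y),
            "maf": np.minimum(f, 1.0 - f),
        }
    )


def _marginal_logistic(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP logistic regression with intercept (Newton iterations)."""
    import statsmodels.api as sm

    m = x.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    for j in range(m):
        design = sm.add_constant(x[:, j])
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=50)
            beta[j] = fit.params[1]
            se[j] = fit.bse[1]
        except Exception:  # separation or non-convergence: leave NaN
            pass
    bad = ~np.isfinite(beta) | ~np.isfinite(se) | (se <= 0)
    if bad.any():
        logger.warning("%d SNPs failed logistic regression; SE set NaN", int(bad.sum()))
        se[bad] = np.nan
    return beta, se


# ---------------------------------------------------------------------------
# Theoretical score-statistic covariance (ground truth for diagnostics)
# ---------------------------------------------------------------------------

def theoretical_cov_diag(data: SimDataset) -> np.ndarray:
    """Ground-truth per-SNP variance of the score-statistic contribution.

    Sigma_j = beta*_j^2 Var(X_j^2) + E(eps_j^2) E(X_j^2), with moments
    taken empirically from the simulated centered genotypes and eps_j the
    marginal residual y - x_j beta*_j for the true marginal effect (equal
    to beta*_j since SNPs are independent).
    """
    xc = data.genotypes.dosages - data.genotypes.dosages.mean(axis=0)
    y = np.asarray(data.phenotype, dtype=float)
    yc = y - y.mean()
    n = len(y)
    beta = data.beta_true
    x2 = xc**2
    e_x2 = x2.mean(axis=0)
    var_x2 = x2.var(axis=0)
    # E(eps_j^2) = mean of (y - x_j beta_j)^2, expanded in moments
    sxy = xc.T @ yc / n
    e_eps2 = float(yc @ yc) / n - 2.0 * beta * sxy + beta**2 * e_x2
    return beta**2 * var_x2 + e_eps2 * e_x2


def theoretical_cov_offdiag(data: SimDataset, i: int, j: int) -> float:
    """Ground-truth covariance Sigma_ji = beta_j beta_i E(X_j^2) E(X_i^2)."""
    xc = data.genotypes.dosages - data.genotypes.dosages.mean(axis=0)
    e2i = float((xc[:, i] ** 2).mean())
    e2j = float((xc[:, j] ** 2).mean())
    return float(data.beta_true[i] * data.beta_true[j] * e2i * e2j)


# ---------------------------------------------------------------------------
# Individual-level oracle
# ---------------------------------------------------------------------------

def score_individuals(geno: GenotypeMatrix, weights: np.ndarray) -> np.ndarray:
    """PRS for each sample from centered dosages: y_hat = Xc w."""
    xc = geno.dosages - geno.dosages.mean(axis=0)
    return xc @ np.asarray(weights, dtype=float)


def _auc(y: np.ndarray, score: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, score))


def oracle_repeated_learning(
    data: SimDataset,
    grid=DEFAULT_GRID,
    K: int = 4,
    valid_frac: float = 0.25,
    seed=None,
) -> TuneResult:
    """Literal repeated learning with individual-level data.

    Each of K rounds holds out round(valid_frac * N) individuals, reruns
    the marginal GWAS on the remaining samples, builds P+T weights at
    every threshold in ``grid``, scores the held-out individuals, and
    records the squared Pearson correlation between PRS and phenotype
    (AUC for binary traits).  The averaged profile selects the threshold.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    y = np.asarray(data.phenotype, dtype=float)
    n = len(y)
    n_valid = int(np.rint(valid_frac * n))
    if n_valid < 30:
        raise ValueError(f"validation split of {n_valid} samples is too small (< 30)")
    binary = data.config is not None and data.config.trait == "binary"

    streams = np.random.SeedSequence(seed).spawn(K)
    r2 = np.zeros((K, len(grid)))
    nsnp = np.zeros((K, len(grid)), dtype=int)
    for k in range(K):
        rng = np.random.default_rng(streams[k])
        vidx = rng.choice(n, size=n_valid, replace=False)
        vmask = np.zeros(n, dtype=bool)
        vmask[vidx] = True
        x_tr = data.genotypes.dosages[~vmask]
        x_va = data.genotypes.dosages[vmask]
        y_tr, y_va = y[~vmask], y[vmask]

        if binary:
            beta, se = _marginal_logistic(x_tr, y_tr)
        else:
            beta, se = _marginal_linear(x_tr, y_tr)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 2.0 * sps.norm.sf(np.abs(beta / se))
        p = np.where(np.isfinite(p), p, 1.0)
        beta = np.where(np.isfinite(beta), beta, 0.0)

        xc_va = x_va - x_va.mean(axis=0)
        wmat = np.where(p[:, None] <= grid[None, :], beta[:, None], 0.0)
        yhat = xc_va @ wmat
        nsnp[k] = (wmat != 0.0).sum(axis=0)
        for j in range(len(grid)):
            if nsnp[k, j] == 0 or yhat[:, j].std() == 0.0:
                r2[k, j] = 0.0
            elif binary:
                r2[k, j] = _auc(y_va, yhat[:, j])
            else:
                r2[k, j] = float(np.corrcoef(yhat[:, j], y_va)[0, 1] ** 2)

    by_lam = {lam: r2[:, j].mean() for j, lam in enumerate(grid)}
    from .prs_eval import select_threshold

    lambda_star = select_threshold(by_lam)
    jstar = int(np.flatnonzero(grid == lambda_star)[0])
    config = {
        "method": "oracle_repeated", "K": K, "valid_frac": valid_frac,
        "n_valid": n_valid, "n_train": n - n_valid,
        "metric": "auc" if binary else "r2", "grid": list(map(float, grid)),
    }
    return TuneResult(grid, r2, lambda_star, int(np.rint(nsnp[:, jstar].mean())), seed, config, nsnp)
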