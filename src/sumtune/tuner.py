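"""Model-tuning procedures over a p-value threshold grid.

Three strategies, all operating purely on summary statistics:

* ``tune_split`` — one training/validation subsample, evaluate the grid.
* ``tune_repeated`` — Monte Carlo cross-validation: K independent
  training/validation subsamples, average R^2 per threshold.
* ``tune_kfold`` — K-fold cross-validation on one exact partition of the
  score statistics; each fold in turn is the validation set while the
  remaining folds are pooled (score statistics and sample sizes sum
  exactly, and the pooled beta/SE are recomputed analytically).

All procedures require LD-pruned input.  They must NOT be run on clumped
summary statistics: clumping selects SNPs using full-sample p-values, and
the resulting tuning curve is invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import prs_eval, subsampler
from .prs_eval import DEFAULT_GRID, select_threshold

logger = logging.getLogger(__name__)


@dataclass
class TuneResult:
    """Per-fold R^2 profile over the threshold grid and the selected model."""

    grid: np.ndarray  # ascending thresholds, length L
    r2_matrix: np.ndarray  # folds x L
    lambda_star: float
    n_snps_star: int
    seed: object = None
    config: dict = field(default_factory=dict)
    n_snps_matrix: np.ndarray = None

    @property
    def r2_mean(self) -> np.ndarray:
        return self.r2_matrix.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.r2_matrix.shape[0]):
            for j, lam in enumerate(self.grid):
                rows.append(
                    {
                        "lambda": lam,
                        "fold": k + 1,
                        "n_snps": int(self.n_snps_matrix[k, j])
                        if self.n_snps_matrix is not None
                        else np.nan,
                        "r2_hat": self.r2_matrix[k, j],
                    }
                )
        return pd.DataFrame(rows)


def _collect(folds_results, grid, lambda_star_from, seed, config):
    grid = np.asarray(sorted(grid), dtype=float)
    r2 = np.array([[r.r2_hat for r in fold] for fold in folds_results])
    nsnp = np.array([[r.n_snps for r in fold] for fold in folds_results])
    by_lam = {lam: r2[:, j].mean() for j, lam in enumerate(grid)}
    lambda_star = select_threshold(by_lam)
    jstar = int(np.flatnonzero(grid == lambda_star)[0])
    n_snps_star = int(np.rint(nsnp[:, jstar].mean()))
    return TuneResult(grid, r2, lambda_star, n_snps_star, seed, config, nsnp)


def _prepare(stats: pd.DataFrame) -> pd.DataFrame:
    score = subsampler.to_score_stats(stats)
    n = stats["n"].to_numpy()
    logger.info(
        "tuning on %d SNPs; per-SNP N min/median/max = %d/%d/%d",
        len(stats), n.min(), int(np.median(n)), n.max(),
    )
    return score


def tune_split(
    stats: pd.DataFrame,
    grid=DEFAULT_GRID,
    valid_frac: float = 0.25,
    seed=None,
    var_y_method: str = "quantile90",
    variance_convention: str = "exact",
) -> TuneResult:
    """Single training/validation split tuning."""
    return tune_repeated(
        stats, grid, K=1, valid_frac=valid_frac, seed=seed,
        var_y_method=var_y_method, variance_convention=variance_convention,
    )


def tune_repeated(
    stats: pd.DataFrame,
    grid=DEFAULT_GRID,
    K: int = 4,
    valid_frac: float = 0.25,
    seed=None,
    var_y_method: str = "quantile90",
    variance_convention: str = "exact",
) -> TuneResult:
    """Repeated learning (Monte Carlo cross-validation) over K subsamples."""
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    grid = sorted(grid)
    score = _prepare(stats)
    n_valid = subsampler.default_n_valid(stats["n"], valid_frac)
    streams = np.random.SeedSequence(seed).spawn(K)
    folds = []
    for k in range(K):
        split = subsampler.subsample_split(
            score, n_valid, streams[k], variance_convention=variance_convention
        )
        folds.append(prs_eval.evaluate_grid(split, split, grid, var_y_method))
    config = {
        "method": "split" if K == 1 else "repeated",
        "K": K, "valid_frac": valid_frac, "n_valid": n_valid,
        "var_y_method": var_y_method, "variance_convention": variance_convention,
        "grid": list(map(float, grid)),
        "n_min": int(stats["n"].min()), "n_median": int(stats["n"].median()),
        "n_max": int(stats["n"].max()),
    }
    return _collect(folds, grid, None, seed, config)


def tune_kfold(
    stats: pd.DataFrame,
    grid=DEFAULT_GRID,
    K: int = 4,
    seed=None,
    var_y_method: str = "quantile90",
    variance_convention: str = "exact",
) -> TuneResult:
    """K-fold cross-validation on one exact partition of the scores.

    The K subsample score vectors sum to the full-sample scores; for each
    rotation the training set pools the other K-1 folds by summing score
    statistics and sample sizes, then recomputes beta/SE analytically.
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    grid = sorted(grid)
    score = _prepare(stats)
    parts = subsampler.kfold_partition(score, K, seed, variance_convention=variance_convention)
    n_full = score["n"].to_numpy(dtype=float)
    s_full = score["s_full"].to_numpy(dtype=float)
    sigma2 = score["sigma2"].to_numpy()
    se_full = score["se_full"].to_numpy()

    folds = []
    for k in range(K):
        s_k = parts[k]["s"].to_numpy(dtype=float)
        n_k = parts[k]["n_k"].to_numpy(dtype=float)
        s_tr = s_full - s_k  # pooled complement, exact by construction
        n_tr = n_full - n_k
        beta_tr, se_tr, p_tr = subsampler._train_summary(s_tr, n_tr, sigma2, se_full, n_full)
        split = pd.DataFrame(
            {
                "snp": score["snp"].to_numpy(),
                "s_train": s_tr,
                "s_valid": s_k,
                "n_train": n_tr.astype(int),
                "n_valid": n_k.astype(int),
                "beta_train": beta_tr,
                "se_train": se_tr,
                "p_train": p_tr,
                "sigma2": sigma2,
            }
        )
        folds.append(prs_eval.evaluate_grid(split, split, grid, var_y_method))
    config = {
        "method": "kfold", "K": K,
        "var_y_method": var_y_method, "variance_convention": variance_convention,
        "grid": list(map(float, grid)),
        "n_min": int(stats["n"].min()), "n_median": int(stats["n"].median()),
        "n_max": int(stats["n"].max()),
    }
    return _collect(folds, grid, None, seed, config)


def selected_model(stats: pd.DataFrame, result: TuneResult) -> pd.DataFrame:
    """Full-sample P+T weights at the selected threshold (snp, allele, weight)."""
    mask = stats["p"].to_numpy(dtype=float) <= result.lambda_star
    out = stats.loc[mask, ["snp", "a1", "beta"]].rename(columns={"a1": "allele", "beta": "weight"})
    return out.reset_index(drop=True)
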