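"""Pruning-and-thresholding PRS weights and summary-level predictive R^2.

A P+T polygenic score keeps SNPs whose training-set p-value passes a
cutoff lambda and weights them by their marginal training-set effect:
Y_hat = X w with w_j = beta_j^(tr) * 1[p_j^(tr) <= lambda].  Its
predictive R^2 on a validation set of n individuals is estimated from
validation score statistics alone:

    R^2_hat = ( (1/n) sum_j w_j S_j^(v) )^2
              ---------------------------------
              Var_hat(Y) * sum_j w_j^2 sigma_j^2

The denominator's Var_hat(Y) uses per-SNP residual-variance proxies
v_j = N_j SE_j^2 sigma_j^2; taking max_j v_j is the simple estimator,
while the 90% quantile of the v_j is more robust to outlier SNPs and is
the default.  Var(Y) only sets the scale of R^2 — it does not move the
argmax over lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .subsampler import snp_variance

logger = logging.getLogger(__name__)

#: default p-value threshold grid, user-overridable
DEFAULT_GRID = (
    5e-8, 1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05,
    0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
)


@dataclass
class PRSModel:
    """SNP weights for one p-value threshold."""

    lam: float
    snps: np.ndarray
    weights: np.ndarray  # zero exactly for excluded SNPs
    included: np.ndarray = field(repr=False)  # boolean mask

    @property
    def n_snps(self) -> int:
        return int(self.included.sum())


@dataclass
class EvalResult:
    lam: float
    r2_hat: float
    n_snps: int
    var_yhat: float
    var_y: float


def pt_weights(train: pd.DataFrame, lam: float) -> PRSModel:
    """P+T weights from training summary statistics.

    ``train`` must carry ``beta_train`` and ``p_train`` (a SplitStats
    frame); SNPs with p_train <= lam get weight beta_train, others 0.
    """
    if not 0.0 < lam <= 1.0:
        raise ValueError(f"p-value threshold must be in (0, 1], got {lam}")
    p = train["p_train"].to_numpy(dtype=float)
    beta = train["beta_train"].to_numpy(dtype=float)
    included = p <= lam
    weights = np.where(included, beta, 0.0)
    return PRSModel(lam, train["snp"].to_numpy(), weights, included)


def _residual_var_proxies(stats: pd.DataFrame) -> np.ndarray:
    """Per-SNP v_j = N_j SE_j^2 sigma_j^2, the marginal residual-variance proxy.

    Works on either full-sample summary statistics (se, n, maf/sigma2) or
    a SplitStats frame (se_train, n_train, sigma2); the product N SE^2 is
    invariant to the subsampling SE rescaling, so both give the same v_j.
    """
    if "se_train" in stats.columns:
        se = stats["se_train"].to_numpy(dtype=float)
        n = stats["n_train"].to_numpy(dtype=float)
    else:
        se = stats["se"].to_numpy(dtype=float)
        n = stats["n"].to_numpy(dtype=float)
    if "sigma2" in stats.columns:
        sigma2 = stats["sigma2"].to_numpy(dtype=float)
    else:
        sigma2 = snp_variance(stats["maf"].to_numpy())
    return n * se**2 * sigma2


def estimate_var_y(stats: pd.DataFrame, method: str = "quantile90") -> float:
    """Estimate the phenotypic variance Var(Y) from summary statistics.

    method='max' is the simple estimator max_j v_j; method='quantile90'
    (default) takes the type-7 90% quantile of the v_j, which is robust
    to a handful of SNPs with inflated standard errors.
    """
    v = _residual_var_proxies(stats)
    if method == "max":
        return float(np.max(v))
    if method == "quantile90":
        return float(np.quantile(v, 0.90))
    raise ValueError(f"unknown Var(Y) method {method!r}")


def summary_r2(model: PRSModel, valid: pd.DataFrame, var_y: float) -> EvalResult:
    """Summary-statistics estimate of the validation predictive R^2.

    ``valid`` is a SplitStats frame aligned with ``model.snps`` carrying
    ``s_valid`` (validation score statistics), ``n_valid`` and ``sigma2``.
    An empty model scores 0 by convention so threshold profiles and the
    argmax stay total.
    """
    if var_y <= 0:
        raise ValueError("var_y must be positive")
    if not np.array_equal(np.asarray(valid["snp"]), model.snps):
        valid = valid.set_index("snp").loc[model.snps].reset_index()
    # n_valid is constant across SNPs for split subsampling; under K-fold
    # partitioning with heterogeneous per-SNP N it can vary slightly, in
    # which case the mean is used as the 1/n normalizer.
    n_valid = float(np.mean(np.asarray(valid["n_valid"], dtype=float)))
    if n_valid <= 0:
        raise ValueError("n_valid must be positive")
    w = model.weights
    var_yhat = float(np.sum(w**2 * valid["sigma2"].to_numpy()))
    if model.n_snps == 0 or var_yhat == 0.0:
        return EvalResult(model.lam, 0.0, model.n_snps, 0.0, var_y)
    num = (np.sum(w * valid["s_valid"].to_numpy()) / n_valid) ** 2
    r2 = float(num / (var_y * var_yhat))
    return EvalResult(model.lam, r2, model.n_snps, var_yhat, var_y)


def select_threshold(results) -> float:
    """Pick the threshold maximizing mean R^2; ties go to the smaller lambda.

    ``results`` may be a sequence of EvalResult (possibly several per
    lambda, across folds) or a mapping lambda -> mean R^2.
    """
    if isinstance(results, dict):
        items = list(results.items())
    else:
        results = list(results)
        if not results:
            raise ValueError("no evaluation results to select from")
        df = pd.DataFrame({"lam": [r.lam for r in results], "r2": [r.r2_hat for r in results]})
        items = list(df.groupby("lam")["r2"].mean().items())
    if not items:
        raise ValueError("no evaluation results to select from")
    items.sort(key=lambda t: t[0])  # ascending lambda: first argmax is sparsest
    top = max(v for _, v in items)
    return float(next(lam for lam, v in items if v == top))


def evaluate_grid(
    train: pd.DataFrame,
    valid: pd.DataFrame,
    grid=DEFAULT_GRID,
    var_y_method: str = "quantile90",
) -> list[EvalResult]:
    """Evaluate the P+T model at every threshold in ``grid``."""
    var_y = estimate_var_y(train, var_y_method)
    return [summary_r2(pt_weights(train, lam), valid, var_y) for lam in sorted(grid)]
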