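"""Reading, harmonization and quality control of GWAS summary statistics.

Summary statistics are held as a pandas DataFrame with canonical columns

    snp, a1, a2, beta, se, p, n, maf

where ``a1`` is the effect allele, ``beta``/``se`` the marginal per-allele
effect estimate and its standard error, ``n`` the per-SNP sample size and
``maf`` the minor allele frequency (possibly NaN until filled from a
reference panel).  Reference allele frequencies use the columns

    snp, a1, a2, freq

with ``freq`` the frequency of ``a1``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: canonical -> default header name in delimited input
DEFAULT_COLUMNS = {
    "snp": "SNP",
    "a1": "A1",
    "a2": "A2",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "n": "N",
    "maf": "MAF",
}

REQUIRED = ("snp", "a1", "a2", "beta", "se", "n")
CANONICAL_ORDER = ["snp", "a1", "a2", "beta", "se", "p", "n", "maf"]

VALID_ALLELES = frozenset("ACGT")
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: smallest p-value kept after clamping exact zeros; downstream only ranks p.
MIN_P = np.nextafter(0.0, 1.0)


class SumStatsError(ValueError):
    """Fatal problem with a summary-statistics input."""


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)
    return 2.0 * sps.norm.sf(np.abs(z))


def read_sumstats(
    path,
    column_map: dict | None = None,
    n_default: int | None = None,
) -> pd.DataFrame:
    """Read a delimited GWAS summary-statistics file.

    Parameters
    ----------
    path
        Tab/whitespace-delimited text file with a header line.
    column_map
        Mapping from canonical names (``snp``, ``a1``, ``a2``, ``beta``,
        ``se``, ``p``, ``n``, ``maf``) to the header names used in the
        file.  Unspecified entries fall back to :data:`DEFAULT_COLUMNS`.
    n_default
        Study-wide sample size to use when the file has no per-SNP N
        column (common for older GWAS that report only the maximum N).

    Returns
    -------
    DataFrame with canonical columns.  ``p`` is filled from ``beta/se``
    under a two-sided normal when absent; rows with ``se <= 0`` or a
    duplicated SNP id are dropped (counts logged).
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)

    raw = pd.read_csv(path, sep=None, engine="python")
    rename = {v: k for k, v in colmap.items() if v in raw.columns}
    df = raw.rename(columns=rename)

    missing = [k for k in REQUIRED if k not in df.columns]
    if "n" in missing and n_default is not None:
        df["n"] = n_default
        missing.remove("n")
    if missing:
        raise SumStatsError(
            f"{path}: missing required column(s) "
            + ", ".join(f"{m} (looked for {colmap[m]!r})" for m in missing)
        )

    for col in ("beta", "se"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce").astype("Int64")
    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()

    if "p" in df.columns:
        df["p"] = pd.to_numeric(df["p"], errors="coerce")
    else:
        df["p"] = np.nan
    fill = df["p"].isna()
    if fill.any():
        df.loc[fill, "p"] = _two_sided_p(df.loc[fill, "beta"], df.loc[fill, "se"])
    zero_p = df["p"] <= 0
    if zero_p.any():
        logger.warning("%d p-values of 0 clamped to %g", int(zero_p.sum()), MIN_P)
        df.loc[zero_p, "p"] = MIN_P

    if "maf" in df.columns:
        df["maf"] = pd.to_numeric(df["maf"], errors="coerce")
    else:
        df["maf"] = np.nan

    bad_se = ~(df["se"] > 0)
    if bad_se.any():
        logger.warning("dropping %d rows with SE <= 0 or missing", int(bad_se.sum()))
        df = df[~bad_se]
    dup = df.duplicated("snp", keep="first")
    if dup.any():
        logger.warning("dropping %d duplicated SNP ids", int(dup.sum()))
        df = df[~dup]
    df = df.dropna(subset=["beta", "n"])

    if len(df) == 0:
        raise SumStatsError(f"{path}: no valid summary-statistics rows")

    _check_p_consistency(df)
    return df[CANONICAL_ORDER].reset_index(drop=True)


def _check_p_consistency(df: pd.DataFrame, rtol: float = 10.0) -> None:
    """Warn when reported p disagrees with beta/se beyond rounding slack."""
    expected = _two_sided_p(df["beta"].to_numpy(), df["se"].to_numpy())
    got = df["p"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.log10(np.maximum(got, MIN_P)) - np.log10(np.maximum(expected, MIN_P))
    off = np.abs(ratio) > np.log10(rtol)
    if off.any():
        logger.warning(
            "%d SNPs have p-values inconsistent with beta/se beyond %gx", int(off.sum()), rtol
        )


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write summary statistics in the canonical tab-delimited dialect."""
    out = df.copy()
    out.columns = [c if c not in DEFAULT_COLUMNS else DEFAULT_COLUMNS[c] for c in out.columns]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_freq(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a PLINK ``.frq``-style allele-frequency table.

    Expects columns SNP, A1, A2 and MAF (or a ``column_map`` pointing at
    equivalents); returns canonical columns ``snp, a1, a2, freq`` with
    ``freq`` the frequency of ``a1``.
    """
    colmap = {"snp": "SNP", "a1": "A1", "a2": "A2", "freq": "MAF"}
    if column_map:
        colmap.update(column_map)
    raw = pd.read_csv(path, sep=None, engine="python")
    missing = [k for k, v in colmap.items() if v not in raw.columns]
    if missing:
        raise SumStatsError(f"{path}: frequency table missing column(s) {missing}")
    df = raw.rename(columns={v: k for k, v in colmap.items()})
    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()
    df["freq"] = pd.to_numeric(df["freq"], errors="coerce")
    df = df.drop_duplicates("snp", keep="first")
    return df[["snp", "a1", "a2", "freq"]].reset_index(drop=True)


def harmonize_alleles(
    stats: pd.DataFrame,
    ref: pd.DataFrame,
    drop_ambiguous: bool = False,
) -> pd.DataFrame:
    """Align summary statistics to a reference panel's allele coding.

    SNPs absent from the reference are removed.  When the effect/other
    alleles are swapped relative to the reference, the effect-size sign is
    flipped and the allele frequency complemented.  Strand-ambiguous pairs
    (A/T, C/G) are removed when ``drop_ambiguous`` is set; residual allele
    mismatches are removed.  Idempotent: output is already reference-coded.
    """
    merged = stats.merge(
        ref[["snp", "a1", "a2", "freq"]].rename(
            columns={"a1": "ref_a1", "a2": "ref_a2", "freq": "ref_freq"}
        ),
        on="snp",
        how="inner",
    )
    n_absent = len(stats) - len(merged)
    if n_absent:
        logger.info("harmonize: %d SNPs absent from reference removed", n_absent)

    same = (merged["a1"] == merged["ref_a1"]) & (merged["a2"] == merged["ref_a2"])
    swapped = (merged["a1"] == merged["ref_a2"]) & (merged["a2"] == merged["ref_a1"])

    ambiguous = pd.Series(
        [(x, y) in AMBIGUOUS_PAIRS for x, y in zip(merged["a1"], merged["a2"])],
        index=merged.index,
    )
    keep = (same | swapped) & ~(drop_ambiguous & ambiguous)
    n_mismatch = int((~(same | swapped)).sum())
    if n_mismatch:
        logger.info("harmonize: %d allele-mismatched SNPs removed", n_mismatch)
    if drop_ambiguous and int((ambiguous & (same | swapped)).sum()):
        logger.info(
            "harmonize: %d strand-ambiguous SNPs removed",
            int((ambiguous & (same | swapped)).sum()),
        )

    out = merged[keep].copy()
    flip = swapped[keep]
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out.loc[flip, ["a1", "a2"]] = out.loc[flip, ["ref_a1", "ref_a2"]].to_numpy()
    # MAF is symmetric under allele complementation; fold back to (0, 0.5]
    f = out["maf"].where(~flip, 1.0 - out["maf"])
    out["maf"] = np.minimum(f, 1.0 - f)
    return out[CANONICAL_ORDER].reset_index(drop=True)


def qc_sample_size(stats: pd.DataFrame, quantile: float = 0.30) -> pd.DataFrame:
    """Remove SNPs whose sample size falls below a quantile of the N distribution.

    GWAS meta-analyses often have heterogeneous per-SNP sample sizes; SNPs
    measured in few cohorts distort subsampling bookkeeping and the R^2
    scale.  The default removes SNPs below the 30% quantile of N, using the
    linear-interpolation (type-7) quantile.
    """
    if not 0.0 <= quantile < 1.0:
        raise SumStatsError(f"quantile must be in [0, 1), got {quantile}")
    if quantile == 0.0:
        return stats
    n = stats["n"].to_numpy(dtype=float)
    cutoff = np.quantile(n, quantile)  # type-7 linear interpolation
    out = stats[stats["n"] >= cutoff].reset_index(drop=True)
    if len(out) == 0:
        raise SumStatsError("sample-size QC removed every SNP")
    logger.info("sample-size QC: %d of %d SNPs retained (N >= %.1f)", len(out), len(stats), cutoff)
    return out


def fill_maf(stats: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Fill missing minor-allele frequencies from a harmonized reference panel.

    SNPs with no frequency in either source are removed.
    """
    merged = stats.merge(ref[["snp", "freq"]], on="snp", how="left")
    ref_maf = np.minimum(merged["freq"], 1.0 - merged["freq"])
    merged["maf"] = merged["maf"].fillna(ref_maf)
    n_dropped = int(merged["maf"].isna().sum())
    if n_dropped:
        logger.info("fill_maf: %d SNPs with no frequency anywhere removed", n_dropped)
    out = merged.dropna(subset=["maf"])
    return out[CANONICAL_ORDER].reset_index(drop=True)
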