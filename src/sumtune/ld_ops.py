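"""Reference-panel genotypes: frequencies and sliding-window LD pruning.

The subsampler treats score statistics as independent across SNPs, which
is defensible only after linkage-disequilibrium pruning.  This module
computes allele frequencies from a genotype panel and enforces a pairwise
r^2 ceiling with a greedy sliding-window prune (window 100 variants, step
5, r^2 <= 0.1 by default).  Clumping is deliberately not provided: keeping
the most significant SNP per region uses full-sample p-values and leaks
information into the tuning procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Additive-dosage genotypes: samples x variants, values in {0, 1, 2}.

    ``dosages[i, j]`` counts copies of allele ``a1[j]`` carried by sample
    ``i``.  Missing genotypes are NaN until mean-imputed.
    """

    dosages: np.ndarray
    snps: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    chrom: np.ndarray = None
    pos: np.ndarray = None
    samples: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snps = np.asarray(self.snps)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snps):
            raise ValueError("dosage matrix must be samples x variants")
        if len(np.unique(self.snps)) != len(self.snps):
            raise ValueError("variant ids must be unique")
        if self.chrom is None:
            self.chrom = np.ones(len(self.snps), dtype=int)
        if self.pos is None:
            self.pos = np.arange(1, len(self.snps) + 1)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset(self, snp_ids) -> "GenotypeMatrix":
        idx = pd.Index(self.snps).get_indexer(snp_ids)
        if (idx < 0).any():
            raise KeyError("unknown variant id in subset request")
        return GenotypeMatrix(
            self.dosages[:, idx], self.snps[idx], np.asarray(self.a1)[idx],
            np.asarray(self.a2)[idx], np.asarray(self.chrom)[idx],
            np.asarray(self.pos)[idx], self.samples,
        )


def compute_freqs(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant frequency of allele ``a1`` (mean dosage / 2).

    Returns the canonical frequency-table columns ``snp, a1, a2, freq``
    plus a ``monomorphic`` flag for variants fixed at 0 or 1.
    """
    if geno.n_variants == 0:
        raise ValueError("empty genotype matrix")
    freq = np.nanmean(geno.dosages, axis=0) / 2.0
    mono = (freq == 0.0) | (freq == 1.0)
    if mono.any():
        logger.warning("%d monomorphic variants flagged", int(mono.sum()))
    return pd.DataFrame(
        {"snp": geno.snps, "a1": geno.a1, "a2": geno.a2, "freq": freq, "monomorphic": mono}
    )


def _impute_standardize(x: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per variant, then center and unit-scale."""
    x = np.array(x, dtype=float)
    mean = np.nanmean(x, axis=0)
    nanmask = np.isnan(x)
    if nanmask.any():
        x[nanmask] = np.broadcast_to(mean, x.shape)[nanmask]
    x -= mean
    sd = x.std(axis=0)
    sd[sd == 0] = np.inf  # monomorphic -> zero column, r^2 = 0 with everything
    return x / sd


def greedy_prune(
    geno: GenotypeMatrix,
    window: int = 100,
    step: int = 5,
    r2_max: float = 0.1,
    pvalues: pd.Series | dict | None = None,
) -> list:
    """Greedy sliding-window LD pruning.

    Variants are walked in (chromosome, position) order.  Inside each
    window of ``window`` variants, pairs with squared Pearson correlation
    above ``r2_max`` are resolved by removing one member — the one with
    the larger GWAS p-value when ``pvalues`` is supplied, otherwise the
    later variant in order — until every kept pair satisfies the ceiling.
    The window then advances by ``step``.  Deterministic given its inputs.

    Returns the kept variant ids in input order.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")

    order = np.lexsort((np.asarray(geno.pos), np.asarray(geno.chrom)))
    z = _impute_standardize(geno.dosages)
    n = geno.n_samples
    m = geno.n_variants

    pv = None
    if pvalues is not None:
        pv = pd.Series(pvalues).reindex(geno.snps).to_numpy(dtype=float)

    kept = np.ones(m, dtype=bool)
    chroms = np.asarray(geno.chrom)[order]
    for start in range(0, m, step):
        stop = min(start + window, m)
        widx = order[start:stop]
        widx = widx[chroms[start:stop] == chroms[start]]  # windows never span chromosomes
        widx = widx[kept[widx]]
        if len(widx) < 2:
            if stop >= m:
                break
            continue
        r2 = (z[:, widx].T @ z[:, widx] / n) ** 2
        np.fill_diagonal(r2, 0.0)
        local = np.ones(len(widx), dtype=bool)
        while True:
            sub = r2[np.ix_(local, local)]
            if sub.size == 0 or sub.max() <= r2_max:
                break
            ii, jj = np.unravel_index(np.argmax(sub), sub.shape)
            live = np.flatnonzero(local)
            a, b = live[ii], live[jj]
            first, second = (a, b) if a < b else (b, a)
            if pv is not None and not np.isnan(pv[widx[[first, second]]]).any():
                drop = first if pv[widx[first]] > pv[widx[second]] else second
            else:
                drop = second
            local[drop] = False
        kept[widx[~local]] = False
        if stop >= m:
            break

    kept_ids = list(np.asarray(geno.snps)[kept])
    logger.info("pruning kept %d of %d variants (r2 <= %g)", int(kept.sum()), m, r2_max)
    return kept_ids


# ---------------------------------------------------------------------------
# PLINK-text and dosage-table I/O
# ---------------------------------------------------------------------------

def read_plink_text(prefix: str) -> GenotypeMatrix:
    """Read PLINK-text genotypes from ``prefix.ped`` / ``prefix.map``.

    Dosages count the minor allele (ties broken alphabetically); '0'
    alleles are treated as missing.
    """
    mapdf = pd.read_csv(
        f"{prefix}.map", sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos"],
    )
    m = len(mapdf)
    samples, rows = [], []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix}.ped: expected {6 + 2 * m} fields per line, got {len(parts)}"
                )
            samples.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype="U1").reshape(len(rows), m, 2)

    a1 = np.empty(m, dtype="U1")
    a2 = np.empty(m, dtype="U1")
    dos = np.full((len(rows), m), np.nan)
    for j in range(m):
        col = alleles[:, j, :]
        obs = col[col != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) == 0:
            a1[j], a2[j] = "0", "0"
            continue
        order = np.lexsort((uniq, counts))  # rarest first, alphabetical on ties
        a1[j] = uniq[order[0]]
        a2[j] = uniq[order[-1]] if len(uniq) > 1 else uniq[order[0]]
        missing = (col == "0").any(axis=1)
        dos[:, j] = (col == a1[j]).sum(axis=1)
        dos[missing, j] = np.nan
    return GenotypeMatrix(
        dos, mapdf["snp"].to_numpy(), a1, a2,
        mapdf["chrom"].to_numpy(), mapdf["pos"].to_numpy(), np.asarray(samples),
    )


def write_plink_text(geno: GenotypeMatrix, prefix: str, phenotype=None) -> None:
    """Write genotypes as PLINK-text ``prefix.ped`` / ``prefix.map``."""
    mapdf = pd.DataFrame(
        {"chrom": geno.chrom, "snp": geno.snps, "cm": 0, "pos": geno.pos}
    )
    mapdf.to_csv(f"{prefix}.map", sep="\t", header=False, index=False)
    n = geno.n_samples
    pheno = np.full(n, -9.0) if phenotype is None else np.asarray(phenotype)
    ids = geno.samples if geno.samples is not None else [f"S{i + 1}" for i in range(n)]
    with open(f"{prefix}.ped", "w") as fh:
        for i in range(n):
            pairs = []
            for j in range(geno.n_variants):
                d = geno.dosages[i, j]
                if np.isnan(d):
                    pairs += ["0", "0"]
                else:
                    d = int(round(d))
                    pairs += [geno.a1[j]] * d + [geno.a2[j]] * (2 - d)
            fh.write(" ".join([str(ids[i]), str(ids[i]), "0", "0", "0", str(pheno[i])] + pairs))
            fh.write("\n")


def read_dosage_table(path) -> GenotypeMatrix:
    """Read a transposed dosage table: one row per variant.

    Columns: ``snp, a1, a2, chrom, pos`` followed by one numeric dosage
    column per sample.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    meta = ["snp", "a1", "a2", "chrom", "pos"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: dosage table missing column(s) {missing}")
    sample_cols = [c for c in df.columns if c not in meta]
    dos = df[sample_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(
        dos, df["snp"].to_numpy(), df["a1"].to_numpy(dtype=str),
        df["a2"].to_numpy(dtype=str), df["chrom"].to_numpy(), df["pos"].to_numpy(),
        np.asarray(sample_cols),
    )
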