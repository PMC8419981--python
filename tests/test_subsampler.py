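import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

import sumtune
from sumtune.subsampler import SubsampleError, _train_summary


class TestSnpVariance:
    @pytest.mark.parametrize("maf, expected", [(0.5, 0.5), (0.25, 0.375), (0.1, 0.18)])
    def test_hwe_values(self, maf, expected):
        assert sumtune.snp_variance(maf) == pytest.approx(expected)

    def test_monotone_increasing_and_limit(self):
        mafs = np.linspace(0.001, 0.5, 50)
        v = sumtune.snp_variance(mafs)
        assert np.all(np.diff(v) > 0)
        assert v[0] < 0.01

    def test_out_of_range_fatal(self):
        for bad in (0.0, -0.1, 0.6):
            with pytest.raises(SubsampleError):
                sumtune.snp_variance(bad)


class TestToScoreStats:
    def test_closed_form_values(self, toy_sumstats):
        stats = toy_sumstats.copy()
        stats.loc[0, ["beta", "maf", "n", "se"]] = [0.2, 0.25, 1000, 0.05]
        score = sumtune.to_score_stats(stats)
        assert score.loc[0, "s_full"] == pytest.approx(0.2 * 0.375 * 1000)  # 75.0
        assert score.loc[0, "var_s"] == pytest.approx(1000 * (0.05 * 0.375) ** 2)  # 0.3515625

    def test_zero_beta_gives_zero_score(self, toy_sumstats):
        stats = toy_sumstats.assign(beta=0.0)
        assert (sumtune.to_score_stats(stats)["s_full"] == 0).all()

    def test_requires_maf(self, toy_sumstats):
        stats = toy_sumstats.copy()
        stats.loc[0, "maf"] = np.nan
        with pytest.raises(SubsampleError, match="MAF"):
            sumtune.to_score_stats(stats)


class TestCovOffdiag:
    def test_values_and_symmetry(self, toy_sumstats):
        a = toy_sumstats.iloc[0].copy()
        b = toy_sumstats.iloc[1].copy()
        a["beta"], a["maf"] = 0.1, 0.5
        b["beta"], b["maf"] = 0.1, 0.5
        assert sumtune.cov_offdiag(a, b) == pytest.approx(0.01 * 0.25)  # 0.0025
        assert sumtune.cov_offdiag(a, b) == sumtune.cov_offdiag(b, a)
        a["beta"] = 0.0
        assert sumtune.cov_offdiag(a, b) == 0.0


class TestSubsampleSplit:
    def test_degenerate_n_valid_zero(self, toy_sumstats):
        score = sumtune.to_score_stats(toy_sumstats)
        split = sumtune.subsample_split(score, 0, rng_seed=1)
        np.testing.assert_array_equal(split["s_train"], score["s_full"])
        assert (split["s_valid"] == 0).all()

    def test_se_scaling_exact(self, toy_sumstats):
        stats = toy_sumstats.assign(n=100, se=0.1)
        score = sumtune.to_score_stats(stats)
        split = sumtune.subsample_split(score, 25, rng_seed=2)
        assert np.allclose(split["se_train"], 0.1 * np.sqrt(100 / 75))
        assert split["se_train"].iloc[0] == pytest.approx(0.115470, abs=1e-6)

    def test_n_valid_too_large_fatal(self, toy_sumstats):
        score = sumtune.to_score_stats(toy_sumstats)
        with pytest.raises(SubsampleError, match="rs"):
            sumtune.subsample_split(score, int(score["n"].min()), rng_seed=3)

    def test_heterogeneous_n_bookkeeping(self, toy_sumstats):
        score = sumtune.to_score_stats(toy_sumstats)
        n_valid = sumtune.default_n_valid(toy_sumstats["n"])  # 25% of min N
        split = sumtune.subsample_split(score, n_valid, rng_seed=4)
        assert (split["n_valid"] == n_valid).all()  # constant across SNPs
        assert (split["n_train"] + split["n_valid"] == score["n"]).all()
        assert split["n_train"].nunique() > 1  # training sizes vary with N_j

    def test_monte_carlo_moments(self, toy_sumstats):
        stats = toy_sumstats.iloc[[0]].assign(n=1000, beta=0.2, se=0.05, maf=0.25)
        score = sumtune.to_score_stats(stats)
        n_valid = 250
        draws = np.array(
            [
                sumtune.subsample_split(score, n_valid, rng_seed=s)["s_train"].iloc[0]
                for s in range(10_000)
            ]
        )
        s_full = score["s_full"].iloc[0]
        var_s = score["var_s"].iloc[0]
        exp_mean = 0.75 * s_full
        exp_var = n_valid * 750 / 1000 * var_s
        mc_se = np.sqrt(exp_var / len(draws))
        assert abs(draws.mean() - exp_mean) < 4 * mc_se
        assert abs(draws.var() / exp_var - 1) < 0.10

    @settings(deadline=None, max_examples=30, derandomize=True,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(seed=st.integers(0, 2**31 - 1), n_valid=st.integers(1, 900))
    def test_conservation_exact_complement(self, toy_sumstats, seed, n_valid):
        score = sumtune.to_score_stats(toy_sumstats)
        split = sumtune.subsample_split(score, n_valid, rng_seed=seed)
        s_full = score["s_full"].to_numpy()
        s_tr = split["s_train"].to_numpy()
        s_va = split["s_valid"].to_numpy()
        # the complement is exact by construction ...
        assert np.array_equal(s_va, s_full - s_tr)
        # ... and additive reconstruction is exact to one ulp of the summands
        tol = np.spacing(np.maximum(np.abs(s_tr), np.abs(s_va)))
        assert np.all(np.abs((s_tr + s_va) - s_full) <= tol)

    def test_literal_variance_convention_differs(self, toy_sumstats):
        score = sumtune.to_score_stats(toy_sumstats)
        a = sumtune.subsample_split(score, 250, rng_seed=5, variance_convention="exact")
        b = sumtune.subsample_split(score, 250, rng_seed=5, variance_convention="literal")
        assert not np.allclose(a["s_train"], b["s_train"])


class TestKfoldPartition:
    def test_conservation_and_sizes(self, toy_sumstats):
        score = sumtune.to_score_stats(toy_sumstats)
        folds = sumtune.kfold_partition(score, K=4, rng_seed=6)
        s_full = score["s_full"].to_numpy()
        partial = sum(f["s"].to_numpy() for f in folds[:-1])
        # last fold is the exact complement of the accumulated draws
        assert np.array_equal(folds[-1]["s"].to_numpy(), s_full - partial)
        total = sum(f["s"].to_numpy() for f in folds)
        tol = 4 * np.spacing(np.max(np.abs([f["s"].to_numpy() for f in folds]), axis=0))
        assert np.all(np.abs(total - s_full) <= tol)
        n_total = sum(f["n_k"].to_numpy() for f in folds)
        np.testing.assert_array_equal(n_total, score["n"].to_numpy())

    def test_k_below_two_fatal(self, toy_sumstats):
        score = sumtune.to_score_stats(toy_sumstats)
        with pytest.raises(SubsampleError):
            sumtune.kfold_partition(score, K=1, rng_seed=7)

    def test_fold_means_approach_equal_share(self, toy_sumstats):
        stats = toy_sumstats.iloc[[0]].assign(n=1000, beta=0.2, se=0.05, maf=0.25)
        score = sumtune.to_score_stats(stats)
        s_full = score["s_full"].iloc[0]
        draws = np.array(
            [
                [f["s"].iloc[0] for f in sumtune.kfold_partition(score, 4, rng_seed=s)]
                for s in range(10_000)
            ]
        )
        sd = np.sqrt(250 * 750 / 1000 * score["var_s"].iloc[0] / len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - s_full / 4) < 4 * sd)

    def test_k2_matches_split_distribution(self, toy_sumstats):
        """K=2 partitioning is distributionally the n_valid = N - round(N/2) split."""
        stats = toy_sumstats.assign(n=1000)
        score = sumtune.to_score_stats(stats)
        kf = np.array(
            [sumtune.kfold_partition(score, 2, rng_seed=s)[0]["s"].iloc[0] for s in range(4000)]
        )
        sp = np.array(
            [
                sumtune.subsample_split(score, 500, rng_seed=s)["s_train"].iloc[0]
                for s in range(4000)
            ]
        )
        assert abs(kf.mean() - sp.mean()) < 4 * sp.std() / np.sqrt(4000) * np.sqrt(2)
        assert abs(kf.var() / sp.var() - 1) < 0.15


class TestOracleCalibration:
    def test_beta_train_matches_individual_level_subsampling(self):
        """Per-SNP moments of subsampled beta match literal re-regression on
        random training subsets of the simulated individuals."""
        cfg = sumtune.SimConfig(n_samples=2000, n_snps=30, h2=0.4, p_causal=0.5, seed=77)
        data = sumtune.simulate_dataset(cfg)
        stats = sumtune.marginal_gwas(data)
        score = sumtune.to_score_stats(stats)
        n = cfg.n_samples
        n_valid = n // 4
        reps = 400

        summ = np.array(
            [
                sumtune.subsample_split(score, n_valid, rng_seed=(900, r))["beta_train"]
                for r in range(reps)
            ]
        )

        rng = np.random.default_rng(901)
        x = data.genotypes.dosages
        y = np.asarray(data.phenotype)
        orc = np.empty((reps, len(stats)))
        for r in range(reps):
            idx = rng.choice(n, size=n - n_valid, replace=False)
            xc = x[idx] - x[idx].mean(axis=0)
            yc = y[idx] - y[idx].mean()
            orc[r] = (xc.T @ yc) / np.einsum("ij,ij->j", xc, xc)

        # two-sample moment checks at alpha = 0.01 must pass for >= 95% of SNPs
        from scipy import stats as sps

        mean_ok = 0
        var_ok = 0
        for j in range(len(stats)):
            z = (summ[:, j].mean() - orc[:, j].mean()) / np.sqrt(
                summ[:, j].var() / reps + orc[:, j].var() / reps
            )
            mean_ok += abs(z) < sps.norm.ppf(0.995)
            f = summ[:, j].var() / orc[:, j].var()
            lo, hi = sps.f.ppf([0.005, 0.995], reps - 1, reps - 1)
            var_ok += lo < f < hi
        assert mean_ok >= 0.95 * len(stats)
        assert var_ok >= 0.95 * len(stats)


class TestHelpers:
    def test_default_n_valid_quarter_of_min(self):
        assert sumtune.default_n_valid(np.array([15567, 20000])) == 3892

    def test_split_sizes_four_fold_design(self):
        assert sumtune.split_sizes(15567, 0.25) == (11675, 3892)
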