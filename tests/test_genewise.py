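"""Moderated paired/spline tests, variance squeezing, BH-FDR, overlaps."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special, stats

import prediagtx as px
from prediagtx.genewise import (
    PairedDifferenceModel,
    SplineTrendModel,
    bh_fdr,
    cumulative_by_year,
    natural_spline_basis,
    squeeze_variances,
    top_n_overlap,
)


def _heteroscedastic_D(seed=42, n_genes=50, n_pairs=8, mean=0.0):
    rng = np.random.default_rng(seed)
    sd = rng.gamma(3, 0.2, size=(n_genes, 1)) ** 0.5
    Y = rng.normal(mean, sd, size=(n_genes, n_pairs))
    return pd.DataFrame(Y, index=[f"g{i}" for i in range(n_genes)])


# ---------------------------------------------------------------------------
# BH step-up


def _bh_oracle(p):
    """Brute-force step-up: q_i = min over j with p_(j) >= p_(i) of
    min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 100), min_size=1, max_size=8))
    def test_matches_brute_force_oracle_on_grid(self, grid):
        p = np.array(grid) / 100.0
        np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=30)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


# ---------------------------------------------------------------------------
# variance squeezing and the moderated t


def _squeeze_oracle(Y):
    """Step-by-step recomputation of the moment-matching squeeze and
    moderated t for an intercept-only paired design (scalar loops)."""
    G, n = Y.shape
    d = n - 1
    means = np.array([Y[g].mean() for g in range(G)])
    s2 = np.array([Y[g].var(ddof=1) for g in range(G)])
    e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
    emean = e.mean()
    evar = ((e - emean) ** 2).sum() / (G - 1)
    rhs = evar - special.polygamma(1, d / 2)
    if rhs > 0:
        x = optimize.brentq(lambda v: special.polygamma(1, v) - rhs, 1e-8, 1e8, xtol=1e-13)
        d0 = 2 * x
        s0 = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
    else:
        d0, s0 = np.inf, np.exp(emean)
    if np.isinf(d0):
        s2_post = np.full(G, s0)
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
    t = means / np.sqrt(s2_post / n)
    p = 2 * stats.t.sf(np.abs(t), d0 + d)
    return d0, s0, t, p


class TestModeratedT:
    def test_matches_stepwise_oracle(self):
        D = _heteroscedastic_D()
        res = PairedDifferenceModel(D).fit()
        d0, s0, t, p = _squeeze_oracle(D.to_numpy())
        assert res.prior_df == pytest.approx(d0, abs=1e-10)
        assert res.prior_var == pytest.approx(s0, abs=1e-10)
        np.testing.assert_allclose(res.table["t"], t, atol=1e-10)
        np.testing.assert_allclose(res.table["p_value"], p, atol=1e-10)
        np.testing.assert_allclose(res.table["q_value"], _bh_oracle(p), atol=1e-10)

    def test_matches_limma_reference(self, tmp_path):
        """Independent cross-check against the R limma implementation of
        variance shrinkage on a small fixture."""
        D = _heteroscedastic_D(seed=7, n_genes=40, n_pairs=6)
        y_path = tmp_path / "Y.tsv"
        out_path = tmp_path / "limma.tsv"
        D.to_csv(y_path, sep="\t")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            Y <- as.matrix(read.delim("{y_path}", row.names=1))
            fit <- lmFit(Y, design=matrix(1, ncol(Y), 1))
            eb <- eBayes(fit)
            out <- data.frame(t=eb$t[,1], p=eb$p.value[,1],
                              d0=eb$df.prior, s0=eb$s2.prior)
            write.table(out, "{out_path}", sep="\\t", quote=FALSE)
            """
        )
        r_file = tmp_path / "check.R"
        r_file.write_text(script)
        subprocess.run(["Rscript", str(r_file)], check=True, capture_output=True)
        ref = pd.read_csv(out_path, sep="\t")
        res = PairedDifferenceModel(D).fit()
        assert res.prior_df == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert res.prior_var == pytest.approx(ref["s0"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(res.table["t"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(res.table["p_value"], ref["p"], atol=1e-8)

    def test_prior_df_zero_is_ordinary_t(self):
        D = _heteroscedastic_D(seed=3)
        res = PairedDifferenceModel(D).fit(prior_df=0.0, prior_var=1.0)
        Y = D.to_numpy()
        n = Y.shape[1]
        t_ref = Y.mean(axis=1) / (Y.std(axis=1, ddof=1) / np.sqrt(n))
        np.testing.assert_allclose(res.table["t"], t_ref, atol=1e-10)

    def test_prior_df_infinite_pools_variance(self):
        D = _heteroscedastic_D(seed=4)
        res = PairedDifferenceModel(D).fit(prior_df=np.inf, prior_var=0.5)
        Y = D.to_numpy()
        n = Y.shape[1]
        t_ref = Y.mean(axis=1) / np.sqrt(0.5 / n)
        np.testing.assert_allclose(res.table["t"], t_ref, atol=1e-10)

    def test_t_monotone_in_mean_for_fixed_variance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        base -= base.mean()
        base /= base.std(ddof=1)
        shifts = [0.1, 0.4, 0.9, 1.5]
        Y = np.array([base + s for s in shifts])
        res = PairedDifferenceModel(pd.DataFrame(Y)).fit(prior_df=0.0, prior_var=1.0)
        assert (np.diff(res.table["t"]) > 0).all()

    def test_constant_covariate_dropped_with_warning(self):
        D = _heteroscedastic_D(seed=5, n_pairs=6)
        with pytest.warns(UserWarning, match="constant covariate"):
            model = PairedDifferenceModel(D, covariate=np.ones(6))
        assert model.X.shape[1] == 1

    def test_null_type_one_error_calibrated(self):
        """Rejection rate at nominal 0.05 on null data is inside the
        binomial band (500 replicates x 200 genes x 30 pairs)."""
        rng = np.random.default_rng(99)
        hits = total = 0
        for _ in range(500):
            Y = rng.normal(0, rng.gamma(3, 0.2, size=(200, 1)) ** 0.5, size=(200, 30))
            res = PairedDifferenceModel(pd.DataFrame(Y)).fit()
            hits += (res.table["p_value"] < 0.05).sum()
            total += 200
        rate = hits / total
        assert abs(rate - 0.05) < 0.01, rate


# ---------------------------------------------------------------------------
# spline trend tests


class TestNaturalSplineBasis:
    def test_dimension_and_linearity_beyond_boundaries(self):
        x = np.linspace(0, 10, 50)
        N = natural_spline_basis(x, df=3)
        assert N.shape == (50, 3)
        # second differences vanish outside the boundary knots
        xx = np.concatenate([np.linspace(-5, -1, 20), np.linspace(11, 15, 20)])
        NN = natural_spline_basis(
            xx, df=3, boundary_knots=(0.0, 10.0), interior_knots=np.quantile(x, [1 / 3, 2 / 3])
        )
        for col in range(3):
            left = NN[:20, col]
            right = NN[20:, col]
            assert np.allclose(np.diff(left, 2), 0, atol=1e-8)
            assert np.allclose(np.diff(right, 2), 0, atol=1e-8)

    def test_duplicate_knots_warn(self):
        x = np.array([1.0, 1.0, 1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="duplicate knots"):
            natural_spline_basis(x, df=3)


class TestSplineTrend:
    def test_null_p_uniformish(self):
        rng = np.random.default_rng(21)
        days = rng.uniform(75, 2630, size=40)
        pvals = []
        for _ in range(500):
            Y = rng.normal(0, 0.4, size=(40, 40))
            res = SplineTrendModel(pd.DataFrame(Y), days).fit()
            pvals.append(res.table["p_value"].to_numpy())
        rate = (np.concatenate(pvals) < 0.05).mean()
        assert abs(rate - 0.05) < 0.015, rate

    def test_pure_offset_not_detected(self):
        """A constant case-control offset with no time shape is absorbed
        by the intercept: rejection stays at the nominal rate."""
        rng = np.random.default_rng(22)
        days = rng.uniform(75, 2630, size=40)
        pvals = []
        for _ in range(200):
            Y = 0.8 + rng.normal(0, 0.4, size=(30, 40))
            res = SplineTrendModel(pd.DataFrame(Y), days).fit()
            pvals.append(res.table["p_value"].to_numpy())
        rate = (np.concatenate(pvals) < 0.05).mean()
        assert abs(rate - 0.05) < 0.03, rate

    def test_half_cosine_trend_ranked_high(self):
        """Planted smooth trajectories (R^2 ~ 0.1) land in the top decile
        by median rank."""
        rng = np.random.default_rng(23)
        n_pairs, n_genes, n_planted = 100, 300, 30
        days = rng.uniform(75, 2630, size=n_pairs)
        sigma = 0.42
        amplitude = sigma / 3 * np.sqrt(2)  # signal variance ~ sigma^2 / 9
        signal = amplitude * np.cos(np.pi * days / days.max())
        Y = rng.normal(0, sigma, size=(n_genes, n_pairs))
        Y[:n_planted] += signal
        res = SplineTrendModel(pd.DataFrame(Y, index=[f"g{i}" for i in range(n_genes)]), days).fit()
        ranks = res.table.iloc[:n_planted]["rank"]
        assert ranks.median() <= n_genes / 10

    def test_constant_gene_reports_p_one(self):
        rng = np.random.default_rng(24)
        days = rng.uniform(75, 2630, size=20)
        Y = rng.normal(size=(10, 20))
        Y[0] = 1.5
        res = SplineTrendModel(pd.DataFrame(Y), days).fit()
        assert res.table.iloc[0]["p_value"] == 1.0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least"):
            SplineTrendModel(pd.DataFrame(np.zeros((5, 4))), np.arange(4.0) + 1)


# ---------------------------------------------------------------------------
# cumulative-by-year and top-N overlap


class TestCumulativeByYear:
    def test_null_has_no_significant_genes(self):
        rng = np.random.default_rng(31)
        days = rng.uniform(75, 2630, size=100)
        Y = pd.DataFrame(rng.normal(0, 0.4, size=(300, 100)))
        table = cumulative_by_year(Y, days)
        # BH at 0.05 controls the FDR, so essentially zero discoveries are
        # expected; tolerate a stray chance hit across the eight slices
        assert table.loc[table["run"], "n_fdr_0.05"].sum() <= 2

    def test_cumulated_n_is_running_count(self):
        rng = np.random.default_rng(32)
        days = rng.uniform(75, 2630, size=60)
        Y = pd.DataFrame(rng.normal(size=(20, 60)))
        table = cumulative_by_year(Y, days)
        expected = [(days <= y * 365.25).sum() for y in range(1, 9)]
        assert list(table["n_cumulated"]) == expected
        assert (np.diff(table["n_cumulated"]) >= 0).all()

    def test_small_slices_marked_not_run(self):
        days = np.full(10, 2000.0)
        Y = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 10)))
        table = cumulative_by_year(Y, days)
        assert not table.loc[1, "run"]
        assert np.isnan(table.loc[1, "n_fdr_0.05"])

    def test_early_divergence_peaks_then_dilutes(self):
        """Genes perturbed only in pairs sampled < 2 years before
        diagnosis: the significant count peaks at the 2-year slice and
        shrinks as unperturbed pairs accumulate."""
        rng = np.random.default_rng(33)
        n_pairs, n_genes = 100, 300
        days = rng.uniform(75, 2630, size=n_pairs)
        Y = rng.normal(0, 0.42, size=(n_genes, n_pairs))
        Y[:40, days < 730] += 0.45
        table = cumulative_by_year(pd.DataFrame(Y), days)
        counts = table["n_fdr_0.05"]
        assert counts.idxmax() == 2
        assert counts.loc[2] > 0
        assert counts.loc[8] < counts.loc[2]


class TestTopNOverlap:
    def _results(self, seed, n_genes=200):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=n_genes)
        table = pd.DataFrame({"p_value": p}, index=[f"g{i}" for i in range(n_genes)])
        return table

    def test_identical_results_full_overlap(self):
        a = self._results(1)
        mat = top_n_overlap({"x": a, "y": a.copy()}, n=50)
        assert mat.loc["x", "y"] == 50

    def test_independent_rankings_near_hypergeometric_mean(self):
        overlaps = [
            top_n_overlap({"x": self._results(2 * s), "y": self._results(2 * s + 1)}, n=50).loc["x", "y"]
            for s in range(100)
        ]
        # E[overlap] = 50 * 50 / 200 = 12.5 under independence
        assert abs(np.mean(overlaps) - 12.5) < 1.5

    def test_n_zero(self):
        mat = top_n_overlap({"x": self._results(5), "y": self._results(6)}, n=0)
        assert (mat.to_numpy() == 0).all()

    def test_n_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            mat = top_n_overlap({"x": self._results(7), "y": self._results(7)}, n=500)
        assert mat.loc["x", "y"] == 200

    def test_requires_two_sets(self):
        with pytest.raises(ValueError, match="two result"):
            top_n_overlap({"x": self._results(8)})
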