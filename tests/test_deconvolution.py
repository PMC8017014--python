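"""Deconvolution, population filtering, NLR and the group comparisons."""

import numpy as np
import pandas as pd
import pytest

import prediagtx as px
from prediagtx.deconvolution import CellFractions, fraction_time_trend, group_tests


def _signature(rng, n_markers=200, n_types=6):
    names = [f"T{t}" for t in range(n_types)]
    S = rng.lognormal(3, 1, size=(n_markers, n_types))
    per = n_markers // n_types
    for t in range(n_types):
        S[t * per : (t + 1) * per, t] *= 8
    return pd.DataFrame(S, index=[f"g{i}" for i in range(n_markers)], columns=names)


class TestDeconvolve:
    def test_exact_linear_recovery(self, rng):
        sig = _signature(rng, n_markers=60, n_types=3)
        f = np.array([0.6, 0.3, 0.1])
        mix = pd.DataFrame({"s0": sig.to_numpy() @ f}, index=sig.index)
        fracs = px.DeconvolutionModel(mix, sig).fit()
        np.testing.assert_allclose(fracs.fractions.loc["s0"], f, atol=1e-8)

    def test_noisy_recovery_rmse(self, rng):
        """Dirichlet mixtures, 5% multiplicative noise, 200 markers,
        6 types, 50 samples: per-type RMSE below 0.05."""
        sig = _signature(rng)
        truth = rng.dirichlet(np.full(6, 2.0), size=50)
        clean = sig.to_numpy() @ truth.T
        noisy = clean + rng.normal(0, 0.05 * clean)
        mix = pd.DataFrame(np.clip(noisy, 0, None), index=sig.index,
                           columns=[f"s{i}" for i in range(50)])
        fracs = px.DeconvolutionModel(mix, sig).fit()
        rmse = np.sqrt(((fracs.fractions.to_numpy() - truth) ** 2).mean(axis=0))
        assert (rmse < 0.05).all(), rmse

    def test_pure_column_gives_unit_vector(self, rng):
        sig = _signature(rng, n_markers=40, n_types=4)
        mix = pd.DataFrame({"s0": sig.iloc[:, 2]}, index=sig.index)
        fracs = px.DeconvolutionModel(mix, sig).fit()
        np.testing.assert_allclose(fracs.fractions.loc["s0"], [0, 0, 1, 0], atol=1e-8)

    def test_fractions_sum_to_one(self, rng):
        sig = _signature(rng, n_markers=60, n_types=5)
        mix = pd.DataFrame(rng.lognormal(4, 1, size=(60, 8)), index=sig.index)
        fracs = px.DeconvolutionModel(mix, sig).fit()
        np.testing.assert_allclose(fracs.fractions.sum(axis=1), 1.0, atol=1e-8)

    def test_too_few_shared_genes(self, rng):
        sig = _signature(rng, n_markers=60, n_types=6)
        mix = pd.DataFrame(rng.lognormal(size=(3, 2)), index=["g0", "g1", "g2"])
        with pytest.raises(ValueError, match="shared"):
            px.DeconvolutionModel(mix, sig)

    def test_single_cell_type_rejected(self, rng):
        sig = _signature(rng, n_markers=10, n_types=2).iloc[:, :1]
        mix = pd.DataFrame(rng.lognormal(size=(10, 1)), index=sig.index)
        with pytest.raises(ValueError, match="2 cell types"):
            px.DeconvolutionModel(mix, sig)


class TestFilterAndNLR:
    def _fracs(self):
        table = pd.DataFrame(
            {
                "Neutrophils": [0.30, 0.40],
                "T cells CD8": [0.30, 0.20],
                "B cells": [0.20, 0.30],
                "Rare": [0.06, 0.04],  # mean exactly 0.05
                "Monocytes": [0.14, 0.06],
            },
            index=["s0", "s1"],
        )
        return CellFractions(table)

    def test_strict_mean_threshold(self):
        kept = px.filter_populations(self._fracs(), min_mean=0.05)
        assert "Rare" not in kept.cell_types  # mean exactly 0.05 -> dropped
        assert "Monocytes" in kept.cell_types  # mean 0.10 -> kept

    def test_min_mean_zero_keeps_all(self):
        kept = px.filter_populations(self._fracs(), min_mean=0.0)
        assert kept.cell_types == self._fracs().cell_types

    def test_nlr_values(self):
        fracs = self._fracs()
        ratio = px.nlr(fracs)
        # lymphocytes = T cells CD8 + B cells
        assert ratio["s0"] == pytest.approx(0.30 / 0.50)
        assert ratio["s1"] == pytest.approx(0.40 / 0.50)

    def test_nlr_zero_neutrophils(self):
        table = pd.DataFrame({"Neutrophils": [0.0], "T cells CD8": [1.0]}, index=["s0"])
        assert px.nlr(CellFractions(table))["s0"] == 0.0

    def test_nlr_zero_lymphocytes_is_missing_with_warning(self):
        table = pd.DataFrame({"Neutrophils": [1.0], "T cells CD8": [0.0]}, index=["s0"])
        with pytest.warns(UserWarning, match="zero lymphocyte"):
            ratio = px.nlr(CellFractions(table))
        assert np.isnan(ratio["s0"])

    def test_nlr_scale_invariant(self, rng):
        table = pd.DataFrame(
            rng.dirichlet(np.ones(3), size=4), columns=["Neutrophils", "T cells CD8", "NK cells"]
        )
        a = px.nlr(CellFractions(table))
        b = (table * 0.5)["Neutrophils"] / (table * 0.5)[["T cells CD8", "NK cells"]].sum(axis=1)
        np.testing.assert_allclose(a, b)

    def test_unknown_label(self):
        with pytest.raises(KeyError, match="unknown"):
            px.nlr(self._fracs(), neutrophil_label="Basophils")


def _meta_and_fracs(n_pairs=40, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows, frac_rows, idx = [], [], []
    for p in range(n_pairs):
        days = rng.uniform(75, 2630)
        for role in ("case", "control"):
            sid = f"p{p}_{role}"
            idx.append(sid)
            rows.append(
                {
                    "sample_id": sid,
                    "pair_id": f"p{p}",
                    "role": role,
                    "days_to_diagnosis": days,
                    "metastatic": True,
                    "smoking_status": rng.choice(["current", "former", "never"]),
                }
            )
            alpha = np.array([0.35 + (shift if role == "case" else 0.0), 0.35, 0.30])
            frac_rows.append(rng.dirichlet(alpha / alpha.sum() * 150))
    meta = pd.DataFrame(rows).set_index("sample_id")
    fracs = CellFractions(
        pd.DataFrame(frac_rows, index=idx, columns=["Neutrophils", "T cells CD8", "Monocytes"])
    )
    return meta, fracs


class TestGroupTests:
    def test_identical_case_control_gives_p_one(self):
        meta, fracs = _meta_and_fracs(10)
        table = fracs.fractions.copy()
        for p in range(10):
            table.loc[f"p{p}_case"] = table.loc[f"p{p}_control"]
        out = group_tests(CellFractions(table), meta, subset="all")
        assert (out["p_paired"] == 1.0).all()

    def test_planted_neutrophil_shift_detected(self):
        meta, fracs = _meta_and_fracs(n_pairs=128, shift=0.02, seed=42)
        out = group_tests(fracs, meta, subset="all")
        assert out.loc["Neutrophils", "p_paired"] < 0.05

    def test_kruskal_wallis_calibrated(self):
        """Three smoking groups from one distribution: ~5% type-I error."""
        rng = np.random.default_rng(7)
        meta, _ = _meta_and_fracs(n_pairs=30, seed=3)
        hits = 0
        reps = 500
        for _ in range(reps):
            table = pd.DataFrame(
                rng.dirichlet(np.ones(3) * 50, size=len(meta)),
                index=meta.index,
                columns=["Neutrophils", "T cells CD8", "Monocytes"],
            )
            out = group_tests(CellFractions(table), meta, subset="all")
            hits += out.loc["Neutrophils", "p_smoking_kw"] < 0.05
        rate = hits / reps
        assert abs(rate - 0.05) < 0.03, rate

    def test_small_subset_refused(self):
        meta, fracs = _meta_and_fracs(10)
        meta["metastatic"] = False
        meta.loc[meta["pair_id"] == "p0", "metastatic"] = True
        with pytest.raises(ValueError, match="need at least 3"):
            group_tests(fracs, meta, subset="metastatic")


class TestFractionTimeTrend:
    def test_constant_column_p_one(self):
        meta, fracs = _meta_and_fracs(20)
        table = fracs.fractions.copy()
        table["Neutrophils"] = 0.4
        out = fraction_time_trend(CellFractions(table), meta)
        assert out.loc["Neutrophils", "p_value"] == 1.0

    def test_linear_trend_detected(self):
        """A fraction drifting linearly over time (R^2 ~ 0.1, n = 100
        cases) is flagged by the spline F-test."""
        rng = np.random.default_rng(11)
        meta, fracs = _meta_and_fracs(n_pairs=100, seed=5)
        table = fracs.fractions.copy()
        cases = meta.index[meta["role"] == "case"]
        days = meta.loc[cases, "days_to_diagnosis"]
        signal = (days - days.mean()) / days.std() * 0.02
        noise = rng.normal(0, 0.06, size=len(cases))
        table.loc[cases, "Monocytes"] = 0.3 + signal + noise
        table = table.clip(0, 1)
        out = fraction_time_trend(CellFractions(table), meta)
        assert out.loc["Monocytes", "p_value"] < 0.05

    def test_null_fraction_p_uniformish(self):
        """Fractions independent of time: p-values roughly uniform."""
        pvals = []
        for seed in range(60):
            meta, fracs = _meta_and_fracs(n_pairs=30, seed=seed)
            out = fraction_time_trend(fracs, meta)
            pvals.append(out["p_value"].to_numpy())
        pvals = np.concatenate(pvals)
        rate = (pvals < 0.05).mean()
        assert abs(rate - 0.05) < 0.04, rate

    def test_requires_enough_cases(self):
        meta, fracs = _meta_and_fracs(4)
        with pytest.raises(ValueError, match="at least 10"):
            fraction_time_trend(fracs, meta)
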