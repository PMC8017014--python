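"""Signature-based immune-cell deconvolution and the NLR.

Bulk blood expression is modelled as a nonnegative mixture of cell-type
reference profiles: for each sample the linear-scale expression over the
marker genes shared with the signature matrix is regressed on the
signature by nonnegative least squares and the coefficients are
normalized to relative fractions summing to one.  The
neutrophil-to-lymphocyte ratio (NLR) divides the neutrophil fraction by
the summed lymphocyte fractions.  Group comparisons use nonparametric
tests (paired Wilcoxon signed-rank across case-control pairs,
Kruskal-Wallis across smoking categories) and natural-spline F-tests
probe nonlinear trends of fractions over years to diagnosis in cases.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genewise import natural_spline_basis
from .synthetic import LYMPHOCYTE_PATTERN

LT3Y_DAYS = 3 * 365.25  # "< 3 years" subgroup cutoff


@dataclass
class CellFractions:
    """Samples x cell-types relative fractions plus per-sample NLR."""

    fractions: pd.DataFrame
    nlr: pd.Series | None = None

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy(dtype=float)
        if (f < -1e-10).any() or (f > 1 + 1e-10).any():
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.fractions.columns)

    def summary(self) -> str:
        med = self.fractions.median().sort_values(ascending=False)
        lines = ["Estimated cell fractions (median per type):"]
        lines += [f"  {t:<28s} {m:.3f}" for t, m in med.items()]
        if self.nlr is not None:
            lines.append(f"  {'NLR (median)':<28s} {self.nlr.median():.3f}")
        return "\n".join(lines)


class DeconvolutionModel:
    """Nonnegative-least-squares mixture deconvolution.

    Parameters
    ----------
    expr_linear : DataFrame, genes x samples on the linear scale
        (2**log2-expression for preprocessed data).
    signature : DataFrame, marker genes x cell types, linear scale.
    """

    def __init__(self, expr_linear: pd.DataFrame, signature: pd.DataFrame) -> None:
        if (signature.to_numpy() < 0).any():
            raise ValueError("signature matrix must be nonnegative")
        if signature.shape[1] < 2:
            raise ValueError("signature must contain at least 2 cell types")
        shared = expr_linear.index.intersection(signature.index)
        if len(shared) < signature.shape[1]:
            raise ValueError(
                f"only {len(shared)} marker genes shared between expression and signature; "
                f"need at least {signature.shape[1]}"
            )
        self.expr = expr_linear.loc[shared]
        self.signature = signature.loc[shared]

    def fit(self) -> CellFractions:
        S = self.signature.to_numpy(dtype=float)
        fracs = np.empty((self.expr.shape[1], S.shape[1]))
        for j, sample in enumerate(self.expr.columns):
            y = self.expr[sample].to_numpy(dtype=float)
            coef, _ = optimize.nnls(S, y)
            total = coef.sum()
            if total <= 0:
                raise ValueError(f"all-zero deconvolution solution for sample {sample!r}")
            fracs[j] = coef / total
        frame = pd.DataFrame(fracs, index=self.expr.columns, columns=self.signature.columns)
        return CellFractions(frame)


def filter_populations(fracs: CellFractions, min_mean: float = 0.05) -> CellFractions:
    """Keep cell types whose mean fraction across samples is strictly
    greater than ``min_mean``.  Fractions are NOT renormalized — the
    comparisons below operate on raw relative fractions."""
    if not 0 <= min_mean < 1:
        raise ValueError("min_mean must be in [0, 1)")
    keep = fracs.fractions.columns[fracs.fractions.mean(axis=0) > min_mean]
    if len(keep) == 0:
        raise ValueError("all cell types removed by the mean-fraction filter")
    return CellFractions(fracs.fractions[keep], nlr=fracs.nlr)


def nlr(
    fracs: CellFractions,
    neutrophil_label: str = "Neutrophils",
    lymphocyte_labels: list[str] | None = None,
) -> pd.Series:
    """Per-sample neutrophil-to-lymphocyte ratio.

    ``lymphocyte_labels`` defaults to every cell type matching T/B/NK/
    plasma-cell naming.  Computed on the unfiltered fraction table.  A
    zero lymphocyte sum yields a missing value with a warning.
    """
    table = fracs.fractions
    if neutrophil_label not in table.columns:
        raise KeyError(f"unknown neutrophil label: {neutrophil_label!r}")
    if lymphocyte_labels is None:
        lymphocyte_labels = [c for c in table.columns if re.search(LYMPHOCYTE_PATTERN, c)]
    missing = [c for c in lymphocyte_labels if c not in table.columns]
    if missing:
        raise KeyError(f"unknown lymphocyte labels: {missing}")
    if not lymphocyte_labels:
        raise ValueError("no lymphocyte cell types identified")
    neu = table[neutrophil_label]
    lymph = table[lymphocyte_labels].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = neu / lymph
    zero = lymph == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) with zero lymphocyte sum; NLR set to missing",
            stacklevel=2,
        )
        ratio[zero] = np.nan
    ratio.name = "NLR"
    return ratio


def _subset_mask(meta: pd.DataFrame, subset: str) -> pd.Series:
    if subset == "all":
        return pd.Series(True, index=meta.index)
    if subset == "metastatic":
        return meta["metastatic"].astype(bool)
    if subset == "metastatic_lt3y":
        return meta["metastatic"].astype(bool) & (meta["days_to_diagnosis"] < LT3Y_DAYS)
    raise ValueError(f"unknown subset: {subset!r}")


def _paired_wilcoxon(case: np.ndarray, ctrl: np.ndarray, exact: bool | None = None) -> float:
    diff = case - ctrl
    diff = diff[~np.isnan(diff)]
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        return 1.0  # all zero differences dropped; p = 1 by convention
    mode = "auto" if exact is None else ("exact" if exact else "approx")
    try:
        return float(stats.wilcoxon(nonzero, zero_method="wilcox", mode=mode).pvalue)
    except ValueError:
        return 1.0


def group_tests(
    fracs: CellFractions,
    meta: pd.DataFrame,
    subset: str = "all",
    exact: bool | None = None,
) -> pd.DataFrame:
    """Case-control and smoking-status tests per cell type and for NLR.

    For each cell type (and the NLR when present): the paired Wilcoxon
    signed-rank p-value over case-control pairs within ``subset`` and the
    Kruskal-Wallis p-value across smoking categories pooling all samples
    of the subset.  ``exact`` selects exact small-sample p-values
    (default: automatic).
    """
    mask = _subset_mask(meta, subset)
    sub = meta.loc[mask]
    pair_ids = sub["pair_id"].unique()
    if len(pair_ids) < 3:
        raise ValueError(f"subset {subset!r} holds {len(pair_ids)} pairs; need at least 3")

    table = fracs.fractions.copy()
    if fracs.nlr is not None:
        table["NLR"] = fracs.nlr
    case_ids = sub.index[sub["role"] == "case"]
    ctrl_ids = sub.index[sub["role"] == "control"]
    case_by_pair = sub.loc[case_ids].reset_index().set_index("pair_id")["sample_id"]
    ctrl_by_pair = sub.loc[ctrl_ids].reset_index().set_index("pair_id")["sample_id"]

    rows = {}
    status = sub["smoking_status"]
    for col in table.columns:
        v = table[col]
        case_vals = v[case_by_pair.loc[pair_ids]].to_numpy(dtype=float)
        ctrl_vals = v[ctrl_by_pair.loc[pair_ids]].to_numpy(dtype=float)
        p_paired = _paired_wilcoxon(case_vals, ctrl_vals, exact=exact)
        groups = [
            v[sub.index[status == s]].dropna().to_numpy(dtype=float)
            for s in ("current", "former", "never")
        ]
        groups = [g for g in groups if g.size > 0]
        if len(groups) >= 2 and np.ptp(np.concatenate(groups)) > 0:
            try:
                p_kw = float(stats.kruskal(*groups).pvalue)
            except ValueError:
                p_kw = 1.0
        else:
            p_kw = 1.0
        rows[col] = {"p_paired": p_paired, "p_smoking_kw": p_kw}
    out = pd.DataFrame(rows).T
    out.index.name = "cell_type"
    out.insert(0, "subset", subset)
    out.insert(1, "n_pairs", len(pair_ids))
    return out


def fraction_time_trend(
    fracs: CellFractions,
    meta: pd.DataFrame,
    df: int = 3,
) -> pd.DataFrame:
    """Nonlinear time-to-diagnosis trend test of each cell fraction.

    Cases only: each fraction (and NLR) is regressed on a natural-spline
    basis (``df`` degrees of freedom) of years to diagnosis; the F-test of
    the spline terms is reported.  Constant columns report p = 1.
    """
    cases = meta.loc[meta["role"] == "case"]
    if len(cases) < 10:
        raise ValueError(f"need at least 10 cases; have {len(cases)}")
    years = cases["days_to_diagnosis"].to_numpy(dtype=float) / 365.25
    N = natural_spline_basis(years, df=df)
    X = np.column_stack([np.ones(len(years)), N])
    q = X.shape[1] - 1
    d = len(years) - X.shape[1]
    table = fracs.fractions.copy()
    if fracs.nlr is not None:
        table["NLR"] = fracs.nlr
    rows = {}
    for col in table.columns:
        y = table[col].reindex(cases.index).to_numpy(dtype=float)
        ok = ~np.isnan(y)
        yv, Xv = y[ok], X[ok]
        if np.ptp(yv) == 0:
            rows[col] = {"F": 0.0, "p_value": 1.0}
            continue
        coef, rss1, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
        rss1 = float(((yv - Xv @ coef) ** 2).sum())
        rss0 = float(((yv - yv.mean()) ** 2).sum())
        dd = ok.sum() - X.shape[1]
        F = (rss0 - rss1) / q / (rss1 / dd) if rss1 > 0 else np.inf
        rows[col] = {"F": max(F, 0.0), "p_value": float(stats.f.sf(max(F, 0.0), q, dd))}
    out = pd.DataFrame(rows).T
    out.index.name = "cell_type"
    return out
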