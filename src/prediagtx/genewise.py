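"""Gene-wise moderated tests on paired expression differences.

Per gene, a linear model is fitted to the case-minus-control log2
differences; residual variances are shrunk toward a common prior by
empirical Bayes before forming t (mean difference) or F (spline time
trend) statistics.  The prior degrees of freedom d0 and prior variance
s0^2 are estimated by moment-matching the marginal distribution of the log
sample variances against a scaled-F model: with residual df d,

    e_g = log(s_g^2) - digamma(d/2) + log(d/2)

has mean log(s0^2) + digamma(d0/2) - log(d0/2) and variance
trigamma(d/2) + trigamma(d0/2), so d0 follows from inverting the trigamma
function on Var(e) - trigamma(d/2) and s0^2 from the mean.  The posterior
(squeezed) variance is s~^2 = (d0 s0^2 + d s^2) / (d0 + d) and moderated
statistics gain d0 extra degrees of freedom.

Multiple testing uses Benjamini-Hochberg step-up q-values throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

DAYS_PER_YEAR = 365.25


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0); trigamma is decreasing."""
    if y <= 0:
        return np.inf
    lo, hi = 1e-8, 1e8
    if special.polygamma(1, lo) < y:
        return lo
    if special.polygamma(1, hi) > y:
        return hi
    return float(optimize.brentq(lambda x: special.polygamma(1, x) - y, lo, hi, xtol=1e-12))


def squeeze_variances(
    s2: np.ndarray,
    df: float,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes variance shrinkage.

    Returns ``(d0, s0sq, s2_post)``.  ``prior_df`` / ``prior_var`` force
    the prior instead of estimating it (``prior_df=0`` disables shrinkage,
    ``prior_df=inf`` pools all genes at the prior variance).
    """
    s2 = np.asarray(s2, dtype=float)
    if df <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    positive = s2 > 0
    if prior_var is None or prior_df is None:
        if positive.sum() < 2:
            raise ValueError("need at least two positive sample variances to estimate the prior")
        z = np.log(s2[positive])
        e = z - special.digamma(df / 2) + np.log(df / 2)
        emean = e.mean()
        evar = e.var(ddof=1)
        rhs = evar - special.polygamma(1, df / 2)
        if prior_df is None:
            d0 = 2 * _trigamma_inverse(rhs) if rhs > 0 else np.inf
        else:
            d0 = float(prior_df)
        if prior_var is None:
            if np.isinf(d0):
                s0sq = float(np.exp(emean))
            else:
                s0sq = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
        else:
            s0sq = float(prior_var)
    else:
        d0, s0sq = float(prior_df), float(prior_var)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
    elif d0 == 0:
        s2_post = s2.copy()
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
    return float(d0), float(s0sq), s2_post


def _fit_many_ols(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the same design to every row of Y via QR (stable for the
    spline design). Returns (coef, rss, XtX_inv)."""
    from scipy.linalg import qr, solve_triangular

    Q, R = qr(X, mode="economic")
    coef = solve_triangular(R, Q.T @ Y.T).T
    resid = Y - coef @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    Rinv = solve_triangular(R, np.eye(R.shape[0]))
    XtX_inv = Rinv @ Rinv.T
    return coef, rss, XtX_inv


def natural_spline_basis(
    x: np.ndarray,
    df: int = 3,
    boundary_knots: tuple[float, float] | None = None,
    interior_knots: np.ndarray | None = None,
) -> np.ndarray:
    """Natural cubic spline basis (no intercept column), R ``ns()`` space.

    Boundary knots default to min/max of ``x``; ``df - 1`` interior knots
    default to evenly spaced quantiles (terciles for df=3).  Uses the
    truncated-power natural-spline construction: the basis is linear
    beyond the boundary knots and spans a space of dimension ``df``.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if boundary_knots is None:
        boundary_knots = (float(x.min()), float(x.max()))
    lo, hi = boundary_knots
    if interior_knots is None:
        probs = np.linspace(0, 1, df + 1)[1:-1]
        interior_knots = np.quantile(x, probs)
    # standardize onto [0, 1] for numerical conditioning of the cubic terms;
    # the spanned space is unchanged
    span = hi - lo
    if span <= 0:
        raise ValueError("boundary knots must span a positive range")
    x = (x - lo) / span
    interior_knots = (np.atleast_1d(interior_knots) - lo) / span
    lo, hi = 0.0, 1.0
    knots = np.unique(np.concatenate([[lo], np.atleast_1d(interior_knots), [hi]]))
    if len(knots) != df + 1:
        warnings.warn(
            f"duplicate knots collapse the spline basis: {df + 1} knots requested, "
            f"{len(knots)} distinct; dimension reduced",
            stacklevel=2,
        )
    K = len(knots)
    if K < 2:
        raise ValueError("need at least two distinct knots")

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - knots[k], 0) ** 3 - np.maximum(x - knots[-1], 0) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    dKm1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dKm1)
    return np.column_stack(cols)


@dataclass
class GenewiseResults:
    """Gene-wise test table plus the fitted shrinkage prior.

    ``table`` is indexed by gene with columns ``estimate``, the test
    statistic (``t`` or ``F``), ``p_value``, ``q_value`` and ``rank``.
    """

    table: pd.DataFrame
    prior_df: float
    prior_var: float
    residual_df: float
    analysis: str

    @property
    def total_df(self) -> float:
        return self.prior_df + self.residual_df

    def n_significant(self, fdr: float = 0.05) -> int:
        return int((self.table["q_value"] <= fdr).sum())

    def top_genes(self, n: int = 100) -> list:
        """Top-n genes by raw p, deterministic tie-break by gene id."""
        tab = self.table
        if n > len(tab):
            warnings.warn(f"n={n} exceeds universe size {len(tab)}; capped", stacklevel=2)
            n = len(tab)
        order = tab.assign(_g=tab.index.astype(str)).sort_values(["p_value", "_g"], kind="mergesort")
        return list(order.index[:n])

    def summary(self) -> str:
        stat_col = "t" if "t" in self.table.columns else "F"
        lines = [
            f"Gene-wise moderated {stat_col}-tests ({self.analysis})",
            f"genes: {len(self.table)}   prior df d0 = {self.prior_df:.3g}   prior var s0^2 = {self.prior_var:.4g}",
            f"residual df = {self.residual_df:g}   total df = {self.total_df:.3g}",
            f"significant at FDR 0.05: {self.n_significant(0.05)}   at FDR 0.10: {self.n_significant(0.10)}",
        ]
        return "\n".join(lines)


def _finish_table(
    genes: pd.Index, estimate: np.ndarray, stat: np.ndarray, stat_name: str, p: np.ndarray
) -> pd.DataFrame:
    q = bh_fdr(p)
    table = pd.DataFrame(
        {"estimate": estimate, stat_name: stat, "p_value": p, "q_value": q}, index=genes
    )
    order = np.lexsort((genes.astype(str), p))
    rank = np.empty(len(p), dtype=int)
    rank[order] = np.arange(1, len(p) + 1)
    table["rank"] = rank
    table.index.name = "gene"
    return table


class PairedDifferenceModel:
    """Moderated one-sample test of zero mean pair difference per gene.

    Parameters
    ----------
    differences : DataFrame, genes x pairs of case-minus-control log2
        differences.
    covariate : optional per-pair covariate (e.g. the pair's case-minus-
        control smoking-index difference); the intercept remains the tested
        effect.
    """

    def __init__(self, differences: pd.DataFrame, covariate: np.ndarray | pd.Series | None = None) -> None:
        self.D = differences
        n = differences.shape[1]
        if n < 3:
            raise ValueError("need at least 3 pairs")
        cols = [np.ones(n)]
        if covariate is not None:
            c = np.asarray(covariate, dtype=float)
            if c.shape[0] != n:
                raise ValueError("covariate length must match the number of pairs")
            if np.std(c) == 0:
                warnings.warn("constant covariate dropped from the design", stacklevel=2)
            else:
                cols.append(c - c.mean())
        self.X = np.column_stack(cols)

    def fit(
        self, prior_df: float | None = None, prior_var: float | None = None
    ) -> GenewiseResults:
        Y = self.D.to_numpy(dtype=float)
        X = self.X
        n, p_dim = X.shape
        d = n - p_dim
        if d <= 0:
            raise ValueError("zero residual degrees of freedom")
        coef, rss, XtX_inv = _fit_many_ols(Y, X)
        s2 = rss / d
        d0, s0sq, s2_post = squeeze_variances(s2, d, prior_df=prior_df, prior_var=prior_var)
        se = np.sqrt(s2_post * XtX_inv[0, 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, coef[:, 0] / se, 0.0)
        df_total = d0 + d
        if np.isinf(df_total):
            p = 2 * stats.norm.sf(np.abs(t))
        else:
            p = 2 * stats.t.sf(np.abs(t), df_total)
        table = _finish_table(self.D.index, coef[:, 0], t, "t", p)
        covs = "with covariate" if p_dim > 1 else "no covariate"
        return GenewiseResults(table, d0, s0sq, d, f"paired moderated t, {covs}")


class SplineTrendModel:
    """Moderated F-test of a smooth time-to-diagnosis trend per gene.

    Each gene's pair differences are regressed on an intercept plus a
    natural cubic spline basis of days to diagnosis (default 3 df;
    boundary knots at min/max, interior knots at terciles).  The F
    statistic tests the spline coefficients jointly, so a pure offset with
    no time shape is absorbed by the intercept.
    """

    def __init__(self, differences: pd.DataFrame, days: pd.Series | np.ndarray, df: int = 3) -> None:
        self.D = differences
        days = np.asarray(days, dtype=float)
        if days.shape[0] != differences.shape[1]:
            raise ValueError("days must align with difference-matrix columns")
        if differences.shape[1] < df + 2:
            raise ValueError(f"need at least df + 2 = {df + 2} pairs")
        N = natural_spline_basis(days, df=df)
        X = np.column_stack([np.ones(days.shape[0]), N])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn(
                f"design rank {rank} < {X.shape[1]} (duplicate days?); spline df reduced",
                stacklevel=2,
            )
            q, r, piv = _qr_pivot(X)
            X = X[:, sorted(piv[:rank])]
        self.X = X
        self.q = X.shape[1] - 1  # tested spline df

    def fit(
        self, prior_df: float | None = None, prior_var: float | None = None
    ) -> GenewiseResults:
        Y = self.D.to_numpy(dtype=float)
        X = self.X
        n, p_dim = X.shape
        d = n - p_dim
        if d <= 0:
            raise ValueError("zero residual degrees of freedom")
        _, rss1, _ = _fit_many_ols(Y, X)
        ybar = Y.mean(axis=1, keepdims=True)
        rss0 = ((Y - ybar) ** 2).sum(axis=1)
        s2 = rss1 / d
        d0, s0sq, s2_post = squeeze_variances(s2, d, prior_df=prior_df, prior_var=prior_var)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(s2_post > 0, (rss0 - rss1) / self.q / s2_post, 0.0)
        F = np.maximum(F, 0.0)
        df_total = d0 + d
        if np.isinf(df_total):  # F(q, inf) == chi2_q / q
            p = stats.chi2.sf(F * self.q, self.q)
        else:
            p = stats.f.sf(F, self.q, df_total)
        # constant rows carry no information: report p = 1 by convention
        constant = rss0 <= 1e-300
        p[constant] = 1.0
        F[constant] = 0.0
        table = _finish_table(self.D.index, (rss0 - rss1), F, "F", p)
        return GenewiseResults(table, d0, s0sq, d, f"natural-spline trend F ({self.q} df)")


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, pivoting=True)
    return q, r, piv


def cumulative_by_year(
    differences: pd.DataFrame,
    days: pd.Series | np.ndarray,
    max_year: int = 8,
    fdr_levels: tuple[float, ...] = (0.05, 0.1),
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Moderated paired tests on cases accumulated year by year.

    For each y = 1..max_year the test is rerun on pairs with days to
    diagnosis <= y * 365.25; rows with fewer than ``min_pairs`` pairs are
    marked not run.
    """
    days = np.asarray(days, dtype=float)
    rows = []
    for y in range(1, max_year + 1):
        mask = days <= y * DAYS_PER_YEAR
        n_cum = int(mask.sum())
        row: dict = {"year": y, "n_cumulated": n_cum, "run": n_cum >= min_pairs}
        if n_cum >= min_pairs:
            res = PairedDifferenceModel(differences.loc[:, mask]).fit()
            for level in fdr_levels:
                row[f"n_fdr_{level:g}"] = res.n_significant(level)
        else:
            for level in fdr_levels:
                row[f"n_fdr_{level:g}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")


def top_n_overlap(
    results: dict[str, "GenewiseResults | pd.DataFrame"], n: int = 100
) -> pd.DataFrame:
    """Pairwise intersection sizes of the top-n gene lists (by raw p)."""
    if len(results) < 2:
        raise ValueError("need at least two result sets")
    tops = {}
    for name, res in results.items():
        if isinstance(res, GenewiseResults):
            tops[name] = set(res.top_genes(n))
        else:
            tab = res.assign(_g=res.index.astype(str)).sort_values(["p_value", "_g"], kind="mergesort")
            if n > len(tab):
                warnings.warn(f"n={n} exceeds universe size {len(tab)}; capped", stacklevel=2)
            tops[name] = set(tab.index[:n])
    names = list(tops)
    mat = pd.DataFrame(index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            mat.loc[a, b] = len(tops[a] & tops[b])
    return mat.astype(int)
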