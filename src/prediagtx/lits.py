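"""Local-in-time statistics (LITS): sliding-window permutation test.

Pairs are ordered by the case's time to diagnosis and grouped into
overlapping windows of ``k`` consecutive pairs (n - k + 1 windows).  Under
the null hypothesis the expected case-minus-control log2 difference is
zero for every gene in every window; the null distribution is generated by
sign-flip permutation of case/control status within pairs (one shared
+-1 per pair across genes and windows).

The window statistic is the mean over genes of the squared one-sample
t statistic of the k differences (sensitive to many small coordinated
shifts; ``max_abs_t`` is available as an alternative).  Raw p-values are
per-window add-one tail probabilities; the family-wise adjusted p-value
compares each window against the permutation distribution of the
max-over-windows statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def make_windows(days: pd.Series, k: int) -> list[list]:
    """Overlapping windows of k pairs consecutive in time to diagnosis.

    ``days`` is indexed by pair id.  Pairs are sorted by days ascending
    (nearest diagnosis first); ties broken by pair id.  Returns the list of
    n - k + 1 windows of pair ids.
    """
    n = len(days)
    if not 2 <= k <= n:
        raise ValueError(f"window size k={k} must satisfy 2 <= k <= n={n}")
    order = sorted(days.index, key=lambda pid: (days[pid], str(pid)))
    return [order[i : i + k] for i in range(n - k + 1)]


@dataclass
class LITSResults:
    """Per-window statistics of the sliding-window permutation test."""

    table: pd.DataFrame  # window, n, day_min, day_max, T, p_raw, p_adjusted
    window_members: list[list]
    k: int
    n_permutations: int
    seed: int
    statistic: str

    @property
    def min_p_adjusted(self) -> float:
        return float(self.table["p_adjusted"].min())

    def best_window(self) -> pd.Series:
        """The window with the smallest raw p (ties: smallest index)."""
        return self.table.loc[self.table["p_raw"].idxmin()]

    def summary(self) -> str:
        best = self.best_window()
        lines = [
            "Local-in-time statistics (sliding-window sign-flip test)",
            f"{len(self.table)} windows of {self.k} pairs   statistic = {self.statistic}   B = {self.n_permutations}   seed = {self.seed}",
            f"minimum adjusted p: {self.min_p_adjusted:.4f}",
            f"best window: #{int(best['window'])} days [{best['day_min']:.0f}, {best['day_max']:.0f}] p_raw = {best['p_raw']:.4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """p-value-versus-time curve (window midpoint days on the x axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mid = (self.table["day_min"] + self.table["day_max"]) / 2
        ax.plot(mid, self.table["p_raw"], marker=".", label="raw p")
        ax.plot(mid, self.table["p_adjusted"], marker=".", label="adjusted p")
        ax.axhline(0.05, color="grey", ls="--", lw=0.8)
        ax.set_xlabel("days to diagnosis (window midpoint)")
        ax.set_ylabel("permutation p-value")
        ax.invert_xaxis()
        ax.legend()
        return ax


class LITSModel:
    """Sliding-window test on a genes x pairs difference matrix.

    Parameters
    ----------
    differences : DataFrame, genes x pairs (case minus control, log2).
    days : Series of days to diagnosis indexed like the columns.
    k : window size (pairs per window).
    statistic : 'mean_t2' (default) or 'max_abs_t'.
    """

    def __init__(
        self,
        differences: pd.DataFrame,
        days: pd.Series,
        k: int = 30,
        statistic: str = "mean_t2",
    ) -> None:
        if statistic not in ("mean_t2", "max_abs_t"):
            raise ValueError(f"unknown statistic: {statistic!r}")
        days = pd.Series(days, index=differences.columns) if not isinstance(days, pd.Series) else days
        self.windows = make_windows(days, k)
        order = sorted(days.index, key=lambda pid: (days[pid], str(pid)))
        self.D = differences[order]
        self.days = days[order]
        self.k = k
        self.statistic = statistic

    def _window_stats(self, S1w: np.ndarray, S2w: np.ndarray) -> np.ndarray:
        """Statistic per window from window sums of d and d^2 (G x W)."""
        k = self.k
        mean = S1w / k
        var = (S2w - S1w**2 / k) / (k - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = np.where(var > 0, mean**2 / (var / k), 0.0)
        if self.statistic == "mean_t2":
            return t2.mean(axis=0)
        return np.sqrt(t2).max(axis=0)

    def fit(self, n_permutations: int = 999, seed: int = 0) -> LITSResults:
        if n_permutations < 99:
            raise ValueError("need at least 99 permutations")
        B = n_permutations
        D = self.D.to_numpy(dtype=float)
        G, n = D.shape
        k = self.k
        W = n - k + 1

        def window_sums(X: np.ndarray) -> np.ndarray:
            c = np.concatenate([np.zeros((X.shape[0], 1)), np.cumsum(X, axis=1)], axis=1)
            return c[:, k:] - c[:, :-k]

        S2w = window_sums(D**2)  # invariant under sign flips
        T_obs = self._window_stats(window_sums(D), S2w)

        rng = np.random.default_rng(seed)
        T_perm = np.empty((B, W))
        for b in range(B):
            s = rng.choice((-1.0, 1.0), size=n)
            T_perm[b] = self._window_stats(window_sums(D * s), S2w)

        exceed = (T_perm >= T_obs[None, :]).sum(axis=0)
        p_raw = (1 + exceed) / (B + 1)
        max_perm = T_perm.max(axis=1)
        p_adj = (1 + (max_perm[:, None] >= T_obs[None, :]).sum(axis=0)) / (B + 1)

        day_values = self.days.to_numpy(dtype=float)
        table = pd.DataFrame(
            {
                "window": np.arange(1, W + 1),
                "n": k,
                "day_min": [day_values[i] for i in range(W)],
                "day_max": [day_values[i + k - 1] for i in range(W)],
                "T": T_obs,
                "p_raw": p_raw,
                "p_adjusted": p_adj,
            }
        )
        return LITSResults(
            table=table,
            window_members=self.windows,
            k=k,
            n_permutations=B,
            seed=seed,
            statistic=self.statistic,
        )
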