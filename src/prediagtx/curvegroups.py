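"""Curve-group analysis of paired expression differences over time.

Time to diagnosis is split into three windows (window/period 1 nearest
diagnosis).  For each gene the case-minus-control log2 differences are
averaged per window and the gene is *designated* when its between-window
sum of squares exceeds the (1 - alpha0) quantile of its own sign-flip
permutation null.  Designated genes are sorted into the six possible
orderings of the three window means ("curve groups": '123' means period 1
has the highest mean, i.e. the case-control difference grows toward
diagnosis).  Observed per-group counts are compared with the counts the
same procedure yields under the sign-flip null; one shared +-1 flip per
pair (applied to all genes) preserves inter-gene correlation.

All p-values use the add-one permutation estimator (1 + #{null >= obs}) /
(B + 1) and therefore never return 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from . import design

CURVE_LABELS = ("123", "132", "312", "321", "213", "231")

# encode a descending-mean ordering (tuple of window indices) as a label
_ORDER_TO_LABEL = {perm: "".join(str(i + 1) for i in perm) for perm in permutations(range(3))}


@dataclass(frozen=True)
class WindowSpec:
    """Day cutoffs c1 < c2 splitting time to diagnosis into 3 windows."""

    c1: float = design.DEFAULT_CUTOFFS[0]
    c2: float = design.DEFAULT_CUTOFFS[1]

    def __post_init__(self) -> None:
        if not 0 < self.c1 < self.c2:
            raise ValueError("cutoffs must satisfy 0 < c1 < c2")


def assign_windows(days: np.ndarray | pd.Series, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Window index (1, 2 or 3) per pair; half-open bins, boundary goes up.

    Window 1: days < c1 (nearest diagnosis); window 2: c1 <= days < c2;
    window 3: days >= c2.
    """
    d = np.asarray(days, dtype=float)
    if (d <= 0).any():
        raise ValueError("all days-to-diagnosis must be positive")
    return 1 + (d >= spec.c1).astype(int) + (d >= spec.c2).astype(int)


def curve_label(m1: float, m2: float, m3: float) -> str:
    """Label = periods sorted by descending mean, ties to the lower period."""
    means = np.array([m1, m2, m3], dtype=float)
    if not np.isfinite(means).all():
        raise ValueError("window means must be finite")
    order = tuple(np.argsort(-means, kind="stable"))
    return _ORDER_TO_LABEL[order]


@dataclass
class CurveGroupResults:
    """Observed/expected curve-group occupancy and permutation p-values."""

    table: pd.DataFrame  # per-label rows + 'global': observed, expected, p_overall, p_period1..3
    designated: dict[str, list]  # label -> designated gene ids
    alpha0: float
    n_permutations: int
    seed: int
    window_counts: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def p_global(self) -> float:
        return float(self.table.loc["global", "p_overall"])

    def summary(self) -> str:
        lines = [
            "Curve-group time-trend test (sign-flip permutation null)",
            f"windows (pairs): {list(self.window_counts)}   alpha0 = {self.alpha0}   B = {self.n_permutations}   seed = {self.seed}",
            "",
            self.table.round(4).to_string(),
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


class CurveGroupModel:
    """Curve-group occupancy test on a genes x pairs difference matrix.

    Parameters
    ----------
    differences : DataFrame, genes x pairs of case-minus-control log2
        expression differences.
    days : per-pair days to diagnosis, aligned with the columns.
    spec : window cutoffs.
    min_pairs_per_window : refuse to fit when any window holds fewer pairs.
    """

    def __init__(
        self,
        differences: pd.DataFrame,
        days: pd.Series | np.ndarray,
        spec: WindowSpec = WindowSpec(),
        min_pairs_per_window: int = 2,
    ) -> None:
        self.D = differences
        self.days = np.asarray(days, dtype=float)
        if self.days.shape[0] != differences.shape[1]:
            raise ValueError("days must align with the difference-matrix columns")
        self.spec = spec
        self.windows = assign_windows(self.days, spec)
        counts = np.array([(self.windows == w).sum() for w in (1, 2, 3)])
        if (counts < min_pairs_per_window).any():
            raise ValueError(f"too few pairs per window: counts = {counts.tolist()}")
        self.window_counts = counts

    # -- internals -------------------------------------------------------

    def _window_operator(self) -> np.ndarray:
        """n_pairs x 3 matrix whose product with D gives window means."""
        n = self.days.shape[0]
        M = np.zeros((n, 3))
        for w in (1, 2, 3):
            mask = self.windows == w
            M[mask, w - 1] = 1.0 / mask.sum()
        return M

    def _between_window_ss(self, means: np.ndarray, pooled: np.ndarray) -> np.ndarray:
        """T = sum_w n_w (m_w - pooled)^2, along the last axis of `means`."""
        dev = means - pooled[..., None]
        return (dev**2 * self.window_counts).sum(axis=-1)

    def fit(
        self,
        alpha0: float = 0.2,
        n_permutations: int = 999,
        seed: int = 0,
        chunk: int = 200,
    ) -> CurveGroupResults:
        if not 0 < alpha0 < 1:
            raise ValueError("alpha0 must be in (0, 1)")
        if n_permutations < 99:
            raise ValueError("need at least 99 permutations")
        D = self.D.to_numpy(dtype=float)
        G, n = D.shape
        B = n_permutations
        Mn = self._window_operator()
        weights = self.window_counts / n  # pooled mean = weighted window means

        means_obs = D @ Mn  # G x 3
        pooled_obs = means_obs @ weights
        T_obs = self._between_window_ss(means_obs, pooled_obs)

        rng = np.random.default_rng(seed)
        flips = rng.choice((-1.0, 1.0), size=(B, n))

        # pass 1: permutation T values per gene -> per-gene designation threshold
        T_perm = np.empty((B, G))
        label_codes = {lab: i for i, lab in enumerate(CURVE_LABELS)}
        lut = np.full(27, -1, dtype=np.int8)
        for perm in permutations(range(3)):
            code = perm[0] * 9 + perm[1] * 3 + perm[2]
            lut[code] = label_codes[_ORDER_TO_LABEL[perm]]

        def _label_codes(means: np.ndarray) -> np.ndarray:
            # means: ... x 3 -> int8 codes of descending-order labels
            order = np.argsort(-means, axis=-1, kind="stable")
            code = order[..., 0] * 9 + order[..., 1] * 3 + order[..., 2]
            return lut[code]

        means_perm_store = np.empty((B, G, 3), dtype=np.float32)
        for start in range(0, B, chunk):
            S = flips[start : start + chunk]  # b x n
            # (D * s) @ Mn == D @ (s[:, None] * Mn), one matmul per chunk
            W = (S[:, :, None] * Mn[None, :, :]).transpose(1, 0, 2).reshape(n, -1)
            mp = (D @ W).reshape(G, S.shape[0], 3).transpose(1, 0, 2)  # b x G x 3
            pooled = mp @ weights
            T_perm[start : start + chunk] = self._between_window_ss(mp, pooled)
            means_perm_store[start : start + chunk] = mp.astype(np.float32)

        # per-gene (1 - alpha0) null quantile, "higher" order statistic
        m = int(np.ceil((1 - alpha0) * B)) - 1
        thresholds = np.partition(T_perm, m, axis=0)[m]
        designated_obs = T_obs > thresholds

        labels_obs = _label_codes(means_obs)
        obs_counts = np.bincount(labels_obs[designated_obs], minlength=6)
        obs_global = int(designated_obs.sum())

        # pass 2: per-permutation designation, label counts and period statistics
        perm_counts = np.empty((B, 6), dtype=np.int64)
        perm_global = np.empty(B, dtype=np.int64)
        U_perm = np.zeros((B, 6, 3))
        for b in range(B):
            desig = T_perm[b] > thresholds
            labs = _label_codes(means_perm_store[b].astype(float))
            perm_global[b] = desig.sum()
            cnt = np.bincount(labs[desig], minlength=6)
            perm_counts[b] = cnt
            if desig.any():
                am = np.abs(means_perm_store[b][desig].astype(float))  # n_desig x 3
                ld = labs[desig]
                for li in range(6):
                    sel = ld == li
                    if sel.any():
                        U_perm[b, li] = am[sel].mean(axis=0)

        # observed per-period magnitude statistic
        U_obs = np.full((6, 3), np.nan)
        am_obs = np.abs(means_obs)
        for li in range(6):
            sel = designated_obs & (labels_obs == li)
            if sel.any():
                U_obs[li] = am_obs[sel].mean(axis=0)

        def add_one_p(null: np.ndarray, obs: float) -> float:
            return float((1 + (null >= obs).sum()) / (B + 1))

        rows = {}
        expected = perm_counts.mean(axis=0)
        for li, lab in enumerate(CURVE_LABELS):
            row = {
                "observed": int(obs_counts[li]),
                "expected": float(expected[li]),
                "p_overall": add_one_p(perm_counts[:, li], obs_counts[li]),
            }
            for w in range(3):
                if np.isnan(U_obs[li, w]):
                    row[f"p_period{w + 1}"] = 1.0
                else:
                    row[f"p_period{w + 1}"] = add_one_p(U_perm[:, li, w], U_obs[li, w])
            rows[lab] = row
        rows["global"] = {
            "observed": obs_global,
            "expected": float(perm_global.mean()),
            "p_overall": add_one_p(perm_global, obs_global),
            "p_period1": np.nan,
            "p_period2": np.nan,
            "p_period3": np.nan,
        }
        table = pd.DataFrame(rows).T
        table.index.name = "curve_group"

        gene_ids = np.asarray(self.D.index)
        designated = {
            lab: [g for g in gene_ids[designated_obs & (labels_obs == li)]]
            for li, lab in enumerate(CURVE_LABELS)
        }
        return CurveGroupResults(
            table=table,
            designated=designated,
            alpha0=alpha0,
            n_permutations=B,
            seed=seed,
            window_counts=self.window_counts,
        )
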