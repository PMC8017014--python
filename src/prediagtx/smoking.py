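"""Comprehensive smoking index (CSI) and its half-life / lag estimation.

The CSI condenses a smoking history — duration ``dur`` (years), intensity
``int`` (average cigarettes/day) and time since cessation ``tsc`` (years) —
into one exposure scalar through an exponential-decay model with half-life
``tau`` and lag ``delta``::

    tsc* = max(tsc - delta, 0)
    dur* = max(dur + tsc - delta, 0) - tsc*
    CSI  = (1 - 0.5**(dur*/tau)) * 0.5**(tsc*/tau) * ln(int + 1)

The lag shifts the decay clock so that the most recent ``delta`` years of
abstinence do not yet count; the half-life controls both how exposure
accumulates with duration and how it decays after quitting.  ``tau`` and
``delta`` are estimated by profile grid search on the log-likelihood of a
logistic regression of case status on the index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class SmokingRecord:
    """One smoking history. ``status`` is 'current', 'former' or 'never'."""

    dur: float
    int_: float
    tsc: float
    status: str = "current"

    def __post_init__(self) -> None:
        if min(self.dur, self.int_, self.tsc) < 0:
            raise ValueError("dur, int and tsc must be nonnegative")
        if self.status == "current" and self.tsc != 0:
            raise ValueError("current smokers have tsc = 0")
        if self.status == "never" and (self.dur != 0 or self.int_ != 0):
            raise ValueError("never smokers have dur = int = 0")


@dataclass(frozen=True)
class CSIParams:
    """Half-life ``tau`` (years, > 0) and lag ``delta`` (years, >= 0)."""

    tau: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")


def csi(
    record: SmokingRecord | None = None,
    params: CSIParams | None = None,
    *,
    dur: np.ndarray | float | None = None,
    int_: np.ndarray | float | None = None,
    tsc: np.ndarray | float | None = None,
) -> float | np.ndarray:
    """Evaluate the smoking index for one record or arrays of histories.

    Either pass a ``SmokingRecord`` or the three component arrays.
    """
    if params is None:
        raise ValueError("params is required")
    if record is not None:
        dur, int_, tsc = record.dur, record.int_, record.tsc
    dur = np.asarray(dur, dtype=float)
    int_ = np.asarray(int_, dtype=float)
    tsc = np.asarray(tsc, dtype=float)
    tsc_star = np.maximum(tsc - params.delta, 0.0)
    dur_star = np.maximum(dur + tsc - params.delta, 0.0) - tsc_star
    value = (1.0 - 0.5 ** (dur_star / params.tau)) * 0.5 ** (tsc_star / params.tau) * np.log1p(int_)
    if value.ndim == 0:
        return float(value)
    return value


def _loglik_logistic(x: np.ndarray, y: np.ndarray) -> float:
    """Maximized log-likelihood of logit(P(y=1)) = a + b*x."""
    X = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                warnings.warn("logistic fit did not fully converge (possible separation)", stacklevel=3)
            return float(res.llf)
        except Exception:  # perfect separation or singular design
            warnings.warn("logistic fit failed (possible complete separation); using null likelihood", stacklevel=3)
            p = y.mean()
            if p in (0.0, 1.0):
                return 0.0
            n1 = y.sum()
            n0 = len(y) - n1
            return float(n1 * np.log(p) + n0 * np.log(1 - p))


@dataclass
class CSIResults:
    """Grid-profile fit of the smoking-index decay parameters."""

    params: CSIParams
    loglik: float
    surface: pd.DataFrame  # tau x delta grid of log-likelihoods
    n: int

    def summary(self) -> str:
        lines = [
            "Comprehensive smoking index — profile grid fit",
            f"n samples: {self.n}",
            f"half-life tau:  {self.params.tau:g} years",
            f"lag delta:      {self.params.delta:g} years",
            f"log-likelihood: {self.loglik:.4f}",
        ]
        return "\n".join(lines)


class CSIModel:
    """Estimate (tau, delta) by maximizing the logistic log-likelihood of
    case status on the index over a parameter grid.

    Parameters
    ----------
    records : iterable of SmokingRecord, or DataFrame with columns
        ``smoke_dur``, ``smoke_int``, ``smoke_tsc``.
    outcome : binary array (1 = case).
    """

    def __init__(self, records: Iterable[SmokingRecord] | pd.DataFrame, outcome: Sequence[int]) -> None:
        if isinstance(records, pd.DataFrame):
            self.dur = records["smoke_dur"].to_numpy(dtype=float)
            self.int_ = records["smoke_int"].to_numpy(dtype=float)
            self.tsc = records["smoke_tsc"].to_numpy(dtype=float)
        else:
            recs = list(records)
            self.dur = np.array([r.dur for r in recs], dtype=float)
            self.int_ = np.array([r.int_ for r in recs], dtype=float)
            self.tsc = np.array([r.tsc for r in recs], dtype=float)
        self.outcome = np.asarray(outcome, dtype=float)
        if self.outcome.shape[0] != self.dur.shape[0]:
            raise ValueError("outcome length must match number of records")
        if self.outcome.sum() == 0 or self.outcome.sum() == len(self.outcome):
            raise ValueError("need at least one case and one control")

    def fit(
        self,
        tau_grid: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0),
        delta_grid: Sequence[float] = (0.0, 1.0, 2.0, 3.0),
    ) -> CSIResults:
        tau_grid = list(tau_grid)
        delta_grid = list(delta_grid)
        if not tau_grid or not delta_grid:
            raise ValueError("parameter grids must be non-empty")
        surface = pd.DataFrame(index=pd.Index(tau_grid, name="tau"), columns=pd.Index(delta_grid, name="delta"), dtype=float)
        best: tuple[float, float] | None = None
        best_ll = -np.inf
        # iterate smallest tau then smallest delta so ties keep the first point
        for tau in sorted(tau_grid):
            for delta in sorted(delta_grid):
                x = csi(params=CSIParams(tau, delta), dur=self.dur, int_=self.int_, tsc=self.tsc)
                ll = _loglik_logistic(np.asarray(x), self.outcome)
                surface.loc[tau, delta] = ll
                if ll > best_ll + 1e-9:
                    best_ll = ll
                    best = (tau, delta)
        assert best is not None
        return CSIResults(params=CSIParams(*best), loglik=best_ll, surface=surface, n=len(self.outcome))


def attach_csi(meta: pd.DataFrame, params: CSIParams, column: str = "csi") -> pd.DataFrame:
    """Return a copy of the sample metadata with a per-sample CSI column."""
    out = meta.copy()
    out[column] = csi(
        params=params,
        dur=meta["smoke_dur"].to_numpy(dtype=float),
        int_=meta["smoke_int"].to_numpy(dtype=float),
        tsc=meta["smoke_tsc"].to_numpy(dtype=float),
    )
    return out
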