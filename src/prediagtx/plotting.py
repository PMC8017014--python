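"""Plot helpers: curve-group trajectories and LITS p-value curves.

These are convenience views of fitted results, not publication figures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_curve_trajectories(
    differences: pd.DataFrame,
    days: pd.Series | np.ndarray,
    genes: list,
    ax=None,
    spline_df: int = 4,
):
    """Spline-smoothed case-minus-control trajectories for selected genes,
    days to diagnosis decreasing to the right (diagnosis at the right)."""
    import matplotlib.pyplot as plt

    from .genewise import natural_spline_basis

    if ax is None:
        _, ax = plt.subplots()
    d = np.asarray(days, dtype=float)
    grid = np.linspace(d.min(), d.max(), 100)
    X = np.column_stack([np.ones(d.size), natural_spline_basis(d, df=spline_df)])
    Xg = np.column_stack(
        [
            np.ones(grid.size),
            natural_spline_basis(
                grid, df=spline_df,
                boundary_knots=(d.min(), d.max()),
                interior_knots=np.quantile(d, np.linspace(0, 1, spline_df + 1)[1:-1]),
            ),
        ]
    )
    for gene in genes:
        y = differences.loc[gene].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        ax.plot(grid, Xg @ coef, lw=1)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("days to diagnosis")
    ax.set_ylabel("case - control (log2)")
    ax.invert_xaxis()
    return ax
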