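"""Probe-level preprocessing of bead-array intensities.

Pipeline: negative-control detection filtering, background correction by
per-array median negative-control subtraction (floored to keep intensities
positive), quantile normalization, log2 transform and probe-to-gene
collapsing.  The background model is deliberately simple — median-subtract
and floor — because the downstream statistics only require positive,
monotonically transformed intensities.

Conventions
-----------
Intensity matrices are pandas DataFrames with probes (or genes) in rows and
samples in columns.  Probe annotation is a DataFrame indexed by probe id
with columns ``gene_symbol`` (NaN when unannotated), ``quality_flag``
(True = poor quality) and ``is_negative_control``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ANNOT_COLUMNS = ("gene_symbol", "quality_flag", "is_negative_control")


@dataclass
class RawIntensityMatrix:
    """Probes x samples nonnegative intensities plus probe annotation."""

    values: pd.DataFrame
    probe_annot: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("probe ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("raw intensities must be nonnegative")
        missing = self.values.index.difference(self.probe_annot.index)
        if len(missing):
            raise ValueError(f"probes missing from annotation: {list(missing[:5])}")
        self.probe_annot = self.probe_annot.loc[self.values.index]

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def negative_controls(self) -> pd.DataFrame:
        return self.values.loc[self.probe_annot["is_negative_control"].astype(bool)]

    def regular_probes(self) -> pd.DataFrame:
        return self.values.loc[~self.probe_annot["is_negative_control"].astype(bool)]


def _require_negative_controls(raw: RawIntensityMatrix) -> pd.DataFrame:
    neg = raw.negative_controls()
    if neg.shape[0] == 0:
        raise ValueError("no negative-control probes present on the arrays")
    return neg


def background_correct(raw: RawIntensityMatrix, offset: float = 1.0) -> RawIntensityMatrix:
    """Subtract each array's median negative-control intensity, floor at
    ``offset`` and drop the negative-control probes.

    The floor guarantees strictly positive intensities so the later log2
    transform is defined.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    neg = _require_negative_controls(raw)
    background = neg.median(axis=0)
    corrected = raw.regular_probes().sub(background, axis=1).clip(lower=offset)
    keep = corrected.index
    return RawIntensityMatrix(corrected, raw.probe_annot.loc[keep])


def detection_filter(
    raw: RawIntensityMatrix,
    min_frac: float = 0.10,
    quantile: float = 0.95,
) -> RawIntensityMatrix:
    """Remove undetected, unannotated and quality-flagged probes.

    A probe is called detected in a sample when its intensity exceeds the
    ``quantile`` (default 0.95, mirroring a detection-p < 0.05 convention)
    of that array's negative-control intensities.  Probes detected in at
    least ``min_frac`` of samples (boundary inclusive) that carry a gene
    annotation and no quality flag are kept.  Negative controls pass
    through untouched so background correction can follow.

    Detection calls are invariant to any per-array monotone shift, so the
    filter may equivalently run before or after background correction; the
    standard pipeline runs it first, on raw intensities.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    neg = _require_negative_controls(raw)
    threshold = neg.quantile(quantile, axis=0)
    regular = raw.regular_probes()
    detected_frac = regular.gt(threshold, axis=1).mean(axis=1)
    annot = raw.probe_annot.loc[regular.index]
    annotated = annot["gene_symbol"].notna() & (annot["gene_symbol"].astype(str).str.len() > 0)
    good_quality = ~annot["quality_flag"].astype(bool)
    keep = regular.index[(detected_frac >= min_frac) & annotated & good_quality]
    if len(keep) == 0:
        raise ValueError("no probes survive the detection/annotation filter")
    kept_index = keep.union(neg.index, sort=False)
    values = raw.values.loc[raw.values.index.intersection(kept_index, sort=False)]
    return RawIntensityMatrix(values, raw.probe_annot.loc[values.index])


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the identical empirical distribution.

    The reference distribution is the across-column mean of order
    statistics.  Ties within a column receive the mean of the reference
    values at their tied ranks (so a fully constant column maps to the
    grand mean of the reference).
    """
    x = values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantile normalization requires a complete matrix")
    n, m = x.shape
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(m):
        order = np.argsort(x[:, j], kind="mergesort")
        col_sorted = x[order, j]
        # contiguous tie groups in the sorted column
        grp = np.concatenate(([0], np.cumsum(np.diff(col_sorted) != 0)))
        sums = np.bincount(grp, weights=reference)
        counts = np.bincount(grp)
        out[order, j] = (sums / counts)[grp]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log2_and_collapse(
    values: pd.DataFrame,
    probe_annot: pd.DataFrame,
    collapse_rule: str = "max_mean",
) -> pd.DataFrame:
    """log2-transform and collapse probes to one row per gene symbol.

    When several probes map to the same gene the probe with the highest
    mean intensity is kept (``max_mean``, the only implemented rule).
    Unannotated probes are dropped.  Returns a genes x samples DataFrame of
    log2 expression, rows sorted by gene symbol.
    """
    if collapse_rule != "max_mean":
        raise ValueError(f"unknown collapse rule: {collapse_rule!r}")
    arr = values.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValueError("log2 transform requires strictly positive values")
    annot = probe_annot.loc[values.index]
    symbols = annot["gene_symbol"]
    keep = symbols.notna() & (symbols.astype(str).str.len() > 0)
    values = values.loc[keep]
    symbols = symbols[keep].astype(str)
    means = values.mean(axis=1)
    best = means.groupby(symbols).idxmax()
    collapsed = values.loc[best.to_numpy()]
    collapsed.index = pd.Index(best.index, name="gene")
    expr = np.log2(collapsed).sort_index()
    if not expr.index.is_unique:
        raise AssertionError("gene ids not unique after collapsing")
    return expr


def run_preprocess(
    raw: RawIntensityMatrix,
    offset: float = 1.0,
    min_frac: float = 0.10,
    detection_quantile: float = 0.95,
    collapse_rule: str = "max_mean",
) -> pd.DataFrame:
    """Full preprocessing: filter, background-correct, quantile-normalize,
    log2 and collapse to genes.  Returns the analysis-ready expression
    matrix (genes x samples, log2 scale)."""
    filtered = detection_filter(raw, min_frac=min_frac, quantile=detection_quantile)
    corrected = background_correct(filtered, offset=offset)
    normalized = quantile_normalize(corrected.values)
    return log2_and_collapse(normalized, corrected.probe_annot, collapse_rule=collapse_rule)
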