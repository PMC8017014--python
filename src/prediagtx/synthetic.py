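"""Synthetic matched case-control cohort generator.

Emulates the data-generating structure the analysis assumes: matched
case-control pairs sampled 0.2-7.2 years before the case's diagnosis,
whole-blood expression driven by a cell-type signature and per-sample cell
fractions (with a neutrophil shift in cases), planted case-minus-control
time-trend genes following predefined curve shapes, negative-control
probes carrying background only, and smoking covariates whose association
with case status runs through the cumulative smoking index.

All randomness flows from ``SyntheticConfig.seed``; two calls with the
same config are bit-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design
from .preprocess import RawIntensityMatrix
from .smoking import CSIParams, csi

CELL_TYPE_NAMES = (
    "Neutrophils",
    "T cells CD8",
    "T cells CD4",
    "B cells",
    "NK cells",
    "Monocytes",
)
# baseline mean blood composition for the default six populations
_BASE_COMPOSITION = (0.34, 0.18, 0.16, 0.10, 0.08, 0.14)

LYMPHOCYTE_PATTERN = r"T cells|B cells|NK|Plasma"


@dataclass(frozen=True)
class SmokingParams:
    """Population smoking-history distributions and the strength of the
    smoking-to-outcome link (through the smoking index)."""

    p_current: float = 0.45
    p_former: float = 0.28
    dur_mean: float = 28.0
    dur_sd: float = 9.0
    int_mean: float = 12.0
    int_shape: float = 4.0
    tsc_mean: float = 10.0
    true_tau: float = 2.0
    true_delta: float = 1.0
    beta: float = 1.5  # log-odds of case status per unit CSI


@dataclass(frozen=True)
class SyntheticConfig:
    n_pairs: int = 128
    frac_metastatic: float = 100 / 128
    n_genes: int = 2000
    n_negative_controls: int = 50
    n_cell_types: int = 6
    days_range: tuple[float, float] = design.DAYS_RANGE
    planted_trends: tuple[tuple[str, int, float], ...] = ()
    neutrophil_shift: float = 0.02
    noise_sd_log2: float = 0.3
    smoking_params: SmokingParams = field(default_factory=SmokingParams)
    seed: int = 0
    exact_counts: bool = False
    # nuisance structure
    n_unannotated: int = 8
    n_low_quality: int = 8
    markers_per_type: int = 30
    dirichlet_concentration: float = 150.0
    background_mean: float = 80.0
    background_sd_log2: float = 0.15
    signal_scale: float = 30.0
    n_batches: int = 4
    cutoffs: tuple[float, float] = design.DEFAULT_CUTOFFS

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be at least 2")
        if not 0 <= self.frac_metastatic <= 1:
            raise ValueError("frac_metastatic must be in [0, 1]")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be nonnegative")
        lo, hi = self.days_range
        if not 0 < lo < hi:
            raise ValueError("days_range must satisfy 0 < min < max")
        planted = sum(n for _, n, _ in self.planted_trends)
        if planted > self.n_genes:
            raise ValueError("planted trend gene counts exceed n_genes")
        if self.n_cell_types < 2:
            raise ValueError("need at least 2 cell types")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator for recovery tests."""

    trend_genes: dict[str, list[str]]
    fractions: pd.DataFrame  # samples x cell types, sum to 1
    csi_params: CSIParams
    trend_effects: pd.DataFrame | None = None  # genes x pairs planted log2 case-control effect


def _cell_type_names(k: int) -> list[str]:
    names = list(CELL_TYPE_NAMES)
    while len(names) < k:
        names.append(f"Cell type {len(names) + 1}")
    return names[:k]


def _base_composition(k: int) -> np.ndarray:
    base = np.asarray(_BASE_COMPOSITION, dtype=float)
    if k <= base.size:
        comp = base[:k]
    else:
        comp = np.concatenate([base, np.full(k - base.size, base.min())])
    return comp / comp.sum()


def _window_centers(cfg: SyntheticConfig) -> np.ndarray:
    lo, hi = cfg.days_range
    c1, c2 = cfg.cutoffs
    return np.array([(lo + c1) / 2, (c1 + c2) / 2, (c2 + hi) / 2])


def trend_effect_curve(days: np.ndarray, label: str, max_effect: float, cfg: SyntheticConfig) -> np.ndarray:
    """Planted case-minus-control log2 effect as a function of days to
    diagnosis: piecewise linear through the three window centers, ordered
    so that the window listed first in ``label`` has the largest mean."""
    if sorted(label) != ["1", "2", "3"]:
        raise ValueError(f"invalid curve label: {label!r}")
    centers = _window_centers(cfg)
    targets = np.empty(3)
    for pos, ch in enumerate(label):  # pos 0 = highest window
        targets[int(ch) - 1] = max_effect * (2 - pos) / 2
    return np.interp(days, centers, targets)


def _simulate_smoking(rng: np.random.Generator, n: int, sp: SmokingParams) -> pd.DataFrame:
    status = rng.choice(
        ["current", "former", "never"],
        size=n,
        p=[sp.p_current, sp.p_former, 1 - sp.p_current - sp.p_former],
    )
    dur = np.clip(rng.normal(sp.dur_mean, sp.dur_sd, size=n), 1.0, 55.0)
    inten = rng.gamma(sp.int_shape, sp.int_mean / sp.int_shape, size=n)
    tsc = rng.exponential(sp.tsc_mean, size=n)
    dur[status == "never"] = 0.0
    inten[status == "never"] = 0.0
    tsc[status != "former"] = 0.0
    tsc[status == "never"] = 0.0
    return pd.DataFrame({"smoking_status": status, "smoke_dur": dur, "smoke_int": inten, "smoke_tsc": tsc})


def _assign_smoking_roles(
    rng: np.random.Generator, n_pairs: int, sp: SmokingParams
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw two smoking histories per pair and assign the case role by a
    conditional logistic draw on the true smoking index, so case status
    genuinely depends on smoking through (true_tau, true_delta).

    Returns the 2*n_pairs-row record table and an index array
    ``member_rows[p] = (case_row, control_row)``.
    """
    smoking = _simulate_smoking(rng, 2 * n_pairs, sp)
    true_params = CSIParams(sp.true_tau, sp.true_delta)
    x2 = csi(
        params=true_params,
        dur=smoking["smoke_dur"].to_numpy(),
        int_=smoking["smoke_int"].to_numpy(),
        tsc=smoking["smoke_tsc"].to_numpy(),
    )
    x2 = np.asarray(x2).reshape(n_pairs, 2)
    p_first_is_case = 1.0 / (1.0 + np.exp(-sp.beta * (x2[:, 0] - x2[:, 1])))
    first_is_case = rng.random(n_pairs) < p_first_is_case
    member_rows = np.empty((n_pairs, 2), dtype=int)
    for p in range(n_pairs):
        a, b = 2 * p, 2 * p + 1
        member_rows[p] = (a, b) if first_is_case[p] else (b, a)
    return smoking, member_rows


def simulate_smoking_cohort(
    n_pairs: int, params: SmokingParams = SmokingParams(), seed: int = 0
) -> pd.DataFrame:
    """Matched-pair smoking histories with case status linked to the true
    smoking index; covariate table for smoking-index recovery studies.

    Returns a DataFrame with columns ``pair_id``, ``role``,
    ``smoking_status``, ``smoke_dur``, ``smoke_int``, ``smoke_tsc``.
    """
    rng = np.random.default_rng(seed)
    smoking, member_rows = _assign_smoking_roles(rng, n_pairs, params)
    rows = []
    for p in range(n_pairs):
        for role, row in zip(("case", "control"), member_rows[p]):
            rec = smoking.iloc[row]
            rows.append(
                {
                    "pair_id": f"pair{p:04d}",
                    "role": role,
                    "smoking_status": rec["smoking_status"],
                    "smoke_dur": float(rec["smoke_dur"]),
                    "smoke_int": float(rec["smoke_int"]),
                    "smoke_tsc": float(rec["smoke_tsc"]),
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[RawIntensityMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one synthetic cohort.

    Returns ``(raw, meta, signature, truth)`` where ``raw`` is the
    probe-level intensity matrix with annotation, ``meta`` the per-sample
    covariate table (indexed by sample id), ``signature`` the marker-gene x
    cell-type linear-scale reference used for deconvolution, and ``truth``
    the planted ground truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sp = cfg.smoking_params
    n_pairs = cfg.n_pairs

    # --- pair-level structure -------------------------------------------
    pair_ids = [f"pair{p:04d}" for p in range(n_pairs)]
    lo, hi = cfg.days_range
    days = rng.uniform(lo, hi, size=n_pairs)
    if cfg.exact_counts:
        n_meta = int(round(cfg.frac_metastatic * n_pairs))
        metastatic = np.zeros(n_pairs, dtype=bool)
        metastatic[rng.choice(n_pairs, size=n_meta, replace=False)] = True
    else:
        metastatic = rng.random(n_pairs) < cfg.frac_metastatic
    age = np.round(np.clip(rng.normal(56.6, 4.0, size=n_pairs), 35, 75), 1)
    batch = rng.integers(0, cfg.n_batches, size=n_pairs)

    # --- smoking histories and case-role assignment ---------------------
    smoking, member_rows = _assign_smoking_roles(rng, n_pairs, sp)
    true_params = CSIParams(sp.true_tau, sp.true_delta)

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    for p in range(n_pairs):
        for role, row in zip(("case", "control"), member_rows[p]):
            sid = f"{pair_ids[p]}_{role}"
            sample_ids.append(sid)
            rec = smoking.iloc[row]
            meta_rows.append(
                {
                    "sample_id": sid,
                    "pair_id": pair_ids[p],
                    "role": role,
                    "days_to_diagnosis": days[p],
                    "metastatic": bool(metastatic[p]),
                    "age": age[p],
                    "batch": int(batch[p]),
                    "smoking_status": rec["smoking_status"],
                    "smoke_dur": float(rec["smoke_dur"]),
                    "smoke_int": float(rec["smoke_int"]),
                    "smoke_tsc": float(rec["smoke_tsc"]),
                }
            )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    # --- cell fractions --------------------------------------------------
    k = cfg.n_cell_types
    type_names = _cell_type_names(k)
    comp = _base_composition(k)
    comp_case = comp.copy()
    comp_case[0] = comp_case[0] + cfg.neutrophil_shift  # neutrophils listed first
    comp_case = comp_case / comp_case.sum()
    conc = cfg.dirichlet_concentration
    frac_case = rng.dirichlet(comp_case * conc, size=n_pairs)
    frac_ctrl = rng.dirichlet(comp * conc, size=n_pairs)
    fractions = np.empty((2 * n_pairs, k))
    fractions[0::2] = frac_case
    fractions[1::2] = frac_ctrl
    fractions_df = pd.DataFrame(fractions, index=sample_ids, columns=type_names)

    # --- reference expression and signature ------------------------------
    n_genes = cfg.n_genes
    gene_ids = [f"GENE{g:05d}" for g in range(n_genes)]
    reference = rng.lognormal(mean=3.0, sigma=1.0, size=(n_genes, k))
    n_markers = min(cfg.markers_per_type * k, n_genes)
    markers_per_type = n_markers // k
    marker_rows: list[int] = []
    for t in range(k):
        rows = range(t * markers_per_type, (t + 1) * markers_per_type)
        for g in rows:
            boost = np.ones(k)
            boost[t] = 8.0
            reference[g] = rng.lognormal(mean=3.0, sigma=0.5) * boost
            marker_rows.append(g)
    signature = pd.DataFrame(
        reference[marker_rows],
        index=[gene_ids[g] for g in marker_rows],
        columns=type_names,
    )

    # --- planted time trends ---------------------------------------------
    trend_genes: dict[str, list[str]] = {}
    effects = np.zeros((n_genes, n_pairs))
    next_gene = n_markers  # plant trends outside the marker block
    for label, n_tr, max_eff in cfg.planted_trends:
        rows = list(range(next_gene, next_gene + n_tr))
        if rows and rows[-1] >= n_genes:
            raise ValueError("not enough non-marker genes to plant all trends")
        next_gene += n_tr
        trend_genes[label] = [gene_ids[g] for g in rows]
        curve = trend_effect_curve(days, label, max_eff, cfg)
        for g in rows:
            effects[g] = curve

    # --- assemble intensities --------------------------------------------
    bulk = reference @ fractions.T  # genes x samples, linear scale
    log2_effect = np.zeros((n_genes, 2 * n_pairs))
    log2_effect[:, 0::2] = effects  # cases only
    noise = rng.normal(0.0, cfg.noise_sd_log2, size=(n_genes, 2 * n_pairs))
    signal = cfg.signal_scale * bulk * 2.0 ** (log2_effect + noise)

    n_extra = cfg.n_unannotated + cfg.n_low_quality
    extra_ref = rng.lognormal(mean=3.0, sigma=1.0, size=(n_extra, k))
    extra_signal = cfg.signal_scale * (extra_ref @ fractions.T) * 2.0 ** rng.normal(
        0.0, cfg.noise_sd_log2, size=(n_extra, 2 * n_pairs)
    )

    n_all_probes = n_genes + n_extra + cfg.n_negative_controls
    background = cfg.background_mean * 2.0 ** rng.normal(
        0.0, cfg.background_sd_log2, size=(n_all_probes, 2 * n_pairs)
    )
    array_factor = 2.0 ** rng.normal(0.0, 0.1, size=2 * n_pairs)

    intensities = np.vstack(
        [
            background[:n_genes] + signal,
            background[n_genes : n_genes + n_extra] + extra_signal,
            background[n_genes + n_extra :],
        ]
    ) * array_factor[None, :]

    probe_ids = (
        [f"PROBE{g:05d}" for g in range(n_genes + n_extra)]
        + [f"NEGCTRL{g:04d}" for g in range(cfg.n_negative_controls)]
    )
    gene_symbol = (
        gene_ids
        + [None] * cfg.n_unannotated
        + [f"LOWQ{g:04d}" for g in range(cfg.n_low_quality)]
        + [None] * cfg.n_negative_controls
    )
    quality_flag = (
        [False] * (n_genes + cfg.n_unannotated)
        + [True] * cfg.n_low_quality
        + [False] * cfg.n_negative_controls
    )
    is_neg = [False] * (n_genes + n_extra) + [True] * cfg.n_negative_controls
    annot = pd.DataFrame(
        {"gene_symbol": gene_symbol, "quality_flag": quality_flag, "is_negative_control": is_neg},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    values = pd.DataFrame(intensities, index=annot.index, columns=sample_ids)
    raw = RawIntensityMatrix(values, annot)

    truth = SyntheticTruth(
        trend_genes=trend_genes,
        fractions=fractions_df,
        csi_params=true_params,
        trend_effects=pd.DataFrame(effects, index=gene_ids, columns=pair_ids),
    )
    return raw, meta, signature, truth


# ---------------------------------------------------------------------------
# fixture I/O: everything as UTF-8 tab-separated text


def write_fixture(directory: str | os.PathLike, cohort: tuple) -> dict[str, str]:
    """Write a generated cohort as tab-separated text files.

    Returns the mapping of component name to file path.  The files
    round-trip losslessly through :func:`read_fixture`.
    """
    raw, meta, signature, truth = cohort
    directory = os.fspath(directory)
    if not os.path.isdir(directory):
        raise FileNotFoundError(f"fixture directory does not exist: {directory}")
    paths = {
        "intensities": os.path.join(directory, "intensities.tsv"),
        "probe_annot": os.path.join(directory, "probe_annot.tsv"),
        "metadata": os.path.join(directory, "metadata.tsv"),
        "signature": os.path.join(directory, "signature.tsv"),
        "truth_fractions": os.path.join(directory, "truth_fractions.tsv"),
        "truth_trend_genes": os.path.join(directory, "truth_trend_genes.tsv"),
        "truth_params": os.path.join(directory, "truth_params.tsv"),
    }
    raw.values.to_csv(paths["intensities"], sep="\t")
    raw.probe_annot.to_csv(paths["probe_annot"], sep="\t")
    meta.to_csv(paths["metadata"], sep="\t")
    signature.to_csv(paths["signature"], sep="\t")
    truth.fractions.to_csv(paths["truth_fractions"], sep="\t")
    rows = [
        {"curve_label": label, "gene": g}
        for label, genes in sorted(truth.trend_genes.items())
        for g in genes
    ]
    pd.DataFrame(rows, columns=["curve_label", "gene"]).to_csv(paths["truth_trend_genes"], sep="\t", index=False)
    pd.DataFrame(
        {"param": ["tau", "delta"], "value": [truth.csi_params.tau, truth.csi_params.delta]}
    ).to_csv(paths["truth_params"], sep="\t", index=False)
    return paths


def read_fixture(directory: str | os.PathLike) -> tuple[RawIntensityMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Read a cohort previously written by :func:`write_fixture`."""
    directory = os.fspath(directory)
    values = pd.read_csv(os.path.join(directory, "intensities.tsv"), sep="\t", index_col=0)
    annot = pd.read_csv(os.path.join(directory, "probe_annot.tsv"), sep="\t", index_col=0)
    annot["gene_symbol"] = annot["gene_symbol"].where(annot["gene_symbol"].notna(), None)
    raw = RawIntensityMatrix(values, annot)
    meta = pd.read_csv(os.path.join(directory, "metadata.tsv"), sep="\t", index_col=0)
    signature = pd.read_csv(os.path.join(directory, "signature.tsv"), sep="\t", index_col=0)
    fractions = pd.read_csv(os.path.join(directory, "truth_fractions.tsv"), sep="\t", index_col=0)
    trend = pd.read_csv(os.path.join(directory, "truth_trend_genes.tsv"), sep="\t")
    trend_genes: dict[str, list[str]] = {}
    for label, grp in trend.groupby("curve_label"):
        trend_genes[str(label)] = list(grp["gene"])
    params = pd.read_csv(os.path.join(directory, "truth_params.tsv"), sep="\t").set_index("param")["value"]
    truth = SyntheticTruth(
        trend_genes=trend_genes,
        fractions=fractions,
        csi_params=CSIParams(float(params["tau"]), float(params["delta"])),
    )
    return raw, meta, signature, truth
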