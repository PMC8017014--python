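"""End-to-end orchestration of the analysis stages.

Stage DAG: simulate -> preprocess -> {csi, deconvolution, differences} ->
{curve groups, LITS, gene-wise tests} -> enrichment -> report.  A single
``RunConfig`` (optionally loaded from YAML) carries all paths, stage
toggles, parameters and seeds; every output table records the seed and
parameters in comment headers, so identical configs reproduce identical
files.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import design
from .curvegroups import CurveGroupModel, WindowSpec
from .deconvolution import (
    DeconvolutionModel,
    LT3Y_DAYS,
    filter_populations,
    fraction_time_trend,
    group_tests,
    nlr,
)
from .enrichment import ora, read_gmt
from .genewise import PairedDifferenceModel, SplineTrendModel, cumulative_by_year, top_n_overlap
from .lits import LITSModel
from .preprocess import run_preprocess
from .smoking import CSIModel, attach_csi
from .synthetic import SyntheticConfig, generate_cohort, write_fixture

logger = logging.getLogger("prediagtx")


def make_differences(
    expr: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Case-minus-control log2 differences per gene and pair.

    Returns ``(D, pair_meta)``: D is genes x pairs; pair_meta (indexed by
    pair id) carries days to diagnosis, metastasis flag, and the
    case-minus-control smoking-index difference when a ``csi`` column is
    present in the sample metadata.
    """
    pairs = meta.groupby("pair_id")
    case_cols, ctrl_cols, pair_rows = [], [], []
    for pair_id, grp in pairs:
        roles = grp["role"].value_counts()
        if roles.get("case", 0) != 1 or roles.get("control", 0) != 1:
            raise ValueError(f"incomplete pair: {pair_id!r}")
        case = grp.index[grp["role"] == "case"][0]
        ctrl = grp.index[grp["role"] == "control"][0]
        case_cols.append(case)
        ctrl_cols.append(ctrl)
        row = {
            "pair_id": pair_id,
            "days_to_diagnosis": float(grp["days_to_diagnosis"].iloc[0]),
            "metastatic": bool(grp["metastatic"].iloc[0]),
        }
        if "csi" in meta.columns:
            row["delta_csi"] = float(meta.loc[case, "csi"] - meta.loc[ctrl, "csi"])
        pair_rows.append(row)
    pair_meta = pd.DataFrame(pair_rows).set_index("pair_id")
    D = pd.DataFrame(
        expr[case_cols].to_numpy() - expr[ctrl_cols].to_numpy(),
        index=expr.index,
        columns=pair_meta.index,
    )
    return D, pair_meta


def subset_pairs(pair_meta: pd.DataFrame, subset: str) -> pd.Index:
    """Pair ids belonging to 'all', 'metastatic' or 'metastatic_lt3y'."""
    if subset == "all":
        return pair_meta.index
    if subset == "metastatic":
        return pair_meta.index[pair_meta["metastatic"]]
    if subset == "metastatic_lt3y":
        return pair_meta.index[
            pair_meta["metastatic"] & (pair_meta["days_to_diagnosis"] < LT3Y_DAYS)
        ]
    raise ValueError(f"unknown subset: {subset!r}")


@dataclass
class RunConfig:
    """All stage parameters, paths, toggles and seeds for one run."""

    output_dir: str = "prediagtx_output"
    seed: int = 0
    # synthetic cohort (used when no input fixture is given)
    synthetic: dict = field(default_factory=dict)
    fixture_dir: str | None = None
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate",
        "preprocess",
        "csi",
        "deconvolution",
        "curvegroups",
        "lits",
        "genewise",
        "enrichment",
    )
    # stage parameters
    offset: float = 1.0
    min_frac: float = 0.10
    detection_quantile: float = 0.95
    cutoffs: tuple[float, float] = design.DEFAULT_CUTOFFS
    alpha0: float = 0.2
    lits_window: int = design.DEFAULT_LITS_WINDOW
    n_permutations: int = 999
    fdr_levels: tuple[float, ...] = (0.05, 0.1)
    top_n: int = 100
    min_mean_fraction: float = 0.05
    subset: str = "metastatic"
    gmt_path: str | None = None
    tau_grid: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0)
    delta_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "cutoffs", "fdr_levels", "tau_grid", "delta_grid"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _write_table(df: pd.DataFrame, path: str, header: dict[str, Any]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in header.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t")


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the enabled stages in DAG order; returns the report dict.

    Any stage failure aborts with the stage name attached to the error.
    """
    report: dict[str, Any] = {"config": asdict(config), "stages": {}}
    os.makedirs(config.output_dir, exist_ok=True)
    state: dict[str, Any] = {}

    def run_stage(name: str, func) -> None:
        if name not in config.stages:
            logger.info("stage %s disabled", name)
            return
        t0 = time.perf_counter()
        logger.info("stage %s: starting", name)
        try:
            func()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        report["stages"][name] = {"seconds": round(dt, 3)}
        logger.info("stage %s: done in %.1fs", name, dt)

    def stage_simulate() -> None:
        if config.fixture_dir is not None:
            from .synthetic import read_fixture

            state["cohort"] = read_fixture(config.fixture_dir)
        else:
            syn = SyntheticConfig(seed=config.seed, **config.synthetic)
            state["cohort"] = generate_cohort(syn)
        raw, meta, signature, truth = state["cohort"]
        state.update(raw=raw, meta=meta, signature=signature, truth=truth)
        report["stages"].setdefault("simulate", {})
        report["n_pairs"] = int(meta["pair_id"].nunique())
        report["n_metastatic"] = int(meta.loc[meta["role"] == "case", "metastatic"].sum())

    def stage_preprocess() -> None:
        if "raw" not in state:
            raise RuntimeError("preprocess requires the simulate stage")
        expr = run_preprocess(
            state["raw"],
            offset=config.offset,
            min_frac=config.min_frac,
            detection_quantile=config.detection_quantile,
        )
        state["expr"] = expr
        report["n_genes"] = int(expr.shape[0])
        _write_table(
            expr,
            os.path.join(config.output_dir, "expression_log2.tsv"),
            {"seed": config.seed, "stage": "preprocess"},
        )

    def stage_csi() -> None:
        meta = state["meta"]
        model = CSIModel(meta, (meta["role"] == "case").astype(int).to_numpy())
        res = model.fit(config.tau_grid, config.delta_grid)
        state["csi_params"] = res.params
        state["meta"] = attach_csi(meta, res.params)
        report["csi"] = {"tau": res.params.tau, "delta": res.params.delta, "loglik": res.loglik}
        _write_table(
            state["meta"][["csi"]],
            os.path.join(config.output_dir, "csi.tsv"),
            {"seed": config.seed, "tau": res.params.tau, "delta": res.params.delta},
        )

    def stage_deconvolution() -> None:
        expr_linear = 2.0 ** state["expr"]
        fracs = DeconvolutionModel(expr_linear, state["signature"]).fit()
        fracs.nlr = nlr(fracs)
        state["fractions"] = fracs
        kept = filter_populations(fracs, config.min_mean_fraction)
        tests = group_tests(kept, state["meta"], subset="all")
        trend = fraction_time_trend(kept, state["meta"])
        report["deconvolution"] = {
            "cell_types_kept": kept.cell_types,
            "median_nlr": float(fracs.nlr.median()),
        }
        out = fracs.fractions.copy()
        out["NLR"] = fracs.nlr
        _write_table(out, os.path.join(config.output_dir, "cell_fractions.tsv"), {"seed": config.seed})
        _write_table(tests, os.path.join(config.output_dir, "fraction_tests.tsv"), {"subset": "all"})
        _write_table(trend, os.path.join(config.output_dir, "fraction_trends.tsv"), {"df": 3})

    def make_diffs() -> None:
        if "D" in state:
            return
        D, pair_meta = make_differences(state["expr"], state["meta"])
        state["D"], state["pair_meta"] = D, pair_meta

    def stage_curvegroups() -> None:
        make_diffs()
        ids = subset_pairs(state["pair_meta"], config.subset)
        sub = state["pair_meta"].loc[ids]
        model = CurveGroupModel(
            state["D"][ids], sub["days_to_diagnosis"], WindowSpec(*config.cutoffs)
        )
        res = model.fit(alpha0=config.alpha0, n_permutations=config.n_permutations, seed=config.seed)
        state["curvegroups"] = res
        report["curvegroups"] = {
            "p_global": res.p_global,
            "observed_global": int(res.table.loc["global", "observed"]),
            "expected_global": float(res.table.loc["global", "expected"]),
        }
        _write_table(
            res.table,
            os.path.join(config.output_dir, "curve_groups.tsv"),
            {"seed": config.seed, "alpha0": config.alpha0, "B": config.n_permutations,
             "subset": config.subset, "cutoffs": config.cutoffs},
        )

    def stage_lits() -> None:
        make_diffs()
        ids = subset_pairs(state["pair_meta"], config.subset)
        sub = state["pair_meta"].loc[ids]
        model = LITSModel(state["D"][ids], sub["days_to_diagnosis"], k=config.lits_window)
        res = model.fit(n_permutations=config.n_permutations, seed=config.seed)
        state["lits"] = res
        best = res.best_window()
        report["lits"] = {
            "n_windows": len(res.table),
            "min_p_adjusted": res.min_p_adjusted,
            "best_window_days": [float(best["day_min"]), float(best["day_max"])],
        }
        _write_table(
            res.table.set_index("window"),
            os.path.join(config.output_dir, "lits.tsv"),
            {"seed": config.seed, "k": config.lits_window, "B": config.n_permutations,
             "subset": config.subset},
        )

    def stage_genewise() -> None:
        make_diffs()
        D, pair_meta = state["D"], state["pair_meta"]
        results = {}
        for subset in ("all", "metastatic", "metastatic_lt3y"):
            ids = subset_pairs(pair_meta, subset)
            if len(ids) < 3:
                continue
            res = PairedDifferenceModel(D[ids]).fit()
            results[f"L {subset}"] = res
            _write_table(
                res.table,
                os.path.join(config.output_dir, f"genewise_{subset}.tsv"),
                {"analysis": res.analysis, "subset": subset},
            )
        for subset in ("all", "metastatic"):
            ids = subset_pairs(pair_meta, subset)
            if len(ids) < 5:
                continue
            res = SplineTrendModel(
                D[ids], pair_meta.loc[ids, "days_to_diagnosis"]
            ).fit()
            results[f"S {subset}"] = res
            _write_table(
                res.table,
                os.path.join(config.output_dir, f"spline_{subset}.tsv"),
                {"analysis": res.analysis, "subset": subset},
            )
        state["genewise"] = results
        meta_ids = subset_pairs(pair_meta, "metastatic")
        cumulative = cumulative_by_year(
            D[meta_ids],
            pair_meta.loc[meta_ids, "days_to_diagnosis"],
            fdr_levels=config.fdr_levels,
        )
        _write_table(
            cumulative, os.path.join(config.output_dir, "cumulative_by_year.tsv"), {"subset": "metastatic"}
        )
        overlap = top_n_overlap(results, n=config.top_n) if len(results) >= 2 else None
        if overlap is not None:
            _write_table(overlap, os.path.join(config.output_dir, "top_overlap.tsv"), {"n": config.top_n})
        report["genewise"] = {
            name: {"n_significant_fdr05": res.n_significant(0.05)} for name, res in results.items()
        }
        if overlap is not None:
            report["top_overlap"] = overlap.to_dict()
        state["cumulative"] = cumulative

    def stage_enrichment() -> None:
        if config.gmt_path is None:
            logger.info("no GMT collection supplied; enrichment uses curve-group lists only if present")
            return
        collection = read_gmt(config.gmt_path)
        universe = list(state["expr"].index)
        lists: dict[str, list] = {}
        if "genewise" in state:
            for name, res in state["genewise"].items():
                lists[name] = res.top_genes(config.top_n)
        if "curvegroups" in state:
            for label, genes in state["curvegroups"].designated.items():
                if genes:
                    lists[f"CG {label}"] = list(genes)
        enrich = {}
        for name, genes in lists.items():
            table = ora(genes, collection, universe)
            enrich[name] = table
            safe = name.replace(" ", "_")
            _write_table(table, os.path.join(config.output_dir, f"ora_{safe}.tsv"), {"list": name})
        report["enrichment"] = {name: int((t["q_value"] <= 0.05).sum()) for name, t in enrich.items()}

    run_stage("simulate", stage_simulate)
    run_stage("preprocess", stage_preprocess)
    run_stage("csi", stage_csi)
    run_stage("deconvolution", stage_deconvolution)
    run_stage("curvegroups", stage_curvegroups)
    run_stage("lits", stage_lits)
    run_stage("genewise", stage_genewise)
    run_stage("enrichment", stage_enrichment)
    report["seed"] = config.seed
    return report
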