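"""Model-summary and expenditure-comparison tables, and the pipeline driver.

Two report styles: per-cell regression summaries (R^2 at each step plus the
likelihood-ratio p-value, with "< 0.001" display below that magnitude) and
positive-deviant vs non-positive-deviant per-capita expenditure comparisons
by state and community type (min-max (mean), with a flag wherever the PD
group's mean is lower).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import Panel, load_panel, validate_panel, write_panel
from .errors import PosdevError, SchemaError
from .identify import (
    CellResults,
    ConsolidatedPDSet,
    DeviantCellResult,
    build_pd_matrix,
    consolidate,
    covariate_sensitivity,
    run_all_cells,
)
from .simulate import SimulationConfig, default_study_config, generate_panel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Table-1-style model summaries


@dataclass(frozen=True)
class ModelSummaryRow:
    state: str
    outcome: str
    year: int | str  # calendar year or "pooled"
    r2_step1: float
    r2_step2: float
    lrt_p: float


def format_p(p: float) -> str:
    """Display convention: values below 0.001 render as '< 0.001'."""
    if p < 0.001:
        return "< 0.001"
    return f"{p:.3f}"


def model_summary_table(results: Sequence[DeviantCellResult]) -> list[ModelSummaryRow]:
    rows = []
    for r in results:
        rows.append(
            ModelSummaryRow(
                state=r.state,
                outcome=r.outcome,
                year="pooled" if r.year is None else int(r.year),
                r2_step1=r.step1_fit.r_squared,
                r2_step2=r.step2_fit.r_squared,
                lrt_p=r.lrt.p_value,
            )
        )
    return rows


def model_summary_frame(rows: Sequence[ModelSummaryRow]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    if len(df):
        df["lrt_p_display"] = df["lrt_p"].map(format_p)
    return df


# ---------------------------------------------------------------------------
# Table-2-style expenditure comparisons


@dataclass(frozen=True)
class ExpenditureComparisonCell:
    state: str  # state name or "Combined"
    community_type: str
    group: str  # "PD" or "non-PD"
    n: int
    pct_of_group: float  # share of the group's state total, in percent
    stats: Mapping[str, tuple[float, float, float] | None]  # var -> (min, max, mean)
    pd_mean_lower: Mapping[str, bool | None]  # var -> True when PD mean < non-PD mean


def _jurisdiction_means(panel: Panel, variables: Sequence[str]) -> pd.DataFrame:
    """Per-jurisdiction values averaged over years first (no double counting)."""
    rm = panel.role_map
    cols = [rm.id_var, rm.state_var] + list(variables)
    df = panel.df[cols + [rm.year_var]]
    g = df.groupby([rm.id_var, rm.state_var], as_index=False)[list(variables)].mean()
    # community type is constant within jurisdiction; take the first value
    ct = panel.df.groupby(rm.id_var).first()
    return g, ct


def expenditure_comparison(
    panel: Panel,
    pd_set: ConsolidatedPDSet,
    expenditure_vars: Sequence[str] | None = None,
    community_var: str = "community_type",
) -> list[ExpenditureComparisonCell]:
    """PD vs non-PD expenditure summaries by state and community type.

    A jurisdiction's expenditure values are averaged across years before
    group statistics; each (stratum, variable) pair carries a flag set to
    True when the PD group's mean is below the non-PD group's.
    """
    rm = panel.role_map
    if expenditure_vars is None:
        expenditure_vars = list(rm.reporting_vars)
    bad = [v for v in expenditure_vars if v not in rm.reporting_vars]
    if bad:
        raise SchemaError(f"expenditure variables not declared as reporting vars: {bad}")
    if community_var not in panel.df.columns:
        raise SchemaError(f"community-type column {community_var!r} missing")

    per_j, first_row = _jurisdiction_means(panel, expenditure_vars)
    per_j = per_j.set_index(rm.id_var)
    per_j[community_var] = first_row[community_var]
    per_j["is_pd"] = [jid in pd_set for jid in per_j.index]

    levels = list(rm.categorical_vars.get(community_var, tuple(sorted(per_j[community_var].unique()))))
    cells: list[ExpenditureComparisonCell] = []

    def block(state_label: str, frame: pd.DataFrame) -> None:
        group_sizes = {g: int((frame["is_pd"] == (g == "PD")).sum()) for g in ("non-PD", "PD")}
        for ctype in levels:
            in_type = frame[frame[community_var] == ctype]
            means: dict[str, dict[str, float | None]] = {}
            rows = {}
            for gname, want in (("non-PD", False), ("PD", True)):
                sub = in_type[in_type["is_pd"] == want]
                stat: dict[str, tuple[float, float, float] | None] = {}
                for v in expenditure_vars:
                    if len(sub) == 0:
                        stat[v] = None
                    else:
                        vals = sub[v].to_numpy(dtype=float)
                        stat[v] = (float(vals.min()), float(vals.max()), float(vals.mean()))
                rows[gname] = (len(sub), stat)
            lower: dict[str, bool | None] = {}
            for v in expenditure_vars:
                a, b = rows["PD"][1][v], rows["non-PD"][1][v]
                lower[v] = None if (a is None or b is None) else bool(a[2] < b[2])
            for gname in ("non-PD", "PD"):
                n, stat = rows[gname]
                denom = group_sizes[gname]
                cells.append(
                    ExpenditureComparisonCell(
                        state=state_label,
                        community_type=ctype,
                        group=gname,
                        n=n,
                        pct_of_group=(100.0 * n / denom) if denom else 0.0,
                        stats=stat,
                        pd_mean_lower=lower,
                    )
                )

    for state in sorted(per_j[rm.state_var].unique()):
        block(state, per_j[per_j[rm.state_var] == state])
    block("Combined", per_j)
    return cells


def expenditure_comparison_frame(
    cells: Sequence[ExpenditureComparisonCell],
) -> pd.DataFrame:
    """Long-format frame, one row per (stratum, group, variable); display
    columns rounded to 2 decimals / whole percents, raw columns kept."""
    rows = []
    for c in cells:
        for v, stat in c.stats.items():
            vmin, vmax, vmean = (None, None, None) if stat is None else stat
            rows.append(
                {
                    "state": c.state,
                    "community_type": c.community_type,
                    "group": c.group,
                    "n": c.n,
                    "pct_of_group": c.pct_of_group,
                    "pct_display": f"{c.pct_of_group:.0f} %",
                    "variable": v,
                    "min": vmin,
                    "max": vmax,
                    "mean": vmean,
                    "display": (
                        "—" if stat is None else f"$ {vmin:.2f}–{vmax:.2f} ({vmean:.2f})"
                    ),
                    "pd_mean_lower": c.pd_mean_lower[v],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flags table


def flags_frame(results: Sequence[DeviantCellResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for (jid, year), score in sorted(r.scores.items()):
            rows.append(
                {
                    "jurisdiction_id": jid,
                    "state": r.state,
                    "outcome": r.outcome,
                    "year": year,
                    "score": score,
                    "flag": r.flags[(jid, year)],
                    "robust": r.robust[(jid, year)],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline driver


@dataclass
class PipelineConfig:
    """Configuration for a full run; loadable from YAML or JSON."""

    simulate: SimulationConfig | None = None
    panel_path: str | None = None
    role_map_path: str | None = None
    threshold: float = -1.0
    min_cells: int = 2
    correlation_cutoff: float = 0.8
    residual_source: str = "step2"
    pooled_years: bool = False
    whole_panel_exclusion: bool = False
    run_sensitivity: bool = True

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        return cls.from_dict(raw, seed=seed)

    @classmethod
    def from_dict(cls, raw: Mapping, seed: int | None = None) -> "PipelineConfig":
        sim = None
        simblock = raw.get("simulate")
        if simblock is not None:
            if simblock.get("default", True):
                sim_seed = seed if seed is not None else int(simblock.get("seed", 0))
                sim = default_study_config(sim_seed)
            else:
                sim = SimulationConfig.from_dict(simblock["config"])
        return cls(
            simulate=sim,
            panel_path=raw.get("panel"),
            role_map_path=raw.get("role_map"),
            threshold=float(raw.get("threshold", -1.0)),
            min_cells=int(raw.get("min_cells", 2)),
            correlation_cutoff=float(raw.get("correlation_cutoff", 0.8)),
            residual_source=str(raw.get("residual_source", "step2")),
            pooled_years=bool(raw.get("pooled_years", False)),
            whole_panel_exclusion=bool(raw.get("whole_panel_exclusion", False)),
            run_sensitivity=bool(raw.get("run_sensitivity", True)),
        )


@dataclass
class PipelineOutput:
    panel: Panel
    cell_results: CellResults
    pd_set: ConsolidatedPDSet
    out_dir: Path


def _config_hash(cfg: PipelineConfig) -> str:
    payload = {
        k: v
        for k, v in dataclasses.asdict(cfg).items()
        if k != "simulate"
    }
    if cfg.simulate is not None:
        payload["simulate"] = cfg.simulate.to_dict()
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: PipelineConfig | str | Path, out_dir: str | Path) -> PipelineOutput:
    """validate -> identify -> consolidate -> sensitivity -> reports.

    Writes the full artifact set to ``out_dir``; all data outputs are pure
    functions of the configuration, so rerunning with an identical config
    reproduces them byte for byte (timestamps live only in the manifest).
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        if config.simulate is not None:
            stage = "simulate"
            panel, truth = generate_panel(config.simulate)
            write_panel(panel, out / "panel.csv")
            (out / "ground_truth.json").write_text(truth.to_json())
            panel.role_map.to_file(out / "role_map.json")
        else:
            if config.panel_path is None or config.role_map_path is None:
                raise SchemaError("config must provide either a simulate block or panel + role_map paths")
            panel = load_panel(config.panel_path, config.role_map_path)

        stage = "validate"
        report = validate_panel(panel, whole_panel_exclusion=config.whole_panel_exclusion)
        (out / "validation.json").write_text(report.to_json())
        (out / "validation.txt").write_text(report.to_text())

        stage = "identify"
        cell_results = run_all_cells(
            panel,
            threshold=config.threshold,
            residual_source=config.residual_source,
            pooled_years=config.pooled_years,
        )
        flags_frame(cell_results.results).to_csv(out / "flags.csv", index=False)

        stage = "consolidate"
        matrix = build_pd_matrix(cell_results.results)
        entries = matrix.entries.copy()
        entries.columns = [f"{o}:{y}" for o, y in entries.columns]
        entries.to_csv(out / "pd_matrix.csv")
        pd_set = consolidate(matrix, config.min_cells, cell_results.results)
        (out / "consolidated.json").write_text(pd_set.to_json())

        if config.run_sensitivity:
            stage = "sensitivity"
            sens = covariate_sensitivity(
                panel, config.correlation_cutoff, config.threshold, config.residual_source
            )
            (out / "sensitivity.json").write_text(json.dumps(sens.to_dict(), indent=2))

        stage = "report"
        summary = model_summary_frame(model_summary_table(cell_results.results))
        summary.to_csv(out / "model_summary.csv", index=False)
        if panel.role_map.reporting_vars:
            comp = expenditure_comparison_frame(expenditure_comparison(panel, pd_set))
            comp.to_csv(out / "expenditure_comparison.csv", index=False)
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        (out / "failure.json").write_text(
            json.dumps({"stage": stage, "error": str(exc)}, indent=2)
        )
        raise

    import datetime

    manifest = {
        "config_hash": _config_hash(config),
        "seed": None if config.simulate is None else config.simulate.seed,
        "posdev_version": __version__,
        "n_records": len(panel),
        "n_cells": len(cell_results.results),
        "n_skipped": len(cell_results.skipped),
        "skipped": [dataclasses.asdict(s) for s in cell_results.skipped],
        "n_positive_deviants": len(pd_set.members),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineOutput(panel=panel, cell_results=cell_results, pd_set=pd_set, out_dir=out)
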