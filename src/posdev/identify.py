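"""Positive-deviant identification per (state, outcome, year) cell.

For each cell the three-step screen is: (1) regress the outcome on context
variables alone; (2) add mechanism variables; (3) compare the nested fits
with a likelihood-ratio test.  Externally studentized residuals from the
full model (step 2) are thresholded — strictly below -1 by default — to flag
candidate positive deviants; the LRT is reported, not gating, so every cell
uses the same residual source.  Influential leverage points are identified
and each cell is refit without them; a jurisdiction's flag is "robust" when
the two runs agree.  Flags across cells are assembled into a jurisdiction x
(outcome, year) matrix and consolidated: only jurisdictions flagged in at
least ``min_cells`` (default 2) cells — multiple outcomes and/or years —
enter the final positive-deviant set.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import Panel, build_design, n_design_columns
from .errors import ConfigError, DegenerateCellError, IntegrityError
from .regression import (
    InfluenceReport,
    LRTResult,
    ModelFit,
    fit_ols,
    influence_diagnostics,
    likelihood_ratio_test,
    studentized_residuals,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = -1.0


@dataclass
class DeviantCellResult:
    """Everything the screen produced for one (state, outcome, year) cell.

    ``scores`` and ``flags`` are keyed by (jurisdiction_id, year) so pooled
    and per-year runs share one shape; ``flags[u]`` is True iff
    ``scores[u] < threshold`` strictly.
    """

    state: str
    outcome: str
    year: int | None  # None = pooled across years
    step1_fit: ModelFit
    step2_fit: ModelFit
    lrt: LRTResult
    scores: dict[tuple[str, int], float]
    flags: dict[tuple[str, int], bool]
    threshold: float
    residual_source: str  # "step2" or "step1"
    influence: InfluenceReport
    sensitivity_flags: dict[tuple[str, int], bool]
    robust: dict[tuple[str, int], bool]

    @property
    def flagged_units(self) -> set[tuple[str, int]]:
        return {u for u, f in self.flags.items() if f}


@dataclass(frozen=True)
class SkippedCell:
    state: str
    outcome: str
    year: int | None
    reason: str


@dataclass
class CellResults:
    results: list[DeviantCellResult]
    skipped: list[SkippedCell]

    def flagged_set(self) -> set[tuple[str, str, int]]:
        """All flagged (jurisdiction, outcome, year) triples."""
        out = set()
        for r in self.results:
            for (jid, year), f in r.flags.items():
                if f:
                    out.add((jid, r.outcome, year))
        return out


def _residual_fit(res_source: str, fit1: ModelFit, fit2: ModelFit) -> ModelFit:
    return fit2 if res_source == "step2" else fit1


def identify_cell(
    panel: Panel,
    state: str,
    outcome: str,
    year: int | None,
    threshold: float = DEFAULT_THRESHOLD,
    residual_source: str = "step2",
    drop_vars: Sequence[str] = (),
    hat_multiplier: float = 2.0,
    cooks_threshold: float | None = None,
) -> DeviantCellResult:
    """Run the three-step screen for one cell.

    ``year=None`` pools the cell's years into a single fit (context repeats
    across years; residuals stay per jurisdiction-year).  Raises
    :class:`DegenerateCellError` for constant outcomes and the fitting errors
    for undersized cells; callers that iterate cells catch these as skips.
    """
    if residual_source not in ("step1", "step2"):
        raise ConfigError(f"unknown residual source {residual_source!r}")
    rm = panel.role_map
    sub = panel.stratum(state, year)
    model_cols = [c for c in rm.model_vars if c not in drop_vars] + [outcome]
    sub = sub[panel.complete_mask(sub, model_cols)]
    sub = sub.sort_values([rm.id_var, rm.year_var], kind="mergesort")
    if len(sub) == 0:
        raise DegenerateCellError(f"no complete records in cell {(state, outcome, year)}")
    y = sub[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0.0 and len(y) > 1:
        raise DegenerateCellError(f"outcome {outcome!r} constant in cell {(state, outcome, year)}")
    unit_ids = list(zip(sub[rm.id_var].astype(str), sub[rm.year_var].astype(int)))

    X1, names1 = build_design(sub, rm, include_mechanism=False, drop_vars=drop_vars)
    X2, names2 = build_design(sub, rm, include_mechanism=True, drop_vars=drop_vars)
    stratum = (state, year)
    fit1 = fit_ols(y, X1, unit_ids, names1, outcome, stratum, step="context_only")
    fit2 = fit_ols(y, X2, unit_ids, names2, outcome, stratum, step="full")
    lrt = likelihood_ratio_test(fit1, fit2)

    src = _residual_fit(residual_source, fit1, fit2)
    t = studentized_residuals(src)
    scores = {u: float(ti) for u, ti in zip(unit_ids, t)}
    flags = {u: bool(np.isfinite(s) and s < threshold) for u, s in scores.items()}

    influence = influence_diagnostics(src, hat_multiplier, cooks_threshold)

    # leverage sensitivity: refit without the influential leverage points
    sens_flags = dict(flags)
    if influence.flagged:
        dropped = set(influence.flagged)
        keep = [u not in dropped for u in unit_ids]
        sub_k = sub[keep]
        y_k = y[np.asarray(keep)]
        ids_k = [u for u in unit_ids if u not in dropped]
        try:
            Xk, nk = build_design(
                sub_k, rm, include_mechanism=(residual_source == "step2"), drop_vars=drop_vars
            )
            fit_k = fit_ols(y_k, Xk, ids_k, nk, outcome, stratum, step="leverage_sensitivity")
            t_k = studentized_residuals(fit_k)
            sens_flags = {u: bool(np.isfinite(ti) and ti < threshold) for u, ti in zip(ids_k, t_k)}
        except Exception as exc:  # cell too small once points removed
            logger.warning("leverage sensitivity refit failed for %s: %s", stratum, exc)
            sens_flags = {u: flags[u] for u in unit_ids if u not in dropped}
        for u in dropped:
            # a removed unit has no recomputed flag; agreement is vacuous
            sens_flags[u] = flags[u]
    robust = {u: flags[u] == sens_flags.get(u, flags[u]) for u in unit_ids}

    return DeviantCellResult(
        state=state,
        outcome=outcome,
        year=year,
        step1_fit=fit1,
        step2_fit=fit2,
        lrt=lrt,
        scores=scores,
        flags=flags,
        threshold=threshold,
        residual_source=residual_source,
        influence=influence,
        sensitivity_flags=sens_flags,
        robust=robust,
    )


def run_all_cells(
    panel: Panel,
    threshold: float = DEFAULT_THRESHOLD,
    residual_source: str = "step2",
    drop_vars: Sequence[str] = (),
    pooled_years: bool = False,
    hat_multiplier: float = 2.0,
    cooks_threshold: float | None = None,
) -> CellResults:
    """Screen every fittable (state, outcome, year) cell, lexicographically.

    Non-fittable or degenerate cells become :class:`SkippedCell` records; the
    run continues past them.
    """
    rm = panel.role_map
    p_full = n_design_columns(rm, include_mechanism=True, drop_vars=drop_vars)
    results: list[DeviantCellResult] = []
    skipped: list[SkippedCell] = []
    years: Sequence[int | None] = [None] if pooled_years else panel.years
    for state, outcome, year in itertools.product(
        panel.states, sorted(rm.outcome_vars), years
    ):
        sub = panel.stratum(state, year)
        if len(sub) == 0:
            skipped.append(SkippedCell(state, outcome, year, "no records"))
            continue
        model_cols = [c for c in rm.model_vars if c not in drop_vars] + [outcome]
        n_complete = int(panel.complete_mask(sub, model_cols).sum())
        if n_complete <= p_full + 1:
            skipped.append(
                SkippedCell(
                    state, outcome, year,
                    f"non-fittable: {n_complete} complete records for {p_full} model columns",
                )
            )
            continue
        try:
            results.append(
                identify_cell(
                    panel, state, outcome, year, threshold, residual_source,
                    drop_vars, hat_multiplier, cooks_threshold,
                )
            )
        except Exception as exc:
            logger.warning("cell %s skipped: %s", (state, outcome, year), exc)
            skipped.append(SkippedCell(state, outcome, year, str(exc)))
    return CellResults(results=results, skipped=skipped)


# ---------------------------------------------------------------------------
# Covariate sensitivity


@dataclass
class SensitivityVariant:
    name: str
    dropped_var: str | None
    jaccard: float
    n_flagged: int


@dataclass
class SensitivityReport:
    correlated_pairs: list[dict]
    variants: list[SensitivityVariant]

    def to_dict(self) -> dict:
        return {
            "correlated_pairs": self.correlated_pairs,
            "variants": [
                {
                    "name": v.name,
                    "dropped_var": v.dropped_var,
                    "jaccard": v.jaccard,
                    "n_flagged": v.n_flagged,
                }
                for v in self.variants
            ],
        }


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def _continuous_model_vars(panel: Panel) -> list[str]:
    rm = panel.role_map
    return [c for c in rm.model_vars if c not in rm.categorical_vars]


def correlated_pairs(panel: Panel, cutoff: float = 0.8) -> list[dict]:
    """Continuous model-covariate pairs whose |sample correlation| exceeds
    the cutoff within at least one state."""
    rm = panel.role_map
    names = _continuous_model_vars(panel)
    found: dict[tuple[str, str], float] = {}
    for state in panel.states:
        sub = panel.stratum(state)
        corr = sub[names].corr().abs()
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                r = float(corr.loc[a, b])
                if np.isfinite(r) and r > cutoff:
                    key = (a, b)
                    found[key] = max(found.get(key, 0.0), r)
    return [{"pair": list(k), "max_abs_corr": v} for k, v in sorted(found.items())]


def _drop_candidate(panel: Panel, pair: Sequence[str]) -> str:
    """The pair member with the larger average |correlation| to all other
    continuous covariates (pooled within-state average); ties alphabetical."""
    names = _continuous_model_vars(panel)
    avg: dict[str, list[float]] = {v: [] for v in pair}
    for state in panel.states:
        corr = panel.stratum(state)[names].corr().abs()
        for v in pair:
            others = [c for c in names if c != v]
            avg[v].append(float(corr.loc[v, others].mean()))
    means = {v: float(np.mean(avg[v])) for v in pair}
    return sorted(pair, key=lambda v: (-means[v], v))[0]


def covariate_sensitivity(
    panel: Panel,
    correlation_cutoff: float = 0.8,
    threshold: float = DEFAULT_THRESHOLD,
    residual_source: str = "step2",
) -> SensitivityReport:
    """Stability of the flagged set under collinearity-driven model changes.

    For every highly correlated covariate pair, rerun the screen with one
    member dropped; also rerun with the parsimonious (context-only) residual
    source.  Each variant reports the Jaccard similarity of its flagged
    (jurisdiction, outcome, year) set against the primary run's.
    """
    primary = run_all_cells(panel, threshold, residual_source).flagged_set()
    pairs = correlated_pairs(panel, correlation_cutoff)
    variants: list[SensitivityVariant] = []
    for entry in pairs:
        drop = _drop_candidate(panel, entry["pair"])
        flagged = run_all_cells(
            panel, threshold, residual_source, drop_vars=(drop,)
        ).flagged_set()
        variants.append(
            SensitivityVariant(
                name=f"drop:{drop}",
                dropped_var=drop,
                jaccard=_jaccard(primary, flagged),
                n_flagged=len(flagged),
            )
        )
    parsimonious = run_all_cells(panel, threshold, residual_source="step1").flagged_set()
    variants.append(
        SensitivityVariant(
            name="parsimonious(context_only)",
            dropped_var=None,
            jaccard=_jaccard(primary, parsimonious),
            n_flagged=len(parsimonious),
        )
    )
    return SensitivityReport(correlated_pairs=pairs, variants=variants)


# ---------------------------------------------------------------------------
# PD matrix and consolidation


@dataclass
class PDMatrix:
    """Jurisdiction x (outcome, year) flag matrix.

    ``entries.loc[jid, (outcome, year)]`` is True/False where the cell was
    fitted and the jurisdiction participated, and pd.NA where absent.
    """

    entries: pd.DataFrame  # index jid, columns MultiIndex (outcome, year)
    state_of: dict[str, str]

    def flag_counts(self) -> pd.Series:
        return self.entries.apply(lambda row: sum(v is True for v in row), axis=1)


def build_pd_matrix(results: Sequence[DeviantCellResult]) -> PDMatrix:
    """Assemble per-cell flags into the consolidation matrix."""
    seen_cells = set()
    for r in results:
        key = (r.state, r.outcome, r.year)
        if key in seen_cells:
            raise IntegrityError(f"duplicate cell result for {key}")
        seen_cells.add(key)

    jids: dict[str, str] = {}
    columns = set()
    for r in results:
        for jid, year in r.flags:
            jids[jid] = r.state
            columns.add((r.outcome, year))
    col_index = pd.MultiIndex.from_tuples(
        sorted(columns), names=["outcome", "year"]
    )
    entries = pd.DataFrame(pd.NA, index=sorted(jids), columns=col_index, dtype=object)
    for r in results:
        for (jid, year), f in r.flags.items():
            entries.loc[jid, (r.outcome, year)] = bool(f)
    return PDMatrix(entries=entries, state_of=jids)


@dataclass
class ConsolidatedPDSet:
    """The final positive-deviant set: jurisdictions flagged in >= min_cells
    (outcome, year) cells, with their flagged cells and robustness notes."""

    members: dict[str, list[tuple[str, int]]]  # jid -> flagged (outcome, year)
    min_cells: int
    robust: dict[str, bool] = field(default_factory=dict)
    state_of: dict[str, str] = field(default_factory=dict)

    def __contains__(self, jid: str) -> bool:
        return jid in self.members

    def by_state(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for jid in self.members:
            st = self.state_of.get(jid, "?")
            counts[st] = counts.get(st, 0) + 1
        return counts

    def to_dict(self) -> dict:
        return {
            "min_cells": self.min_cells,
            "members": {
                j: {
                    "flagged_cells": [[o, y] for o, y in sorted(cells)],
                    "robust": self.robust.get(j),
                    "state": self.state_of.get(j),
                }
                for j, cells in sorted(self.members.items())
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def consolidate(
    matrix: PDMatrix,
    min_cells: int = 2,
    results: Sequence[DeviantCellResult] | None = None,
) -> ConsolidatedPDSet:
    """Keep jurisdictions flagged in >= min_cells cells, over all outcomes
    and years: two outcomes in one year qualify, as does one outcome in two
    years.  When cell results are supplied, a member is annotated robust iff
    every one of its flagged cells survived the leverage-sensitivity refit.
    """
    if min_cells < 1:
        raise ConfigError("min_cells must be >= 1")
    members: dict[str, list[tuple[str, int]]] = {}
    for jid, row in matrix.entries.iterrows():
        cells = [(o, y) for (o, y), v in row.items() if v is True]
        if len(cells) >= min_cells:
            members[jid] = sorted(cells)

    robust: dict[str, bool] = {}
    if results is not None:
        robust_lookup: dict[tuple[str, str, int], bool] = {}
        for r in results:
            for (jid, year), rb in r.robust.items():
                robust_lookup[(jid, r.outcome, year)] = rb
        for jid, cells in members.items():
            robust[jid] = all(robust_lookup.get((jid, o, y), True) for o, y in cells)

    return ConsolidatedPDSet(
        members=members,
        min_cells=min_cells,
        robust=robust,
        state_of=dict(matrix.state_of),
    )
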