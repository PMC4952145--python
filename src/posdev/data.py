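"""Panel schema, variable roles, and CSV/config input-output.

The analysis unit is a jurisdiction-year: one row per (jurisdiction, year)
carrying outcome variables Y, context variables Z (factors the jurisdiction's
health department cannot readily change), mechanism variables X (factors under
some departmental control), and per-capita expenditure columns used only for
reporting.  A :class:`VariableRoleMap` declares which column plays which role;
a :class:`Panel` bundles a typed table with its role map.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CategoryError, IntegrityError, ParseError, SchemaError

MISSING_TOKENS = ("", "NA")


@dataclass(frozen=True)
class VariableRoleMap:
    """Declares the role of every column the pipeline touches.

    Parameters
    ----------
    outcome_vars
        Outcome columns Y.  All default outcomes are rates where lower is
        better (teen births, late/no prenatal care, infant mortality, low
        birth weight).
    context_vars
        Context columns Z; may include categorical columns such as the
        core-based-statistical-area community type.
    mechanism_vars
        Mechanism columns X (service-delivery indicators, latent score).
    reporting_vars
        Per-capita expenditure columns used only in comparison tables.
    categorical_vars
        Mapping from categorical column name to its allowed category set.
    lower_is_better
        Per-outcome flag; positive deviance means a *negative* residual for
        lower-is-better outcomes.
    reference_levels
        Per-categorical reference level used when building indicator columns.
    """

    outcome_vars: tuple[str, ...]
    context_vars: tuple[str, ...]
    mechanism_vars: tuple[str, ...]
    id_var: str = "jurisdiction_id"
    state_var: str = "state"
    year_var: str = "year"
    reporting_vars: tuple[str, ...] = ()
    categorical_vars: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    lower_is_better: Mapping[str, bool] = field(default_factory=dict)
    reference_levels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "outcome_vars", tuple(self.outcome_vars))
        object.__setattr__(self, "context_vars", tuple(self.context_vars))
        object.__setattr__(self, "mechanism_vars", tuple(self.mechanism_vars))
        object.__setattr__(self, "reporting_vars", tuple(self.reporting_vars))
        object.__setattr__(
            self,
            "categorical_vars",
            {k: tuple(v) for k, v in dict(self.categorical_vars).items()},
        )
        if not self.lower_is_better:
            object.__setattr__(
                self, "lower_is_better", {o: True for o in self.outcome_vars}
            )
        groups = [
            tuple(self.outcome_vars),
            tuple(self.context_vars),
            tuple(self.mechanism_vars),
            tuple(self.reporting_vars),
            (self.id_var, self.state_var, self.year_var),
        ]
        seen: dict[str, int] = {}
        for gi, g in enumerate(groups):
            for name in g:
                if name in seen and seen[name] != gi:
                    raise SchemaError(
                        f"column {name!r} declared in more than one role group"
                    )
                if g.count(name) > 1:
                    raise SchemaError(f"column {name!r} declared twice in one role")
                seen[name] = gi
        if not self.outcome_vars:
            raise SchemaError("at least one outcome variable must be declared")
        if not self.context_vars:
            raise SchemaError("at least one context variable must be declared")
        model_vars = set(self.context_vars) | set(self.mechanism_vars)
        for name in self.categorical_vars:
            if name not in model_vars:
                raise SchemaError(
                    f"categorical variable {name!r} is not a context or mechanism column"
                )
        for o, flag in self.lower_is_better.items():
            if o not in self.outcome_vars:
                raise SchemaError(f"lower_is_better names unknown outcome {o!r}")

    @property
    def model_vars(self) -> tuple[str, ...]:
        return self.context_vars + self.mechanism_vars

    @property
    def all_declared(self) -> tuple[str, ...]:
        return (
            (self.id_var, self.state_var, self.year_var)
            + self.outcome_vars
            + self.context_vars
            + self.mechanism_vars
            + self.reporting_vars
        )

    def numeric_vars(self) -> tuple[str, ...]:
        cat = set(self.categorical_vars)
        return tuple(
            c
            for c in self.outcome_vars + self.context_vars + self.mechanism_vars + self.reporting_vars
            if c not in cat
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["categorical_vars"] = {k: list(v) for k, v in self.categorical_vars.items()}
        for key in ("outcome_vars", "context_vars", "mechanism_vars", "reporting_vars"):
            d[key] = list(d[key])
        d["lower_is_better"] = dict(self.lower_is_better)
        d["reference_levels"] = dict(self.reference_levels)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariableRoleMap":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown role-map keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "VariableRoleMap":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


def default_role_map() -> VariableRoleMap:
    """Role map matching the synthetic study panel (and the study's variable lists)."""
    return VariableRoleMap(
        outcome_vars=(
            "teen_birth_rate",
            "late_prenatal_rate",
            "infant_mortality_rate",
            "low_birth_weight_pct",
        ),
        context_vars=(
            "total_expenditures",
            "population",
            "medicaid_births",
            "community_type",
            "social_disadvantage",
            "pct_child_poverty",
            "pct_hs_education",
            "pct_african_american",
            "pct_hispanic",
            "providers_per_capita",
        ),
        mechanism_vars=(
            "alt_provider",
            "clinician_executive",
            "service_delivery_score",
        ),
        reporting_vars=(
            "percap_mch_expend",
            "percap_wic_expend",
            "percap_fp_expend",
            "percap_mica_expend",
        ),
        categorical_vars={
            "community_type": ("metropolitan", "micropolitan", "rural")
        },
        reference_levels={"community_type": "metropolitan"},
    )


@dataclass(frozen=True)
class PanelRecord:
    """One jurisdiction-year row; ``values`` maps column name -> number or label."""

    jurisdiction_id: str
    state: str
    year: int
    values: Mapping[str, object]

    def is_complete(self, columns: Sequence[str]) -> bool:
        for c in columns:
            v = self.values.get(c)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return False
        return True


@dataclass
class Panel:
    """A typed jurisdiction-year table plus its role map.

    Backed by a :class:`pandas.DataFrame`; one row per (jurisdiction, year).
    """

    df: pd.DataFrame
    role_map: VariableRoleMap

    def __post_init__(self):
        rm = self.role_map
        keys = self.df[[rm.id_var, rm.year_var]]
        dup = keys.duplicated()
        if dup.any():
            j, y = keys[dup].iloc[0]
            raise IntegrityError(f"duplicate (jurisdiction, year) = ({j!r}, {y})")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def states(self) -> list[str]:
        return sorted(self.df[self.role_map.state_var].unique())

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.df[self.role_map.year_var].unique())

    def records(self) -> Iterator[PanelRecord]:
        rm = self.role_map
        value_cols = [c for c in self.df.columns if c not in (rm.id_var, rm.state_var, rm.year_var)]
        for _, row in self.df.iterrows():
            yield PanelRecord(
                jurisdiction_id=str(row[rm.id_var]),
                state=str(row[rm.state_var]),
                year=int(row[rm.year_var]),
                values={c: row[c] for c in value_cols},
            )

    def stratum(self, state: str, year: int | None = None) -> pd.DataFrame:
        rm = self.role_map
        mask = self.df[rm.state_var] == state
        if year is not None:
            mask &= self.df[rm.year_var] == year
        return self.df[mask]

    def complete_mask(self, df: pd.DataFrame, columns: Sequence[str]) -> pd.Series:
        """True where every listed column is non-missing (listwise within the cell)."""
        mask = pd.Series(True, index=df.index)
        for c in columns:
            col = df[c]
            if c in self.role_map.categorical_vars:
                mask &= col.notna() & (col != "")
            else:
                mask &= col.notna()
        return mask


def _type_columns(raw: pd.DataFrame, role_map: VariableRoleMap) -> pd.DataFrame:
    """Convert string cells to typed values, locating any parse failure."""
    rm = role_map
    df = pd.DataFrame(index=raw.index)
    df[rm.id_var] = raw[rm.id_var].astype(str)
    df[rm.state_var] = raw[rm.state_var].astype(str)
    year = pd.to_numeric(raw[rm.year_var].replace(list(MISSING_TOKENS), np.nan), errors="coerce")
    bad = year.isna() & raw[rm.year_var].notna() & ~raw[rm.year_var].isin(MISSING_TOKENS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"unparseable year {raw[rm.year_var].iloc[i]!r} at row {i + 2}",
            row=i + 2, column=rm.year_var,
        )
    if year.isna().any():
        i = int(np.flatnonzero(year.isna().to_numpy())[0])
        raise ParseError(f"missing year at row {i + 2}", row=i + 2, column=rm.year_var)
    df[rm.year_var] = year.astype(int)

    for c in rm.numeric_vars():
        # parse with Python's float (exact strtod) so full-precision values
        # round-trip bit-exactly; pandas' fast parser does not guarantee that
        vals = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw[c].to_numpy()):
            if pd.isna(cell) or cell in MISSING_TOKENS:
                vals[i] = np.nan
                continue
            try:
                vals[i] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"unparseable numeric cell {cell!r} in column {c!r} at row {i + 2}",
                    row=i + 2, column=c,
                ) from None
        df[c] = vals

    for c, levels in rm.categorical_vars.items():
        col = raw[c].replace(list(MISSING_TOKENS), np.nan)
        bad = col.notna() & ~col.isin(levels)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CategoryError(
                f"value {raw[c].iloc[i]!r} in column {c!r} at row {i + 2} "
                f"is not one of {levels}",
                row=i + 2, column=c,
            )
        df[c] = col
    # carry through undeclared columns untouched (as strings)
    for c in raw.columns:
        if c not in df.columns:
            df[c] = raw[c]
    return df


def load_panel(path: str | Path, role_map: str | Path | VariableRoleMap) -> Panel:
    """Read a comma-separated panel table and attach its role map.

    Missing values are empty cells or ``NA``.  Raises :class:`SchemaError` for
    absent declared columns, :class:`ParseError`/:class:`CategoryError` with
    row/column coordinates for bad cells, and :class:`IntegrityError` for
    duplicate (jurisdiction, year) keys.
    """
    if not isinstance(role_map, VariableRoleMap):
        role_map = VariableRoleMap.from_file(role_map)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    missing = [c for c in role_map.all_declared if c not in raw.columns]
    if missing:
        raise SchemaError(f"declared columns missing from header: {missing}")
    return Panel(df=_type_columns(raw, role_map), role_map=role_map)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write the panel as CSV at full float precision (round-trips bit-exactly)."""
    df = panel.df.copy()
    for c in panel.role_map.numeric_vars():
        df[c] = df[c].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Design-matrix construction


def build_design(
    df: pd.DataFrame,
    role_map: VariableRoleMap,
    include_mechanism: bool = True,
    drop_vars: Sequence[str] = (),
) -> tuple[np.ndarray, list[str]]:
    """Encode model columns into a design matrix with an explicit intercept.

    Categorical columns become indicator columns against their declared
    reference level (named ``col=level``); continuous columns pass through.
    """
    cols = [c for c in role_map.context_vars if c not in drop_vars]
    if include_mechanism:
        cols += [c for c in role_map.mechanism_vars if c not in drop_vars]
    names = ["intercept"]
    arrays = [np.ones(len(df))]
    for c in cols:
        if c in role_map.categorical_vars:
            levels = role_map.categorical_vars[c]
            ref = role_map.reference_levels.get(c, levels[0])
            for lev in levels:
                if lev == ref:
                    continue
                names.append(f"{c}={lev}")
                arrays.append((df[c] == lev).to_numpy(dtype=float))
        else:
            names.append(c)
            arrays.append(df[c].to_numpy(dtype=float))
    return np.column_stack(arrays), names


def n_design_columns(role_map: VariableRoleMap, include_mechanism: bool = True,
                     drop_vars: Sequence[str] = ()) -> int:
    """Number of encoded design columns including the intercept."""
    cols = [c for c in role_map.context_vars if c not in drop_vars]
    if include_mechanism:
        cols += [c for c in role_map.mechanism_vars if c not in drop_vars]
    p = 1
    for c in cols:
        if c in role_map.categorical_vars:
            p += len(role_map.categorical_vars[c]) - 1
        else:
            p += 1
    return p


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class CellValidation:
    state: str
    outcome: str
    year: int
    n_complete: int
    n_incomplete: int
    n_model_columns: int
    fittable: bool


@dataclass
class ValidationReport:
    """Per (state, outcome, year) completeness and fittability report."""

    cells: list[CellValidation]
    year_gaps: list[dict]

    def cell(self, state: str, outcome: str, year: int) -> CellValidation:
        for c in self.cells:
            if (c.state, c.outcome, c.year) == (state, outcome, year):
                return c
        raise KeyError((state, outcome, year))

    def to_dict(self) -> dict:
        return {
            "cells": [dataclasses.asdict(c) for c in self.cells],
            "year_gaps": self.year_gaps,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lines = ["state outcome year n_complete n_excluded fittable"]
        for c in self.cells:
            lines.append(
                f"{c.state} {c.outcome} {c.year} {c.n_complete} "
                f"{c.n_incomplete} {'yes' if c.fittable else 'NO'}"
            )
        for g in self.year_gaps:
            lines.append(f"year gap: state {g['state']} missing years {g['missing_years']}")
        return "\n".join(lines)


def validate_panel(panel: Panel, whole_panel_exclusion: bool = False) -> ValidationReport:
    """Report completeness and fittability for every (state, outcome, year) cell.

    Exclusion is listwise within each cell's model columns: a record missing
    only outcome A still participates in outcome B's cell.  With
    ``whole_panel_exclusion`` a jurisdiction missing *any* model or outcome
    value in *any* year is excluded everywhere (the stricter study-style rule).
    """
    rm = panel.role_map
    df = panel.df
    all_years = set(panel.years)
    year_gaps = []
    for state in panel.states:
        state_years = set(int(y) for y in panel.stratum(state)[rm.year_var].unique())
        if state_years != all_years:
            year_gaps.append(
                {"state": state, "missing_years": sorted(all_years - state_years)}
            )

    excluded_ids: set[str] = set()
    if whole_panel_exclusion:
        need = list(rm.model_vars) + list(rm.outcome_vars)
        complete = panel.complete_mask(df, need)
        excluded_ids = set(df.loc[~complete, rm.id_var].astype(str))

    p_full = n_design_columns(rm, include_mechanism=True)
    cells = []
    for state in panel.states:
        for outcome in rm.outcome_vars:
            model_cols = list(rm.model_vars) + [outcome]
            for year in panel.years:
                sub = panel.stratum(state, year)
                if len(sub) == 0:
                    continue
                mask = panel.complete_mask(sub, model_cols)
                if excluded_ids:
                    mask &= ~sub[rm.id_var].astype(str).isin(excluded_ids)
                n_complete = int(mask.sum())
                cells.append(
                    CellValidation(
                        state=state,
                        outcome=outcome,
                        year=int(year),
                        n_complete=n_complete,
                        n_incomplete=int(len(sub) - n_complete),
                        n_model_columns=p_full,
                        fittable=n_complete > p_full + 1,
                    )
                )
    return ValidationReport(cells=cells, year_gaps=year_gaps)
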