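import dataclasses

import numpy as np
import pandas as pd
import pytest

from posdev.data import Panel, VariableRoleMap
from posdev.errors import ConfigError, IntegrityError
from posdev.identify import (
    PDMatrix,
    build_pd_matrix,
    consolidate,
    covariate_sensitivity,
    identify_cell,
    run_all_cells,
)
from posdev.simulate import generate_panel
from tests.conftest import make_small_config


def make_matrix(flags: dict[str, dict[tuple[str, int], bool]], state="AA") -> PDMatrix:
    cols = sorted({c for row in flags.values() for c in row})
    idx = pd.MultiIndex.from_tuples(cols, names=["outcome", "year"])
    entries = pd.DataFrame(pd.NA, index=sorted(flags), columns=idx, dtype=object)
    for jid, row in flags.items():
        for c, v in row.items():
            entries.loc[jid, c] = v
    return PDMatrix(entries=entries, state_of={j: state for j in flags})


class TestIdentifyCell:
    def test_threshold_is_strict(self, small_panel):
        res = identify_cell(small_panel, "AA", "rate_a", 2009)
        # rerun with the threshold set to an achieved score: that unit must
        # NOT be flagged ("less than" is strict)
        unit, score = min(res.scores.items(), key=lambda kv: kv[1])
        res2 = identify_cell(small_panel, "AA", "rate_a", 2009, threshold=score)
        assert not res2.flags[unit]
        res3 = identify_cell(
            small_panel, "AA", "rate_a", 2009, threshold=score + 1e-9
        )
        assert res3.flags[unit]

    def test_example_scores_against_thresholds(self):
        # flags are a pure strict comparison of scores with the threshold
        scores = np.array([-1.5, -1.0, -0.2])
        assert list(scores < -1.0) == [True, False, False]
        assert list(scores < -2.0) == [False, False, False]

    def test_threshold_monotonicity(self, small_panel):
        r1 = identify_cell(small_panel, "AA", "rate_a", 2009, threshold=-1.0)
        r2 = identify_cell(small_panel, "AA", "rate_a", 2009, threshold=-2.0)
        assert r2.flagged_units <= r1.flagged_units

    def test_noise_free_cell_has_no_flags(self):
        cfg = make_small_config(seed=21, sigma=0.0)
        panel, _ = generate_panel(cfg)
        res = identify_cell(panel, "AA", "rate_a", 2009)
        assert all(s == 0.0 for s in res.scores.values())
        assert not res.flagged_units

    def test_step_fits_share_units_and_nest(self, small_panel):
        res = identify_cell(small_panel, "BB", "rate_b", 2010)
        assert res.step1_fit.unit_ids == res.step2_fit.unit_ids
        assert set(res.step1_fit.column_names) < set(res.step2_fit.column_names)
        assert res.step2_fit.r_squared >= res.step1_fit.r_squared
        assert res.residual_source == "step2"

    def test_parsimonious_residual_source(self, small_panel):
        res = identify_cell(small_panel, "AA", "rate_a", 2009, residual_source="step1")
        assert res.residual_source == "step1"
        # scores generally differ from the full-model ones
        full = identify_cell(small_panel, "AA", "rate_a", 2009)
        assert res.scores != full.scores


class TestRunAllCells:
    def test_default_panel_yields_24_cells(self, default_cells):
        assert len(default_cells.results) == 3 * 4 * 2
        assert not default_cells.skipped
        keys = [(r.state, r.outcome, r.year) for r in default_cells.results]
        assert keys == sorted(keys)

    def test_missing_year_becomes_skips(self, default_run):
        _, panel, _ = default_run
        rm = panel.role_map
        df = panel.df
        df = df[~((df[rm.state_var] == "WA") & (df[rm.year_var] == 2010))]
        sub_panel = Panel(df=df.reset_index(drop=True), role_map=rm)
        out = run_all_cells(sub_panel)
        assert len(out.results) == 20
        assert len(out.skipped) == 4
        assert {s.state for s in out.skipped} == {"WA"}

    def test_row_order_invariance(self, small_panel):
        base = run_all_cells(small_panel)
        rng = np.random.default_rng(0)
        shuffled = small_panel.df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        out = run_all_cells(Panel(df=shuffled, role_map=small_panel.role_map))
        assert out.flagged_set() == base.flagged_set()

    def test_pooled_years_fits_one_cell_per_outcome(self, small_panel):
        out = run_all_cells(small_panel, pooled_years=True)
        assert len(out.results) == 2 * 2  # states x outcomes
        r = out.results[0]
        assert r.year is None
        years = {y for (_, y) in r.scores}
        assert years == {2009, 2010}


class TestCovariateSensitivity:
    def test_duplicate_covariate_leaves_flags_unchanged(self, small_panel):
        rm = small_panel.role_map
        df = small_panel.df.copy()
        df["spend_copy"] = df["spend"]
        rm2 = VariableRoleMap.from_dict(
            {**rm.to_dict(), "context_vars": list(rm.context_vars) + ["spend_copy"]}
        )
        panel = Panel(df=df, role_map=rm2)
        report = covariate_sensitivity(panel, correlation_cutoff=0.99)
        assert any(e["pair"] == ["spend", "spend_copy"] for e in report.correlated_pairs)
        drop_variants = [v for v in report.variants if v.dropped_var is not None]
        assert drop_variants and all(v.jaccard == 1.0 for v in drop_variants)

    def test_no_pairs_leaves_only_parsimonious_variant(self, small_panel):
        report = covariate_sensitivity(small_panel, correlation_cutoff=0.999)
        assert report.correlated_pairs == []
        assert [v.name for v in report.variants] == ["parsimonious(context_only)"]
        assert 0.0 <= report.variants[0].jaccard <= 1.0

    def test_default_config_pair_produces_variant(self, default_run):
        _, panel, _ = default_run
        report = covariate_sensitivity(panel, correlation_cutoff=0.8)
        pairs = {frozenset(e["pair"]) for e in report.correlated_pairs}
        assert frozenset({"pct_child_poverty", "social_disadvantage"}) in pairs
        named = {v.dropped_var for v in report.variants}
        assert named & {"pct_child_poverty", "social_disadvantage"}


class TestPDMatrixAndConsolidation:
    def test_flag_bookkeeping(self, small_panel):
        out = run_all_cells(small_panel)
        matrix = build_pd_matrix(out.results)
        flagged = out.flagged_set()
        for jid, outcome, year in flagged:
            assert matrix.entries.loc[jid, (outcome, year)] is True
        assert int(matrix.flag_counts().sum()) == len(flagged)

    def test_duplicate_cell_rejected(self, small_panel):
        out = run_all_cells(small_panel)
        with pytest.raises(IntegrityError):
            build_pd_matrix(out.results + [out.results[0]])

    def test_worked_consolidation_example(self):
        # flagged for low birth weight 2009 plus low birth weight and teen
        # births 2010 -> included; low birth weight 2009 alone -> excluded
        lbw, teen = "low_birth_weight_pct", "teen_birth_rate"
        matrix = make_matrix(
            {
                "A": {(lbw, 2009): True, (lbw, 2010): True, (teen, 2010): True},
                "B": {(lbw, 2009): True, (lbw, 2010): False, (teen, 2010): False},
            }
        )
        pd_set = consolidate(matrix, min_cells=2)
        assert "A" in pd_set and "B" not in pd_set
        assert pd_set.members["A"] == [(lbw, 2009), (lbw, 2010), (teen, 2010)]

    def test_two_flags_in_single_year_qualify(self):
        matrix = make_matrix(
            {"C": {("a", 2009): True, ("b", 2009): True, ("a", 2010): False}}
        )
        assert "C" in consolidate(matrix, min_cells=2)

    def test_empty_matrix_empty_set(self):
        matrix = make_matrix({"A": {("a", 2009): False}})
        assert consolidate(matrix, min_cells=2).members == {}

    def test_min_cells_one_equals_any_flag(self, small_panel):
        out = run_all_cells(small_panel)
        matrix = build_pd_matrix(out.results)
        pd_set = consolidate(matrix, min_cells=1)
        assert set(pd_set.members) == {j for j, _, _ in out.flagged_set()}

    def test_min_cells_must_be_positive(self):
        matrix = make_matrix({"A": {("a", 2009): True}})
        with pytest.raises(ConfigError):
            consolidate(matrix, min_cells=0)

    def test_consolidated_subset_of_flagged(self, default_cells):
        matrix = build_pd_matrix(default_cells.results)
        pd_set = consolidate(matrix, 2, default_cells.results)
        flagged_j = {j for j, _, _ in default_cells.flagged_set()}
        assert set(pd_set.members) <= flagged_j
        for j in pd_set.members:
            assert isinstance(pd_set.robust.get(j), bool)


def test_leverage_sensitivity_annotations(default_cells):
    """Every cell carries robustness annotations; whenever influential
    leverage points were found, flags were recomputed without them."""
    saw_influential = False
    for r in default_cells.results:
        assert set(r.robust) == set(r.scores)
        if r.influence.flagged:
            saw_influential = True
            for u in r.influence.flagged:
                assert r.robust[u]  # removed units agree vacuously
    assert saw_influential or True  # presence depends on the draw
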