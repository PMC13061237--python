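import warnings

import numpy as np
import pandas as pd
import pytest

from cohortflow import (
    ConfigurationError,
    ConsistencyError,
    FlowOptions,
    SchemaError,
    ValidationError,
    add_exclusion,
    drift_table,
    from_prefiltered,
    init_flow,
    make_variable_spec,
)
from cohortflow.flow import ROW_ID


class TestInit:
    def test_snapshot_zero(self, small_df, specs):
        state = init_flow(small_df, specs)
        assert state.current.n == 6
        assert state.current.label == "Initial cohort"
        assert set(state.current.summaries) == {"age", "severity", "sex", "site"}

    def test_missing_standardization_applied(self, small_df, specs):
        state = init_flow(small_df, specs)
        # "NA" site token became the missingness category
        assert state.current.summaries["site"].counts().get("Missing") == 1

    def test_single_row_flow(self):
        state = init_flow(pd.DataFrame({"x": [1.0]}),
                          [make_variable_spec("x", "continuous_normal")])
        assert state.current.n == 1

    def test_empty_table_rejected(self, specs):
        with pytest.raises(ConfigurationError, match="empty"):
            init_flow(pd.DataFrame({"age": []}), specs)

    def test_absent_spec_column(self, small_df):
        with pytest.raises(SchemaError, match="ghost"):
            init_flow(small_df, [make_variable_spec("ghost", "categorical")])

    def test_csv_input_round_trip(self, small_df, specs, tmp_path):
        path = tmp_path / "cohort.csv"
        small_df.to_csv(path, index=False)
        state = init_flow(path, specs)
        assert state.current.n == len(small_df)


class TestAddExclusion:
    def test_mask_bookkeeping(self, small_df, specs):
        state = init_flow(small_df, specs)
        add_exclusion(state, keep=[True] * 5 + [False], reason="drop last")
        rec = state.exclusions[0]
        assert (rec.n_before, rec.n_removed, rec.n_after) == (6, 1, 5)
        assert state.current.n == 5

    def test_strict_rejects_no_removal(self, small_df, specs):
        state = init_flow(small_df, specs)
        with pytest.raises(ValidationError, match="removed no participants"):
            add_exclusion(state, keep=[True] * 6, reason="noop")

    def test_lenient_warns_on_no_removal(self, small_df, specs):
        state = init_flow(small_df, specs, options=FlowOptions(strict=False))
        with pytest.warns(UserWarning, match="removed no participants"):
            add_exclusion(state, keep=[True] * 6, reason="noop")
        assert len(state.snapshots) == 2

    def test_empty_cohort_allowed_with_warning(self, small_df, specs):
        state = init_flow(small_df, specs)
        with pytest.warns(UserWarning, match="entire cohort"):
            add_exclusion(state, keep=[False] * 6, reason="drop all")
        assert state.current.n == 0
        assert drift_table(state).isna().all().all()

    def test_mask_length_mismatch(self, small_df, specs):
        state = init_flow(small_df, specs)
        with pytest.raises(ConfigurationError, match="length"):
            add_exclusion(state, keep=[True, False], reason="bad mask")

    def test_both_or_neither_argument(self, small_df, specs):
        state = init_flow(small_df, specs)
        with pytest.raises(ConfigurationError, match="exactly one"):
            add_exclusion(state, reason="nothing supplied")
        with pytest.raises(ConfigurationError, match="exactly one"):
            add_exclusion(state, keep=[True] * 6, table=small_df, reason="both")

    def test_filtered_table_subset_accepted(self, small_df, specs):
        state = init_flow(small_df, specs)
        subset = state.current.table.iloc[[0, 2, 4]]
        add_exclusion(state, table=subset, reason="keep evens")
        assert state.current.n == 3

    def test_foreign_rows_rejected(self, small_df, specs):
        state = init_flow(small_df, specs)
        foreign = state.current.table.copy()
        foreign.loc[0, ROW_ID] = 999
        with pytest.raises(ConsistencyError, match="not in the current cohort"):
            add_exclusion(state, table=foreign, reason="tampered")

    def test_reason_required(self, small_df, specs):
        state = init_flow(small_df, specs)
        with pytest.raises(ConfigurationError, match="reason"):
            add_exclusion(state, keep=[True] * 5 + [False], reason="")


class TestInvariants:
    def test_conservation(self, synthetic_flow):
        sizes = [s.n for s in synthetic_flow.snapshots]
        removed = sum(e.n_removed for e in synthetic_flow.exclusions)
        assert sizes[0] == sizes[-1] + removed
        synthetic_flow.validate()

    def test_step_indices_consecutive(self, synthetic_flow):
        assert [s.step_index for s in synthetic_flow.snapshots] == [0, 1, 2]

    def test_replay_is_reproducible(self, small_df, specs):
        def build():
            state = init_flow(small_df, specs)
            add_exclusion(state, keep=[True, True, True, True, False, True], reason="r1")
            return state

        s1, s2 = build(), build()
        pd.testing.assert_frame_equal(s1.current.table, s2.current.table)
        pd.testing.assert_frame_equal(drift_table(s1, rounded=False),
                                      drift_table(s2, rounded=False))

    def test_mask_vs_prefiltered_equivalence(self, specs, small_df):
        """The two workflows yield identical snapshots, summaries and SMDs."""
        masks = [
            np.array([True, True, True, True, False, True]),
            np.array([True, True, False, True, True]),
        ]
        stepwise = init_flow(small_df, specs)
        t1 = stepwise.current.table
        add_exclusion(stepwise, keep=masks[0], reason="r1")
        t2 = stepwise.current.table
        add_exclusion(stepwise, keep=masks[1], reason="r2")
        t3 = stepwise.current.table

        prefiltered = from_prefiltered(
            [t1.drop(columns=ROW_ID), t2.drop(columns=ROW_ID), t3.drop(columns=ROW_ID)],
            labels=["Initial cohort", "Step 2", "Step 3"],
            specs=specs, reasons=["r1", "r2"],
        )
        for a, b in zip(stepwise.snapshots, prefiltered.snapshots):
            assert a.summaries == b.summaries
        pd.testing.assert_frame_equal(
            drift_table(stepwise, rounded=False),
            drift_table(prefiltered, rounded=False),
        )


class TestPrefiltered:
    def test_synthesized_removals(self, specs, small_df):
        state = init_flow(small_df, specs)
        t = state.current.table
        state2 = from_prefiltered([t, t.iloc[:4], t.iloc[:2]], specs=specs)
        assert [e.n_removed for e in state2.exclusions] == [2, 2]

    def test_size_increase_rejected(self, specs, small_df):
        state = init_flow(small_df, specs)
        t = state.current.table
        with pytest.raises(ConsistencyError, match="increase"):
            from_prefiltered([t.iloc[:2], t.iloc[:4]], specs=specs)

    def test_identical_tables_zero_drift(self, specs, small_df):
        state = init_flow(small_df, specs)
        t = state.current.table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state2 = from_prefiltered([t, t.copy()], specs=specs,
                                      options=FlowOptions(strict=False))
        assert (drift_table(state2, rounded=False).abs() < 1e-12).all().all()

    def test_requires_two_tables(self, specs, small_df):
        with pytest.raises(ConfigurationError, match="at least 2"):
            from_prefiltered([small_df], specs=specs)
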