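import numpy as np
import pandas as pd
import pytest

from cohortflow import (
    FlowOptions,
    add_exclusion,
    eicu_like,
    generate_selected_flow,
    init_flow,
    make_variable_spec,
)


@pytest.fixture
def small_df():
    """Tiny hand-checkable participant table with mixed types and missingness."""
    return pd.DataFrame(
        {
            "age": [30.0, 40.0, np.nan, 50.0, 60.0, 70.0],
            "severity": [5.0, 5.0, 8.0, 13.0, 21.0, 34.0],
            "sex": ["F", "M", "M", "F", None, "M"],
            "site": ["A", "A", "B", "B", "C", "NA"],
        }
    )


@pytest.fixture
def specs():
    return [
        make_variable_spec("age", "continuous_normal"),
        make_variable_spec("severity", "continuous_nonnormal"),
        make_variable_spec("sex", "categorical"),
        make_variable_spec("site", "categorical"),
    ]


@pytest.fixture
def small_flow(small_df, specs):
    state = init_flow(small_df, specs)
    add_exclusion(state, keep=[True, True, True, True, False, True],
                  reason="Complete sex", label="Sex known")
    add_exclusion(state, keep=[True, True, False, True, True],
                  reason="Age recorded", label="Age known")
    return state


@pytest.fixture(scope="session")
def synthetic_flow():
    """Moderate synthetic ICU-like flow with a planted selection mechanism."""
    from cohortflow import easy_flow

    cfg = eicu_like(n=4000, seed=11)
    df, masks = generate_selected_flow(cfg)
    reasons = [s.reason for s in cfg.selection]
    return easy_flow(df, masks, reasons, options=FlowOptions(strict=False))
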