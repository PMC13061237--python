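import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from cohortflow import (
    DegenerateInputError,
    ProportionVector,
    drift_between,
    flag_meaningful,
    init_flow,
    make_variable_spec,
    smd_binary,
    smd_continuous,
    smd_correction,
    smd_multicategory,
)
from cohortflow.fixtures import EICU_STEPS, MIMIC_STEPS


def hedges_exact(df: int) -> float:
    """Exact gamma-ratio form of the small-sample correction factor."""
    return math.exp(gammaln(df / 2) - gammaln((df - 1) / 2)) / math.sqrt(df / 2)


def pv(counts: dict) -> ProportionVector:
    return ProportionVector.from_counts(list(counts), list(counts.values()))


class TestContinuous:
    def test_unit_shift_at_unit_pooled_sd(self):
        assert smd_continuous(0, 1, 50, 1, 1, 50, correct=False) == pytest.approx(-1.0)

    def test_identical_cohorts_zero(self):
        assert smd_continuous(5.0, 2.0, 30, 5.0, 2.0, 30) == 0.0

    def test_severity_shift_from_printed_summaries(self):
        """Published ICU severity summaries give a medium effect (0.5)."""
        value = smd_continuous(56.2, 24.6, 117_489, 69.0, 26.2, 17_161)
        assert round(abs(value), 1) == 0.5

    def test_zero_variance_equal_means(self):
        assert smd_continuous(3.0, 0.0, 10, 3.0, 0.0, 10) == 0.0

    def test_zero_variance_unequal_means_degenerate(self):
        with pytest.raises(DegenerateInputError):
            smd_continuous(3.0, 0.0, 10, 4.0, 0.0, 10)

    def test_antisymmetry(self):
        a = smd_continuous(1.0, 2.0, 40, 3.0, 1.5, 60)
        b = smd_continuous(3.0, 1.5, 60, 1.0, 2.0, 40)
        assert a == pytest.approx(-b, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(0.01, 100.0),
        b=st.floats(-50.0, 50.0),
        m1=st.floats(-10.0, 10.0),
        m2=st.floats(-10.0, 10.0),
        s1=st.floats(0.1, 5.0),
        s2=st.floats(0.1, 5.0),
    )
    def test_scale_invariance(self, a, b, m1, m2, s1, s2):
        """x -> a*x + b applied to both cohorts leaves the SMD unchanged."""
        base = smd_continuous(m1, s1, 30, m2, s2, 40, correct=False)
        scaled = smd_continuous(a * m1 + b, a * s1, 30, a * m2 + b, a * s2, 40,
                                correct=False)
        assert scaled == pytest.approx(base, abs=1e-10)


class TestBinary:
    def test_mortality_transition_from_printed_summaries(self):
        assert round(smd_binary(0.0747, 65_366, 0.0674, 61_360), 2) == 0.03

    def test_equal_proportions_zero(self):
        assert smd_binary(0.5, 100, 0.5, 100) == 0.0

    def test_closed_form(self):
        # |0.2-0.8| / sqrt((0.16+0.16)/2) = 0.6/0.4
        assert smd_binary(0.2, 100, 0.8, 100, correct=False) == pytest.approx(1.5)

    def test_degenerate_proportions(self):
        with pytest.raises(DegenerateInputError):
            smd_binary(0.0, 10, 1.0, 10)

    def test_magnitude_symmetry(self):
        assert smd_binary(0.3, 50, 0.6, 70) == smd_binary(0.6, 70, 0.3, 50)


class TestMultiCategory:
    def test_ethnicity_shift_from_printed_summaries(self):
        """6-level ethnicity shift over the final selection step rounds to 0.2."""
        value = smd_multicategory(pv(EICU_STEPS[2]["ethnicity"]),
                                  pv(EICU_STEPS[3]["ethnicity"]))
        assert round(value, 1) == 0.2

    def test_insurance_shift_from_printed_summaries(self):
        value = smd_multicategory(pv(MIMIC_STEPS[0]["insurance"]),
                                  pv(MIMIC_STEPS[1]["insurance"]))
        assert round(value, 2) == 0.07

    def test_identical_vectors_zero(self):
        v = ProportionVector.make(["a", "b", "c"], [0.5, 0.3, 0.2], 100)
        assert smd_multicategory(v, v) == 0.0

    def test_k2_reduces_to_binary(self):
        """Closed-form oracle: 200 random 2-category pairs match smd_binary."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            p1, p2 = rng.uniform(0.02, 0.98, size=2)
            v1 = ProportionVector.make(["yes", "no"], [p1, 1 - p1], 100)
            v2 = ProportionVector.make(["yes", "no"], [p2, 1 - p2], 100)
            expected = smd_binary(p1, 100, p2, 100, correct=False)
            assert smd_multicategory(v1, v2) == pytest.approx(expected, abs=1e-10)

    def test_drop_category_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = rng.integers(3, 7)
            p1 = rng.dirichlet(np.ones(k))
            p2 = rng.dirichlet(np.ones(k))
            labels = [f"c{i}" for i in range(k)]
            v1 = ProportionVector.make(labels, p1, 500)
            v2 = ProportionVector.make(labels, p2, 500)
            values = [smd_multicategory(v1, v2, drop_category=d) for d in range(k)]
            assert max(values) - min(values) < 1e-8

    def test_union_alignment_of_absent_categories(self):
        v1 = ProportionVector.make(["a", "b"], [0.6, 0.4], 100)
        v2 = ProportionVector.make(["a", "b", "c"], [0.5, 0.3, 0.2], 100)
        # no error; category c aligned as 0 in the first cohort
        assert smd_multicategory(v1, v2) > 0

    def test_invalid_sum_rejected(self):
        from cohortflow import ConfigurationError

        with pytest.raises(ConfigurationError, match="sum"):
            ProportionVector.make(["a", "b"], [0.5, 0.4], 100)

    def test_renormalization_path(self):
        v = ProportionVector.make(["a", "b"], [0.5, 0.4], 100, normalize=True)
        assert sum(v.proportions) == pytest.approx(1.0, abs=1e-12)


class TestCorrection:
    def test_exact_gamma_form(self):
        """The factor is the exact gamma ratio; the textbook approximation
        1 - 3/(4 df - 1) tracks it to 1e-3 once df >= 6."""
        assert smd_correction(10, 10) == pytest.approx(hedges_exact(18), rel=1e-12)
        assert smd_correction(10, 10) == pytest.approx(1 - 3 / 71, abs=1e-3)
        for df in range(6, 501):
            assert abs((1 - 3 / (4 * df - 1)) - hedges_exact(df)) < 1e-3
        # below df=6 the approximation drifts; the exact form does not
        assert abs((1 - 3 / 7) - hedges_exact(2)) > 1e-3

    def test_large_sample_limit(self):
        j = smd_correction(100_000, 100_000)
        assert 0.9999 < j < 1.0

    def test_monotone_in_df(self):
        assert smd_correction(10, 10) < smd_correction(51, 51) < 1.0

    def test_small_df_rejected(self):
        from cohortflow import ConfigurationError

        with pytest.raises(ConfigurationError):
            smd_correction(1, 1)


class TestDriftBetween:
    def test_identical_snapshots_all_zero(self, small_flow):
        snap = small_flow.snapshots[0]
        for dv in drift_between(snap, snap, small_flow.specs):
            assert dv.smd == 0.0

    def test_planted_mean_shift_recovered(self):
        """Generative oracle: a 0.4-pooled-SD shift is recovered within 0.05."""
        import pandas as pd

        rng = np.random.default_rng(99)
        spec = [make_variable_spec("x", "continuous_normal")]
        a = pd.DataFrame({"x": rng.normal(0.0, 1.0, 5000)})
        b = pd.DataFrame({"x": rng.normal(0.4, 1.0, 5000)})
        sa = init_flow(a, spec).snapshots[0]
        sb = init_flow(b, spec).snapshots[0]
        (dv,) = drift_between(sa, sb, spec)
        assert dv.smd == pytest.approx(0.4, abs=0.05)

    def test_empty_cohort_yields_nan(self, small_df, specs):
        import warnings

        from cohortflow import FlowOptions, add_exclusion

        state = init_flow(small_df, specs, options=FlowOptions(strict=False))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            add_exclusion(state, keep=[False] * 6, reason="remove all")
        values = drift_between(state.snapshots[0], state.snapshots[1], specs)
        assert all(math.isnan(v.smd) for v in values)

    def test_signed_later_minus_earlier_for_continuous(self):
        """A mean that falls over the step yields a negative drift value."""
        import pandas as pd

        spec = [make_variable_spec("x", "continuous_normal")]
        a = init_flow(pd.DataFrame({"x": [10.0, 12.0, 14.0]}), spec).snapshots[0]
        b = init_flow(pd.DataFrame({"x": [4.0, 6.0, 8.0]}), spec).snapshots[0]
        (dv,) = drift_between(a, b, spec)
        assert dv.smd < 0


class TestFlagging:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.05, False), (0.1, False), (0.11, True), (-0.3, True), (float("nan"), False)],
    )
    def test_meaningful_threshold(self, value, expected):
        assert flag_meaningful(value) is expected
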