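import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synertri.dose_response import FitResult
from synertri.models import Endpoint, ValidationError
from synertri.synergy import (
    NoActiveComponentError,
    categorize_ci,
    combination_index,
    combination_interval,
)


class TestCombinationIndex:
    def test_two_term_extraction_published_row(self):
        # macrophage IL-6: chamomile inactive -> two terms
        res = combination_index(14.0, 152.0, None, 5.0)
        assert round(res.ci_value, 2) == 0.13
        assert res.included == ("A", "B")
        assert res.symbol == "++++"

    def test_three_term_published_row(self):
        res = combination_index(6.0, 251.0, 39.0, 17.0)
        assert round(res.ci_value, 2) == 1.11
        assert res.category == "slight_antagonism"

    def test_equal_potencies_give_exactly_one(self):
        for x in (1.0, 14.0, 0.37, 152.0):
            res = combination_index(x, x, x, x)
            assert res.ci_value == 1.0
            assert res.category == "nearly_additive"

    def test_ci_equals_sum_of_terms(self):
        res = combination_index(14.0, 152.0, 39.0, 17.0)
        assert res.ci_value == pytest.approx(sum(res.terms.values()), rel=1e-12)
        assert res.ic50_comb * 3 == pytest.approx(res.ic50_combination_total, rel=1e-15)

    def test_all_absent_raises(self):
        with pytest.raises(NoActiveComponentError):
            combination_index(None, None, None, 10.0)

    @pytest.mark.parametrize("bad", [0.0, -3.0, math.nan])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValidationError):
            combination_index(bad, 10.0, 10.0, 10.0)
        with pytest.raises(ValidationError):
            combination_index(10.0, 10.0, 10.0, bad)

    @given(
        a=st.floats(0.1, 1e3), b=st.floats(0.1, 1e3),
        c=st.floats(0.1, 1e3), comb=st.floats(0.1, 1e3),
        scale=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=80, deadline=None)
    def test_unit_invariance(self, a, b, c, comb, scale):
        base = combination_index(a, b, c, comb).ci_value
        scaled = combination_index(scale * a, scale * b, scale * c, scale * comb).ci_value
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_monotonicity(self):
        base = combination_index(14.0, 152.0, 39.0, 17.0).ci_value
        assert combination_index(14.0, 152.0, 39.0, 18.0).ci_value > base
        assert combination_index(15.0, 152.0, 39.0, 17.0).ci_value < base


class TestCategorisation:
    @pytest.mark.parametrize(
        "value,category,symbol",
        [
            (0.13, "strong_synergism", "++++"),
            (0.3, "synergism", "+++"),
            (0.67, "synergism", "+++"),
            (0.73, "moderate_synergism", "++"),
            (0.83, "moderate_synergism", "++"),
            (0.87, "slight_synergism", "+"),
            (0.9, "nearly_additive", "0"),
            (1.0, "nearly_additive", "0"),
            (1.10, "nearly_additive", "0"),
            (1.11, "slight_antagonism", "-"),
            (1.3, "moderate_antagonism", "--"),
            (2.0, "antagonism", "---"),
            (5.0, "strong_antagonism", "----"),
        ],
    )
    def test_band_assignment(self, value, category, symbol):
        cat, sym, oos = categorize_ci(value)
        assert (cat, sym) == (category, symbol)
        assert not oos

    def test_out_of_scale_flags(self):
        cat, _, oos = categorize_ci(12.0)
        assert cat == "strong_antagonism" and oos
        cat, _, oos = categorize_ci(0.05)
        assert cat == "strong_synergism" and oos

    @pytest.mark.parametrize("bad", [0.0, -1.0, math.nan])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValidationError):
            categorize_ci(bad)


def _fit(half_max, se_log10):
    import math as m

    return FitResult(
        endpoint=Endpoint.IL6, treatment_label="t", direction="inhibition",
        top=100.0, bottom=0.0, log10_half_max=m.log10(half_max), hill=1.0,
        half_max=half_max, ci95=(half_max / 2, half_max * 2), se_log10=se_log10,
        df=20, converged=True, flat=False, residual_sd=1.0, n_points=24,
    )


class TestCombinationInterval:
    def test_zero_errors_degenerate_to_point(self):
        point = combination_index(14.0, 152.0, None, 5.0).ci_value
        lo, hi = combination_interval(_fit(14, 0.0), _fit(152, 0.0), None,
                                      _fit(5, 0.0), n_boot=200, seed=1)
        assert lo == pytest.approx(point, rel=1e-12)
        assert hi == pytest.approx(point, rel=1e-12)

    def test_contains_point_and_deterministic(self):
        args = (_fit(14, 0.05), _fit(152, 0.1), None, _fit(5, 0.05))
        point = combination_index(14.0, 152.0, None, 5.0).ci_value
        lo, hi = combination_interval(*args, n_boot=2000, seed=7)
        assert lo < point < hi
        assert (lo, hi) == combination_interval(*args, n_boot=2000, seed=7)
        assert (lo, hi) != combination_interval(*args, n_boot=2000, seed=8)

    def test_unconverged_fit_rejected(self):
        bad = FitResult(
            endpoint=Endpoint.IL6, treatment_label="t", direction="inhibition",
            top=100.0, bottom=0.0, log10_half_max=None, hill=None, half_max=None,
            ci95=None, se_log10=None, df=20, converged=False, flat=False,
            residual_sd=1.0, n_points=24,
        )
        with pytest.raises(ValidationError):
            combination_interval(_fit(14, 0.1), None, None, bad)
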