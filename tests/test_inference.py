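import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synertri.inference import (
    dunnett_max_abs_cdf,
    is_active,
    one_way_anova_dunnett,
    two_way_anova_dunnett,
)
from synertri.models import Endpoint, ValidationError


class TestOneWayDunnett:
    def test_identical_constant_groups_give_p_one(self):
        groups = {"s": [5.0, 5.0, 5.0], "a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0]}
        res = one_way_anova_dunnett(groups, "s")
        assert all(c.adjusted_p == 1.0 for c in res.comparisons)

    def test_single_comparison_reduces_to_pooled_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 5)
        res = one_way_anova_dunnett({"s": a, "x": b}, "s")
        _, p = stats.ttest_ind(b, a, equal_var=True)
        assert res.comparisons[0].adjusted_p == pytest.approx(p, abs=1e-6)

    def test_matches_scipy_dunnett(self):
        """Independent oracle: scipy's Dunnett test (randomised multivariate-t
        integration) agrees with the deterministic quadrature."""
        rng = np.random.default_rng(9)
        s = rng.normal(0, 1, 4)
        tr = [rng.normal(mu, 1, 4) for mu in (0.3, 1.2, 2.5)]
        mine = one_way_anova_dunnett(
            {"s": s, "a": tr[0], "b": tr[1], "c": tr[2]}, "s"
        )
        ref = stats.dunnett(*tr, control=s)
        got = [c.adjusted_p for c in mine.comparisons]
        np.testing.assert_allclose(got, ref.pvalue, atol=5e-4)

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(4)
        groups = {"s": rng.normal(0, 1, 4)}
        groups.update({f"g{i}": rng.normal(0.5, 1, 4) for i in range(3)})
        res = one_way_anova_dunnett(groups, "s")
        for c in res.comparisons:
            raw = 2 * stats.t.sf(abs(c.t_statistic), res.df_error)
            assert c.adjusted_p >= raw - 1e-12

    def test_monotone_in_mean_difference(self):
        base = {"s": [0.0, 0.1, -0.1], "b": [0.5, 0.6, 0.4]}
        p_small = one_way_anova_dunnett({**base, "a": [0.3, 0.4, 0.2]}, "s").adjusted_p("a")
        p_large = one_way_anova_dunnett({**base, "a": [1.3, 1.4, 1.2]}, "s").adjusted_p("a")
        assert p_large < p_small

    def test_insufficient_replication_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova_dunnett({"s": [1.0], "a": [1.0, 2.0]}, "s")

    def test_missing_control_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova_dunnett({"a": [1.0, 2.0], "b": [1.0, 2.0]}, "x")

    def test_degenerate_variance_unequal_means(self):
        res = one_way_anova_dunnett({"s": [1.0, 1.0], "a": [2.0, 2.0]}, "s")
        assert res.comparisons[0].adjusted_p == 0.0


def test_cdf_is_monotone_and_bounded():
    lam = [np.sqrt(0.5)] * 3
    vals = [dunnett_max_abs_cdf(t, lam, 8) for t in (0.5, 1.0, 2.0, 4.0)]
    assert all(0 <= v <= 1 for v in vals)
    assert np.all(np.diff(vals) > 0)
    assert dunnett_max_abs_cdf(50.0, lam, 8) == pytest.approx(1.0, abs=1e-9)


class TestTwoWayDunnett:
    @staticmethod
    def _frame(rng, time_effect=0.0, trt_effect=0.0, n=3):
        rows = []
        for trt in ("s", "a", "b"):
            for t in (4.0, 24.0, 48.0):
                mu = (trt != "s") * trt_effect + (t / 48.0) * time_effect
                for v in rng.normal(mu, 1.0, n):
                    rows.append({"treatment": trt, "time_h": t, "value": v})
        return pd.DataFrame(rows)

    def test_time_constant_data_zero_time_ss(self):
        df = self._frame(np.random.default_rng(0), 0.0, 0.0)
        # make values independent of time: copy the t=4 block to others
        base = df[df.time_h == 4.0]["value"].to_numpy()
        for t in (24.0, 48.0):
            df.loc[df.time_h == t, "value"] = base
        res = two_way_anova_dunnett(df, "s")
        assert res.anova_table["time"]["ss"] == pytest.approx(0.0, abs=1e-18)
        assert res.anova_table["interaction"]["ss"] == pytest.approx(0.0, abs=1e-18)

    def test_single_time_reduces_to_one_way(self):
        rng = np.random.default_rng(1)
        df = self._frame(rng)
        sub = df[df.time_h == 48.0]
        two = two_way_anova_dunnett(sub, "s")
        groups = {t: g["value"].to_numpy() for t, g in sub.groupby("treatment")}
        one = one_way_anova_dunnett(groups, "s")
        got = {c.label: c.adjusted_p for c in two.per_time[48.0].comparisons}
        want = {c.label: c.adjusted_p for c in one.comparisons}
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-12)

    def test_underreplicated_cell_rejected(self):
        df = self._frame(np.random.default_rng(2))
        df = df.drop(df[(df.treatment == "a") & (df.time_h == 24.0)].index[:2])
        with pytest.raises(ValidationError, match="cells"):
            two_way_anova_dunnett(df, "s")

    def test_strong_effect_detected_within_time(self):
        df = self._frame(np.random.default_rng(3), trt_effect=6.0)
        res = two_way_anova_dunnett(df, "s")
        assert res.per_time[48.0].adjusted_p("a") < 0.001


class TestIsActive:
    def test_truth_table(self):
        rng = np.random.default_rng(5)
        sig = one_way_anova_dunnett(
            {"s": rng.normal(0, 0.2, 4), "a": rng.normal(5, 0.2, 4)}, "s"
        )
        ns = one_way_anova_dunnett(
            {"s": rng.normal(0, 1, 4), "a": rng.normal(0, 1, 4)}, "s"
        )
        assert is_active(sig, flat_curve_verdict=False)
        assert not is_active(sig, flat_curve_verdict=True)
        assert not is_active(ns, flat_curve_verdict=False)
        assert not is_active(ns, flat_curve_verdict=True)


def test_highest_myrrh_concentration_detected_on_il6():
    """Power spot-check against generator truth: with the default noise the
    top myrrh concentration suppresses IL-6 far below the stimulated control
    and the within-time Dunnett comparison flags it."""
    from synertri.pipeline import _dunnett_for_treatment
    from synertri.synthetic import GeneratorConfig, generate_assay

    hits = 0
    n = 20
    for seed in range(n):
        ds, _ = generate_assay(GeneratorConfig(noise_cv=0.15, seed=seed))
        dn = _dunnett_for_treatment(ds, Endpoint.IL6, "myrrh", 48.0)
        top_label = max(
            (c.label for c in dn.comparisons),
            key=lambda lbl: float(lbl.split("=")[1]),
        )
        hits += dn.adjusted_p(top_label) < 0.05
    assert hits >= int(0.9 * n)
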