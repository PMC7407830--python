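"""ANOVA + Dunnett significance layer.

Several treatment levels (typically the concentration steps of one extract)
are compared against the single shared stimulated control with familywise
error control. Adjusted two-sided p-values come from the exact Dunnett
distribution: with a common control, the t statistics are jointly
multivariate t with correlations lambda_i * lambda_j,
lambda_i = sqrt(n_i / (n_i + n0)), and

    P(max_i |T_i| <= t) =
      E_U E_Z  prod_i [ Phi((tU + l_i Z)/sqrt(1-l_i^2))
                        - Phi((-tU + l_i Z)/sqrt(1-l_i^2)) ]

where Z is the shared standard-normal control variate and U = chi_nu /
sqrt(nu) the pooled-variance scale. The two-dimensional integral is
evaluated by deterministic quadrature (Gauss-Hermite in Z, adaptive
quadrature in U), so the reported stars are reproducible without a seed.

Mediator release measured at several time points uses a two-factor
fixed-effects ANOVA (treatment, time, interaction); Dunnett comparisons are
then run within each time point against the same-time stimulated control
using the pooled two-way error term.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import integrate, stats

from .models import Endpoint, ValidationError

__all__ = [
    "Significance",
    "DunnettComparison",
    "DunnettResult",
    "TwoWayResult",
    "dunnett_max_abs_cdf",
    "one_way_anova_dunnett",
    "two_way_anova_dunnett",
    "is_active",
]


class Significance(str, enum.Enum):
    ns = "ns"
    p05 = "*"
    p01 = "**"
    p001 = "***"
    p0001 = "****"


def _stars(p: float) -> Significance:
    if p < 1e-4:
        return Significance.p0001
    if p < 1e-3:
        return Significance.p001
    if p < 1e-2:
        return Significance.p01
    if p < 0.05:
        return Significance.p05
    return Significance.ns


@dataclass(frozen=True)
class DunnettComparison:
    label: str
    mean_difference: float
    t_statistic: float
    adjusted_p: float
    significant_at: Significance


@dataclass(frozen=True)
class DunnettResult:
    comparisons: tuple[DunnettComparison, ...]
    control_label: str
    df_error: int
    n_groups: int
    anova_f: float
    anova_p: float
    endpoint: Endpoint | None = None

    def adjusted_p(self, label: str) -> float:
        for c in self.comparisons:
            if c.label == label:
                return c.adjusted_p
        raise KeyError(label)

    @property
    def any_significant(self) -> bool:
        return any(c.adjusted_p < 0.05 for c in self.comparisons)


@dataclass(frozen=True)
class TwoWayResult:
    """Two-factor ANOVA decomposition plus within-time Dunnett results."""

    anova_table: dict[str, dict[str, float]]  # effect -> {ss, df, F, p}
    per_time: dict[float, DunnettResult]
    df_error: int
    mse: float


_GH_NODES, _GH_WEIGHTS = hermegauss(80)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)  # E[f(Z)] = sum w f(z)


def dunnett_max_abs_cdf(t: float, lambdas: Sequence[float], df: int) -> float:
    """P(max_i |T_i| <= t) for Dunnett statistics vs a shared control.

    ``lambdas`` are sqrt(n_i / (n_i + n0)) for the full comparison family;
    ``df`` the pooled error degrees of freedom. Deterministic to the
    quadrature tolerance (~1e-9).
    """
    if t <= 0:
        return 0.0
    lam = np.asarray(lambdas, dtype=float)
    if np.any((lam <= 0) | (lam >= 1)):
        raise ValidationError("lambdas must lie strictly in (0, 1)")
    comp = np.sqrt(1.0 - lam**2)
    z = _GH_NODES

    def inner(s: float) -> float:
        # product over comparisons of the conditional band probability
        a = (s + lam[:, None] * z[None, :]) / comp[:, None]
        b = (-s + lam[:, None] * z[None, :]) / comp[:, None]
        band = stats.norm.cdf(a) - stats.norm.cdf(b)
        return float(np.dot(np.prod(band, axis=0), _GH_WEIGHTS))

    sqrt_df = np.sqrt(df)

    def integrand(u: float) -> float:
        return stats.chi.pdf(u * sqrt_df, df) * sqrt_df * inner(t * u)

    val, _ = integrate.quad(
        integrand, 0.0, np.inf, epsabs=1e-10, epsrel=1e-10, limit=200
    )
    return min(max(val, 0.0), 1.0)


def one_way_anova_dunnett(
    groups: Mapping[str, Sequence[float]],
    control_label: str = "s",
    endpoint: Endpoint | None = None,
) -> DunnettResult:
    """Pooled-variance one-way ANOVA with Dunnett comparisons vs the control."""
    if control_label not in groups:
        raise ValidationError(f"control group {control_label!r} not among groups")
    if len(groups) < 2:
        raise ValidationError("need at least one treatment group besides the control")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValidationError(f"group {k!r} has < 2 replicates")
        if not np.all(np.isfinite(a)):
            raise ValidationError(f"group {k!r} has non-finite values")

    labels = [k for k in arrays if k != control_label]
    ns = {k: a.size for k, a in arrays.items()}
    means = {k: float(a.mean()) for k, a in arrays.items()}
    n_total = sum(ns.values())
    k_groups = len(arrays)
    df_error = n_total - k_groups
    mse = sum((a.size - 1) * a.var(ddof=1) for a in arrays.values()) / df_error

    grand = sum(a.sum() for a in arrays.values()) / n_total
    ss_between = sum(ns[k] * (means[k] - grand) ** 2 for k in arrays)
    if mse > 0:
        f_stat = (ss_between / (k_groups - 1)) / mse
        anova_p = float(stats.f.sf(f_stat, k_groups - 1, df_error))
    else:
        f_stat = np.inf if ss_between > 0 else 0.0
        anova_p = 0.0 if ss_between > 0 else 1.0

    n0 = ns[control_label]
    lambdas = [np.sqrt(ns[k] / (ns[k] + n0)) for k in labels]
    comparisons = []
    for k in labels:
        diff = means[k] - means[control_label]
        if mse > 0:
            se = np.sqrt(mse * (1.0 / ns[k] + 1.0 / n0))
            t_stat = diff / se
            p = 1.0 - dunnett_max_abs_cdf(abs(t_stat), lambdas, df_error)
        else:
            # degenerate pooled variance: equality of means decides
            t_stat = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        comparisons.append(
            DunnettComparison(
                label=k,
                mean_difference=float(diff),
                t_statistic=float(t_stat),
                adjusted_p=float(p),
                significant_at=_stars(float(p)),
            )
        )
    return DunnettResult(
        comparisons=tuple(comparisons),
        control_label=control_label,
        df_error=int(df_error),
        n_groups=int(k_groups),
        anova_f=float(f_stat),
        anova_p=anova_p,
        endpoint=endpoint,
    )


def two_way_anova_dunnett(
    data: pd.DataFrame,
    control_label: str = "s",
    value_col: str = "value",
    treatment_col: str = "treatment",
    time_col: str = "time_h",
    endpoint: Endpoint | None = None,
) -> TwoWayResult:
    """Two-factor fixed-effects ANOVA with within-time Dunnett comparisons.

    With a single time level this reduces exactly to the one-way analysis.
    Cells (treatment x time) must all be populated with >= 2 replicates.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[treatment_col, time_col, value_col]].rename(
        columns={treatment_col: "treatment", time_col: "time_h", value_col: "value"}
    )
    if control_label not in set(df["treatment"]):
        raise ValidationError(f"control group {control_label!r} not in data")
    times = sorted(df["time_h"].unique())
    counts = df.groupby(["treatment", "time_h"]).size().unstack(fill_value=0)
    empty = [(t, h) for t in counts.index for h in counts.columns if counts.loc[t, h] < 2]
    if empty:
        raise ValidationError(f"treatment x time cells with < 2 replicates: {empty}")

    if len(times) == 1:
        groups = {t: g["value"].to_numpy() for t, g in df.groupby("treatment")}
        one = one_way_anova_dunnett(groups, control_label, endpoint=endpoint)
        table = {
            "treatment": {
                "ss": np.nan,
                "df": one.n_groups - 1,
                "F": one.anova_f,
                "p": one.anova_p,
            }
        }
        return TwoWayResult(
            anova_table=table,
            per_time={float(times[0]): one},
            df_error=one.df_error,
            mse=np.nan,
        )

    model = smf.ols("value ~ C(treatment) * C(time_h)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    table = {}
    name_map = {
        "C(treatment)": "treatment",
        "C(time_h)": "time",
        "C(treatment):C(time_h)": "interaction",
        "Residual": "residual",
    }
    for raw, eff in name_map.items():
        row = aov.loc[raw]
        table[eff] = {
            "ss": float(row["sum_sq"]),
            "df": float(row["df"]),
            "F": float(row["F"]) if np.isfinite(row.get("F", np.nan)) else np.nan,
            "p": float(row["PR(>F)"]) if np.isfinite(row.get("PR(>F)", np.nan)) else np.nan,
        }
    df_error = int(table["residual"]["df"])
    mse = table["residual"]["ss"] / df_error if df_error > 0 else 0.0

    per_time: dict[float, DunnettResult] = {}
    for h in times:
        sub = df[df["time_h"] == h]
        cells = {t: g["value"].to_numpy() for t, g in sub.groupby("treatment")}
        labels = [t for t in cells if t != control_label]
        n0 = cells[control_label].size
        lambdas = [np.sqrt(cells[t].size / (cells[t].size + n0)) for t in labels]
        comps = []
        control_mean = cells[control_label].mean()
        for t in labels:
            diff = cells[t].mean() - control_mean
            if mse > 0:
                se = np.sqrt(mse * (1.0 / cells[t].size + 1.0 / n0))
                t_stat = diff / se
                p = 1.0 - dunnett_max_abs_cdf(abs(t_stat), lambdas, df_error)
            else:
                t_stat = np.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            comps.append(
                DunnettComparison(
                    label=t,
                    mean_difference=float(diff),
                    t_statistic=float(t_stat),
                    adjusted_p=float(p),
                    significant_at=_stars(float(p)),
                )
            )
        per_time[float(h)] = DunnettResult(
            comparisons=tuple(comps),
            control_label=control_label,
            df_error=df_error,
            n_groups=len(cells),
            anova_f=table["treatment"]["F"],
            anova_p=table["treatment"]["p"],
            endpoint=endpoint,
        )
    return TwoWayResult(anova_table=table, per_time=per_time, df_error=df_error, mse=float(mse))


def is_active(dunnett: DunnettResult, flat_curve_verdict: bool) -> bool:
    """Activity verdict feeding combination-index term extraction.

    A treatment counts as active on an endpoint iff at least one of its
    concentration levels differs significantly from the stimulated control
    (Dunnett-adjusted p < 0.05) and the fitted curve was not flat.
    """
    return dunnett.any_significant and not flat_curve_verdict
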