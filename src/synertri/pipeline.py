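"""End-to-end orchestration: normalize -> fit -> test -> combination index.

``run_analysis`` drives the full analysis of one :class:`AssayDataset`; the
half-maximal concentrations feeding the combination index are taken at 48 h.
``replicate_table1`` bypasses fitting entirely and recomputes the
combination-index column directly from the published half-maximal point
estimates (the published table's own inputs), which pins down the synergy
arithmetic independently of any data generation or curve fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import published as pub
from .dose_response import FitResult, fit_enhancement, fit_inhibition
from .inference import DunnettResult, is_active, one_way_anova_dunnett, two_way_anova_dunnett
from .models import AssayDataset, Endpoint
from .normalization import normalize_teer_series, percent_of_stimulated
from .plate_io import extract_series, write_results_table, write_run_report
from .synergy import (
    CombinationIndexResult,
    NoActiveComponentError,
    combination_index,
    combination_interval,
)

__all__ = ["RunConfig", "EndpointResult", "run_analysis", "replicate_table1"]


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings: component mapping, inference level, seeds, output."""

    components: tuple[str, str, str] = pub.COMPONENTS
    combination_label: str = pub.COMBINATION
    endpoints: tuple[Endpoint, ...] = tuple(Endpoint)
    time_h: float = 48.0
    alpha: float = 0.05
    n_boot: int = 2000
    seed: int = 0
    outdir: Path | None = None

    def __post_init__(self) -> None:
        if len(set(self.components)) != 3:
            raise ValueError("component mapping must name exactly three distinct labels")


@dataclass
class EndpointResult:
    endpoint: Endpoint
    fits: dict[str, FitResult | None]
    dunnett: dict[str, DunnettResult | None]
    active: dict[str, bool]
    ci: CombinationIndexResult | None
    ci_interval: tuple[float, float] | None
    errors: dict[str, str] = field(default_factory=dict)


def _dunnett_for_treatment(
    ds: AssayDataset, endpoint: Endpoint, label: str, time_h: float
) -> DunnettResult:
    """Dunnett comparisons of a treatment's concentration levels vs the
    stimulated control, using the design the endpoint was measured under
    (two-way over time for multi-time mediators, one-way otherwise)."""
    from .normalization import teer_difference

    treated = ds.rows(endpoint=endpoint, treatment=label, control_class="treated")
    control = ds.rows(endpoint=endpoint, control_class="s")

    def _vals(rows: pd.DataFrame) -> np.ndarray:
        if endpoint.is_teer:
            return np.asarray(
                teer_difference(
                    rows["value_before"].to_numpy(float),
                    rows["value_after"].to_numpy(float),
                )
            )
        return rows["value"].to_numpy(float)

    frames = []
    for rows, name in ((treated, None), (control, "s")):
        sub = pd.DataFrame(
            {
                "treatment": (
                    rows["concentration_ug_ml"].map(lambda c: f"c={c:g}")
                    if name is None
                    else "s"
                ),
                "time_h": rows["time_h"].astype(float),
                "value": _vals(rows),
            }
        )
        frames.append(sub)
    data = pd.concat(frames, ignore_index=True)
    n_times = data["time_h"].nunique()
    if n_times > 1:
        two = two_way_anova_dunnett(data, control_label="s", endpoint=endpoint)
        return two.per_time[float(time_h)]
    groups = {t: g["value"].to_numpy() for t, g in data.groupby("treatment")}
    return one_way_anova_dunnett(groups, control_label="s", endpoint=endpoint)


def analyse_endpoint(
    ds: AssayDataset, endpoint: Endpoint, config: RunConfig
) -> EndpointResult:
    labels = (*config.components, config.combination_label)
    fits: dict[str, FitResult | None] = {}
    dunnett: dict[str, DunnettResult | None] = {}
    active: dict[str, bool] = {}
    errors: dict[str, str] = {}

    for label in labels:
        try:
            series = extract_series(ds, endpoint, label, config.time_h)
            if endpoint.is_teer:
                fit = fit_enhancement(normalize_teer_series(series))
            else:
                fit = fit_inhibition(percent_of_stimulated(series))
            fits[label] = fit
        except Exception as exc:  # degradation contract: keep other stages
            fits[label] = None
            errors[f"fit:{label}"] = f"{type(exc).__name__}: {exc}"
        try:
            dunnett[label] = _dunnett_for_treatment(ds, endpoint, label, config.time_h)
        except Exception as exc:
            dunnett[label] = None
            errors[f"dunnett:{label}"] = f"{type(exc).__name__}: {exc}"
        fit = fits[label]
        dn = dunnett[label]
        if fit is None or dn is None:
            active[label] = False
        else:
            active[label] = is_active(dn, fit.flat) and fit.active

    ci = None
    ci_interval = None
    comb = config.combination_label
    if active.get(comb) and fits[comb] is not None:
        half = {
            lbl: (fits[lbl].half_max if active.get(lbl) and fits[lbl] else None)
            for lbl in config.components
        }
        try:
            a, b, c = (half[lbl] for lbl in config.components)
            ci = combination_index(a, b, c, fits[comb].half_max, endpoint=endpoint)
        except NoActiveComponentError as exc:
            errors["ci"] = f"{type(exc).__name__}: {exc}"
        if ci is not None:
            try:
                fa, fb, fc = (
                    fits[lbl] if active.get(lbl) else None
                    for lbl in config.components
                )
                ci_interval = combination_interval(
                    fa, fb, fc, fits[comb], n_boot=config.n_boot, seed=config.seed
                )
            except Exception as exc:
                errors["ci_interval"] = f"{type(exc).__name__}: {exc}"
    else:
        errors.setdefault("ci", "combination treatment inactive or unfitted; CI skipped")

    return EndpointResult(
        endpoint=endpoint,
        fits=fits,
        dunnett=dunnett,
        active=active,
        ci=ci,
        ci_interval=ci_interval,
        errors=errors,
    )


def run_analysis(ds: AssayDataset, config: RunConfig | None = None) -> dict:
    """Analyse every requested endpoint; returns the full-precision report.

    When ``config.outdir`` is set, also writes the published-style summary
    CSV (``results_table.csv``) and the JSON run report (``run_report.json``).
    Deterministic given (dataset, config, seed).
    """
    from . import __version__

    config = config or RunConfig()
    results = [analyse_endpoint(ds, ep, config) for ep in config.endpoints]

    report = {
        "software": {"name": "synertri", "version": __version__},
        "config": {
            "components": list(config.components),
            "combination_label": config.combination_label,
            "time_h": config.time_h,
            "alpha": config.alpha,
            "n_boot": config.n_boot,
            "seed": config.seed,
        },
        "dataset_metadata": dict(ds.metadata),
        "teer_sign_convention": "difference stored as after - before; decline negative",
        "endpoints": {},
    }
    for res in results:
        ep_report: dict = {"active": res.active, "errors": res.errors}
        # which inactivity trigger fired per treatment (flat curve vs no
        # Dunnett-significant level); both are recorded explicitly
        ep_report["inactive_triggers"] = {
            lbl: {
                "flat_curve": bool(fit.flat) if fit is not None else None,
                "no_significant_level": (
                    (not res.dunnett[lbl].any_significant)
                    if res.dunnett.get(lbl) is not None
                    else None
                ),
            }
            for lbl, fit in res.fits.items()
        }
        ep_report["fits"] = {
            lbl: (
                None
                if fit is None
                else {
                    "direction": fit.direction,
                    "top": fit.top,
                    "bottom": fit.bottom,
                    "hill": fit.hill,
                    "half_max": fit.half_max,
                    "log10_half_max": fit.log10_half_max,
                    "ci95": list(fit.ci95) if fit.ci95 else None,
                    "se_log10": fit.se_log10,
                    "converged": fit.converged,
                    "flat": fit.flat,
                    "residual_sd": fit.residual_sd,
                    "n_points": fit.n_points,
                    "df": fit.df,
                }
            )
            for lbl, fit in res.fits.items()
        }
        ep_report["dunnett"] = {
            lbl: (
                None
                if dn is None
                else {
                    "df_error": dn.df_error,
                    "n_groups": dn.n_groups,
                    "anova_f": dn.anova_f,
                    "anova_p": dn.anova_p,
                    "comparisons": [
                        {
                            "label": c.label,
                            "mean_difference": c.mean_difference,
                            "adjusted_p": c.adjusted_p,
                            "significant_at": c.significant_at.value,
                        }
                        for c in dn.comparisons
                    ],
                }
            )
            for lbl, dn in res.dunnett.items()
        }
        if res.ci is not None:
            label_of = dict(zip(("A", "B", "C"), config.components))
            ep_report["combination_index"] = {
                "value": res.ci.ci_value,
                "rounded": round(res.ci.ci_value, 2),
                "category": res.ci.category,
                "symbol": res.ci.symbol,
                "included": [label_of[k] for k in res.ci.included],
                "terms": {label_of[k]: v for k, v in res.ci.terms.items()},
                "bootstrap_interval": list(res.ci_interval) if res.ci_interval else None,
            }
        else:
            ep_report["combination_index"] = None
        report["endpoints"][res.endpoint.name] = ep_report

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table_rows = [
            {"endpoint": r.endpoint, "fits": {
                lbl: (fit if r.active.get(lbl) else None)
                for lbl, fit in r.fits.items()
            }, "ci": r.ci}
            for r in results
        ]
        write_results_table(table_rows, outdir / "results_table.csv")
        write_run_report(report, outdir / "run_report.json")
    return report


def replicate_table1() -> pd.DataFrame:
    """Recompute the published combination-index column from the published
    half-maximal point estimates themselves (no fitting involved).

    Returns one row per endpoint with the computed value (2 dp), its
    category symbol, the published value/symbol and a pass flag at 2 dp.
    """
    rows = []
    for ep_name, vals in pub.TABLE1_HALF_MAX.items():
        endpoint = Endpoint[ep_name]
        a, b, c = (vals[lbl] for lbl in pub.COMPONENTS)
        res = combination_index(a, b, c, vals[pub.COMBINATION], endpoint=endpoint)
        printed_value, printed_symbol = pub.TABLE1_CI[ep_name]
        computed = round(res.ci_value, 2)
        rows.append(
            {
                "endpoint": endpoint.display,
                "ci_computed": computed,
                "symbol_computed": res.symbol,
                "ci_published": printed_value,
                "symbol_published": printed_symbol,
                "match": computed == printed_value and res.symbol == printed_symbol,
            }
        )
    return pd.DataFrame(rows)
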