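"""Reading, validation and writing of the assay's tabular data and results.

Input is a single long (tidy) CSV dialect: one row per well-measurement,
UTF-8, ``.`` decimal separator, with the header columns of
:data:`synertri.models.SCHEMA_COLUMNS`. TEER wells carry paired
``value_before``/``value_after`` readings in one row so the 48 h difference
is explicit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .models import (
    SCHEMA_COLUMNS,
    AssayDataset,
    ControlClass,
    Endpoint,
    LookupError_,
    SchemaError,
    ValidationError,
)
from .normalization import ConcentrationResponseSeries, teer_difference

__all__ = [
    "read_dataset",
    "write_dataset",
    "extract_series",
    "write_results_table",
    "write_run_report",
]

#: columns that must appear in an input header (unit-bearing names on purpose)
_REQUIRED = tuple(c for c in SCHEMA_COLUMNS if c not in ("value_before", "value_after"))


def read_dataset(path: str | Path, format: str = "long_csv") -> AssayDataset:
    """Read and validate a long-format plate CSV into an :class:`AssayDataset`."""
    if format != "long_csv":
        raise ValueError(f"unsupported format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty input file: {path}") from exc
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for opt in ("value_before", "value_after"):
        if opt not in df.columns:
            df[opt] = np.nan
    df = df[list(SCHEMA_COLUMNS)]
    for col in ("concentration_ug_ml", "time_h", "value", "value_before", "value_after"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["replicate"] = df["replicate"].astype(int)
    return AssayDataset(df=df.reset_index(drop=True))


def write_dataset(ds: AssayDataset, path: str | Path) -> Path:
    """Write an :class:`AssayDataset` back to the long CSV dialect.

    Reals are serialised with 17 significant digits so a write/read round
    trip preserves them bit-for-bit.
    """
    path = Path(path)
    ds.df.to_csv(path, index=False, float_format="%.17g")
    return path


def extract_series(
    ds: AssayDataset,
    endpoint: Endpoint,
    treatment_label: str,
    time_h: float = 48.0,
) -> ConcentrationResponseSeries:
    """Pull the raw concentration-response series for one endpoint x treatment.

    Returns well-level pairs sorted by concentration ascending, with the
    matched control anchors (stimulated mean, plus the inactivated or
    unstimulated mean per the endpoint's compartment) at the same time point.
    TEER rows are reduced to their before/after difference.
    """
    treated = ds.rows(
        endpoint=endpoint,
        control_class=ControlClass.treated.value,
        treatment=treatment_label,
        time_h=time_h,
    )
    if len(treated) == 0:
        raise LookupError_(
            f"no rows for endpoint={endpoint.name}, treatment={treatment_label!r}, "
            f"time={time_h} h"
        )

    def _values(rows: pd.DataFrame) -> np.ndarray:
        if endpoint.is_teer:
            return np.asarray(
                teer_difference(
                    rows["value_before"].to_numpy(float),
                    rows["value_after"].to_numpy(float),
                )
            )
        return rows["value"].to_numpy(float)

    s_rows = ds.rows(endpoint=endpoint, control_class="s", time_h=time_h)
    ref_rows = ds.rows(endpoint=endpoint, control_class=endpoint.reference_control, time_h=time_h)
    if len(s_rows) == 0 or len(ref_rows) == 0:
        raise LookupError_(
            f"missing control wells (s and/or {endpoint.reference_control}) for "
            f"{endpoint.name} at {time_h} h"
        )
    conc = treated["concentration_ug_ml"].to_numpy(float)
    resp = _values(treated)
    order = np.argsort(conc, kind="stable")
    return ConcentrationResponseSeries(
        endpoint=endpoint,
        treatment_label=treatment_label,
        concentrations=conc[order],
        responses=resp[order],
        s_mean=float(np.mean(_values(s_rows))),
        ref_mean=float(np.mean(_values(ref_rows))),
        time_h=float(time_h),
        scale="raw",
    )


def _fmt_half_max(fit) -> str:
    if fit is None or not getattr(fit, "converged", False) or fit.half_max is None:
        return "-"
    lo, hi = fit.ci95 if fit.ci95 is not None else (float("nan"), float("nan"))
    return f"{fit.half_max:.0f} ({lo:.1f}-{hi:.1f})"


def write_results_table(results: Iterable[Mapping], path: str | Path) -> Path:
    """Emit a published-style summary CSV: one row per endpoint.

    Each item of ``results`` maps treatment labels to
    :class:`~synertri.dose_response.FitResult` (or None for
    inactive/unfitted) under ``fits``, plus ``endpoint`` and ``ci``
    (a :class:`~synertri.synergy.CombinationIndexResult` or None).
    Half-maximal concentrations are rounded to integers, the combination
    index to two decimals; "-" marks cells with no significant effect.
    """
    results = list(results)
    if not results:
        raise ValidationError("no results to write")
    path = Path(path)
    rows = []
    for item in results:
        endpoint: Endpoint = item["endpoint"]
        fits = item["fits"]
        ci = item.get("ci")
        row = {"endpoint": endpoint.display}
        for label, fit in fits.items():
            row[label] = _fmt_half_max(fit)
        if ci is not None:
            row["combination_index"] = f"{ci.ci_value:.2f} ({ci.symbol})"
        else:
            row["combination_index"] = "-"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_run_report(report: Mapping, path: str | Path) -> Path:
    """Serialise the full-precision run report (fits, tests, CIs, seeds) as JSON."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Endpoint):
        return obj.name
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in vars(obj).items()}
    raise TypeError(f"not JSON serialisable: {type(obj)}")
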