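"""Ternary Chou-style combination index for an equal-parts three-extract mix.

For an endpoint with individual half-maximal concentrations IC50_A, IC50_B,
IC50_C and a combination IC50 (expressed as *total* extract concentration),
each component's share of the combination potency is one third of the total
(the mixture is equal parts), and

    CI = IC50_comb / IC50_A + IC50_comb / IC50_B + IC50_comb / IC50_C

with IC50_comb = IC50(combination, total) / 3. A component with no
significant effect on the endpoint contributes no term (its ratio is
extracted from the sum). CI < 0.9 indicates synergism, 0.9-1.10 a nearly
additive interaction, and CI > 1.10 antagonism, with finer Chou bands below.
The TEER barrier endpoint uses EC50s in the same formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import Endpoint, ValidationError

__all__ = [
    "CombinationIndexResult",
    "NoActiveComponentError",
    "combination_index",
    "categorize_ci",
    "combination_interval",
    "CATEGORY_SYMBOLS",
]


class NoActiveComponentError(ValueError):
    """All three component terms were extracted; the CI is undefined."""


#: Chou interaction bands, half-open and closed at the lower edge except the
#: nearly-additive band which is closed on both sides. The printed edge cases
#: (0.83 -> moderate synergism, 1.11 -> slight antagonism) pin the convention.
_BANDS = [
    (0.10, 0.30, "strong_synergism", "++++"),
    (0.30, 0.70, "synergism", "+++"),
    (0.70, 0.85, "moderate_synergism", "++"),
    (0.85, 0.90, "slight_synergism", "+"),
]

CATEGORY_SYMBOLS = {
    "strong_synergism": "++++",
    "synergism": "+++",
    "moderate_synergism": "++",
    "slight_synergism": "+",
    "nearly_additive": "0",
    "slight_antagonism": "-",
    "moderate_antagonism": "--",
    "antagonism": "---",
    "strong_antagonism": "----",
}


@dataclass(frozen=True)
class CombinationIndexResult:
    endpoint: Endpoint | None
    ic50_a: float | None
    ic50_b: float | None
    ic50_c: float | None
    ic50_combination_total: float
    ic50_comb: float  # one third of the combination total
    terms: dict[str, float]  # component key -> ic50_comb / ic50_i
    included: tuple[str, ...]
    ci_value: float
    category: str
    symbol: str
    out_of_scale: bool = False


def categorize_ci(ci_value: float) -> tuple[str, str, bool]:
    """Map a CI value to its Chou interaction band.

    Returns ``(category, symbol, out_of_scale)``; values below 0.1 or above
    10 clamp to the strongest band with the out-of-scale flag set.
    """
    if not math.isfinite(ci_value) or ci_value <= 0:
        raise ValidationError(f"combination index must be positive, got {ci_value}")
    if ci_value < 0.10:
        return "strong_synergism", "++++", True
    for lo, hi, cat, sym in _BANDS:
        if lo <= ci_value < hi:
            return cat, sym, False
    if 0.90 <= ci_value <= 1.10:
        return "nearly_additive", "0", False
    if ci_value <= 1.20:
        return "slight_antagonism", "-", False
    if ci_value <= 1.45:
        return "moderate_antagonism", "--", False
    if ci_value <= 3.3:
        return "antagonism", "---", False
    if ci_value <= 10.0:
        return "strong_antagonism", "----", False
    return "strong_antagonism", "----", True


def combination_index(
    ic50_a: float | None,
    ic50_b: float | None,
    ic50_c: float | None,
    ic50_combination_total: float,
    endpoint: Endpoint | None = None,
) -> CombinationIndexResult:
    """Compute the ternary combination index with term extraction.

    ``None`` marks a component with no significant effect on this endpoint;
    its term is omitted. ``ic50_combination_total`` is the total concentration
    of the equal-parts mixture at half-maximal effect; each component is
    credited one third of it.
    """
    if not (math.isfinite(ic50_combination_total) and ic50_combination_total > 0):
        raise ValidationError(
            f"combination IC50 must be positive, got {ic50_combination_total}"
        )
    components = {"A": ic50_a, "B": ic50_b, "C": ic50_c}
    for key, val in components.items():
        if val is not None and not (math.isfinite(val) and val > 0):
            raise ValidationError(f"IC50_{key} must be positive or None, got {val}")
    included = tuple(k for k, v in components.items() if v is not None)
    if not included:
        raise NoActiveComponentError(
            "no component had a significant effect; combination index undefined"
        )
    ic50_comb = ic50_combination_total / 3.0
    # each term is total/(3*ic50_i); this form keeps the equal-potency case
    # (all inputs identical) at exactly 1.0 in floating point
    terms = {k: ic50_combination_total / (3.0 * components[k]) for k in included}
    ci_value = float(math.fsum(terms.values()))
    category, symbol, oos = categorize_ci(ci_value)
    return CombinationIndexResult(
        endpoint=endpoint,
        ic50_a=ic50_a,
        ic50_b=ic50_b,
        ic50_c=ic50_c,
        ic50_combination_total=ic50_combination_total,
        ic50_comb=ic50_comb,
        terms=terms,
        included=included,
        ci_value=ci_value,
        category=category,
        symbol=symbol,
        out_of_scale=oos,
    )


def combination_interval(
    fit_a,
    fit_b,
    fit_c,
    fit_comb,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Parametric-bootstrap percentile interval on the combination index.

    An uncertainty-propagation extension beyond the point CI: log10 IC50s of
    every included component and the combination are resampled from normal
    distributions at each fit's asymptotic standard error, the CI is
    recomputed per draw, and the 2.5/97.5 percentiles are returned.
    Deterministic given ``seed``. Inactive components (``fit_a/b/c`` is None)
    stay extracted in every draw.
    """
    fits = {"A": fit_a, "B": fit_b, "C": fit_c}
    active = {k: f for k, f in fits.items() if f is not None}
    if not active:
        raise NoActiveComponentError("no active component fits supplied")
    for name, f in {**active, "comb": fit_comb}.items():
        if f is None or not f.converged or f.log10_half_max is None:
            raise ValidationError(f"fit {name!r} unconverged: cannot propagate uncertainty")
        if f.se_log10 is None or not math.isfinite(f.se_log10):
            raise ValidationError(f"fit {name!r} has no finite standard error")
    rng = np.random.default_rng(seed)
    draws = {
        k: 10.0 ** rng.normal(f.log10_half_max, f.se_log10, n_boot)
        for k, f in active.items()
    }
    comb = 10.0 ** rng.normal(fit_comb.log10_half_max, fit_comb.se_log10, n_boot)
    ci = (comb / 3.0) * sum(1.0 / draws[k] for k in draws)
    lo, hi = np.percentile(ci, [2.5, 97.5])
    return float(lo), float(hi)
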