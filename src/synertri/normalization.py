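"""Control-anchored transformations.

Mediator release is expressed as percent of the stimulated control (the
``s`` wells define 100%). Barrier integrity uses the TEER difference over
the 48 h incubation; the normalized TEER scale runs from the stimulated
control (0%, most barrier decline) to the unstimulated monolayer (100%).

Sign convention for the TEER difference: stored as ``after - before`` so
that barrier decline is negative. The normalization anchors absorb the
convention — any fixed choice yields identical normalized values — and
reports emit the magnitude of decline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .models import Endpoint, ValidationError

__all__ = [
    "ConcentrationResponseSeries",
    "DegenerateControlError",
    "percent_of_stimulated",
    "teer_difference",
    "normalize_teer",
    "normalize_teer_series",
    "fold_induction",
]


class DegenerateControlError(ValueError):
    """Control anchors are zero, non-positive or coincide."""


Scale = Literal["raw", "percent_of_stimulated", "normalized_teer"]


@dataclass(frozen=True)
class ConcentrationResponseSeries:
    """Well-level (concentration, response) pairs for one endpoint x treatment.

    Concentrations are µg/mL, strictly positive and sorted ascending
    (replicate wells repeat a concentration). Anchors stay on the raw scale:
    ``s_mean`` is the stimulated-control mean; ``ref_mean`` the inactivated
    (``ua``) or unstimulated (``us``) mean matched to the endpoint's
    compartment. For TEER series, responses and anchors are resistance
    differences (after - before, Ohm).
    """

    endpoint: Endpoint
    treatment_label: str
    concentrations: np.ndarray  # shape (n,)
    responses: np.ndarray  # shape (n,)
    s_mean: float
    ref_mean: float
    time_h: float = 48.0
    scale: Scale = "raw"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValidationError("concentrations and responses must be 1-D and aligned")
        if np.any(c <= 0):
            raise ValidationError("concentrations must be strictly positive")
        if np.any(np.diff(c) < 0):
            raise ValidationError("concentrations must be sorted ascending")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)

    @property
    def n_concentrations(self) -> int:
        return int(np.unique(self.concentrations).size)

    def __len__(self) -> int:
        return int(self.concentrations.size)


def percent_of_stimulated(series: ConcentrationResponseSeries) -> ConcentrationResponseSeries:
    """Rescale a raw mediator series so the stimulated control equals 100%.

    Each response ``r`` maps to ``100 * r / s_mean``. Positively homogeneous:
    rescaling all raw values and the anchor together leaves output unchanged.
    """
    if series.endpoint.is_teer:
        raise ValidationError("percent_of_stimulated applies to mediator endpoints only")
    if series.scale != "raw":
        raise ValidationError(f"expected a raw-scale series, got {series.scale!r}")
    if not series.s_mean > 0:
        raise DegenerateControlError(
            f"stimulated-control mean must be positive, got {series.s_mean}"
        )
    # divide first: a response equal to the anchor maps to exactly 100.0
    return replace(
        series,
        responses=(series.responses / series.s_mean) * 100.0,
        scale="percent_of_stimulated",
    )


def teer_difference(value_before: float, value_after: float) -> float:
    """TEER change over the incubation, as ``after - before`` (Ohm).

    Negative values mean barrier decline. Accepts scalars or arrays.
    """
    vb = np.asarray(value_before, dtype=float)
    va = np.asarray(value_after, dtype=float)
    if np.any(vb <= 0) or np.any(va <= 0):
        raise ValidationError("TEER readings must be positive Ohm")
    out = va - vb
    return float(out) if out.ndim == 0 else out


def normalize_teer(diff, s_diff_mean: float, us_diff_mean: float):
    """Map a TEER difference onto the 0% (stimulated) / 100% (unstimulated) scale.

    ``100 * (diff - s_diff_mean) / (us_diff_mean - s_diff_mean)``; affine
    invariant — shifting all differences and anchors by a constant leaves
    the result unchanged.
    """
    span = us_diff_mean - s_diff_mean
    if span == 0:
        raise DegenerateControlError("stimulated and unstimulated TEER anchors coincide")
    # divide first: the anchors map to exactly 0.0 and 100.0
    out = ((np.asarray(diff, dtype=float) - s_diff_mean) / span) * 100.0
    return float(out) if out.ndim == 0 else out


def normalize_teer_series(series: ConcentrationResponseSeries) -> ConcentrationResponseSeries:
    """Apply :func:`normalize_teer` to a raw TEER-difference series."""
    if not series.endpoint.is_teer:
        raise ValidationError("normalize_teer_series applies to the TEER endpoint only")
    if series.scale != "raw":
        raise ValidationError(f"expected a raw-scale series, got {series.scale!r}")
    return replace(
        series,
        responses=normalize_teer(series.responses, series.s_mean, series.ref_mean),
        scale="normalized_teer",
    )


def fold_induction(level_stimulated: float, level_reference: float) -> float:
    """Ratio of stimulated to reference mean mediator level (dimensionless)."""
    if not level_reference > 0:
        raise DegenerateControlError(
            f"reference level must be positive, got {level_reference}"
        )
    return float(level_stimulated) / float(level_reference)
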