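"""Synthetic plate-data generator with known ground truth.

Emulates the statistical structure of the co-culture assay so every
downstream stage is testable without laboratory data: LPS fold-induction of
each mediator over its reference control, monotone 4PL inhibition curves for
treated wells, a rising Hill recovery curve for the TEER barrier embedded in
paired before/after resistance readings, and multiplicative log-normal noise
(ELISA-type errors scale with level and stay positive).

For a treated mediator well at concentration x the mean response is

    ua + (s - ua) * [floor + (1 - floor) / (1 + (x / ic50)^hill)]

and the observed value is the mean times ``LogNormal(0, sigma)`` with sigma
chosen so the coefficient of variation equals ``noise_cv``. Inactive
treatment x endpoint cells (``ic50 = None``) are flat at the stimulated
level plus noise. The combination curve is generated from its own directly
specified IC50 rather than composed from the parts, so the implied true
combination index is a free, testable parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import published as pub
from .models import AssayDataset, Endpoint
from .synergy import CombinationIndexResult, combination_index

__all__ = [
    "TrueCurve",
    "GeneratorConfig",
    "SyntheticTruth",
    "ConfigError",
    "generate_assay",
    "make_table1_fixture",
    "table1_truth",
    "all_active_config",
]


class ConfigError(ValueError):
    """Generator configuration violates an invariant."""


@dataclass(frozen=True)
class TrueCurve:
    """Ground-truth curve for one treatment x endpoint cell.

    ``ic50`` is the half-maximal concentration in µg/mL (total concentration
    for the combination); ``None`` marks an inactive cell (flat response at
    the stimulated level). ``floor`` is the residual release at saturating
    concentration as a fraction of the stimulated level (inhibition
    endpoints only)."""

    ic50: float | None
    hill: float = 1.0
    floor: float = 0.0


def _default_baselines() -> dict[str, float]:
    # reference-control mediator levels, pg/mL, realistic ELISA magnitudes
    return {
        "IL6": 100.0,
        "TNF": 120.0,
        "PGE2_M": 150.0,
        "IL8": 80.0,
        "MCP1": 400.0,
        "PGE2_IEC": 30.0,
    }


def table1_truth() -> dict[str, dict[str, TrueCurve]]:
    """Truth preset whose half-maximal concentrations equal the published
    point estimates; published '-' cells map to inactive."""
    return {
        label: {
            ep: TrueCurve(ic50=vals[label])
            for ep, vals in pub.TABLE1_HALF_MAX.items()
        }
        for label in (*pub.COMPONENTS, pub.COMBINATION)
    }


_MULTI_TIME_ENDPOINTS = {"IL6", "TNF", "IL8", "MCP1"}  # cytokines/chemokines


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and truth parameters of the generator.

    Defaults reproduce the assay's concentration ranges and LPS
    fold-inductions, with the published potencies as the default truth;
    8 log-spaced concentrations per range, 3 treated and 6 control
    replicate wells, 15% noise.
    """

    baselines: dict[str, float] = field(default_factory=_default_baselines)
    fold_induction: dict[str, float] = field(
        default_factory=lambda: dict(pub.FOLD_INDUCTION)
    )
    concentration_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(pub.CONCENTRATION_RANGES)
    )
    n_concentrations: int = 8
    truth: dict[str, dict[str, TrueCurve]] = field(default_factory=table1_truth)
    replicates: int = 3
    control_replicates: int = 6
    noise_cv: float = 0.15
    teer_baseline: float = 500.0  # Ohm
    teer_drop_fraction: float = 0.3  # stimulated barrier decline
    teer_us_gain_fraction: float = 0.1  # unstimulated barrier gain
    bud_effect: float = 0.7  # fractional effect of the positive control
    bud_concentration_um: float = 0.1
    time_profile: dict[float, float] = field(
        default_factory=lambda: {4.0: 0.4, 24.0: 0.8, 48.0: 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ConfigError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.replicates < 1 or self.control_replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if not 0 < self.teer_drop_fraction < 1:
            raise ConfigError("teer_drop_fraction must lie in (0, 1)")
        if self.teer_baseline <= 0:
            raise ConfigError("teer_baseline must be positive Ohm")
        for label, curves in self.truth.items():
            for ep, curve in curves.items():
                if curve.ic50 is not None and not curve.ic50 > 0:
                    raise ConfigError(f"non-positive ic50 for {label}/{ep}")
                if not curve.hill > 0:
                    raise ConfigError(f"non-positive hill for {label}/{ep}")
                if not 0 <= curve.floor < 1:
                    raise ConfigError(f"floor for {label}/{ep} must lie in [0, 1)")

    def grid(self, label: str) -> np.ndarray:
        lo, hi = self.concentration_ranges[label]
        return np.geomspace(lo, hi, self.n_concentrations)

    def times(self, endpoint: Endpoint) -> tuple[float, ...]:
        if endpoint.name in _MULTI_TIME_ENDPOINTS:
            return tuple(sorted(self.time_profile))
        return (48.0,)


@dataclass(frozen=True)
class SyntheticTruth:
    """Realised generator configuration plus derived true quantities."""

    config: GeneratorConfig

    def true_curve(self, label: str, endpoint: Endpoint) -> TrueCurve:
        return self.config.truth[label][endpoint.name]

    def true_half_max(self, label: str, endpoint: Endpoint) -> float | None:
        return self.true_curve(label, endpoint).ic50

    def implied_ci(self, endpoint: Endpoint) -> CombinationIndexResult | None:
        """True combination index implied by the truth, via the same formula
        the synergy stage applies (inactive cells stay extracted)."""
        comb = self.true_half_max(pub.COMBINATION, endpoint)
        if comb is None:
            return None
        a, b, c = (self.true_half_max(lbl, endpoint) for lbl in pub.COMPONENTS)
        if a is None and b is None and c is None:
            return None
        return combination_index(a, b, c, comb, endpoint=endpoint)


def _sigma(noise_cv: float) -> float:
    return math.sqrt(math.log1p(noise_cv**2))


def _hill_fraction(x: np.ndarray, ic50: float, hill: float) -> np.ndarray:
    """Remaining fraction of the inducible signal: 1/(1 + (x/ic50)^hill)."""
    return 1.0 / (1.0 + (x / ic50) ** hill)


def generate_assay(config: GeneratorConfig) -> tuple[AssayDataset, SyntheticTruth]:
    """Draw one full synthetic plate dataset; identical config => identical data."""
    rng = np.random.default_rng(config.seed)
    sig = _sigma(config.noise_cv)

    def noise(n: int) -> np.ndarray:
        if sig == 0:
            return np.ones(n)
        return rng.lognormal(mean=0.0, sigma=sig, size=n)

    rows: list[dict] = []
    labels = (*pub.COMPONENTS, pub.COMBINATION)

    def add_mediator(endpoint: Endpoint, treatment: str, cclass: str,
                     conc: float, time_h: float, mean: float, n: int) -> None:
        vals = mean * noise(n)
        for rep, v in enumerate(vals, start=1):
            rows.append(
                dict(
                    endpoint=endpoint.name,
                    compartment=endpoint.compartment.value,
                    treatment=treatment,
                    control_class=cclass,
                    concentration_ug_ml=conc,
                    time_h=time_h,
                    replicate=rep,
                    value=float(v),
                    value_before=np.nan,
                    value_after=np.nan,
                )
            )

    def add_teer(treatment: str, cclass: str, conc: float,
                 mean_diff: float, n: int) -> None:
        endpoint = Endpoint.TEER
        before = config.teer_baseline * noise(n)
        diffs = mean_diff * noise(n)
        for rep, (vb, d) in enumerate(zip(before, diffs), start=1):
            rows.append(
                dict(
                    endpoint=endpoint.name,
                    compartment=endpoint.compartment.value,
                    treatment=treatment,
                    control_class=cclass,
                    concentration_ug_ml=conc,
                    time_h=48.0,
                    replicate=rep,
                    value=np.nan,
                    value_before=float(vb),
                    value_after=float(vb + d),
                )
            )

    # --- mediator endpoints -------------------------------------------------
    for endpoint in Endpoint:
        if endpoint.is_teer:
            continue
        ua = config.baselines[endpoint.name]
        fold = config.fold_induction[endpoint.name]
        ref_class = endpoint.reference_control
        for t in config.times(endpoint):
            prof = config.time_profile[t]
            s_level = ua * (1.0 + (fold - 1.0) * prof)
            add_mediator(endpoint, "control", "s", 0.0, t, s_level,
                         config.control_replicates)
            add_mediator(endpoint, "control", ref_class, 0.0, t, ua,
                         config.control_replicates)
            bud_mean = ua + (s_level - ua) * (1.0 - config.bud_effect)
            add_mediator(endpoint, "budesonide", "bud", 0.0, t, bud_mean,
                         config.replicates)
            for label in labels:
                curve = config.truth[label][endpoint.name]
                grid = config.grid(label)
                if curve.ic50 is None:
                    means = np.full(grid.size, s_level)
                else:
                    frac = curve.floor + (1.0 - curve.floor) * _hill_fraction(
                        grid, curve.ic50, curve.hill
                    )
                    means = ua + (s_level - ua) * frac
                for x, mu in zip(grid, means):
                    add_mediator(endpoint, label, "treated", float(x), t,
                                 float(mu), config.replicates)

    # --- TEER barrier endpoint ---------------------------------------------
    diff_s = -config.teer_drop_fraction * config.teer_baseline
    diff_us = config.teer_us_gain_fraction * config.teer_baseline
    add_teer("control", "s", 0.0, diff_s, config.control_replicates)
    add_teer("control", "us", 0.0, diff_us, config.control_replicates)
    add_teer("budesonide", "bud", 0.0,
             diff_s + (diff_us - diff_s) * config.bud_effect, config.replicates)
    for label in labels:
        curve = config.truth[label][Endpoint.TEER.name]
        grid = config.grid(label)
        if curve.ic50 is None:
            recovery = np.zeros(grid.size)
        else:
            recovery = grid**curve.hill / (grid**curve.hill + curve.ic50**curve.hill)
        for x, rec in zip(grid, recovery):
            add_teer(label, "treated", float(x),
                     diff_s + (diff_us - diff_s) * float(rec), config.replicates)

    df = pd.DataFrame(rows)
    metadata = {
        "synthetic": True,
        "seed": config.seed,
        "noise_cv": config.noise_cv,
        "bud_concentration_um": config.bud_concentration_um,
    }
    return AssayDataset(df=df, metadata=metadata), SyntheticTruth(config=config)


def make_table1_fixture(
    seed: int, noise_cv: float = 0.05
) -> tuple[AssayDataset, SyntheticTruth]:
    """Low-noise preset whose true potencies equal the published point
    estimates, so the full pipeline recovers the published summary table
    approximately and its combination-index column near-exactly."""
    cfg = GeneratorConfig(truth=table1_truth(), noise_cv=noise_cv, seed=seed)
    return generate_assay(cfg)


def all_active_config(**overrides) -> GeneratorConfig:
    """Truth variant with every treatment x endpoint cell active.

    Inactive published cells are filled with in-range potencies so that
    identifiability and recovery can be checked on the complete 7 x 4 design.
    """
    fill = {
        ("chamomile", "IL6"): 80.0,
        ("coffee_charcoal", "TNF"): 200.0,
        ("chamomile", "MCP1"): 100.0,
        ("chamomile", "TEER"): 60.0,
    }
    truth = table1_truth()
    truth = {
        label: {
            ep: (
                replace(curve, ic50=fill[(label, ep)])
                if curve.ic50 is None
                else curve
            )
            for ep, curve in curves.items()
        }
        for label, curves in truth.items()
    }
    return GeneratorConfig(truth=truth, **overrides)
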