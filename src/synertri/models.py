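"""Domain model for the co-culture inflammation assay.

The experimental design: THP-1 macrophages in the basolateral compartment are
activated with LPS and release cytokines (IL-6, TNF) and PGE2; the stimulated
intestinal epithelial cell (IEC) monolayer releases chemokines (IL-8, MCP-1)
and PGE2 apically, and its barrier integrity is tracked as transepithelial
electrical resistance (TEER, Ohm) before and 48 h after treatment.

Treatments are three plant extracts (myrrh, coffee charcoal, chamomile
flower), their equal-parts ternary combination, and a budesonide positive
control; untreated wells fall into three control classes:

``s``    stimulated control (LPS-activated macrophages, no treatment)
``ua``   inactivated control (macrophages present, no LPS)
``us``   unstimulated control (IEC monolayer without macrophages)
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "Compartment",
    "Direction",
    "Endpoint",
    "ControlClass",
    "AssayDataset",
    "SCHEMA_COLUMNS",
    "ValidationError",
    "SchemaError",
    "LookupError_",
]


class SchemaError(ValueError):
    """A required column is missing or mislabelled."""


class ValidationError(ValueError):
    """A row violates a value-level invariant."""


class LookupError_(KeyError):
    """A requested (endpoint, treatment, time) cell does not exist."""


class Compartment(str, enum.Enum):
    macrophage_basolateral = "macrophage_basolateral"
    epithelial_apical = "epithelial_apical"
    epithelial_barrier = "epithelial_barrier"


class Direction(str, enum.Enum):
    #: treatment suppresses mediator release (IC50)
    inhibition = "inhibition"
    #: treatment restores the TEER barrier (EC50)
    enhancement = "enhancement"


class Endpoint(enum.Enum):
    """Measured endpoint with its compartment and effect direction."""

    IL6 = ("M-IL-6", Compartment.macrophage_basolateral, Direction.inhibition)
    TNF = ("M-TNF", Compartment.macrophage_basolateral, Direction.inhibition)
    PGE2_M = ("M-PGE2", Compartment.macrophage_basolateral, Direction.inhibition)
    IL8 = ("IEC-IL-8", Compartment.epithelial_apical, Direction.inhibition)
    MCP1 = ("IEC-MCP-1", Compartment.epithelial_apical, Direction.inhibition)
    PGE2_IEC = ("IEC-PGE2", Compartment.epithelial_apical, Direction.inhibition)
    TEER = ("TEER", Compartment.epithelial_barrier, Direction.enhancement)

    def __init__(self, display: str, compartment: Compartment, direction: Direction):
        self.display = display
        self.compartment = compartment
        self.direction = direction

    @property
    def is_teer(self) -> bool:
        return self is Endpoint.TEER

    @property
    def reference_control(self) -> str:
        """Control class anchoring the low/reference level.

        Macrophage mediators are referenced against the inactivated control
        (``ua``); epithelial mediators and TEER against the unstimulated
        monolayer (``us``).
        """
        if self.compartment is Compartment.macrophage_basolateral:
            return "ua"
        return "us"

    @classmethod
    def parse(cls, token: str) -> "Endpoint":
        t = str(token).strip()
        for ep in cls:
            if t == ep.name or t == ep.display:
                return ep
        # tolerate case differences on the enum name only
        for ep in cls:
            if t.upper() == ep.name:
                return ep
        raise ValidationError(f"unknown endpoint label: {token!r}")


class ControlClass(str, enum.Enum):
    s = "s"
    ua = "ua"
    us = "us"
    bud = "bud"
    treated = "treated"


#: required long-format columns; TEER rows additionally use value_before/value_after
SCHEMA_COLUMNS = (
    "endpoint",
    "compartment",
    "treatment",
    "control_class",
    "concentration_ug_ml",
    "time_h",
    "replicate",
    "value",
    "value_before",
    "value_after",
)


@dataclass
class AssayDataset:
    """Long-format plate table: one row per well-measurement.

    ``df`` carries the columns of :data:`SCHEMA_COLUMNS`. Mediator rows use
    ``value`` (pg/mL); TEER rows use ``value_before``/``value_after`` (Ohm)
    and leave ``value`` empty. Concentrations are µg/mL throughout; the
    budesonide concentration (µM) lives in ``metadata``, off the shared axis.
    """

    df: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in SCHEMA_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if len(self.df) == 0:
            raise ValidationError("empty dataset: no measurement rows")
        df = self.df
        # label-level checks
        for token in df["endpoint"].unique():
            Endpoint.parse(token)
        bad_cc = set(df["control_class"].unique()) - {c.value for c in ControlClass}
        if bad_cc:
            raise ValidationError(f"unknown control_class label(s): {sorted(bad_cc)}")
        # value-level checks
        is_teer = df["endpoint"].map(lambda t: Endpoint.parse(t).is_teer)
        med = df.loc[~is_teer]
        neg = med.index[med["value"].astype(float) < 0]
        if len(neg):
            raise ValidationError(f"negative mediator value at row index {neg[0]}")
        teer = df.loc[is_teer]
        if len(teer):
            vb = teer["value_before"].astype(float)
            va = teer["value_after"].astype(float)
            bad = teer.index[(vb <= 0) | (va <= 0) | vb.isna() | va.isna()]
            if len(bad):
                raise ValidationError(
                    f"TEER values must be positive Ohm; bad row index {bad[0]}"
                )
        neg_c = df.index[df["concentration_ug_ml"].astype(float) < 0]
        if len(neg_c):
            raise ValidationError(f"negative concentration at row index {neg_c[0]}")

    def endpoints(self) -> list[Endpoint]:
        return sorted(
            {Endpoint.parse(t) for t in self.df["endpoint"].unique()},
            key=lambda e: e.name,
        )

    def treatments(self) -> list[str]:
        m = self.df["control_class"] == ControlClass.treated.value
        return sorted(self.df.loc[m, "treatment"].unique())

    def rows(
        self,
        endpoint: Endpoint | None = None,
        control_class: str | None = None,
        treatment: str | None = None,
        time_h: float | None = None,
    ) -> pd.DataFrame:
        df = self.df
        mask = np.ones(len(df), dtype=bool)
        if endpoint is not None:
            mask &= df["endpoint"].map(lambda t: Endpoint.parse(t) is endpoint).to_numpy()
        if control_class is not None:
            mask &= (df["control_class"] == control_class).to_numpy()
        if treatment is not None:
            mask &= (df["treatment"] == treatment).to_numpy()
        if time_h is not None:
            mask &= np.isclose(df["time_h"].astype(float).to_numpy(), float(time_h))
        return df.loc[mask]

    def __len__(self) -> int:
        return len(self.df)
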