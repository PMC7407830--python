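"""Published summary potencies of the ternary extract combination study.

Half-maximal concentrations (µg/mL; EC50 for the TEER barrier endpoint,
IC50 otherwise) reported for the three individual extracts and their
equal-parts combination in the LPS-stimulated macrophage/IEC co-culture
model, together with the published combination-index column. A ``None``
entry marks a component with no significant effect on that endpoint (its
term is extracted from the combination index).

Component order: A = myrrh, B = coffee charcoal, C = chamomile flower.
"""

from __future__ import annotations

MYRRH = "myrrh"
COFFEE = "coffee_charcoal"
CHAMOMILE = "chamomile"
COMBINATION = "combination"

#: the three individual components, in A/B/C order
COMPONENTS = (MYRRH, COFFEE, CHAMOMILE)

#: endpoint name -> {treatment label -> half-maximal concentration, µg/mL}
TABLE1_HALF_MAX: dict[str, dict[str, float | None]] = {
    "IL6": {MYRRH: 14.0, COFFEE: 152.0, CHAMOMILE: None, COMBINATION: 5.0},
    "TNF": {MYRRH: 15.0, COFFEE: None, CHAMOMILE: 98.0, COMBINATION: 26.0},
    "PGE2_M": {MYRRH: 6.0, COFFEE: 251.0, CHAMOMILE: 39.0, COMBINATION: 17.0},
    "IL8": {MYRRH: 42.0, COFFEE: 106.0, CHAMOMILE: 268.0, COMBINATION: 59.0},
    "MCP1": {MYRRH: 35.0, COFFEE: 293.0, CHAMOMILE: None, COMBINATION: 54.0},
    "PGE2_IEC": {MYRRH: 13.0, COFFEE: 136.0, CHAMOMILE: 51.0, COMBINATION: 17.0},
    "TEER": {MYRRH: 48.0, COFFEE: 98.0, CHAMOMILE: None, COMBINATION: 80.0},
}

#: endpoint name -> (published CI rounded to 2 dp, published category symbol)
TABLE1_CI: dict[str, tuple[float, str]] = {
    "IL6": (0.13, "++++"),
    "TNF": (0.67, "+++"),
    "PGE2_M": (1.11, "-"),
    "IL8": (0.73, "++"),
    "MCP1": (0.58, "+++"),
    "PGE2_IEC": (0.59, "+++"),
    "TEER": (0.83, "++"),
}

#: tested concentration ranges (µg/mL; total concentration for the combination)
CONCENTRATION_RANGES: dict[str, tuple[float, float]] = {
    MYRRH: (0.1, 100.0),
    COFFEE: (1.0, 500.0),
    CHAMOMILE: (0.1, 200.0),
    COMBINATION: (0.25, 150.0),
}

#: LPS fold-induction of each mediator vs its reference control at 48 h
FOLD_INDUCTION: dict[str, float] = {
    "IL6": 8.5,
    "TNF": 3.3,
    "PGE2_M": 6.4,
    "IL8": 12.1,
    "MCP1": 1.6,
    "PGE2_IEC": 34.0,
}
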