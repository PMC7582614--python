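"""Published reference values from the large-corpus cuffless-BP study.

These constants are the study-condition *inputs* this package ships with:
the per-feature gamma values computed on ~2.17 million MIMIC II cardiac
cycles (the canonical ranking input for feature selection), and the model
performance figures used to exercise the BHS/AAMI grading logic.  They are
data, not results this package claims to recompute -- reproducing them
would require the external waveform corpus.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = [
    "REFERENCE_GAMMA",
    "SELECTED_32",
    "LOWEST_32",
    "BHS_MODEL_PERFORMANCE",
    "AAMI_MODEL_ERRORS",
]

_NAN = math.nan

#: gamma per feature on the reference corpus; NaN marks features whose
#: gamma was too large to be considered (unstable ratio features).
REFERENCE_GAMMA: pd.Series = pd.Series(
    {
        "hr": 0.01281,
        "t1": _NAN,
        "t2": 0.01653,
        "t3": 0.01637,
        "t4": 0.01604,
        "t5": 0.01634,
        "t6": 0.01628,
        "t7": 0.01673,
        "t8": 0.01628,
        "AS": 0.01276,
        "dAS": 0.01455,
        "sdAS": 0.01405,
        "DS": 0.01405,
        "dDS": 0.01646,
        "sdDS": 0.01298,
        "S1": 0.01556,
        "S2": 0.01411,
        "AA": 0.01381,
        "dAA": 0.01255,
        "sdAA": 0.01298,
        "DA": 0.01232,
        "dDA": 0.01228,
        "sdDA": 0.01265,
        "RAAD": _NAN,
        "dRAAD": _NAN,
        "sdRAAD": _NAN,
        "PI": 0.01261,
        "dPI": 0.01313,
        "sdPI": 0.01305,
        "dVI": 0.01296,
        "sdVI": 0.01299,
        "AID": 0.01324,
        "dAID": 0.01311,
        "sdAID": 0.01305,
        "dDID": 0.01322,
        "sdDID": 0.01310,
        "PIR": _NAN,
        "dPIR": _NAN,
        "sdPIR": _NAN,
        "dRIPV": 0.01305,
        "sdRIPV": 0.01350,
        "AT": 0.01348,
        "dAT": 0.01634,
        "sdAT": 0.01673,
        "DT": 0.01490,
        "dDT": 0.01628,
        "sdDT": 0.01628,
        "dTVO": 0.01569,
        "sdTVO": 0.01438,
        "Slope_a": 0.01308,
        "S3": 0.01333,
        "S4": 0.01323,
        "RtArea": _NAN,
        "NI": 0.01230,
        "AI": 0.01277,
        "AI1": 0.01274,
        "RSD": 0.01405,
        "RSC": 0.01286,
        "RDC": 0.01611,
    },
    name="gamma",
)

#: the published final 32-feature set (lowest-gamma set with S1/S2 swapped
#: in for sdAS/sdDS on domain grounds)
SELECTED_32: frozenset[str] = frozenset(
    {
        "hr", "AS", "DS", "AA", "dAA", "sdAA", "DA", "dDA", "sdDA",
        "PI", "dPI", "sdPI", "dVI", "sdVI", "AID", "dAID", "sdAID",
        "dDID", "sdDID", "dRIPV", "sdRIPV", "AT", "Slope_a", "S3", "S4",
        "NI", "AI", "AI1", "RSD", "RSC", "S1", "S2",
    }
)

#: the 32 features with the lowest finite gamma on the reference corpus
LOWEST_32: frozenset[str] = (SELECTED_32 - {"S1", "S2"}) | {"sdAS", "sdDS"}

#: published cumulative percentages of absolute error <= 5 / 10 / 15 mmHg
BHS_MODEL_PERFORMANCE: dict[str, tuple[float, float, float]] = {
    "SBP": (80.63, 95.86, 98.78),
    "DBP": (90.19, 98.29, 99.59),
}

#: published (mean error, sd of error) pairs in mmHg
AAMI_MODEL_ERRORS: dict[str, tuple[float, float]] = {
    "SBP": (3.21, 3.35),
    "DBP": (2.23, 2.44),
}
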