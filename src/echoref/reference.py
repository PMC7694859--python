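"""Published reference constants for canine M-mode allometric scaling.

These are the multicenter all-nonsighthound screening-population values
(n = 6097): the allometric formulas Y = a * BW**b per variable, and the
percentile indexing constants whose product with BW**b reconstructs the
corresponding percentile curve (the 2.5th/97.5th pair gives the
approximate 95% prediction interval).

``CORNELL_LVDD`` carries the older single-study LVDd constants
(exponent 0.294) used in the field for comparison, including the 95th
percentile value 1.70 adopted as a cardiomegaly criterion in clinical
trial inclusion rules.
"""

from __future__ import annotations

#: Allometric coefficients (a, b) of Y = a * BW**b, all-nonsighthound group.
ALLOMETRIC_AB = {
    "LVDd": (1.38, 0.322),
    "LVDs": (0.87, 0.346),
    "IVSd": (0.36, 0.289),
    "IVSs": (0.51, 0.276),
    "LVWd": (0.40, 0.261),
    "LVWs": (0.60, 0.247),
}

#: Percentile -> indexing constant (value of Y / BW**b at that percentile).
INDEX_CONSTANTS = {
    "LVDd": {2.5: 1.17, 5.0: 1.20, 25.0: 1.30, 50.0: 1.38, 75.0: 1.46, 95.0: 1.59, 97.5: 1.63},
    "LVDs": {2.5: 0.70, 5.0: 0.72, 25.0: 0.81, 50.0: 0.87, 75.0: 0.94, 95.0: 1.05, 97.5: 1.09},
    "IVSd": {2.5: 0.27, 5.0: 0.28, 25.0: 0.33, 50.0: 0.36, 75.0: 0.40, 95.0: 0.47, 97.5: 0.49},
    "IVSs": {2.5: 0.38, 5.0: 0.40, 25.0: 0.46, 50.0: 0.51, 75.0: 0.56, 95.0: 0.65, 97.5: 0.68},
    "LVWd": {2.5: 0.30, 5.0: 0.31, 25.0: 0.36, 50.0: 0.40, 75.0: 0.44, 95.0: 0.51, 97.5: 0.53},
    "LVWs": {2.5: 0.46, 5.0: 0.48, 25.0: 0.55, 50.0: 0.60, 75.0: 0.65, 95.0: 0.75, 97.5: 0.78},
}

#: Scaling exponent published alongside the indexing constants.
INDEX_EXPONENT = {v: b for v, (_, b) in ALLOMETRIC_AB.items()}

#: Body-weight grid (kg) of the published prediction-interval table.
PI_TABLE_BW_GRID = (
    2, 3.5, 5, 7.5, 10, 12.5, 15, 17.5, 20, 22.5, 25, 27.5,
    30, 32.5, 35, 40, 45, 50, 55, 60, 65, 70, 75,
)

#: Older single-study LVDd comparison constants (exponent 0.294).
CORNELL_LVDD = {"exponent": 0.294, "constants": {2.5: 1.27, 95.0: 1.70, 97.5: 1.85}}
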