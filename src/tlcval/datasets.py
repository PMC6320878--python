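"""Published study data for the combined effervescent-tablet assay.

Everything here was printed in the original validation study of the
TLC-densitometric determination of acetylsalicylic acid (ASA) and ascorbic
acid (AA) in *Polopiryna C* tablets (label claim 500 mg ASA + 200 mg AA):
the eight-run robustness design with per-run tablet contents, the
ten-replicate assay series for both analytes, the iodometric reference
series for AA, and the calibration summaries.  These are the only real
data the method ever published, so they ship as code rather than files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LABEL_CLAIM_MG = {"ASA": 500.0, "AA": 200.0}

#: Chromatographic constants of the method: migration position as a fraction
#: of the solvent-front distance (R_F) and the UV absorption maximum (nm).
RF_VALUES = {"AA": 0.18, "SA": 0.56, "ASA": 0.80}
LAMBDA_MAX_NM = {"ASA": 200.0, "AA": 268.0, "SA": 299.0}
FRONT_DISTANCE_MM = 75.0

#: Published calibration summaries (area AU vs amount µg/spot):
#: A = intercept + slope · x, with the validated range.
CALIBRATION_SUMMARY = {
    "ASA": {"intercept": 2547.7, "slope": 1532.7, "range": (1.50, 9.00)},
    "AA": {"intercept": 370.9, "slope": 1944.8, "range": (1.50, 13.50)},
}

#: Factor labels of the seven-factor robustness screen.
ROBUSTNESS_FACTORS = (
    "chamber type",
    "sorbent type",
    "plate activation temperature",
    "extraction time",
    "chloroform volume",
    "ethanol volume",
    "chamber saturation time",
)

# 8-run saturated two-level design (2^(7-4)); rows are experiments 1..8.
_DESIGN_ROWS = (
    (+1, +1, +1, +1, +1, +1, +1),
    (+1, +1, -1, +1, -1, -1, -1),
    (+1, -1, +1, -1, -1, +1, -1),
    (+1, -1, -1, -1, +1, -1, +1),
    (-1, +1, +1, -1, +1, -1, -1),
    (-1, +1, -1, -1, -1, +1, +1),
    (-1, -1, +1, +1, -1, -1, +1),
    (-1, -1, -1, +1, +1, +1, -1),
)

#: Tablet contents (mg/tablet) measured in the eight robustness runs.
ROBUSTNESS_RESPONSES = {
    "ASA": (503.5, 494.5, 506.5, 482.5, 519.0, 510.5, 473.5, 494.0),
    "AA": (207.2, 182.2, 200.4, 199.6, 207.0, 204.0, 192.2, 198.2),
}

#: Ten-replicate assay series (mg/tablet).  "AA_iodometric" is the reference
#: wet-chemistry series used for the method comparison.
ASSAY_SERIES = {
    "ASA": (487.8, 478.2, 469.8, 491.6, 476.3, 465.7, 502.2, 498.1, 489.2, 495.3),
    "AA": (204.6, 203.4, 201.6, 205.8, 201.8, 199.6, 205.6, 203.8, 201.8, 203.8),
    "AA_iodometric": (203.2, 202.8, 202.0, 205.8, 201.6, 198.4, 200.6, 198.0, 198.2, 202.2),
}


def design_matrix() -> np.ndarray:
    """The 8x7 ±1 robustness design matrix as an integer array."""
    return np.array(_DESIGN_ROWS, dtype=int)


def robustness_table() -> pd.DataFrame:
    """Design matrix plus both response columns, one row per experiment."""
    df = pd.DataFrame(design_matrix(), columns=[f"X{i}" for i in range(1, 8)])
    df.insert(0, "experiment", np.arange(1, 9))
    df["y_ASA"] = ROBUSTNESS_RESPONSES["ASA"]
    df["y_AA"] = ROBUSTNESS_RESPONSES["AA"]
    return df


def assay_table() -> pd.DataFrame:
    """Tidy long table of the three ten-replicate assay series."""
    rows = []
    for method, analyte, key in (
        ("TLC-densitometry", "ASA", "ASA"),
        ("TLC-densitometry", "AA", "AA"),
        ("iodometric", "AA", "AA_iodometric"),
    ):
        for value in ASSAY_SERIES[key]:
            rows.append({"method": method, "analyte": analyte, "value_mg": value})
    return pd.DataFrame(rows)
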