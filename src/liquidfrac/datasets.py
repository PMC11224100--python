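"""Reference count tables from a 130-patient PSMA-PET / ctDNA
prostate-cancer cohort, bundled as numeric fixtures.

These integer cross-tabulations are the published study-level inputs the
comparative statistics operate on; patient-level data are not public, so
analyses needing individual records use :mod:`liquidfrac.synthetic_data`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: PSA strata as printed: left-open, right-closed intervals (ng/mL)
PSA_BREAKS = [0.0, 0.5, 1.0, 2.0, 3689.0]
PSA_RANGE_LABELS = ["(0, 0.5]", "(0.5, 1.0]", "(1.0, 2.0]", "(2.0, 3689.0]"]

#: PET-positive / PET-negative counts per PSA stratum
PET_BY_PSA = np.array([[13, 10], [5, 6], [12, 3], [72, 9]])

#: ctDNA-positive / ctDNA-negative counts per PSA stratum
CTDNA_BY_PSA = np.array([[3, 20], [2, 9], [6, 9], [29, 52]])

#: rows hsPC, CRPC; columns PET-positive, PET-negative
PET_BY_CASTRATION = np.array([[40, 19], [62, 9]])

#: rows hsPC, CRPC; columns ctDNA-detected, ctDNA-not-detected
CTDNA_BY_CASTRATION = np.array([[15, 44], [25, 46]])

N_PATIENTS = 130


def discovery_counts_frame() -> pd.DataFrame:
    """Both modalities' discovery counts by PSA stratum, as one table."""
    df = pd.DataFrame({
        "psa_range": PSA_RANGE_LABELS,
        "pet_positive": PET_BY_PSA[:, 0],
        "pet_negative": PET_BY_PSA[:, 1],
        "ctdna_positive": CTDNA_BY_PSA[:, 0],
        "ctdna_negative": CTDNA_BY_PSA[:, 1],
    })
    df["total"] = df["pet_positive"] + df["pet_negative"]
    return df
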