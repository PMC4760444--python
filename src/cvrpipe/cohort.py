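"""Example six-subject cohort: per-subject printed measurements.

Sea-level measurements taken before and one week after a three-week stay
at 5050 m in six healthy adults: gray/white matter volumes (mL),
white-matter hyperintensity (WMHI) counts, and gray/white matter CVR
(% per mmHg).  WMHI could not be read at baseline for subject 5, so lesion
counts cover five subjects.  These per-subject numbers serve as worked
inputs for the summary and group-statistics machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["volumetry_table", "cvr_table", "wmhi_counts", "rest_summary_reference"]


def volumetry_table() -> pd.DataFrame:
    """Per-subject gray/white matter volumes (mL) at both sessions."""
    return pd.DataFrame(
        {
            "subject": [1, 2, 3, 4, 5, 6],
            "gm_ml_pre": [733, 569, 653, 686, 701, 667],
            "gm_ml_post": [718, 544, 631, 670, 689, 653],
            "wm_ml_pre": [666, 509, 614, 659, 643, 601],
            "wm_ml_post": [652, 490, 623, 659, 633, 590],
        }
    ).astype({"subject": int})


def wmhi_counts() -> pd.DataFrame:
    """Per-subject white-matter hyperintensity counts (five readable subjects)."""
    return pd.DataFrame(
        {
            "subject": [1, 2, 3, 4, 5, 6],
            "wmhi_pre": [3, 1, 3, 38, np.nan, 0],
            "wmhi_post": [6, 1, 4, 37, np.nan, 0],
        }
    )


def cvr_table() -> pd.DataFrame:
    """Per-subject gray/white matter CVR (% per mmHg) at both sessions."""
    return pd.DataFrame(
        {
            "subject": [1, 2, 3, 4, 5, 6],
            "gm_cvr_pre": [0.30, 0.34, 0.27, 0.31, 0.33, 0.31],
            "gm_cvr_post": [0.39, 0.42, 0.31, 0.23, 0.41, 0.32],
            "wm_cvr_pre": [0.27, 0.19, 0.15, 0.12, 0.19, 0.17],
            "wm_cvr_post": [0.20, 0.21, 0.18, 0.16, 0.22, 0.15],
        }
    )


def rest_summary_reference() -> dict:
    """Group-mean resting ventilatory state at the baseline session."""
    return {
        "fb_bpm": 12.6,
        "vt_l": 1.0,
        "ve_lpm": 11.0,
        "peto2_mmHg": 101.8,
        "petco2_mmHg": 41.4,
        "spo2_pct": 96.4,
    }
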