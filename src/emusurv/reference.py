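"""Published descriptive counts of the reference claims cohort.

The real claims cohort behind this package's design is access-restricted; what
is public is its descriptive table: per-arm counts for every categorical
covariate and both outcomes (treated arm = endovascular repair, N = 3960;
control arm = open repair, N = 3866).  ``reference_cohort()`` rebuilds a
cohort table whose marginal counts match those numbers exactly, which is
sufficient input for the descriptive-statistics engine (marginal summaries do
not depend on the joint structure, which is filled independently here).  Race
has 7 and 8 missing entries per arm so that the published non-missing
denominators (3953 and 3858) are reproduced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CONDITION_COLUMNS

__all__ = ["REFERENCE_N", "REFERENCE_COUNTS", "reference_cohort"]

REFERENCE_N = {"arm1": 3960, "arm0": 3866}

#: (treated count, control count) per variable
REFERENCE_COUNTS = {
    "male": (3023, 2786),
    "race": {"white": (3588, 3550), "black": (249, 178), "other": (116, 130)},
    "year": {2011: (808, 1013), 2012: (869, 913), 2013: (819, 785),
             2014: (837, 701), 2015: (627, 454)},
    "conditions": {
        "chf": (464, 299), "arrhythmia": (596, 438), "valvular": (199, 172),
        "coronary": (758, 603), "diabetes": (329, 256),
        "hypertension": (1250, 1078), "copd": (707, 584),
        "lower_extremity_vascular": (26, 27),
        "renal_atherosclerosis": (20, 27), "vascular_intestine": (7, 2),
        "renal_failure": (493, 358), "other_renal": (3, 1),
        "kidney_transplant": (4, 3), "liver": (33, 30),
        "cerebrovascular": (93, 67), "other_neuro": (153, 114),
        "hyperlipidemia": (817, 687), "cancer": (132, 87),
        "rheumatoid": (76, 39), "prior_aaa": (511, 440),
    },
    "outcomes": {"d_long": (2430, 2542), "d_short": (1107, 1704)},
}


def _fill(n: int, k: int) -> np.ndarray:
    out = np.zeros(n, dtype=int)
    out[:k] = 1
    return out


def reference_cohort() -> pd.DataFrame:
    """Cohort table with the published per-arm marginal counts."""
    frames = []
    for arm_key, arm in (("arm1", 1), ("arm0", 0)):
        n = REFERENCE_N[arm_key]
        pick = 0 if arm == 1 else 1
        df = pd.DataFrame({"treatment": np.full(n, arm)})
        df["age"] = np.linspace(66, 95, n)  # placeholder continuous values
        df["sex"] = np.where(_fill(n, REFERENCE_COUNTS["male"][pick]),
                             "male", "female")
        race = np.array([None] * n, dtype=object)
        pos = 0
        for lv, counts in REFERENCE_COUNTS["race"].items():
            race[pos:pos + counts[pick]] = lv
            pos += counts[pick]
        df["race"] = race  # remaining entries stay missing
        year = np.empty(n, dtype=int)
        pos = 0
        for yr, counts in REFERENCE_COUNTS["year"].items():
            year[pos:pos + counts[pick]] = yr
            pos += counts[pick]
        df["repair_year"] = year
        for cond in CONDITION_COLUMNS:
            df[cond] = _fill(n, REFERENCE_COUNTS["conditions"][cond][pick])
        for col, counts in REFERENCE_COUNTS["outcomes"].items():
            df[col] = _fill(n, counts[pick])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
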