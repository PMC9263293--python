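"""Bundled reference data: the demographic table of the example cohort.

Two groups of 25 university students — "TC" (regular Tai Chi practitioners)
and matched controls — with per-subject age and sex.  Used by the
demographics checks and as a template for synthetic-cohort covariates.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_cohort", "TC_AGES", "CONTROL_AGES", "SEX_TABLE"]

#: per-subject ages, TC group (n = 25)
TC_AGES = [
    24, 23, 22, 20, 20, 20, 21, 21, 21, 23, 21, 21, 23,
    22, 21, 22, 20, 22, 22, 21, 20, 20, 20, 20, 20,
]

#: per-subject ages, control group (n = 25)
CONTROL_AGES = [
    21, 21, 21, 21, 22, 23, 22, 22, 22, 22, 22, 22, 21,
    21, 22, 21, 22, 21, 21, 22, 21, 22, 22, 22, 21,
]

_TC_SEX = [
    "F", "F", "M", "M", "M", "M", "M", "M", "M", "M", "M", "F", "M",
    "M", "M", "M", "M", "M", "M", "F", "F", "F", "F", "F", "M",
]

_CONTROL_SEX = [
    "M", "M", "M", "M", "F", "M", "M", "F", "M", "M", "M", "M", "F",
    "M", "M", "M", "M", "M", "M", "M", "M", "M", "F", "F", "F",
]

#: 2x2 sex-by-group counts [[TC_M, TC_F], [control_M, control_F]]
SEX_TABLE = [
    [_TC_SEX.count("M"), _TC_SEX.count("F")],
    [_CONTROL_SEX.count("M"), _CONTROL_SEX.count("F")],
]


def reference_cohort() -> pd.DataFrame:
    """The reference demographic table as a tidy DataFrame.

    Columns: ``subject_id, group, age, sex``.
    """
    rows = []
    for k, (age, sex) in enumerate(zip(TC_AGES, _TC_SEX)):
        rows.append(
            {"subject_id": f"TC{k + 1:02d}", "group": "TC", "age": age, "sex": sex}
        )
    for k, (age, sex) in enumerate(zip(CONTROL_AGES, _CONTROL_SEX)):
        rows.append(
            {"subject_id": f"CT{k + 1:02d}", "group": "CT", "age": age, "sex": sex}
        )
    return pd.DataFrame(rows)
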