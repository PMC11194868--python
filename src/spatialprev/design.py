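"""Covariate design matrix shared by the simulator and the CAR models.

The regression design mirrors the analysis variables: indicator columns
for the four non-reference socioeconomic categories (reference: most
advantaged) and for the high-Indigenous group (reference: low).  An
optional Indigenous x disadvantage interaction expansion is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SEIFA_LEVELS = [
    "most_advantaged",
    "advantaged",
    "medium",
    "disadvantaged",
    "most_disadvantaged",
]

#: design columns in order, after the optional intercept
EFFECT_NAMES = [
    "advantaged",
    "medium",
    "disadvantaged",
    "most_disadvantaged",
    "indigenous_high",
]


def build_design(
    table: pd.DataFrame,
    include_intercept: bool = True,
    interaction: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Build the regression design matrix from a derived area table.

    Returns (X, column_names).  Requires ``seifa_category`` and
    ``indigenous_group`` columns (see ``derive_analysis_variables``).
    """
    for col in ("seifa_category", "indigenous_group"):
        if col not in table.columns:
            raise ValueError(f"table lacks derived column {col!r}")
    n = len(table)
    cols, names = [], []
    if include_intercept:
        cols.append(np.ones(n))
        names.append("intercept")
    cat = table["seifa_category"].to_numpy()
    for level in SEIFA_LEVELS[1:]:
        cols.append((cat == level).astype(float))
        names.append(level)
    high = (table["indigenous_group"].to_numpy() == "high").astype(float)
    cols.append(high)
    names.append("indigenous_high")
    if interaction:
        for level in SEIFA_LEVELS[1:]:
            cols.append(high * (cat == level))
            names.append(f"indigenous_high:{level}")
    return np.column_stack(cols), names
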