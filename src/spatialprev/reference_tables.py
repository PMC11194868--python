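"""Published cluster-composition tables from the 2021 Australian census
small-area childhood-asthma analysis.

These counts — cold-spot (low-low) and hot-spot (high-high) SA2s broken
down by area deprivation category, Indigenous-density group, and their
combination — are public summary data used as fixed inputs for the
cross-tabulation and chi-square utilities.  2,321 SA2s were analysed in
total; 465 were hot spots and 548 cold spots.
"""

from __future__ import annotations

import pandas as pd

from .esda import ClusterCrossTab

__all__ = [
    "TOTAL_AREAS_ANALYSED",
    "seifa_crosstab",
    "indigenous_crosstab",
    "interaction_crosstab",
]

TOTAL_AREAS_ANALYSED = 2321

_SEIFA_ROWS = {
    # category: (cold_spot, hot_spot)
    "most_advantaged": (171, 24),
    "advantaged": (128, 61),
    "medium": (94, 99),
    "disadvantaged": (71, 140),
    "most_disadvantaged": (84, 141),
}

_INDIGENOUS_ROWS = {
    "low": (384, 72),
    "high": (164, 393),
}

_INTERACTION_ROWS = {
    "low:most_advantaged": (159, 17),
    "low:advantaged": (94, 17),
    "low:medium": (61, 22),
    "low:disadvantaged": (33, 11),
    "low:most_disadvantaged": (37, 5),
    "high:most_advantaged": (12, 7),
    "high:advantaged": (34, 44),
    "high:medium": (33, 77),
    "high:disadvantaged": (38, 129),
    "high:most_disadvantaged": (47, 136),
}


def _tab(rows: dict) -> ClusterCrossTab:
    counts = pd.DataFrame(
        rows, index=["cold_spot", "hot_spot"]
    ).T.astype(int)
    return ClusterCrossTab(counts=counts)


def seifa_crosstab() -> ClusterCrossTab:
    """Cluster counts by the five deprivation categories."""
    return _tab(_SEIFA_ROWS)


def indigenous_crosstab() -> ClusterCrossTab:
    """Cluster counts by Indigenous-density group (median split at 2.08%)."""
    return _tab(_INDIGENOUS_ROWS)


def interaction_crosstab() -> ClusterCrossTab:
    """Cluster counts by the Indigenous x deprivation combination."""
    return _tab(_INTERACTION_ROWS)
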