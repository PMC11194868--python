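"""Area-table ingest: schema validation, exclusion rules, derived variables.

The analysis retains only areas that can support small-area estimation:
at least 5 children aged 0-14, total population of at least 200, a
recorded deprivation (SEIFA-IRSD) score, and at least one retained
neighbour (spatial methods need connectivity).  The isolation check runs
after the population filters and iterates to a fixed point, since
dropping an area can isolate its last neighbour.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import SEIFA_LEVELS
from .graph import AreaGraph

__all__ = [
    "SchemaError",
    "ValidationError",
    "EmptyResultError",
    "read_area_table",
    "apply_exclusions",
    "derive_analysis_variables",
]

MIN_CHILDREN = 5
MIN_POPULATION = 200

REQUIRED_COLUMNS = [
    "area_id",
    "child_pop",
    "total_pop",
    "indigenous_pct",
    "seifa_score",
    "seifa_decile",
]


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


class ValidationError(ValueError):
    """Input values violate a table invariant."""


class EmptyResultError(RuntimeError):
    """Exclusion rules removed every area."""


def read_area_table(path) -> pd.DataFrame:
    """Read an area table CSV and validate its invariants.

    Requires the columns ``area_id, child_pop, total_pop,
    indigenous_pct, seifa_score, seifa_decile`` plus at least one of
    ``asthma_count`` (needed for the regression stage) or
    ``prevalence_pct`` (sufficient for LISA-only runs).  Missing SEIFA
    scores stay as NaN — they are an exclusion reason, never zero.
    """
    table = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"required column missing: {col!r}")
    if "asthma_count" not in table.columns and "prevalence_pct" not in table.columns:
        raise SchemaError("need either 'asthma_count' or 'prevalence_pct'")
    if table["area_id"].duplicated().any():
        dup = table.loc[table["area_id"].duplicated(), "area_id"].iloc[0]
        raise ValidationError(f"duplicate area_id: {dup!r}")
    for col in ("child_pop", "total_pop", "asthma_count"):
        if col in table.columns and (table[col].dropna() < 0).any():
            raise ValidationError(f"negative values in column {col!r}")
    if "asthma_count" in table.columns:
        bad = table["asthma_count"] > table["child_pop"]
        if bad.any():
            aid = table.loc[bad, "area_id"].iloc[0]
            raise ValidationError(
                f"asthma_count exceeds child_pop for area {aid!r}"
            )
    if (table["child_pop"] > table["total_pop"]).any():
        raise ValidationError("child_pop exceeds total_pop for some areas")
    return table


def apply_exclusions(
    table: pd.DataFrame,
    graph: AreaGraph,
    min_children: int = MIN_CHILDREN,
    min_population: int = MIN_POPULATION,
) -> tuple[pd.DataFrame, AreaGraph, pd.DataFrame]:
    """Apply the retention rules; returns (table, graph, exclusion_log).

    Drops areas with fewer than ``min_children`` children, total
    population below ``min_population``, a missing SEIFA score, or — in
    an iterated second pass — no neighbours among the retained areas.
    The log records one (area_id, reason) row per dropped area; the
    returned graph is the induced subgraph on the retained areas, in
    table order.
    """
    pos = {aid: i for i, aid in enumerate(graph.area_ids)}
    missing = [a for a in table["area_id"] if a not in pos]
    if missing:
        raise ValidationError(f"areas absent from the graph: {missing[:5]}")

    log: list[tuple] = []
    keep = table.copy()

    m = keep["child_pop"] < min_children
    log += [(a, f"children < {min_children}") for a in keep.loc[m, "area_id"]]
    keep = keep[~m]
    m = keep["total_pop"] < min_population
    log += [(a, f"population < {min_population}") for a in keep.loc[m, "area_id"]]
    keep = keep[~m]
    m = keep["seifa_score"].isna() | keep["seifa_decile"].isna()
    log += [(a, "missing SEIFA") for a in keep.loc[m, "area_id"]]
    keep = keep[~m]

    # isolation: iterate until stable, since removals cascade
    while True:
        retained = set(pos[a] for a in keep["area_id"])
        iso = [
            a
            for a in keep["area_id"]
            if not (graph.neighbours[pos[a]] & retained)
        ]
        if not iso:
            break
        log += [(a, "no retained neighbours") for a in iso]
        keep = keep[~keep["area_id"].isin(iso)]

    if keep.empty:
        raise EmptyResultError("all areas excluded; nothing to analyse")
    sub = graph.subgraph([pos[a] for a in keep["area_id"]])
    log_df = pd.DataFrame(log, columns=["area_id", "reason"])
    return keep.reset_index(drop=True), sub, log_df


def derive_analysis_variables(
    table: pd.DataFrame,
    indigenous_threshold: float | None = None,
) -> pd.DataFrame:
    """Add prevalence, the Indigenous dichotomy and the 5-level
    deprivation category.

    ``prevalence_pct`` is ``100 * asthma_count / child_pop`` (kept as
    given when counts are absent).  ``indigenous_group`` is "high" iff
    ``indigenous_pct`` is at or above the threshold — by default the
    median of the retained areas, recomputed from the data because the
    published 2.08% cut-off is itself a data median.  The threshold used
    is recorded in ``table.attrs["indigenous_threshold"]``.  SEIFA
    deciles map pairwise onto the five categories, decile 1-2 being most
    disadvantaged.
    """
    out = table.copy()
    if "asthma_count" in out.columns:
        if (out["child_pop"] <= 0).any():
            raise RuntimeError(
                "zero child population after exclusions; internal error"
            )
        out["prevalence_pct"] = 100.0 * out["asthma_count"] / out["child_pop"]
    # tables without counts or prevalence still get the covariate groupings
    # (the count simulator derives them before attaching counts)

    thr = (
        float(np.median(out["indigenous_pct"]))
        if indigenous_threshold is None
        else float(indigenous_threshold)
    )
    out["indigenous_group"] = np.where(
        out["indigenous_pct"] >= thr, "high", "low"
    )

    dec = out["seifa_decile"].to_numpy()
    if not np.isin(dec, np.arange(1, 11)).all():
        raise ValidationError("seifa_decile values must lie in 1..10")
    # deciles 1-2 -> most_disadvantaged, ..., 9-10 -> most_advantaged
    idx = (dec - 1) // 2  # 0..4, 0 = most disadvantaged
    out["seifa_category"] = [SEIFA_LEVELS[::-1][i] for i in idx]
    out.attrs["indigenous_threshold"] = thr
    return out
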