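"""End-to-end pipeline: ingest -> weights -> ESDA -> cross-tabs -> CAR
models -> model comparison, with one master seed and per-stage
substreams (adding a stage never perturbs an earlier stage's
randomness).  Every artefact is a plain-text file; rerunning with the
same configuration and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .car import CarModelSpec, compute_waic, fit_car_leroux, fit_car_localised, posterior_summary
from .design import SEIFA_LEVELS
from .esda import classify_lisa, chi_square_test, crosstab_clusters, local_moran, moran_mc
from .graph import AreaGraph
from .ingest import apply_exclusions, derive_analysis_variables, read_area_table
from .weights import build_weights, queen_contiguity, read_edge_list, read_geojson, write_edge_list

log = logging.getLogger("spatialprev")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "descriptives"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-serialisable)."""

    table: str | None = None  # area-table CSV; None -> synthetic fixture
    geometry: str | None = None  # GeoJSON FeatureCollection
    edges: str | None = None  # adjacency edge-list CSV
    synthetic: dict = field(default_factory=lambda: {"rows": 30, "cols": 30})
    min_children: int = 5
    min_population: int = 200
    n_perm: int = 999
    alpha: float = 0.05
    models: list = field(default_factory=lambda: ["leroux", "localised:5"])
    mcmc: dict = field(default_factory=dict)  # CarModelSpec overrides
    stage: str = "all"  # esda | car | all
    outdir: str = "pipeline_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if self.stage not in ("esda", "car", "all"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage in ("car", "all") and not self.models:
            raise ValueError("no models configured")
        for m in self.models:
            if m != "leroux" and not m.startswith("localised:"):
                raise ValueError(f"unknown model {m!r}")


@dataclass
class ReportBundle:
    descriptives: pd.DataFrame
    moran: dict
    lisa_labels: pd.DataFrame | None
    crosstabs: dict
    waic: dict
    summaries: dict
    best_model: str | None
    manifest: dict
    paths: dict


def descriptives(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD (divide-by-(n-1)), median and range per analysis variable.

    With a single row the SD is undefined and reported as NaN.
    """
    if table.empty:
        raise ValueError("empty table")
    rows = []
    for col in ("child_pop", "total_pop", "prevalence_pct", "indigenous_pct", "seifa_score"):
        if col not in table.columns:
            continue
        x = table[col].to_numpy(dtype=float)
        rows.append(
            {
                "variable": col,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if x.size > 1 else np.nan,
                "median": float(np.median(x)),
                "min": float(np.min(x)),
                "max": float(np.max(x)),
            }
        )
    return pd.DataFrame(rows)


def _fmt_pct(x: float) -> float:
    # 1 decimal place, round-half-even, matching the N (%) convention
    return float(np.round(x, 1))


def _crosstab_csv(tab, path) -> None:
    out = tab.counts.copy()
    pct = tab.column_percentages()
    for col in ("cold_spot", "hot_spot"):
        out[f"{col}_pct"] = [_fmt_pct(v) for v in pct[col]]
    out.index.name = "category"
    out.to_csv(path)


def _spawn_seeds(master: int, labels: list[str]) -> dict:
    seqs = np.random.SeedSequence(master).spawn(len(labels))
    return {
        lab: int(s.generate_state(1)[0] % (2**31)) for lab, s in zip(labels, seqs)
    }


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the configured stages in order; returns the report bundle
    and writes all artefacts under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    seeds = _spawn_seeds(
        config.seed,
        ["synthetic", "moran_prev", "moran_seifa", "moran_indig", "lisa", "car"],
    )

    # ---- inputs
    try:
        if config.table is None:
            from .synthetic import simulate_dataset, write_fixture

            log.info("no input table: generating the default synthetic fixture")
            rows = config.synthetic.get("rows", 30)
            cols = config.synthetic.get("cols", 30)
            table_raw, graph, _, truth = simulate_dataset(
                rows, cols, seed=seeds["synthetic"]
            )
            fx = write_fixture(outdir / "fixture", table_raw, graph, truth)
            table = read_area_table(fx["table"])
        else:
            table = read_area_table(config.table)
            if config.geometry:
                ids, polys = read_geojson(config.geometry)
                graph = queen_contiguity(polys, ids)
            elif config.edges:
                graph = read_edge_list(config.edges, list(table["area_id"]))
            else:
                raise ValueError("need geometry or edges with an input table")
    except Exception as e:
        raise RuntimeError(f"stage 'ingest' failed: {e}") from e

    # ---- exclusions + derived variables
    table, graph, excl = apply_exclusions(
        table, graph, config.min_children, config.min_population
    )
    table = derive_analysis_variables(table)
    paths["exclusions"] = outdir / "exclusions.csv"
    excl.to_csv(paths["exclusions"], index=False)

    desc = descriptives(table)
    paths["descriptives"] = outdir / "descriptives.csv"
    desc.to_csv(paths["descriptives"], index=False)

    w_row = build_weights(graph, "row_standardised")
    w_bin = build_weights(graph, "binary")

    moran: dict = {}
    lisa_df = None
    crosstabs: dict = {}
    if config.stage in ("esda", "all"):
        try:
            for var, key in (
                ("prevalence_pct", "moran_prev"),
                ("seifa_score", "moran_seifa"),
                ("indigenous_pct", "moran_indig"),
            ):
                res = moran_mc(
                    table[var].to_numpy(), w_row, config.n_perm, seed=seeds[key]
                )
                moran[var] = {"I": res.I_obs, "pseudo_p": res.pseudo_p}
            lisa = local_moran(
                table["prevalence_pct"].to_numpy(),
                w_row,
                config.n_perm,
                seed=seeds["lisa"],
            )
            lisa = classify_lisa(lisa, alpha=config.alpha)
            lisa_df = pd.DataFrame(
                {
                    "area_id": table["area_id"],
                    "local_I": lisa.local_i,
                    "pseudo_p": lisa.pseudo_p,
                    "label": lisa.label,
                }
            )
            paths["lisa"] = outdir / "lisa_labels.csv"
            lisa_df.to_csv(paths["lisa"], index=False)
            if graph.polygons is not None:
                _write_label_geojson(graph, lisa_df, outdir / "lisa_labels.geojson")
                paths["lisa_geojson"] = outdir / "lisa_labels.geojson"

            interact = (
                table["indigenous_group"].astype(str)
                + ":"
                + table["seifa_category"].astype(str)
            )
            blocks = {
                "seifa": (table["seifa_category"], SEIFA_LEVELS[::-1]),
                "indigenous": (table["indigenous_group"], ["low", "high"]),
                "interaction": (interact, None),
            }
            for name, (cats, order) in blocks.items():
                tab = crosstab_clusters(lisa.label, np.asarray(cats), order)
                # drop empty category rows before the test; skip it when a
                # margin is still empty (degenerate on small fixtures)
                occupied = tab.counts[tab.counts.sum(axis=1) > 0]
                if len(occupied) >= 2 and (occupied.sum(axis=0) > 0).all():
                    from dataclasses import replace as _replace

                    tested = chi_square_test(_replace(tab, counts=occupied))
                    tab.chi2, tab.df, tab.p_value = (
                        tested.chi2,
                        tested.df,
                        tested.p_value,
                    )
                crosstabs[name] = tab
                paths[f"crosstab_{name}"] = outdir / f"crosstab_{name}.csv"
                _crosstab_csv(tab, paths[f"crosstab_{name}"])
            paths["moran"] = outdir / "moran.json"
            with open(paths["moran"], "w") as fh:
                json.dump(moran, fh, indent=2)
        except Exception as e:
            raise RuntimeError(f"stage 'esda' failed: {e}") from e

    waic: dict = {}
    summaries: dict = {}
    best = None
    if config.stage in ("car", "all"):
        try:
            car_seeds = _spawn_seeds(seeds["car"], list(config.models))
            for model in config.models:
                mspec = CarModelSpec(seed=car_seeds[model], **config.mcmc)
                if model == "leroux":
                    chains = fit_car_leroux(table, w_bin, mspec)
                else:
                    mspec.G = int(model.split(":")[1])
                    chains = fit_car_localised(table, w_bin, mspec)
                waic[model] = compute_waic(chains).waic
                summ = posterior_summary(chains)
                summaries[model] = summ
                safe = model.replace(":", "")
                paths[f"summary_{model}"] = outdir / f"summary_{safe}.csv"
                summ.to_csv(paths[f"summary_{model}"], index=False)
            best = min(waic, key=waic.get)
            paths["waic"] = outdir / "waic.json"
            with open(paths["waic"], "w") as fh:
                json.dump({"waic": waic, "best_model": best}, fh, indent=2)
        except Exception as e:
            raise RuntimeError(f"stage 'car' failed: {e}") from e

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return ReportBundle(
        descriptives=desc,
        moran=moran,
        lisa_labels=lisa_df,
        crosstabs=crosstabs,
        waic=waic,
        summaries=summaries,
        best_model=best,
        manifest=manifest,
        paths=paths,
    )


def _write_label_geojson(graph: AreaGraph, lisa_df: pd.DataFrame, path) -> None:
    from shapely.geometry import mapping

    labels = dict(zip(lisa_df["area_id"], lisa_df["label"]))
    feats = []
    for aid, poly in zip(graph.area_ids, graph.polygons):
        feats.append(
            {
                "type": "Feature",
                "properties": {"area_id": aid, "lisa_label": labels.get(aid)},
                "geometry": mapping(poly),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
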