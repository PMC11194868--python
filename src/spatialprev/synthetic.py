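"""Synthetic area-table generator with known ground truth.

Emulates the statistical structure of a national census small-area
table: ~2,000 areas with child populations averaging ~1,991 (range
10-7,889), an area deprivation score with mean 999 / SD 82.5 that is
itself spatially autocorrelated, a right-skewed Indigenous-population
percentage with median 2.08, and asthma counts drawn from a Poisson
log-linear model with a log child-population offset and spatially
correlated (Leroux) random effects.  Every draw is deterministic given
its seed, and the generating parameters are returned as a
:class:`SyntheticTruth` so recovery tests can compare estimates against
the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .design import EFFECT_NAMES, build_design
from .graph import AreaGraph
from .weights import SpatialWeights, _binary_matrix, build_weights, write_edge_list

__all__ = [
    "CovariateMarginals",
    "SyntheticTruth",
    "simulate_covariates",
    "sample_leroux_field",
    "simulate_counts",
    "sample_localised_structure",
    "calibrated_intercept",
    "default_truth",
    "simulate_dataset",
    "write_fixture",
]

#: default covariate effects on the log-prevalence scale, ordered as
#: EFFECT_NAMES; prevalence ratios 0.99, 1.01, 1.04, 1.10 across the
#: deprivation gradient and 1.13 for high Indigenous density.
DEFAULT_EFFECTS = np.log([0.99, 1.01, 1.04, 1.10, 1.13])

#: national average childhood asthma prevalence the generator targets (%)
DEFAULT_PREVALENCE_PCT = 6.27


@dataclass(frozen=True)
class CovariateMarginals:
    """Marginal distribution parameters for the covariate simulator.

    Defaults reproduce the descriptive statistics of the 2021 Australian
    census SA2 table this generator emulates.
    """

    child_pop_mean: float = 1991.0
    child_pop_sd: float = 1227.98
    child_pop_min: int = 10
    child_pop_max: int = 7889
    #: children aged 0-14 as a fraction of total population (mean)
    child_share_mean: float = 0.1827
    child_share_conc: float = 100.0
    seifa_mean: float = 999.0
    seifa_sd: float = 82.5
    #: neighbourhood-averaging passes for the deprivation score; chosen so
    #: the score's global Moran's I sits near 0.6 on a queen lattice
    seifa_smooth_passes: int = 1
    indigenous_median: float = 2.08
    indigenous_sigma: float = 1.19
    indigenous_smooth_passes: int = 3
    indigenous_max: float = 95.9

    def validate(self) -> None:
        if self.child_pop_sd <= 0 or self.seifa_sd <= 0 or self.indigenous_sigma <= 0:
            raise ValueError("scale parameters must be positive")
        if self.child_pop_min > self.child_pop_max:
            raise ValueError("child_pop bounds reversed")
        if self.child_pop_min < 1:
            raise ValueError("child_pop_min must be >= 1")
        if not (0 < self.child_share_mean < 1):
            raise ValueError("child_share_mean must lie in (0, 1)")
        if self.indigenous_median <= 0 or self.indigenous_max <= 0:
            raise ValueError("Indigenous-percentage parameters must be positive")


@dataclass
class SyntheticTruth:
    """Generating parameters behind a synthetic count table."""

    beta: np.ndarray  # intercept + EFFECT_NAMES coefficients, log scale
    phi: np.ndarray  # per-area random effect, log scale
    rho: float  # Leroux spatial-dependence parameter in [0, 1)
    tau2: float  # random-effect marginal variance
    cluster_assignments: np.ndarray | None = None  # classes 1..G
    cluster_intercepts: np.ndarray | None = None  # strictly increasing
    seed: int = 0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if not (0 <= self.rho < 1):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.tau2 <= 0:
            raise ValueError(f"tau2 must be positive, got {self.tau2}")


def _smooth(z: np.ndarray, A, deg: np.ndarray, passes: int) -> np.ndarray:
    """Average each area with its neighbours, `passes` times, then
    re-standardise to zero mean, unit (population) variance."""
    for _ in range(passes):
        z = (z + A @ z) / (1.0 + deg)
    return (z - z.mean()) / z.std()


def simulate_covariates(
    graph: AreaGraph,
    marginals: CovariateMarginals | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the covariate block of an area table.

    Columns: ``area_id, child_pop, total_pop, seifa_score, seifa_decile,
    indigenous_pct``.  Child populations are lognormal (clipped to the
    stated range); the deprivation score and the Indigenous percentage
    are built from spatially smoothed Gaussian noise so both fields are
    spatially autocorrelated, as in the census data they emulate.
    Deciles are rank-derived: the 10 groups differ in size by at most 1,
    decile 1 holding the lowest (most disadvantaged) scores.
    """
    if graph.n_areas == 0:
        raise ValueError("graph is empty")
    m = marginals or CovariateMarginals()
    m.validate()
    rng = np.random.default_rng(seed)
    n = graph.n_areas
    A = _binary_matrix(graph)
    deg = graph.degrees().astype(float)

    cv2 = (m.child_pop_sd / m.child_pop_mean) ** 2
    sig = np.sqrt(np.log1p(cv2))
    mu = np.log(m.child_pop_mean) - 0.5 * sig**2
    child = np.exp(rng.normal(mu, sig, size=n))
    child = np.clip(np.rint(child), m.child_pop_min, m.child_pop_max).astype(np.int64)

    a = m.child_share_mean * m.child_share_conc
    b = (1 - m.child_share_mean) * m.child_share_conc
    share = rng.beta(a, b, size=n)
    total = np.maximum(np.rint(child / share), child).astype(np.int64)

    z = _smooth(rng.standard_normal(n), A, deg, m.seifa_smooth_passes)
    seifa = m.seifa_mean + m.seifa_sd * z
    order = np.argsort(seifa, kind="stable")
    decile = np.empty(n, dtype=np.int64)
    # sizes differ by <= 1: first (n % 10) groups get the extra area
    sizes = [n // 10 + (1 if k < n % 10 else 0) for k in range(10)]
    start = 0
    for k, s in enumerate(sizes):
        decile[order[start : start + s]] = k + 1
        start += s

    u = _smooth(rng.standard_normal(n), A, deg, m.indigenous_smooth_passes)
    indig = np.exp(np.log(m.indigenous_median) + m.indigenous_sigma * u)
    indig = np.minimum(indig, m.indigenous_max)

    return pd.DataFrame(
        {
            "area_id": list(graph.area_ids),
            "child_pop": child,
            "total_pop": total,
            "seifa_score": seifa,
            "seifa_decile": decile,
            "indigenous_pct": indig,
        }
    )


def sample_leroux_field(
    weights: SpatialWeights,
    rho: float,
    tau2: float,
    seed: int = 0,
    size: int = 1,
) -> np.ndarray:
    """Exact draws of a Leroux-correlated Gaussian field.

    The field has zero mean and precision
    ``Q = (rho * (D - W) + (1 - rho) * I) / tau2`` with ``D`` the diagonal
    neighbour-count matrix and ``W`` the binary adjacency.  ``rho = 0``
    gives iid N(0, tau2); ``rho -> 1`` approaches the intrinsic CAR.
    Sampling factorises Q (Cholesky) and solves against standard
    normals, so draws are exact rather than MCMC approximations.

    Returns shape ``(n,)`` when ``size == 1``, else ``(size, n)``.
    """
    if not (0 <= rho < 1):
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    if tau2 <= 0:
        raise ValueError(f"tau2 must be positive, got {tau2}")
    g = weights.graph
    n = g.n_areas
    A = _binary_matrix(g).toarray()
    D = np.diag(g.degrees().astype(float))
    Q = (rho * (D - A) + (1 - rho) * np.eye(n)) / tau2
    # upper Cholesky Q = U' U ; x = U^{-1} z  =>  cov(x) = Q^{-1}
    U = sla.cholesky(Q, lower=False)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((size, n))
    x = sla.solve_triangular(U, z.T, lower=False).T
    return x[0] if size == 1 else x


def calibrated_intercept(
    X_effects: np.ndarray,
    beta_effects: np.ndarray,
    phi: np.ndarray,
    target_prev_pct: float = DEFAULT_PREVALENCE_PCT,
) -> float:
    """Intercept such that the area-mean expected prevalence equals the
    target: b0 = log(p) - log(mean_i exp(x_i'b + phi_i))."""
    lin = X_effects @ beta_effects + phi
    return float(np.log(target_prev_pct / 100.0) - np.log(np.mean(np.exp(lin))))


def simulate_counts(
    table: pd.DataFrame,
    truth: SyntheticTruth,
    seed: int | None = None,
) -> pd.DataFrame:
    """Attach Poisson asthma counts: Y_i ~ Poisson(E_i exp(x_i'beta + phi_i))
    with E_i the child population.

    If the table lacks the derived analysis variables the standard
    derivation (median Indigenous split, decile grouping) is applied
    first; the returned copy carries them.  When the truth includes a
    localised cluster structure, the cluster intercept of each area's
    class is added to the linear predictor.
    """
    from .ingest import derive_analysis_variables

    if (table["child_pop"] <= 0).any():
        raise ValueError("child populations must be positive")
    out = table.copy()
    if "seifa_category" not in out.columns:
        out = derive_analysis_variables(out)
    X, _ = build_design(out, include_intercept=True)
    if X.shape[1] != truth.beta.shape[0]:
        raise ValueError(
            f"beta has {truth.beta.shape[0]} entries but design has "
            f"{X.shape[1]} columns"
        )
    if truth.phi.shape[0] != len(out):
        raise ValueError("phi length does not match table")
    eta = X @ truth.beta + truth.phi
    if truth.cluster_assignments is not None:
        eta = eta + truth.cluster_intercepts[truth.cluster_assignments - 1]
    mu = out["child_pop"].to_numpy() * np.exp(eta)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    out["asthma_count"] = rng.poisson(mu)
    out["prevalence_pct"] = 100.0 * out["asthma_count"] / out["child_pop"]
    return out


def sample_localised_structure(
    graph: AreaGraph,
    G: int,
    seed: int = 0,
    spacing: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Spatially contiguous partition into G classes with ordered intercepts.

    G seed areas are drawn at random and classes grow by neighbour
    accretion in random order, so each class is connected in the queen
    graph.  Returns ``(assignments, intercepts)`` with assignments in
    ``1..G`` and intercepts strictly increasing, centred on zero and
    ``spacing`` apart on the log scale.
    """
    n = graph.n_areas
    if G < 2 or G > 10:
        raise ValueError(f"G must lie in 2..10, got {G}")
    if G > n:
        raise ValueError(f"G = {G} exceeds the number of areas ({n})")
    rng = np.random.default_rng(seed)
    assign = np.zeros(n, dtype=np.int64)
    seeds = rng.choice(n, size=G, replace=False)
    for g, s in enumerate(seeds, start=1):
        assign[s] = g
    while (assign == 0).any():
        frontier = [
            (i, assign[j])
            for i in np.flatnonzero(assign == 0)
            for j in graph.neighbours[i]
            if assign[j] > 0
        ]
        if not frontier:
            raise ValueError("graph is disconnected; cannot grow contiguous classes")
        rng.shuffle(frontier)
        claimed = {}
        for i, g in frontier:
            claimed.setdefault(i, g)
        for i, g in claimed.items():
            assign[i] = g
    intercepts = spacing * (np.arange(G) - (G - 1) / 2.0)
    return assign, intercepts


def sample_penalty_labels(
    n: int,
    G: int,
    delta: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Class labels drawn iid from the localised model's own penalty
    prior, ``P(Z_i = g) \\propto exp(-delta (g - G*)^2)`` with
    ``G* = (G + 1)/2``.

    Unlike :func:`sample_localised_structure` the resulting classes are
    not spatially contiguous — this is the label distribution the
    localised model itself assumes, so data built from it give a nested
    model-comparison fixture.
    """
    if G < 2 or G > 10:
        raise ValueError(f"G must lie in 2..10, got {G}")
    g = np.arange(1, G + 1)
    p = np.exp(-delta * (g - (G + 1) / 2.0) ** 2)
    p /= p.sum()
    rng = np.random.default_rng(seed)
    return rng.choice(g, size=n, p=p)


def default_truth(
    table: pd.DataFrame,
    weights: SpatialWeights,
    seed: int = 0,
    rho: float = 0.99,
    tau2: float = 0.3,
    effects: np.ndarray | None = None,
    target_prev_pct: float = DEFAULT_PREVALENCE_PCT,
    clusters: tuple[np.ndarray, np.ndarray] | None = None,
) -> SyntheticTruth:
    """Ground truth with the package's default study conditions.

    Effects default to :data:`DEFAULT_EFFECTS`; the intercept is
    calibrated so the area-mean expected prevalence hits the target
    (the covariate and random effects would otherwise shift it upward).
    """
    from .ingest import derive_analysis_variables

    tab = table
    if "seifa_category" not in tab.columns:
        tab = derive_analysis_variables(tab)
    eff = DEFAULT_EFFECTS.copy() if effects is None else np.asarray(effects, float)
    phi = sample_leroux_field(weights, rho=rho, tau2=tau2, seed=seed)
    X, _ = build_design(tab, include_intercept=False)
    extra = np.zeros(len(tab))
    ca, ci = (None, None) if clusters is None else clusters
    if ca is not None:
        extra = ci[ca - 1]
    b0 = calibrated_intercept(X, eff, phi + extra, target_prev_pct)
    return SyntheticTruth(
        beta=np.concatenate([[b0], eff]),
        phi=phi,
        rho=rho,
        tau2=tau2,
        cluster_assignments=ca,
        cluster_intercepts=ci,
        seed=seed,
    )


def simulate_dataset(
    rows: int = 30,
    cols: int = 30,
    seed: int = 0,
    marginals: CovariateMarginals | None = None,
    **truth_kwargs,
):
    """One-call generator: lattice -> covariates -> truth -> counts.

    Returns ``(table, graph, weights, truth)`` where the table carries
    counts and derived analysis variables.  Sub-seeds for covariates,
    random effects and counts are spawned from the master seed so the
    streams are independent.
    """
    from .graph import generate_lattice

    graph = generate_lattice(rows, cols)
    ss = np.random.SeedSequence(seed).spawn(3)
    s_cov, s_phi, s_cnt = (int(s.generate_state(1)[0] % (2**31)) for s in ss)
    table = simulate_covariates(graph, marginals, seed=s_cov)
    weights = build_weights(graph, "binary")
    truth = default_truth(table, weights, seed=s_phi, **truth_kwargs)
    table = simulate_counts(table, truth, seed=s_cnt)
    return table, graph, weights, truth


FIXTURE_COLUMNS = [
    "area_id",
    "child_pop",
    "total_pop",
    "asthma_count",
    "indigenous_pct",
    "seifa_score",
    "seifa_decile",
]


def write_fixture(
    outdir,
    table: pd.DataFrame,
    graph: AreaGraph,
    truth: SyntheticTruth | None = None,
) -> dict:
    """Write a plain-text fixture: table CSV, GeoJSON geometry, edge-list
    CSV and (optionally) the generating truth as JSON.

    Returns the mapping of artefact name to path.
    """
    from shapely.geometry import mapping

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    cols = [c for c in FIXTURE_COLUMNS if c in table.columns]
    paths["table"] = outdir / "area_table.csv"
    table[cols].to_csv(paths["table"], index=False)

    if graph.polygons is not None:
        feats = [
            {
                "type": "Feature",
                "properties": {"area_id": aid},
                "geometry": mapping(poly),
            }
            for aid, poly in zip(graph.area_ids, graph.polygons)
        ]
        paths["geometry"] = outdir / "areas.geojson"
        with open(paths["geometry"], "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    paths["edges"] = outdir / "edges.csv"
    write_edge_list(graph, paths["edges"])

    if truth is not None:
        payload = {
            "beta": truth.beta.tolist(),
            "phi": truth.phi.tolist(),
            "rho": truth.rho,
            "tau2": truth.tau2,
            "seed": truth.seed,
        }
        if truth.cluster_assignments is not None:
            payload["cluster_assignments"] = truth.cluster_assignments.tolist()
            payload["cluster_intercepts"] = truth.cluster_intercepts.tolist()
        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(payload, fh)
    return paths
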