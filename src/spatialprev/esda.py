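"""Exploratory spatial data analysis: global and local Moran's I with
Monte-Carlo pseudo p-values, LISA cluster classification, and
cluster-by-covariate cross-tabulation with a chi-square test.

Pseudo p-values follow the permutation convention
``p = (r + 1) / (M + 1)`` with ``r`` the number of permuted statistics
at least as extreme as the observed one, one-sided in the direction of
the observed departure from expectation.  Local statistics use
conditional permutation: area i's value is held fixed while the other
n - 1 values are shuffled across its neighbours.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .weights import SpatialWeights

__all__ = [
    "MoranResult",
    "LisaResult",
    "ClusterCrossTab",
    "DegenerateInputError",
    "DegenerateTableError",
    "DegenerateTableWarning",
    "global_moran",
    "moran_mc",
    "local_moran",
    "classify_lisa",
    "crosstab_clusters",
    "chi_square_test",
]

HOT = "high_high"
COLD = "low_low"
QUADRANT_LABEL = {
    "HH": "high_high",
    "LL": "low_low",
    "HL": "high_low",
    "LH": "low_high",
}


class DegenerateInputError(ValueError):
    """Values carry no variation; Moran statistics are undefined."""


class DegenerateTableError(ValueError):
    pass


class DegenerateTableWarning(UserWarning):
    pass


@dataclass
class MoranResult:
    I_obs: float
    expected_I: float
    n_perm: int
    perm_values: np.ndarray
    pseudo_p: float


@dataclass
class LisaResult:
    """Per-area local Moran statistics.

    ``quadrant`` holds the raw Moran-scatterplot quadrant (HH/LL/HL/LH);
    ``label`` is filled by :func:`classify_lisa` and additionally allows
    ``non_significant``.
    """

    local_i: np.ndarray
    pseudo_p: np.ndarray
    quadrant: np.ndarray
    n_perm: int
    label: np.ndarray | None = None
    alpha: float | None = None


@dataclass
class ClusterCrossTab:
    """Hot-spot/cold-spot counts by sociodemographic category.

    ``counts`` has one row per category and the columns ``cold_spot``
    and ``hot_spot``; outlier and non-significant areas are excluded.
    """

    counts: pd.DataFrame
    chi2: float | None = None
    df: int | None = None
    p_value: float | None = None

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def column_percentages(self) -> pd.DataFrame:
        """Each cell as a percentage of its column total."""
        return 100.0 * self.counts / self.counts.sum(axis=0)

    def column_share(self, rows, column: str) -> float:
        """Percentage of a column's total falling in the given rows."""
        sub = self.counts.loc[list(rows), column].sum()
        return 100.0 * float(sub) / float(self.counts[column].sum())


def _standardise(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    z = x - x.mean()
    s = np.sqrt(np.mean(z**2))  # population (divide-by-n) variance
    if s == 0:
        raise DegenerateInputError("values are constant; Moran's I undefined")
    return z / s


def global_moran(values, weights: SpatialWeights) -> float:
    """Global Moran's I:
    ``I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with
    ``z_i = x_i - mean(x)``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 areas")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise DegenerateInputError("values are constant; Moran's I undefined")
    return float(n / weights.s0 * (z @ weights.lag(z)) / denom)


def _pseudo_p(obs: float, perm: np.ndarray, expected: float) -> float:
    # small tolerance so exact ties (exhaustive enumeration of symmetric
    # arrangements) are counted as "at least as extreme" despite rounding
    eps = 1e-12 * max(1.0, abs(obs))
    if obs >= expected:
        r = int(np.sum(perm >= obs - eps))
    else:
        r = int(np.sum(perm <= obs + eps))
    return (r + 1) / (perm.size + 1)


def moran_mc(
    values,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> MoranResult:
    """Permutation test for global Moran's I.

    Values are shuffled across areas ``n_perm`` times (or over all n!
    arrangements when ``exhaustive``); the pseudo p-value is one-sided
    in the direction of the departure of the observed I from its
    expectation -1/(n-1).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    obs = global_moran(x, weights)
    expected = -1.0 / (n - 1)
    z = x - x.mean()
    denom = float(z @ z)
    scale = n / weights.s0 / denom

    if exhaustive:
        perm_vals = np.array(
            [
                scale * float(zp @ weights.lag(np.asarray(zp)))
                for zp in (np.array(p) for p in itertools.permutations(z))
            ]
        )
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        perm_vals = np.empty(n_perm)
        for r in range(n_perm):
            zp = z[rng.permutation(n)]
            perm_vals[r] = scale * float(zp @ weights.lag(zp))
    p = _pseudo_p(obs, perm_vals, expected)
    return MoranResult(obs, expected, perm_vals.size, perm_vals, p)


def local_moran(
    values,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> LisaResult:
    """Local Moran statistics with conditional-permutation p-values.

    ``I_i = z_i * sum_j w_ij z_j`` with z standardised by the global
    mean and population variance; with row-standardised weights the mean
    of the local statistics equals the global I.  For each area the
    remaining n - 1 values are permuted across its neighbours while its
    own value stays fixed; the direction of the one-sided p-value is set
    by the conditional expectation ``-z_i^2 / (n - 1)``.
    """
    z = _standardise(values)
    n = z.size
    if n < 3:
        raise ValueError("local Moran needs at least 3 areas")
    lag = weights.lag(z)
    local = z * lag
    expected = -(z**2) / (n - 1)

    quadrant = np.empty(n, dtype=object)
    for i in range(n):
        zi, li = z[i], lag[i]
        if zi > 0:
            quadrant[i] = "HH" if li >= 0 else "HL"
        elif zi < 0:
            quadrant[i] = "LL" if li <= 0 else "LH"
        else:  # tie at the mean: quadrant by the lag sign alone
            quadrant[i] = "HH" if li > 0 else "LL"

    W = weights.W
    pseudo = np.empty(n)
    if exhaustive:
        for i in range(n):
            others = np.delete(z, i)
            row = W.getrow(i)
            nbr_pos = {j: w for j, w in zip(row.indices, row.data)}
            # positions of neighbours within the "others" vector
            nbr_in_others = [j if j < i else j - 1 for j in row.indices]
            wvals = row.data
            perm_stats = []
            for perm in itertools.permutations(others):
                arranged = np.asarray(perm)
                perm_stats.append(z[i] * float(arranged[nbr_in_others] @ wvals))
            pseudo[i] = _pseudo_p(local[i], np.asarray(perm_stats), expected[i])
        return LisaResult(local, pseudo, quadrant, n_perm=len(perm_stats))

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    # one bank of permutations of 0..n-2, shared across areas
    base = np.tile(np.arange(n - 1), (n_perm, 1))
    perms = rng.permuted(base, axis=1)
    for i in range(n):
        row = W.getrow(i)
        k = row.indices.size
        if k == 0:
            pseudo[i] = 1.0
            continue
        others = np.delete(z, i)
        draws = others[perms[:, :k]]  # (n_perm, k) permuted neighbour values
        perm_stats = z[i] * (draws @ row.data)
        pseudo[i] = _pseudo_p(local[i], perm_stats, expected[i])
    return LisaResult(local, pseudo, quadrant, n_perm=n_perm)


def classify_lisa(lisa: LisaResult, alpha: float = 0.05, fdr: bool = False) -> LisaResult:
    """Attach 5-way cluster labels: the quadrant name where the pseudo
    p-value clears ``alpha`` (optionally Benjamini-Hochberg adjusted),
    ``non_significant`` elsewhere.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    p = lisa.pseudo_p
    if fdr:
        m = p.size
        order = np.argsort(p)
        thresh = alpha * (np.arange(1, m + 1)) / m
        passed = p[order] <= thresh
        cutoff = p[order][passed].max() if passed.any() else -1.0
        sig = p <= cutoff
    else:
        sig = p <= alpha
    labels = np.array(
        [QUADRANT_LABEL[q] if s else "non_significant" for q, s in zip(lisa.quadrant, sig)],
        dtype=object,
    )
    return replace(lisa, label=labels, alpha=alpha)


def crosstab_clusters(
    labels,
    categories,
    category_order=None,
) -> ClusterCrossTab:
    """Cross-tabulate LISA labels against a per-area factor.

    Only cold-spot (low-low) and hot-spot (high-high) areas enter the
    table; outliers and non-significant areas are excluded, matching
    the convention of reporting cluster composition by its two main
    cluster types.
    """
    labels = np.asarray(labels, dtype=object)
    categories = np.asarray(categories, dtype=object)
    if labels.shape != categories.shape:
        raise ValueError("labels and categories must align by area")
    if category_order is None:
        category_order = list(pd.unique(categories))
    counts = pd.DataFrame(
        0, index=list(category_order), columns=["cold_spot", "hot_spot"], dtype=int
    )
    for lab, col in ((COLD, "cold_spot"), (HOT, "hot_spot")):
        mask = labels == lab
        vc = pd.Series(categories[mask]).value_counts()
        for cat, c in vc.items():
            counts.loc[cat, col] = int(c)
    tab = ClusterCrossTab(counts=counts)
    if (counts.sum(axis=0) == 0).any():
        warnings.warn(
            "empty hot-spot or cold-spot margin; chi-square skipped",
            DegenerateTableWarning,
        )
    return tab


def chi_square_test(tab: ClusterCrossTab) -> ClusterCrossTab:
    """Pearson chi-square test of independence, no continuity correction.

    ``chi2 = sum (O - E)^2 / E`` with expected counts from the product
    of margins over the grand total; p from the upper tail of the
    chi-square distribution with (r-1)(c-1) degrees of freedom.
    """
    O = tab.counts.to_numpy(dtype=float)
    row_m = O.sum(axis=1)
    col_m = O.sum(axis=0)
    if (row_m == 0).any() or (col_m == 0).any():
        raise DegenerateTableError("zero margin; chi-square undefined")
    total = O.sum()
    E = np.outer(row_m, col_m) / total
    chi2 = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df))
    return ClusterCrossTab(counts=tab.counts, chi2=chi2, df=df, p_value=p)
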