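"""Spatial spread / VAF classification of mutations and group statistics.

Mutations are binned by geographic spread (private, regional 2-10 / 11-20
fields, widespread 21-30 / >30 fields) and assigned to the three clonality
classes: **alpha** (low-VAF, confined to fewer than ``min_cluster_fields``
fields), **beta** (expanded but with median present-field VAF below the
clonal threshold of 0.20) and **gamma** (expanded, clonal, median VAF above
0.20).  The per-mutation VAF distribution shape is labelled right-skewed
(neutral 1/v² signature: cumulative count linear in 1/f), binomial-clonal
(single mode with binomial-sampling dispersion at the sequencing depth),
uniform, or indeterminate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GROUPS, FieldMap, MutationTable

__all__ = [
    "SPREAD_CLASSES",
    "GREEK_CLASSES",
    "SHAPES",
    "ClassAssignment",
    "spread_class",
    "assign_greek",
    "vaf_shape",
    "classify_mutations",
    "presence_counts_by_group",
    "group_distribution_test",
    "bh_fdr",
    "driver_proportions",
]

SPREAD_CLASSES = (
    "private",
    "regional_2_10",
    "regional_11_20",
    "widespread_21_30",
    "widespread_gt30",
)
GREEK_CLASSES = ("alpha", "beta", "gamma")
SHAPES = ("right_skewed", "binomial_clonal", "uniform", "indeterminate")

#: display floor for calling a mutation present in a field
DEFAULT_PRESENCE_THRESHOLD = 0.01
#: VAF separating consistently-low expanded clones (beta) from clonal (gamma)
DEFAULT_CLONAL_VAF = 0.20
#: minimum number of fields for a mutation to count as an expanded cluster
DEFAULT_MIN_CLUSTER_FIELDS = 3


def spread_class(presence: Sequence[bool] | np.ndarray) -> str:
    """Bin a boolean presence vector into the five geographic spread classes."""
    n = int(np.asarray(presence, dtype=bool).sum())
    if n == 0:
        raise ValueError("mutation is absent from every field")
    if n == 1:
        return "private"
    if n <= 10:
        return "regional_2_10"
    if n <= 20:
        return "regional_11_20"
    if n <= 30:
        return "widespread_21_30"
    return "widespread_gt30"


def assign_greek(
    vafs: Sequence[float] | np.ndarray,
    min_cluster_fields: int = DEFAULT_MIN_CLUSTER_FIELDS,
    clonal_vaf: float = DEFAULT_CLONAL_VAF,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> str:
    """Assign alpha/beta/gamma from the per-field VAF vector of one mutation."""
    v = np.asarray(vafs, dtype=float)
    present = v >= presence_threshold
    n = int(present.sum())
    if n == 0:
        raise ValueError("mutation is absent from every field")
    if n < min_cluster_fields:
        return "alpha"
    return "beta" if float(np.median(v[present])) < clonal_vaf else "gamma"


def vaf_shape(
    vafs_present: Sequence[float] | np.ndarray,
    n_min: int = 8,
    depth: int = 300,
    r2_min: float = 0.9,
    mode_range: tuple[float, float] = (0.15, 0.5),
    dispersion_factor: float = 1.5,
    ks_alpha: float = 0.05,
) -> str:
    """Label the shape of a VAF collection.

    Rules, applied in order:

    1. *right_skewed* — the cumulative count M(f) = #{v >= f} regressed on
       1/f has R² >= ``r2_min`` and the sample skewness is positive (the
       neutral-growth expectation);
    2. *binomial_clonal* — a single mode with mean in ``mode_range`` whose
       dispersion is consistent with binomial read sampling at ``depth``
       (observed SD <= dispersion_factor * sqrt(v(1-v)/depth));
    3. *uniform* — Kolmogorov-Smirnov distance to Uniform(min, max) not
       significant at ``ks_alpha``;
    4. otherwise *indeterminate*.  Fewer than ``n_min`` values are always
       indeterminate.
    """
    v = np.asarray(vafs_present, dtype=float)
    v = v[v > 0]
    if v.size < n_min:
        return "indeterminate"

    # neutral 1/f-cumulative linearity on the interior of the support.  The
    # test is only informative over a wide frequency range (any narrow
    # unimodal cluster is locally linear in 1/f), so it additionally requires
    # the support to span at least a factor of 2 and the 1/f fit to beat a
    # plain linear-in-f fit.
    lo, hi = np.quantile(v, [0.05, 0.95])
    if hi > 2 * lo > 0:
        grid = np.linspace(lo, hi, 20)
        m = np.array([(v >= f).sum() for f in grid], dtype=float)
        if np.std(m) > 0:
            r_inv = np.corrcoef(1.0 / grid, m)[0, 1]
            r_lin = np.corrcoef(grid, m)[0, 1]
            if (
                r_inv**2 >= r2_min
                and r_inv**2 > r_lin**2
                and stats.skew(v) > 0
            ):
                return "right_skewed"

    mean = float(v.mean())
    if mode_range[0] <= mean <= mode_range[1]:
        expected_sd = math.sqrt(mean * (1 - mean) / depth)
        if v.std(ddof=1) <= dispersion_factor * expected_sd:
            return "binomial_clonal"

    if v.max() > v.min():
        ks = stats.kstest(v, stats.uniform(loc=v.min(), scale=v.max() - v.min()).cdf)
        if ks.pvalue > ks_alpha:
            return "uniform"
    return "indeterminate"


@dataclass(frozen=True)
class ClassAssignment:
    """Per-mutation classification plus per-class bookkeeping."""

    table: pd.DataFrame  # n_fields_present, spread_class, greek_class,
    #                      median_present_vaf, shape, cosmic_driver
    presence_threshold: float
    clonal_vaf: float
    min_cluster_fields: int

    def class_counts(self) -> pd.Series:
        counts = self.table["greek_class"].value_counts()
        return counts.reindex(GREEK_CLASSES, fill_value=0)

    def spread_counts(self) -> pd.Series:
        counts = self.table["spread_class"].value_counts()
        return counts.reindex(SPREAD_CLASSES, fill_value=0)

    def ids_in_class(self, greek: str) -> list[str]:
        return list(self.table.index[self.table["greek_class"] == greek])


def classify_mutations(
    mutations: MutationTable,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    min_cluster_fields: int = DEFAULT_MIN_CLUSTER_FIELDS,
    clonal_vaf: float = DEFAULT_CLONAL_VAF,
    driver_genes: Iterable[str] | None = None,
    shape_n_min: int = 8,
    depth: int = 300,
) -> ClassAssignment:
    """Classify every mutation in a table; order-invariant and vectorised."""
    vaf = mutations.vaf.to_numpy(dtype=float)
    present = vaf >= presence_threshold
    n_present = present.sum(axis=1)
    if (n_present == 0).any():
        absent = list(mutations.meta.index[n_present == 0][:5])
        raise ValueError(f"mutation(s) absent from every field, e.g. {absent}")

    masked = np.where(present, vaf, np.nan)
    median_present = np.nanmedian(masked, axis=1)

    spread = np.select(
        [n_present == 1, n_present <= 10, n_present <= 20, n_present <= 30],
        SPREAD_CLASSES[:4],
        default=SPREAD_CLASSES[4],
    )
    greek = np.where(
        n_present < min_cluster_fields,
        "alpha",
        np.where(median_present < clonal_vaf, "beta", "gamma"),
    )
    shapes = np.full(len(vaf), "indeterminate", dtype=object)
    for i in np.flatnonzero(n_present >= shape_n_min):
        shapes[i] = vaf_shape(vaf[i][present[i]], n_min=shape_n_min, depth=depth)

    drivers = set(driver_genes or ())
    table = pd.DataFrame(
        {
            "n_fields_present": n_present,
            "spread_class": spread,
            "greek_class": greek,
            "median_present_vaf": median_present,
            "shape": shapes,
            "cosmic_driver": mutations.meta["gene"].isin(drivers),
        },
        index=mutations.meta.index,
    )
    return ClassAssignment(table, presence_threshold, clonal_vaf, min_cluster_fields)


def presence_counts_by_group(
    mutations: MutationTable,
    field_map: FieldMap,
    subset: Sequence[str] | None = None,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    nonsilent_only: bool = True,
) -> pd.Series:
    """Count mutation-presence events per histology group (NU_LGIN/HGIN/UC)."""
    meta = mutations.meta
    ids = pd.Index(subset) if subset is not None else meta.index
    if nonsilent_only:
        ids = ids[~meta.loc[ids, "silent"]]
    presence = mutations.vaf.loc[ids] >= presence_threshold
    groups = field_map.group_of().reindex(presence.columns)
    counts = {g: int(presence.loc[:, groups == g].to_numpy().sum()) for g in GROUPS}
    return pd.Series(counts).reindex(GROUPS)


def _log_table_prob(table: np.ndarray, lgamma=math.lgamma) -> float:
    """Log multivariate-hypergeometric probability of a 2x3 table."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    num = sum(lgamma(x + 1) for x in (*r, *c))
    den = lgamma(n + 1) + sum(lgamma(x + 1) for x in table.ravel())
    return num - den


def group_distribution_test(
    table: Sequence[Sequence[int]] | np.ndarray,
    max_enumeration: int = 500,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Exact (or seeded Monte-Carlo) Fisher test for a 2x3 contingency table.

    Tests the null that mutations are equally distributed over the three
    sample groups.  The p-value is the total null probability of tables with
    the observed margins whose probability does not exceed the observed
    table's.  Full enumeration when the grand total is <= ``max_enumeration``,
    otherwise Monte-Carlo with at least 1e5 draws under a fixed seed.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 3):
        raise ValueError(f"expected a 2x3 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    n = int(t.sum())
    if n == 0:
        return 1.0
    r1 = int(t[0].sum())
    c1, c2, c3 = (int(x) for x in t.sum(axis=0))
    logp_obs = _log_table_prob(t)
    tol = 1e-12 * abs(logp_obs) + 1e-12

    if n <= max_enumeration:
        total = 0.0
        for a in range(max(0, r1 - c2 - c3), min(r1, c1) + 1):
            for b in range(max(0, r1 - a - c3), min(r1 - a, c2) + 1):
                cand = np.array(
                    [[a, b, r1 - a - b], [c1 - a, c2 - b, c3 - (r1 - a - b)]]
                )
                lp = _log_table_prob(cand)
                if lp <= logp_obs + tol:
                    total += math.exp(lp)
        return min(1.0, total)

    if n_mc < 100_000:
        raise ValueError("Monte-Carlo mode requires at least 1e5 draws")
    rng = np.random.default_rng(seed)
    a = rng.hypergeometric(c1, n - c1, r1, size=n_mc)
    b = rng.hypergeometric(c2, n - c1 - c2, r1 - a, size=n_mc)
    # vectorised log-probabilities over sampled tables
    from scipy.special import gammaln

    cells = np.stack([a, b, r1 - a - b, c1 - a, c2 - b, c3 - (r1 - a - b)], axis=1)
    const = (
        sum(gammaln(x + 1) for x in (r1, n - r1, c1, c2, c3)) - gammaln(n + 1)
    )
    lp = const - gammaln(cells + 1).sum(axis=1)
    return float(np.mean(lp <= logp_obs + tol))


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def driver_proportions(
    assignment: ClassAssignment,
    mutations: MutationTable,
    driver_list: Iterable[str],
    by: str = "gene",
) -> pd.Series:
    """Fraction of each greek class whose gene (or locus) is in the driver list."""
    if len(assignment.table) == 0:
        raise ValueError("empty class assignment")
    if by not in ("gene", "locus"):
        raise ValueError("by must be 'gene' or 'locus'")
    drivers = set(driver_list)
    hit = mutations.meta[by].isin(drivers)
    out = {}
    for g in GREEK_CLASSES:
        ids = assignment.ids_in_class(g)
        out[g] = float(hit.loc[ids].mean()) if ids else float("nan")
    return pd.Series(out)
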