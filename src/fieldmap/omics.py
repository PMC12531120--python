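"""Monotonic dysregulation calling, signature scores, ssGSEA, enrichment.

Stage effects are mean log2 differences of each histology group (NU_LGIN,
HGIN, UC) versus the control samples, with Wilcoxon rank-sum p-values and
Benjamini-Hochberg q-values per group across analytes.  An analyte is called
*monotonically dysregulated* when its effect keeps one sign, does not shrink
along NU_LGIN → HGIN → UC (within tolerance τ), and is significant at the UC
stage; wave 1 analytes are already significant in NU/LGIN, wave 2 first at
HGIN.  Missing values (unquantified analytes) are excluded pairwise.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GROUPS, FieldMap, OmicsMatrix
from .mutation_classes import bh_fdr

__all__ = [
    "stage_effects",
    "call_monotonic",
    "signature_score",
    "ssgsea_es",
    "pathway_enrichment",
    "rna_protein_concordance",
    "score_table",
    "builtin_score_sets",
    "builtin_signature_scores",
    "builtin_marker_directions",
]


def _ranksum_p_block(x: np.ndarray, n_group: int, max_combos: int = 200_000) -> np.ndarray:
    """Exact two-sided rank-sum p-values for a complete-data block.

    ``x`` is analytes x (group samples then control samples); the exact
    conditional permutation distribution of the control rank sum is
    enumerated (mid-ranks, so ties are handled exactly); two-sided p is the
    null probability of a rank sum at least as far from its expectation.
    Falls back to the normal approximation with tie correction when the
    number of arrangements exceeds ``max_combos``.
    """
    from itertools import combinations
    from math import comb

    n_tot = x.shape[1]
    n_ctrl = n_tot - n_group
    if n_group < 1 or n_ctrl < 1:
        return np.ones(x.shape[0])
    if comb(n_tot, n_ctrl) > max_combos:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(
                x[:, :n_group], x[:, n_group:], axis=1, alternative="two-sided"
            )
        p = np.asarray(res.pvalue, dtype=float)
        return np.where(np.isnan(p), 1.0, p)
    ranks = stats.rankdata(x, axis=1, method="average")
    mu = n_ctrl * (n_tot + 1) / 2.0
    obs = np.abs(ranks[:, n_group:].sum(axis=1) - mu)
    combos = np.zeros((n_tot, comb(n_tot, n_ctrl)), dtype=float)
    for j, idx in enumerate(combinations(range(n_tot), n_ctrl)):
        combos[list(idx), j] = 1.0
    null = np.abs(ranks @ combos - mu)
    return (null >= obs[:, None] - 1e-9).mean(axis=1)


def _ranksum_p(group: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Per-analyte exact rank-sum p, missing values excluded pairwise.

    Analytes sharing a missingness pattern are tested in one vectorised
    block; an analyte with no usable observation on either side gets p = 1.
    """
    x = np.concatenate([group, ctrl], axis=1)
    n_group = group.shape[1]
    miss = np.isnan(x)
    p = np.ones(x.shape[0])
    patterns, inverse = np.unique(miss, axis=0, return_inverse=True)
    for k in range(patterns.shape[0]):
        rows = np.flatnonzero(inverse == k)
        keep = ~patterns[k]
        ng = int(keep[:n_group].sum())
        nc = int(keep[n_group:].sum())
        if ng < 1 or nc < 1:
            continue
        p[rows] = _ranksum_p_block(x[np.ix_(rows, np.flatnonzero(keep))], ng)
    return p


def stage_effects(
    matrix: OmicsMatrix,
    field_map: FieldMap,
    low_coverage_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-analyte stage effects and rank-sum q-values versus controls.

    The effect is the mean log2 abundance of the group minus the control
    mean; the p-value is an exact conditional Wilcoxon rank-sum permutation
    test (mid-ranks) against the controls, BH-corrected across analytes
    within each group.  Returns a frame with ``effect_<g>``, ``p_<g>``,
    ``q_<g>`` for each group plus a ``low_coverage`` flag for analytes
    quantified in fewer than half the samples (flagged, never dropped).
    """
    ctrl = matrix.controls().to_numpy(dtype=float)
    if ctrl.shape[1] < 1:
        raise ValueError("no control samples")
    groups_by_field = field_map.group_of()
    sample_ids = matrix.map_sample_ids
    known = [s for s in sample_ids if s in groups_by_field.index]
    present_groups = set(groups_by_field.reindex(known).dropna())
    missing = [g for g in GROUPS if g not in present_groups]
    if missing:
        raise ValueError(
            f"group(s) {missing} have no samples; groups present: "
            f"{sorted(present_groups)}"
        )

    out = pd.DataFrame(index=matrix.values.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctrl_mean = np.nanmean(ctrl, axis=1)
    vals = matrix.values
    for g in GROUPS:
        cols = [s for s in known if groups_by_field[s] == g]
        if len(cols) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
        x = vals[cols].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[f"effect_{g}"] = np.nanmean(x, axis=1) - ctrl_mean
        p = _ranksum_p(x, ctrl)
        out[f"p_{g}"] = p
        out[f"q_{g}"] = bh_fdr(p)
    n_all = len(matrix.values.columns)
    out["low_coverage"] = (
        matrix.values.notna().sum(axis=1) < low_coverage_fraction * n_all
    )
    return out


def call_monotonic(
    effects: pd.DataFrame,
    q_cut: float = 0.05,
    tau: float = 0.0,
) -> pd.DataFrame:
    """Call monotone direction and wave from a stage-effect frame.

    Monotone up: e(NU_LGIN) <= e(HGIN) + τ, e(HGIN) <= e(UC) + τ, e(UC) > 0
    and q(UC) < ``q_cut`` (mirrored for down).  Wave 1 when q(NU_LGIN) <
    q_cut; wave 2 when not wave 1 and q(HGIN) < q_cut; late monotone analytes
    (significant only at UC) carry wave 0.  Idempotent, order-invariant.
    """
    e1, e2, e3 = (effects[f"effect_{g}"].to_numpy(dtype=float) for g in GROUPS)
    q1, q2, q3 = (effects[f"q_{g}"].to_numpy(dtype=float) for g in GROUPS)
    up = (e1 <= e2 + tau) & (e2 <= e3 + tau) & (e3 > 0) & (q3 < q_cut)
    down = (e1 >= e2 - tau) & (e2 >= e3 - tau) & (e3 < 0) & (q3 < q_cut)
    monotone = up | down
    direction = np.where(up, "up", np.where(down, "down", "none"))
    wave = np.where(
        monotone & (q1 < q_cut), 1, np.where(monotone & (q2 < q_cut), 2, 0)
    )
    out = effects.copy()
    out["monotone"] = monotone
    out["direction"] = direction
    out["wave"] = wave
    return out


def _control_z(matrix: OmicsMatrix) -> pd.DataFrame:
    """Per-analyte z-scores of every sample against the control mean/SD."""
    ctrl = matrix.controls().to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mu = np.nanmean(ctrl, axis=1)
        if ctrl.shape[1] >= 2:
            sd = np.nanstd(ctrl, axis=1, ddof=1)
        else:
            sd = np.full(len(mu), np.nan)
    sd = np.where((sd > 0) & np.isfinite(sd), sd, np.nan)
    z = (matrix.values.to_numpy(dtype=float) - mu[:, None]) / sd[:, None]
    return pd.DataFrame(z, index=matrix.values.index, columns=matrix.values.columns)


def signature_score(
    matrix: OmicsMatrix,
    up_set: Iterable[str],
    down_set: Iterable[str] = (),
) -> pd.Series:
    """Mean-z difference score per sample: mean z(up) − mean z(down).

    z-scores are taken against the control mean and SD per analyte; a sample
    identical to the control means scores 0.  An empty down set drops the
    second term.  Raises when no member of either set is quantified.
    """
    z = _control_z(matrix)
    up = [g for g in up_set if g in z.index]
    down = [g for g in down_set if g in z.index]
    if not up and not down:
        raise ValueError("no member of either gene set is present in the matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        up_term = z.loc[up].mean(axis=0, skipna=True) if up else 0.0
        down_term = z.loc[down].mean(axis=0, skipna=True) if down else 0.0
    score = up_term - down_term
    score.name = "score"
    return score


def ssgsea_es(
    expression: pd.Series,
    gene_set: Iterable[str],
    alpha: float = 0.75,
) -> float:
    """Single-sample GSEA enrichment score (maximum-deviation convention).

    Analytes are ranked by expression (descending); in-set and out-of-set
    analytes accumulate weight rank_value^alpha (rank value decreasing from
    N to 1), and the ES is the signed maximum deviation between the two
    weighted cumulative distributions, in [−1, 1].  Weighting both sides
    identically makes the in/out labels exchangeable under a random set, so
    the null ES is centred at 0; the statistic is rank-based, hence
    invariant under strictly monotone transforms of the expression vector.
    """
    expr = expression.dropna()
    if len(expr) < 10:
        raise ValueError("need at least 10 quantified analytes")
    members = set(gene_set) & set(expr.index)
    if not members:
        raise ValueError("gene set does not intersect the expression vector")
    order = expr.sort_values(ascending=False, kind="mergesort")
    n = len(order)
    in_set = order.index.isin(members)
    if in_set.all():
        raise ValueError("gene set covers the whole expression vector")
    rank_value = np.arange(n, 0, -1, dtype=float)  # N for the top analyte
    w = rank_value**alpha
    w_in = np.where(in_set, w, 0.0)
    w_out = np.where(in_set, 0.0, w)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(w_out) / w_out.sum()
    dev = p_in - p_out
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def pathway_enrichment(
    hit_genes: Iterable[str],
    universe: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric upper-tail) enrichment per gene set."""
    hits = set(hit_genes)
    uni = set(universe)
    if not hits <= uni:
        raise ValueError("hit genes must be a subset of the universe")
    m = len(uni)
    n = len(hits)
    rows = []
    for name, members in gene_sets.items():
        in_uni = set(members) & uni
        k = len(in_uni & hits)
        big_k = len(in_uni)
        p = float(stats.hypergeom.sf(k - 1, m, big_k, n)) if big_k else 1.0
        rows.append({"set": name, "overlap": k, "set_size": big_k, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out


def rna_protein_concordance(
    calls_rna: pd.DataFrame,
    calls_protein: pd.DataFrame,
) -> pd.DataFrame:
    """Analytes monotonically dysregulated in the same direction on both
    platforms (the RNA/protein concordant set)."""
    shared = calls_rna.index.intersection(calls_protein.index)
    if len(shared) == 0:
        raise ValueError("no shared analyte identifiers between the platforms")
    r = calls_rna.loc[shared]
    p = calls_protein.loc[shared]
    both = (
        r["monotone"].to_numpy()
        & p["monotone"].to_numpy()
        & (r["direction"].to_numpy() == p["direction"].to_numpy())
    )
    out = pd.DataFrame(
        {
            "direction": r["direction"][both],
            "wave_rna": r["wave"][both],
            "wave_protein": p["wave"][both],
        },
        index=shared[both],
    )
    return out


# ---------------------------------------------------------------------------
# built-in marker sets
# ---------------------------------------------------------------------------

_SETS: dict[str, list[str]] = {
    "BASAL": ["KRT6A", "KRT14", "KRT16", "KRT5", "CXCL8", "IL1R2", "FBXO5", "E2F1"],
    "LUMINAL": ["UPK3B", "UPK1A", "PAX8", "FOXA1", "TFAP2B", "PIK3C2G", "GATA3"],
    "EMT_UP": ["VIM", "ZEB1", "ZEB2", "SNAI1", "SNAI2", "TWIST1", "TGFB1"],
    "EMT_DOWN": ["CDH1", "CLDN1", "TJP1", "DSP"],
    "OXPHOS": ["NDUFA1", "NDUFB5", "NDUFS2", "SDHB", "UQCRC1", "COX5A",
               "ATP5F1A", "ATP5MC1"],
    "TCA": ["CS", "IDH3A", "FH", "MDH2", "SUCLA2", "ACO2"],
    "GLYCOLYSIS": ["LDHA", "HK2", "PKM", "SLC2A1", "ENO1"],
    "IMMUNE": ["CD3E", "CD8A", "GZMB", "PRF1", "CD4"],
    "T_EXHAUSTION": ["PDCD1", "CTLA4", "LAG3", "HAVCR2", "TOX"],
}

#: score name -> (up set, down set); sign conventions follow the field's
#: usage: negative BLT = basal-shifted, negative EMT = mesenchymal-shifted,
#: negative energy = oxidative metabolism lost to glycolysis.
_SCORES: dict[str, tuple[str, str]] = {
    "BLT": ("LUMINAL", "BASAL"),
    "EMT": ("EMT_DOWN", "EMT_UP"),
    "energy": ("OXPHOS", "GLYCOLYSIS"),
    "immune": ("IMMUNE", ""),
    "T_exhaustion": ("T_EXHAUSTION", ""),
}


def builtin_score_sets() -> dict[str, list[str]]:
    """Editable marker gene sets behind the built-in signature scores."""
    return {k: list(v) for k, v in _SETS.items()}


def builtin_signature_scores() -> dict[str, tuple[str, str]]:
    return dict(_SCORES)


def builtin_marker_directions() -> dict[str, str]:
    """Expected monotone direction of each built-in marker gene."""
    up = ["BASAL", "EMT_UP", "GLYCOLYSIS", "IMMUNE", "T_EXHAUSTION"]
    down = ["LUMINAL", "EMT_DOWN", "OXPHOS", "TCA"]
    out: dict[str, str] = {}
    for grp in up:
        for g in _SETS[grp]:
            out.setdefault(g, "up")
    for grp in down:
        for g in _SETS[grp]:
            out.setdefault(g, "down")
    return out


def score_table(
    matrix: OmicsMatrix,
    gene_sets: Mapping[str, Iterable[str]] | None = None,
    scores: Mapping[str, tuple[str, str]] | None = None,
    pathways: Mapping[str, Iterable[str]] | None = None,
    alpha: float = 0.75,
) -> pd.DataFrame:
    """Per-sample named signature scores plus optional ssGSEA pathway ES."""
    gene_sets = dict(gene_sets) if gene_sets is not None else builtin_score_sets()
    scores = dict(scores) if scores is not None else builtin_signature_scores()
    out = pd.DataFrame(index=matrix.values.columns)
    for name, (up_name, down_name) in scores.items():
        up = gene_sets.get(up_name, [])
        down = gene_sets.get(down_name, []) if down_name else []
        try:
            out[name] = signature_score(matrix, up, down)
        except ValueError:
            out[name] = np.nan
    if pathways:
        for pname, members in pathways.items():
            vals = []
            for col in matrix.values.columns:
                try:
                    vals.append(ssgsea_es(matrix.values[col], members, alpha=alpha))
                except ValueError:
                    vals.append(np.nan)
            out[f"ES_{pname}"] = vals
    return out
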