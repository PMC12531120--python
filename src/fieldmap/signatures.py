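"""96-context spectra, reference-signature refitting, bootstrap significance.

Spectra are assembled over the canonical 96 trinucleotide motifs and refit
against a fixed reference catalog by non-negative least squares; the fitted
weights ("weight scores") are renormalised to sum to 1.  A signature's
bootstrap p-value is the fraction of case-resampled refits in which its
weight effectively vanishes (<= ``w_min``); p < 0.005 is called significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .io_formats import MOTIFS_96, SUBSTITUTIONS, MutationTable, SignatureCatalog
from .mutation_classes import bh_fdr

__all__ = [
    "SIGNIFICANCE_P",
    "ContextSpectrum",
    "SignatureWeights",
    "context_spectrum",
    "fit_weights",
    "bootstrap_significance",
    "substitution_class_comparison",
]

#: bootstrap significance cut for a signature's presence
SIGNIFICANCE_P = 0.005


@dataclass(frozen=True)
class ContextSpectrum:
    """Counts over the 96 canonical motifs for a labelled mutation group."""

    counts: pd.Series
    label: str = ""

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(MOTIFS_96):
            raise ValueError("spectrum must be indexed by the 96 canonical motifs")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalised(self) -> np.ndarray:
        t = self.counts.sum()
        return self.counts.to_numpy(dtype=float) / t


@dataclass(frozen=True)
class SignatureWeights:
    """Refit mixture weights, one per reference signature."""

    weights: pd.Series  # sums to 1
    residual: float
    pvalues: pd.Series | None = None  # bootstrap p per signature

    def significant(self, p_cut: float = SIGNIFICANCE_P) -> pd.Series:
        if self.pvalues is None:
            raise ValueError("no bootstrap p-values attached")
        return self.pvalues < p_cut


def context_spectrum(
    mutations: MutationTable,
    subset: Sequence[str] | None = None,
    label: str = "",
) -> ContextSpectrum:
    """Tally SNV trinucleotide contexts over the canonical motif order.

    INS/DEL rows are ignored; a subset with no SNVs is an error.
    """
    meta = mutations.meta
    ids = pd.Index(subset) if subset is not None else meta.index
    if len(ids) == 0:
        raise ValueError("empty mutation subset")
    ctx = meta.loc[ids]
    ctx = ctx.loc[ctx["mtype"] == "SNV", "context"]
    if len(ctx) == 0:
        raise ValueError("subset contains no SNVs (indels carry no context)")
    counts = ctx.value_counts().reindex(MOTIFS_96, fill_value=0)
    counts.index.name = "context"
    return ContextSpectrum(counts.astype(int), label=label)


def spectrum_from_contexts(contexts: Sequence[str], label: str = "") -> ContextSpectrum:
    """Build a spectrum directly from motif strings (used by resamplers)."""
    counts = pd.Series(contexts).value_counts().reindex(MOTIFS_96, fill_value=0)
    counts.index.name = "context"
    return ContextSpectrum(counts.astype(int), label=label)


def fit_weights(
    spectrum: ContextSpectrum, catalog: SignatureCatalog
) -> SignatureWeights:
    """Non-negative least-squares refit of a spectrum against the catalog.

    The fit is scale-invariant: the spectrum is normalised to a probability
    vector before solving, and the non-negative solution is renormalised to
    sum to exactly 1.
    """
    if spectrum.total <= 0:
        raise ValueError("spectrum is empty")
    a = catalog.matrix.to_numpy(dtype=float)
    b = spectrum.normalised()
    if a.shape[0] != b.shape[0]:
        raise ValueError("catalog/spectrum dimension mismatch")
    w, rnorm = nnls(a, b)
    total = w.sum()
    if total <= 0:  # pathological: catalog orthogonal to spectrum
        w = np.full(len(w), 1.0 / len(w))
        total = 1.0
    weights = pd.Series(w / total, index=catalog.signature_names, name="weight")
    return SignatureWeights(weights=weights, residual=float(rnorm))


def _pruned_nnls(a: np.ndarray, b: np.ndarray, w_min: float) -> np.ndarray:
    """NNLS refit with iterative sparsity pruning.

    Signatures whose normalised weight falls below ``w_min`` are removed and
    the remainder refit until the active set is stable — the standard sparse
    refitting step, which keeps sampling noise from parking small spurious
    weights on absent signatures.
    """
    k = a.shape[1]
    active = np.arange(k)
    w_full = np.zeros(k)
    for _ in range(k):
        w, _ = nnls(a[:, active], b)
        total = w.sum()
        w = w / total if total > 0 else np.full(len(active), 1.0 / len(active))
        keep = w > w_min
        if keep.all() or not keep.any():
            w_full[:] = 0.0
            w_full[active] = w
            return w_full
        active = active[keep]
    w_full[:] = 0.0
    w_full[active] = w
    return w_full


def bootstrap_significance(
    mutations: MutationTable,
    catalog: SignatureCatalog,
    subset: Sequence[str] | None = None,
    B: int = 1000,
    w_min: float = 0.01,
    seed: int = 0,
) -> SignatureWeights:
    """Bootstrap p-values for each signature's contribution.

    SNVs are resampled with replacement B times and refit with sparsity
    pruning at ``w_min``; p(signature k) is the fraction of replicates in
    which weight(k) effectively vanishes (<= ``w_min``).  A signature that
    genuinely contributes keeps a stable weight in every replicate (p = 0);
    an absent one is pruned away in almost all replicates (p near 1).
    Reproducible bit-exactly under a fixed seed.
    """
    if B < 100:
        raise ValueError("B < 100 cannot resolve the 0.005 significance cut")
    spec = context_spectrum(mutations, subset)
    n = spec.total
    if n < 50:
        warnings.warn(f"only {n} SNVs; bootstrap p-values will be unstable")
    point = fit_weights(spec, catalog)
    rng = np.random.default_rng(seed)
    probs = spec.normalised()
    exceed = np.zeros(catalog.n_signatures)
    a = catalog.matrix.to_numpy(dtype=float)
    for _ in range(B):
        resampled = rng.multinomial(n, probs).astype(float)
        w = _pruned_nnls(a, resampled / n, w_min)
        exceed += w <= w_min
    pvals = pd.Series(exceed / B, index=catalog.signature_names, name="p")
    return SignatureWeights(point.weights, point.residual, pvalues=pvals)


def _per_sample_fractions(
    mutations: MutationTable,
    member_ids: pd.Index,
    presence_threshold: float,
) -> pd.DataFrame:
    """Six-class substitution fractions per field, over a mutation subset."""
    meta = mutations.meta.loc[member_ids]
    snv_ids = meta.index[meta["mtype"] == "SNV"]
    presence = mutations.vaf.loc[snv_ids] >= presence_threshold
    sub = mutations.meta.loc[snv_ids, "substitution"]
    out = {}
    for s in SUBSTITUTIONS:
        out[s] = presence.loc[sub == s].sum(axis=0)
    frac = pd.DataFrame(out)
    totals = frac.sum(axis=1)
    frac = frac.div(totals.replace(0, np.nan), axis=0)
    frac["n_snv"] = totals
    return frac


def substitution_class_comparison(
    mutations: MutationTable,
    sample_groups: Mapping[str, str] | pd.Series | None = None,
    mutation_groups: Mapping[str, str] | pd.Series | None = None,
    presence_threshold: float = 0.01,
) -> dict[str, pd.DataFrame]:
    """Compare six-class substitution fractions between groups.

    Exactly one grouping must be supplied: ``sample_groups`` maps fields to
    groups (e.g. NU_LGIN/HGIN/UC) and compares whole-sample spectra between
    the sample groups; ``mutation_groups`` maps mutation ids to groups (e.g.
    alpha/beta/gamma or dormant/progressive) and compares, across all fields,
    the per-field fractions of each mutation group.

    Returns ``{"fractions": per-(field, group) table, "tests": per class and
    group-pair Wilcoxon rank-sum p with BH q across the six classes}``.
    Pairs where either group has fewer than 2 usable samples are skipped with
    a warning.
    """
    if (sample_groups is None) == (mutation_groups is None):
        raise ValueError("supply exactly one of sample_groups / mutation_groups")

    blocks = []
    if sample_groups is not None:
        sg = pd.Series(sample_groups)
        frac = _per_sample_fractions(mutations, mutations.meta.index, presence_threshold)
        frac.insert(0, "group", sg.reindex(frac.index))
        blocks.append(frac)
    else:
        mg = pd.Series(mutation_groups)
        for g in sorted(mg.unique()):
            ids = pd.Index(mg.index[mg == g])
            f = _per_sample_fractions(mutations, ids, presence_threshold)
            f.insert(0, "group", g)
            blocks.append(f)
    fractions = pd.concat(blocks)
    groups = [g for g in pd.unique(fractions["group"]) if pd.notna(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")

    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            pvals = []
            for s in SUBSTITUTIONS:
                x = fractions.loc[fractions["group"] == g1, s].dropna()
                y = fractions.loc[fractions["group"] == g2, s].dropna()
                if len(x) < 2 or len(y) < 2:
                    pvals.append(np.nan)
                    continue
                if x.nunique() == 1 and y.nunique() == 1 and x.iloc[0] == y.iloc[0]:
                    pvals.append(1.0)  # exact tie; rank test is degenerate
                    continue
                res = stats.mannwhitneyu(x, y, alternative="two-sided")
                pvals.append(float(res.pvalue))
            pvals = np.asarray(pvals, dtype=float)
            if np.isnan(pvals).all():
                warnings.warn(f"comparison {g1} vs {g2} skipped: group too small")
                continue
            q = np.full(6, np.nan)
            ok = ~np.isnan(pvals)
            if ok.any():
                q[ok] = bh_fdr(pvals[ok])
            for s, p, qq in zip(SUBSTITUTIONS, pvals, q):
                rows.append({"group1": g1, "group2": g2, "substitution": s,
                             "p": p, "q": qq})
    tests = pd.DataFrame(rows)
    return {"fractions": fractions, "tests": tests}
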