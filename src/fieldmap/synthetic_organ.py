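"""Whole-organ synthetic dataset with known ground truth.

Emulates the data structure of a whole-organ cystectomy map: ~37 mucosal
fields on a grid with an invasive-carcinoma (UC) focus surrounded by a
high-grade (HGIN) ring on a background of normal/low-grade (NU/LGIN) mucosa;
three planted mutation classes —

* **alpha** — private neutral mutations, one field each, VAFs drawn from the
  neutral clone-size law f(v) ∝ 1/v² (cumulative count linear in 1/f);
* **beta** — regionally expanded low-VAF clones spanning 3-20 contiguous
  fields (4-neighbour growth), per-field VAF ~ Uniform(0.02, 0.18);
* **gamma** — one widespread high-VAF plaque covering every HGIN/UC field
  (>=21 fields), per-field VAF ~ Normal(0.35, 0.05²) truncated to [0.2, 0.5]

— plus RNA/protein/metabolite abundance matrices with planted monotonically
dysregulated analytes (two waves and a late group) and baseline controls.

Default parameters are the study's conditions: 12,431 alpha / 54 beta / 324
gamma mutations with their SNV/INS/DEL splits, 45 loci recurrently hit in two
classes (so 12,764 distinct loci), 37 fields, a 30-year history with a 5-year
progressive era whose detectable arrival-rate break is the gamma onset at
2 years, 8,475 proteins, 91 metabolites, 3 control samples per platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    GROUPS,
    MOTIFS_96,
    FieldMap,
    MutationTable,
    OmicsMatrix,
    SignatureCatalog,
)

__all__ = [
    "ConfigError",
    "OmicsPlatformConfig",
    "OrganConfig",
    "SyntheticTruth",
    "OrganData",
    "plant_histology",
    "reference_catalog",
    "neutral_vaf_sample",
    "generate_organ",
]


class ConfigError(ValueError):
    """Raised for generator configurations that cannot be realised."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OmicsPlatformConfig:
    """Planted structure of one analyte x sample matrix."""

    n_analytes: int
    n_up: int  # monotonically upregulated analytes
    n_down: int
    wave1_up: int  # of n_up, already dysregulated in NU/LGIN
    wave1_down: int
    wave2_up: int  # first dysregulated at the HGIN transition
    wave2_down: int
    n_transient: int = 0  # dysregulated early but regressing; never monotone
    missing_fraction: float = 0.0

    def validate(self) -> None:
        if min(asdict(self).values()) < 0:
            raise ConfigError("omics counts and fractions must be non-negative")
        if self.n_up + self.n_down + self.n_transient > self.n_analytes:
            raise ConfigError("planted analytes exceed matrix size")
        if self.wave1_up + self.wave2_up > self.n_up:
            raise ConfigError("wave counts exceed monotone-up count")
        if self.wave1_down + self.wave2_down > self.n_down:
            raise ConfigError("wave counts exceed monotone-down count")
        if not 0 <= self.missing_fraction < 1:
            raise ConfigError("missing_fraction must be in [0, 1)")


_RNA_DEFAULT = OmicsPlatformConfig(
    n_analytes=20795, n_up=502, n_down=772,
    wave1_up=212, wave1_down=142, wave2_up=3, wave2_down=51,
    n_transient=200, missing_fraction=0.0,
)
_PROTEIN_DEFAULT = OmicsPlatformConfig(
    n_analytes=8475, n_up=1150, n_down=1354,
    wave1_up=350, wave1_down=350, wave2_up=50, wave2_down=50,
    n_transient=100, missing_fraction=0.08,
)
_METABOLITE_DEFAULT = OmicsPlatformConfig(
    n_analytes=91, n_up=15, n_down=15,
    wave1_up=5, wave1_down=5, wave2_up=2, wave2_down=2,
    n_transient=4, missing_fraction=0.05,
)


@dataclass(frozen=True)
class OrganConfig:
    """Generator parameters; defaults are the study conditions."""

    # histology grid
    rows: int = 5
    cols: int = 8
    n_fields: int = 37
    uc_height: int = 3
    uc_width: int = 3
    ring_width: int = 1
    n_lgin: int = 4

    # history (years); ages are years before observation
    total_years: float = 30.0
    progressive_years: float = 5.0  # beta + gamma era
    gamma_years: float = 2.0  # gamma sweep era = planted arrival-rate break

    # per-class mutation counts (SNV, INS, DEL)
    n_alpha: tuple[int, int, int] = (11698, 448, 285)
    n_beta: tuple[int, int, int] = (51, 1, 2)
    n_gamma: tuple[int, int, int] = (315, 2, 7)
    # loci recurrently mutated in both alpha and gamma
    shared_loci: tuple[int, int, int] = (42, 1, 2)

    n_beta_clones: int = 6
    beta_span: tuple[int, int] = (3, 20)
    gamma_min_span: int = 21

    # VAF laws
    alpha_vaf_range: tuple[float, float] = (0.01, 0.25)
    beta_vaf_range: tuple[float, float] = (0.02, 0.18)
    gamma_vaf: tuple[float, float, float, float] = (0.35, 0.05, 0.20, 0.50)

    silent_fraction: float = 0.25
    driver_prob: tuple[float, float, float] = (0.02, 0.15, 0.40)  # alpha/beta/gamma
    n_driver_genes: int = 100

    # per-class signature mixtures over the 12 reference signatures
    alpha_mixture: tuple[float, ...] = tuple([1 / 12] * 12)
    beta_mixture: tuple[float, ...] = (0.5,) + tuple([0.5 / 11] * 11)
    gamma_mixture: tuple[float, ...] = (0.7, 0.0, 0.0, 0.0, 0.0, 0.3) + (0.0,) * 6

    # growth model used to define true selection coefficients
    r0: float = 1.0  # baseline net growth per year
    n_cells_per_field: float = 1e6

    # omics
    rna: OmicsPlatformConfig = field(default_factory=lambda: _RNA_DEFAULT)
    protein: OmicsPlatformConfig = field(default_factory=lambda: _PROTEIN_DEFAULT)
    metabolite: OmicsPlatformConfig = field(default_factory=lambda: _METABOLITE_DEFAULT)
    n_controls: int = 3
    noise_sigma: float = 0.5
    effect_wave1: tuple[float, float, float] = (1.0, 2.0, 3.0)
    effect_wave2: tuple[float, float, float] = (0.0, 2.0, 3.0)
    effect_late: tuple[float, float, float] = (0.0, 0.5, 3.0)
    effect_transient: tuple[float, float, float] = (2.0, 1.0, 0.0)
    concordant_proteins: int = 486  # proteins monotone in the same direction as mRNA

    def validate(self) -> None:
        if self.rows * self.cols < self.n_fields:
            raise ConfigError("grid smaller than requested field count")
        for name in ("n_alpha", "n_beta", "n_gamma", "shared_loci"):
            if min(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.total_years <= 0 or self.r0 <= 0 or self.n_cells_per_field <= 0:
            raise ConfigError("rates and sizes must be positive")
        if not 0 < self.progressive_years < self.total_years:
            raise ConfigError("progressive era must lie inside the total history")
        if not 0 < self.gamma_years <= self.progressive_years:
            raise ConfigError("gamma era must lie inside the progressive era")
        if self.beta_span[0] < 1 or self.beta_span[0] > self.beta_span[1]:
            raise ConfigError("invalid beta span range")
        if self.noise_sigma < 0 or min(self.driver_prob) < 0:
            raise ConfigError("negative rates are not allowed")
        for mix in (self.alpha_mixture, self.beta_mixture, self.gamma_mixture):
            arr = np.asarray(mix, dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1) > 1e-9:
                raise ConfigError("signature mixtures must be non-negative and sum to 1")
        for p in (self.rna, self.protein, self.metabolite):
            p.validate()

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# histology map
# ---------------------------------------------------------------------------


def _field_id(r: int, c: int) -> str:
    return f"{chr(ord('A') + r)}{c + 1}"


def plant_histology(
    rows: int = 5,
    cols: int = 8,
    uc_height: int = 3,
    uc_width: int = 3,
    ring_width: int = 1,
    n_fields: int | None = None,
    n_lgin: int = 4,
) -> FieldMap:
    """Lay out one contiguous UC block, a surrounding HGIN ring, NU/LGIN rest.

    The UC block is placed interior (ring included) against the right edge of
    the grid.  If ``n_fields`` is below the grid size, NU/LGIN fields are
    dropped from the row-major tail until the count is met.
    """
    if rows < 1 or cols < 1:
        raise ConfigError("grid must have positive dimensions")
    if uc_height * uc_width > 0:
        if uc_height + 2 * ring_width > rows or uc_width + 2 * ring_width > cols:
            raise ConfigError("UC focus plus ring does not fit inside the grid")
        r0 = ring_width
        c0 = cols - uc_width - ring_width
    grades: dict[tuple[int, int], str] = {}
    for r in range(rows):
        for c in range(cols):
            grades[(r, c)] = "NU"
    if uc_height * uc_width > 0:
        for r in range(r0 - ring_width, r0 + uc_height + ring_width):
            for c in range(c0 - ring_width, c0 + uc_width + ring_width):
                grades[(r, c)] = "HGIN"
        for r in range(r0, r0 + uc_height):
            for c in range(c0, c0 + uc_width):
                grades[(r, c)] = "UC"

    cells = [(r, c) for r in range(rows) for c in range(cols)]
    if n_fields is not None:
        n_drop = rows * cols - n_fields
        if n_drop < 0:
            raise ConfigError("n_fields exceeds grid size")
        droppable = [rc for rc in reversed(cells) if grades[rc] == "NU"]
        if len(droppable) < n_drop:
            raise ConfigError("cannot drop enough NU fields to reach n_fields")
        dropped = set(droppable[:n_drop])
        cells = [rc for rc in cells if rc not in dropped]

    # LGIN: the NU fields nearest the lesion become low-grade
    nu_cells = [rc for rc in cells if grades[rc] == "NU"]
    if n_lgin > 0 and uc_height * uc_width > 0:
        centre = (r0 + uc_height / 2, c0 + uc_width / 2)
        nu_sorted = sorted(
            nu_cells,
            key=lambda rc: (max(abs(rc[0] - centre[0]), abs(rc[1] - centre[1])), rc),
        )
        for rc in nu_sorted[: min(n_lgin, len(nu_sorted))]:
            grades[rc] = "LGIN"

    table = pd.DataFrame(
        {
            "row": [r for r, _ in cells],
            "col": [c for _, c in cells],
            "grade": [grades[rc] for rc in cells],
        },
        index=pd.Index([_field_id(r, c) for r, c in cells], name="field_id"),
    )
    return FieldMap(table)


def _contiguous_patch(
    field_map: FieldMap, size: int, rng: np.random.Generator,
    seed_fields: Sequence[str] | None = None,
) -> list[str]:
    """Grow a 4-neighbourhood-contiguous patch of ``size`` fields."""
    t = field_map.table
    coord_of = {fid: (t.at[fid, "row"], t.at[fid, "col"]) for fid in t.index}
    by_coord = {v: k for k, v in coord_of.items()}
    if seed_fields:
        patch = list(seed_fields)
    else:
        patch = [str(rng.choice(t.index.to_numpy()))]
    chosen = set(patch)
    while len(patch) < size:
        frontier = set()
        for fid in patch:
            r, c = coord_of[fid]
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = by_coord.get((r + dr, c + dc))
                if nb is not None and nb not in chosen:
                    frontier.add(nb)
        if not frontier:
            break  # patch hit the organ boundary; return what fits
        nxt = sorted(frontier)[rng.integers(len(frontier))]
        patch.append(nxt)
        chosen.add(nxt)
    return patch


# ---------------------------------------------------------------------------
# reference signature catalog (synthetic)
# ---------------------------------------------------------------------------


def reference_catalog(n_signatures: int = 12) -> SignatureCatalog:
    """Synthetic 12-signature reference catalog over the 96 canonical motifs.

    Not COSMIC content: a deterministic stand-in with the same shape.
    Signature 1 is clock-like (C>T at NpCpG) and signature 6 is a second,
    distinct C>T-rich profile, so the planted 'signature 1 prominence' of the
    expanded clones is recoverable by refitting.
    """
    if n_signatures < 2:
        raise ConfigError("catalog needs at least 2 signatures")
    rng = np.random.default_rng(961)  # fixed: the catalog is a constant
    cols = {}
    motifs = list(MOTIFS_96)

    sig1 = np.full(96, 0.1 / 80)
    for i, m in enumerate(motifs):
        if "[C>T]" in m and m.endswith("G"):  # X[C>T]G, the CpG transition
            sig1[i] = 0.15
        elif "[C>T]" in m:
            sig1[i] = 0.025
    cols["Signature.1"] = sig1 / sig1.sum()

    sig6 = np.full(96, 0.15 / 80)
    for i, m in enumerate(motifs):
        if "[C>T]" in m and m[0] == "G":  # G[C>T]X
            sig6[i] = 0.55 / 4
        elif "[C>A]" in m:
            sig6[i] = 0.30 / 16
    cols["Signature.6"] = sig6 / sig6.sum()

    for k in range(2, n_signatures + 1):
        if k == 6:
            continue
        w = rng.dirichlet(np.full(96, 0.3))
        cols[f"Signature.{k}"] = w
    order = [f"Signature.{k}" for k in range(1, n_signatures + 1)]
    return SignatureCatalog(pd.DataFrame(cols, index=motifs)[order])


# ---------------------------------------------------------------------------
# mutation layer
# ---------------------------------------------------------------------------


def neutral_vaf_sample(
    n: int, rng: np.random.Generator, lo: float = 0.01, hi: float = 0.25
) -> np.ndarray:
    """Sample from the neutral clone-size law f(v) ∝ 1/v² on [lo, hi].

    Inverse-CDF: with u ~ U(0,1), v = 1 / (1/lo - u (1/lo - 1/hi)); the
    cumulative count above a frequency f is then linear in 1/f.
    """
    u = rng.random(n)
    return 1.0 / (1.0 / lo - u * (1.0 / lo - 1.0 / hi))


def _sample_contexts(
    n: int, mixture: np.ndarray, catalog: SignatureCatalog, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Draw (context, signature-of-origin) pairs from a signature mixture."""
    names = catalog.signature_names
    sig_idx = rng.choice(len(names), size=n, p=mixture)
    contexts = np.empty(n, dtype=object)
    for k in np.unique(sig_idx):
        mask = sig_idx == k
        col = catalog.matrix.iloc[:, k].to_numpy()
        contexts[mask] = rng.choice(MOTIFS_96, size=mask.sum(), p=col / col.sum())
    return list(contexts), [names[k] for k in sig_idx]


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`generate_organ`."""

    mutations: pd.DataFrame  # greek_class, age, selection, clone_id, signature, driver
    analytes: dict[str, pd.DataFrame]  # per platform: monotone/direction/wave/effects
    driver_genes: list[str]
    clone_footprints: dict[str, list[str]]
    transition_age: float  # planted arrival-rate break (gamma onset), years
    progressive_onset: float  # start of the beta+gamma era, years
    config: OrganConfig
    seed: int


@dataclass
class OrganData:
    field_map: FieldMap
    mutations: MutationTable
    omics: dict[str, OmicsMatrix]
    truth: SyntheticTruth
    catalog: SignatureCatalog


def _make_class(
    prefix: str,
    counts: tuple[int, int, int],
    mixture: np.ndarray,
    catalog: SignatureCatalog,
    rng: np.random.Generator,
    cfg: OrganConfig,
) -> pd.DataFrame:
    """Per-mutation annotation frame for one greek class (no VAFs yet)."""
    n_snv, n_ins, n_del = counts
    n = n_snv + n_ins + n_del
    mtype = ["SNV"] * n_snv + ["INS"] * n_ins + ["DEL"] * n_del
    contexts = ["."] * n
    signatures = [""] * n
    if n_snv:
        ctx, sig = _sample_contexts(n_snv, mixture, catalog, rng)
        contexts[:n_snv] = ctx
        signatures[:n_snv] = sig
    ids = [f"{prefix}{i:06d}" for i in range(n)]
    driver = rng.random(n) < {"a": cfg.driver_prob[0], "b": cfg.driver_prob[1],
                              "g": cfg.driver_prob[2]}[prefix]
    gene_pool_size = 18000
    genes = np.where(
        driver,
        [f"DRV{rng.integers(cfg.n_driver_genes):03d}" for _ in range(n)],
        [f"G{rng.integers(gene_pool_size):05d}" for _ in range(n)],
    )
    return pd.DataFrame(
        {
            "gene": genes,
            "locus": [f"L_{mid}" for mid in ids],
            "mtype": mtype,
            "substitution": [c[2:5] if c != "." else "" for c in contexts],
            "context": contexts,
            "silent": rng.random(n) < cfg.silent_fraction,
            "signature": signatures,
            "driver": driver,
        },
        index=pd.Index(ids, name="mutation_id"),
    )


def generate_organ(
    config: OrganConfig | None = None, seed: int = 0, include_omics: bool = True
) -> OrganData:
    """Generate the full synthetic organ: map, mutations, omics, truth.

    ``include_omics=False`` skips the abundance matrices (mutation-only
    studies such as seed sweeps of the classifier or the clock)."""
    cfg = config or OrganConfig()
    cfg.validate()
    catalog = reference_catalog()
    ss = np.random.SeedSequence(seed)
    rng_mut, rng_rna, rng_prot, rng_metab = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    field_map = plant_histology(
        cfg.rows, cfg.cols, cfg.uc_height, cfg.uc_width,
        cfg.ring_width, cfg.n_fields, cfg.n_lgin,
    )
    fields = field_map.field_ids
    n_fields = len(fields)
    groups = field_map.group_of()

    # --- gamma footprint: every HGIN/UC field, grown to >= gamma_min_span ---
    n_gamma_total = sum(cfg.n_gamma)
    gamma_fields: list[str] = []
    if n_gamma_total:
        gamma_fields = sorted(
            field_map.fields_in_group("HGIN") + field_map.fields_in_group("UC")
        )
        if len(gamma_fields) < cfg.gamma_min_span:
            if n_fields < cfg.gamma_min_span + 1:
                raise ConfigError(
                    f"gamma clone needs >= {cfg.gamma_min_span} fields but the organ "
                    f"has only {n_fields}"
                )
            gamma_fields = _contiguous_patch(
                field_map, cfg.gamma_min_span, rng_mut, seed_fields=gamma_fields
            )

    # --- per-class annotation frames ---
    alpha = _make_class("a", cfg.n_alpha, np.asarray(cfg.alpha_mixture), catalog, rng_mut, cfg)
    beta = _make_class("b", cfg.n_beta, np.asarray(cfg.beta_mixture), catalog, rng_mut, cfg)
    gamma = _make_class("g", cfg.n_gamma, np.asarray(cfg.gamma_mixture), catalog, rng_mut, cfg)

    # recurrently mutated loci: a subset of alpha loci coincide with gamma loci
    for mt, n_shared in zip(("SNV", "INS", "DEL"), cfg.shared_loci):
        a_ids = alpha.index[alpha["mtype"] == mt]
        g_ids = gamma.index[gamma["mtype"] == mt]
        k = min(n_shared, len(a_ids), len(g_ids))
        if k:
            alpha.loc[a_ids[:k], "locus"] = gamma.loc[g_ids[:k], "locus"].to_numpy()

    # --- VAF matrices ---
    n_alpha_total, n_beta_total = len(alpha), len(beta)
    vaf = np.zeros((n_alpha_total + n_beta_total + n_gamma_total, n_fields))
    fid_pos = {f: i for i, f in enumerate(fields)}

    home = rng_mut.integers(n_fields, size=n_alpha_total)
    vaf[np.arange(n_alpha_total), home] = neutral_vaf_sample(
        n_alpha_total, rng_mut, *cfg.alpha_vaf_range
    )
    clone_of = pd.Series("", index=alpha.index.append(beta.index).append(gamma.index))
    clone_footprints: dict[str, list[str]] = {}

    if n_beta_total:
        clones = max(1, min(cfg.n_beta_clones, n_beta_total))
        sizes = np.array_split(np.arange(n_beta_total), clones)
        for ci, members in enumerate(sizes):
            span = int(rng_mut.integers(cfg.beta_span[0], cfg.beta_span[1] + 1))
            patch = _contiguous_patch(field_map, span, rng_mut)
            cols = [fid_pos[f] for f in patch]
            lo, hi = cfg.beta_vaf_range
            block = rng_mut.uniform(lo, hi, size=(len(members), len(cols)))
            vaf[np.ix_(n_alpha_total + members, cols)] = block
            cname = f"beta_{ci}"
            clone_footprints[cname] = patch
            clone_of.iloc[n_alpha_total + members] = cname

    if n_gamma_total:
        mu, sd, lo, hi = cfg.gamma_vaf
        a, b = (lo - mu) / sd, (hi - mu) / sd
        cols = [fid_pos[f] for f in gamma_fields]
        block = stats.truncnorm.rvs(
            a, b, loc=mu, scale=sd, size=(n_gamma_total, len(cols)),
            random_state=rng_mut,
        )
        vaf[n_alpha_total + n_beta_total :, cols] = block
        clone_footprints["gamma"] = list(gamma_fields)
        clone_of.iloc[n_alpha_total + n_beta_total :] = "gamma"

    meta = pd.concat([alpha, beta, gamma])
    truth_cols = meta[["signature", "driver"]].copy()
    meta = meta.drop(columns=["signature", "driver"])
    vaf_df = pd.DataFrame(vaf, index=meta.index, columns=fields)
    mutations = MutationTable(meta, vaf_df)

    # --- true ages (years before observation) and selection coefficients ---
    T, P, Gy = cfg.total_years, cfg.progressive_years, cfg.gamma_years
    ages = np.concatenate(
        [
            rng_mut.uniform(0, T, n_alpha_total),
            rng_mut.uniform(Gy, P, n_beta_total),
            rng_mut.uniform(0, Gy, n_gamma_total),
        ]
    )
    mass = 2.0 * vaf.sum(axis=1) * cfg.n_cells_per_field
    with np.errstate(divide="ignore"):
        sel = np.maximum(0.0, np.log(np.maximum(mass, 1.0)) / (cfg.r0 * ages) - 1.0)
    greek = np.array(
        ["alpha"] * n_alpha_total + ["beta"] * n_beta_total + ["gamma"] * n_gamma_total
    )
    mutation_truth = pd.DataFrame(
        {
            "greek_class": greek,
            "age": ages,
            "selection": sel,
            "clone_id": clone_of.to_numpy(),
            "signature": truth_cols["signature"],
            "driver": truth_cols["driver"],
        },
        index=meta.index,
    )

    # --- omics ---
    omics: dict[str, OmicsMatrix] = {}
    analyte_truth: dict[str, pd.DataFrame] = {}
    if include_omics:
        from .omics import builtin_marker_directions

        sample_groups = groups.reindex(fields)
        if cfg.protein.n_analytes > cfg.rna.n_analytes:
            raise ConfigError("protein matrix larger than the RNA gene universe")
        rna_ids = [f"G{i:05d}" for i in range(cfg.rna.n_analytes)]
        prot_ids = rna_ids[: cfg.protein.n_analytes]

        marker_dirs = builtin_marker_directions()
        rna_truth, prot_truth = _plan_monotone_sets(
            cfg, rna_ids, prot_ids, marker_dirs, rng_rna
        )
        metab_ids = [f"M{i:03d}" for i in range(cfg.metabolite.n_analytes)]
        metab_truth = _plan_platform(cfg.metabolite, metab_ids, rng_metab)
        _rename_metabolites(metab_truth)

        omics = {
            "rna": _emit_matrix(cfg, cfg.rna, rna_truth, sample_groups, rng_rna),
            "protein": _emit_matrix(cfg, cfg.protein, prot_truth, sample_groups, rng_prot),
            "metabolite": _emit_matrix(cfg, cfg.metabolite, metab_truth, sample_groups, rng_metab),
        }
        analyte_truth = {"rna": rna_truth, "protein": prot_truth, "metabolite": metab_truth}

    truth = SyntheticTruth(
        mutations=mutation_truth,
        analytes=analyte_truth,
        driver_genes=[f"DRV{i:03d}" for i in range(cfg.n_driver_genes)],
        clone_footprints=clone_footprints,
        transition_age=Gy,
        progressive_onset=P,
        config=cfg,
        seed=seed,
    )
    return OrganData(field_map, mutations, omics, truth, catalog)


# ---------------------------------------------------------------------------
# omics planting helpers
# ---------------------------------------------------------------------------


def _plan_platform(
    pc: OmicsPlatformConfig, ids: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Assign monotone direction / wave / transient labels over analyte ids."""
    n = len(ids)
    perm = rng.permutation(n)
    truth = pd.DataFrame(
        {"monotone": False, "direction": "none", "wave": 0, "transient": False},
        index=pd.Index(ids, name="analyte_id"),
    )
    up = perm[: pc.n_up]
    down = perm[pc.n_up : pc.n_up + pc.n_down]
    trans = perm[pc.n_up + pc.n_down : pc.n_up + pc.n_down + pc.n_transient]
    truth.iloc[up, truth.columns.get_loc("monotone")] = True
    truth.iloc[up, truth.columns.get_loc("direction")] = "up"
    truth.iloc[down, truth.columns.get_loc("monotone")] = True
    truth.iloc[down, truth.columns.get_loc("direction")] = "down"
    truth.iloc[trans, truth.columns.get_loc("transient")] = True
    _assign_waves(truth, up, pc.wave1_up, pc.wave2_up)
    _assign_waves(truth, down, pc.wave1_down, pc.wave2_down)
    return truth


def _assign_waves(truth: pd.DataFrame, idx: np.ndarray, w1: int, w2: int) -> None:
    col = truth.columns.get_loc("wave")
    truth.iloc[idx[:w1], col] = 1
    truth.iloc[idx[w1 : w1 + w2], col] = 2
    # remaining monotone analytes are late (first significant only in UC): wave 0


def _force_wave1(truth: pd.DataFrame, ids: Sequence[str]) -> None:
    """Move ``ids`` into wave 1, demoting same-direction wave-1 analytes to
    the late group so the planted wave counts stay exact."""
    for i in ids:
        if truth.at[i, "wave"] == 1 or not truth.at[i, "monotone"]:
            continue
        direction = truth.at[i, "direction"]
        donors = truth.index[
            (truth["wave"] == 1)
            & (truth["direction"] == direction)
            & (~truth.index.isin(ids))
        ]
        if len(donors):
            truth.at[donors[0], "wave"] = truth.at[i, "wave"]
        truth.at[i, "wave"] = 1


def _plan_monotone_sets(
    cfg: OrganConfig,
    rna_ids: list[str],
    prot_ids: list[str],
    marker_dirs: Mapping[str, str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plan RNA and protein truth with an exact planted concordant overlap.

    ``concordant_proteins`` analytes are monotone in the same direction on
    both platforms and no others are, so noiseless recovery is exact; named
    marker genes (basal keratins up, uroplakins down, OXPHOS/TCA enzymes
    down, LDHA up, ...) are drawn from the concordant pool and forced into
    wave 1 so signature scores move monotonically with stage.
    """
    rna_t = _plan_platform(cfg.rna, rna_ids, rng)
    pc = cfg.protein
    prot_index = pd.Index(prot_ids, name="analyte_id")
    rna_dir = rna_t["direction"].reindex(prot_index).fillna("none")

    n_conc = min(cfg.concordant_proteins, pc.n_up + pc.n_down)
    conc_up = min(round(n_conc * pc.n_up / max(1, pc.n_up + pc.n_down)), pc.n_up)
    conc_down = min(n_conc - conc_up, pc.n_down)
    up_shared = list(prot_index[rna_dir == "up"])
    down_shared = list(prot_index[rna_dir == "down"])
    conc_up = min(conc_up, len(up_shared))
    conc_down = min(conc_down, len(down_shared))
    chosen_up = up_shared[:conc_up]
    chosen_down = down_shared[:conc_down]
    taken = set(chosen_up) | set(chosen_down)

    # fill remaining slots only from analytes NOT monotone on RNA in the same
    # direction, so the concordant count is exactly conc_up + conc_down
    rest = list(rng.permutation([i for i in prot_ids if i not in taken]))
    rest_dir = rna_dir.reindex(pd.Index(rest))
    up_pool = [i for i in rest if rest_dir[i] != "up"]
    down_pool = [i for i in rest if rest_dir[i] != "down"]
    up = chosen_up + up_pool[: pc.n_up - conc_up]
    down = chosen_down + [i for i in down_pool if i not in set(up)][: pc.n_down - conc_down]
    occupied = set(up) | set(down)
    trans = [i for i in rest if i not in occupied][: pc.n_transient]

    prot_t = pd.DataFrame(
        {"monotone": False, "direction": "none", "wave": 0, "transient": False},
        index=prot_index,
    )
    prot_t.loc[up, "monotone"] = True
    prot_t.loc[up, "direction"] = "up"
    prot_t.loc[down, "monotone"] = True
    prot_t.loc[down, "direction"] = "down"
    prot_t.loc[trans, "transient"] = True
    prot_t.loc[up[: pc.wave1_up], "wave"] = 1
    prot_t.loc[up[pc.wave1_up : pc.wave1_up + pc.wave2_up], "wave"] = 2
    prot_t.loc[down[: pc.wave1_down], "wave"] = 1
    prot_t.loc[down[pc.wave1_down : pc.wave1_down + pc.wave2_down], "wave"] = 2

    # marker genes: rename concordant monotone analytes to field-standard names
    renames: dict[str, str] = {}
    pools = {"up": iter(chosen_up), "down": iter(chosen_down)}
    for marker, direction in marker_dirs.items():
        src = next(pools[direction], None)
        if src is not None:
            renames[src] = marker
    rna_t.rename(index=renames, inplace=True)
    prot_t.rename(index=renames, inplace=True)
    _force_wave1(rna_t, list(renames.values()))
    _force_wave1(prot_t, list(renames.values()))
    return rna_t, prot_t


_METABOLITE_MARKERS = {
    "up": ["lactate", "glycerol-3-phosphate", "betaine", "taurine", "farnesyl-PP",
           "alpha-ketoglutarate"],
    "down": ["5-CMP", "homocysteine", "cystathionine", "dCMP", "ADP", "glutamine",
             "acetylcarnitine", "carnitine"],
}


def _rename_metabolites(truth: pd.DataFrame) -> None:
    renames = {}
    for direction, names in _METABOLITE_MARKERS.items():
        pool = list(truth.index[(truth["direction"] == direction)])
        for src, name in zip(pool, names):
            renames[src] = name
    truth.rename(index=renames, inplace=True)


def _emit_matrix(
    cfg: OrganConfig,
    pc: OmicsPlatformConfig,
    truth: pd.DataFrame,
    sample_groups: pd.Series,
    rng: np.random.Generator,
) -> OmicsMatrix:
    """Materialise one abundance matrix from its planted truth."""
    ids = list(truth.index)
    n = len(ids)
    samples = list(sample_groups.index)
    ctrl_ids = [f"CTRL{i + 1}" for i in range(cfg.n_controls)]
    baseline = rng.normal(8.0, 2.0, size=n)

    group_pos = {g: i for i, g in enumerate(GROUPS)}
    wave = truth["wave"].to_numpy()
    dirn = truth["direction"].to_numpy()
    mono = truth["monotone"].to_numpy()
    trans = truth["transient"].to_numpy()
    effects = np.zeros((n, 3))
    for w, profile in ((1, cfg.effect_wave1), (2, cfg.effect_wave2), (0, cfg.effect_late)):
        for d, sign in (("up", 1.0), ("down", -1.0)):
            effects[mono & (wave == w) & (dirn == d)] = sign * np.asarray(profile)
    tsign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    effects[trans] = tsign[trans, None] * np.asarray(cfg.effect_transient)
    for g in range(3):
        truth[f"effect_{GROUPS[g]}"] = effects[:, g]

    gcol = sample_groups.map(group_pos).to_numpy()
    vals = (
        baseline[:, None]
        + effects[:, gcol]
        + rng.normal(0, cfg.noise_sigma, size=(n, len(samples)))
    )
    ctrl = baseline[:, None] + rng.normal(0, cfg.noise_sigma, size=(n, cfg.n_controls))
    mat = np.concatenate([vals, ctrl], axis=1)
    if pc.missing_fraction > 0:
        mask = rng.random(mat.shape) < pc.missing_fraction
        mat = np.where(mask, np.nan, mat)
    df = pd.DataFrame(mat, index=pd.Index(ids, name="analyte_id"),
                      columns=samples + ctrl_ids)
    return OmicsMatrix(df, tuple(ctrl_ids))
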