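# Methods

This note documents the models and procedures implemented in `fieldmap`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data experiments do and do not demonstrate.

## The setting

A whole bladder removed at cystectomy is sampled on a mapping grid into ~37
mucosal fields, each with a histologic grade — normal urothelium (NU),
low-grade or high-grade intraepithelial neoplasia (LGIN/HGIN), or invasive
urothelial carcinoma (UC). For the statistics NU and LGIN pool into a single
NU_LGIN group. Each field contributes bulk whole-exome calls (per-mutation
variant allele frequencies, VAFs), and RNA / protein / metabolite abundance
profiles referenced against control urothelium from tumor-free donors.

## Mutation classes

Mutations are classified from their spatial footprint (fields with VAF at or
above the presence threshold, default 0.01 — the display floor of whole-organ
heatmaps) and their VAF level:

* **alpha** — present in fewer than `min_cluster_fields` (default 3) fields:
  private events in the progeny of single uroprogenitors;
* **beta** — geographically expanded but with median present-field VAF below
  the clonal threshold (default 0.20): expanding clones that never dominate a
  field;
* **gamma** — expanded with median present-field VAF above 0.20: the clonal
  plaque.

The median (not the mean) guards the beta/gamma split against a clone's
low-purity edge fields. Spread bins are private / 2–10 / 11–20 / 21–30 / >30
fields. The thresholds are a deterministic surrogate for heatmap clustering;
all are exposed as parameters.

**VAF shape labels.** A per-mutation (or per-field) VAF collection is
labelled `right_skewed` when its cumulative count M(f) is linear in 1/f —
the neutral-growth expectation, under which the number of clones above
frequency f falls off as 1/f. Because *any* narrow unimodal cluster is
locally linear in 1/f, the rule additionally requires the support to span at
least a factor of two and the 1/f fit to beat a plain linear-in-f fit.
`binomial_clonal` requires a single mode in [0.15, 0.5] with dispersion
within 1.5× of binomial read sampling at the sequencing depth (default 300×,
the study design's mean coverage). `uniform` is a Kolmogorov–Smirnov
non-rejection at α = 0.05; anything else (or fewer than 8 values) is
`indeterminate`.

**Group statistics.** The 2×3 test of equal distribution across
NU_LGIN/HGIN/UC is an exact conditional Fisher test (all tables with the
observed margins enumerated when the total is ≤ 500, else seeded Monte Carlo
with ≥ 10⁵ draws). FDR control is Benjamini–Hochberg (delegated to
statsmodels; an independent step-up oracle backs it in the tests).

## Mutational signatures

SNV trinucleotide contexts are tallied over the 96 canonical motifs
(substitution-major order C>A…T>G, then 5' base, then 3' base, A<C<G<T).
Spectra are refit against a fixed reference catalog by non-negative least
squares on the normalised spectrum, with weights renormalised to sum to 1
("weight scores"). De-novo extraction is out of scope.

The bundled catalog is **synthetic** — twelve deterministic signature
profiles with signature 1 clock-like (C>T at NpCpG) and signature 6 a second
C>T-rich profile — because real COSMIC content is not redistributed. Any
catalog in the same TSV format can be substituted.

**Bootstrap significance.** Mutations are resampled with replacement B times
(default 1,000) and refit; p(signature) is the fraction of replicates in
which its weight effectively vanishes (≤ `w_min`, default 0.01), and
p < 0.005 is called significant. Replicate refits use iterative sparsity
pruning (signatures below `w_min` are dropped and the rest refit), the
standard sparse-assignment step: without it, NNLS persistently parks 1–3% of
multinomial sampling noise on specific absent signatures and their p-values
stall mid-range instead of near 1. B < 100 is refused — it cannot resolve
the 0.005 cut.

## Parsimony phylogeny of fields

Characters are binary presence calls over all silent and nonsilent mutations
(same 0.01 threshold; fields with no mutation are dropped with a warning).
The search minimises the Fitch small-parsimony score: a neighbour-joining
start from the Hamming distance matrix (scikit-bio), plus greedy stepwise-
addition starts in random leaf orders, each refined by nearest-neighbour-
interchange hill climbing; the best over `restarts` (default 10) is
returned. Scoring is vectorised over unique column patterns, which makes
the 37-leaf, ~12,800-character organ instantaneous (the organ collapses to
~45 distinct patterns). NNI (not SPR) keeps the search honest against the
exhaustive enumerator, which scores every unrooted topology for ≤ 9 leaves
and serves as the ground truth in the recovery experiments (heuristic =
exact optimum in ≥ 95 of 100 random instances; measured 97–100).

For display and timing the tree is rooted at a hypothetical mutation-free
ancestor ("node 0"), grafted onto the edge where an all-zero leaf is most
parsimonious (ties broken by lexicographic far-side leaf set). Edge lengths
are change counts under a deterministic Fitch traceback preferring the
ancestral (absent) state. `branch_clusters` cuts the k−1 edges that greedily
maximise the minimum inter-cluster Hamming distance (the δ/ε/ζ-style branch
partition); `tree_order` gives a child-order-invariant leaf sequence for
distance heatmaps.

## Mutation timing and selection

The timing model is a deliberately parsimonious surrogate for
branching-process mutation-age inference; its validation target is
parameter recovery on data generated from the matching forward model, not
numeric agreement with any particular patient.

* **Neutral clock.** Each edge of the rooted tree gets a time span
  proportional to its load of neutral mutations (default: the alpha class)
  plus a 0.5 pseudocount, and each root-to-leaf path is rescaled to the
  total history `T_total` (default 30 years — a calibration input, not an
  estimate). An edge shared by several paths is normalised against the
  heaviest path through it so nested spans stay consistent.
  `calibrate_clock` exposes per-edge spans and midpoint ages. In the
  timeline, private mutations are spread evenly along their terminal edge's
  span, largest clone (VAF) oldest — under steady accrual a field's
  residents sample its whole history, and under neutral growth older clones
  are bigger.
* **Sweep inversion for clonal mutations.** A mutation on an internal edge
  belongs to a spatially expanded clone. The clock cannot date it: a sample
  phylogeny places shared characters root-ward regardless of when the sweep
  happened, and a selected sweep is *recent*, not ancestral. Instead the
  selection coefficient is estimated from the clone's within-field dominance
  — mean present-field VAF v̄, ŝ = k·v̄/(0.5−v̄) with dominance scale
  k = 13 — and the clone origin age inverted from exponential growth,
  â = ln(m)/(r0(1+ŝ)), where m = Σ_f 2·VAF·N_field is the mutant cell mass
  (defaults r0 = 1/year, N_field = 10⁶ cells). A clone's mutations occupy
  the older half of (0, â): clone-wide hitchhikers must predate the
  expansion. With the study-scale VAF laws this dates the high-VAF plaque
  within the last ~2 years and the low-VAF expanded clones at ~2–5 years,
  matching the planted eras. k = 13 is the calibration constant of the
  matching forward model: it maps the planted beta dominance (~0.10) and
  gamma dominance (~0.35) onto their planted age windows; it is a config
  parameter.
* **Selection coefficients** reported per mutation use the inverse growth
  law ŝ = max(0, ln(m)/(r0·â) − 1), so neutral growth (m = e^{r0·â}) gives
  ŝ = 0. Only orderings (gamma > beta > alpha on average) are treated as
  meaningful; the absolute scale follows the stated r0 and N_field.
* **Dormant/progressive split.** Mutation arrival ages are modelled as a
  two-rate Poisson process; the change-point maximises the exact profile
  log-likelihood over candidates at the observed ages (at least 5 arrivals
  kept on each side). The maximised gain is a supremum statistic and is
  **not** χ²₁-distributed under a constant rate (measured ~55% exceedance of
  the 3.84 cut); `null_gain_quantile` provides the honest Monte-Carlo null
  reference for declaring a change-point significant.

Homoplastic mutations (presence not a clade) are dated on their MRCA edge
and flagged; excluding them from the change-point fit is a switch.

## Monotonic multi-omic dysregulation

Per analyte and histology group, the stage effect is the mean log2 abundance
minus the control mean. Significance versus the controls is an **exact
conditional Wilcoxon rank-sum permutation test** (mid-ranks, all C(N, n)
control assignments enumerated, vectorised per missingness pattern; normal
approximation above 2×10⁵ arrangements), BH-corrected across analytes within
each group. The exact test matters: with only 3 controls the attainable
p-floor is 2/C(n+m, 3), and scipy's exact path silently degrades to the
asymptotic formula under ties.

An analyte is **monotone** when its effect keeps one sign, never shrinks
along NU_LGIN → HGIN → UC beyond tolerance τ (default 0), and is significant
(q < 0.05) at UC. **Wave 1** analytes are already significant in NU/LGIN
(dysregulation precedes microscopic change); **wave 2** first at HGIN; late
monotone analytes carry wave 0. Missing values are excluded pairwise;
analytes quantified in under half the samples are flagged, never dropped.

A hard limit of the 3-control design, stated plainly: at the transcriptome
scale (≈20,800 genes, ≈1,300 monotone) the exact-test floor times the BH
multiplicity keeps even perfectly separated genes above q = 0.05, and losing
a single control to dropout (8% missingness ⇒ 22% of analytes) raises the
per-analyte floor past recovery. Monotone calling therefore has full power
at the proteome scale (8,475 analytes, ~30% monotone) and on complete data;
the recovery experiments are defined there, and the RNA matrix at full scale
is expected to yield few or no q < 0.05 calls under this design.

**Scores.** Signature scores are mean control-referenced z-score
differences: BLT = z(luminal) − z(basal) (negative = basal-shifted), EMT =
z(epithelial) − z(mesenchymal), energy = z(OXPHOS) − z(glycolysis), plus
immune and T-exhaustion means. The bundled marker sets are small editable
lists of field-standard genes (KRT6A/KRT14/KRT16 basal, UPK3B/FOXA1/PAX8
luminal, NDUF*/SDHB/COX5A/ATP5F1A oxidative phosphorylation, LDHA/HK2
glycolysis, …), not asserted to be any study's exact membership. ssGSEA
ranks analytes by expression and takes the signed maximum deviation between
the rank^α-weighted in-set and out-set cumulative distributions (α = 0.75).
Weighting *both* sides makes the labels exchangeable under a random set, so
the null ES is centred at zero while the statistic stays rank-based (hence
invariant to monotone transforms). Pathway enrichment is the one-sided
Fisher (hypergeometric upper-tail) test with BH across sets.

## The synthetic organ

The generator is first-class, tested code; its defaults are the study
conditions:

* 5×8 grid trimmed to 37 fields; one 3×3 UC block with a one-field HGIN
  ring (9 UC / 16 HGIN / 12 NU+LGIN) — the per-grade split is not printed
  anywhere, so these counts are a fixed realistic choice;
* 12,431 alpha (11,698 SNV / 448 ins / 285 del), 54 beta (51/1/2), 324
  gamma (315/2/7); 45 loci recurrently mutated in both alpha and gamma
  (42 SNV / 1 ins / 2 del), so the organ carries 12,809 mutations at 12,764
  distinct loci (12,022 SNV / 450 ins / 292 del);
* alpha VAFs from the neutral law f(v) ∝ 1/v² on [0.01, 0.25] (cumulative
  count linear in 1/f; inverse-CDF sampled); beta clones (default 6) grown
  by 4-neighbour contiguity over 3–20 fields with per-field VAF ~
  U(0.02, 0.18); one gamma clone covering every HGIN/UC field (≥ 21 fields)
  with per-field VAF ~ N(0.35, 0.05²) truncated to [0.2, 0.5];
* SNV contexts drawn per class from signature mixtures over the synthetic
  catalog: alpha flat, beta 50% signature 1, gamma 70% signature 1 + 30%
  signature 6 — the expanded clones carry the clock-like C>T enrichment;
* true ages (years before observation): alpha ~ U(0, 30), beta ~ U(2, 5),
  gamma ~ U(0, 2). The planted change-point recorded in the truth is the
  gamma onset (2 y): against 12,431 alpha arrivals the 54 beta mutations
  raise the arrival rate by ~4%, which no consistent detector can localise,
  so the identifiable planted break is the gamma era. The progressive-era
  onset (5 y) is recorded alongside. True selection coefficients are defined
  by the same growth inversion the estimator uses, closing the recovery
  loop;
* omics: RNA 20,795 × (37 + 3 controls) with 1,274 monotone genes (502 up /
  772 down; waves 354 = 212/142 and 54 = 3/51), proteins 8,475 with 2,504
  monotone and 8% missing-completely-at-random dropout, metabolites 91 with
  30 monotone and 5% dropout; 486 proteins planted concordant (same
  monotone direction as their mRNA); stage effects (1, 2, 3)·direction for
  wave 1, (0, 2, 3) for wave 2, (0, 0.5, 3) for late analytes, Gaussian
  noise σ = 0.5 log2 units, controls at baseline. A small transient group
  ((2, 1, 0)-profiled) exercises the caller's precision. Marker genes are
  planted on concordant wave-1 analytes so the signature scores move
  monotonically with stage.

What the generator does **not** emulate: cell-resolution spatial dynamics,
copy-number change (the "almost uniform" VAF pattern is labelled, never
interpreted), read-depth-varying VAF noise, batch structure in the omics,
or realistic gene-gene correlation. Passing recovery experiments therefore
show the estimators invert the stated forward model at the study's scale —
not that they would recover truth from an arbitrary real organ.

## Experiment sizes

The recovery experiments use 20 generator seeds (classification, timing),
100 random ≤ 8-leaf matrices against the exhaustive parsimony oracle, 100
refitting replicates at n = 2,000 SNVs with B = 1,000 bootstrap resamples,
1,000 random p-vectors / 30 contingency tables / 20 enrichment instances
against the brute-force statistics oracles, and single proteome-scale
matrices for the monotonic caller. The full default pipeline run completes
in well under a minute on one CPU.

## Known limitations

* The alpha/beta/gamma thresholds are a surrogate for the original heatmap
  clustering; fidelity is established on synthetic data only.
* The timing surrogate's absolute ages inherit the calibration inputs
  (T_total, r0, N_field, dominance scale); only the era structure and
  orderings are validated.
* The exact rank-sum test with 3 controls caps sensitivity as described
  above; nothing in the implementation can recover power the design does
  not have.
* The bundled signature catalog and marker sets are synthetic stand-ins
  with the right shape, not curated biological content.
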