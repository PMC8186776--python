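# Methods

## Problem and model

`mirstab` ranks genes of a miRNA-seq count matrix by how suitable they are
as qRT-PCR internal controls. Suitability is operationalised as a
multi-component stability score: each component measures one way a gene
can fail as a reference — pooled or per-pair fold change between tissues,
heavy high- or low-expression tails, high coefficient of variation, weak
absolute expression, or association with clinical covariates — and each is
mapped onto a common 0–100 scale before aggregation.

Expression is CPM (`counts / library size × 1e6`); library size is the
column sum unless supplied. Genes expressed below 5.9 CPM in more than 5%
of samples are removed before scoring (5.9 CPM corresponds to an average
read count of 20 at the library sizes of bulk miRNA-seq); the boundary
case of exactly 5% passes, a literal reading of "more than".

### Percentile windows

Every component restricts a value set to a percentile window (a, b):
the entries v with P_a ≤ v ≤ P_b, where percentiles use linear
interpolation on sorted values (the numpy/R type-7 default). One
convention is used everywhere; the choice matters less than its
consistency. For a window that excludes every value — possible only for
vectors of fewer than ~5 entries — the full vector is used instead, so
trimmed statistics remain defined on tiny groups.

Windows on signed per-pair log2 fold changes are taken on the signed
values: (90, 100) is the most-positive decile (over-expression outliers),
(0, 10) the most-negative (under-expression).

### Sigmoid transform

A raw value x becomes a score via

    S(x) = 100 / (1 + Sq · (max(x − IV, 0)/(IP − IV))^CS)

which is 100 for x ≤ IV (ideal value), 100/(1+Sq) at x = IP (inflection
point), and monotone decreasing beyond IV. The parameter table (IV, IP,
CS, Sq, CA, W per family) ships as editable configuration; the S_EA
(average expression) family uses IV = 1/log2(10) and IP = 1/log2(5),
i.e. penalisation starts below a trimmed mean of 10 CPM and reaches half
score at 5 CPM, aligned with the 5.9 CPM expression filter.

### Aggregation

The overall score is a weighted geometric mean over all component
instances with factors min(S_i + CA_i, 100). The constant add CA_i is a
floor: a single collapsed component (score → 0) cannot annihilate the
product. The cap at 100 keeps the score on the 0–100 scale and makes the
ideal reference gene — constant, well expressed, uncorrelated with the
clinic — an exact fixed point at 100; without the cap, CA > 0 components
would push the ideal gene to ≈103, which contradicts a score "out of
100". Each two-group instance carries its family's full weight W (so the
15 clinical-correlation slices contribute 15·W each for S_Cp and S_Cr);
an alternative normalisation by times-applied is representable through
the editable parameter table.

Fold-change ratios floor both sides at 0.5 CPM: log2(max(a, 0.5)/max(b,
0.5)). This leaves typical post-filter values untouched (a trimmed mean
of 200 vs 100 CPM gives exactly 1.0), keeps zero expression defined, and
maps two silent groups to 0. An additive pseudocount was rejected because
it biases every ratio, not only degenerate ones.

Undefined component values — correlation against a constant or
nearly-empty vector, standard deviation of fewer than 3 values, p-values
of slices with fewer than 3 complete observations — skip their instance
and remove its weight from ΣW rather than inventing a neutral score.
p-values are floored at 1e-300 before −log2. If the trimmed mean CPM is
≤ 1, S_EA's raw value is +∞ and its score 0; since S_EA has CA = 0 the
overall score then raises an error — unreachable after the expression
filter, and deliberately loud if filtering is bypassed.

### Grouping criteria

Two-group mode (tumor vs normal) instantiates the full table: paired
families use patients with both tissues (unpaired samples still join the
pooled components). Multigroup mode (tumor subtypes, metadata-driven)
removes the paired families, computes S_DP between every unordered
subgroup pair at weight W/C(k,2), applies the per-group families to each
subgroup at weight W/k, and keeps one pooled S_EA across all subgroup
samples (its slice is not otherwise determined; pooling matches its
"average expression" role). The per-family weight totals are therefore
independent of k.

### Clinical correlations

Ordinal encodings: T 1–4, N 0–3, M 0–1, stage I < IIA < IIB < IIIA <
IIIB < IIIC < IV coded 1–7 (sub-stages kept distinct), neoplasm status
tumor-free 0 / with-tumor 1; unknown or undefined labels are missing,
never zero. Three expression vectors are correlated with the five
features: (10–90)-trimmed tumor CPM, trimmed normal CPM, and the trimmed
per-pair log2 fold change — trimming removes samples (and their codes)
whose expression lies outside the window, the only reading under which
the percentile subscript affects a correlation. Normal samples and pairs
inherit the clinical annotation of the patient's tumor. Spearman uses
average-rank ties; p-values use the t approximation on n−2 degrees of
freedom for determinism and speed (exact permutation would only matter
for the smallest subgroups).

### Robust Rank Aggregation

Ranks are normalised by the universe size m; genes absent from a list
get the worst rank 1 (conservative). For sorted normalised ranks r₍₁₎ ≤
… ≤ r₍L₎, ρ = minₖ P(Beta(k, L−k+1) ≤ r₍ₖ₎) and the reported corrected
score is min(1, L·ρ), the Bonferroni bound over k. Final order is
ascending ρ with lexicographic tie-break.

### qPCR validation

Raw-Ct standard deviation (sample SD, n−1) over detected samples is the
stability measure; undetected reactions are missing, never imputed to the
cycle limit. ΔCt = Ct(target) − Ct(IC) is computed on samples where both
assays were detected (dropped samples are counted). The paired tumor vs
normal comparison defaults to the two-sided Wilcoxon signed-rank test —
robust at the 12–34 pair scale and exact without ties — with a paired
t-test available; identical vectors short-circuit to p = 1. Direction
"up" means lower ΔCt in tumor, i.e. target up-regulation relative to the
IC.

## Synthetic cohorts

The generator emulates a paired tumor/normal bulk miRNA-seq cohort with
unbalanced tumor subgroups. Defaults (all configurable in `SimConfig`):

* 200 genes × (40 paired patients + 160 tumor-only); subgroup sizes are a
  fixed largest-remainder split of the 795:39:125 ER+/Her2/TNBC imbalance
  (166/8/26 at 200 tumors) — the imbalance is part of the design, only
  patient assignment is random.
* Library sizes log-normal around 5 million reads (sdlog 0.35); baseline
  expression log10-uniform over ~1–20000 CPM.
* Counts are negative binomial with dispersion 0.2 (typical bulk
  miRNA-seq); a per-patient, per-gene log-normal effect (sd 0.4 log2)
  shared between a patient's tumor and normal sample induces the pair
  correlation that the paired fold-change components exploit.
* Planted classes: 5 *stable* genes (|log2FC| ≤ 0.05 everywhere, NB
  dispersion 0.05, patient-effect sd 0.15 — "stable" includes
  between-patient stability, well expressed at 50–5000 CPM), 45
  *unstable* genes (tumor/normal and/or subgroup log2FC of magnitude
  0.5–2, plus ±2 log2 shifts in a random 3% of samples), optional
  *clinical-linked* genes (log2 expression slope 0.3 per stage code), and
  background genes with modest random effects (sd 0.2 tumor/normal, 0.15
  per subgroup).
* Clinical codes follow breast-cohort-like frequencies, stage derived
  from T and N, ~10% missingness; normals inherit their patient's codes.
* Effect *signs* are chosen greedily so the abundance-weighted configured
  total CPM stays balanced across conditions. CPM normalisation divides
  by each sample's total, so unbalanced planted effects on abundant genes
  would otherwise leak a spurious fold change into every gene — including
  the planted stable ones — breaking the ground-truth labels the tests
  rely on. Magnitudes are drawn first and never changed; per-sample
  configured CPMs are renormalised to sum to one million.

The generator reproduces the cohort *structure* the scoring assumes; it
does not model batch effects, isoform structure, GC/length biases or
miRNA-specific sequence effects, so passing tests demonstrate correct
computation and sensible behaviour under realistic noise, not performance
on any real cohort.

The qPCR generator draws Ct = baseline + sample offset (sd 0.5, shared
across assays — the input variation ΔCt removes) − tumor shift + noise
(sd 0.4, the scale of triplicate-averaged Cts), with values beyond 37
cycles reported undetected. Internal controls are modelled as stable
(no tumor shift) or drifting (shifted like the target), reproducing the
mechanism by which a drifting IC masks real up-regulation.

## Numerical and design choices

* Deterministic ordering everywhere: scores sort descending with
  lexicographic gene-id tie-break; reruns are byte-identical.
* Ranks are ordinal (a permutation), not dense, so downstream rank
  aggregation is well defined under ties.
* All randomness flows through `numpy.random.default_rng(seed)`; one seed
  fully determines a cohort.
* The brute-force oracle used in tests (naive percentiles, direct means,
  textbook Spearman, binomial-sum beta CDF) shares no code with the
  scoring path; agreement is required to 1e-9 relative.

## Known limitations

* Scores above ~95 compress differences between very stable genes; the
  consensus ranking, not the score difference, is the intended readout.
* The t-approximation Spearman p-value is anticonservative below ~10
  samples; the smallest subgroups therefore add noise (not bias) to the
  clinical components.
* With an 8-sample subgroup (the scaled Her2-like group), the
  between-subgroup fold-change components have sampling noise of ~0.16
  log2 even for perfectly stable genes; occasional deep rank drops of a
  truly stable gene under the subtype criterion are expected at this
  cohort size and disappear at the full-cohort subgroup sizes.
* TCGA isoform ingestion sums read counts per annotated mature form;
  cross-mapped reads are counted once per file row.
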