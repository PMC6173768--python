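# Methods

This note documents the models and procedures implemented in `cnaload`, the
defaults and why they were chosen, and what the synthetic cohorts do and do
not emulate.

## Signal model and logR profiles

A tumor sample of purity ρ with c tumor copies in a genomic bin has expected
read count

    E[count] = depth · (ρ·c + (1 − ρ)·2) / 2,

where `depth` is the expected diploid per-bin count. Profiles are
median-normalized: `logR = log2(count / median positive count)`. This
assumes the diploid state is the median bin state; the synthetic arm
catalogs are therefore direction-balanced (gains ≈ losses per archetype) so
that even genomes with ~60% of bins altered keep diploid as the median. Real
aneuploid tumors can violate this (ploidy shifts), which is why the original
analyses used a purity/ploidy-aware segmenter; here purity enters only as a
signal-attenuation parameter and ploidy estimation is out of scope.

Zero-count bins are flagged missing, imputed with the profile median logR
for segmentation, and excluded from MAPD.

## QC

A sample passes iff it has **more than 1,000,000 mapped reads** and
**MAPD < 0.4**. MAPD is the mean of |logRᵢ₊₁ − logRᵢ| over adjacent
within-chromosome bin pairs (pairs touching a missing bin dropped). "Mean
absolute pair-wise deviation" is ambiguous between the adjacent-pair mean,
the classic adjacent-pair median, and all-pairs; all-pairs diverges with
scale, so the adjacent-pair mean is the default and the median variant is
available via `compute_mapd(..., stat="median")`. For i.i.d. Gaussian noise
of SD σ, E[MAPD] = 2σ/√π; this calibration is verified by simulation in the
test suite.

## Segmentation

Per-chromosome recursive binary segmentation on logR: the best split of a
segment maximizes the residual-sum-of-squares reduction
n₁n₂/n·(μ̂₁ − μ̂₂)², and a split is accepted while its gain strictly exceeds
a BIC-like threshold

    λ · log(n_chrom) · σ̂²,     λ = 2.0 by default,

with σ̂ the robust per-profile noise SD estimated from adjacent-bin
differences (median|Δ| / (0.6745·√2)). Noiseless profiles therefore split
exactly at their changepoints and constant profiles stay single segments.
On small noiseless inputs with ≤2 breakpoints, greedy binary segmentation
coincides with exhaustive minimization of RSS + threshold·k (tested against
a brute-force oracle). λ = 2.0 keeps false breakpoints rare at the default
noise level while detecting the ≥0.3-logR jumps that arm-level events
produce; it is exposed on the CLI (`--penalty`).

Segment means are discretized by the five-level table with the boundary
conventions exactly as stated: −0.1 and 0.1 inclusive to diploid, −1.3
belonging to loss, 0.9 to gain.

Copy-number load per sample: `altered_fraction` = fraction of bins in
segments with |mean logR| > 0.1; `n_breakpoints` = segments − chromosomes.

## Recurrent CNAs

Per bin and direction, the recurrence score is the canonical
frequency×amplitude sum G = Σ over samples of the amplitude beyond the
±0.1 neutral band. Significance uses a permutation null: each permutation
circularly shifts every sample's per-bin amplitude track within each
chromosome by an independent uniform offset, preserving per-sample event
number and length. Because shifts are within-chromosome, each chromosome's
bins are compared against the null distribution of **that chromosome's
maximum G** (an acrocentric arm covering ~85% of its chromosome still
leaves enough room for the shift null to be informative; events covering an
entire chromosome would not, which constrains the synthetic catalogs — see
below). Empirical p-values use the add-one rule
p = (1 + #{null ≥ G}) / (1 + n_perm), so p is never exactly 0; both
directions are pooled for Benjamini–Hochberg adjustment and regions are
reported at q < 0.25.

Significant bins are merged into maximal same-direction runs per chromosome
and trimmed to the contiguous core around the peak whose G stays within 95%
of the run maximum — flat arm-level runs survive intact, focal spikes are
tightened to their core. Regions covering >70% (strict) of either arm are
whole-arm, the rest focal. The per-sample region-level signal is the
length-weighted mean segment logR over the region's bins (the choice of
mean over peak-bin is a documented open point; the mean is robust to
single-bin noise), discretized by the same five-level table into the
samples × regions call matrix.

Whole-arm aberrations additionally enter the clustering feature space as
one feature per arm whose median per-bin signal is non-diploid in ≥25% of
samples, mirroring the two feature families (focal and whole-arm) used for
clustering.

## Consensus clustering

Each of `reps` repetitions draws ⌈0.8·n⌉ samples without replacement,
Ward-links them on Euclidean distance over the five-level codes and cuts at
k = 3; consensus(i,j) = co-cluster count / co-sample count. Final labels
come from Ward linkage on (1 − consensus). k is fixed at 3; a binary
(Jaccard-style) view of the call matrix exists but Euclidean distance on
codes is the default, since the codes carry amplitude information.
Clusters are canonicalized by ascending median altered fraction (ties:
median breakpoints, then the smaller original label), so cluster 1 is
always the most copy-number-stable group. Reclustering agreement between
two labelings is computed after Hungarian matching, with the full
cross-tabulation reported so cluster-2↔3 switching is visible.

## CIN score, threshold and classifier

CIN score = fraction of regions (focal + whole-arm features) with a
non-diploid call; CIN-high iff score ≥ 0.25 (boundary inclusive). Whether
the denominator should be recurrent regions or chromosome arms is
ambiguous; the region universe is primary here, and because the whole-arm
feature family tiles most of the genome the two readings track each other
closely.

`optimize_cin_threshold` re-derives the dichotomy from survival data: for
each grid point it fits the treatment effect within the CIN-high stratum
and picks the threshold with the strongest protective **evidence** — the
most negative Wald z of the treatment log-HR — with ties toward the smaller
threshold. The z criterion, rather than the raw log-HR, is used because the
raw estimate drifts to small, noisy, high-threshold strata; with the
z criterion the scan localizes a true dichotomy to within one grid step in
most replicates (tested).

Cluster assignment for replication cohorts is a random forest over the
region codes (500 trees, √p features per split, Gini; standard choices).
Out-of-bag permutation importance follows the classic definition: per tree,
the OOB error increase after permuting each predictor, averaged over trees
and normalized by the SD of the per-tree differences (a constant feature
gets importance exactly 0). Cross-validation is stratified 10-fold with
every sample in exactly one validation set. Replication cohorts with
missing features are imputed with training-set median codes (error if >20%
missing).

## Survival and outcome statistics

Cox models are fitted with lifelines (Efron tie handling, Wald CIs),
complete-case per model, requiring ≥10 events. Categorical covariates are
pre-encoded as dummies with fixed references: cluster 1, CIN-low, the
no-BVZ arm, mono-chemotherapy backbone. Interaction models add products of
the arm indicator with non-reference stratum dummies and report the
interaction terms; stratified effects fit the arm within each stratum
(skipped with a warning if an arm is missing or events < 10).

Two-arm power for a hazard ratio `hr`:

* Schoenfeld approximation: power = Φ(δ − z₁₋α/₂) + Φ(−δ − z₁₋α/₂) with
  δ = √(d·p(1−p))·|ln hr|, d expected events, p allocation fraction. At
  hr = 1 this returns exactly α.
* Simulation: rejection fraction of the two-sided log-rank test over
  exponential two-arm replicates; agrees with the approximation within ~2
  points at d ≥ 200 (tested). The event fraction defaults to 1.0
  (advanced-disease PFS: essentially all patients progress within the
  follow-up window).

Enrichment: two-sided Fisher exact tests per mutation/MSI/hypermutator flag
(one-vs-rest per cluster) and chi-square tests per clinical variable, with
raw p-values (no multiplicity correction, matching how such panels are
conventionally reported). Hypermutator means **more than** 10 mutations per
megabase (strict).

Xenograft series are classified by mRECIST: progression at the first
measurement ≥135% of baseline, regression if any measurement ≤50% of
baseline before progression, stable otherwise with censoring at study end;
arms are compared by the two-sided log-rank test.

## The synthetic cohort generator

The generator defines the conditions under which the pipeline is validated:

* **Genome**: 22 autosomes proportioned like the human genome, linearly
  scaled to ~2,900 bins of 100 kb (one-tenth scale) with centromere-derived
  arm boundaries, so whole-cohort analyses run in seconds to minutes; a
  full-scale layout is available via configuration.
* **Archetypes**: three catalogs of arm-level and focal events with
  per-cluster probabilities. Cluster 1 is nearly quiet (~1–3% altered);
  cluster 2 alters a 16-arm core set (p = 0.7) plus a small
  cluster-2-specific arm set; cluster 3 alters the core (0.8) plus a 16-arm
  extended set (0.75), reaching ~60–70% altered. A few focal regions are
  more frequent in clusters 1/2 than 3, so membership is not a pure
  function of load. Two structural constraints are deliberate: gains and
  losses are balanced within each archetype (median normalization validity,
  above), and high-probability same-direction events never occupy both arms
  of one chromosome (the circular-shift null would otherwise saturate and
  lose power to detect those arms). Focal catalog events sit on arms
  outside the recurrent arm sets so that peak trimming resolves focal and
  whole-arm signals as separate regions.
* **Mutations**: per-cluster Bernoulli rates reproducing the enrichment
  pattern — cluster 1 high for MSI/POLE-POLD1/BRAF/PIK3CA and hypermutator,
  low for TP53; clusters 2–3 the reverse. The mutation rate per Mb is drawn
  consistently with the hypermutator flag (uniform 12–60 vs 0.5–9 /Mb).
* **Clinical & survival**: age ~ N(63, 10), T/N/M stages mildly enriched in
  clusters 2–3 (metastatic probability 0.25/0.45/0.52 by cluster, ~45%
  overall), chemotherapy backbone mono vs doublet, BVZ arm assigned
  independently of cluster (185/409 by default; confounding can be switched
  on). PFS and OS are exponential (Weibull shape configurable, default 1 —
  constant hazards suffice because only hazard ratios are analyzed) with a
  cluster-1 reference median of 9 months, cluster prognostic HRs
  (1, 0.48, 0.57), a BVZ main effect of 1.15 in cluster 1 and interaction
  terms giving within-cluster BVZ HRs (1.15, 0.58, 0.69), small covariate
  effects, and administrative censoring at 60 months.
* **Noise**: Poisson counting noise at depth 400 reads/bin (~1.15 M mapped
  reads, inside the QC pass region) plus multiplicative log-normal logR
  noise of SD 0.12, which puts MAPD around 0.15–0.25 — a plausible FFPE
  shallow-seq regime; the true noise level of such data is not pinned down,
  so this is a free parameter of the generator.
* **Determinism**: one global seed; per-sample substreams derive from
  (seed, sample index), so identical configurations reproduce cohorts
  exactly.
* **Xenografts**: exponential (optionally logistic) growth from 250 mm³
  with per-animal rate heterogeneity, arm-specific rate multipliers
  (negative = shrinkage), twice-weekly measurements over 4 weeks, and
  multiplicative log-normal measurement noise.

What the generator does **not** emulate: GC/mappability and genomic-wave
artifacts, replication-timing structure, subclonality, allele-specific
signal, ploidy shifts, correlated event co-occurrence beyond the catalog
probabilities, informative censoring, and covariate-dependent treatment
assignment (unless enabled). Passing tests therefore demonstrate that the
pipeline's inference is correct under its stated assumptions, not that
those assumptions hold in any particular real dataset.

## Problem sizes and numerical choices

Validation runs use the scaled genome with cohorts of 300 samples
(unit/property tests) and 908 samples (end-to-end checks), 120–200
permutations for the recurrence null, and 150–200 consensus repetitions;
Cox parameter-recovery checks use 200–500 replicates at the analysis'
stated group sizes, and power simulations 2,000 replicates. Empirical
p-values use the add-one rule; BH q-values are clipped monotone;
consensus matrices are symmetrized and their diagonal fixed at 1; Cox
non-convergence raises an explicit error rather than returning estimates.

## Limitations

* Total-copy-number segmentation only; no purity/ploidy inference — logR
  amplitudes are attenuated by purity, so five-level calls near thresholds
  depend on tumor content.
* The permutation null conditions on per-sample event structure within
  chromosomes; events spanning an entire chromosome are undetectable by the
  shift null (they are still captured by the arm-level feature family).
* The ≥25% CIN rule and the 70% arm rule are applied to the scaled genome's
  region universe; on other layouts the absolute thresholds keep their
  definitions but the region universe changes.
* Survival simulation is proportional-hazards by construction, so
  model-misspecification behavior (non-PH) is untested.
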