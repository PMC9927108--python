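# Methods

This note documents the models, rules, and numerical conventions the
package implements, the design choices made where several reasonable
conventions exist, and what the synthetic benchmark does and does not
demonstrate.

## The synthetic study

`multikingdom.simulate` generates a complete case-control metagenome study
with recorded ground truth. The default `TruthConfig` encodes the study
conditions used throughout the tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| `n_oa` / `n_hc` | 44 / 46 | cohort sizes (patients vs controls) |
| `n_bact_species` / `n_fungal_species` / `n_votus` | 120 / 30 / 40 | features per kingdom, a desk-scale reduction of the thousands profiled in a real cohort |
| `frac_differential` | 0.2 | fraction of features per kingdom given a planted effect |
| `effect_size` | 8 | multiplicative fold-change of planted features in their enriched group |
| `dispersion` | 1.5 | log-scale SD of the baseline abundances |
| `age_mean/sd`, `bmi_mean/sd`, `p_female` | 60/8 yr, 24/3 kg/m², 0.5 | covariates, drawn independently of group (an age- and BMI-matched design) |
| `confound_strength` | 0 (off) | optional log-abundance loading of standardized BMI on four null bacterial features |
| `host_coupling` | off | optional: each differential vOTU's abundance tracks a same-direction differential bacterial species (shared latent factor, log-normal noise of SD 0.3) |

Baseline abundances are log-normal(0, `dispersion`) per feature and
sample — a deliberate stand-in, since abundance tables in a real study
come from read mapping and no parametric form is implied by the data; the
downstream tests are rank-based and insensitive to the marginal shape.
Planted effects are split evenly between the two groups (half enriched in
patients, half in controls). This balance is essential: abundances are
later renormalized per sample (closure), and one-sided planting would
shift every null feature systematically in the opposite direction, making
a "false discovery" criterion meaningless. The real study likewise found
enriched features in both directions.

Genomes and contigs use a uniform ACGT alphabet (GC content is not
modeled). Near-duplicate viral contigs are produced by prefix truncation
(truncated length / base length is exactly the planted coverage) and
uniform random substitutions without indels (1 − substitutions/length is
exactly the planted identity), so the identity estimator can be checked
against the truth to ±0.01. CRISPR arrays are planted as 3 exact repeat
copies (25–40 bp) separated by two unique spacers (28–40 bp); the genome
bases flanking the array are forced to differ from the spacers' boundary
bases so that maximal-extension detection recovers the planted coordinates
exactly rather than by chance extension. Protospacers are verbatim copies
of a host-genome spacer written into the base contig of a vOTU.

Predictor verdicts are drawn per tool from sensitivity/specificity
parameters, with the three tools erring independently; at
`sens = spec = 1` the triage reproduces the planted truth exactly, which
is what the recovery criteria use. Decoy (non-viral) contigs cut from the
host genomes provide the negatives.

What the generator does **not** emulate: sequencing error and read-level
simulation, assembly artifacts, phylogenetic correlation among taxa,
compositional interactions beyond closure, degenerate CRISPR repeats, and
gene-annotation noise. Passing recovery tests therefore demonstrates that
the pipeline's logic is correct under its stated rules, not that those
rules are robust to real-data noise sources the generator omits.

## Virome construction

* **Triage.** A contig is viral iff length > 5,000 bp and at least one
  predictor votes viral: viral genes > microbial genes, or a positive
  binary call, or score > 0.9 with p < 0.01 (all strict inequalities).
* **Quality gate.** Keep contigs > 10,000 bp or of Medium/High/Complete
  quality ("medium or better"; Complete passes).
* **Identity/coverage.** The shorter sequence is infix-aligned inside the
  longer (edlib, free end-gaps on the longer). Identity is matched bases
  over alignment columns. Coverage is the aligned fraction of the longer
  sequence — i.e. how much of a clustering representative the candidate
  covers; an exact 60% prefix of a contig has identity 1.0 and coverage
  0.6, and a truncated near-duplicate's coverage equals its truncation
  fraction. Inside clustering, the edit-distance search is capped at
  (1 − thr)/thr × query length, which cannot change any merge decision
  (identity ≥ thr implies distance below the cap) but makes rejecting
  unrelated pairs cheap.
* **Dereplication.** Greedy longest-first centroid clustering (the CD-HIT
  convention): contigs sorted by decreasing length (ties by id), each
  joins the first centroid with identity ≥ 0.95 and coverage ≥ 0.70, else
  founds a new vOTU. Centroid comparison only — no complete linkage — so
  similarity chains split deterministically at the centroid. The founder
  (longest member, lexicographically first id on ties) is the
  representative.
* **Family vote.** The family hit by the largest fraction of the vOTU's
  predicted genes wins if that fraction is ≥ 25% (inclusive); ties and
  all-below-threshold are "unclassified". Unannotated genes count in the
  denominator.
* **CRISPR detection.** Arrays of ≥ 2 exact repeat copies (21–48 bp)
  separated by 18–58 bp spacers, found by seeding on recurring 21-mers at
  spacer-compatible distances and extending the repeat maximally in both
  directions. Exact copies only — a simplification of the classic
  repeat-finding algorithms that is adequate for mutation-free arrays; on
  50 kb i.i.d. random sequence the false-positive rate is ≈ 0.
* **Host assignment.** A spacer hits a vOTU iff it matches the
  representative on either strand over its full length with ≤ 1
  substitution (pigeonhole search on exact spacer halves). This stands in
  for a short-read BLAST with a bit-score cutoff, which in practice
  selects the same regime of near-exact ~25–50 bp matches. The genus with
  the most hits is the primary host; zero hits or a tied maximum give
  "unassigned".

## Statistics

* Shannon is −Σ p ln p (nats) over positive entries; Simpson is the
  Gini-Simpson form 1 − Σ p² (the vegan default); diversity is compared
  between groups by Student's t.
* Rarefaction draws, for every subset size, 30 random sample subsets
  without replacement and reports the median and quartiles of the number
  of features present in the subset union.
* PCoA is classical scaling of −D²/2 with double centering; axes with
  positive eigenvalues only, variance fractions over the positive
  spectrum, no Lingoes/Cailliez correction.
* PERMANOVA uses Anderson's pseudo-F from the squared-distance partition
  and p = (1 + #{F* ≥ F}) / (1 + n_perm) with 1,000 permutations, so the
  smallest attainable p is 1/1001. The test is one-factor and unadjusted.
* Differential abundance is a per-feature two-sided Wilcoxon rank-sum
  test using the normal approximation with tie correction and no
  continuity correction (cohort sizes ~45 per group make exact
  enumeration unnecessary); a feature constant across all samples gets
  p = 1. BH adjustment is applied separately per feature family
  (bacteria, fungi, vOTUs, pathways, KOs), mirroring separately reported
  q-value sets; significance is q < 0.05 except vOTUs at q < 0.01. The
  enriched group is the one with the higher mean relative abundance,
  reported only below the q threshold.
* KO frequency between the two enriched vOTU sets uses the same rank-sum
  + BH machinery on 0/1 presence indicators.

## Network

Partial Spearman correlation residualizes the rank-transformed feature
vectors on the rank-transformed covariates (age, sex encoded 0/1, BMI) by
least squares with an intercept and correlates the residuals. With no
covariates this is exactly Spearman's rho. Edges keep |rho| > 0.6
(strict). Fungal features participate in the computation; their exclusion
is never hard-coded. A vOTU with ≥ 1 retained edge to a bacterial species
is bacterium-dependent, otherwise bacterium-independent.

Known limitation: rank residualization removes monotone confounding only
approximately, and when the covariate explains most of both features'
variance the residual vectors are small, so the residual-correlation
estimator is noisy — at n = 90 and ~90% shared variance individual
adjusted values occasionally reach ~0.3 even though their median is near
zero. At the confounding the generator's knob injects (~80% shared
variance at the default dispersion) the adjusted correlation stays far
below the 0.6 edge threshold, which is what the network criterion checks.

## Classification

A bagged random forest (1,000 trees, √p features per split). Out-of-sample
scores come from out-of-bag class votes by default — native to bagging and
requiring no extra fitting — with stratified 5-fold cross-validation
available (`scheme="cv5"`); the report records which scheme produced the
AUC, and no single choice is presented as canonical. AUC is the
Mann-Whitney rank statistic P(score⁺ > score⁻) + ½P(tie). The 95% CI is a
percentile bootstrap (2,000 resamples) stratified by class so every
resample contains both classes. Importances are mean impurity decrease,
sorted descending.

## Problem sizes and determinism

The acceptance suite runs the clustering oracle on 200 contigs of ~5 kb
against a numba-jitted exact Smith-Waterman oracle, PERMANOVA calibration
on 500 null simulations of 40 samples, CI coverage on 200 repetitions of
2,000-resample bootstraps, and recovery/null screens over 20 seeds —
sizes chosen so each suite completes in minutes on one CPU while keeping
the Monte-Carlo error well inside the asserted tolerances. All randomness
flows through explicit integer seeds (`numpy.random.default_rng`);
identical seeds give byte-identical synthetic outputs and identical
statistical reports.
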