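# Methods

This note documents the models, conventions and numerical choices behind
`mifspatial`, and what its synthetic validation does and does not show
about real data.

## Data model and scope

The pipeline starts from per-cell tables as exported by mIF image-analysis
software (Inform/phenoptr-style): one row per segmented cell with 2-D
nucleus coordinates (µm), tumor/stroma compartment, and boolean marker
calls. Everything upstream — spectral unmixing, tissue and cell
segmentation, intensity thresholding — is out of scope; marker positivity
is taken as given. Coordinates are per-core with an arbitrary origin; all
statistics are translation- and rotation-invariant, so no registration is
needed.

The analysis unit is the *tissue site*: one 1-mm TMA core keyed by
patient × region (invasive margin IM / tumor center TC) × core index ×
staining panel. With two stained panels on serial sections there is no
cell-level correspondence between panels, so panels are treated as
independent sites and **no cross-panel distance is ever computed on real
data**. The synthetic generator instead emits a single `combined` panel
(all 11 markers on one site), which is the only self-consistent way to
exercise CD8-to-CD4/CMV/CAF nearest-neighbor analyses end to end.

## Phenotype gating

Gating is an ordered rule list (first match wins, fallback `other`), which
makes the leaf labels a partition of the cells by construction — verified
exhaustively over all 2^k marker combinations per panel. Precedence
choices, fixed so that composition plots are mutually exclusive:

- pan-CK dominates all stromal/immune markers (epithelial identity wins);
- within CD8+ T cells, Tim3 (terminal dysfunction) dominates PD-1/CD103
  (predysfunction); the predysfunctional gate accepts *either* PD-1 or
  CD103 — a scheme file can tighten this to the conjunction;
- CD31 (endothelium) dominates αSMA (fibroblast), so αSMA+ pericyte-like
  cells on vessels count as microvessel;
- CD4 rules precede CD31/αSMA (lymphocyte lineage markers are the more
  specific call for rare double-positives).

Aggregate populations (`CD8_Ttotal`, `CD4_Ttotal`, `cancer`) are named
unions of leaf labels, so subset counts nest by construction. GZMB is
carried as an annotation flag only; no gate uses it. Compartment is
retained per cell but unused by the default gates.

## Spatial statistics

For phenotype A, cancer cells C, radius r, within one site:

- **density(A)** = 1000 · n(A)/n(total), where the denominator counts every
  segmented cell including `other`;
- **mNND(A−B)** = Σᵢ d_min(Aᵢ−B)/n(A) with Euclidean nucleus-to-nucleus
  distances; when A and B overlap, a cell is excluded from its own
  neighbor search *by identity, not by zero distance*, so coincident
  distinct nuclei remain valid neighbors;
- **CCPS(A)** = Σᵢ n(Cᵢ →r A)/n(C) with a **closed** ball (d ≤ r counts —
  fixed for bit-reproducibility); a cancer cell that is itself A-labelled
  never counts itself.

Numerics: neighbor queries use `scipy.spatial.cKDTree`; the test suite
checks them against an O(n²) brute-force oracle — distances are identical
doubles, and means agree to 1e-12 relative (floating-point summation
order is the only difference). Undefined values (no source cells, no
cancer cells, empty site) are NaN and propagate as missing; they are never
imputed as zero. No edge correction is applied at the core boundary; cells
near the rim have positively biased NNDs and truncated proximity balls
(≈1% on CCPS at r = 30 µm on a 1-mm core), a bias shared with conventional
TMA practice and common to all groups being compared.

**Aggregation** to patient × region pools numerators and denominators
across cores (Σ counts / Σ totals; Σ distance sums / Σ source counts).
Coordinates are never pooled: cores are disjoint pieces of tissue and
cross-core "neighbors" would be artifacts. A core where a metric is
undefined contributes nothing; a patient-region with no analyzable core is
missing.

**Population inclusion.** A phenotype enters cohort analysis in a region
only if its cohort-median patient-level density is ≥ 5 ‰ (inclusive
boundary). Applying the rule at cohort-median level (rather than per site
or per patient) keeps the analyzed population set identical across
patients; the threshold and its scope are configurable.

## Cohort statistics

- Mann-Whitney U, two-sided; exact enumeration when both groups have ≤ 20
  observations, tie-corrected normal approximation otherwise.
- Wilcoxon signed-rank for IM vs TC, pairs incomplete on either side
  excluded, zero differences dropped; an all-zero configuration is an
  error rather than p = 1.
- Logistic (LNM) and Cox (RFS) models: the exposure term is locked;
  adjustment covariates are removed by backward elimination while their
  Wald p exceeds 0.05 (the stay threshold is a parameter). Adjustment sets
  follow oncology-cohort convention: age dichotomized at 60 years, gender,
  histology (LUSC vs LUAD; other histologies drop out listwise), tumor
  diameter at 3 cm, plus node status for survival models. Variance
  inflation factors are reported per term and flagged at VIF ≥ 10
  (tolerance ≤ 0.1). Complete separation yields a structured
  non-converged result, not an exception. Exposures default to a
  cohort-median split; continuous exposures and explicit cutpoints are
  options.
- Survival stratification replaces interactive cutpoint software with the
  closest published-method equivalent: the cutpoint maximizing the
  two-group log-rank statistic over all splits that keep ≥ 10% of patients
  per group, with a permutation p-value (default 1000 permutations of the
  marker values) that accounts for the maximal selection. The log-rank
  statistic is computed by a vectorized implementation (validated against
  `lifelines.statistics.logrank_test` to 1e-8) because the search
  evaluates it tens of thousands of times.
- Spearman correlations use pairwise listwise deletion (≥ 3 complete
  pairs), with tiers * 0.01 ≤ p < 0.05, ** 0.001 ≤ p < 0.01, *** p < 0.001;
  constant vectors give an undefined, flagged entry.
- The hypoxia contrast scores each site's mean CMV (or CAF) count within
  r of hypoxic (pan-CK+/Hif-1α+) versus normoxic cancer cells and compares
  the per-site scores with the Mann-Whitney U test; sites lacking either
  subpopulation are dropped.

## Synthetic cohorts

The generator emulates the sampling design of a 279-patient NSCLC TMA
study: 1-mm discs, two cores per patient × region, lymph-node prevalence
0.308, clinical marginals near the published cohort (65% male, 64%
adenocarcinoma, median age ≈ 62). Structure per core:

- cancer cells: Thomas cluster process (Poisson-mean 8 nest centers,
  Gaussian spread σ = 60 µm) — nests, not CSR;
- immune/stromal phenotypes: homogeneous Poisson at per-region,
  per-stratum intensities; defaults give ~1500–1700 cells per core with
  the qualitative contrasts the pipeline should detect (CD8 subsets and
  microvessels enriched in IM, fibroblasts in TC; node-positive patients
  with fewer predysfunctional CD8 in TC and more dysfunctional CD8 in IM);
- pairwise couplings: *attraction* adds Poisson(strength × n_source)
  target points Gaussian-scattered around sources; *repulsion* deletes
  target points with probability strength · exp(−d²/2s²) to the nearest
  source;
- the *barrier* places a configurable share of fibroblasts in an annulus
  around nest centers and deletes CD8 (not CD4) cells within the nest +
  annulus reach with a per-patient thinning probability. In the
  barrier-recovery scenario a patient-level strength b ~ U(0,1) jointly
  scales fibroblast abundance (0.25 + 1.5b), CD8 thinning (0.8b) and mild
  CD4 recruitment (1 + 0.8b); the CD4 coupling reflects the observed
  positive fibroblast-CD4 association in immune-excluded tumors and makes
  the "CD4 non-negative" arm of the sign pattern a property of the
  generator rather than a coin flip;
- marker flags are synthesized to be consistent with the default scheme
  (with realistic randomization of non-defining markers), so gating
  recovers the generating labels with 100% agreement;
- survival is exponential proportional hazards (baseline 1/1500 per day,
  default log-HR on node status) with independent uniform censoring — the
  simplest model satisfying the Cox assumptions;
- all randomness flows through one PCG64 generator; a fixed seed is
  bit-reproducible.

Points falling outside the disc (cluster offspring, annulus cells) are
projected radially back inside; this slightly concentrates mass at the rim
for strongly clustered configurations but leaves pure-Poisson
configurations untouched (they pass a quadrat variance/mean dispersion
check).

The clinical-layer simulator (`simulate_association_cohort`) skips point
patterns entirely: it draws dichotomized covariates at study-like
marginals and injects a known odds ratio on LNM and/or hazard ratio on
RFS. Parameter-recovery validation runs there because coverage of a CI is
a property of the model layer, not of the point patterns; problem sizes
(200 cohorts of 300 patients) were chosen to give binomially stable
coverage estimates at interactive runtimes.

**What passing tests do not show.** The generator does not simulate
staining noise, segmentation error, marker spillover, panel
misregistration, irregular core shapes, missing cores, or within-patient
correlation beyond the shared intensities — so synthetic validation
demonstrates correctness of the computations and recoverability of
injected effects, not robustness to imaging artifacts. Published effect
estimates from real cohorts (e.g. OR ≈ 5.8 for dysfunctional CD8 density)
appear here only as *injected ground truth* for recovery tests; the
package makes no claim to reproduce any specific cohort's estimates.

## Validation problem sizes

The acceptance harness (`scripts/acceptance.py`, mirrored by
`tests/test_acceptance.py`) uses: 100 random sites (≤ 500 cells) for
oracle equivalence; 20 replicates of CSR at λ = 10⁻³/µm² on a 2000 × 2000
µm window for the closed forms 1/(2√λ) ≈ 15.81 µm and λπr² ≈ 2.827 (3%
tolerance covers Monte-Carlo noise plus the ~1% uncorrected edge bias);
200 cohorts × 300 patients for CI coverage (≥ 90% at nominal 95%); 100
barrier cohorts × 30 patients for the sign pattern (≥ 95% success); and
exhaustive marker-combination enumeration for the partition checks.
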