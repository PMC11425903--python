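# Methods

This note records the models, conventions and numerical choices behind
`microstab`, and what the synthetic cohorts do and do not establish.

## Study design assumed

Nine subjects sampled at ordered timepoints S1 (pre-intervention
baseline), S2–S5 (sterile diet), S6–S9 (normal diet), plus one healthy
family member per subject sampled once (F). Phases are a function of the
timepoint and are validated on input. A handful of samples may be missing;
the generator emulates this with random dropout of patient samples
(baseline and family kept), yielding roughly 83 of 90 samples.

## Diversity and stability

* **Shannon** is reported in nats (natural log), the convention of the R
  `vegan` ecosystem. **Chao1** is the bias-corrected estimator
  S_obs + F1(F1−1)/(2(F2+1)); it requires integer (rarefied) counts and
  rejects relative abundances, where singletons are undefined.
* **Rarefaction** subsamples each sample without replacement
  (multivariate hypergeometric), drops samples below the requested depth
  rather than padding them, and preserves the zero pattern. The default
  depth is the minimum column sum among samples above a floor of 1000
  reads; the published analyses this mirrors do not state their depth, so
  it is exposed as configuration.
* **AVD** (average variation degree) for a group of k samples:
  the grand sum of |x_ij − x̄_i|/δ_i over samples j and OTUs i, divided by
  k × n, with x̄_i and δ_i the *within-group* mean and sample standard
  deviation (ddof = 1, configurable) of OTU i and n counting only OTUs
  with δ_i > 0 (zero-dispersion OTUs carry no information and would
  divide by zero). The index is invariant to global rescaling, so rarefied
  counts and relative abundances give the same value; rarefied counts are
  the documented input. A group whose samples are all identical reports
  AVD 0 with a warning.

  A property worth knowing: per OTU, mean|deviation|/sd is a *shape*
  statistic. It is near 1 for balanced two-state (present/absent or
  high/low) patterns with tight states, ≈0.80 for Gaussian spread, and
  falls towards 0.6 for heavy-tailed or single-outlier patterns. Group
  AVD therefore ranks groups by how bimodal-and-tight their per-OTU
  cross-sample patterns are — which is what separates a cohort of
  divergently collapsing patients from a set of independent healthy
  adults (heavy between-person spread). Added independent noise moves a
  group *towards* the Gaussian level from either side, not monotonically
  up, which is why the test suite asserts the shape ordering rather than
  a noise-monotonicity claim.
* **PERMANOVA** partitions squared Bray–Curtis dissimilarities into
  among/within sums of squares; p-values come from label permutations
  with p = (1 + #{F* ≥ F}) / (n_perm + 1), seeded. **PCoA** is classical
  scaling of the double-centred squared-dissimilarity matrix; negative
  eigenvalues are reported, positive-eigenvalue axes retained.
* **Rank-sum tests** use exact enumeration when the combined sample is
  ≤ 20 and untied, and the tie-corrected normal approximation otherwise.

## RMT network construction

Per sample group: taxa present in ≥ 50% of the group's samples are kept
and log10-transformed. Zeros are handled by mode:

* `missing` — zeros become NaN and correlations are pairwise-complete,
  with pairs below half the group's sample count (min 4 complete
  observations) set to r = 0;
* `pseudocount` — zeros are replaced by half the smallest positive count
  before the log, so every pair uses all samples;
* `auto` (default) — `missing` for ≥ 30 samples, `pseudocount` below.

The adaptive default exists because pairwise-complete estimation with few
samples zeroes many pairs, pre-sparsifying the correlation matrix; the
spacing statistics of such a matrix look Poisson at low thresholds and
the transition scan mis-fires. Zero replacement (the convention of the
standard network platforms) keeps the low-threshold regime noise-like.
With ≥ 30 samples pairwise-complete is the stricter and preferred option,
since pseudocounted shared absences otherwise manufacture positive
correlation.

The threshold scan proceeds in steps of 0.01 from max(0.30, 2/√(n_obs−1))
— correlations below about two null standard errors cannot be separated
from sampling noise — to 0.99. At each candidate s the matrix is
hard-thresholded (|r| < s zeroed, diagonal kept), taxa with no remaining
off-diagonal entry are dropped, and if ≥ 30 taxa remain the spectrum is
computed and unfolded: numerically degenerate eigenvalues are collapsed,
and the cumulative spectral density is fitted by a monotone PCHIP
interpolant through ~m/8 quantile knots (4–20); eigenvalues mapped
through the fit have unit mean spacing. Both reference laws — Poisson
e^{−d} and the Wigner surmise (πd/2)e^{−πd²/4} — are tested by χ² with
⌈√#spacings⌉ equal-probability bins. A step qualifies when Poisson is not
rejected (p > 0.05) *and* fits better than the Wigner surmise; the
threshold is the first of two consecutive qualifying steps. A formal GOE
rejection is deliberately not required: at the 30–70 spacings these
matrices yield, the χ² test rarely has the power to reject GOE even when
Poisson clearly fits better, and demanding it makes the scan fail on
exactly the small groups the design produces. If no step qualifies the
scan raises an error recommending a wider range — never a silent default.
All knobs (scan range, step, bin rule, knot count, consecutive-step
count) are arguments, and every step's p-values are returned for audit.

Networks connect taxa with |r| ≥ threshold; edges carry the correlation
sign and |r| as weight; isolated nodes are removed. The topology record
reports n, L, avgK = 2L/n (an exact identity), sign-blind mean local
clustering, mean shortest-path distance pooled over connected pairs
within components, Freeman degree centralization Σ(k_max − k_i)/((n−1)(n−2)),
and the positive-edge fraction. Small-world σ = (C/C_rand)/(GD/GD_rand)
against ≥ 10 Erdős–Rényi graphs matched to the largest component's n and
L (degree-preserving rewiring is a possible alternative null; the matched
G(n, L) ensemble is the convention this σ formula assumes). Robustness:
remove ⌊n/2⌋ random nodes, report the mean proportion of survivors that
keep at least one edge. Vulnerability: max over nodes of the relative
global-efficiency loss when that node is deleted. Module detection is
greedy modularity maximization (deterministic; module IDs ordered by each
community's smallest node label); Zi/Pi follow the standard definitions
with sd = 0 mapped to Zi = 0, and roles use the 2.5 / 0.62 grid.

For the collapse comparison the baseline network pools S1 with the family
samples and the sterile-endpoint network pools S4 with S5 — single
timepoints (9 samples) cannot support a stable correlation estimate, and
the published analyses likewise drop or merge low-sample groups. If the
sterile scan finds no transition the pool widens to S3–S5.

## Cohesion

Computed on relative abundances over all taxa (not the network-filtered
subset — both are supported). Observed pairwise Pearson correlations are
corrected by subtracting the mean over 200 taxa-shuffle null iterations
(each taxon's abundances permuted across samples, cross-correlated
against the observed matrix, symmetrised). Pairs with fewer than 3
co-nonzero samples and zero-variance taxa get corrected r = 0. Per taxon,
positive (negative) connectedness is the mean of its positive (negative)
corrected correlations; per sample, C_pos and C_neg are the
abundance-weighted sums, so C_pos ≥ 0 ≥ C_neg and both are bounded by the
extreme connectedness values.

## Association

Spearman screens run all pairs between two feature tables (typically the
top-30 most abundant taxa, ranked by mean relative abundance with
lexicographic tie-breaks, against the six SCFAs), with
Benjamini–Hochberg correction across the whole screen; complete data use
a vectorized rank-correlation path with the t approximation, incomplete
data fall back to pairwise-complete with a 4-observation floor. The
Mantel test correlates off-diagonal entries of two distance matrices with
a joint row/column permutation p-value (two-sided, seeded). Phase changes
of a taxon are reported in percentage points by default, with a fold mode
available, because "up by X%" is ambiguous between the two readings; the
mode is always explicit in output.

## The synthetic cohort generator

Counts are compositional: per-taxon log-weights are built, exponentiated,
normalised, and drawn as a multinomial at a lognormal per-sample depth
(mean 20 000, log-sd 0.25). The ingredients, with defaults:

* **Baseline profile.** Per-taxon log-mean abundances ~ N(0, 1.5²);
  per-taxon occupancy ~ Beta(8, 2) and each person (subject or family
  member) carries a taxon with that probability — person-specific gut
  membership. Beneficial taxa are pinned near the 90th abundance
  percentile and carried by everyone (core commensals).
* **Between-person spread.** Every person has a persistent log-abundance
  offset with sd 1.8, module-structured so that it carries the planted
  correlations. Patients' offsets are scaled by 0.25: hospitalized
  subjects share one standardized diet and environment, family members
  live in different households. This is the channel that makes the family
  group's per-OTU patterns heavy-tailed (lower AVD) while patient groups
  stay comparatively tight.
* **Planted modules.** 5 blocks of n_taxa/10 taxa; taxon i in module m
  has loading a_i with a_i² uniform in module_rho ± 0.15 (default 0.8),
  so within-module latent correlations a_i·a_j are heterogeneous and
  rankable; one latent Gaussian factor per module per sample plus the
  person-level module factor.
* **Collapse.** A schedule c(t) ramps 0 → 1 over S2–S5 and decays through
  S6–S9; every channel scales with intensity = collapse_severity × c(t),
  so severity 0 is a true null cohort. Each subject's intensity follows
  c(t)^rate with a lognormal (sd 0.7) per-subject rate — subjects collapse
  at different speeds and converge at the endpoint. Channels: (i) the
  baseline weight profile is raised to a power γ(intensity) calibrated by
  root-finding so the expected Shannon drops by the given fraction;
  (ii) each subject loses a nested random subset of taxa (probability =
  intensity, 70% of the loss order shared taxon vulnerability, 30%
  subject-specific chance) — losses are structural zeros; (iii) bloom
  taxa capture a community share 0.67 × intensity (lognormal subject
  noise, sd 0.3, capped at 0.9), split by a Dirichlet draw;
  (iv) beneficial taxa lose 4 log-units × intensity; (v) patients'
  person offsets and biological noise shrink mildly (× (1 − 0.3·intensity)),
  the shared-regime homogenization seen as convergence at the sterile
  endpoint.
* **Family samples** use baseline parameters with within-person noise
  scaled by 0.6 and no collapse channels.
* **SCFAs** are linear in the summed relative abundance of the beneficial
  (producer) taxa plus a 20% baseline term and 10% Gaussian measurement
  noise, clipped at 0; concentrations are in µg/g with realistic base
  levels (acetic 3000 down to valeric 120). Only ~70% of retained samples
  carry SCFA measurements, mirroring incomplete measurement coverage.

**What the generator does not emulate:** sequencing error and chimeras,
phylogenetic structure (so no UniFrac), taxon-specific overdispersion
beyond the lognormal, true ecological dynamics (interactions are static
latent factors, not Lotka–Volterra), and realistic family α-diversity —
the heavy person offsets that give the family group its between-person
spread also bias its per-sample evenness low, so simulated family Shannon
sits below patient baseline rather than at it. Passing tests on these
cohorts show the pipeline recovers planted compositional, correlation and
stability structure at realistic sample sizes; they do not certify
behaviour under real sequencing artefacts.

**Calibration stance.** Generator defaults were chosen once, by pilot
simulation, to place the synthetic cohorts in the regime the assumed
study design describes (Shannon ≈ 4 at baseline collapsing by ~60%,
pathogen blooms of tens of percent, networks of one-to-few hundred nodes
at thresholds 0.6–0.9, sterile-phase AVD above family); the validation
suite was frozen afterwards and the defaults not revisited.

## Problem sizes in the validation suite

Statistical calibration uses 1000 null replicates (PERMANOVA with 199
permutations on 12 samples; rank-sum on 10 + 10) and 500 null Spearman
screens of 30 × 6 features; planted-edge recovery averages 10 cohorts of
100 taxa × 60 samples; the collapse signature runs on one full default
cohort. These sizes give the tests stable outcomes while keeping the
whole suite around half a minute.

## Known limitations

* The NNSD χ² tests are noisy below ~40 spacings; the consecutive-step
  rule and the noise-floor scan start mitigate but do not eliminate
  occasional missed transitions on very small groups (the scan then
  errors and the caller widens the pool).
* Pi's theoretical ceiling 1 − 1/k (k modules touched) is not separately
  enforced; values are validated to lie in [0, 1).
* The Wigner surmise is itself an approximation to the exact GOE spacing
  law (~2% error), detectable as spurious GOE rejection beyond ~400
  spacings; matrices here are far smaller.
* Cohesion's taxa-shuffle null corrects prevalence and compositional
  artefacts only in expectation; strongly structured zero patterns can
  leave residual bias in corrected correlations.
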