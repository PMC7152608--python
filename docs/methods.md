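# Methods

This note records the statistical models implemented in `seedcourse`,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the known limitations a user
should weigh before trusting a result.

## Study design and data model

The package targets a factorial developmental time course over a
diversity panel: `n_lines` inbred lines × an ordered set of
days-after-anthesis (DAA) sampling points × locations × replicates
(defaults 22 × {8, 13, 18, 23, 28, 33} × 2 × 2 = 528 potential samples,
with a default missing fraction of 109/528 emulating field attrition).
Expression is 3′-tag RNA-seq, so one count per transcript per sample
and no transcript-length correction anywhere.

Counts are modelled as negative binomial:
`count(t, s) ~ NB(mean = sf_s · μ_{t,s}, dispersion α_t)` with
`Var = μ + α μ²`. Size factors `sf_s` are median-of-ratios estimators
over transcripts with positive counts in every sample, rescaled to
geometric mean one. Variance stabilization is the shifted log,
`log2(count/sf + 1)`: downstream stages consume the matrix only through
variance ranking, linear models and PCA, for which a shifted log of
depth-normalized counts is an accepted stabilizer; a dispersion-trend
VST would change nothing structural downstream.

## QC path

* Sample filter: column sum ≥ `min_mapped` (default 500 000 for real
  data; pipeline runs on simulated matrices auto-scale the threshold by
  transcript count, ≈ 8.4 reads per transcript, so the same per-transcript
  depth standard applies at any simulation size).
* Transcript filter: ≥ `min_count` (2) counts in ≥ `min_samples` (10)
  samples. The alternative literal reading — *remove* transcripts with
  fewer than 2 counts in at least 10 samples — is available behind
  `literal_removal=True`; the retained-expression reading is standard
  practice and is the default.
* Sample PCA: top 500 transcripts by variance, centered (not scaled)
  per transcript.
* Outlier-cluster removal: 2-means on PCs 1–2. A split is accepted only
  when (a) the minor group holds ≥ 5% of samples and (b) the 2-means
  partition reaches mean silhouette ≥ 0.65. The silhouette criterion is
  essential: 2-means happily halves a *continuous* developmental
  gradient (silhouette ≈ 0.56–0.61 in our simulations, and ≈ 0.6 for a
  pure 1-D gradient), whereas two genuinely distinct sample clusters
  score ≥ ~0.7. Without it the QC stage silently cut simulated time
  courses in half. Differential expression uses the major cluster only;
  lsmean/heritability analyses keep all QC-passing samples.

## Differential expression

Per transcript, an NB GLM with log link and log-size-factor offset,
fitted by IRLS (convergence: max coefficient change < 1e-8, cap 100
iterations; linear predictor clipped to ±30 for overflow safety;
non-converged fits propagate missing p-values).

Dispersion: per-transcript method-of-moments from within-cell residual
variance of normalized counts (cells = genotype × time), clipped to
[1e-8, 10], then shrunk toward a gamma-GLM trend `α ≈ a₀ + a₁/μ` by a
weight-0.5 geometric mean. This keeps the mean–dispersion structure
that drives test calibration while skipping the full empirical-Bayes
apparatus of dedicated packages; there is no outlier-count treatment
(no Cook's-distance step) and no shrunken fold changes.

Tests:

* Interaction screen: LRT of `~ genotype + time + genotype:time` vs
  `~ genotype + time`, χ² with (G−1)(T−1) df, BH across transcripts,
  flagged at FDR 0.1 and removed before pattern coding (a transcript
  whose temporal shape depends on genotype has no single panel-level
  pattern).
* Adjacent contrasts: Wald test on the difference of consecutive
  time-level coefficients in `~ genotype + time`; sign of log2FC is
  later minus earlier; BH within each interval (one family per
  contrast). On 2000-transcript null simulations the per-interval
  BH-significant fraction is ≪ 0.05 and raw p-values are slightly
  conservative (≈ 0.033 below 0.05), so FDR control holds.

## Temporal pattern coding

Character i of a DET's code is `u`/`d` if interval i is BH-significant
at α = 0.05 with positive/negative log2FC, else `0`; all-zero codes are
excluded from the DET universe. 3ᵏ possible codes for k intervals
(243 for the six-point course). Statistics: distinct-pattern count,
top-k mass (default k = 20), monotone fraction (non-zero characters all
identical), and the down-then-up share among direction reversers.
Pattern ranking breaks count ties lexicographically. The permutation
null shuffles each interval's column independently across transcripts
(n_perm default 1000) — marginals preserved exactly, inter-interval
dependence destroyed; codes that become all-zero drop out of that
permutation's universe, mirroring the observed universe's definition.
Summaries report null min/max/mean and add-one-smoothed empirical tail
probabilities, because the interesting observations sit beyond the null
extrema.

## Latent adjustment, lsmeans, GCoE subclustering

One latent factor is estimated as PC1 of the residuals after projecting
each transcript on the known design (Line, Location,
Replication-within-Location, Time) — the leading surrogate variable
under the standard latent-factor model. Because that PC lives in the
orthogonal complement of the design space, removing its fitted
contribution cannot alter design effects. The factor count is fixed at
one.

Least-squares means: per transcript, OLS on
`~ Line + Location + Location/Replication + Time` (treatment coding,
nested replicate dummies); a line's lsmean is its prediction averaged
with equal weight over all observed levels of the other factors. On a
balanced design this reduces exactly to the line's sample mean. Fits
use the pseudo-inverse, so unbalanced data with empty cells degrade
gracefully (minimum-norm solution).

Subclustering: transcripts of one TCoE set, represented by per-line
lsmean profiles standardized per transcript (center + scale, so shape
matters rather than magnitude), Euclidean distance, Ward linkage
(compact, size-balanced clusters — the cluster-size test assumes
comparable size vectors). Eigengene: PC1 over lines × member
transcripts (centered only), sign fixed so the score correlates
positively with the mean member profile.

Cluster-count selection follows the rule "heritabilities of all
subclusters relatively high and with low variation", codified as
`score(k) = median(h²) − λ·IQR(h²)` with λ = 1 over k = 4…20; scores
within 0.01 of the best tie and go to the smallest k, so featureless
data default to the low end. **Known limitation (verified analytically
and by simulation):** this score cannot recover a planted module count.
Any linear combination of equally K-structured module signals is itself
K-structured, so a merged pair of equally heritable modules yields an
equally heritable — indeed less noisy — eigengene, and an h²-only score
never penalizes merging; moreover the REML h² of a single realized
module signal at 22 lines is noisy enough (a true-0.9 module can
estimate at 0) that selection among a handful of such values is
noise-dominated. A variance-explained-weighted variant was tried and
did not rescue recovery, so the simple rule was kept. Treat the chosen
k as a reasonable partition granularity, not as an estimate of a true
module count.

## Heritability

`estimate_h2` fits `y = μ + u + e`, `u ~ N(0, K σ²ᵤ)`, `e ~ N(0, I σ²ₑ)`
by REML, profiling the ratio λ = σ²ᵤ/σ²ₑ in the eigenbasis of K: grid of
121 log-spaced points on [1e-6, 1e6] plus bounded scalar refinement
(xatol 1e-10 in log₁₀ space). The LRT against λ = 0 uses the
0.5·χ²₀ + 0.5·χ²₁ boundary mixture (plain χ²₁ behind
`boundary_mixture=False`); likelihood improvements below 1e-8 collapse
to the boundary, so exactly-flat surfaces resolve deterministically to
h² = 0. Singular K (any marker-centered GRM has rank ≤ n−1) gets a
1e-6 spectral ridge with a warning. The implementation agrees with a
dense-matrix REML oracle to < 1e-4 in h² on random instances.

Two structural facts shape every heritability experiment here:

* **K = I is unidentifiable.** With one observation per line the
  restricted likelihood depends on (λ, σ²ₑ) only through σ²ₑ(λ+1) — the
  surface is exactly flat. A GRM built from *m* independent markers has
  spectrum collapsing toward 1 at width ≈ 2√(n/m), so thousands of
  independent simulated markers reproduce this degeneracy and single-trait
  h² estimates pile onto the 0/1 boundaries. Real panels escape through
  linkage disequilibrium: what matters is the *effective* number of
  independent loci, typically a few hundred at most. The generator's
  marker count should therefore be read as effective loci (pipeline
  default 200; identifiability experiments use 50, roughly two
  independent segments per chromosome for a 21-chromosome cereal).
* **Null h² is boundary-heavy.** Under the no-genetics null at n = 22,
  5–15% of REML fits land at h² ≈ 1 when K is near diagonal; a
  family-structured K (block relatedness, e.g. 4 families at 0.6)
  spreads the spectrum, tightens the null (97.5% quantile ≈ 0.55–0.6)
  and makes real-vs-permuted separations meaningful. Power experiments
  accordingly use `simulate.structured_grm`.

The permutation null for module h² shuffles line identity of the lsmean
matrix against K (n_perm default 50), then re-runs subclustering, PC1
and REML — breaking genetics while preserving the expression covariance
among transcripts. (A common permutation of line coordinates leaves
transcript–transcript distances unchanged, so the subclusters are
identical by construction and the null is effectively over permuted
eigengenes; the stages are re-run anyway for fidelity.)

Metabolite heritability uses the all-random RCBD model
`~ Line + Location + Location/Replication + Location:Line`, fitted by
EM-REML (dense 88 × 88 algebra; EMS method-of-moments starting values,
convergence 1e-6 relative, components truncated at zero afterwards),
with `h² = σ²_L / (σ²_L + σ²_{L×Loc}/n_loc + σ²_e/(n_loc·n_rep))` —
denominators 2 and 4 for the default two-location, two-replicate
layout. The fit matches lme4 on shared fixtures and the EMS closed
forms on balanced ones. Note the estimator's null distribution at 22
lines is wide (single null draws reach h² ≈ 0.45, confirmed against
lme4), so the h² > 0.4 metabolite filter passes a non-trivial share of
non-heritable metabolites at this panel size; the downstream
permutation comparison, not the filter, carries the inferential weight.

## Cluster-size test

For one TCoE set: cluster the standardized profiles into k = 8, sort
sizes descending, drop the smallest → a 7-vector. Each of n_perm
(default 1000) permutations shuffles every transcript's line profile
independently (preserving each transcript's value multiset, destroying
co-association), re-clusters, and produces a null size vector. The
observed vector's squared Mahalanobis distance from the null mean under
the null covariance is referred to χ² with k−1 = 7 df; a singular null
covariance falls back to the pseudo-inverse with a warning. Calibration
on independence-null data gives type-I error ≈ 0.06–0.08 at α = 0.05
with 200 permutations (the estimated-moments inflation of a plug-in
Mahalanobis statistic), inside the accepted [0.02, 0.09] band.
Bonferroni screening across sets uses p < α/m.

## Metabolite–module association

Metabolites passing the heritability filter are collapsed to per-line
means (an lsmean aggregation is available via `--aggregate`), then
regressed one at a time on each GCoE eigengene: OLS slope test, t with
n_lines − 2 df. No multiplicity correction on the metabolite × module
grid — at panel size the power is too low to clear it — inference rests
on the permutation comparison: PC1 scores permuted across lines per
module (default 100 permutations), all regressions recomputed, and the
observed p-value collection compared with the permuted one (per-module
quantiles plus a one-sided rank-sum statistic for observed < permuted).
The rank-sum p-value should be read qualitatively: permuted predictors
are shared across metabolites within a permutation, so its independence
assumptions are only approximate.

## Synthetic-data generator

What it emulates: the factorial design with uniform random missingness;
NB counts with per-transcript log-uniform dispersion on [0.01, 1] and
log-uniform per-sample depth factors (default [0.5, 2]); temporal mean
profiles that follow the assigned pattern codes with a configurable
per-interval step (default 1.0 log2 unit; power/round-trip studies use
2.0); module-structured per-line offsets — a shared genetic value drawn
against the GRM carrying fraction h² of a total line variance (default
line SD 0.5 log2 units) plus transcript-specific line noise; one
continuous latent batch factor loading on a random 30% of transcripts;
markers as independent biallelic dosages with MAF uniform on
[0.05, 0.5]; metabolites linear in a module eigengene plus location,
location × line, replicate-within-location and residual noise, one
measurement per plot.

What it does not emulate: read-level artifacts (no FASTQ, no mapping
ambiguity), transcript-length or GC effects, spatially or temporally
structured missingness (the real study lost samples for field reasons),
LD between markers (hence marker count = effective loci), a *discrete*
batch that would reproduce a two-cluster sample split (the latent
factor is continuous — the outlier-split test uses explicit blob
fixtures instead), and any real metabolite correlation structure.
Passing tests on these simulations demonstrates statistical correctness
of the machinery, not robustness to every artifact of real tag-seq
data.

## Problem sizes in the test and acceptance suites

Simulation-backed checks run at sizes chosen to make each statistical
property measurable while keeping the full suite interactive: null
calibration of the adjacent contrasts uses 2000 transcripts on a
12-line complete design; Mahalanobis calibration uses 400
independence-null sets of 60 transcripts with 200 permutations;
regression-null uniformity uses 10⁴ metabolite–module pairs; h²
recovery uses 200–400 replicate traits at true h² = 0.8 under a fixed
50-locus GRM; the structured-vs-permuted contrast uses 8 sets × 2
modules × 20 members at module h² 0.95 under a 4-family relationship
matrix, against 50 line permutations. `scripts/acceptance.py` re-runs
all of these from scratch in a few minutes on one CPU.
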