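# Methods

## The model

`sleepcca` implements a two-block canonical correlation analysis (CCA)
linking a small sleep block **X** (n subjects × p_x variables; by
default the 7 PSQI sub-components: satisfaction, latency, duration,
efficiency, disturbance, medication, daytime dysfunction) to a wide
behavioral/biopsychosocial block **Y** (n × p_y; mental health,
cognition, substance use, personality, affect, physical health,
demographics). CCA finds weight vectors (a_k, b_k) maximizing
corr(X a_k, Y b_k) subject to orthogonality with earlier components;
each solution is a *latent component* (LC) with canonical correlation
ρ_k and per-subject canonical score pair.

Numerically the fit whitens each column-standardized block by a thin
SVD (singular values below `rank_tol` × the largest are dropped, which
handles rank deficiency gracefully) and takes the SVD of the
cross-product of the two whitened bases. This is algebraically
equivalent to the generalized eigenproblem on the joint covariance —
the test suite asserts agreement to 1e-8 — but avoids explicitly
inverting covariance matrices. Weight columns are scaled so canonical
scores have unit sample variance.

Interpretation is carried by *structure coefficients* (loadings): the
Pearson correlation of each original variable with its block's
canonical score. Unlike raw weights, loadings remain interpretable
under multicollinearity. A deterministic sign convention is applied:
each component is flipped so the sleep variable with the largest
|loading| loads positively (so "higher score = worse sleep" reads
consistently); any deterministic rule would do, but one is required for
reproducible output and stable bootstrap alignment.

**Covariance explained.** The share of the X–Y covariance carried by
component k is defined as σ_k²/Σ_j σ_j², with σ_k the sample covariance
of the k-th score pair (equal to ρ_k for unit-variance scores). A
definition via singular values of the cross-correlation matrix would
differ only in normalization; the squared score-covariance convention
is used throughout and the fractions always sum to 1.

**Standardization** uses the sample standard deviation (n−1). Missing
values are rejected rather than imputed, mirroring complete-case
designs; constant columns raise an explicit error naming the column. A
rank-based inverse-normal transform (Blom offset: Φ⁻¹((r−3/8)/(n+1/4)),
average ranks on ties) is available as a robustness variant for both
blocks. No regularization is applied by default (the intended regime is
n ≫ p); a ridge term on the whitened covariances is exposed as a hook.

## Inference

### Restricted permutations

Twin cohorts violate exchangeability: monozygotic (MZ) twins, dizygotic
(DZ) twins and non-twin siblings are mutually dependent. Valid
permutations therefore only (i) swap same-role members within a family
and (ii) swap whole families slot-wise within classes of identical role
composition (the multiset of member roles). This is the standard
two-level scheme of permutation toolboxes for family data; a simpler
"permute freely within role strata" scheme is selectable
(`scheme="role_stratified"`). For small designs an exhaustive
enumerator provides the sampler's oracle; the sampler's support and
uniformity are asserted against it in tests.

The test statistic for component k is the k-th canonical correlation of
a refit after permuting the behavior block's rows. Because permuting
rows commutes with column standardization and whitening, each null draw
costs only one small SVD of Ux′PUy instead of a full refit. The null is
not centered at zero (the maximal correlation over weight vectors is
positive even for independent blocks), so the per-component null
distribution must come from the refit, not from a Fisher-z
approximation. p-values use the add-one convention
p = (1+#{null ≥ obs})/(1+B), so p ≥ 1/(B+1) and is never 0;
Benjamini–Hochberg FDR is applied across the K component p-values
(pooling with post-hoc tests is deliberately off by default).

### Bootstrap loading stability

Subjects are resampled with replacement (B = 1,000 by default;
whole-family resampling available by flag as a robustness option), the
CCA refit, and the replicate's components aligned to the original fit:
greedy matching on the |correlation| of concatenated weight vectors,
then a sign flip so the matched correlation is positive. Alignment is
essential — component order and sign are arbitrary in each refit, and
without it the loading distributions are meaningless mixtures. Per
loading the replicate sd is the reported uncertainty, the 95% CI is
mean ± 1.96·sd, and significance is z = mean/sd against a standard
normal with BH-FDR within each component's family of loadings (the
significance rule behind "bold" markers is a design choice; the z-based
normal test is the simplest defensible one). Replicates that produce a
constant column are redrawn with bounded retries and counted.

### Family-aware cross-validation

Whole families are shuffled with a seeded generator and dealt
round-robin into k = 5 folds, so no family ever spans folds and fold
sizes differ by at most one family. Per fold, the CCA is fit on the
training folds, held-out data are standardized with the *training*
means/sds and projected onto the training weights, and the held-out
sleep–behavior score correlation is recorded per component; the summary
is the mean across folds. Its permutation p-value permutes the held-out
pairings by admissible within-fold permutations — one defensible
construction among several the literature leaves unspecified; it is
documented, not asserted as canonical.

## Connectome stages

**Censoring.** Frames with FD > 0.2 mm or DVARS > 75 are outliers;
censoring dilates 1 frame back and 2 forward, kept segments shorter
than 5 frames are dropped, and a run with > 50% censored frames is
excluded. **RSFC.** Per run, Pearson correlation over kept frames
(clipped to ±(1−1e−7) before Fisher z, since atanh(±1) diverges), then
z-matrices averaged across non-excluded runs into one symmetric
parcels × parcels matrix per subject.

**GLMs.** After optional OLS residualization of confounds (age, sex,
education; pseudo-inverse fallback with a warning under collinearity),
each edge is regressed on the per-subject *composite score* — the
average of the sleep and behavior canonical scores for one LC (a
single-block variant is a config switch). The edge-wise map is reported
unthresholded. The network-wise analysis first averages connectivity
within/between networks per subject (diagonal blocks over unique
within-network pairs excluding self-pairs; single-parcel networks give
a missing marker), then fits one GLM per unique network pair
(18 networks → 171 tests) with BH-FDR across pairs; F = T² for the
single-predictor model. Exact-fit edges (zero residual variance) are
flagged rather than dividing by zero. The FDR family is one LC's
network-wise tests; pooling across LCs is available but off.

**Graph metrics.** On the LC's edge-wise beta matrix (or the
sample-average RSFC matrix, as a control): normalize by the maximal
|weight|; handle negative weights by zeroing them (default) or taking
absolute values — the formulas presuppose nonnegative strengths and the
choice is a config option because no convention is canonical for signed
beta matrices. Module-degree z standardizes within-module strength
against the node's module (population sd, the Brain Connectivity
Toolbox convention; sd = 0 or singleton modules give z = 0).
Participation coefficient is 1 − Σ_m (k_im/k_i)², zero for isolated
nodes. The integration/segregation summary min–max scales z and PC
across nodes and reports (scaled z + ε)/(scaled PC + ε) per node with
ε = 1e−6, plus per-network medians; "normalized" in the within:between
ratio is interpreted as this per-metric scaling (a toolbox-internal
normalization is an equally plausible reading; this one is documented
and guarded against division by zero).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
not the content of any real cohort:

* **Families.** Subjects are partitioned into families drawn from
  templates (singletons, MZ/DZ pairs, sibling pairs/trios, twin + sib)
  with a default mix resembling a young-adult twin cohort (~20%
  singletons, ~40% twin-pair families, ~35% sibling families, ~10%
  three-member families).
* **Two blocks.** K latent pairs (u_k, v_k) are jointly Gaussian with
  corr = `planted_rho[k]` (default (0.7, 0.4, 0.1)). Each block is an
  invertible linear mixing of its latents, p−K−1 structured noise
  dimensions and a family-effect direction, then column-standardized.
  Because the latents are exactly linearly recoverable from the
  columns, the *population* canonical correlations equal `planted_rho`
  exactly — the property that makes recovery tests sharp. Loading sign
  patterns are sparse (±1 on about a third of each block's columns)
  and drawn to be linearly independent of each other and of the
  family direction.
* **Family effect.** A unit-variance per-subject effect with
  intra-pair correlation `family_icc` (defaults MZ = 0.5, DZ = 0.3,
  SIB = 0.2 — a heritability-like ordering), built from nested family-,
  twin-pair- and individual-level components, enters every column of a
  block scaled by `family_scale` (default 0.4). The effect is drawn
  independently per block: the identical *mechanism* shapes the
  within-block exchangeability structure (which the restricted
  permutation must respect) without planting a cross-block signal, so
  the null generator genuinely satisfies the null. A
  `shared_family_effect` flag injects the same realised values into
  both blocks for studying the confounded case.
* **Connectomes.** Per subject, symmetric zero-diagonal matrices with
  iid Gaussian edge noise (sd 1) plus `slope × composite_score` added
  uniformly to chosen network-pair edge blocks. Planted slopes are free
  parameters (no empirical effect sizes exist to copy); the default
  test setting (slope 0.3, noise sd 1, n = 400) was chosen once for
  comfortable but non-trivial recovery.

What the generator does **not** emulate: ordinal/skewed questionnaire
marginals (a quartile-discretization option exists for the sleep block
but is off by default, since the analysis treats the scores
numerically), realistic fMRI temporal autocorrelation, spatially
structured connectivity noise, or missing-data mechanisms. Passing
tests therefore certify the *statistical machinery* — calibration,
recovery, coverage, determinism — under the assumed model, not
performance on real cohort idiosyncrasies.

## Numerical and reproducibility choices

* `rank_tol` = 1e−10 (relative) for effective rank; rank-deficient
  blocks reduce K with a warning; n ≤ p raises an error advising
  dimensionality reduction.
* Correlation clipping at 1−1e−7 before Fisher z; loadings clipped to
  [−1, 1] against rounding.
* The pipeline derives an independent named seed stream per stage from
  the master seed (fixed stage registry, append-only), so adding a
  stage never perturbs earlier stages' draws; re-running one config
  reproduces every table bitwise, which the manifest's SHA-256 digests
  certify.
* Tables are written with 17 significant digits so text round-trips
  are exact (`float_precision="round_trip"` on read).

## Problem sizes

The validation suite exercises the pipeline at desk scale, chosen to
make each property sharp at modest cost: oracle agreement on 100 random
small blocks (n = 50, p ≤ 4); recovery at n = 2000 over 20 seeds;
permutation calibration on 500 null cohorts (n = 200, 199
permutations); bootstrap coverage over 200 cohorts (n = 400, 200
replicates); CV at n = 2000; GLM recovery at n = 400 with 50 parcels.
`scripts/acceptance.py` re-measures the same quantities with somewhat
fewer Monte-Carlo replicates (200 null cohorts, 100 coverage cohorts,
10 recovery seeds) — the package's chosen reporting sizes — and prints
each value with the problem size used.

## Known limitations

* The p-value grid of a B-permutation test is 1/(B+1)-coarse; with the
  default B = 10,000 the smallest attainable p is ~1e−4.
* Bootstrap CIs are normal-approximation (mean ± 1.96 sd); percentile
  intervals would need larger B for stable tails.
* The two-level permutation scheme treats families with identical role
  multisets as exchangeable units; cohorts with covariate-dependent
  family structure would need finer blocks.
* Graph metrics on thresholded beta matrices depend on the
  negative-weight policy; conclusions should be checked under both
  provided policies.
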