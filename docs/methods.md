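# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of `flpscape`.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The classification rule

Specimens carry an ordinal androchromy class 1–4 (fraction of sexually
dimorphic patches that are male-like; 1 = 0%, 4 ≥ 50%).  Classes {1,2}
binarize to the heterochrome morph, {3,4} to the androchrome morph; the
cut is configurable (`androchrome_min_class` ∈ {3,4}).  Only specimens
tagged female enter species summaries, and specimens recorded as "sexed by
plumage" are dropped at ingestion — using plumage to sex a bird and then
scoring its plumage against its sex is circular.

A species is called **FLP** when its androchrome proportion reaches
`presence_min_prop` (default 0.10) *and* unimodality of the female scores
is rejected (dip test, α = 0.05); it is called **non-FLP** when at least
`absence_min_females` (default 19) females were sampled without meeting
the presence rule, carrying the external dichromatism flag
(dichromic/monochromic); otherwise it stays unclassified.  The 19-female
default gives an 85% chance of catching a 10%-frequency morph
(1 − 0.9¹⁸ ≈ 0.85); `required_sample_size` inverts this design rule.  The
published absence rule also excludes species previously reported as FLP;
with no literature table in scope this is exposed as an optional
`previously_flp` override that forces such species to "unclassified"
rather than "absent".  The default sensitivity grid crosses
presence ∈ {5%, 10%} × class cut ∈ {3, 4} × absence ∈ {10, 19} females
(eight matrices); the exact published combinations are not recoverable, so
the grid is fully configurable.  Raising the presence threshold can only
shrink the FLP set, and raising the absence threshold can only shrink the
absent set; the test suite asserts both monotonicities.

## The dip statistic and its calibration

`dip_statistic` computes Hartigan & Hartigan's dip — the minimal sup-norm
distance from the empirical CDF to any unimodal CDF (convex below the
mode, concave above, atom permitted at the mode) — exactly, not by
approximation.  The implementation scans mode locations over the data
values; for a fixed mode the CDF constrains the fit to vertical bands
(two-sided at the mode), each limb reduces to a hull feasibility value
(greatest convex minorant of the band floor; mirrored for the concave
limb), and the residual coupling between limbs — the left limb's
lowest achievable endpoint may still exceed the right limb's highest
achievable start — is resolved by pivoting on two-anchor chord-extension
certificates that are linear in the distance.  The suite verifies exact
agreement (1e−12) with an independent linear-programming minimax on
hundreds of small samples, including ties, plus the analytic anchors
(dip = 1/4 for an even two-point mixture, 1/(2n) for an equally spaced
grid).

`dip_test` returns the fraction of uniform(0,1) reference samples of the
same size whose dip is at least the observed one.  The uniform is the
conventional calibrating distribution (the least-favourable unimodal
case), so the test is *exact* against uniform data — the calibration test
verifies type-I error within Monte-Carlo error of the nominal 5% — and
*conservative* against lighter-tailed unimodal data such as a Gaussian
(near-zero rejection at n = 100).  Ordinal class scores are tied, so they
are jittered uniformly on [class − ½, class + ½] before the statistic;
values are sorted before the seeded jitter so the p-value cannot depend on
specimen record order.  Reference tables are cached per (n, n_boot, seed).

## The Mk stage

The plumage character (monochromic, dichromic, FLP) follows a 3-state
continuous-time Markov chain with rate matrix Q; ER (1 free rate), SYM (3)
and ARD (6) parameterizations are supported.  Likelihoods use Felsenstein
pruning with per-node rescaling (stable beyond 500 tips); transition
matrices exp(Qt) come from a single eigendecomposition broadcast across
all branch lengths, with a per-branch `expm` fallback when the eigenbasis
is ill-conditioned.  Zero-length branches are perturbed to 1e−8 before
exponentiation.  Fitting maximizes over log-rates in [1e−9, 100] by
multi-start L-BFGS-B (default 5 starts, log-uniform on [1e−2, 10]); a
constant-state dataset is unidentifiable and is reported with an
`at_lower_bound` flag rather than an error.  The root prior defaults to
uniform (⅓,⅓,⅓); an observed-conditional (FitzJohn-style) prior is
selectable in the CLI, since the natural root treatment is genuinely
ambiguous for this analysis.  AICc uses n = number of tips, the
convention for single-character fits.

Marginal ancestral states combine the pruning conditionals with an
up-pass carrying the information in the rest of the tree (equivalent to
rerooting at each node); both likelihood and marginals are verified
against exhaustive enumeration over all internal-node state assignments
on trees up to 6 tips.  Independent origins are counted on edges: a node
is "FLP" when its marginal exceeds 0.5, and an origin is an FLP child
under a non-FLP parent (a focal root adds one).  Counting focal *nodes*
instead would conflate one gain spread over a clade with many gains; the
edge rule is the documented default.  Root-state stability is the SD of
root marginals over replicates that drop 10% of tips at random and refit
(a faster mode reuses the full-data rates).

Model selection reports the AICc ranking and the ΔAICc < 2 equivalence
set, with ties broken toward fewer parameters.  On data simulated under
ER the equivalence set contains ER in ≫ 80% of replicates, while the
strict argmin lands on ER only ~80% of the time — the expected
chi-squared overlap of nested models, not an implementation artifact.

## The synthetic study

Every generator is a pure function of its spec and seed.

* **Tree** — pure-birth (Yule), the simplest process with realistic
  branch-length heterogeneity; the expected mean root-to-tip depth is
  Σ_{k=2..n} 1/(kλ), which the suite checks by simulation.  Study trees
  are rescaled to unit mean depth (`tree_depth = 1.0`), the relative
  scaling commonly applied to published time trees; at the default ER
  rate 0.9 this yields roughly one expected change per root-to-tip path,
  the regime where ancestral states are informative.  Unscaled deep trees
  put the same rate in saturation: the root marginal pins to the
  stationary distribution and the tip-drop SD collapses to zero.
* **Specimen scores** — females draw from a two-component class mixture:
  heterochrome over {1,2} with weights (0.9, 0.1) and, with probability
  `androchrome_freq` (default 0.3 within FLP species), androchrome over
  {3,4} with weights (0.1, 0.9).  The components concentrate at the
  extreme classes because FLP describes *discrete* morphs; flatter
  components would produce a near-monotone histogram no unimodality test
  should reject.  Males are Class 4.  `class_noise` misreads classes by
  ±1, truncated at {1,4}, mimicking observer/specimen-quality error.
  Sexing-method tags follow the archive composition (38% gonad, 60%
  unknown, 2% plumage-sexed).  The two-component form is an assumption:
  the real within-species distribution of female scores is documented
  only as bimodal.
* **Colors and bills** — per species, androchrome males and Class-1
  females form two clusters in the 51-channel space separated by
  `color_separation` (default 80 channel units) along a random unit axis
  with isotropic noise (sd 5); variable females sit uniformly along the
  inter-cluster segment, matching the heterochrome→androchrome continuum
  framing without asserting an unknown density.  On the latent coordinate
  a (−1 = female mean, +1 = male mean), bill = species mean +
  `planted_slope`·a + noise (sd 0.5 mm).  Panel sizes default to 10
  males, 6 Class-1 females, 11 variable females — the reported per-species
  averages of such photographic panels.
* **Covariates** — continuous covariates evolve by Brownian motion;
  binary ones threshold a latent Brownian value at the quantile giving
  target prevalences (25% migratory, 30% dominant).  FLP ties to the
  covariates through a probit-style latent predictor over the *observed*
  (standardized) covariates plus a Brownian residual, thresholded at 25%
  prevalence; when plumage states are supplied externally the same
  association is planted conditionally by shifting covariates.  Body
  length is confined to 6–22 cm.  Among non-FLP species 57% are
  monochromic, the composition implied by reporting FLP as both ~41% of
  non-monochromic and ~23% of all classified species.

What passing tests show — and what they do not: the generators produce
clean two-cluster color structure, exactly bimodal score mixtures, and
exactly Brownian covariates.  Real specimens add fading, subspecies
variation, patch-segmentation error and non-Brownian trait evolution;
recovery rates here are upper bounds on what identical settings would
achieve on museum data.

## Discriminant scoring and validation

Features are standardized, reduced by PCA (components capped at
n_train − 2 and at 95% cumulative variance — text-level preprocessing of
the original is not recoverable, so this is the package's own choice),
and a two-group Fisher axis w ∝ S_w⁻¹(m̄₁ − m̄₀) is computed on the
reduced space using pooled within-class *scatter* matrices, which makes
the axis exactly invariant to duplicating the training set.  LD1 is
standardized affinely so the male training mean is +1 and the Class-1
female mean −1 (midpoint 0); this gives the planted slope a defined
scale.  An axis is **validated** only if the *leave-one-out* LD1 ranges
of the two training groups do not overlap.  In-sample range overlap — the
more obvious criterion — cannot fail here: with ~16 training skins in a
≥ 14-dimensional reduced space, Fisher separates even identical groups
perfectly, so zero color separation would still "validate".  The LOO
criterion rejects such null axes while passing genuinely separated ones;
in-sample (`no_overlap`) and 2-pooled-SD (`2sd`) rules remain selectable.

Slopes are ordinary least squares of the relative morphometric on LD1
over females only (males inform axis training and species-mean centering);
significance uses the Bonferroni per-test α = family α / n_tests with
n_tests = the number of species whose axis validated.  Blomberg's K is

K = (MSE₀/MSE) / E_BM[MSE₀/MSE],  with â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1),
MSE₀ = Σ(xᵢ−â)²/(n−1), MSE = (x−â)ᵀV⁻¹(x−â)/(n−1),
E_BM = [tr(V) − n/(1ᵀV⁻¹1)]/(n−1),

with a one-tailed permutation p (fraction of tip-label shuffles with
K ≥ observed).  K is affinely invariant and centers on 1 under Brownian
simulation; the implementation matches an independent reference
(phytools `phylosig`) to 10 decimals on a fixed 5-tip example.

## PGLS

The binary FLP response is fitted by Gaussian generalized least squares
with the Brownian covariance V (entry = shared root-to-MRCA path length),
mirroring the standard caper-style analysis; a phylogenetic logistic
model is deliberately not offered, to keep the estimand the same.  The
fit whitens through the Cholesky factor of V (ridge 1e−10, logged, if V
is not positive definite), tests coefficients on n − p degrees of
freedom, reduces exactly to OLS at V = I, and is invariant to rescaling
V.  No branch-length transform (λ/κ/δ) is estimated by default — the
original analysis reports none — and the Brownian V is used as fixed.
Because the response is 0/1, coefficient p-values are approximate; the
package's simulations show planted-sign recovery is excellent while null
rejection rates can run slightly above nominal.

## Problem sizes and determinism

The default test suite runs in ~2 minutes and the acceptance script in
~5 minutes on one CPU, with the stochastic stages sized accordingly: 20
replicate 300–500-tip trees for rate recovery (10 in the script), 100–200
tip-drop replicates for root stability, 100–500 replicates for dip
calibration, 100–200 trees for K calibration, 20–40 replicates at 167
species for PGLS recovery.  All randomness flows through explicit integer
seeds via `numpy.random.default_rng`; identical configurations reproduce
output files byte-for-byte (the pipeline manifest records seeds and
SHA-256 checksums).

## Known limitations

* End-to-end, classification errors propagate: with ~30 females per
  species the dip requirement misses a substantial fraction of true-FLP
  species (conservative, not anticonservative), and those misses act as
  state-dependent misclassification in the Mk stage — on the demonstration
  study they push AICc toward ARD even though states were generated under
  ER.  Rate-recovery tests therefore use the true simulated states; the
  demonstration scripts show the honest end-to-end behavior.
* The dip test calibrated on the uniform is conservative for peaked
  unimodal alternatives; power statements hold for separated mixtures.
* Gaussian PGLS on a binary trait estimates a linear probability model;
  effect sizes are on that scale, not log-odds.
* The Mk stage fits plain 3-state models only — no hidden-rate classes,
  no stochastic character mapping, no correlated evolution.
* Polytomies are resolved arbitrarily with zero-length branches (then
  perturbed to 1e−8); UV reflectance and image processing are out of
  scope, and climate values are consumed as precomputed species means.
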