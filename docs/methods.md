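# Methods

This note documents the models, numerical choices and limitations of
`ddclock`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Droplet classification and methylation estimation

Each channel of a well is classified independently with two amplitude
thresholds (`t_total` below all positives, `t_allele` below the
labeled-allele cluster). The boundary convention is *strictly greater
than the threshold is above*: instruments do not document their rule,
and a deterministic, stated convention matters more than the handful of
droplets it can move. 2D amplitude views are an inspection aid in
practice and play no computational role here; droplets in the
inter-cluster "rain" region are assigned purely by the thresholds, with
no model-based rescue.

The methylation fraction is the droplet-count ratio `M/(M+U)`, the
assay's printed estimator. It deliberately ignores droplet co-occupancy;
at the recommended ≤ 10% positive droplets the bias is negligible. An
opt-in occupancy-corrected estimator is provided
(`poisson.corrected_methylation`): treating the two alleles as
independent Poisson processes, the negative fraction factorizes
(e^{−λ_total} = e^{−λ_M}·e^{−λ_U}), so

    λ_allele = −ln(1 − n_allele/n_total),
    λ_other  = −ln(1 − p_total) − λ_allele,
    beta_corrected = λ_M / (λ_M + λ_U).

A naive alternative — computing λ_other from the *single-positive*
fraction alone — is biased upward for the labeled allele, because
droplets holding both alleles sit in the labeled-allele cluster and are
invisible to the single-positive count; the factorized version above is
used for exactly that reason, and a Monte-Carlo test confirms it
outperforms the count ratio at p ≈ 0.5.

`M + U = 0` (no positive droplets) is an explicit error, never a silent
0 or NaN: an empty channel carries no methylation information.

## Poisson QC

Occupancy is λ = −ln(1 − p) with p the positive-droplet fraction;
saturated wells (p ≥ 1) are an error for the estimators and a failed
verdict for QC. The QC rule has three inclusive gates: positive
fraction ≤ 0.10, single-molecule fraction ≥ 0.95, and at least one
positive droplet. The first two gates are not perfectly consistent at
their joint boundary — p = 0.10 implies a single-molecule fraction of
94.8%, so the single-molecule gate binds at p ≈ 0.0967 — a property of
the stated thresholds, preserved as printed. A Wilson score interval on
`M/(M+U)` is available as an extension; the assay itself reports point
estimates only.

## Droplet-well simulator

The generator emulates the observation model the quantification stage
assumes, not PCR chemistry:

1. methylated molecules per CpG ~ Binomial(total_molecules, true_beta);
2. molecules placed uniformly at random over `n_droplets` (per-droplet
   counts are then Binomial(N, 1/D), indistinguishable from Poisson at
   D = 20,000 — verified by a pooled chi-square test in the suite);
3. true cluster labels from placements (any labeled-allele molecule →
   high cluster; else any molecule → single-positive; else negative);
4. amplitudes from per-cluster Gaussians. Defaults (means 1000/4000/8000,
   SDs 100/150/200) are synthetic: real instrument amplitude scales are
   not published for this assay. The gap between adjacent clusters is
   ≥ 6 SDs, so midpoint thresholds (2500, 6000) classify error-free in
   the no-rain case and every mis-assignment in tests is attributable
   to the rain artifact;
5. rain: with probability `rain_fraction`, a high-cluster droplet's
   amplitude is redrawn uniformly on the inter-threshold interval —
   displacement of upper positives into the lower cluster, the artifact's
   observed phenomenology, without inventing an amplitude distribution
   for it.

Mass-to-copies conversion assumes 3.3 pg per haploid genome and an
"amplifiable fraction" default of 0.2 reflecting bisulfite degradation
and partitioning losses; this is a modeling choice (placing a 40 ng
input near ~2,400 amplifiable copies per target, the top of the
assay's characterized range), not a measured constant. Dilution series
scale per-CpG copy numbers by descending factors with deterministic
per-well child seeds (`SeedSequence(seed, spawn_key=(level, rep))`), so
the entire series is bit-reproducible. A two-fold series from ~12,000
down to ~94 molecules descends from ~9,000 positive droplets into the
tens; Poisson statistics cannot reach the ~13 positives the real assay
shows at its lowest input from ~94 molecules — the real low end reflects
DNA losses the generator intentionally does not model.

What a green end-to-end test establishes: thresholding + count-ratio +
QC recover known methylation levels from an ideal partitioning
experiment. It does not establish robustness to probe chemistry,
droplet-volume variation, spectral overlap, or degraded DNA.

## Cohort simulator

Ages are uniform on [0, 95]; sex is a balanced label with no effect on
methylation (matching the absence of sex bias in blood for this panel).
Each CpG has a mean trajectory — linear for *ASPA*, *C1orf132*, *FHL2*;
saturating, beta(age) = asymptote + (baseline − asymptote)·e^{−rate·age},
for *ELOVL2*, *EDARADD*, *CCDC102B*, whose real trajectories flatten
with age — plus Gaussian noise on the beta scale, clipped to [0, 1]
(< 0.2% of values under defaults, so the noise is effectively
untruncated). The saturating form is a stated stand-in: the true
functional forms are not published.

Default parameters were frozen once by Monte-Carlo
(`scratch/tune_cohort_defaults.py`) so that per-CpG |Pearson r| with age
at n = 351 lands in 0.80–0.95 with the blood-observed signs (+ for
*ELOVL2*, *FHL2*; − otherwise), e.g. noise SDs of 0.045–0.095 on
baseline/asymptote spans of 0.4–0.8. Train/test splitting is stratified
by age decile with largest-remainder apportionment, so the requested
test fraction is met exactly while both halves cover the age range.

## Preprocessing

For the three nonlinear CpGs, a monotone transform is chosen per CpG
from a fixed candidate grid — identity, log(β + 0.01), logit on β
clipped to [0.01, 0.99], √β, β² — by maximizing training |Pearson r|
with age; identity is always a candidate, so the chosen transform can
never reduce training |r|, and ties break toward identity for
determinism. All markers are then standardized with training mean and
SD (divisor n − 1). Fitted state is a pure function of the training
data; a dedicated test mutates the test set and asserts the state is
untouched.

## Clock families

ENR, SVM (linear and RBF) and GBR delegate to scikit-learn with
hyperparameters selected by 5-fold unshuffled cross-validation on
training data only; grids are deliberately small (the point of this
package is comparison under one protocol, not per-family tuning
heroics). The elastic-net alpha grid extends to 10⁻⁸ with solver
tolerance 10⁻¹⁰ so that a noiseless linear cohort is recovered to
numerical precision. All fits are deterministic under the seed.

KDR is implemented from the standard Klemera–Doubal construction (see
README for the BA_E / BA_EC formulas). s_BA is estimated as the
training variance of BA_E − CA minus the propagated marker-noise
variance of BA_E (1/Σ(k_j/s_j)²), floored at 0.5 years; per-marker
residual SDs are floored at 10⁻⁸ to keep exact markers finite. A marker
with numerically zero slope on age is rejected with an explicit error.
BA_EC defaults on, since the estimator family is normally used with
chronological age as an input; BA_E is the age-blind option.

On synthetic cohorts generated *from* chronological age, there is no
true biological-age deviation, so the excess-variance estimate of s_BA
collapses to its floor and BA_EC shrinks almost entirely to CA. That is
the estimator working as designed, and it is why size-comparison
experiments (subset search) and the age-blind worked example use BA_E:
with BA_EC, held-out error on such cohorts mostly measures the
shrinkage, not the markers.

## Evaluation and subset search

Metrics are Pearson r, R² = 1 − SS_res/SS_tot (negative allowed out of
sample), MAE and RMSE in years; r is NaN-flagged when either vector has
zero variance (narrow age ranges legitimately depress r and can
degenerate). Age acceleration is either absolute (predicted − CA) or
relative (OLS residual of predicted on CA within the evaluated group);
relative acceleration sums to zero by construction and removes the
regression-to-the-mean slope component.

The subset search fits every CpG combination of sizes 2–6 (57 in all)
per requested family, evaluates train and test, flags per-fit failures
in a status column, and ranks by test MAE with deterministic
tie-breaking (fewer CpGs, then lexicographic subset).

## Model files

Clocks serialize to versioned JSON. KDR and elastic-net state are plain
floats (Python's repr round-trips doubles exactly); tree and kernel
models embed the fitted estimator as a base64 pickle blob — the only
way to guarantee bit-identical predictions for those model classes —
with the selected hyperparameters stored alongside for readability.

## Known limitations

- Thresholds are user-supplied; no automatic cluster detection.
- The amplitude model, mass-to-copies conversion and cohort
  trajectories are synthetic stand-ins, parameterized and documented as
  such; quantitative results on simulated data characterize the
  algorithms, not the wet-lab assay.
- Single-well quantification only (no merged-well statistics, no
  copies/µl volume calibration).
- The clock stage assumes one sample per row and complete six-CpG
  panels (subsets are explicit choices, not missing-data handling).
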