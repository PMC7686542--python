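# Methods

`gcflow` implements a directed ("effective") connectivity analysis for
ROI-level resting-state BOLD time series: bivariate Granger causality between
every ordered pair of 52 ROIs grouped into six subsystems — the three
default-network (DN) subsystems (medial temporal lobe MTL, dorsomedial
prefrontal DM, midline Core), the two frontoparietal-control subsystems
(FPCNA, FPCNB) and the dorsal attention network (DAN) — followed by
consensus-edge selection, information-flow-strength (IFS) statistics,
sliding-window co-evolution, a regulatory-effect index for the FPCNA, and
linear-SVM classification. Because the clinical cohort behind this design is
not publicly deposited, the package ships a generative model with planted
ground truth, and every quantitative claim in the test suite is made against
that stated world.

## Signal conditioning

Nuisance regressors (motion, drift, tissue means — whatever the user
supplies) are removed by OLS against `[intercept | confounds]`; residuals are
exactly orthogonal to the design. Filtering is a zero-phase (forward–
backward) Butterworth bandpass, 0.01–0.08 Hz by default at TR = 2 s, with
reflective padding. Zero-phase matters because the Granger estimator is
lag-based; a causal one-pass filter would shift energy across lags.

Numerical caveat: *broadband* idempotence of the filter is limited by its
transition bands. For this band a second pass changes a white-noise input by
~21 % RMS at order 2 and still ~10 % at order 8 (computable directly from the
|H|² response), so "filtering twice ≈ filtering once" holds only for in-band
content, which is what the test asserts. Filter order is configurable
(`RunConfig.filter_order`, default 2).

The narrow passband has a real scientific consequence on synthetic VAR data:
it smears lag-1 structure over many samples, so *single-subject* edge ranking
degrades after filtering (AUC ~0.9 raw vs ~0.6 filtered at T=190), while
*group contrasts* survive because the planted attenuation affects all
subjects equally. Example 02 demonstrates this.

## Granger causality

For an ordered pair (x → y) and order p (default 1):

    restricted:  y_t ~ 1 + y_{t-1..t-p}
    full:        y_t ~ 1 + y_{t-1..t-p} + x_{t-1..t-p}
    F_{x→y} = ln(RSS_restricted / RSS_full)   [nats, ≥ 0]

This is the Geweke log variance ratio with the maximum-likelihood (1/T_eff)
variance convention, which cancels in the ratio. F is treated as a
nonnegative *strength* so that IFS sums over edge sets are well defined; a
signed variant (sign of the summed x-lag coefficients) exists behind a flag
for sensitivity analyses only. Negative values from finite precision are
clipped to 0.

`pairwise_gc` vectorises all R(R−1) pair regressions through shared lag
cross-moment matrices: columns are centred (equivalent to the intercept) and
each pair costs one (2p)×(2p) normal-equation solve. Agreement with a plain
two-regression `lstsq` oracle is ~1e-15; singular designs (e.g. duplicated
series) fall back to a pseudoinverse. Model order is user-set; a BIC-based
suggestion utility (`suggest_order`) is provided but never applied silently.

## Synthetic cohorts (the stated world)

Data are generated from a stationary VAR(1), x_t = A x_{t−1} + e_t with unit
Gaussian innovations and a 200-sample burn-in. Defaults, chosen once:

| parameter | value | rationale |
|---|---|---|
| subjects | 27 NC + 24 AD | the study's group sizes |
| T, TR | 190, 2 s | the study's series length |
| self-decay | 0.4 | mild autocorrelation typical of filtered BOLD |
| within-subsystem edges | density 0.15, strength 0.4 | denser intra-system coupling |
| between-subsystem edges | density 0.08, min 2 per ordered pair, strength 0.4, random sign | every inter-system statistic has planted signal |
| stability | rescale so ρ(|A|) ≤ 0.9 | guaranteed stationarity with modulation headroom |
| AD contrast | ×0.5 on all DN-incident off-diagonal couplings | one-parameter version of the disease effect |

The stability rescale shrinks nominal strengths (max |coupling| ≈ 0.16 at the
defaults); "strength 0.4" refers to the pre-rescale parameters.

Co-evolution scenarios multiply two directed edge sets (FPCNA→Core and
Core→DAN by default) by a slow gain envelope — a 0.005 Hz sinusoid plus
Gaussian-smoothed noise (σ ≈ 25 s), clipped to [0.2, 1.8] — shared between
the sets for "coordinated" subjects and drawn independently otherwise. So
that 30-sample windowed GC can resolve the envelope above estimation noise,
the modulated edges are set to strength 0.3 post-rescale and the background
couplings are shrunk (bisection) until the peak-gain coupling matrix keeps
ρ(|A|) < 0.95.

The regulation scenario plants a common driver: one FPCNA ROI's unit-variance
series d is added (scaled by `driver_sd`) to every ROI of the driven
subsystems, giving each driven pair a full correlation of v/(v+1) (v =
driver_sd²) that vanishes after the FPCNA is regressed out.

What the generator does *not* emulate: hemodynamic convolution, measurement
noise spectra, scanner drift, motion artefacts, spatial structure, or
subject-level coupling heterogeneity (all subjects of a group share one A).
A green recovery test therefore establishes estimator correctness and power
under ideal VAR dynamics, not robustness to fMRI physics.

## IFS statistics

Regional IFS splits each ROI's summed GC by direction (in/out) and by whether
partners share its subsystem (intra/inter); the four pairwise sums are exact
by construction. Since every directed edge is counted once as inflow and once
as outflow, the tables obey conservation laws (per-network Σ intra-in =
Σ intra-out; global Σ inter-in = Σ inter-out = Σ inter-system IFS) that the
tests assert to 1e-10 (summation order differs, so bitwise equality is not
expected). Inter-system IFS sums masked GC over each of the 30 ordered
subsystem pairs.

Group inference: pooled-variance (Student) t (df = n₁+n₂−2 = 49 at the study
sizes) rather than Welch, matching the reported degrees of freedom; regional
tests at uncorrected p < 0.01; the 30 inter-system tests additionally
BH-FDR-corrected at q = 0.05 (the step-up threshold is returned so
thresholding reproduces the mask). Forward/feedback coupling between FPCNA
and each DN subsystem is a per-group Pearson correlation compared across
groups with the Fisher Z test, Z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) +
1/(n₂−3)). Intra-vs-inter IFS correlations are reported uncorrected, as in
the source analysis. Degenerate inputs (zero pooled variance) yield t = 0 at
equal means and a flagged ±∞ otherwise.

Whether regional IFS should be computed on consensus-masked or unmasked
matrices is not pinned down by the source; masked is the default
(`RunConfig.use_masked_regional`), consistent with "other connections become
0", with unmasked available.

## Consensus features

Features are the R(R−1) = 2652 ordered-pair GC values. The two-class F-score
F = [(m⁺−m)² + (m⁻−m)²]/(s⁺² + s⁻²) (sample variances) ranks features
*inside each leave-one-out training fold* (the leakage-safe reading; a
global-ranking variant exists behind a flag). Ties rank by feature id
(stable); zero within-class variance with distinct means scores +∞ with a
warning. The retained count k is data-driven — the smallest k maximising
LOOCV accuracy of a linear SVM on the top-k features — rather than a
hard-coded optimum, since the published value (1320, yielding 813 consensus
edges) is specific to the undeposited cohort. The consensus mask is the
intersection of fold-wise top-k sets; an empty intersection warns rather than
errors. SVM features are standardised with training-fold statistics (the
source is silent on scaling).

## Dynamic co-evolution

Windows are half-open, 0-based, `round(60 s / TR)` = 30 samples, stepped by
3 samples (6 s): T=190 gives 54 windows with last start 159. Within each
window GC is re-estimated (same estimator and order; data re-centred but not
re-filtered — filtering is a whole-series operation) and averaged over the
subsystem pair's cross-network ROI pairs, restricted to the consensus mask by
default. Co-evolution is the Pearson correlation between two windowed IFS
series, Fisher-z per subject, then a one-sample t per group and a pooled
two-sample t across groups.

## FPCNA regulatory effect

For each block (within-Core, within-MTL, within-DM, Core–DAN, DM–DAN):
full strength = Σ atanh(r) over the block's unordered pairs; partial strength
= the same after residualising every block ROI against
`[intercept | all FPCNA series]` (algebraically the block partial correlation
given the FPCNA; verified against a precision-matrix oracle); the regulatory
effect is their difference. Fisher z is applied per pair *before* summing
(the literal reading of the source). Linearly dependent FPCNA regressors are
dropped with a warning. Paired t within group (full vs partial), pooled
two-sample t on the effect across groups.

## Classification

AD is the positive class. LOOCV with a linear SVM at C = 1 (the libsvm
default), per-fold training standardisation; AUC from held-out decision
values via the Mann–Whitney identity with ties counted half. Significance by
label permutation with the full LOOCV re-run per permutation and the add-one
estimator p = (1 + #{permuted ≥ observed})/(1 + n_perm), so p is never
exactly 0 — a run beating all 1000 permutations reports p = 1/1001, not the
literal "p = 0".

Implementation note: the inner loop calls scikit-learn's low-level libsvm
binding directly (with the binary sign flip its estimator applies), because
the permutation test refits ~10⁶ tiny SVMs and estimator-object overhead is
~60× the solver cost. Equivalence with `SVC(kernel="linear")` predictions and
decision values is asserted in the tests.

Calibration caveat: LOOCV accuracy is a discrete statistic, so with small
cohorts ties make the add-one p conservative (stochastically larger than
uniform). The calibration study uses 40 subjects and 5 features, where the
statistic has enough support for a KS uniformity check to be meaningful; at
n ≈ 16 the tie mass dominates and p is strongly super-uniform. This
conservatism never inflates false positives.

## Pipeline and reproducibility

`run_pipeline` chains all stages and writes TSV report tables with a fixed
float format; identical config + seed ⇒ byte-identical outputs. All
randomness flows from `RunConfig.rng_seed` / per-function seeds through
`numpy` `SeedSequence` spawning. Simulation-heavy validation studies are
scaled (cohort sizes, replicate counts) to run on one CPU in minutes; the
replicate counts of the recovery studies are kept at their stated values.

## Known limitations

- Bivariate GC inherits indirect-path and common-driver confounds;
  conditional/multivariate or spectral GC are out of scope.
- The generative model's idealisations (above) mean recovery results bound
  what the estimator can do, not what fMRI data will give.
- The default partition ships plausible ROI labels for the six subsystems;
  the exact 52-label table of the original atlas is not public, so the file
  is a synthetic stand-in (labels only need to be unique and consistently
  partitioned).
- Broadband filter idempotence is physically unattainable at low filter
  orders (see above); only in-band idempotence is guaranteed.
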