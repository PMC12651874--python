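# Methods

This note documents the models, conventions and numerical choices behind
`copmech`, and what the synthetic cohort does and does not establish.

## The analysis problem

The package targets a small-cohort study design: 12 Parkinson's disease
(PD) patients — half receiving a targeted trunk-rotation exercise
program, half standard care — measured on a force plate before and
after a 10-week intervention, plus 6 healthy controls measured once.
Each subject-session contributes a 30 s quiet-standing trial and a
gait-initiation trial (3 s still, then a first step on a verbal cue),
sampled at 1000 Hz. The analysis asks three questions: can
mechanics-informed COP features separate patients from controls without
labels; does the intervention move patients' biomechanical signatures;
and which features carry the signal.

## Synthetic cohort generator

The original recordings are not publicly deposited, so a seeded
simulator stands in for them. It is designed to reproduce the
*statistical contrasts* the analysis depends on, with closed-form
ground truth for testing — not subject-specific biomechanics.

**Standing sway.** The latent COP follows an Ornstein–Uhlenbeck
diffusion per axis, discretized by Euler–Maruyama:
`c[t+1] = c[t] + θ(μ − c[t])Δt + σ√Δt·ε`. The OU process was chosen
over, say, filtered noise or an inverted-pendulum simulation because
its stationary standard deviation `σ/√(2θ)` gives the feature extractor
an analytic oracle. Units: COP in mm, σ in mm/√s, θ in 1/s. Defaults:
θ = 1/s on both axes; healthy σ_ML = σ_AP = 1 mm/√s; PD σ_ML = 3,
σ_AP = 2 mm/√s. These magnitudes are stand-ins — only the *directions*
of the group contrasts (PD larger ML RMS, larger AP path length,
smaller APA) are anchored to the study design; absolute sway magnitudes
of the real cohort are unknown.

**Gait initiation.** After `cue_time` = 3 s of baseline, the COP runs a
cosine-ramp excursion of `apa_ml_amplitude` toward the swing limb and
`apa_ap_amplitude` posteriorly over 0.5 s (loading), then reverses past
baseline to −0.5× the amplitude on the stance side over 0.6 s
(unloading), plus white template noise (SD 1 mm). Healthy ML amplitude
30 mm; PD 0.6×. Ground-truth boundaries (onset = cue, loading end =
ramp peak, unloading end = first baseline recrossing) ride in trial
metadata so segmentation can be scored.

**Force/moment channels.** Fz is body weight with 0.5 % multiplicative
noise; Mx = COP_AP·Fz and My = −COP_ML·Fz hold exactly (COP in metres),
so recomputing the COP from the channels recovers the latent trajectory
to machine precision wherever Fz clears the validity threshold. Shear
follows the small-angle inverted-pendulum relation
`F_h = mg(x_COM − x_COP)/h` with the COM taken as the 0.5 Hz low-pass
of the COP and h = 1 m, plus a 0.5 N sensor-noise floor. The
mechanically coupled shear matters: if Fx/Fy were fixed-scale sensor
noise, their standard deviations would carry no between-subject signal,
and z-scoring would amplify pure estimator noise into unit-variance
nuisance axes that dilute the channel-SD feature block — on real plates
shear fluctuations scale with sway, and the generator reproduces that.
Mz remains free-moment sensor noise (SD 0.1 N·m) and is the one
deliberately uninformative channel.

**Cohort structure.** Subjects get log-normal parameter jitter
(SD 0.10) around their group preset; post sessions add smaller session
jitter (SD 0.03). The intervention is a convex shift of a treated
patient's parameters toward the healthy preset by λ = 0.6 — a direction
without an invented magnitude. Demographics (age, sex, BMI, mass) are
drawn in the ranges of the target population (healthy controls younger,
as in the study). Identical (config, seed) yields identical trials.

**What passing tests show.** The generator emulates stationary Gaussian
sway, a stereotyped APA, and group contrasts of known direction. It
does not emulate tremor spectra, non-stationarity, freezing episodes,
foot placement, or realistic inter-feature correlation structure, so
end-to-end successes here demonstrate that the *pipeline* recovers
planted structure at study-scale n — not that the clinical findings
would replicate.

## Preprocessing

COP is derived with moments referenced to the plate surface (a `z0`
term is available for plates that report about a sensor plane); samples
with Fz < 50 N are masked invalid. Transients are trimmed: 2 s head and
tail for standing; for gait trials only the pre-cue head, leaving 1 s
of baseline. Filtering is a zero-phase (forward–backward) 4th-order
Butterworth low-pass at 10 Hz — standard posturography practice; cutoff
and order are configurable since the study protocol does not pin them.
Axis convention: x = mediolateral, y = anterior–posterior.

## Features

Standing: per-axis path length Σ|Δ|, planar path length Σ√(Δx²+Δy²),
RMS and variance on the demeaned series (population normalization, so
`var = rms²` holds identically; the channel-SD block uses the n−1
sample convention instead), mean velocity = path length / duration, and
sway area as the 95 % prediction ellipse `π·χ²₂(0.95)·√det(cov)`
(χ²₂(0.95) = 5.991; a convex hull is a reasonable alternative but the
ellipse is differentiable in the data and testable against the uniform
circle). These are standard stabilometry conventions, stated here
because the field uses several variants.

Gait segmentation: onset is the first post-cue sample whose planar
deviation from the baseline mean exceeds 3 baseline SDs sustained for
50 ms (baseline window 2 s, or what remains before the cue); loading
ends at the extremum of the dominant ML excursion (the swing-limb
direction is auto-detected from the early excursion sign, since limb
dominance is not part of the data contract); unloading ends at the ML
baseline recrossing. "Displacement" is net displacement magnitude and
"velocity" is net displacement over phase duration — chosen so that the
loading-phase ML displacement reads directly as APA amplitude;
path-length-based variants would conflate amplitude with noise.

Standardization is a joint column z-score over all rows entering an
analysis (pre and post sessions together), because embedding and
clustering must place all sessions in one space. Zero-variance columns
are an error rather than silently dropped.

## Selection and validation

Forward selection greedily adds the feature maximizing inner-CV
accuracy (stratified, subject-blocked 3-fold), stopping at 3 features;
ties break by column order and are logged. Wrappers: logistic
regression (C = 1) and KNN (k = 5); hyperparameters follow common
defaults since none are specified by the protocol. Outer evaluation is
leave-one-subject-out with selection re-run per fold. All resampling is
blocked by subject so pre/post sessions never straddle a split.

The permutation test permutes subject labels and recomputes the
cross-validated metric; p = (1 + #{perm ≥ obs})/(B + 1). Two statistics
are offered: fold accuracy, and the AUC of leave-one-subject-out
out-of-fold scores. Accuracy at n ≈ 24 is heavily tied, which makes the
test conservative (measured null rejection ≈ 0.037 at α = 0.05); the
near-tie-free AUC statistic is calibrated (≈ 0.047) and is what the
validation suite uses. For KNN with LOSO the neighbor structure does
not depend on the labels, so all permutations are evaluated in one
vectorized pass; this is what makes 1000-replicate calibration studies
cost seconds.

The case bootstrap resamples subjects with replacement over the
out-of-fold predictions and reports 95 % percentile intervals;
single-class resamples are redrawn and counted. McFadden's pseudo-R² is
`1 − lnL(model)/lnL(intercept-only)` from an unpenalized logistic fit;
under (quasi-)separation the likelihood is unbounded and the value is
recomputed from a lightly ridge-penalized fit and flagged.

## Embedding and clustering

t-SNE is implemented exactly: squared-distance Gaussian conditionals
with per-point bandwidth found by bisection on the Shannon perplexity
(tolerance 1e−5, 200 iterations), symmetrized to the joint
`P = (P_{j|i} + P_{i|j})/2n`; an alternative `affinity="joint"` variant
normalizes the per-point kernels in a single sum, for comparison with
formulations that write the normalization jointly. The embedding
minimizes KL(P‖Q) with the 1-df Student-t kernel by gradient descent:
1000 iterations, learning rate max(n/4, 50), momentum 0.5→0.8 at
iteration 250, early exaggeration ×4 for 100 iterations, init
N(0, 1e−4), centered each step; the KL trace is recorded against the
un-exaggerated P and the best post-exaggeration iterate is returned.
Duplicate points (zero distances) require an explicit jitter scale.
A warning fires when perplexity exceeds (n−1)/3. Runs are deterministic
given a seed; the recipes fix seed 42.

K-means is best-of-n_init (default 10) Lloyd from k-means++ seeds;
empty clusters are reseeded from the farthest point. The elbow curve
reports WCSS per k with an advisory knee at the maximum second
difference — advisory because elbow reading is a judgment call, and the
recipes instead fix the k values of interest (diagnosis k = 2;
intervention k = 3, 5; convergence k = 2–4; baseline k = 2). One
caveat established during validation: best-of-n_init Lloyd matches the
exhaustive-partition WCSS optimum on clusterable (blob) instances, but
unstructured point sets exist whose global optimum is a fixed point
unreachable from any data-point initialization — a property of
Lloyd/k-means++ itself (scikit-learn behaves identically).

Validity indices use the textbook definitions; a singleton cluster's
silhouette is 0 by convention. "Unseen data" validation is an
out-of-bag bootstrap: fit K-means on an in-bag resample, assign
out-of-bag points to the nearest centroid, score the indices on the
out-of-bag points only; replicates with fewer than k+1 out-of-bag
points or a collapsed assignment are skipped and counted. DBSCAN
(defaults eps = 0.687, min_samples = 2) runs on the embedding
coordinates, matching where K-means operates.

## Effects and attribution

Cohen's d uses the pooled-SD form, first sample minus second, with the
extended magnitude ladder (negligible < 0.2 ≤ small < 0.5 ≤ medium
< 0.8 ≤ large < 1.2 ≤ very large < 2.0 ≤ huge). Group comparisons use
Welch's unequal-variance t-test — at n = 6 per group, variance
homogeneity is not a safe assumption, and on the bundled cohort table
it reproduces the published demographic p-values where the pooled test
does not. ANOVA and Kruskal–Wallis (tie-corrected, χ² approximation)
cover the session-cell comparisons; degenerate inputs (identical data)
return statistic 0, p = 1 by convention.

Shapley attribution is exact: the interventional value of a coalition
is the mean model output with absent features marginalized over a
background sample (the analysis table itself), and φ is the full
coalition-enumeration sum (≤ 12 features; the recipes use 3). Additivity
`Σφ = f(x) − base` is asserted at 1e−9 on every call. The explained
model is the PD-vs-healthy logistic probability on the selected
features.

## Validation suite and problem sizes

The `benchmarks` module fixes the study sizes used by the test suite
and `scripts/acceptance.py`: oracle equivalence on 6–8-point instances
(exhaustive enumeration is exact there); OU RMS recovery from a batch
of four 300 s trials (a single trial's RMS carries ~4 % sampling error
at θ = 1/s, so the batch mean is compared); permutation calibration
with 1000 null replicates at B = 200 and bootstrap coverage with 2000
replicates — replication chosen so the Monte-Carlo error of the
estimated rate is small against the width of the calibration bands; and
25-seed success rates for the end-to-end recipes at full study
conditions (18 subjects, 30 s at 1000 Hz). The planted-feature recovery
study uses a cohort variant whose gait templates are equalized across
groups, so the ML-RMS and AP-path-length analogues are the only
carriers of group signal by construction.

## Known limitations

* The simulator's parameter magnitudes are plausible, not estimated
  from the undeposited cohort; cluster coordinates and index values on
  real data are qualitative anchors only.
* Gaussian OU sway has no tremor peak and no long-range
  stabilogram-diffusion structure.
* The run manifest records config hash, seeds and package version but
  deliberately no wall-clock timestamp, so that identical runs produce
  byte-identical bundles.
* Frequency-domain posturography, recursive feature elimination and
  exhaustive subset search are out of scope.
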