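# Methods

## Generative model of the synthetic cohorts

A cohort is defined by a metabolite panel, per-class effect signatures,
two matrix efficiency profiles and an acquisition configuration.

**Panel.** Each metabolite has a name, an m/z position in [100, 1000] Da
and a base abundance drawn lognormally (median 50 a.u., log-sd 0.8 —
spanning the 2–3 decades of dynamic range typical of serum LDI signals).
The panel always contains the eight named serum biomarkers
(2-oxovaleric acid, histamine, glucose, 5-hydroxymethyluracil, 2-furoic
acid, methylmalonic acid, 4-methylcatechol, L-carnitine);
5-hydroxymethyluracil is fixed at m/z 164.98 and 4-methylcatechol at
147.02, the remaining six default to nominal protonated masses and are
configurable. Background metabolites get uniform random m/z; band quotas
can force background mass into specific windows so band-specific signal
can be planted.

**Sample model.** A sample of class $c$ has abundances
$a_i = b_i \exp(\beta_{c,i} + \varepsilon_i)$, with $\beta$ the planted
log-fold effect (zero for healthy controls) and
$\varepsilon_i \sim N(0, \sigma_b)$, $\sigma_b = 0.3$ by default —
lognormal biological variation, the conventional model for metabolite
intensity data.

**Matrix profiles.** Gain curves are raised-cosine bumps (amplitude 1.0)
on a flat floor (0.05): GNS over 200–300 Da, SiNW over 100–200 Da. The
floor keeps out-of-band analytes visible but near the detector noise, so
each matrix is genuinely more informative about its own band.

**Shot rendering.** A shot spectrum on the m/z grid (default 0.05 Da
steps) is the gain-weighted sum of Gaussian peaks (constant FWHM, default
0.3 Da — a deliberate simplification that makes resolving power
m/FWHM ≈ 600 at 180 Da computable and testable), multiplied by a per-shot
lognormal scale (sd 0.05), plus an exponentially decaying baseline and
additive Gaussian detector noise truncated at zero. An affine mass drift
(slope, offset) can be planted; the default acquisition is 20 spots × 25
shots = 500 shots per sample per matrix.

**Feature-level shortcut.** For classifier-scale cohorts the chain
render → accept → accumulate → TIC-normalize → bin is integrated in closed
form: each metabolite contributes gain × abundance to its 0.5-Da bin,
half-normal detector noise (sd 2.0 a.u. pre-normalization) is added per
bin, rows are TIC-normalized. This is exact for noise-free rendering with
no drift and keeps the large experiments inside interactive runtimes; the
shot-level path is exercised by the preprocessing tests.

What the generator does **not** emulate: isotope envelopes, adducts,
matrix cluster ions, ion suppression, peak-shape changes with m/z, or any
real serum composition. Passing tests therefore demonstrate that the
pipeline recovers *planted* structure under the stated noise model — not
clinical performance on patient sera, whose effect sizes and abundances
are unknown here.

## Preprocessing

* **Baseline**: SNIP iterative clipping, growing window up to 50 grid
  points, operating directly on intensities, with odd-reflection edge
  padding (clamped padding systematically under-subtracts sloped baselines
  at the spectrum ends). On a pure linear ramp the residual is at machine
  precision; Gaussian peak apexes on a ramp are preserved to a few
  percent.
* **Denoising**: Savitzky–Golay (window 7, order 3). The noise sd is
  1.4826 × MAD of the smoothing residual, divided by the filter's exact
  residual factor $\sqrt{1 - 2c_0 + \sum c_j^2}$ so the estimate is
  unbiased for iid noise.
* **Peak picking**: prominence-floored local maxima (floor 2 × noise sd);
  apex position and height refined by a log-parabola through the three
  apex samples (exact for Gaussian peaks); FWHM by linear interpolation at
  half height; S/N = apex / noise sd; resolving power = m/FWHM.
* **Shot acceptance**: a shot is kept iff one peak inside m/z 100–500 has
  resolving power > 300 **and** S/N > 30 (strict inequalities, conjunction
  on a single peak). Acceptance is applied per shot, before accumulation.
* **Accumulation**: pointwise mean of accepted shots; zero accepted shots
  flags the sample × matrix as failed QC.
* **Calibration**: each of the six calibrants (serine 105.09, glucose
  180.16, tryptophan 204.23, sucrose 342.29, maltotriose 504.44,
  amylopentaose 828.72) is matched to the nearest peak within 0.5 Da; a
  least-squares affine fit observed → reference is applied to the run.
  Two matches suffice (a two-point affine fit is exact). A planted drift
  of slope 1e-4 / offset 0.05 Da is recovered to 1e-6 / 1e-3 noise-free.
* **Normalization**: total ion current over 100–1000 Da. Median or other
  normalizers would be drop-in replacements; TIC is the default.
* **Binning**: half-open [lo, hi) bins, uniform 0.5 Da, 1800 features;
  the terminal edge at exactly 1000 Da folds into the last bin.
* **Standards QC**: PCA over standard-spot feature vectors; a spot is an
  outlier when its distance from the centroid in the first two component
  scores exceeds the median distance plus k (default 3) robust standard
  deviations.

## Classification

Per matrix: `StandardScaler` → linear SVM (C default 1.0, grid
{0.01, 0.1, 1, 10, 100} for selection by 5×5 stratified CV) →
sigmoid calibration fitted on out-of-fold decision values (5 folds,
single calibrator, final SVM refit on all training data). The linear
kernel is required anyway for SVM-RFE weight extraction.

**Log-intensity input.** When the features are spectral bin intensities
the classifiers operate on $\log(x + 10^{-9})$. Multiplicative intensity
variation is additive and symmetric on that scale, so the two classes'
calibrated score distributions stay mirror-alike — the condition under
which the accuracy-optimal threshold sits at the calibration midpoint
(0.5 per model, 1.0 fused). Measured on large fresh cohorts, the true
optimal fused θ is 1.00 with log input versus ≈0.985 with raw input
(the wider spread of the up-shifted class drags the density crossing
down). The flag is off for arbitrary (possibly signed) feature frames.

**Decision rules.** Fused score = sum of the two calibrated cancer
probabilities; cancer iff score ≥ θ (the boundary itself counts as
cancer; the alternative strict reading differs on a measure-zero set of
continuous scores). Tissue of origin: per-matrix one-vs-rest calibrated
probabilities summed across matrices, argmax with ties broken in the
fixed order HCC, NSCLC, PAAD, CRC, GC, PTC. A majority-vote combiner
(category wins iff its vote share strictly exceeds one half, otherwise
reject) is provided for hard-label ensembles.

Models persist as plain JSON (scaler moments, weight vector, offset,
sigmoid coefficients, class order, log flag), so stored models reproduce
pipeline probabilities exactly.

## Feature ranking

SVM-RFE standardizes features (zero mean, unit variance), fits the linear
SVM with a tight solver tolerance (1e-8, so near-tied weight criteria are
resolved by the optimum rather than solver slack), eliminates the feature
with the smallest $w_i^2$ (ties: lower index first), and repeats. The
elimination step is configurable; for wide matrices an adaptive schedule
drops 20% of the surviving features per iteration until 100 remain, then
reverts to single-feature elimination — within-batch order still follows
the criterion, and the suite checks the adaptive ranking matches the
exact loop on its deep prefix. The discriminative report attaches raw
two-sided Wilcoxon rank-sum p-values (Benjamini–Hochberg is available but
off: the reference presentation reports raw values) plus group
median/quartiles for violin rendering; the heatmap export z-scores class
means per feature across classes.

## θ sweeps and their estimator

`sweep_theta` computes (θ, sensitivity, specificity) on a uniform grid
(default step 0.01; the study protocol uses 0.05) and the trapezoidal
AUC, which equals the pairwise-comparison probability (checked against an
exhaustive oracle). The empirical accuracy curve has a flat, noisy
maximum, so `best_theta` stabilizes the argmax with two standard devices:
a 3-point moving average, and the one-standard-error rule — every θ whose
accuracy is within one binomial standard error of the maximum counts as a
maximizer — then returns the plateau midpoint snapped to the grid (on
odd-width plateaus the midpoint rounds toward the shoulder that falls off
more slowly). For deployment tables (`compare_models`) the upper plateau
edge is reported instead, trading nothing in accuracy for extra
specificity, the natural choice for a screening assay.

## The θ-optimum study

The study condition is a balanced two-class cohort, 200 samples per
class, whose planted signature is split between the two matrix bands:
four background metabolites per band, two up and two down at |logFC| 0.7.
The ± balance keeps the class-conditional score distributions symmetric
(the condition under which the optimum sits at the midpoint); the
magnitude was chosen once so that a single-matrix model reaches a
held-out AUC ≈ 0.9 — strong but imperfect, leaving measurable headroom
for fusion (≈ 0.97), mirroring the qualitative single-vs-fusion gap the
dual-matrix design exists to exploit. The cohort is split 50/50: the θ
estimate is driven by the held-out score sample, so the estimation
protocol trades training size for evaluation size (the generator's
default cohort split remains 80/20). Per seed, the argmax-accuracy θ is
read off a 0.05 grid; the study reports the mode over 30 independent
seeds (count ties break toward the sample median). Measured over 80
seeds, the per-seed estimate has sd ≈ 0.07–0.08 around means 1.00
(fused) and 0.50 (single), and the 30-seed mode lands within one grid
step of the midpoint with probability ≥ 0.97. One grid step is the
resolution at which the modal estimate is meaningful.

The biomarker-recovery study plants the eight biomarkers round-robin
across the six cancers at logFC 1.5 (plus sparse overlapping background
signatures at ±0.8) in a seven-class cohort of 100 samples per class,
and asks whether the planted bins surface in the union of top-10
discriminative lists; under these conditions recovery is typically 8/8.

## Numerical and degenerate-input conventions

Zero-variance features are zeroed by the standardizer and eliminated
first (lowest index first) by RFE. All-zero spectra fail TIC
normalization with a QC error rather than producing NaNs. Probabilities
are validated to [0, 1] and fused scores to [0, 2]. Seeds: every
stochastic routine takes an explicit seed or generator; repeat seeds are
derived from the master seed.

## Known limitations

Single-charge, centroid-free Gaussian peak model; no isotope or adduct
chemistry; calibration is a global affine fit (no lock-mass
recalibration); the synthetic effect magnitudes are design choices, not
estimates of any clinical cohort; multiclass accuracy is conditional on
the binary gate, so binary errors propagate.
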