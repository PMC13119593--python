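# Methods

`liversep` quantifies liver fibrosis from complex multi-echo gradient-echo
(mGRE) MRI by separating tissue magnetic susceptibility into a
paramagnetic source χ⁺ (iron) and a diamagnetic source χ⁻ (collagen), and
evaluating |χ⁻| as an ordinal biomarker of histological fibrosis stage.
This note records the models, the numerical choices, what the synthetic
data do and do not emulate, and the known limitations.

## Signal model and reconstruction chain

Per voxel the mGRE signal follows the single-peak fat model

S(t_j) = (W + F·e^(−i2πν t_j)) · e^(−R2\* t_j) · e^(−i2π f t_j)

with complex water/fat amplitudes W, F, fat resonance offset ν
(−440 Hz at 3 T ≈ −3.45 ppm; a single peak, configurable), effective
transverse decay R2\* (s⁻¹) and field shift f (Hz). The default protocol
is 8 echoes, TE₁ = 2.6 ms, ΔTE = 2.7 ms at 3 T (Larmor 127.74 MHz).

1. **R2\* (ARLO).** Closed-form auto-regression on echo-magnitude
   triplets: for equally spaced echoes, y_i − y_{i+2} = R2\*·∫y dt with the
   integral by Simpson's rule; the least-squares slope over all triplets
   is the estimate, clamped at zero. Within 0.25% of a nonlinear LS fit
   on noiseless mono-exponentials over R2\* ∈ [15, 300] s⁻¹ (Simpson
   truncation is the only error source). With fat present, the
   water–fat beat modulates the magnitudes (ΔTE is neither in- nor
   out-of-phase) and biases ARLO upward by several percent at
   PDFF ≈ 0.1; this mirrors acquisition reality and is why relaxometry
   validation uses fat-free specimens.
2. **Field initialization.** The mean inter-echo phase step per voxel is
   the argument of Σ_j S(t_j)·conj(S(t_{j+1})) — a magnitude-weighted
   phase-slope estimate immune to per-echo wraps — aliased at
   1/ΔTE = 370 Hz and resolved spatially with scikit-image's
   reliability-ordered phase unwrapper. The global 2π branch is pinned
   by the median against the wrapped map. This initializer replaces a
   joint unwrapping/chemical-shift solver; it only seeds the IDEAL fit.
3. **IDEAL.** Alternating closed-form complex least squares for (W, F)
   and a damped Gauss–Newton step on f, to |Δf| < 0.005 Hz or 50
   iterations. The alternation converges linearly (rate ≈ 0.7), so the
   step tolerance is kept well below the 0.1 Hz accuracy sought —
   stopping at |Δf| < 0.1 Hz would leave ≈ 0.2 Hz error. The residual is
   non-increasing at every voxel (steps are halved, then rejected, if
   they would increase it). R2\* is held at the ARLO estimate by default
   (well-posed at 8 echoes); `co_estimate_r2s=True` refines R2\* inside
   the fit and is used by the pipeline's PDFF output, because a fixed
   fat-beating-biased decay skews the W/F split (specimen-mean PDFF
   error up to 0.03 fixed vs ≤ 0.001 co-estimated on noiseless fatty
   specimens). PDFF = F/(W+F), zero where W+F = 0.
4. **Masking.** The specimen mask is R2\* ≥ 15 s⁻¹, eroded by a 3-D ball
   (default radius 1 voxel), optional exclusion regions (the programmatic
   stand-in for manual vessel/air-bubble erasure), largest connected
   component kept. The water-balloon mask in the pipeline is the largest
   low-R2\* (< 5 s⁻¹) high-signal component outside the specimen — a
   stand-in for manual delineation.
5. **QSM.** The dipole kernel is the Lorentz-corrected k-space form
   D(k) = 1/3 − (k·b₀)²/|k|², D(0) = 0; fields in Hz are
   larmor·10⁻⁶·F⁻¹[D·F[χ_ppm]] with zero-padding by half the grid per
   axis (configurable) to suppress wrap-around. Background removal is
   projection onto dipole fields (PDF): weighted least squares for
   sources supported outside the signal mask, solved with LSQR (the
   normal-equation CG stalls when the background support is large).
   Inversion is morphology-enabled (MEDI-style): minimize
   ‖w(f − d\*χ)‖₂² + λ‖M_E∇χ‖₁ with magnitude weights w normalized to
   unit mean, field in ppm units, and M_E excluding the top 30% of
   magnitude-gradient voxels; solved by IRLS with CG inner solves
   (defaults: λ = 10⁻³, 30 outer iterations, CG tol 10⁻³ — the IRLS loop
   must run to convergence; its early iterations are heavily smoothed
   and stopping there biases specimen means). The map is referenced to
   the water-balloon mean (exactly zero after referencing).

   On the λ convention: the default λ = 10⁻³ applies to the objective
   written above (field in ppm, unit-mean weights). Conventions that
   place a large constant (≈10³) on the data term are equivalent up to
   rescaling; the value quoted here belongs to this package's scaling.

## Source separation

Total susceptibility decomposes as χ = χ⁺ + χ⁻ with χ⁺ ≥ 0 and χ⁻ ≤ 0,
and both magnitudes add to static dephasing through one tissue constant
r (Hz/ppm):

R2\* ≈ r·(χ⁺ + |χ⁻|).

(The source-separation literature writes χ = χ⁺ − χ⁻ with χ⁻ a
magnitude; storing χ⁻ as a signed non-positive field reconciles that
with the field term d\*(χ⁺+χ⁻) and the sign-clipping rule. The reported
biomarker is |χ⁻|.)

* **Rapid per-voxel split** — exact inversion of the 2×2 system:
  χ⁺ = (R2\*/r + χ)/2, |χ⁻| = (R2\*/r − χ)/2, negative values reset to
  zero, then averaged over the specimen mask (clip-then-average). Used
  inside the decay-constant search where ~10⁴ evaluations are needed.
* **Regularized separation** — joint minimization of an R2\*-consistency
  term, a dipole-field term, edge-aware L1 smoothness on χ⁺+χ⁻ (weight
  2λ₁) and on each source (λ₁ each, R2\*-derived edge mask), and a
  balloon-homogeneity penalty (λ₂, balloon means recomputed from the
  current iterate each outer iteration). Both data terms are normalized
  to unit value at the zero iterate so w₁ = w₂ = 1, λ₁ = 10⁻³,
  λ₂ = 10⁻¹ are scale-free defaults; the L1 and balloon terms are
  normalized by their voxel counts. Solved by IRLS/CG on the stacked
  (χ⁺, χ⁻) system; the objective is non-increasing across outer
  iterations by construction (a non-decreasing step reverts and stops).
  Sign clipping is applied after optimization (switchable to
  per-iteration projection). On noiseless phantoms at the generating r,
  specimen means are recovered within ≈5% (χ⁺) and ≈5–11% (|χ⁻|); a
  residual non-susceptibility baseline b in R2\* biases |χ⁻| upward by
  exactly b/2r, so model validation uses source-dominated conditions.

## Learning the dephasing constant

r is unknown for liver and is learned by minimizing the joint log-loss
of three one-feature logistic models — F0–1 vs F2–3, F2–3 vs F4, F0–1 vs
F4 — where the feature is the specimen-mean |χ⁻| from the rapid split at
candidate r. The search is exhaustive over r ∈ [50, 300] Hz/ppm, step 1
(ties resolve to the smallest r and are flagged). Logistic fits are
ridge-penalized (10⁻⁴ on the slope of the within-fold z-scored feature)
so the loss stays finite under perfect separation — unavoidable at
N ≈ 20 — and are solved by a damped Newton iteration vectorized across
the whole r grid (grid × leave-one-out needs ≈15,000 fits; scikit-learn
and scipy refits serve as independent oracles in the tests). To avoid
double dipping, leave-one-out cross-validation assigns each sample the r
learned from the other N−1 samples; each sample's final maps use its
fold's constant. The brain-literature default r = 262 Hz/ppm is computed
alongside for comparison.

Identifiability caveat: the grid criterion optimizes *discrimination*,
not parameter fit. The rapid-split feature at wrong r is
|χ⁻| + α(r)·χ⁺ (+ baseline terms) with α = (r_true/r − 1)/(r_true/r + 1),
so the search scans a one-parameter family of iron/fibrosis mixtures.
The minimum sits at the generating constant only when admixed iron is
pure between-sample noise for staging; when iron carries independent
stage information the optimum shifts toward smaller r. The default
synthetic cohort (below) is in the regime where the learned constant is
stable (LOOCV fold SD a few Hz/ppm) and close to, but not exactly at,
the generating value; the dedicated parameter-recovery design
(`CohortSpec.for_parameter_recovery`) makes iron a strong
stage-independent nuisance and recovers r_true = 150 within ±5 on ≈95%
of seeds.

## Statistics

Mann–Whitney U counts pairs with a > b plus half-ties, so
AUC = U/(n₁n₂) exactly (tie-aware). The default p-value is the
continuity-corrected normal approximation, μ = n₁n₂/2,
σ² = n₁n₂(n₁+n₂+1)/12 — at n = 10 vs 10 this reproduces published
AUC-to-p pairings (AUC 0.88 → p 0.0046, 0.83 → 0.014, 0.81 → 0.021,
0.80 → 0.026, 0.76 → 0.054, 0.65 → 0.27) to two significant figures; an
exact enumeration method is available. ROC curves sweep all thresholds;
the operating point maximizes the Youden index J = sens + spec − 1, ties
toward the lower cutoff; orientation auto-flips so AUC ≥ 0.5 and is
recorded. Spearman correlation is Pearson on mid-ranks. The staging
report emits pairwise group tests (F0–1 vs F2–3, F2–3 vs F4), the
treatment-relevant F0–2 vs F3–4 ROC table for all seven metrics
(|χ⁻| and χ⁺ at optimized and default r, R2\*, χ, PDFF %), Spearman vs
stage, and χ⁺ across iron-grade groups (none / I0–1 / I2–3). p-values
round to 2 significant figures, AUC to 2 decimals.

## The synthetic cohort

All test data come from a digital phantom: a slab specimen (superellipsoid,
emulating ~7×5×1.5 cm explant sections) inside a cylindrical agarose mold
with air outside and a spherical water balloon (χ = 0 reference) above the
slab. Fibrosis is diamagnetic texture — diffuse at stages 0–1, septa-like
bands at 2–3, a nodular lattice at stage 4 — whose specimen mean |χ⁻| is
drawn per stage from a lognormal matched to 0.11 ± 0.011, 0.12 ± 0.0077,
0.17 ± 0.049, 0.19 ± 0.013 and 0.42 ± 0.25 ppm for F0…F4 (specimen means
are positive and right-skewed; for the low-SD stages the lognormal is
near-Gaussian). Iron is a diffuse paramagnetic load with mild granular
modulation, drawn from heavily right-skewed lognormals with stage-rising
means (0.15/0.15/0.35/0.35/0.8 ppm, SD 0.5): most low-stage samples carry
trace iron (grade "none"), cirrhotic samples are usually loaded, matching
the rising prevalence of stainable iron with stage while iron grade — not
stage — drives the paramagnetic magnitude. A stage-independent baseline
dephasing (15 ± 3 s⁻¹ between specimens; fixation, microstructure) adds to
R2\* = baseline + r_true·(χ⁺+|χ⁻|) with r_true = 150 Hz/ppm. Fat fraction
is drawn per stage (1–8% for F0–2, 5–18% for F3–4). Echo noise is complex
Gaussian, SD 1% of the mean first-echo specimen magnitude. Cohort counts
are 3/2/5/2/8 for F0…F4 (5/7/8 across the F0–1/F2–3/F4 groups).

Under these defaults, across 50-seed replicate blocks: the LOOCV-learned
r is stable (fold SD ≈ 7 Hz/ppm, cohort means ≈ 115–150); |χ⁻| at the
learned r matches or beats |χ⁻| at the default 262 Hz/ppm on all three
stage-pair AUCs in ≈82–84% of replicates; Spearman(|χ⁻|, stage) > 0.5 in
≥ 98%. The default-r biomarker subtracts ≈0.21·χ⁺ from the feature, which
both adds iron noise and removes stage-correlated signal — the mechanism
behind its inferiority here.

Two study-scale choices: per-sample maps for cohort-level analyses are
generated at 32³ (`make_metric_cohort` adds measurement noise directly to
the true R2\*/χ maps, bypassing echo simulation — appropriate wherever
only specimen-level metrics matter); full echo-level reconstruction runs
at the 48×48×32 study grid. The 48×48×32 grid (rather than a flatter
64×64×32 FOV at the same 32 slices) keeps the slab's aspect ratio closer
to the real specimens; see the limitation below.

What the phantom does **not** emulate: multi-peak fat spectra, coil
sensitivities, k-space sampling and partial-volume effects,
formalin-fixation R2\* drift beyond a random baseline, vessels/air
bubbles (available but off by default), and any spatial correlation
between histology-sampled subregions and the imaged volume. Passing
tests therefore validate the algorithm chain and its statistical
behaviour under the stated generative model, not clinical performance.

## Known limitations

* **Background-removal leakage at desk scale.** The component of the
  specimen's field that is harmonic over the balloon/agarose regions can
  be mimicked by sources outside the signal mask, so the projection
  absorbs part of it (4–9% RMS over the specimen across realizations;
  worse for flat, FOV-filling specimens). Balloon referencing cancels
  most of the resulting shared shading — a quantitative argument for the
  balloon protocol itself — leaving a few-percent specimen-mean χ error
  at the 48×48×32 study grid, but up to tens of percent for strongly
  flattened geometry. Polynomial detrending, mask erosion,
  background-support gaps and alternating background re-estimation were
  evaluated and do not remove the effect; it shrinks with FOV margins.
* **Eq.-3 additivity.** The dephasing model ignores cross-terms between
  sources, fat–iron interference and voxel-size nonlinearity; a residual
  non-susceptibility baseline b biases |χ⁻| by b/2r.
* **Learned r is condition-specific.** The log-loss optimum depends on
  the cohort's iron/fibrosis joint distribution (see identifiability
  caveat); transferring a learned constant across acquisition or tissue
  conditions is not supported by the synthetic evidence here.
* **Small-N statistics.** With 20 samples, ROC/AUC values move in steps
  of ~0.01–0.03 and the Youden operating point is volatile; the package
  reports them as the field does, but replicate-level properties are the
  more meaningful validation currency.
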