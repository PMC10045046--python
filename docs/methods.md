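# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic phantoms do and do not
emulate, and the design decisions taken where the design was genuinely
open.

## Synthetic phantoms

Each phantom is a square grayscale slice (default 64 px, 1 mm/px) holding
one centered nodule on a constant lung-field background (level 60, optional
low-frequency gradient).  The nodule is an **area-preserving ellipse**
(axis ratio drawn uniformly in [1, 1.4]) whose polar boundary radius is
perturbed sinusoidally,

r(θ) = r_ellipse(θ) · (1 + 0.35·s·sin(9θ + φ)),

where s ∈ [0, 1] is the spiculation level.  The 9-lobe odd harmonic avoids
alignment with the ellipse axes; the amplitude 0.35 at s = 1 roughly
doubles the perimeter at constant area, matching the visual scale of
strongly spiculated nodules.  The binary mask is the set of pixels inside
r(θ); the intensity image adds the contrast (default 100) inside the mask,
applies a mild Gaussian blur (σ = 0.7 px) as a partial-volume stand-in, and
optionally adds i.i.d. Gaussian noise.  Intensities follow an 8-bit-like
scale so noise σ of 10–20 corresponds to visibly noisy low-dose CT.

Sensor vectors are drawn from class-conditional Gaussians
(benign mean 0, malignant mean 3, σ = 1, 5 dimensions): the tabular device
channel has no published content, so this is a declared stand-in chosen to
be separably informative and nothing more.

Per-sample seeds derive from the master seed by a counter-based rule
(`SeedSequence(master, spawn_key=(index,))`), so datasets extend without
reshuffling existing samples.

The `separable_dataset` preset fixes the study condition used by the
classifier checks: 50/50 classes, benign 6–9 mm and nearly smooth,
malignant 13–17 mm and strongly spiculated, nodule contrast three times
the noise σ.  What passing tests on these phantoms shows is that the
pipeline's machinery (features, optimizer, network) works end to end; it
says nothing about performance on real CT, where nodule/parenchyma
contrast, anatomy clutter and annotation noise are far harsher.
Non-goals: anatomically realistic lungs, 3-D nodule growth.

## Denoiser

One-level separable wavelet decomposition (default `sym4`, an 8-tap
orthogonal wavelet) in **periodization mode**, so subband shapes are
⌈dim/2⌉ and the transform is orthonormal (Parseval holds to 1e−12,
reconstruction to 1e−8, both tested).

Per subband the BayesShrink quantities are: σ_N from the finest subband
(HH/HHH) via the MAD estimator median(|coeffs|)/0.6745 — the absolute
value matters, a signed median of detail coefficients is ≈ 0; σ_y as the
RMS of the subband; σ_s = √max(σ_y² − σ_N², 0); T_B = σ_N²/σ_s.  When
σ_s = 0 the subband is indistinguishable from pure noise and T_B is set to
max|coeff| (shrink-all sentinel).

The modifier Υ(β) is the printed rational curve fit; β defaults to the
subband's own MAD noise deviation with a global override available.  Υ is
negative for β < ≈0.038, so the collaborative threshold uses |Υ|; a
negative threshold has no meaning.

Collaborative filtering processes each detail subband: reference blocks
(8×8, stride 4, last row/column always covered) are matched by squared
distance within a ±16 px window; the best 16 blocks (the reference always
included — with tied distances a plain argsort could drop it and leave
pixels uncovered) are stacked and 3-D DCT-transformed; coefficients below
T_B·|Υ|·√(2 log N²) (N = 64 pixels per block) are zeroed (hard) or shrunk
(soft), the group DC coefficient is exempt; inverse transforms are
aggregated with weights 1/(1 + #retained).  The approximation subband
passes through untouched: its coefficients carry the image mean structure
and are not sparse, so shrinkage there only removes signal.  3-D subbands
are processed slice by slice (blocks and matching stay in-plane).  The
Wiener refinement stage of full BM3D is deliberately out of scope.

Filtering accuracy (1/MSE)·100 is unbounded as MSE → 0; the MSE is floored
at 1e−12 (cap 1e14) and an exact match raises a warning.

A Taylor-series view of a 3-D frame motivates treating subband
coefficients as local derivative information, but assigns no operational
step; it is documented here and not implemented.

## Preprocessing

Z-score with the population standard deviation followed by min–max
rescaling to [0, 1]: the plain Z-score cannot satisfy a unit-range
contract, the affine rescale preserves both the standardization intent and
the range; the combined map is invariant to positive affine transforms of
the input (property-tested).  Constant images map to 0.5.

Relative entropy uses log base 2 (bits).  Zero bins are floored at
ε = 1e−12 and both vectors renormalized, keeping the divergence finite and
non-negative (Gibbs); floating-point residues are clamped at 0.  The
square-root variant is exactly √D_RE, selected by a flag.  The frame scan
compares each frame to the **last kept** frame, not its immediate
predecessor, so a long run of near-duplicates collapses to one
representative; the first frame is always kept and the output is a
subsequence (idempotence is tested).  CT slices are treated as a single
ordered sequence; no shot segmentation is attempted.

## Features

GLCM: quantization to 8 levels by min–max over the masked region (integer
images already within range pass through), offsets
{(0,1), (1,0), (1,1), (1,−1)} symmetrized and averaged.  Texture formulas
are the standard Haralick forms — contrast Σp(i−j)², correlation as the
normalized cross-moment, homogeneity Σp/(1+|i−j|), entropy −Σp log₂p —
with correlation reported as an undefined marker when a marginal variance
vanishes.  Equivalence with a brute-force double loop is tested to 1e−10
on 100 random images, and against `skimage.feature.graycomatrix` as an
independent cross-check.

Shape: area = pixel count · spacing²; the boundary is an 8-connected Moore
trace through pixel centers (ties clockwise from north).  The closed
pixel-center polygon underestimates the region's boundary by about
2π·(1/2) — it traces the r−½ contour of a digital disk — so the traced
perimeter Q adds a +π·spacing correction.  Circularity = 4πA/Q²;
roundness = 4πA/L² with L the weighted Freeman perimeter estimate, which
is less biased on smooth digital shapes.  Discrete masks can still exceed
the continuous isoperimetric bound slightly; tests allow circularity up to
1.15.  Aspect ratio is the best-fit-ellipse major/minor axis ratio
(degenerate masks report 1.0).

Intensity: first-order statistics of the masked pixels.  The 3rd/4th
moments are *central but not standardized*, matching the histogram-moment
definitions used throughout; uniformity is histogram energy ΣH² over 256
equal-width bins; smoothness 1 − 1/(1+σ²) is scale-dependent by
construction.

Semantic: diameter 2√(A/π) in mm; size bins (−∞,4], (4,7], (7,20], (20,∞)
mm with boundary diameters in the lower bin; spiculation is the artifact
convention clamp01(1 − circularity); morphology thresholds are spiculation
≥ 0.45 → Spiculated, < 0.2 → Smooth/Lobulated split at aspect ratio 1.25,
else Irregular.  Upper-lobe location is not computable from a patch and is
passed through as metadata.  The named-but-undefined spectral/spatial
entropy variants and "sum of square variance" are intentionally not
computed.

## Classifier

Input modes: 32×32 or 64×64 image patches (3 conv layers of 3×3 same-pad
filters (8, 16, 16), each followed by ReLU and 2×2 max-pool, then a
fully-connected softmax), 1-D feature vectors (dense ReLU stack of the
same depth, hidden widths (32, 16)), and fusion (sensor vector
concatenated onto the flattened features entering the final layer).
Training is categorical cross-entropy with Adam (lr 1e−3, β 0.9/0.999),
batch size 1, 5 epochs, per-epoch seeded shuffling; the epoch loss is the
mean over batches.  Everything is NumPy, so a fixed seed gives
bit-identical initializations, loss histories and predictions; the
analytic gradients are verified against central finite differences to
1e−4 relative (they agree to ~1e−10).  Input images should be normalized
(the pipeline Z-scores them); input sizes must be divisible by the pooling
depth.  Splits are stratified 80/20 with largest-remainder per-class
allocation so |train| = round(0.8·n) exactly.  Prediction can abstain when
the class-distribution entropy exceeds a bound in bits.  The per-class
prior components count(class)/total are retained as a diagnostic.
Non-goals: transfer learning, augmentation, GPU training.

## PSO

Canonical inertia-weighted form V ← wV + c₁r₁(pbest−p) + c₂r₂(gbest−p)
with w = 0.85, c₁ = c₂ = 2, 10 particles, r₁/r₂ per dimension per
particle, positions clamped to bounds, gbest updated immediately
(asynchronously).  Because c₁+c₂ = 4 exceeds the stability bound 2(1+w),
a *fixed* velocity cap leaves the swarm oscillating around the optimum; the
cap is therefore annealed — half the dimension range shrunk by w per
iteration — which preserves early exploration and restores late
convergence without introducing any constant beyond those above (sphere
benchmark: optimality gap ~1e−4 in 30 iterations).  Integer dimensions
stay continuous inside the swarm and are rounded at decode time;
categorical dimensions index their choice list.  Non-finite objective
values skip the particle with a warning.  Fitness is 1 − RMSE of predicted
probabilities against one-hot targets (bounded above by 1); a 1 − MSE
variant sits behind a flag.  During hyperparameter search each candidate
trains for 2 epochs; the final refit uses the full epoch budget.  Both the
default 10-iteration setting and larger presets are plain arguments,
nothing is hard-coded.

## Evaluation

Sensitivity is TP/(TP+FN) — the recall of the diseased — and the F-score
is the harmonic mean of precision and sensitivity; the accuracy identity
acc·n = sens·P + spec·N is property-tested.  Any metric with a zero
denominator is reported as an explicit `None`/"undefined", never a silent
0.  The learning-curve generator parameterizes over the **training-set**
size with a fixed 20% test reserve, which resolves the otherwise ambiguous
"number of instances" axis.

## Problem sizes and determinism

All test and acceptance workloads are sized for a single CPU: 64×64
phantoms (20 per noise level) for the denoiser benefit check, 32³ volumes
for noise-sigma recovery, 120 samples at 32×32 for classifier sanity, 80
samples with feature-vector input for the tuning comparisons.  Every
stochastic step takes an explicit seed; the acceptance script threads one
`--seed` through all of them.

## Known limitations

Phantoms are far easier than clinical CT (high contrast, clean
backgrounds, exact masks); the collaborative filter is the
single-pass thresholding stage only; the spiculation score is a proxy
(1 − circularity), not a clinically validated measure; DICOM support
covers single-slice secondary-capture round trips, not full series
semantics; the CNN is deliberately small and CPU-bound.
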