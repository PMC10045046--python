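# lungcad

A small, fully tested lung-nodule computer-aided-diagnosis (CAD) pipeline
for grayscale CT slices, exercised end to end on synthetic phantoms.  It is
aimed at researchers who want a reproducible, CPU-only reference
implementation of a classical CAD stack:

1. **Denoising** — one-level wavelet decomposition into subbands
   (LL…HH in 2-D, LLL…HHH in 3-D), a BayesShrink-style adaptive threshold
   per subband

   σ_N = median(|SB_finest|)/0.6745,  σ_s = √max(σ_y² − σ_N², 0),  T_B = σ_N²/σ_s,

   a curve-fitted threshold modifier
   Υ(β) = (p₁β² + p₂β + p₃)/(β + q) with p₁ = 0.9592, p₂ = 3.648,
   p₃ = −0.138, q = 0.1245, and a block-matching collaborative filter that
   stacks similar patches, 3-D DCT-transforms the stack and hard/soft
   thresholds coefficients at T_B·|Υ|·√(2 log N²).  The denoising score is
   the *filtering accuracy* (1/MSE)·100.
2. **Preprocessing** — Z-score intensity normalization rescaled to [0, 1]
   and redundant-frame elimination by relative entropy (KL divergence,
   bits) between 256-bin intensity histograms of consecutive slices.
3. **Features** — GLCM texture statistics (contrast, correlation,
   homogeneity, entropy), mask shape descriptors (area, aspect ratio,
   roundness and circularity 4πA/P², traced perimeter), first-order
   intensity statistics, and semantic attributes (size bin, diameter,
   spiculation score, morphology category).
4. **Classification** — a compact multi-layer CNN
   (3 × [conv → ReLU → max-pool] → fully connected softmax) written in
   NumPy with manual backprop and Adam, trained at batch size 1 for 5
   epochs; feature-vector and sensor-fusion input paths are provided.
5. **Hyperparameter tuning** — inertia-weighted particle swarm
   optimization (w = 0.85, c₁ = c₂ = 2, 10 particles) maximizing the
   fitness 1 − RMSE(one-hot truth, predicted probabilities).
6. **Evaluation** — accuracy, sensitivity, specificity, precision and
   F-score from confusion counts, with explicit "undefined" markers for
   zero denominators.

Real LIDC-IDRI / LISS data are *not* required: the `phantoms` module
generates CT-like slices with one elliptical (benign) or spiculated
(malignant) nodule per image, additive Gaussian noise and class-conditional
sensor vectors, all bit-reproducible from a seed.

## Worked example

```bash
python examples/02_denoise_phantom.py
```

```
MSE vs clean:   noisy  226.33   denoised   59.98
filtering accuracy: noisy 0.442%   denoised 1.667%
estimated noise sigma from finest subband: 14.87 (true 15.0)
```

The phantom was corrupted with σ = 15 Gaussian noise; the denoiser removes
roughly three quarters of the noise energy (MSE 226 → 60, filtering
accuracy ×3.8) and the MAD estimator recovers the injected noise level to
within 1%.  The other scripts in `examples/` walk through phantom
generation, frame filtering, feature extraction, classifier training
(`examples/05`: 96/24 stratified split, epoch losses falling
0.65 → 0.02, all held-out metrics 100% on the separable set) and PSO
tuning (`examples/06`: sphere optimality gap ≈ 1e-4, non-decreasing
gbest trace).

A thin CLI wraps the same library calls:

```bash
lungcad simulate --n 60 --out ds/
lungcad features --in ds/manifest.csv --out features.csv
lungcad pipeline --out run/ --n 60 --seed 0
```

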