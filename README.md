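# flrw — feature-learning-based random-walk liver segmentation

Segmenting the liver in contrast-enhanced CT is hard precisely where it
matters: stomach, heart, and subcostal fat share the liver's attenuation, so
any method driven by intensity alone bleeds across those boundaries.  `flrw`
implements a pipeline that injects *texture* into the seeded random walker:

1. **Per-pixel texture features.**  Every pixel x is described by the window
   concatenation f(x) = [f_LBP ; f_GLCM ; f_Haar ; f_HOG] — local binary
   pattern codes, twelve Haralick-style co-occurrence statistics, fifteen
   Haar rectangle filters, and a gradient-orientation histogram
   (157 dimensions at the default 11×11 window).
2. **PCA fusion.**  Features are centred and projected onto the leading
   eigenvectors of the training covariance, y = U_D^T (f − f̄).
3. **AdaBoost of RBF-SVMs.**  Weak SVMs h_t with shrinking kernel width are
   boosted (α_t = ½ ln((1−e_t)/e_t), weights renormalized each cycle); the
   margin C(y) = Σ_t α_t h_t(y) becomes a per-pixel liver probability
   p(l=1|x) = e^C/(1+e^C) — the *probability image*.
4. **Automatic seeds.**  The histogram mode inside the liver's gray band
   ([125, 155] by default) anchors thresholds s1 = peak−39, s2 = peak+26;
   strict thresholding, erosion, and a largest-component step produce liver
   and background seeds.
5. **Probability-aware random walker.**  Lattice edges are weighted
   ω_ij = exp(−β[(1−α)(T_i−T_j)² + α(p_i−p_j)²]) with β = 150, α = 0.5; the
   walker potential solves the graph-Laplacian Dirichlet problem
   argmin_x x^T L x with seeds as boundary values, and pixels with x > ½ are
   liver.  α = 0 recovers the classic intensity-only walker (the RW
   baseline).
6. **Evaluation.**  Dice/ACC, VOE, RVD, FN, FP (volumetric, %), ASD, RMSE,
   MSD (surface distances, mm), and the MICCAI 2007 calibration
   S = max(100 − 25 ε/ε̄, 0) in which a reference human rater scores 75.

Because the method's claim is about texture, the package ships a synthetic
phantom generator whose "liver" and adjacent "confuser" share their mean
intensity but not their texture — the exact failure mode the probability
term repairs — so the entire pipeline is testable without any scan data.

## Worked example

`examples/segment_and_evaluate.py` trains on three phantoms and segments a
held-out one with and without the texture term:

```
RW   (alpha=0.0): Dice  96.45%  VOE  6.86%  RVD  0.00%  ASD 1.50mm  MSD 19.65mm  -> total score 69.6
FLRW (alpha=0.5): Dice  99.39%  VOE  1.21%  RVD  0.71%  ASD 0.24mm  MSD 1.41mm  -> total score 95.4
```

The intensity-only walker (RW) leaks into the confuser organ through their
shared-intensity contact and loses about three Dice points; the
probability-aware weights (FLRW) close that leak and every error measure
drops.  The other scripts in `examples/` demonstrate the phantom generator,
the probability image, the automatic seeding chain, and the score
calibration, each printing what its numbers mean.

A thin CLI mirrors the library:

```sh
flrw phantom --n 15 --out data/ --seed 7
flrw train   --images data/phantom000.mhd ... --masks data/phantom000_mask.mhd ... --out model.flrw
flrw segment --image data/phantom010.mhd --model model.flrw --out seg.mhd
flrw evaluate --gold data/phantom010_mask.mhd --pred seg.mhd --report report.json
flrw sweep   --image data/phantom010.mhd --gold data/phantom010_mask.mhd --model model.flrw --out sweep.csv
```

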