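# Methods

This note defines every estimator and rule the package applies, in the
order the pipeline runs them.

## 1. Parameter grid

Nine investigation groups vary one acquisition/reconstruction parameter
at a time around a common reference setting (3 min acquisition, 256
matrix, no z-filter, 5 mm Gaussian post-filter, TOF-OSEM with 2
iterations × 28 subsets):

| group | varied parameter | levels |
|---|---|---|
| acquisition_time | minutes | 1, 1.5, 2, 3, 4, 5, 6, 8, 10, 12.5, 15 |
| matrix_size | voxels | 128, 192, 256, 384 |
| z_filter | kernel label | None, Light, Standard, Heavy |
| gaussian_filter | FWHM mm | 0 … 10 in 0.5 steps |
| bpl_beta | penalty β | 50 … 1000 (13 levels) |
| osem_updates | iterations × subsets | {1,2,3,4,5,6,8,10} × {16,28,32} |
| osem_iterations | iterations | 8 levels, averaged over subsets |
| osem_subsets | subsets | 3 levels, averaged over iterations |
| algorithm | categorical | OSEM, TOF-OSEM, OSEM+PSF, TOF-OSEM+PSF, BPL, TOF-BPL |

94 settings in total. The z-filter labels are encoded None→1, Light→2,
Standard→4, Heavy→6. Before any function fitting, the numeric level
axis is rescaled so every value is positive and never exactly 1
(required by the log and 1/log candidate functions): acquisition time,
encoded z-filter weight and iteration counts are multiplied by 10; the
Gaussian FWHM is shifted by +2 mm; all other axes pass through.

## 2. Digital phantom and reconstruction surrogate

The phantom is a NEMA-IQ-style arrangement: six spheres of 37, 28, 22,
17, 13 and 10 mm diameter, coplanar on a 114.4 mm ring, at 20 kBq/mL on
a 5 kBq/mL background (4:1), around a 50 mm cold lung-insert cylinder.
The label map adds two 30 mm background sample VOIs and a 25 mm lung
VOI — nine regions. Rasterization supersamples boundary voxels 4× per
axis, so the 4:1 contrast is exact on interior voxels and partial-volume
mixtures appear only at boundaries.

Reconstruction is modelled in image space: (i) resampling to the target
matrix; (ii) Gaussian smoothing whose FWHM combines, in quadrature, the
system resolution (4 mm, sharpened by a 1.05 factor when PSF modelling
is on), the configured post-filter, and a BPL term
7·exp(−β/350) mm; (iii) a normalized 3-tap axial kernel for the
z-filter, heavier labels smoothing more; (iv) additive Gaussian noise
with σ = σ₀ · (t/3 min)^(−1/2) · (updates/56)^(1/2), scaled by 0.85
under TOF. All randomness flows from named `SeedSequence` substreams of
one master seed.

## 3. Feature extraction

Each VOI yields the fixed 107-feature set (shape 14, first-order 18,
GLCM 24, GLDM 14, GLRLM 16, GLSZM 16, NGTDM 5), computed natively in
IBSI style: intensities are discretized into 64 fixed bins between the
VOI minimum and maximum; co-occurrence (single-voxel offset) and
run-length matrices are computed for the 13 unique 3D directions and
averaged; size-zone zones use 26-connectivity; dependence counts use the
26-neighbourhood at zero tolerance; shape features come from a marching
cubes mesh at the 0.5 iso-level of the padded mask. A VOI too small or
too uniform to support a family yields `valid = False` records with a
reason; the filter then removes that (feature, region) pair from the
entire group so every downstream regions × levels matrix is complete.

## 4. Robustness classification

For one feature and group, let v(r, s) be its value in region r at
level s.

* Per-region CV: 100 · SD_s(v)/|mean_s(v)| (sample SD). Regions whose
  mean is within 1e−8 of zero relative to the SD are flagged and
  excluded from the mean — percentage CV is meaningless at a zero
  crossing.
* CV_mean: arithmetic mean of the unflagged per-region CVs.
* ICC: two-way, absolute-agreement, single-measurement intraclass
  correlation from the ANOVA mean squares,
  (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),
  with regions as subjects (n) and levels as raters (k). Negative
  estimates are reported as computed; degenerate (constant) matrices
  give NaN.
* Gate: robust ⇔ CV_mean < 10 **and** ICC > 0.90. A NaN on either
  side classifies as non-robust.

## 5. Parametric correction

For each non-robust feature × group (the categorical algorithm group is
excluded), the level means across regions are fitted with all eight
candidates f(x) = α·g(x) + β, g ∈ {x, x², x³, 1/x, 1/x², 1/x³, log x,
1/log x}, by closed-form weighted least squares. Weights are intrinsic:
the inverse of the across-region variance at each level, capped at 10⁶
times their median so a zero-variance level cannot dominate. Candidates
are ranked by AIC = n·ln(RSS_w/n) + 2k with k = 3; ties resolve to the
earlier family in the fixed order. The correction rearranges the fit:
corrected(r, s) = (v(r, s) − β̂)/g(x_s). Outcome categories:

* **correctable** — the per-region CVs drop significantly (one-sided
  Wilcoxon signed-rank, post < pre, α = 0.05), the ICC point estimate
  improves, and the corrected feature passes the robustness gate;
* **moderately correctable** — significant CV drop and ICC improvement
  without passing the gate;
* **not correctable** — otherwise.

The correction exactly flattens data generated by its own model class
(region-specific α, shared β, zero noise); with region-specific offsets
a residual (β_r − β̂)/g(x) term remains, which the Wilcoxon gate then
judges on its merits.

## 6. Mixed-effects attribution

Per feature × group, a linear mixed model value ~ parameter + volume +
intensity (all z-scored) is fitted with a per-region random intercept
and a random slope in the parameter (REML). Volume is the VOI mesh
volume and intensity its mean uptake, both taken from the same
extraction records per (region, level). For the categorical algorithm
group, the parameter enters as fixed level contrasts with random
intercepts only, and its reported coefficient (the largest-magnitude
contrast) is flagged non-comparable to the numeric groups. Significance
uses the engine's large-sample Wald p-values at α = 0.05, and each
record carries a convergence flag.

## 7. Study summaries

* **Predicted probabilities.** A Bayesian binomial mixed model
  logit P(robust) = group level + feature random intercept (variational
  Bayes with fixed, deterministic start values) yields each feature's
  predicted probability per group; the median and interquartile range
  are reported, with degenerate (all-0/all-1) levels flagged.
* **Pairwise group tests.** Robustness-outcome distributions of two
  groups are compared with the two-sample Cramér–von Mises statistic on
  midranks. When the number of splits C(N, n) ≤ 10⁵ the permutation
  null is enumerated exactly; otherwise p = (b + 1)/(n_perm + 1) from
  seeded random permutations (default 9999). P-values are
  Bonferroni-adjusted over the group pairs.
* **Odds ratios.** Per group, the per-feature significance indicators of
  the three fixed effects enter a logistic mixed model
  significant ~ effect type + feature random intercept; the
  volume-vs-parameter and intensity-vs-parameter contrasts are reported
  as odds ratios with Wald 95% intervals, flagged when complete
  separation makes the interval unbounded.

## 8. Reproducibility

Every stochastic stage draws from `numpy.random.SeedSequence(master,
spawn_key=(stage, group, level))`. Two pipeline runs with the same
master seed produce byte-identical CSV outputs; the manifest records
stage counts and library versions.
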