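# radiorobust

Robustness analysis of PET radiomic features across acquisition and
reconstruction settings, on a fully synthetic, reproducible test bed.

## The problem

Radiomic features — quantitative descriptors of intensity, shape and
texture computed over a volume of interest (VOI) — are candidate imaging
biomarkers, but their values shift when the image acquisition or
reconstruction protocol changes. A feature that is not *robust* to such
protocol variation cannot transfer between scanners or studies. This
package implements the complete analysis workflow of a phantom-based
robustness study of [18F]-FDG-PET radiomics:

1. **Parameter grid** (`radiorobust.grid`) — nine investigation groups
   spanning 94 setting variations: acquisition time (11 levels), matrix
   size (4), z-axis filter (4), Gaussian post-filter FWHM (21), BPL
   penalty β (13), OSEM update combinations (24), plus iterations (8)
   and subsets (3) aggregated from the update grid, and six
   reconstruction algorithms (OSEM / TOF-OSEM / ±PSF / BPL / TOF-BPL).
2. **Digital phantom** (`radiorobust.phantom`) — a NEMA-IQ-style phantom
   (six spheres 10–37 mm at 20 kBq/mL on a 4:1 sphere-to-background
   ratio, a cold lung insert, two background sample VOIs) rasterized
   with 4× boundary supersampling, and an image-domain surrogate for
   reconstruction effects: resolution changes combined in quadrature,
   z-kernel smoothing, and Gaussian noise scaling as
   t^(−1/2)·(updates/56)^(1/2), attenuated by TOF.
3. **Feature extraction** (`radiorobust.extraction`,
   `radiorobust.features`) — a native IBSI-style extractor computing the
   fixed 107-feature set per VOI (shape 14, first-order 18, GLCM 24,
   GLDM 14, GLRLM 16, GLSZM 16, NGTDM 5) with 64 fixed intensity bins
   and texture matrices averaged over the 13 unique 3D directions.
4. **Robustness classification** (`radiorobust.robustness`) — a feature
   is robust to a group's variation when the mean across regions of its
   per-region percentage CV stays below 10% **and** the two-way
   absolute-agreement single-measurement ICC exceeds 0.90.
5. **Parametric correction** (`radiorobust.correction`) — non-robust
   features are fitted against the (rescaled) setting value with eight
   candidate functions f(x) = α·g(x) + β,
   g ∈ {x, x², x³, 1/x, 1/x², 1/x³, log x, 1/log x}, by weighted least
   squares with AIC model selection; the rearranged correction
   (value − β)/g(x) is applied and its CV reduction gated by a
   one-sided Wilcoxon signed-rank test, yielding *correctable* /
   *moderately correctable* / *not correctable* outcomes.
6. **Effect attribution** (`radiorobust.effects`) — linear mixed-effects
   models (value ~ parameter + volume + intensity, per-region random
   intercept and slope) separate genuine parameter dependence from
   region size and intensity effects.
7. **Study summaries** (`radiorobust.summaries`) — logistic mixed models
   give per-group predicted probabilities of robustness; groups are
   compared with a permutation two-sample Cramér–von Mises test
   (Bonferroni-adjusted) and volume/intensity-vs-parameter odds ratios.

`radiorobust.pipeline.run_all` chains all stages into one seeded,
byte-reproducible run; the `radiorobust` console script exposes each
stage on the command line.

## Worked example

Simulate four z-filter reconstructions of the digital phantom, extract
the 107 features per VOI, classify robustness and attempt correction:

```python
import pandas as pd
from radiorobust import (
    PhantomSpec, SettingSpec, EffectModel, build_activity_map,
    make_voi_masks, simulate_reconstruction, extract_features,
    RobustnessModel, CorrectionModel,
)

phantom = PhantomSpec(axial_extent=120.0)
activity = build_activity_map(phantom, matrix_size=256)
masks, _ = make_voi_masks(phantom, matrix_size=256)

records = []
for i, zf in enumerate(["None", "Light", "Standard", "Heavy"]):
    recon = simulate_reconstruction(activity, SettingSpec(z_filter=zf),
                                    EffectModel(), seed=i)
    frame = extract_features(recon, masks)
    frame["group"] = "z_filter"
    frame["level"] = zf
    frame["x_value"] = float({"None": 1, "Light": 2,
                              "Standard": 4, "Heavy": 6}[zf])
    records.append(frame)
table = pd.concat(records, ignore_index=True)

robustness = RobustnessModel(table).fit()
print(robustness.frame["robust"].value_counts().to_string())
print(robustness.frame[robustness.frame.feature == "first-order_Mean"]
      [["feature", "cv_mean", "icc", "robust"]].to_string(index=False))

correction = CorrectionModel(table, robustness).fit()
print(correction.summary().to_string(index=False))
```

Output:

```text
robust
True     67
False    40
         feature    cv_mean      icc  robust
first-order_Mean 281.321456 0.999307   False
   group        category  n
z_filter not correctable 40
```

67 of the 107 features tolerate the z-filter sweep. `first-order_Mean`
fails the CV gate despite an excellent ICC because the cold lung insert
has near-zero mean activity, which inflates percentage CVs — exactly the
kind of region-dependent fragility the study is designed to expose. With
only four noisy levels, none of the 40 non-robust features passes the
Wilcoxon-gated correction here; longer sweeps (e.g. the 21-level
Gaussian filter group) give the correction engine more to work with.

The full pipeline over any subset of groups:

```bash
radiorobust run --seed 2024 --out study_run
# or per stage:
radiorobust grid --list
radiorobust simulate --matrix 256 --seed 0 --out sim/
radiorobust extract --image sim/image.nii.gz --mask sim/labels.nii.gz --out features.csv
```

`run` writes `features.csv`, `robustness.csv`, `corrections.csv`,
`fits.csv`, `effects.csv`, `pp_robustness.csv`,
`pairwise_robustness.csv`, `odds_ratios.csv` and a `manifest.json` with
stage counts and library versions. Two runs with the same master seed
produce byte-identical CSVs.

## Reproduction

```bash
# unit + acceptance tests
python -m pytest -q tests/

# recompute the headline quantities from scratch (about 45 s)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script re-derives, from nothing but the given seed: the
94-setting grid size, the 107-feature extraction count, the phantom's
4:1 interior activity ratio, the AIC family-recovery rate of the
correction engine, the ICC-vs-ANOVA oracle gap, the null calibration of
the Cramér–von Mises test and of the mixed-model intensity effect, and
the byte-identity of two identically seeded pipeline runs.

## Documentation

See `docs/methods.md` for the statistical methods note (definitions,
estimators, gating rules and the reconstruction surrogate's closed
forms).
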