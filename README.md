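# repeatomics

Test–retest repeatability analysis of radiomic features in prostate
multiparametric MRI (mpMRI).

Quantitative imaging features extracted from delineated lesions are only
useful as biomarkers if they are *repeatable*: a feature measured twice on
the same patient, with no interim treatment, should agree. `repeatomics`
implements a complete repeatability pipeline for paired (test/retest)
prostate mpMRI — a T2-weighted volume and an ADC map per scan, with a
prostate-gland mask and lesion masks — and a synthetic phantom generator so
every stage runs and is testable without any patient data.

The pipeline:

1. **Standardization** — per scan and per modality, intensities are
   z-scored against the whole gland: `(v − μ_gland) / σ_gland`.
2. **Habitat convergence** — from each lesion, two low-ADC "habitat"
   sub-regions resembling aggressive (restricted-diffusion) tumor:
   a 15-mm sphere around the lesion centroid thresholded at `μ − k·σ` of
   local ADC and clipped to the gland, and the largest contiguous
   within-lesion region at or below the median lesion ADC.
3. **Feature extraction** — a 307-feature IBSI-aligned signature per region
   and modality: C1 size/shape (45), C2 intensity, histogram and
   texture-matrix features — GLCM, GLRLM, GLSZM, NGTDM (107), C3 filter-bank
   textures — 125 Laws kernel triples and 30 undecimated Haar wavelet
   subband features (155).
4. **Repeatability screening** — per feature, Lin's concordance correlation
   coefficient across the cohort,

       CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²),

   and the dynamic range

       DR = 1 − mean|Test_i − Retest_i| / (Max − Min),

   with the pooled test∪retest range in the denominator. A feature passes a
   cutoff c when **both** CCC ≥ c and DR ≥ c.
5. **Redundancy reduction** — features passing the base cutoff are grouped
   by R² (squared Pearson correlation of subject-wise test/retest-averaged
   values); each group keeps its highest-DR representative, applied greedily
   and recursively at R² cutoffs 0.99 and 0.95.

The result is a summary table of reproducible, non-redundant feature counts
at joint cutoffs 0.65…0.95 with one column per region variant × modality
(raw/z-scored × radiologist/habitat), plus the ranked selected-feature lists.

## Worked example

```python
from repeatomics import (PhantomConfig, RepeatabilityModel,
                         extract_cohort_features, generate_phantom_cohort)

cases = generate_phantom_cohort(PhantomConfig(n_patients=10, seed=7))
fm, _ = extract_cohort_features(
    cases, variants=("radiologist_raw", "habitat_sphere_raw"),
    modalities=("ADC",))
results = RepeatabilityModel(fm).fit()
print(results.summary(rsq_cutoff=0.99))
```

prints

```
region_variant habitat_sphere_raw radiologist_raw
modality                      ADC             ADC
ccc_and_dr
>=0.95                         22               7
>=0.90                         97              46
>=0.85                        141              87
>=0.80                        173             115
>=0.75                        194             122
>=0.70                        213             139
>=0.65                        221             151
```

Each cell counts features that survived redundancy reduction (R² ≥ 0.99) of
the CCC-and-DR ≥ 0.65 set and whose CCC and DR also reach the row's cutoff;
columns nest monotonically by construction. On this phantom the sphere
habitat yields more repeatable ADC features than the radiologist-drawn
region — delineation jitter perturbs the lesion boundary, while the habitat
re-converges onto the same low-ADC anatomy at both timepoints. Shape
features fare worst under boundary jitter, e.g.

```
F52:Vol-(mm^3)  CCC = 0.259  DR = 0.764
```

fails the joint 0.65 cutoff on CCC despite an acceptable dynamic range.
(A 10-patient phantom is far more optimistic than a real 15-lesion cohort:
the phantom's between-patient spread is controlled and its noise Gaussian,
so many more features pass than would on patient data.)

There is also a CLI:

```bash
repeatomics catalog --out catalog.json           # the 307-feature catalog
repeatomics simulate --mode phantom --out cohort --patients 10 --seed 7
repeatomics run --manifest cohort/manifest.json --out results --seed 7
```

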