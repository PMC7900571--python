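# carthick

Knee articular cartilage thickness from segmentation label volumes, with
WORMS region parcellation and cohort statistics.

Given 3-D integer label volumes (NIfTI) of the femur, tibia, patella and
their cartilages — from any segmentation source — `carthick` measures
per-point cartilage thickness, averages it over the 14 WORMS regions
(FMA … FLP, TMA … TLP, PM, PL), and analyses region thickness across a
cohort: all-pairwise Tukey comparisons and age × sex / age × laterality
interaction regressions. A synthetic module supplies knee phantoms with
analytically known thickness and cohorts calibrated to published
healthy-knee region statistics, so the whole pipeline is testable without
any image data.

## The method

Thickness is measured by a signed-distance / gradient dot-product scheme.
With signed Euclidean distance fields d_B (bone) and d_C (cartilage),
negative inside and positive outside, each cartilage boundary voxel is
classified by the sign of ∇d_B · ∇d_C: negative means the boundary faces
the bone (**inner**, the bone–cartilage interface), positive means it faces
away (**outer**, the articular surface). Thickness at every inner point is
read from a distance map seeded at the outer points, with a sub-voxel
surface correction (see `docs/methods.md`). All distances are in physical
mm on anisotropic grids (e.g. 0.5 × 0.5 mm in-plane, 3 mm slices).

Cohort statistics follow the classical program: Tukey simultaneous 95% CIs
from the studentized-range distribution for all pairwise region/sex/side
mean differences (a pair is significant iff its interval excludes zero),
and OLS fits thickness ~ age + condition + age:condition, where the
interaction coefficient is the difference between condition-specific age
slopes and its p-value below 0.05 declares the age trend inconsistent
between conditions.

## Worked example

```python
import carthick as ct

# phantom knee with known 2.0 mm femoral shell, measured end to end
vol, truth = ct.make_phantom(ct.default_knee_spec())
record = ct.run_subject(vol)
print(record.round(2))
```

```
FMA    1.88
FMC    1.88
FMP    1.88
FLA    1.88
FLC    1.88
FLP    1.88
TMA    1.48
TMC    1.45
TMP    1.48
TLA    1.48
TLC    1.45
TLP    1.48
PM     1.77
PL     1.82
Name: thickness_mm, dtype: float64
```

The femoral regions recover the true 2.0 mm shell to within ~0.1 mm, the
tibial regions the true 1.5 mm shell to within ~0.05 mm; the patellar
facet (true 2.2 mm) is a short arc whose free edges pull its mean down —
all within the one-in-plane-voxel accuracy the voxelisation supports.

```python
# calibrated synthetic cohort, n = 2,481: region comparisons
from carthick.stats import get_comparison, tukey_pairwise

df = ct.make_cohort(ct.CohortSpec(seed=1))
long = df.melt(id_vars=["subject_id", "age", "sex", "side"],
               value_vars=list(ct.synthetic.REGION_NAMES),
               var_name="region", value_name="thickness")
cmp = get_comparison(tukey_pairwise(long, "region", "thickness"),
                     "FMA", "TMA")
print(f"FMA - TMA: {cmp.diff_of_means:.3f} mm "
      f"[{cmp.ci_low:.3f}, {cmp.ci_high:.3f}], significant={cmp.significant}")
```

```
FMA - TMA: 0.578 mm [0.561, 0.596], significant=True
```

i.e. medial anterior femoral cartilage is ≈ 0.58 mm thicker than medial
anterior tibial cartilage, with a simultaneous 95% CI excluding zero.

A CLI mirrors the stages (`carthick phantom | cohort | thickness | regions
| stats | dice | run-all`); exit codes are 0 success, 2 input error,
3 degenerate geometry.

## Layout

- `src/carthick/thickness.py` — distance fields, boundary classification, thickness
- `src/carthick/regions.py` — 14-region geometric atlas, alignment hook, point assignment
- `src/carthick/metrics.py` — Dice similarity coefficient and reports
- `src/carthick/stats.py` — Tukey comparisons, interaction regressions, CI bands
- `src/carthick/synthetic.py` — phantoms, cohorts, mask perturbation
- `src/carthick/pipeline.py`, `cli.py` — orchestration and command line
- `docs/methods.md` — model, assumptions, numerical choices, limitations
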