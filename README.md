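# spinecurve

Automatic measurement of spinal curvature (the Cobb angle) from
anterior-posterior (AP) view spine radiographs.

Scoliosis severity is graded by the Cobb angle: the angle between the
upper endplate of the uppermost involved vertebra and the lower endplate
of the lowest involved vertebra. Manual measurement is slow and shows
substantial inter- and intra-observer variation, so `spinecurve`
implements a fully automatic pipeline:

1. **Spine ROI isolation** — the film is reduced to a quarter of its
   size; vertical and horizontal intensity-projection profiles locate
   the spinal column band (threshold mean + c·sd around the profile
   maximum) and the T1–L5 row range (skull-gap minimum above, pelvis
   discontinuity below).
2. **Vertebra detection** — maximum-intensity H×W windows (51×13 by
   default) trace central line segments down the spine; 11×5 sibling
   window pairs find the left/right spine boundaries, whose per-row
   midpoints form the central spinal curve (CSC). A progressive
   threshold ladder γ_t = 16·t, t = 1…15 binarises the outer thirds of
   the spine band; each threshold's empty projection bins vote,
   f_t(y) = [p_t(y) = 0], and the accumulated histogram
   P(y) = Σ_t f_t(y) separates dark intervertebral discs (many votes)
   from bright vertebrae (few), yielding the 17 vertebra boxes.
3. **Vertebra segmentation** — each 256×128 vertebra chip is segmented
   either by an encoder-decoder network (U-Net, Residual U-Net or
   Dense U-Net with concatenation skips, trained with Adam on an L2
   loss) or by a training-free classical segmenter (Otsu threshold +
   central-component selection). The networks are implemented in pure
   numpy with explicit backpropagation — no GPU framework required.
4. **Cobb angle** — each mask is reduced to its minimum-area bounding
   rectangle (MBR); the top/bottom edges stand in for the endplates and

   φ = max over pairs (a,b), b−a ≥ 2, of arctan |(m_a − m_b)/(1 + m_a·m_b)|

   gives the Cobb angle, signed negative when the curve bends rightward.
   Severity: <10° spinal curve, 10–20° mild, 20–40° moderate, >40° severe.

A **phantom generator** renders AP-like radiographs (17 stacked
vertebra-like quadrilaterals on a curved centerline with known endplate
tilts, soft-tissue torso, skull and pelvis landmarks, noise) with exact
analytic ground truth, so every stage is testable without clinical
data. A **statistics module** ships a 35-image expert/novice/automatic
measurement table and recomputes the observer-agreement battery
(descriptives, one-way ANOVA, Pearson, Spearman rank correlation, ICC).

## Worked example

```python
from spinecurve import generate_phantom, scoliotic_spec, measure_spine

sample = generate_phantom(scoliotic_spec(20.0, seed=3))
print(f"true Cobb angle: {sample.true_cobb_deg:+.1f} deg")

result = measure_spine(sample.image, segmenter="classical")
print(f"measured:        {result.phi:+.1f} deg ({result.severity}), "
      f"end vertebrae {result.upper_label}-{result.lower_label}")
```

prints

```
true Cobb angle: +19.1 deg
measured:        +17.9 deg (mild), end vertebrae T1-L4
```

i.e. the phantom was built to bow ~20° to the left; the full pipeline
(ROI → detection → classical segmentation → MBR) recovers the angle
within 1.2° here and within ±5° on ≥80% of phantoms spanning 5–45°. The same flow is available from the shell:

```sh
spinecurve simulate --n 5 --seed 1 --out phantoms/
spinecurve measure --in phantoms/phantom_000.png --out report.json
spinecurve stats --session 1 --out agreement.json
```

`agreement.json` contains, among others, the expert session-1 summary
−0.703 ± 12.552° and automatic-vs-expert correlations above 0.93,
meaning the rectangle-based automatic measurement agrees with the
expert about as well as the two human observers agree with each other.

## Testing

```sh
python -m pytest tests/
```
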