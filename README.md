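# spinemetrics

Quantitative assessment of lumbar spinal stenosis from segmented axial
MRI slices.

Given a six-class label image of an axial slice at disc level
(1 = Unregistered, 2 = intervertebral disc/IVD, 3 = posterior elements/PE,
4 = thecal sac/TS, 5 = the space between anterior and posterior vertebral
elements/AAP, 6 = Other) and the grayscale image it segments,
`spinemetrics`:

1. **refines the clinically important boundaries to sub-pixel precision**
   — the IVD boundary facing the canal (A2 = E23 ∪ E24 ∪ E25) and the PE
   top boundary (A3 = E23 ∪ E34 ∪ E35) — with a contour evolution on a
   *Modified Boundary Grid*: a (2H−1)×(2W−1) structure holding labels at
   odd/odd cells and Gaussian-smoothed image gradients at the interface
   cells between them.  Each boundary cell moves perpendicular to its
   interface to the position of maximal gradient magnitude within a
   search width *w*; sweeps repeat until the change count, averaged over
   *n* sweeps, drops below τ; *k* rounds of ×2 upsampling refine the
   boundary to the nearest 2^−(k+1) of a pixel.  Unlike classical active
   contours, the evolution applies **only to the selected region pairs**
   — every other boundary is left bitwise untouched.
2. **locates nine anatomical landmarks**: the foraminal bridge endpoints
   T_L, B_L, T_R, B_R (the shortest disc-to-PE segment on each side), the
   canal-arch apex B_M, the disc centroid D_C, the extremal canal-side
   disc point q = argmax_{z∈M_IVD}(|z·T̄_LT_R| − d(z, B_M)), the chord
   intersection p, and the projection q′ of q on the B_M–D_C line.
3. **measures** the left/right foraminal widths d(T_L,B_L), d(T_R,B_R)
   and the anteroposterior canal diameter d(B_M, q′) in mm, and **grades
   disc herniation** from the ratio r = d(B_M, q′)/d(B_M, p):
   normal if r ≥ 1.1, severe if r ≤ 0.8, minor in between.

A seeded **phantom generator** draws synthetic axial slices (kidney-shaped
disc with controllable herniation, PE arch with canal indentation and
articular horns, thecal sac, AAP space, frame) with every landmark and
measurement known analytically, plus an annotation-noise model (boundary
jitter, 1×1 holes), so the whole pipeline is testable without MRI data.
An **evaluation** module scores boundary accuracy (boundary-F1 at a
distance tolerance), landmark errors, intra-rater variation and
herniation-category agreement.

## Worked example

```python
import spinemetrics as sm

# a 200x200 phantom with a herniated disc (analytic ratio 0.72)
spec  = sm.solve_herniation_amplitude(sm.PhantomSpec.scaled(200, seed=7), 0.72)
study = sm.generate_phantom(spec)

result = sm.run_slice(study.composite, study.label,
                      sm.RunConfig(mm_per_pixel=spec.mm_per_pixel))
m = result.measurements
print(f"truth    r={study.truth_measurements.r:.3f}  category={study.truth_category}")
print(f"measured r={m.r:.3f}  category={m.category}")
print(f"d_L = {m.d_L:.2f} mm   d_R = {m.d_R:.2f} mm   d_AP = {m.d_AP:.2f} mm")
```

prints

```
truth    r=0.720  category=severe
measured r=0.719  category=severe
d_L = 4.07 mm   d_R = 4.21 mm   d_AP = 14.40 mm
```

The pipeline recovers the analytic herniation ratio of the phantom to
0.001 and grades the disc *severe* (r ≤ 0.8); the foraminal widths match
the designed 4 mm gaps to a fraction of a pixel (0.8 mm/px here).

## Command line

```bash
spinemetrics phantom  --n-studies 5 --seed 1 --out-dir cohort/
spinemetrics run      --image slice.tiff --label slice.png \
                      --spacing-mm 0.5 --out result.json --render overlay.png
spinemetrics batch    --manifest cohort/cohort-manifest.csv --out results.csv
spinemetrics evaluate --pred-label pred.png --gt-label gt.png \
                      --dt 1 --dt 2 --dt 3 --out report.json
spinemetrics show-config
```

Exit codes: 0 success, 2 label-schema violation, 3 required anatomy not
found, 4 evolution stopped at the sweep cap (result still written).

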