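# oscillocobb

Automatic Cobb angle measurement and Lenke classification of adolescent
idiopathic scoliosis (AIS) from vertebral corner landmarks, using
endplate-tilt **oscillograms**.

## Who this is for

Researchers and tool builders working on automated scoliosis assessment
who already have vertebral corner annotations — whether from a keypoint
detector or manual labelling — and need the downstream geometry and
classification: curve detection with end-vertebra identification, regional
Cobb angles, structural-curve determination from side-bending views, Lenke
typing, and the agreement statistics (MAE, ICC) used to validate such
systems against human raters.  The package deliberately consumes landmarks,
not pixels: no image I/O, no detector.

## The method

Each of the 17 vertebrae T1–L5 is annotated with its four body corners on up
to four views (coronal standing, sagittal, left/right side-bending).  For a
view, the tilt of every endplate is

```
theta_i = atan2(y_right - y_left, x_right - x_left)        i = 1 .. 34
```

in image coordinates (y down; positive tilt slopes down toward image-right).
The ordered sequence `theta_1 .. theta_34` (T1 superior → L5 inferior) is
the *oscillogram*.  A scoliotic curve appears as a peak–trough pair: the
end (terminal) vertebrae own the maximally opposed endplates, and

```
Cobb = theta_peak - theta_trough
```

Alternating peaks/troughs are found with a prominence-filtered scan;
adjacent pairs with at least `min_cobb` (default 10°) of height become
curves, assigned to the proximal-thoracic (PT), main-thoracic (MT) or
thoracolumbar/lumbar (TL/L) region by their apex vertebra.  A region with no
detected pair falls back to the max−min tilt over its span, so all three
regions always report a Cobb value.

Classification follows the bending-view rule: a minor curve is **structural**
iff its residual Cobb on side-bending stays strictly above 25°; the major
(largest) curve is structural by definition.  The structural pattern
(PT, MT, TL/L) plus the major region maps to Lenke types 1–6.  The sagittal
thoracic modifier comes from T5–T12 kyphosis,
`|theta(T12 inf) − theta(T5 sup)|`: "−" below 10°, "+" above 40°, "N"
between (strict at both boundaries).  The lumbar modifier is not computed —
it requires pelvic landmarks outside this data model.

A synthetic spine simulator (`oscillocobb.synthetic_spine`) generates
four-view landmark sets with analytically known ground truth for all six
Lenke patterns and drives the test suite; `oscillocobb.agreement_stats`
implements MAE and ICC(2,1) with F-based confidence intervals.

## Worked example

```python
import dataclasses
from oscillocobb import preset_for_type, simulate_case, measure_case, Region

params = dataclasses.replace(preset_for_type(1), landmark_noise_sd=1.5, seed=42)
views, truth = simulate_case(params)       # four-view synthetic Lenke-1 case
m = measure_case(views)
```

Running `python examples/01_measure_simulated_case.py` prints:

```
case preset-lenke1
   PT: Cobb  26.6 deg (T1 sup -> T6 sup, apex T4), bending residual  17.3 deg (right_bending)
   MT: Cobb  51.4 deg (T6 sup -> T12 sup, apex T9), bending residual  35.2 deg (right_bending)
  TLL: Cobb  22.8 deg (T12 sup -> L4 inf, apex L2), bending residual  15.7 deg (right_bending)
  T5-T12 kyphosis: 27.5 deg
  Lenke type 1, sagittal modifier 'N'
  simulator truth: type 1, MT Cobb 51.4 deg
```

The 51.4° main-thoracic curve stays above 25° on bending (35.2°), so it is
structural; PT and TL/L correct below 25°, so the case is Lenke type 1 with
a normal ("N") sagittal profile.  The other examples render the oscillogram
signatures of all six types, build an MAE/ICC agreement table, and exercise
the JSON/CSV landmark schemas.

There is also a thin CLI:

```bash
oscillocobb simulate --lenke-type 3 --n 5 --seed 7 --out-dir sim/
oscillocobb measure --coronal sim/<case>/coronal.json \
    --sagittal sim/<case>/sagittal.json \
    --left-bend sim/<case>/left_bending.json \
    --right-bend sim/<case>/right_bending.json \
    --out measurement.json --svg oscillogram.svg
oscillocobb evaluate --pred measurements/ --ref sim/ --out report.json
```

## Layout

- `src/oscillocobb/landmark_model.py` — annotation types, JSON/CSV I/O, validation
- `src/oscillocobb/oscillogram_geometry.py` — tilts, oscillograms, extrema, Cobb, case measurement
- `src/oscillocobb/lenke_classifier.py` — structural assessment, Lenke type, sagittal modifier
- `src/oscillocobb/synthetic_spine.py` — simulator with ground truth, presets for types 1–6
- `src/oscillocobb/agreement_stats.py` — MAE, ICC (six forms), case-set comparison reports
- `src/oscillocobb/cli.py` — `oscillocobb measure / simulate / evaluate / oscillogram`
- `docs/methods.md` — model, conventions, parameter choices, limitations
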