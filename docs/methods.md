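# Methods

## The oscillogram model

A landmark set gives the four body corners of each vertebra T1–L5 on one
radiographic view, in raster image coordinates (origin top-left, y grows
downward).  The tilt of an endplate through its two corner points is
`atan2(dy, dx)` in degrees, positive when the endplate slopes downward
toward image-right.  Because corner annotations keep the left corner
strictly left of the right corner, tilts live in (−90°, 90°); an exactly
vertical endplate is rejected as a degenerate annotation rather than mapped
to ±90°, since at radiograph scales it can only be a labelling mistake.

The *oscillogram* of a view is the ordered sequence of all 34 endplate
tilts, T1-superior first.  Its key property: a scoliotic curve's end
vertebrae carry the maximally opposed endplate tilts, so each curve is one
peak–trough pair and the pair's height difference is the curve's Cobb
angle.  The oscillogram is invariant under translation and uniform scaling
of the landmarks (hence pixel/millimetre units never need conversion), and
a global rotation of the image by φ shifts every tilt by φ.

"Left"/"right" always means image left/right.  Whether image-left is the
patient's left depends on the projection (AP vs PA), which annotations do
not record; patient side is therefore documented but never asserted, and
every classification output is invariant under left–right mirroring.

## Peak/trough detection

With only 34 samples, detection is a direct alternating-extrema scan, no
smoothing by default (a centered moving average is available via
`smoothing_window`, off by default because it systematically attenuates
peak heights and thus Cobb angles):

1. Turning points are collected with plateaus represented by their most
   cranial index; the first/last endplate is included when it extends a
   monotone run.  Strict alternation of peaks and troughs is automatic.
2. Prominence of an interior extremum is its smallest tilt difference to
   the adjacent extrema.  A *terminal* extremum (first/last of the list) is
   additionally measured against the neutral tilt of 0°: its prominence is
   `min(gap-to-neighbour, |value|)`.  A boundary endplate only counts as a
   curve terminus when it is meaningfully tilted — a spine that starts
   level at T1 does not begin with an end vertebra, while a monotone ramp
   from −20° to +20° genuinely has its termini at T1 and L5.
3. Sub-prominence extrema are pruned iteratively, smallest first: a
   terminal extremum is dropped alone; an interior one is dropped together
   with its closest neighbour, which preserves alternation and never
   discards a tilt outside the value band of the surviving neighbours.
   Ties break toward the cranial index, everywhere, so output is
   deterministic.

Default `min_prominence` is 5°, below typical inter-observer variability of
endplate selection; `min_cobb` is 10°, the conventional floor for calling a
curve scoliotic.

## Regions, curves, Cobb angles

Region spans (inclusive endplate indices): PT = T1-sup..T6-inf (0–11),
MT = T5-sup..T12-inf (8–23), TL/L = T10-sup..L4-inf (18–31).  They overlap
deliberately because adjacent curves share end vertebrae.  Two routes give a
region's Cobb:

- **Pair route** (primary): adjacent extremum pairs with height ≥
  `min_cobb` become candidate curves; each is assigned a region via its
  apex — the vertebra between the ends whose centroid lies farthest from
  the chord joining the end centroids (apex in T1–T5 → PT, T6–T11 → MT,
  T12–L5 → TL/L).  The largest candidate per region wins.
- **Span route** (fallback and oracle): max−min tilt over the region span.
  Regions with no candidate report this value, so a flat spine yields three
  zero-Cobb curves rather than an error.

Whenever a region's span contains exactly one detected pair, the two routes
agree exactly — the pruning rule above guarantees the series stays inside
the band of surviving extrema — and the pair route never exceeds the span
route.  Both properties are exercised over randomized synthetic spines in
the acceptance suite.

End vertebrae are reported as the vertebrae owning the extremal endplates,
with whichever surface the extremum falls on; the classical convention
(superior endplate of the upper end, inferior of the lower) is not forced,
because the oscillogram selects endplates, not vertebra surfaces.

Curve convexity is the side of the chord on which the apex centroid lies.

## Bending views, kyphosis, classification

Side-bending Cobb is re-detected freely on each bending view's own
oscillogram by default.  `lock_end_vertebrae_on_bending` instead evaluates
the coronal end endplates on the bending series; both are defensible, and
free re-detection was chosen as default because bending changes which
endplates are maximally tilted.  The per-region *residual* is the minimum
over available bending views — side-label-agnostic, matching the corrective
intent of bending radiographs (the film that corrects the curve is the one
that reveals its flexibility).

T5–T12 kyphosis is `|tilt(T12 inferior) − tilt(T5 superior)|` on the
sagittal oscillogram.

Structural rule: a minor curve is structural iff residual > 25° (strict,
so a residual of exactly 25° is nonstructural); the major curve — largest
coronal Cobb, with MT preferred over TL/L over PT on exact ties — is
structural by definition.  The (PT, MT, TL/L) structural pattern plus major
region maps to Lenke types:

| pattern | major | type |
|---|---|---|
| −, S, − | MT | 1 |
| S, S, − | MT | 2 |
| −, S, S | MT | 3 |
| S, S, S | MT or TL/L | 4 |
| −, −, S | TL/L | 5 |
| −, S, S | TL/L | 6 |

Any other pattern (e.g. structural PT only, or a PT major curve) returns a
null type with an explanatory note rather than a guess.  The sagittal
modifier is "−" below 10°, "+" above 40°, "N" otherwise, strict at both
boundaries so 10° and 40° map to "N".  The classical sagittal structural
criteria (T2–T5 and T10–L2 kyphosis ≥ 20° upgrading minor curves) are
available behind `canonical_lenke_sagittal_criteria` but off by default:
the bending rule alone defines structurality here.  The lumbar modifier
(A/B/C) is never computed; it needs the centre sacral vertical line, i.e.
pelvic landmarks absent from the data model, and is serialized as null.

## Synthetic spines

The simulator exists to give every other module a test bed with exact
ground truth.  The coronal tilt profile is a sum of signed
derivative-of-Gaussian bumps over the endplate coordinate t ∈ [0, 33]:

```
theta(t) = sum_k  s_k * A_k * u_k * exp((1 - u_k^2)/2),   u_k = (t - mu_k)/sigma_k
```

normalized so each bump's extrema are ±A_k at mu_k ± sigma_k.  One bump is
one curve: amplitude A (so an isolated curve has Cobb ≈ 2A), apex at mu,
end vertebrae near mu ± sigma, sign from the convexity side.  This form was
chosen because it controls the oscillogram shape directly, so the six
Lenke signatures are reproducible by construction.

Vertebral rectangles are placed cranial→caudal with the prescribed endplate
tilts; `wedging_fraction` (default 0.3) splits each vertebra's local tilt
between rigid rotation and endplate non-parallelism (vertebral wedging),
and centroids drift laterally with the local tilt so the apex is displaced
toward the convexity.  Bending views reuse the profile with each curve's
amplitude multiplied by (1 − flexibility) when the bend is toward its
convex side, unchanged otherwise — the simplest model that produces the
structural/nonstructural dichotomy.  The sagittal view is a smooth
kyphosis arc affinely rescaled so the realized T5–T12 angle hits the target
exactly, whatever the wedging fraction.  Isotropic Gaussian corner noise is
added last, seeded.

Ground truth (per-view regional Cobb, residuals, structural flags, type,
kyphosis, modifier) is computed from the *noise-free* tilt sequences with
the same span max−min oracle the measurement side uses as fallback, so on
noise-free landmarks the full pipeline reproduces truth to floating-point
precision — the core self-consistency property of the package.

Default geometry is pixels at a ~1460 px T1–L5 span (vertebra height 65 px,
width 90 px, disc 22 px — a full-spine radiograph scale), default corner
noise 1.5 px.  The six presets use canonical anchors (PT apex T3, MT apex
T9, TL/L apex L1, alternating convexity) with amplitudes and flexibilities
chosen so each preset's realized structural pattern matches its type with
at least ~8° of margin from the 25° switch point; adjacent curves share a
merged end-vertebra extremum, as in real multi-curve patterns.  The presets
approximate clinically typical magnitudes (main curves 45–80°, PT in
Lenke 1 around half the MT curve); no attempt is made to match any specific
cohort's joint distribution.

What the simulator does **not** emulate: rib/scapular occlusion and other
sagittal recognition artifacts, vertebral rotation, detector-specific
landmark error structure (noise here is i.i.d. Gaussian), coronal
imbalance, and transitional anatomy.  Passing tests therefore demonstrate
the correctness of the geometry, rules and statistics — not the performance
of any landmark detector on real radiographs.

## Agreement statistics

`mae` returns the mean and sample SD (n−1) of absolute paired differences.
`icc` implements all six classical forms from the two-way ANOVA mean
squares; the default ICC(2,1) (two-way random effects, absolute agreement,
single measure) is the standard for method-comparison designs because it
counts systematic offsets between raters against agreement.  Confidence
limits use the F-distribution formulation (Satterthwaite degrees of freedom
for the absolute-agreement forms); average-measure forms apply the
Spearman–Brown step-up to the single-measure limits.  A constant matrix has
an undefined ICC and is reported as 1.0 with a warning.  ICC on
integer-coded Lenke types replicates common practice in this literature but
is statistically questionable; a warning is logged and unweighted Cohen's
kappa is reported alongside.  Missing indicator values are dropped listwise
per indicator with logged counts; nothing is imputed.

## Numerical and scale choices

- All tie-breaks (span argmax/argmin, apex selection, extremum pruning,
  major-curve ties) resolve toward the cranial index / thoracic region, so
  every output is deterministic given inputs and config.
- Noise-free recovery is asserted at 1e-6° (observed ~1e-13°); landmark
  JSON/CSV round-trips are exact because coordinates are coerced to Python
  floats whose repr round-trips.
- Test and acceptance problem sizes — 500 randomized spines for the oracle
  equivalence sweep, 300 mixed-preset cases at 2 px noise for recovery —
  keep the whole suite under a few seconds while giving Monte-Carlo
  standard errors well below the asserted margins (the noisy mean absolute
  Cobb error is ~2.6–2.8° across seeds against a 3° bound, and type
  accuracy is ≥99% against a 90% bound).

## Known limitations

- No pixel-level processing: the package starts where a landmark detector
  ends, and its accuracy on real radiographs is bounded by that detector.
- The lumbar modifier and vertebral rotation (Nash–Moe), coronal balance
  and CSVL are out of scope of the landmark data model.
- Lenke typing requires bending views and the sagittal modifier requires
  the sagittal view; absent views yield nulls with notes, never guesses.
- ICC confidence intervals assume the usual normal-theory ANOVA model;
  for the integer-coded type they are at best descriptive.
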