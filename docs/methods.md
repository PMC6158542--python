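# Methods

This note documents the models behind `isletquant`: what each one assumes,
the defaults and why, the numerical choices, and what the synthetic
generators do and do not capture about real islet preparations.

## The IEQ and its binned estimator

One islet equivalent (IEQ) is the volume of a 150 μm sphere, so an islet of
diameter *d* carries exactly (d/150)³ IEQ.  The classic counting procedure
assigns each islet to a 50 μm diameter bin (50–100, …, 300–350, >350 μm) and
multiplies bin counts by per-bin factors.  Because the numeric factor table
was never standardised in print, the package derives factors from the
definition in two dialects:

- **midpoint** (default): factor = ((lo+hi)/2 / 150)³ — the IEQ of the bin's
  midpoint diameter.
- **mean_volume**: factor = (hi⁴ − lo⁴)/(4·(hi−lo)·150³) — the expected IEQ
  of a diameter uniform on [lo, hi).  By convexity of the cube this always
  exceeds the midpoint factor; the two dialects bracket defensible readings
  of "a unique factor that converts the islet number and diameter into IEQs".

Neither dialect claims bit-compatibility with any laboratory's legacy table;
`ieq_binned` accepts a custom factor mapping for that purpose.  Boundary
rule is half-open [lo, hi): a 100 μm islet is in 100–150.  The open top bin
(">350") uses its dialect factor over [350, 400) by default (configurable via
`top_bin_width`).  The optional sub-50 μm bin spans [20, 50) μm — 20 μm is the
floor of the calibrated diameter→cells conversion range — and islets below
20 μm are always excluded.

As bin width shrinks, both dialects converge to the exact-diameter total for
any batch.  The *midpoint* gap shrinks as O(width²) when within-bin
diameters are uniform; for finite random batches the signed gap can cross
zero, so convergence — not monotone gap shrinkage — is the guaranteed
property.

## Diameter conventions

When two to four axes are measured per islet, the representative diameter
defaults to the **arithmetic mean of the axes** (configurable: major axis or
equal-volume diameter).  Circularity is defined only on 2-D projections
(4πA/P², capped at 1.0 to absorb pixel-discretisation overshoot); no 3-D
sphericity is computed.  All lengths are μm throughout; unit conversion
happens only at I/O boundaries (CSV columns carry `_um` suffixes).

## Cell-number calibration (diameter → cells)

The conversion curve is a power law cells(d) = α·d^β fitted by ordinary
least squares on log–log axes, with a quadratic-in-log alternative for
curvature checks.  A power law is the minimal strictly monotone form that
can encode sub-cubic scaling (β < 3), i.e. the observation that small islets
carry disproportionately many cells for their nominal volume; when β < 3 the
cell share of sub-50 μm islets always exceeds their IEQ volume share.
Fitting requires ≥ 10 islets with ≥ 1 cell spanning ≥ 2 size bins.

The shipped default curves are **synthetic calibrations for simulation, not
clinical conversion tables** (the published conversion spreadsheets'
coefficients are not public):

- rat: β = 2.6; α anchored so the mean cell density E[cells/d] over the rat
  size distribution equals 3.5 cells/μm (the bench value from dissociating
  individually measured rat islets).  The anchoring integral is evaluated by
  quadrature over the truncated lognormal, so the constant is deterministic.
- human: β = 2.6; α anchored so cells(150 μm) = 1560, the estimated cell
  content of one IEQ.

Density statistics report mean ± SEM of per-islet cells/diameter ratios;
`percent_underestimation(a, b) = 100·(1 − b/a)` compares actual-diameter
against binned-diameter densities (3.5 → 2.8 cells/μm is a 20%
underestimate).  Predictions are rounded to integers per islet; share
computations use the continuous curve so the β = 3 case reproduces volume
shares exactly.

## Synthetic prep generator

**Diameters.** Lognormal matched by moments to the species profile's
(mean, sd) and truncated to its published range; lognormal because diameters
are positive and right-skewed.  The shipped profiles mirror published
per-species summaries (human 108 ± 6 μm over 30–>400; rat 115 ± 5 over
30–350; adult pig 156 ± 8 over 50–250; …).  Those sd values are
across-study spreads of the *mean*, so the generated preps are much narrower
than a real prep's islet-to-islet spread; consequences: (i) a generated rat
prep concentrates in the 100–150 μm bin, which makes binning bias vivid,
and (ii) heavy-tail phenomena (a few giant islets dominating volume) are not
reproduced at the default profiles.  Passing a custom `SpeciesProfile` with
a prep-level sd restores the broad case.  The goat profile ships
range-only (its published summary prints a range in mean ± sd position) and
refuses to sample without explicit moments.

**Shape.** Axis ratios b/a and c/a are independent N(0.82, 0.05²) and
N(0.70, 0.05²) clipped to (0.05, 1]; the larger draw becomes b/a so that
a ≥ b ≥ c.  The 0.05 ratio spread is a modelling choice (published values are
means only).  The major axis follows from the mean-axes convention:
a = 3d/(1 + b/a + c/a).

**Projected outline and circularity.** The projection is the (a, b) ellipse:
area πab/4 exactly, perimeter from the complete elliptic integral
(`scipy.special.ellipe`).  Boundary irregularity multiplies the perimeter by
1 + m·|ε| with ε ~ N(0, 1).  The magnitude m is solved per size class (brentq
on a Gauss–Hermite expectation, 64 nodes) so the *expected* mean circularity
equals the class target: 0.801 for islets below 125 μm, 0.740 above —
reproducing the observation that large islets are less circular.  The
125 μm small/large cutoff is configurable (100 μm is also in use in the
literature).  Solved magnitudes are cached; targets above the smooth-ellipse
expectation (~0.984 at default ratios) are rejected as unreachable.

**Cells.** Poisson with mean from the calibration curve, so integer counts
carry realistic counting noise.

**Seeding.** One seed per prep; diameters, shapes, and cell counts each use
an independent child stream of a `SeedSequence`, so preps are
bit-reproducible and adding islets does not reshuffle earlier stages.

## Technician mis-binning model

Each islet's true bin shifts one bin up with probability `p_upbin`, one down
with `p_downbin`; shifts beyond the lowest or top bin leave the assignment
unchanged.  Two calibrations are of interest:

- `calibrate_technician` (the default calibration): total mis-binning rate
  0.4 (the package's own choice of a plausibly sloppy operator; the split,
  not the rate, is the calibrated quantity) divided between up and down so
  the *expected* batch IEQ change is zero.  A replicate count's error is then
  a near-symmetric sum of many per-islet shifts, so roughly half of
  replicate counts overestimate the truth — the multicenter repeat-count
  phenomenon.  Because up-shifts gain more IEQ than down-shifts lose
  (factors grow cubically), the zero-mean split is down-leaning
  (p_down > p_up); mild skew leaves the overestimation fraction near, not
  exactly at, 0.5.
- an over-estimating operator (e.g. p_up = 0.3, p_down = 0.05, the
  `demo-flaws` default): reproduces the bench finding that staff
  over-estimate diameters during binning, deflating apparent cell density
  when counts are normalised to the bin diameter.

## Aliquot sampling

Islets settle fast, so a pipetted aliquot is a biased sample.
`simulate_aliquot` draws ⌈fraction·n⌉ islets without replacement with weight
∝ d^bias using Gumbel-perturbed order sampling (equivalent to sequential
probability-proportional-to-weight draws).  Bias 0 is uniform — the scaled
total IEQ estimator is then unbiased; positive bias enriches large islets
and inflates volume estimates.  The model captures composition bias only,
not pipetting volume error or islet fragmentation.

## Imaging

Rendering places each islet's projected ellipse (random orientation, smooth
low-harmonic radial roughness of amplitude 0.05) on a jittered grid sized so
objects never touch, colours it from a red-hue HSV model with per-islet
stain-intensity jitter (deep red to pink), and adds brown exocrine blobs
until the islet share of tissue area matches the prep's purity.  Colour
models are synthetic conventions chosen to be separable, not measured stain
spectra.  Segmentation is deliberately the classical pipeline — saturation
threshold for tissue, hue threshold (split at 0.045) for islet vs exocrine,
connected components, 20 μm minimum equivalent diameter — because the goal
is an oracle-testable counting pipeline, not state-of-the-art segmentation.
Touching objects are *not* split (no watershed by default): merged islets
are a documented error source, and the region count (always ≤ the true
count) keeps the merging visible.  Diameters are recovered from region area
(equivalent diameter); at 2 μm/px the round-trip median diameter error is
rasterisation-limited (< 5 μm) and ≥ 95% of islets ≥ 30 μm are detected.
Purity is the islet-classified fraction of segmented tissue area and is
scale-invariant.

## Dose–outcome analysis

Outcomes are ordered failure < partial response < normal glycemia.  A group
is *fully successful* only at 100% normal glycemia; threshold operations
(minimum fully-successful dose, maximum incomplete dose) use that strict
reading, so a 33/33/33 mixed group counts as incomplete.  The monotonicity
check ranks groups by expected outcome score (category index weighted by
fractions) and flags every pair where a dose less than or equal to another's
has a strictly better outcome — including equal doses with different
outcomes, the signature of a dose metric that fails to determine outcome.
On the bundled canine→mouse reference series, cell dose is monotone
(threshold between 5.13 and 6.17 M cells) while IEQ dose is not (2500 IEQ
appears with both partial and fully normal outcomes); the overlap of the two
threshold ranges under IEQ is reported, never hidden.

## Problem sizes and tolerances

Statistical test fixtures use the sizes at which the checked quantities are
comfortably resolved: 10³–10⁴ islets for distribution moments and
circularity targets (mean circularity within ±0.01 at n = 10³), 350 islets ×
Poisson counts for density (±0.1 cells/μm), 100 replicate calibrations at
n = 300 for exponent recovery (median |β̂ − β| < 0.05), 200 replicate counts
for the overestimation fraction (±0.05), 500 aliquot replicates for
unbiasedness, and 50 rendered preps of 50 islets at 2 μm/px for imaging
round trips.

## Known limitations

- Default species sd values are across-study spreads (see above); generated
  preps are narrower than real ones.
- The default calibration curves are synthetic anchors, not fitted clinical
  conversions; β = 2.6 encodes sub-cubic scaling qualitatively.
- No in-situ (pancreas section) morphometry, no isolation enzymology, no
  viability or function modelling, no instrument-specific factor tables.
- Rendering never overlaps objects, so segmentation merging must be induced
  deliberately (e.g. by shrinking the field); real crowded preps merge more.
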