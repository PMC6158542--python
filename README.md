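# isletquant

Quantifying the volume of isolated pancreatic islets is deceptively hard:
islets span 20–400+ μm in diameter, are rarely spherical, settle quickly in
liquid, and are counted by eye against a 50 μm grid.  The field's standard
unit, the **islet equivalent (IEQ)** — the tissue volume of a perfect 150 μm
sphere, so an islet of diameter *d* is worth (d/150)³ IEQ — is in practice
computed by *binning* islets into 50 μm diameter categories and multiplying
each bin's count by a per-bin factor, a procedure with well-documented
reliability problems.

`isletquant` is a toolkit for researchers and islet-isolation labs who want
to compute these quantities rigorously and to measure how much each step of
the procedure distorts them.  It provides:

- **Morphometry** — sphere/ellipsoid volumes, equal-area equivalent diameter,
  2-D circularity 4πA/P².
- **IEQ estimation** — exact-diameter IEQ and Ricordi-style binned IEQ with
  two factor dialects (bin-midpoint and uniform-bin mean volume), optional
  sub-50 μm bin, and custom legacy factor tables.
- **Cell-number conversion** — a power-law calibration curve
  cells(d) = α·d^β fitted from single-islet dissociation counts, the
  cells-per-IEQ constant (1560 cells = 1 IEQ), and the density statistics
  (cells per μm of diameter) that expose binning bias.
- **Synthetic preps** — species-parameterised ground-truth generators
  (lognormal diameters, ellipsoidal shapes with b/a ≈ 0.82 and c/a ≈ 0.70,
  size-dependent circularity, Poisson dissociation counts), a technician
  mis-binning model, and settling-biased aliquot sampling.
- **Imaging** — synthetic dithizone-stained brightfield rendering (red
  islets, brown exocrine tissue) and the matching digital counting pipeline:
  hue-threshold segmentation, per-region morphometry, purity estimation.
- **Dose analysis** — transplant dose–outcome thresholds and monotonicity
  checks comparing cell-number dosing against IEQ dosing.

## Worked example

Simulate a 500-islet rat prep, then count it both ways:

```bash
isletquant simulate --species rat --n 500 --seed 7 --out prep.csv --truth-json truth.json
isletquant count --table prep.csv --scheme exact
isletquant count --table prep.csv --dialect midpoint
```

The exact-diameter count returns the true volume:

```json
{"n_islets": 500, "scheme": "exact", "total_ieq": 225.296}
```

The binned count of the *same* islets reports 289.35 IEQ: every islet in
this prep (mean diameter ≈ 115 μm) lands in the 100–150 μm bin, whose
midpoint factor is (125/150)³ ≈ 0.5787, so the narrow size distribution is
overestimated by ~28%.  Binning error is not an abstraction — it is the gap
between those two numbers.

The end-to-end flaw demonstration simulates the dissociation experiment that
quantifies the bias as a cell density:

```bash
isletquant demo-flaws --species rat --n 350 --seed 7
```

```json
{
  "density_actual_cells_per_um": 3.489,
  "density_binned_cells_per_um": 3.062,
  "percent_underestimation": 12.2,
  ...
}
```

Dividing each islet's dissociated cell count by its *measured* diameter
gives ≈ 3.5 cells/μm; dividing by the 50 μm bin diameter assigned by a
technician who over-estimates sizes 30% of the time deflates the apparent
density — the same signature seen at the bench.

Library use mirrors the CLI:

```python
import isletquant as iq

prep = iq.sample_prep("rat", 500, seed=7)
batch = prep.to_batch()
print(iq.ieq_exact_total(batch))               # 225.296
print(iq.ieq_binned(batch).total_ieq)          # 289.352
print(iq.cells_from_ieq(1.0))                  # 1560
```

## Documentation

See `docs/methods.md` for the models, their assumptions, default parameter
values, and known limitations of the synthetic generators.
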