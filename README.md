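# osmech

Optical-stretcher mechanophenotyping of single cells: active/passive
Kelvin–Voigt analysis of step-stress creep curves, synthetic cohort
generation with known ground truth, axis tracking from phase-contrast
frames, per-cell feature assembly, and random-forest discrimination of
circulating-tumor-cell (CTC) candidates from peripheral blood mononuclear
cells (PBMC).

## The problem

A dual-beam optical stretcher applies a contact-free step stress σ₀ (order
1 Pa, set linearly by laser power: 0.38 Pa and 80 pN at 400 mW) to a
suspended cell for a stretch duration T, then drops back to trapping power
while the cell relaxes. From the tracked long/short axes two deformation
signals are derived — the relative deformation d(t) = (L−L₀)/L₀ and the
elliptic deformation ε(t) = (L/S)/e₀ − 1, which captures the Poisson
effect. Each stretch-phase curve is fitted with a Kelvin–Voigt solid
extended by an active contractility term,

    η γ′(t) + E γ(t) = max(σ₀ − a·t, 0),   γ(0) = 0,

giving the elastic modulus E (Pa), viscosity η (Pa·s), relaxation time
τ = η/E and activity a (Pa/s); a cell is *active* when a > 0.001 Pa/s.
Shape restoration R = d(T) − d(T + 1.5 s) quantifies elastic recoil after
the step. Morphology (effective radius, area, relative brightness, resting
ellipticity, degree of rotation), deformation scalars, all fit parameters
and the laser power form a per-cell feature matrix that a random forest
uses to discriminate CTC candidates from PBMC, with permutation
importances, KS-test comparisons and fold-enrichment summaries rounding
out the analysis. A seeded synthetic-data module simulates complete
cohorts (axis traces, optionally rendered frame stacks) from known ground
truth, so the whole pipeline is testable end to end. See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
import osmech as m

# a seeded synthetic cohort: 200 PBMC-like + 200 CTC-candidate-like cells,
# each measured at 400, 800 or 1200 mW (chosen at random per cell)
bundle = m.run_pipeline({"n_per_class": 200,
                         "rf": {"n_trees": 200, "cv_repeats": 2}}, seed=7)

med = bundle["summary"].medians
print(med[["relative_def_end_stretch", "elliptic_def_end_stretch",
           "shape_restoration"]].round(4))
rep = bundle["classification"]
print(f"RF accuracy {rep.accuracy:.2f}  sensitivity {rep.sensitivity:.2f} "
      f"specificity {rep.specificity:.2f}")
ks = bundle["ks_tables"]
pooled = ks[ks.scope == "pooled"]
print(pooled[["metric", "D", "p_value", "stars"]].to_string(index=False))
```

prints

```
               relative_def_end_stretch  elliptic_def_end_stretch  shape_restoration
PBMC                             0.0157                    0.0224             0.0072
CTC_candidate                    0.0102                    0.0117             0.0089
RF accuracy 0.87  sensitivity 0.85 specificity 0.88
                  metric     D      p_value stars
relative_def_end_stretch 0.215 1.547968e-04   ***
elliptic_def_end_stretch 0.300 1.771987e-08   ***
       shape_restoration 0.150 1.983924e-02     *
```

The PBMC-like class deforms elliptically about twice as much as the
CTC-candidate class (0.0224 vs 0.0117 at the end of the stretch) while the
CTC class restores more of its shape during relaxation (0.0089 vs 0.0072)
— the two direction-of-effect signatures the preset encodes — and the
forest separates the classes well above chance. Being population medians
of broadly overlapping distributions, the exact values and the modest
restoration gap shift from seed to seed. The same stages are
available from the shell:

```bash
osmech simulate --out sim/ --seed 42 --n-per-class 50
osmech fit --traces sim/traces.csv --protocol sim/protocol_0.json --out fits.csv
osmech featurize --traces sim/traces.csv --protocol sim/protocol_0.json \
       --truth sim/ground_truth.csv --out matrix.csv
osmech classify --matrix matrix.csv --schema matrix.schema.json --out report.json
osmech run --out bundle/ --seed 42
osmech enrichment --proportions 3.26 0.25   # fold=13.04 headline=13
```

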