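# lignoquant

Quantitative in situ chemical imaging of lignified plant cell walls.

Lignin — the phenolic polymer that stiffens and waterproofs vascular
tissue — is deposited with cell-type- and wall-layer-specific
concentration and composition by oxidative enzymes such as laccases.
Dissecting which enzyme paralog does what requires measuring lignin
chemistry *in place*, cell by cell and layer by layer, rather than on
ground tissue. `lignoquant` packages the analysis layer of that kind of
study for microscopists and plant cell-wall biologists:

- **Enzyme-activity kinetics** — time-lapse brightfield stacks of
  sections oxidizing chromogenic substrates (DAF, DAB, PYGL) are turned
  into per-region oxidation rates: uncalibrated optical density
  `OD = log10(white / value)`, background correction against unlignified
  phloem, automatic linear-phase detection, slope in OD·min⁻¹, and
  subtraction of non-enzymatic rates from autoclaved controls.
- **Histochemistry** — Wiesner (phloroglucinol-HCl) staining quantified
  as stained − unstained differential absorbance with phloem-reference
  correction; Mäule staining as HSB hue in degrees (circular mean) plus
  stained-image absorbance.
- **Raman microspectroscopy** — asymmetric least-squares baseline
  correction (λ = 100,000, p = 0.01), axis alignment to the 378 cm⁻¹
  cellulose band, and ratiometric descriptors: lignin/cellulose, S/G,
  G_CHO/G_CHOH (coniferaldehyde vs coniferyl-alcohol units) and a
  two-band cellulose crystallinity index.
- **Morphometrics** — vessel (tracheary-element) collapse scored as
  convexity = polygon area / convex-hull area on kernel-smoothed traced
  perimeters; cell-wall autofluorescence line profiles normalized to the
  compound-middle-lamella mean; wall-thickness swelling ratios across
  fresh/dried/rehydrated states.
- **Statistics** — per-biological-replicate aggregation, one-way
  ANOVA + Tukey-HSD with compact letter displays (the letters above the
  bars in genotype-comparison figures), SVD-based PCA of lignin
  descriptors, and percent-area composition of pyrolysis-GC/MS pyrograms.
- **Synthetic phantoms** — seeded generators for every input the
  pipelines consume (kinetics stacks, stained sections, spectra, vessel
  outlines, line profiles) with machine-readable ground truth, so the
  whole package is testable without any microscope.

## Worked example

Simulate a 4-lobed collapsed vessel outline and score its convexity:

```sh
lignoquant simulate outline --seed 1 --collapse 0.5 -o sim
lignoquant convexity --outlines sim/outlines.csv --no-smooth -o shapes
cat shapes/shapes.csv
```

```
shape_id,area,hull_area,convexity,raw_convexity,perimeter,smoothed
vessel_a0.5_k4,1000.6,1198.73,0.834721,0.834721,158.981,False
```

The generator's ground truth (`sim/truth.csv`) lists 0.834791 from a
10,000-vertex dense oracle — the analyzer agrees to 0.008%. A convexity
of 1 is a fully inflated (convex) vessel; 0.83 reflects the four inward
folds of a partially collapsed one.

Oxidation rates from noisy lag/linear/plateau absorbance traces:

```python
from lignoquant.synthetic import gen_kinetic_traces
from lignoquant.kinetics import KineticTrace, detect_linear_phase

df = gen_kinetic_traces(1, n_traces=3)
for tid, g in df.groupby("trace_id"):
    r = detect_linear_phase(KineticTrace(tid, g.time_min.to_numpy(),
                                         g.absorbance.to_numpy()))
    print(f"{tid}: slope={r.slope:.6f} OD/min "
          f"(true {g.true_slope.iloc[0]:.6f}), window={r.window}, r2={r.r2:.4f}")
```

```
trace0000: slope=0.001602 OD/min (true 0.001625), window=(30.0, 180.0), r2=0.9950
trace0001: slope=0.000950 OD/min (true 0.000954), window=(10.0, 180.0), r2=0.9694
trace0002: slope=0.000868 OD/min (true 0.000910), window=(20.0, 180.0), r2=0.9877
```

Each slope is the linear-phase oxidation rate after the initial
unspecific-staining lag, with the detected window and its fit quality.

The CLI exposes every stage: `simulate`, `activity`, `wiesner`, `maule`,
`raman`, `convexity`, `profile`, `swelling`, `stats`, `pca`, `pyrogram`.
Every run writes a provenance JSON (config hash, version, timestamp) next
to its outputs, and numeric CSVs print 6 significant digits so identical
seeds reproduce outputs byte-for-byte.

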