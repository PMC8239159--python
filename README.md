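# guindex

Glucose-unit-index (GUI) calibration, N-glycan annotation and label-free
quantification for permethylated-glycan LC-MS runs.

## The problem

The retention time of a glycan on a given LC column carries real
structural information — compositional isomers separate
chromatographically even though they share one m/z — but absolute
retention times are not comparable across columns, gradients or
laboratories. The standard remedy in glycomics is to spike a dextrin
ladder (linear glucose oligomers, GU 2, 3, …) into the sample as an
internal retention standard and express every elution position as a
**Glucose Unit Index**: the (fractional) number of glucose units that
would elute at the same time. Doing this by hand — finding each rung in
the raw data, fitting a standard curve, reading off GUIs — is tedious
and error-prone. `guindex` automates the whole chain for permethylated
N-glycan runs supplied as mzML:

1. **Ladder detection** — each scan is searched for the theoretical m/z
   of each rung's most abundant isotope ion (charges up to +3, proton
   adduct by default, 10 ppm). Because noise produces spurious rung
   matches, the rung→retention-time assignment is resolved by dynamic
   programming over the elution-order constraint: with `score[i][u] =
   intensity(i,u) + max_{j≤u} score[i−1][j]`, the traceback is the
   maximum-intensity non-decreasing GU sequence over the scans, and
   each rung's retention time is its most intense assigned scan.
2. **Calibration** — GUI is regressed on retention time,
   `y = β₀ + β₁x + … + βₙxⁿ` (cubic by default) or the same form in
   `log x`, solving the normal equations `β = (XᵀX)⁻¹Xᵀy` by
   Gauss–Jordan elimination on a centered/scaled design. R² is
   reported; any retention time can then be mapped to a GUI value.
3. **Annotation** — candidate compositions are enumerated under
   biosynthesis bounds (#HexNAc≤12, #Hex≤12, #Fuc≤5, #NeuAc≤4, with an
   N-glycan-core filter), their aggregated isotope envelopes are
   computed with the BRAIN recursion, and each composition's most
   abundant isotope ion is searched in every MS1 scan via a bucket
   index. A hit is extended to the neighboring isotope positions and
   scored against the theoretical envelope with the Pearson
   correlation r (invariant to linear intensity transformations);
   matches with r ≥ 0.9 become annotations carrying the calibrated GUI.
4. **Quantification** — per composition, an extracted-ion chromatogram
   is built from the summed intensities of the three most probable
   isotope peaks (top-3-isotope quantification). Isomer peaks are
   detected apex-outward (boundary at ≥ 50 % of apex, extended to the
   nearest local minima), integrated trapezoidally, and summed across
   charge states; each isomer is reported with its apex GUI.

A synthetic-run generator (`guindex.synth`) emulates the whole
experiment — ladder on a smooth GU→rt curve, glycan envelopes at
chosen GUIs or retention times, decoy noise — with a ground-truth
manifest, so every stage is testable without instrument data.

## Worked example

```bash
guindex synth --out demo --seed 7        # synthetic run + ground truth
guindex all demo/synthetic.mzML --out results
```

`results/summary.json` reports 11 ladder rungs assigned (GU 2–12),
calibration R² = 0.9999995, and 5 annotated compositions from 116
(composition, charge, scan) envelope matches. The quantification table:

```
composition             isomer  apex_rt  gui      left_rt  right_rt  area    total_area
HexNAc2Hex3Fuc0NeuAc0   1       25.85    5.00242  25.3     26.35     270366  270366
HexNAc2Hex5Fuc0NeuAc0   1       35.15    6.9983   34.65    35.7      270329  270329
HexNAc4Hex5Fuc0NeuAc0   1       30       5.87186  29.45    30.55     515331  515331
HexNAc4Hex5Fuc0NeuAc2   1       42       8.58009  41.45    42.55     187786  187786
HexNAc4Hex5Fuc1NeuAc0   1       36       7.18935  35.45    36.55     223004  223004
```

The first two glycans were planted at target GUIs 5.0 and 7.0; the
pipeline reports 5.002 and 6.998. `area` is the trapezoidal
top-3-isotope XIC area (intensity·minutes) of each detected isomer;
`total_area` sums a composition's isomers across charge states. The
generator's manifest gives the analytic areas (h·σ·√2π times the top-3
envelope fraction) for comparison — they agree to well under 1 %.

Each stage also runs standalone (`guindex ladder|calibrate|annotate|quantify`)
from the previous stage's output files; see `guindex --help`.

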