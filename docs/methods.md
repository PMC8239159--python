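# Methods

This note documents the models, algorithms, parameter choices and
numerical decisions behind `guindex`, and what the synthetic test bed
does and does not demonstrate.

## Chemistry layer

Elemental formulas are integer element→count maps with element-wise
arithmetic. Monoisotopic atomic masses and isotope abundances (C, H,
N, O, S, Na) are IUPAC/CODATA values embedded as constants in
`constants.py`; no runtime lookup. The m/z convention is
`(M + z·m_adduct)/z` with cation masses for H⁺ (1.007276) and Na⁺
(22.989222); the electron mass (< 0.0006 Da) is neglected, far below
the 10 ppm working tolerance.

Permethylation is modeled composition-wise: each residue contributes a
fixed permethylated increment (Hex C₉H₁₆O₅, HexNAc C₁₁H₁₉NO₅, Fuc
C₇H₁₂O₄, NeuAc C₁₆H₂₇NO₇) and the molecule closes with dimethylated
water (C₂H₆O), i.e. a free, methylated reducing end — the chemistry of
a spiked permethylated dextrin ladder. A permethylated linear glucan of
g units is therefore C(9g+2)H(16g+6)O(5g+1) (g = 2: C₂₀H₃₈O₁₁,
454.2414 Da). An alditol (reduced-end) variant adds CH₄ and is off by
default. Native residues use the usual anhydro increments plus H₂O.

Candidate N-glycan compositions are enumerated inside per-residue
bounds (defaults 12, 12, 5, 4 for HexNAc, Hex, Fuc, NeuAc) under a
three-clause biosynthesis filter implemented as one replaceable
predicate: (a) HexNAc ≥ 2 and Hex ≥ 3 (trimannosyl-chitobiose core),
(b) Fuc ≤ HexNAc (fucoses need GlcNAc attachment sites), (c) NeuAc ≤
max(0, HexNAc − 2) (sialylation capped by antennary GlcNAc count).
This filter is a declared design choice, not a claim about any other
software's exact rule set; swapping the predicate changes the search
space without touching the pipeline.

## Aggregated isotope envelopes (BRAIN)

Envelopes are aggregated by nucleon-number offset (A, A+1, …), the
right granularity for unit-resolved LC-MS. For element e with
abundance polynomial Q_e(x) = Σ_j P_ej x^j and v_e atoms, the
molecular polynomial is Q(x) = Π_e Q_e(x)^{v_e}; its coefficients are
the aggregated probabilities. They are computed without expanding the
product via Newton–Girard identities: with ψ_l = Σ_e v_e Σ_roots
r^{-l} (inverse-root power sums of each tiny per-element polynomial,
roots from `numpy.roots`), the recursion is j·q_j = −Σ_{l≤j} ψ_l
q_{j−l}, q₀ = Π_e P_e0^{v_e}. Centroid masses come from a companion
power series: the mass-weighted element polynomial divided by Q_e
(series long division), convolved with q; the centroid of aggregate j
is w_j/q_j. Ten aggregated peaks are computed by default — truncation
below 1e−6 for the largest default composition (~341 carbons). The
engine agrees with a brute-force multinomial convolution oracle to
better than 1e−10 per peak (asserted in tests); small negative
round-off in the far tail is clamped to zero.

## Ladder detection and assignment

Each rung's search anchor is its most abundant aggregated isotope ion
(monoisotopic for small rungs), searched at every configured charge and
adduct with the ppm tolerance; per scan and rung only the most intense
match is kept. The rung→time assignment maximizes total matched
intensity over all non-decreasing GU sequences — the elution-order
constraint that a longer glucan never elutes earlier — by dynamic
programming, `score[i][u] = intensity(i,u) + max_{j≤u} score[i−1][j]`.
Ties prefer the same-rung predecessor, which yields contiguous elution
blocks. The printed recurrence alone would score every path equally;
the per-cell intensity term is what makes the "true rungs are more
intense than decoys" assumption operative. Each rung's final retention
time is its highest-intensity scan on the optimal path; rungs with no
supported scan are omitted with a warning. The DP is verified against
exhaustive enumeration on small instances. The default GU range is
2–12; an optional absolute intensity floor (default off) can suppress
baseline matches for the weak high-GU rungs.

One rung is assigned per scan during traceback; a scan containing
several rung envelopes contributes the one on the optimal path.

## Calibration

GUI is the regression target, retention time (or log rt) the
predictor: y = β₀ + β₁f(x) + … + βₙf(x)ⁿ, default cubic, both fit
kinds always available. The least-squares solution uses the normal
equations solved by Gauss–Jordan elimination with partial pivoting —
the classical formulation — but on a mean-centered, standard-deviation-
scaled abscissa, because a raw minute-scale cubic Vandermonde system
loses ~10 digits of conditioning. Coefficients are back-transformed
for reporting; evaluation uses the scaled form. Agreement with a QR-
based `numpy.linalg.lstsq` oracle is pinned to 1e−8 in tests. R² = 1 −
SS_res/SS_tot is computed on the fit points. Degenerate inputs
(< order+1 distinct rts, duplicate rts, non-positive rts for the log
kind) raise a calibration error naming the condition. Extrapolation
beyond the fitted rt range is permitted and flagged in the annotation
report.

## Annotation

The anchor-first search: a composition/charge/adduct is considered in
a scan only if its most abundant isotope ion has a peak within
tolerance (it is the most likely peak to be observed at all). The
envelope is then extended to the neighboring aggregated positions at
spacing 1.00335/z around the *observed* anchor m/z, pairing each
theoretical position with the nearest in-tolerance peak (0 where
absent). Scoring is the Pearson correlation between theoretical and
observed intensity vectors — scale- and offset-invariant, so detector
gain does not matter; zero-variance vectors are rejected as unscorable.
The scored envelope covers ≥ 99.9 % cumulative probability, never
fewer than 3 peaks. The cutoff (default 0.9) is compared on signed r.
Annotations are per (composition, charge, adduct, scan); merging
across scans and charges happens only in quantification.

Near-isobaric anchor collisions do occur in the full composition space
(especially half-integer spacings at z = 2–3 aligning with another
species' A+k peak). Such cross-matches read a *shifted* envelope,
which decorrelates from the candidate's own shape; on the synthetic
test bed the 0.9 Pearson cutoff rejects all of them (zero-noise
soundness is asserted exactly in tests). On real serum data
interferences can survive any threshold, which is why annotations
should be cross-checked against a GUI library or MS/MS where
available — both out of scope here.

## Quantification

Per composition and charge/adduct with at least one annotation, the
XIC sums the intensities matched at the three most probable theoretical
isotope m/z values per MS1 scan (unmatched → 0, keeping the trace
dense). "Three most probable" rather than "first three" is a
documented choice; they coincide for all but the largest compositions.
Isomer peaks are detected iteratively: global apex among unassigned
points, outward walk while intensity ≥ cutoff·apex (≥, so a boundary
exactly at 50 % is included), then extension to the nearest local
minimum (first point whose next outward neighbor is not lower); the
span is marked assigned and the search repeats above the minimum-apex
floor (default 0 = off). Areas are trapezoidal integrals of intensity
over minutes with inclusive bounds — excluding the boundary samples
would discard real signal at half-height, and intensity·time units are
what make areas comparable across runs; a raw intensity-sum mode
(`area_mode: sum`) mirrors the plain summation definition for users
who want it. Isomers are merged across charge states when apexes fall
within 0.2 min (configurable); the most intense trace defines the
isomer's apex rt, hence its GUI.

## Synthetic data: what it emulates, what it does not

The generator plants, on a regular scan grid (default 0.05 min over
8–58 min), Gaussian elution profiles carrying exact BRAIN envelopes:
the dextrin ladder GU 2–12 on a fixed increasing cubic GUI(rt) curve
spanning ~10–56 min (rungs placed on its numerical inverse, heights
decaying 0.75× per GU from 10⁶, σ = 0.12 min, mimicking the weak
high-GU rungs of real ladders), plus five N-glycans — two placed at
target GUIs 5.0 and 7.0, one at two charge states, one fucosylated and
one disialylated species — and uniform-m/z decoys with log-normal
intensities (5 per scan in the default noisy spec, median intensity
20 % of the weakest rung). Everything is deterministic under the seed.
Envelope contributions below 1 count are dropped, so zero-noise runs
have finite, attributable peak lists. A JSON manifest records planted
rts, GUIs, heights and analytic areas (h·σ·√2π scaled by the top-3
envelope fraction).

Passing on this bed shows the algorithms do what they claim under
ideal chromatography and exact envelopes. It does not demonstrate
robustness to peak tailing, isotope-structured chemical background,
co-eluting near-isobars within tolerance, saturation, or charge-state
envelope distortion — all present in real serum data.

The five planted compositions and the default conditions were fixed
once as the package's standard demonstration; test problem sizes
(e.g. 50–100 seeds for the stochastic rates, 1001 scans per run) are
chosen to make the suite quick on a single CPU while keeping the
stochastic assertions well-powered.

## Numerical and interface choices

- mzML only; the reader is a focused stream parser (stdlib
  ElementTree) for MS1-level content: 32/64-bit float arrays, zlib or
  no compression, second/minute time units. The writer emits minimal
  standard mzML with uncompressed 64-bit arrays, lossless at float
  precision.
- Centroiding: contiguous above-zero profile regions are split at
  internal local minima; each sub-region yields one stick at the
  intensity-weighted m/z with the region's maximum intensity.
  Idempotent; centroided input passes through untouched.
- Charge derivation: isotope-companion spacing test at 1.00335/z,
  preferring the largest consistent z (a z=2 envelope also exhibits
  1 Th spacings, so denser spacing is the more specific evidence).
- Bucket index: peaks hashed by ⌊m/z / width⌋ with width defaulting to
  the tolerance at the top of the m/z range, so a query touches ≤ 3
  buckets; query results are provably identical to a linear scan
  (property-tested).
- All report files have fixed column order and float formatting;
  re-running any stage on identical input is byte-identical. Stage
  wall-times go to the stderr log, not into summary.json, to keep
  outputs reproducible.
- The command-line interface exposes each stage (`ladder`,
  `calibrate`, `annotate`, `quantify`, `all`, `synth`) with
  intermediate JSON/TSV handoff, so any stage can be re-run or
  debugged in isolation.

## Known limitations

- Compositions only; no linkage/topology, no O-glycan rules, no MS/MS
  verification, no FDR control, no cross-run alignment or
  normalization.
- Each run calibrates itself; there is no calibration transfer.
- Quantification does not deconvolve distinct compositions whose ions
  fall within tolerance of each other; their XICs will share signal.
- The biosynthesis filter is intentionally permissive; tightening it
  is a one-function change.
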