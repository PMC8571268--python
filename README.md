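# fibriltools

Quantitative analysis of ex vivo amyloid fibrils: worm-like-chain
mechanics from traced filaments, helical-parameter geometry, consensus
aggregation-propensity scoring, and ordered-core/mutation statistics.

Amyloid fibrils extracted from patient tissue — such as the immunoglobulin
light-chain (AL) fibrils that deposit in the heart in systemic AL
amyloidosis — are characterized by electron tomography (filament traces),
cryo-EM helical reconstruction (rise/twist), sequence-based aggregation
predictors, and structural annotation of the ordered fibril core. This
package implements the downstream numerics of that workflow for
structural biologists and biophysicists, together with a discrete
worm-like-chain simulator so every stage can be validated against known
ground truth.

## The models

**Persistence length.** A traced fibril is a 3D polygonal chain with
contour length *L* (sum of segment lengths) and end-to-end distance *R*.
The worm-like-chain model predicts

&nbsp;&nbsp;&nbsp;&nbsp;⟨R²⟩ = 2PL·(1 − (P/L)(1 − e^(−L/P)))

for a population with persistence length *P*. Fitting this to measured
(Lᵢ, Rᵢ²) pairs by unweighted nonlinear least squares estimates *P*; the
bending rigidity follows as *B* = k_B·T·P.

**Helical geometry.** A fibril advancing by a rise (Å) and twist
(degrees) per subunit has pitch = rise × 360/|twist|; a ribbon-like
fibril shows two apparent crossovers per turn, so crossover ≈ pitch/2.
Negative twist = left-handed.

**Consensus aggregation score.** Per-residue outputs of TANGO, WALTZ,
FoldAmyloid, Aggrescan and PASTA are binarized by their published
thresholds and summed into a 0–5 score; runs of 5 mark aggregation-prone
segments, runs of 0 mark segments with no predicted propensity.

**Ordered core.** Annotated ordered residue ranges and mutation positions
give the ordered-residue fraction and the number of mutations inside the
ordered core, aggregated across structures as mean ± sample SD.

## Worked example

The `demo` subcommand runs the synthetic pipeline end to end: simulate a
cohort of 195 discrete worm-like chains at P = 0.74 μm (segment 10 nm,
contour lengths uniform on 0.3–2.0 μm), measure each chain's (L, R²),
fit the WLC model, and convert to a bending rigidity:

```text
$ fibriltools demo --seed 20211105 --out demo_out
simulated 195 chains at P = 0.74 um (seed 20211105)
fitted  P = 0.76 um (95% CI 0.69-0.83, n = 195)
bending rigidity B = 3.2e-27 N m^2 at 300 K
reports in demo_out/
```

The fitted P lands within the sampling error of the generating 0.74 μm;
`demo_out/fit.json` holds the full-precision fit, CI, residual sum of
squares and the seeded configuration.

Helical parameters of a reconstructed fibril, with a consistency check
against a crossover spacing measured from images:

```text
$ fibriltools helix --rise-a 4.76 --twist-deg -1.46 --crossover-nm 55
pitch     = 117 nm
crossover = 55 nm
twist     = -1.46 deg (left-handed)
routes rise+twist vs crossover: relative discrepancy 6.7%
```

A rise of 4.76 Å at −1.46° per subunit implies a 117 nm pitch, hence a
58.7 nm half-pitch crossover; the 55 nm measured crossover disagrees by
6.7%, below the default 10% flagging tolerance.

Bending rigidity with propagated uncertainty:

```text
$ fibriltools rigidity --p-um 0.74 --se-um 0.08
B = 3.1e-27 N m^2 (P = 0.74 um, T = 300.0 K), SE = 3e-28 N m^2
```

The other subcommands (`simulate`, `measure`, `fit`, `aggscore`,
`segments`) expose the same stages on files; see `fibriltools --help`.
The library API (`fibriltools.simulate`, `.geometry`, `.wlc`, `.helix`,
`.aggregation`, `.core`) offers everything the CLI does, returning
dataclasses and pandas DataFrames.

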