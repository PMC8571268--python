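# Methods

## Scope

`fibriltools` implements the quantitative stages of an ex vivo amyloid
fibril characterization: estimating the persistence length and bending
rigidity of a traced fibril population, converting among the helical
parameters of a reconstructed fibril, combining five aggregation
predictors into a per-residue consensus score, and mapping mutations onto
ordered-core annotations. It deliberately does not acquire or reconstruct
images: tomogram segmentation, fibril tracing, helical reconstruction and
model building all happen upstream, and the package consumes their text
exports (point files, parameter values, predictor tables, annotations).

## Worm-like-chain model and fit

A traced fibril is a polygonal chain. Its contour length L is the sum of
segment lengths; its end-to-end distance R is the distance between the
first and last vertex. For a worm-like chain (WLC) of persistence length
P the ensemble expectation is

    E[R^2] = 2 P L (1 − (P/L)(1 − e^(−L/P))).

`fit_persistence_length` minimizes the unweighted squared deviation of
the measured R_i^2 from this expectation over the fibril population
(nonlinear least squares, positivity enforced by a box [1e−3, 1e3] um,
objective tolerance 1e−10, at most 500 iterations). The starting value is
the freely-jointed-chain moment estimate mean(R^2)/(2 mean(L)). For
L/P < 1e−4 the expectation is evaluated by the series L^2 (1 − L/(3P)) to
avoid catastrophic cancellation; the branch point was checked for
continuity. An estimate at a box bound is flagged (`at_bound`): perfectly
straight chains satisfy R^2 = L^2 for any large P, so the boundary flag
is the correct diagnosis rather than an error.

Bending rigidity is B = k_B T P with the exact SI Boltzmann constant and
T = 300 K by default; SE(B) = k_B T SE(P) propagates linearly.

### Confidence intervals and their measured coverage

Two 95% intervals for P are available:

- **linearized** (default): SE from the Jacobian at the optimum with a
  t(n−1) quantile — the interval a standard curve-fitting tool reports.
- **bootstrap**: percentile interval over B = 1000 (configurable)
  resampled-fibril refits.

R^2 is strongly heteroscedastic in L (longer chains fluctuate more), which
the unweighted fit ignores. Under the default study conditions (below) the
fit is unbiased — signed median relative bias ≈ 0.05% over 200 replicate
studies — but the homoscedastic linearized interval covers the generating
P in only ~80% of replicates, while the bootstrap interval covers ~95%.
The linearized interval is kept as the default for comparability with
common curve-fitting output; the bootstrap is the interval to trust for
population-level uncertainty, and it is the one the coverage test
exercises. Bootstrap refits use a damped Gauss–Newton iteration on the
same objective (agrees with the general optimizer to < 1e−7 relative);
the general-purpose optimizer's per-call overhead would otherwise
dominate at ~10^5 refits.

## Discrete-WLC simulator

The simulator stands in for traced-fibril data so the whole pipeline is
testable without microscopy. A chain with n = round(L/l) segments of
exact length l (default 10 nm) is grown segment by segment: the first
tangent is uniform on the sphere (R and L are rotation invariant, so this
only randomizes raw coordinates); each subsequent tangent bends by a
polar angle whose cosine is drawn from the Boltzmann density
p(c) ∝ exp(a c), a = P/l, via the closed-form inverse CDF
c = 1 + ln(1 − u(1 − e^(−2a)))/a, and by a uniform azimuth. The mean
bend cosine is then the Langevin form coth(a) − 1/a = e^(−l/P)(1 + O((l/P)^2));
with the validity bound l ≤ 0.2 P enforced by the spec of a simulation,
and the default l = P/74, the discretization bias in the effective
persistence length is ~2e−4 relative — negligible against the fit's
sampling error. Requested contour lengths are realized to the nearest
whole segment (within l/2); the manifest records realized lengths, and
ensemble comparisons must use them (R^2 ≈ L^2 for stiff chains is
sensitive to even a half-segment length change).

Randomness: every fibril draws its length, conformation and optional
Gaussian point jitter from a stream keyed by (root seed, fibril index),
so cohorts are bit-reproducible and independent of generation order.
Default study conditions emulate the tracing study the package targets:
195 fibrils, P = 0.74 um, contour lengths uniform on [0.3, 2.0] um
(the real length distribution is unpublished; the uniform range matches
the order of magnitude of tomogram traces and is configuration, not
fact), segment 10 nm, no jitter. Under these conditions a single-cohort
fit has a sampling SD of ~0.054 um.

What the simulator does not emulate: excluded volume, surface adsorption
(2D pre-equilibration), finite fibril width, tracing error correlated
along the chain (jitter is iid isotropic Gaussian), and length-dependent
tracing bias. Passing recovery tests therefore demonstrate correctness of
the estimator under the WLC model, not robustness to every artifact of
real tomogram tracing.

## Helical geometry

Conversions among rise (Å/subunit), twist (deg/subunit, negative =
left-handed), pitch (nm/turn) and crossover spacing (nm) assume a C1
single-protofilament helix with one subunit per rise step. Crossover =
pitch/2 by default (a ribbon-like fibril's projected width modulates
twice per turn); `crossovers_per_turn` is exposed for other morphologies.
`consistency_report` computes the pitch by every available route,
reports pairwise relative discrepancies (relative to the smaller
estimate) and flags those above a tolerance (default 10%). It reports
disagreement — e.g. an image-measured crossover vs the reconstruction's
rise/twist — without adjudicating which measurement is wrong.

## Consensus aggregation score

Five external predictors (TANGO, WALTZ, FoldAmyloid, Aggrescan, PASTA)
assign per-residue aggregation potentials; the package consumes a
normalized TSV of their outputs rather than parsing five unstable native
formats. Each predictor is binarized by a strict threshold (TANGO > 0,
WALTZ > 0, FoldAmyloid > 0.062 with only runs of ≥ 5 consecutive
flagged residues kept — the whole run is flagged — Aggrescan > −0.02,
PASTA < −2.8); the consensus score of a residue is the number of
flagging predictors (0–5). The WALTZ rule is applied per residue by
default; a whole-sequence mode (flag all residues iff the summed score
passes) is available behind a flag because the phrase "total sequence
score" admits either reading, and only the per-residue reading yields a
residue-resolved consensus. Segment calls are maximal runs at a target
score, optionally length-filtered.

## Ordered-core statistics

Annotations are 1-based inclusive residue ranges plus mutation positions.
`ordered_fraction` is covered residues over sequence length;
`mutations_in_ordered` counts mutation positions inside any range.
Aggregation across structures reports the mean and the sample SD (n−1);
the dispersion convention of published "±" values is not always stated,
and sample SD is the assumption here. A single structure yields a mean
and an explicitly undefined SD. Display output rounds to whole percent;
machine output keeps full precision. The FOR001 annotation (118 residues,
core 9–52 and 68–108, mutations at 17, 52, 53, 82, 93, 99) ships as a
convenience constant; annotations for other fibril structures are user
inputs.

The Gill–von Hippel extinction coefficient uses the published 280 nm
coefficient set (Trp 5550, Tyr 1340, cystine 150 M^−1 cm^−1) and is
configurable, since published per-protein values cannot be decomposed
without the exact sequence and disulfide count.

## Problem sizes used in the checks

The recovery check fits one 195-chain cohort (~1 s). The coverage check
runs 200 replicate studies with B = 400 bootstrap refits each (~90 s).
Ensemble-vs-model checks use 2000 chains per condition at L/P = 0.25, 1
and 4. Bend-angle sampling checks use 1e5 draws. These sizes put
Monte-Carlo error well below the effect sizes being tested while keeping
the full suite in a few minutes.

## Known limitations

- The unweighted fit is the field's convention but not efficient under
  the true heteroscedasticity; a weighted or variance-modeled fit would
  tighten the CI and is intentionally out of scope.
- Only the R²-versus-L regression estimator of P is provided (no
  tangent-correlation or Fourier-mode estimators).
- The planar (xy-projection) measurement mode changes the meaning of R
  without changing the 3D WLC model used in the fit; interpreting a
  planar fit requires care and the 3D mode is the default throughout.
- Predictor thresholds binarize published program outputs; the programs
  themselves are not reimplemented or executed.
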