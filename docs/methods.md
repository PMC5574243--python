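# Methods

## The model

The pipeline treats a single-channel EEG epoch — one fixed-length window of
N amplitude samples x₁..x_N at sampling rate f_s — as the unit of analysis
and reduces it to six statistics:

* **Approximate entropy.** ApEn(m, r) = φ^m(r) − φ^{m+1}(r) with
  φ^m(r) = (N−m+1)^{−1} Σᵢ log Cᵢ^m(r), where Cᵢ^m(r) is the fraction of
  length-m templates within Chebyshev (max-abs) distance r of template i.
  Counting **includes the self-match**, which guarantees Cᵢ > 0 (the log is
  always defined) and makes ApEn of a constant epoch exactly 0, at the cost
  of a small negative bias at short N. Chebyshev distance and self-match
  inclusion follow the original formulation of the statistic. Defaults are
  the literature-standard m = 2 and r = 0.2·SD of the epoch ("relative"
  mode); an absolute-units mode is available. ApEn needs N ≥ m + 2.
* **SD / SE.** Population standard deviation (divisor N) and the standard
  error SD/√N. SE is implemented as SD/√N even though one rendering of the
  defining formula elides the radical; the near-identical normalized SD and
  SE columns in feature tables are consistent with any fixed-N proportional
  relation, and SD/√N is the universal definition.
* **MMAV.** (1/N) Σ wₙ·|xₙ| with wₙ = 1.0 for 1-based indices
  ⌈0.25N⌉ ≤ n ≤ ⌊0.75N⌋ and 0.5 otherwise. The rectification |xₙ| is
  explicit: MAV-family features are defined on full-wave rectified data.
* **Spectral roll-off.** The lowest frequency k·f_s/N (one-sided spectrum,
  ⌊N/2⌋+1 bins) at which the cumulative magnitude reaches 85% (configurable)
  of the total. The defining expression is a threshold quantity
  (0.85 × Σ|Xₙ|); the feature returned is the frequency that satisfies it.
  A zero spectrum yields 0 Hz with a warning.
* **Zero crossings.** Count of consecutive-sample sign changes whose
  amplitude jump |xₙ − xₙ₋₁| is at least a threshold (default 0, the plain
  sign-change count). Samples exactly at zero inherit the previous nonzero
  sign so a touch of the axis is not counted twice.

Feature vectors are min-max normalized **column-wise across a template**
to [0, 1]; a constant column maps to 0.5 by convention. Min-max was chosen
because the published template values all lie in [0, 1] and proportional
columns (SD, SE) normalize to near-identical values there, which min-max —
being scale-invariant — reproduces. Normalization is idempotent.

## k-NN classification

Distances between feature vectors: Euclidean, cityblock, cosine
(1 − cosine similarity) and correlation (1 − Pearson r; the conventional
correlation distance). The classifier ranks template rows by distance
(stable sort, ties broken by row index) and applies one of four rules:

* `nearest_neighbour` — majority label among the k nearest; majority ties
  resolve to the closest row's label;
* `random_neighbour` — uniform draw among the k nearest, seeded (the stream
  is keyed on the seed and the query bytes, so results are reproducible);
* `smallest_neighbour` — the label of the farthest row within the k set;
* `similarity_weighted` — argmax over classes of summed cosine similarity
  to the k nearest rows, the category-score pathway.

The random- and smallest-neighbour rules are documented interpretations:
their original description names them without defining them, and these are
the most natural readings (a random committee member, and the weakest one).
The similarity pathway and the distance ranking are likewise presented side
by side in the source material without reconciliation; here distance
ranking + rule is the default and the similarity argmax is exposed as the
fourth rule. With k = 1 the first three rules coincide.

Published accuracy tables for this classifier (60/40/20% patterns) derive
from clinical recordings that were never deposited, so they cannot be
reproduced; the package reproduces the evaluation *structure* (the
k × metric × rule accuracy grid and confusion matrices) on synthetic
templates instead, and asserts the qualitative ordering that the nearest-
neighbour rule is at least as accurate as the smallest-neighbour rule.

## Level-of-epilepsy regression

ApEn measured from epileptic EEG rises with patient age; a polynomial
Y = b₀ + b₁x + … + b_k x^k fitted by ordinary least squares captures the
trend. Fits use the raw age scale (so coefficients are directly comparable
with the bundled reference models); a centered/scaled option exists for
conditioning on wider domains. The bundled reference models are the
published 3rd- and 4th-order fits and two 7th-order "residual" polynomials.
The residual polynomials' provenance (what was regressed on what) is not
explained in their source; they are bundled verbatim, evaluable, and play
no role in order selection.

Prediction error follows the published table's conventions exactly: the
interpreted value is rounded to 3 significant figures, the percent deviation
100·|interpreted − actual|/actual is computed in exact decimal arithmetic,
and the result is reported to 2 decimals with half-up rounding. Binary
floating point cannot reproduce the printed 5.13% cell (it lands at
5.124999…), hence the decimal route. The published table's age-80 column is
**not reproducible** from the published coefficients — direct evaluation
gives ≈ 0.0296 (3rd order) and ≈ 0.0298 (4th) against printed 0.0310/0.0312,
an unresolvable inconsistency in the source — so ages 20/40/60 are the
verified cells and age 80 is excluded throughout.

Order selection splits the cohort with a seeded shuffle (default 50%
held out), fits each candidate order on the training half and compares
mean *unrounded* relative deviation on the held-out half; rounding to table
precision inside selection would quantize away real differences. Orders
within 1e-6 percentage points of the best tie toward the lower order, the
parsimony argument that favours the cubic over the quartic.

## Synthetic data

`seizurekit.synthetic` emulates the two statistical contrasts the method
needs, with defaults chosen once as a plausible desk-scale configuration:

* **Epochs**: 256 samples at 128 Hz (2 s). The *epileptic* kind is a
  spike-wave surrogate — a 3 Hz fundamental (the classic ictal discharge
  band) plus two harmonics with 1/h amplitude fall-off, passed through a
  quadratic peak-sharpening nonlinearity, with a seeded phase offset and
  optional white noise. The *normal* kind is 1/f-amplitude-shaped coloured
  noise. Both are scaled to unit RMS so the classes differ in *structure*,
  not power. At zero added noise the epileptic ApEn is below half the
  matched normal ApEn for every tested seed. Classification experiments add
  white noise of SD 0.3 (on the unit-RMS scale) so the classes overlap
  non-trivially.
* **Cohorts**: ApEn(age) = polynomial trend + Gaussian noise, clipped at 0.
  Clipping keeps the values physical but slightly biases fits when the
  noise SD is comparable to the trend value at the youngest ages; test
  cohorts start at age 5 where the trend is several noise SDs above zero.
* **Seeding**: one top-level seed expands to per-subject substreams via
  `SeedSequence(seed, spawn_key=(index,))`, so adding subjects never
  perturbs earlier ones and every generator is a pure function of its spec.

What the surrogates do **not** capture: real ictal morphology and evolution,
artifacts, inter-channel structure, non-stationarity, and any genuine
age–ApEn relationship — passing tests demonstrate the pipeline's
correctness and its sensitivity to rhythmicity, not clinical performance.

## Numerical notes

* ApEn pairwise distances are computed in memory-bounded chunks; results
  match an exhaustive O(N²) counting oracle to 1e-10.
* ApEn under added noise is monotone increasing only in the low-noise
  regime (up to roughly 0.2 of the signal amplitude at these N); beyond
  that, finite-N saturation sets in and ApEn declines. Tests assert the
  monotone region.
* Roll-off bin search applies a 1e-12 relative slack to the cumulative
  threshold so exact-fraction boundaries are not missed to rounding.
* CSV floats are written at full repr precision and parsed with pandas'
  round-trip parser, so all artifacts round-trip bit-exactly and repeated
  pipeline runs are byte-identical.
* Problem sizes in the test and acceptance runs (20-subject templates,
  256-sample epochs, 200-point cohorts, 10–50 seed replicates) are the
  package's chosen desk-scale defaults; they keep the full suite under a
  minute while giving the stochastic assertions comfortable margins.

## Known limitations

* Single-channel only; no filtering, artifact handling or segmentation —
  epochs are caller-provided.
* No confidence or prediction intervals on the regression models.
* The EDF format is not read; epochs are ingested from plain-text CSV.
* k-NN is brute-force (templates are tens of rows; no kd-tree needed).
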