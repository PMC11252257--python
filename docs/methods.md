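# Methods

## Profiles and the f2 similarity factor

A dissolution profile is stored as paired vectors of sampling times (h)
and cumulative % of label claim released. The similarity factor

f2 = 50 · log10{ 100 · [1 + (1/n) Σⱼ (Rⱼ − Tⱼ)²]^(−1/2) }

uses base-10 logarithms (required to reproduce the worked value 85.79
from the packaged reference/predicted pair) and, by default, all shared
time points. The regulatory convention of truncating points after the
reference passes 85% release is available behind an explicit
`truncate_after_85` flag but is off by default, because the packaged
worked example uses all ten points including the 82/83% values at 24 h.
Reports round f2 to two decimals; every internal comparison uses the
unrounded value. Profiles with release up to 110% are accepted and
flagged (assay variability), not rejected; each profile is treated as a
single curve, with no vessel-to-vessel structure.

Comparing two profiles requires identical time vectors and n ≥ 3; a
mismatch error names the first differing time point.

## Experimental design

The design module generates two-level fractional factorials in Yates
standard order from defining generators, maps ±1 coding to factor units
and appends center runs. The study design is 2^(6−2)+1 = 17 runs over
the six variable excipients. The defining generators are not uniquely
determined by a run count, so the package defaults to the standard
resolution-IV choice E=ABC, F=BCD, overridable in `DesignSpec`. The
center point defaults to the optimized composition (50, 10, 15, 33.5,
15.73, 40 mg), the modal row of the packaged study table.

The packaged 17-batch table ships verbatim rather than being
regenerated: its factor levels (e.g. sodium citrate ∈ {25, 45, 50, 55,
75} mg) do not collapse onto a clean two-level coding, so no generator
choice reproduces it exactly. Batch masses are validated against the
400 mg nominal with a ±0.75 mg tolerance; offenders produce warnings
carrying the per-batch discrepancy, not errors, because several printed
batches total 399.5 or 400.5 mg and rejecting them would make the
shipped study unusable.

## Synthetic dissolution generator

The generator stands in for the wet-lab dissolution study. Each batch's
cumulative release follows the Weibull law F(t) = f_max·(1 −
exp(−(t/τ)^β)), chosen over simpler kinetic laws (zero/first order,
Higuchi, Hixson–Crowell) because its two shape parameters span both
first-order and sigmoidal curve families with the fewest knobs.

Composition enters through per-mg slopes on log τ, f_max and β applied
to each excipient's deviation from the center composition. Default
signs encode the qualitative pharmaceutics: the enteric polymers and
the lipid matrix former raise τ (slower release), the fillers lower it,
and sodium citrate mainly lifts f_max. Defaults (baseline f_max = 90%,
τ = 12 h, β = 1.3; slopes of order 0.01 per mg on log τ) were set once
so that the 17 default batches release between roughly 60 and 95% at
24 h with visibly different shapes — the qualitative behaviour of a
real MR dissolution panel — and are asserted against that range in the
tests. Gaussian noise with sd 1.5% release (typical dissolution assay
scatter) is added per time point; profiles are then clipped to
[0, 105]% and made non-decreasing with a running maximum, as cumulative
data are. Per-batch seeds are spawned from the study seed and batch
index, making whole studies bit-reproducible.

What the generator does *not* emulate: mechanistic dissolution physics
(pH-stage apparatus, Noyes–Whitney), correlated vessel noise, and any
numerical agreement with the real study's unpublished batch profiles.
Passing tests therefore demonstrate that the pipeline recovers
structure the generator put in — not that it would reproduce any
particular laboratory dataset.

## Surrogate network and training

The surrogate is a single-hidden-layer perceptron, by default 6-10-10:
tanh hidden units, linear output units. Inputs and targets are both
min-max normalized to [−1, 1] with ranges fitted on the training subset
only (normalizing targets as well as inputs is the symmetric choice;
the transform is affine and inverted on prediction). Degenerate
dimensions (min = max) map to 0.

Samples are split 70/15/15 into training/validation/test by a seeded
shuffle; validation and test sizes are the rounded fractions and the
remainder trains (17 samples → 11/3/3). Weights initialize uniformly in
[−0.5, 0.5] scaled by 1/√fan-in; biases start at zero.

Training is Levenberg–Marquardt on the flattened parameter vector:
each epoch solves (JᵀJ + μI)Δθ = −Jᵀe, where J is the Jacobian of the
per-sample, per-output residuals computed analytically by
backpropagation (finite differences serve as the test oracle only). A
step is accepted only if it reduces the training SSE; otherwise μ is
multiplied by 10 and the step retried, and on acceptance μ is scaled by
0.1. Defaults μ₀ = 0.001, cap 10¹⁰ and validation patience 6 follow
long-standing damped-Gauss–Newton training conventions for this
architecture. Stopping occurs at the MSE goal, the epoch cap, μ
exceeding its cap, or `patience` consecutive validation-MSE increases —
in the last case the best-validation weights are restored. A singular
damped normal matrix after full μ escalation and a non-finite loss are
hard errors naming the epoch.

The estimator surface is scikit-learn style (`MLPSurrogate.fit/predict`,
`get_params`), with the trained weights, biases and normalization
ranges in an immutable `SurrogateModel` that serializes to plain JSON
with exact float round-trip. Per-subset quality is the Pearson R
between flattened predictions and targets; subsets too small for a
correlation report `None` rather than a number.

## Grid optimization

The trained surrogate makes exhaustive what-if evaluation cheap, so the
optimizer is a deterministic Cartesian grid search (a seeded
random-sampling fallback is signposted when the grid exceeds the 10⁶
candidate cap). Mass balance is handled by designating one slack
excipient — lactose monohydrate by default, the conventional filler —
whose mass is whatever brings the tablet to 400 mg; candidates pushing
the slack outside its own bounds are discarded. An unconstrained mode
with a tolerance filter is available instead. Each candidate's
predicted profile is scored with f2 against the reference; ties break
toward the candidate nearest the domain center, then lexicographically,
so results are reproducible. The default domain spans each excipient's
studied range with five levels (quarter-range steps), ~1,500 feasible
candidates after mass balance.

## End-to-end benchmark

`dissolvenn.pipeline.run_synthetic_pipeline(seed)` chains the stages:
generate the 17-batch study with assay noise, train the surrogate,
grid-search against a reference produced by the *noiseless* generator
at the optimized center composition. It reports both the search's best
f2 and the winning formulation's "generator-truth" f2 (rescoring its
noiseless profile against the reference), which separates search
quality from surrogate error. With the defaults this benchmark runs in
well under a second per seed; the acceptance script repeats it for 10
seeds and reports the median best f2.

## Numerical choices and limitations

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`/`SeedSequence`; fixed seeds give
  bit-identical studies, training reports and search results.
- f2 identity (f2(A, A) = 100) and symmetry are exact in floating
  point; the oracle-agreement tests require 1e−9.
- The noiseless generator matches the Weibull closed form to 1e−12;
  the analytic Jacobian matches central finite differences to 1e−4
  relative.
- Known limitations: one hidden layer only (no depth search), grid
  rather than gradient/evolutionary search over the surrogate, no
  bootstrap confidence intervals on f2, no difference factor f1, and no
  claim of agreement with unpublished laboratory profiles.
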