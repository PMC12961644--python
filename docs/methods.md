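# Methods

## Problem setting

A stimulus encoder for a visual prosthesis maps a grayscale camera image
`x` to per-electrode stimulation parameters `y = {f_i, p_i, a_i}` —
pulse frequency (Hz), pulse duration (ms) and amplitude (µA) of a
charge-balanced biphasic pulse train on each electrode `i` of an
implanted array.  Delivered stimulation must respect biophysical limits;
this package treats those limits as formal inequality constraints
`V_k(y) ≤ 0` on encoder outputs and searches, by coverage-guided fuzzing
(CGF), for inputs whose outputs violate them.

## Safety constraints

Four constraints are implemented, each with a signed value `V` (positive
= violation) and a dimensionless violation proportion `α/c` (quantity
over limit; > 1 = violation):

| id | scope | value | proportion |
|----|-------|-------|------------|
| PI | per electrode | `2·p_i − 1000/f_i` (ms) | `2·p_i·f_i / 1000` |
| CD | per electrode | `p_i·a_i − ε1` (nC) | `p_i·a_i / ε1` |
| IC | aggregate | `Σ a_i − ε2` (µA) | `Σ a_i / ε2` |
| AE | aggregate | `Σ [a_i>0] − ε3` | `count / ε3` |

Units are normalized internally to Hz / ms / µA / nC, which makes the
charge product exact (µA·ms = nC).  Two device presets are provided:
epiretinal (ε1 = 628 nC, ε2 = 6000 µA, ε3 = 100) and intracortical Utah
array (ε1 = 20.4 nC, ε2 = 3600 µA, ε3 = 30).

Numerical conventions:

* An electrode is *active* iff `a_i > 0` strictly.  Electrodes with zero
  amplitude, and electrodes with `f_i = 0` (no pulse train exists),
  are excluded from the PI check and reported safe with proportion 0.
* The PI constraint has no canonical `α/c` form; we rewrite
  `V_PI = α − c` with `α = 2p` and `c = 1000/f`, giving the proportion
  `2pf/1000`.  This choice is ours; it preserves the sign equivalence
  `V > 0 ⇔ α/c > 1` needed by the proportion-binned coverage metric and
  the violation degree.
* Violation degree is `max(0, α/c − 1)`: zero for safe electrodes,
  continuous at the boundary, linear above it.
* Severity strata: proportion in (1, 1.05] is *marginal*, (1.05, 1.30]
  *moderate*, above 1.30 *catastrophic* (5% and 30% over the limit).
  Class intervals are closed on their upper end so ties break
  deterministically.

## Fuzzing loop

The fuzzer starts from a seed corpus `S`.  Each iteration selects one
seed, generates `m = 10` mutants from it, runs each through the encoder,
and applies two *independent* checks: a mutant is recorded as a
violation iff any constraint fires, and admitted to `S` iff it strictly
increases coverage.  A violating mutant that adds no coverage is
recorded but not admitted; an admitted safe mutant enters the corpus
with selection count 0.  Testing stops when the budget (counted in
encoder invocations, seeds included) is exhausted.

Seed selection is probabilistic with weight `max(1 − g/γ, p_min)` for a
seed selected `g` times before (defaults γ = 20, p_min = 0.05, both
configurable): fresh seeds are preferred, no seed is starved.  Weights
are renormalized at each draw.

Mutation applies exactly one transform per call, chosen uniformly from:
translation (±10% of side), rotation (±15°), scale ([0.85, 1.15]), shear
(±10°), brightness (±0.2), contrast (gain [0.7, 1.3] about mid-gray),
Gaussian blur (σ ∈ [0.5, 2] px), additive Gaussian noise (σ ∈ [0.01,
0.05]), and sparse pixel perturbation (≤ 5% of pixels, sup-norm ≤ 0.05).
Geometric transforms fill exposed borders with black; all outputs are
clamped to [0, 1] and keep the input dimensions.  Compounded distortion
arises only through lineage, when an admitted mutant is later selected
as a seed — this chaining is what lets a coverage-guided run drift far
from the seed distribution while single-step baselines cannot.

Equal-budget comparison between metrics of different computational cost
uses a deterministic per-test `cost_weight`: the effective budget is
`floor(test_limit / cost_weight)`, with a calibration utility measuring
the weight from warm-up tests.  We deliberately do not budget by live
wall-clock time, which is irreproducible; the cost-ratio scaling
preserves the fairness argument as a fixed, loggable number.

## Coverage metrics

All metrics share one incremental interface: a state holds a set of
covered *cells* out of a fixed total, `Cov = covered/total ∈ [0, 1]`,
monotone, order-free in its final value.  Admission queries are
two-phase (peek, then commit) so a rejected candidate never corrupts
state.  Binning is half-open `[lo_k, lo_{k+1})` with the top bin closed;
values outside `[lo, hi)` clamp to the outermost bins.

* **VO-KMVP** bins each constraint's violation proportion into K bins;
  total = `K·|V_A| + K·|V_E|·|I|` over aggregate and electrode-wise
  constraint streams.  Default support [0, 2] with K = 50: proportions
  up to twice the limit span the severity strata of interest.  The
  support and K are our defaults (exposed in config), not reproductions
  of any reference configuration.
* **VO-KMOC** bins every output dimension over ranges profiled on a
  preprocessing dataset (K = 50 default).
* **VO-KMVP-V** is VO-KMVP restricted to the violating region
  (support [1, hi]); safe proportions contribute nothing.
* **VO-VCC** tracks which of the four constraint *types* have been
  violated at least once.
* **I-KMIC** bins each pixel over [0, 1] (K = 10 default).
* **I-Div-approx** bins a projected feature space of the input.  The
  default projector is a fixed seeded random linear map to 32 features —
  deterministic and download-free; any feature extractor (e.g. an
  autoencoder) can be plugged in.
* **Neuron-coverage baselines** (white-box, require activation access):
  N-NC (threshold 0.75 on per-layer min-max-scaled activations), N-KMNC
  (K = 1000 bins per neuron inside the profiled range; out-of-range
  activations belong to the boundary metrics, not KMNC), N-NBC
  (below-low/above-high corners), N-SNAC (above-high only), N-TKNC
  (top-K per layer, K = 1).
* **Basic strategies**: B-N never admits, B-A admits everything, B-FR
  generates fully random images with no corpus, B-Local repeatedly
  perturbs the seed with the most attributed violations.

## Diversity of discovered violations

Geometric diversity is `GD = det(A Aᵀ)` for the matrix `A` of stacked
input-feature rows.  The default feature extractor is deterministic and
dependency-free (14×14 downsampled pixels + 16-bin intensity histogram,
212 dimensions — chosen to exceed the 200-row diversity subsets, since
the Gram determinant is identically zero once rows outnumber feature
dimensions);
rows are L2-normalized before the determinant, which is computed via a
log-determinant factorization and reported as 0 for rank-deficient Gram
matrices.  On the raw scale the determinant of ~200 unit rows underflows
for *any* input set (even maximally diverse random images sit near
log-det ≈ −770), so the reported and score-compared statistic is the
log-determinant; the raw value is kept alongside it.  Min-max
normalization of the score channel is affine, so using the log scale
changes only the geometry of the comparison, not its ordering within a
strategy set.  A pretrained-CNN extractor is a pluggable hook, off by
default to keep the package free of downloads; GD magnitudes are
therefore not comparable across extractors, only across strategies under
one extractor.

Violation-space diversity stacks, per violating test, the concatenated
per-electrode vector `[degree_PI, degree_CD, a_i/amp_max]` (amplitudes
normalized by `amp_max`, default ε2, since no single electrode can
safely exceed the whole-array current ceiling) and reports the Euclidean
norm of the per-column population standard deviations over all `3·|I|`
columns.  Both measures are computed on five random subsets of 200
violations and averaged; with fewer violations all are used once, and
zero violations define the result as (0, 0) with a warning.

Strategy comparison min-max normalizes violation counts and the two
diversity channels to [0, 1] across strategies, averages GD and STD
(equal weight, configurable) into a combined diversity score, and
averages that with normalized violations.  A channel with no spread
contributes 0 for every strategy; scoring against a frozen baseline can
legitimately exceed 1.

## Synthetic testbed

The encoders under test are analytic functions of 2×2 (retinal) or 4×4
(cortical) image-patch statistics, not trained networks, so their unsafe
regions are provable:

* retinal (15×15 array, 30×30 images): per patch with mean µ, std σ and
  edge energy e (mean |∂x| + mean |∂y|), `a = 100µ`, `f = 20 + 200σ`,
  `p = 0.45 + 40e`.  Certificates: the all-zero image is fully safe; the
  all-white image drives Σa = 22 500 µA over ε2; a period-2 grating
  yields f = 120 Hz and p = 40.45 ms, so 2pf/1000 ≈ 9.7 (physically
  impossible) and p·a ≈ 2022 nC over ε1; dense images co-activate all
  225 electrodes, over ε3.
* cortical (96-channel array, 60 mapped, 40×24 images): amplitudes only
  (`a = 110µ` on mapped channels), fixed feasible pulse shape
  (f = 300 Hz, p = 0.17 ms, so PI can never fire and p·a ≤ 18.7 nC
  stays under ε1); bright dense images exceed both ε3 (60 > 30 active)
  and ε2 (6600 > 3600 µA).

The gains were chosen by a reachability analysis, not only by the
certificates: the charge-violation region must be attainable through
chains of admitted mutations (it requires jointly bright and
high-edge-energy patches), while the six default seed images (blank,
dim, low-contrast grating/blobs/noise/checker) sit far enough inside the
safe region of PI/CD/IC that a *single* mutation step cannot cross the
pulse-timing boundary.  This separation is what makes discovery a real
test of coverage-gated exploration rather than of the mutation operators
alone.  Dense seeds do trip the co-activation limit (225 active > 100) —
retained deliberately, mirroring how deployed encoders violate aggregate
limits under ordinary inputs.

What the testbed does *not* emulate: trained-network input-output
geometry (real encoders are approximately safe on their training
distribution by optimization, not by construction), phosphene forward
models and perceptual losses, electrode-specific thresholds, and
hardware clipping.  One visible consequence: fully random images are
strongly violating for the analytic toys, so the B-FR baseline is far
stronger here than it would be against a trained encoder.  Passing tests
demonstrate the correctness of the fuzzing machinery and the *relative*
behavior of strategies on provable ground truth — not violation rates of
any real device.

A small fixed-weight NumPy MLP (two ReLU hidden layers, sigmoid-squashed
outputs scaled into valid ranges) provides the white-box target for the
neuron-coverage baselines; it exposes per-layer activations and is a
pure function of (image, weight seed).

## Problem sizes and determinism

Default experiment sizes are 30×30 images, 225 electrodes, budgets of
2000 tests for discovery comparisons and 200 random tests for
coverage-equivalence checks; the scheduler statistics use 10^5 draws
checked at 3σ.  All randomness flows from one seeded NumPy generator per
run; runs serialize their resolved configuration, and identical
(config, seed) pairs reproduce violations and coverage traces
byte-identically.  Violation records keep every violating input;
distinct-cell counts (constraint × electrode) are derived at reporting
time.

## Known limitations

* Stimulation is evaluated per output vector; sequential (time-varying)
  stimulation and violations arising across a sequence are out of scope.
* The degree/amplitude normalization in violation space and the PI
  proportion are package conventions (documented above), not physical
  standards.
* Coverage metric hyperparameters (K values, bin supports) are exposed
  defaults; their tuning trades off admission selectivity (too coarse
  behaves like never-admit, too fine like always-admit).
* The white-box metrics require an encoder that exposes activations;
  they are unavailable (with a clear error) for black-box encoders.
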