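# stimfuzz

Coverage-guided fuzzing for the safety of machine-learning stimulus
encoders in neurostimulation devices.

Visual prostheses (and other neural interfaces) increasingly use learned
encoders that map camera images directly to per-electrode electrical
stimulation.  Such an encoder can be perceptually excellent and still,
under an unlucky input, prescribe stimulation that exceeds biophysical
safety limits — delivering too much charge to one electrode, too much
total current, pulses that cannot physically fit in their own period, or
co-activating too many channels at once.  `stimfuzz` is a stress-testing
tool for engineers and researchers who need to *measure* that risk for a
trained (black-box) encoder, rather than trust its training objective.

## What it does

An encoder `M` maps an image `x` to stimulation parameters
`y = {f_i, p_i, a_i}` (pulse frequency in Hz, pulse duration in ms,
amplitude in µA on each electrode `i`).  Safety is a set of inequality
constraints `V_k(y) ≤ 0`:

```
V_PI = 2·p_i − 1000/f_i        (physically impossible pulse, per electrode)
V_CD = p_i·a_i − ε1            (charge per electrode, nC)
V_IC = Σ_i a_i − ε2            (instantaneous current, µA)
V_AE = Σ_i [a_i > 0] − ε3      (simultaneously active electrodes)
```

The fuzzer mutates seed images, runs each mutant through the encoder,
records every input whose output violates any constraint, and keeps a
mutant as a new seed only if it increases a *coverage* measure.  The two
core coverage metrics operate directly on outputs: one bins the
violation proportion `α/c` of every constraint (driving tests toward
and beyond the safety boundary), the other bins every output dimension
over profiled ranges (driving breadth of explored stimulation patterns).
Baseline strategies (no admission, admit-everything, fully random
inputs, local perturbation) and the classical white-box neuron-coverage
metrics are implemented behind the same interface for equal-budget
comparison.  Discovered violations are summarized by count, severity
stratum (marginal / moderate / catastrophic: 5% and 30% over the limit),
and two diversity measures — the Gram-determinant geometric diversity of
input features and the per-electrode violation-space spread.

Because the encoders a clinic would test are proprietary, the package
ships a synthetic testbed: analytic toy encoders for a 15×15 retinal
array (three parameters per electrode) and a 60-of-96 cortical array
(amplitudes only) whose unsafe regions are provable in closed form, plus
parametric image generators.  Everything runs deterministically from a
seed, with no downloads and no GPU.

## Worked example

```python
import numpy as np
from stimfuzz import (FuzzConfig, fuzz, SeedSet, RETINAL_LIMITS,
                      ToyRetinalEncoder, default_seed_images)
from stimfuzz.diversity import subsampled_diversity

encoder = ToyRetinalEncoder()
seeds = SeedSet()
for img in default_seed_images(30, 30):
    seeds.add_image(img)

config = FuzzConfig(test_limit=2000, metric_id="VO-KMVP",
                    limits=RETINAL_LIMITS, rng_seed=1)
result = fuzz(seeds, config, encoder)

types = sorted({c.value for v in result.violations
                for c in v.record.constraints_violated})
div = subsampled_diversity(result.violations, 225,
                           amp_max=RETINAL_LIMITS.eps2_current,
                           rng=np.random.default_rng(1))
print(f"tests executed:       {result.tests_executed}")
print(f"violations found:     {len(result.violations)}")
print(f"violation types:      {types}")
print(f"distinct cells:       {len(result.distinct_cells())}")
print(f"final coverage:       {result.coverage_trace[-1]:.3f}")
print(f"violation-space STD:  {div.std_mean:.3f}")
```

prints

```
tests executed:       2006
violations found:     1915
violation types:      ['AE', 'CD', 'IC', 'PI']
distinct cells:       190
final coverage:       0.403
violation-space STD:  0.450
```

Reading this: starting from six mild seed images, 2006 encoder
invocations produced 1915 violating inputs covering all four constraint
types, spread over 190 distinct (constraint, electrode) cells of the
15×15 array; the proportion-binning coverage metric had filled 40% of
its bins.  The same run with the no-admission baseline (`metric_id=
"B-N"`) finds far fewer distinct cells and typically misses the
charge-limit violations entirely — the coverage gate is what lets
mutation chains drift into the narrow unsafe regions.

## Command line

```
stimfuzz fuzz     --config run.yaml --out results/         # one campaign
stimfuzz compare  --config cmp.yaml --out results/         # ≥2 strategies, equal budget
stimfuzz audit    --log stim_log.csv --limits CORTICAL     # check recorded outputs
stimfuzz calibrate --metric VO-KMVP                        # per-test cost weight
stimfuzz gen-images --kind grating --out seeds/            # synthetic seed PNGs
```

A run directory contains `violations.jsonl`, `coverage_trace.csv`, a
seeds manifest and the fully resolved `run_config.yaml`; identical
configs and seeds reproduce these files byte-identically.

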