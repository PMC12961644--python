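"""Coverage-guided fuzzing loop and equal-budget strategy runners.

The main loop selects a seed, generates ``m`` mutants from it, runs each
through the encoder, checks the four safety constraints, records every
violating input, and admits a mutant into the seed corpus only when it
strictly increases coverage.  The coverage check and the violation check
are independent: a violating mutant that adds no coverage is recorded but
not admitted, and a coverage-increasing safe mutant is admitted without
being recorded.

Budgets are counted in encoder invocations.  Wall-clock fairness between
metrics of different computational cost is approximated deterministically
through a per-test ``cost_weight``: the effective budget is
``floor(test_limit / cost_weight)``, with an optional calibration utility
measuring the weight from warm-up tests.
"""

from __future__ import annotations

import io
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .constraints import (
    SafetyLimits,
    StimulationVector,
    ViolationRecord,
    evaluate_all,
    write_violations_jsonl,
)
from .coverage import (
    RANGE_BASED_METRICS,
    WHITE_BOX_METRICS,
    BinningSpec,
    CoverageState,
    ProfiledRanges,
    RandomProjector,
    TestObservation,
    make_metric,
    preprocess_ranges,
)
from .mutation import (
    ImageInput,
    MutationRanges,
    SchedulerParams,
    SeedEntry,
    SeedSet,
    choose_seed,
    local_perturb,
    mutate,
    random_image,
)

__all__ = [
    "FuzzConfig",
    "FoundViolation",
    "FuzzResult",
    "fuzz",
    "test_mutants",
    "effective_budget",
    "run_conventional",
    "run_b_local",
    "calibrate_cost_weight",
]


@dataclass
class FuzzConfig:
    """Resolved configuration of one fuzzing run."""

    test_limit: int = 1000
    m: int = 10  # mutants per iteration
    metric_id: str = "VO-KMVP"
    limits: SafetyLimits = None  # type: ignore[assignment]
    rng_seed: int = 0
    scheduler: SchedulerParams = field(default_factory=SchedulerParams)
    binning: BinningSpec = field(default_factory=lambda: BinningSpec(K=50, range_lo=0.0, range_hi=2.0))
    mutation_ranges: MutationRanges = field(default_factory=MutationRanges)
    cost_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.limits is None:
            raise ValueError("FuzzConfig requires safety limits")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.test_limit < 0:
            raise ValueError("test_limit must be >= 0")

    def to_dict(self) -> dict:
        return {
            "test_limit": self.test_limit,
            "m": self.m,
            "metric_id": self.metric_id,
            "limits": {
                "eps1_charge": self.limits.eps1_charge,
                "eps2_current": self.limits.eps2_current,
                "eps3_active": self.limits.eps3_active,
            },
            "rng_seed": self.rng_seed,
            "scheduler": {
                "gamma": self.scheduler.gamma,
                "p_min": self.scheduler.p_min,
            },
            "binning": {
                "K": self.binning.K,
                "range_lo": self.binning.range_lo,
                "range_hi": self.binning.range_hi,
            },
            "cost_weight": self.cost_weight,
        }


@dataclass
class FoundViolation:
    """A recorded violation together with its triggering input/output."""

    record: ViolationRecord
    image: ImageInput
    stim: StimulationVector


@dataclass
class FuzzResult:
    """Outcome of a run: violations, final corpus, coverage trace."""

    violations: list[FoundViolation]
    final_seed_set: SeedSet
    coverage_trace: list[float]
    tests_executed: int
    config: Optional[FuzzConfig] = None
    strategy: str = ""

    @property
    def violation_records(self) -> list[ViolationRecord]:
        return [v.record for v in self.violations]

    def distinct_cells(self) -> set:
        """Distinct (constraint, electrode) cells among the violations —
        aggregate constraints use electrode = None."""
        cells = set()
        for v in self.violations:
            for r in v.record.results:
                cells.add((r.constraint_id.value, r.electrode_index))
        return cells

    def violations_jsonl(self) -> str:
        buf = io.StringIO()
        write_violations_jsonl(self.violation_records, buf)
        return buf.getvalue()

    def coverage_trace_csv(self) -> str:
        lines = ["test_index,coverage"]
        for i, c in enumerate(self.coverage_trace):
            lines.append(f"{i},{c!r}")
        return "\n".join(lines) + "\n"

    def save(self, out_dir: str | Path) -> None:
        """Write violations.jsonl, coverage_trace.csv, seeds_manifest.json
        and run_config.yaml to a results directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "violations.jsonl").write_text(self.violations_jsonl())
        (out / "coverage_trace.csv").write_text(self.coverage_trace_csv())
        manifest = {
            "strategy": self.strategy,
            "tests_executed": self.tests_executed,
            "n_violations": len(self.violations),
            "seed_ids": self.final_seed_set.ids,
        }
        (out / "seeds_manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=2) + "\n"
        )
        if self.config is not None:
            (out / "run_config.yaml").write_text(
                yaml.safe_dump(self.config.to_dict(), sort_keys=True)
            )


def effective_budget(test_limit: int, cost_weight: float = 1.0) -> int:
    """Tests actually granted to a strategy of per-test cost
    ``cost_weight`` relative to the baseline: floor(limit / weight)."""
    if cost_weight <= 0:
        raise ValueError("cost_weight must be positive")
    return int(test_limit / cost_weight)


def calibrate_cost_weight(
    encoder,
    metric: CoverageState,
    limits: SafetyLimits,
    images: Sequence[ImageInput],
    baseline_cost: Optional[float] = None,
    n_warmup: int = 100,
) -> float:
    """Measure the mean per-test cost (encode + constraint check + coverage
    update) over warm-up tests; returns cost / baseline_cost, or the raw
    cost in seconds when no baseline is given."""
    if not images:
        raise ValueError("calibration needs warm-up images")
    start = time.perf_counter()
    for i in range(n_warmup):
        img = images[i % len(images)]
        obs = _observe(img, encoder, limits)
        metric.peek(obs)
    cost = (time.perf_counter() - start) / n_warmup
    if baseline_cost is None:
        return cost
    if baseline_cost <= 0:
        raise ValueError("baseline_cost must be positive")
    return cost / baseline_cost


def _observe(image: ImageInput, encoder, limits: SafetyLimits) -> TestObservation:
    if hasattr(encoder, "encode_with_activations"):
        stim, acts = encoder.encode_with_activations(image)
    else:
        stim, acts = encoder.encode(image), None
    return TestObservation.from_test(image, stim, limits, activations=acts)


class _Run:
    """Per-run mutable state shared by the loop helpers."""

    def __init__(self, config: FuzzConfig, metric: CoverageState, encoder) -> None:
        self.config = config
        self.metric = metric
        self.encoder = encoder
        self.rng = np.random.default_rng(config.rng_seed)
        self.violations: list[FoundViolation] = []
        self.trace: list[float] = []
        self.tests = 0
        self._id_counter = 0

    def next_id(self, prefix: str) -> str:
        self._id_counter += 1
        return f"{prefix}-{self._id_counter:06d}"

    def execute(self, image: ImageInput, seed_entry: Optional[SeedEntry] = None
                ) -> TestObservation:
        """Run one test: encode, check constraints, record violations,
        append the coverage trace.  Does NOT touch coverage state."""
        obs = _observe(image, self.encoder, self.config.limits)
        _, record = evaluate_all(obs.stim, self.config.limits, input_id=image.input_id)
        if record is not None:
            self.violations.append(FoundViolation(record, image, obs.stim))
            if seed_entry is not None:
                seed_entry.violations_spawned += 1
        self.tests += 1
        return obs


def _build_metric(
    config: FuzzConfig,
    encoder,
    profiling_inputs: Optional[Sequence[ImageInput]],
    image_shape: tuple[int, int],
) -> CoverageState:
    metric_id = config.metric_id
    white_box = hasattr(encoder, "encode_with_activations")
    if metric_id in WHITE_BOX_METRICS and not white_box:
        raise ValueError(
            f"{metric_id} needs a white-box encoder exposing activations"
        )
    ranges: Optional[ProfiledRanges] = None
    projector = None
    if metric_id == "I-Div-approx":
        projector = RandomProjector(image_shape)
    if metric_id in RANGE_BASED_METRICS:
        if not profiling_inputs:
            raise ValueError(f"{metric_id} requires profiling inputs")
        ranges = preprocess_ranges(profiling_inputs, encoder, projector=projector)
    layer_sizes = getattr(encoder, "layer_sizes", None)
    n_electrodes = encoder.array_spec.n_electrodes
    return make_metric(
        metric_id,
        n_electrodes=n_electrodes,
        image_shape=image_shape,
        binning=config.binning,
        ranges=ranges,
        layer_sizes=layer_sizes,
        projector=projector,
    )


def test_mutants(
    seeds: SeedSet,
    run: _Run,
) -> None:
    """One iteration: choose a seed, generate and test m mutants; each
    mutant is admitted iff it strictly increases coverage and recorded iff
    it violates (independent checks)."""
    config = run.config
    entry = choose_seed(seeds, config.scheduler, run.rng)
    for _ in range(config.m):
        mutant = mutate(
            entry.image, run.rng, config.mutation_ranges,
            input_id=run.next_id("mut"),
        )
        obs = run.execute(mutant, seed_entry=entry)
        new_cells = run.metric.peek(obs)
        if new_cells:
            run.metric.commit(new_cells)
            seeds.add(SeedEntry(image=mutant))
        run.trace.append(run.metric.coverage)


def fuzz(
    seeds: Optional[SeedSet],
    config: FuzzConfig,
    encoder,
    profiling_inputs: Optional[Sequence[ImageInput]] = None,
    metric: Optional[CoverageState] = None,
) -> FuzzResult:
    """Run the coverage-guided fuzzing loop.

    Seeds are evaluated first (they count against the budget and their
    violations are recorded), then mutation iterations of ``m`` mutants
    run until the effective budget is exhausted.  The ``B-FR`` strategy
    needs no seeds and generates fully random images; ``B-Local``
    dispatches to :func:`run_b_local`.  A pre-built ``metric`` (any
    :class:`CoverageState`) may be injected, bypassing construction from
    ``config.metric_id``.
    """
    if config.metric_id == "B-Local":
        if seeds is None or len(seeds) == 0:
            raise ValueError("B-Local requires seeds")
        return run_b_local(seeds, config, encoder)

    image_shape = getattr(encoder, "image_shape", None)
    if image_shape is None:
        if seeds is None or len(seeds) == 0:
            raise ValueError("cannot infer image shape without seeds")
        image_shape = seeds[0].image.shape

    if metric is None:
        metric = _build_metric(config, encoder, profiling_inputs, image_shape)
    run = _Run(config, metric, encoder)
    budget = effective_budget(config.test_limit, config.cost_weight)

    if config.metric_id == "B-FR":
        corpus = SeedSet()
        while run.tests < budget:
            img = random_image(*image_shape, run.rng, input_id=run.next_id("rand"))
            obs = run.execute(img)
            metric.observe(obs)
            run.trace.append(metric.coverage)
        return FuzzResult(
            violations=run.violations,
            final_seed_set=corpus,
            coverage_trace=run.trace,
            tests_executed=run.tests,
            config=config,
            strategy=config.metric_id,
        )

    if seeds is None or len(seeds) == 0:
        raise ValueError(f"{config.metric_id} requires a non-empty seed set")
    if config.test_limit < len(seeds):
        raise ValueError("test_limit must cover at least the initial seeds")

    # initial pass: coverage of the seed corpus, seed violations recorded
    for entry in seeds:
        obs = run.execute(entry.image)
        metric.observe(obs)
        run.trace.append(metric.coverage)

    while run.tests < budget:
        test_mutants(seeds, run)

    return FuzzResult(
        violations=run.violations,
        final_seed_set=seeds,
        coverage_trace=run.trace,
        tests_executed=run.tests,
        config=config,
        strategy=config.metric_id,
    )


def run_conventional(
    test_set: Sequence[ImageInput],
    encoder,
    limits: SafetyLimits,
) -> FuzzResult:
    """Conventional testing: evaluate a fixed test set once, no mutation,
    no seed admission; same logs so diversity/reporting apply uniformly."""
    violations: list[FoundViolation] = []
    trace: list[float] = []
    for img in test_set:
        stim = (
            encoder.encode_with_activations(img)[0]
            if hasattr(encoder, "encode_with_activations")
            else encoder.encode(img)
        )
        _, record = evaluate_all(stim, limits, input_id=img.input_id)
        if record is not None:
            violations.append(FoundViolation(record, img, stim))
        trace.append(0.0)
    return FuzzResult(
        violations=violations,
        final_seed_set=SeedSet(),
        coverage_trace=trace,
        tests_executed=len(test_set),
        strategy="conventional",
    )


def run_b_local(
    seeds: SeedSet,
    config: FuzzConfig,
    encoder,
) -> FuzzResult:
    """B-Local strategy: after an initial pass over the seeds, repeatedly
    apply bounded local perturbation to the seed that has spawned the most
    violations; no coverage gating, nothing admitted to the corpus."""
    run = _Run(config, make_metric("B-Local", n_electrodes=encoder.array_spec.n_electrodes, image_shape=(1, 1)), encoder)
    budget = effective_budget(config.test_limit, config.cost_weight)

    entries = list(seeds)
    for entry in entries:
        if run.tests >= budget:
            break
        run.execute(entry.image, seed_entry=entry)
        run.trace.append(0.0)

    while run.tests < budget:
        best = max(entries, key=lambda e: e.violations_spawned)
        mutant = local_perturb(
            best.image, run.rng,
            amplitude=config.mutation_ranges.perturb_amplitude,
            fraction=config.mutation_ranges.perturb_fraction,
            input_id=run.next_id("local"),
        )
        run.execute(mutant, seed_entry=best)
        run.trace.append(0.0)

    return FuzzResult(
        violations=run.violations,
        final_seed_set=seeds,
        coverage_trace=run.trace,
        tests_executed=run.tests,
        config=config,
        strategy="B-Local",
    )
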